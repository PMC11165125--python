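"""Tabular formats and panel configuration.

Plain CSV/TSV and JSON only: genotypes at a locus are per-locus dosage
multisets, not sequences, so no sequence-oriented format applies, and the
instruments' raw chip files are out of scope.  Schemas:

* **plate CSV** — ``sample_id, locus_id, conc_A, conc_B, conc_C,
  conc_ctrl, dna_conc`` with optional ``pos_A, pos_B, pos_C, pos_ctrl,
  n_partitions, partition_vol`` columns carrying raw partition counts.
* **genotype table TSV/CSV** — ``line_id, locus_id, genotype``.
* **panel JSON** — ``{"defaults": {...}, "loci": [{"locus_id": ...,
  "composite_A": ...}, ...]}``.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import pandas as pd

from .calling import DqPCRMeasurement, LocusPanel, PartitionCounts
from .genotype import GenotypeError, HomoeologGenotype, parse_genotype

__all__ = [
    "read_plate_csv",
    "read_genotype_table",
    "write_genotype_table",
    "read_panel_json",
    "SchemaError",
]

PLATE_REQUIRED = ["sample_id", "locus_id", "conc_A", "conc_B", "conc_C",
                  "conc_ctrl", "dna_conc"]
PLATE_PARTITION = ["pos_A", "pos_B", "pos_C", "pos_ctrl",
                   "n_partitions", "partition_vol"]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def read_plate_csv(path) -> list[DqPCRMeasurement]:
    """Read dqPCR measurements; partition columns are used when present."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in PLATE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    has_parts = all(c in df.columns for c in PLATE_PARTITION)
    out = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            parts = None
            if has_parts and not pd.isna(row["pos_A"]):
                parts = PartitionCounts(
                    int(row["pos_A"]), int(row["pos_B"]), int(row["pos_C"]),
                    int(row["pos_ctrl"]), int(row["n_partitions"]),
                    float(row["partition_vol"]),
                )
            out.append(DqPCRMeasurement(
                locus_id=str(row["locus_id"]),
                sample_id=str(row["sample_id"]),
                conc_A=float(row["conc_A"]), conc_B=float(row["conc_B"]),
                conc_C=float(row["conc_C"]), conc_ctrl=float(row["conc_ctrl"]),
                dna_conc=float(row["dna_conc"]), partitions=parts,
            ))
        except (ValueError, TypeError) as e:
            raise SchemaError(f"{path}:{line_no}: {e}") from e
    return out


def read_genotype_table(path) -> pd.DataFrame:
    """Read a lines × loci genotype table (long format).

    Returns a DataFrame with columns ``line_id, locus_id, genotype``
    (strings) and ``parsed`` (:class:`HomoeologGenotype`); duplicate
    (line, locus) pairs and malformed genotype strings are errors.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    needed = ["line_id", "locus_id", "genotype"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    dup = df.duplicated(subset=["line_id", "locus_id"])
    if dup.any():
        first = df[dup].iloc[0]
        raise SchemaError(
            f"{path}: duplicate entry for line {first['line_id']!r} "
            f"locus {first['locus_id']!r}"
        )
    parsed = []
    for i, s in enumerate(df["genotype"]):
        try:
            parsed.append(parse_genotype(str(s)))
        except GenotypeError as e:
            raise SchemaError(f"{path}:{i + 2}: bad genotype {s!r}: {e}") from e
    df = df.copy()
    df["parsed"] = parsed
    df["has_x"] = [g.has_x() for g in parsed]
    return df


def write_genotype_table(df: pd.DataFrame, path, header_comment: str = "") -> None:
    path = Path(path)
    cols = [c for c in df.columns if c not in ("parsed",)]
    with path.open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df[cols].to_csv(fh, sep="\t", index=False)


def read_panel_json(path) -> dict[str, LocusPanel]:
    """Read a panel configuration into per-locus :class:`LocusPanel`."""
    cfg = json.loads(Path(path).read_text())
    defaults = cfg.get("defaults", {})
    panels: dict[str, LocusPanel] = {}
    for entry in cfg.get("loci", []):
        merged = {**defaults, **entry}
        lid = merged.get("locus_id")
        if not lid:
            raise SchemaError(f"{path}: panel entry missing locus_id: {entry}")
        if lid in panels:
            raise SchemaError(f"{path}: duplicate locus_id {lid!r}")
        panels[lid] = LocusPanel(
            locus_id=lid,
            composite_A=bool(merged.get("composite_A", False)),
            p_min=float(merged.get("p_min", 0.80)),
            slope_tol=float(merged.get("slope_tol", 0.06)),
            t_max=int(merged.get("t_max", 12)),
            n_eff=int(merged.get("n_eff", 1000)),
        )
    return panels


def log(msg: str) -> None:
    print(msg, file=sys.stderr)
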