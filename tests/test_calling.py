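"""dqPCR ratio fitting, slope resolution and genotype calling."""

import math

import numpy as np
import pytest

from hexaseg import (
    DqPCRMeasurement,
    HomoeologGenotype,
    LocusPanel,
    call_genotype,
    fit_ratio,
    joint_call_sample,
    partitions_to_concentration,
    per_copy_slope,
    resolve_total_copies,
)
from hexaseg.calling import SaturationError
from hexaseg.simulate import simulate_dqpcr

PANEL = LocusPanel()
S_TRUE = 0.35  # per-genome single-copy slope used by the simulator default


class TestPartitionsToConcentration:
    def test_no_positives(self):
        assert partitions_to_concentration(0, 26000, 0.00034) == 0.0

    def test_half_positive_closed_form(self):
        v = 0.00034
        assert partitions_to_concentration(13000, 26000, v) == pytest.approx(
            math.log(2) / v
        )

    def test_ten_percent_analytic(self):
        # -ln(0.9)/0.001
        assert partitions_to_concentration(2600, 26000, 0.001) == pytest.approx(
            105.3605, abs=1e-3
        )

    def test_saturation_and_range_errors(self):
        with pytest.raises(SaturationError):
            partitions_to_concentration(26000, 26000, 0.001)
        with pytest.raises(ValueError):
            partitions_to_concentration(26001, 26000, 0.001)


class TestFitRatio:
    @pytest.mark.parametrize(
        "concs, expected",
        [((2.0, 3.0, 1.0), (2, 3, 1)), ((4.0, 0.0, 1.0), (4, 0, 1)),
         ((1.0, 1.0, 1.0), (1, 1, 1)), ((5.0, 5.0, 5.0), (1, 1, 1))],
    )
    def test_exact_proportions(self, concs, expected):
        ranked = fit_ratio(*concs, PANEL)
        ratio, p = ranked[0]
        assert ratio == expected
        assert p > 0.999

    def test_composite_probe_space(self):
        # genotype AAABCC through a composite AB probe: signals (4, 1, 2)
        ranked = fit_ratio(4.0, 1.0, 2.0, PANEL, composite=True)
        assert ranked[0][0] == (3, 1, 2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_ratio(0.0, 0.0, 0.0, PANEL)


class TestSlopes:
    def test_per_copy_slope_printed_example(self):
        # control concentration whose 5-copy slope is 0.431 gives 0.359 at 6
        conc = 0.431 * 5 * 10.0
        assert per_copy_slope(conc, 6, 10.0) == pytest.approx(0.359, abs=5e-4)

    def test_scaling_identity(self):
        assert per_copy_slope(7.0, 1, 2.0) == 2 * per_copy_slope(7.0, 2, 2.0)

    def test_zero_copies(self):
        with pytest.raises(ZeroDivisionError):
            per_copy_slope(1.0, 0, 1.0)


class TestResolveTotalCopies:
    def test_null_signaled_worked_example(self):
        """5-copy control slope 0.431 vs S_ABC 0.349: 5 copies rejected
        (0.082 > 0.06), 6 accepted (discrepancy 0.01) -> one X copy."""
        dna = 10.0
        conc_ctrl = 0.431 * 5 * dna
        t, x, flags = resolve_total_copies(0.349, conc_ctrl, dna, 5, PANEL)
        assert (t, x) == (6, 1)
        assert not flags

    def test_exact_agreement(self):
        t, x, flags = resolve_total_copies(0.35, 0.35 * 6 * 2.0, 2.0, 6, PANEL)
        assert (t, x, flags) == (6, 0, set())

    def test_control_null_flag(self):
        # control one copy short of the discriminatory total
        t, x, flags = resolve_total_copies(0.35, 0.35 * 5 * 2.0, 2.0, 6, PANEL)
        assert t == 5 and x == 0
        assert "control_null" in flags

    def test_monotonic_in_control(self):
        dna = 2.0
        prev = 0
        for copies in range(4, 9):
            t, _, _ = resolve_total_copies(0.35, 0.35 * copies * dna, dna, 4, PANEL)
            assert t == copies > prev
            prev = t


def _measurement(genotype, dna=10.0, s=S_TRUE, composite=False, **kw):
    return simulate_dqpcr(genotype, dna, per_copy_slope_true=s,
                          composite_A=composite, **kw)


class TestCallGenotype:
    def test_composite_4_1_2_calls_AAABCC(self):
        m = _measurement("AAABCC", composite=True)
        c = call_genotype(m, LocusPanel(composite_A=True), reference_slope=S_TRUE)
        assert str(c.genotype) == "AAABCC"
        assert c.ratio == (3, 1, 2)

    def test_2_3_1_calls_AABBBC(self):
        c = call_genotype(_measurement("AABBBC"), PANEL, reference_slope=S_TRUE)
        assert str(c.genotype) == "AABBBC"

    def test_null_signaled_X_from_control_excess(self):
        c = call_genotype(_measurement("AAAACX"), PANEL, reference_slope=S_TRUE)
        assert str(c.genotype) == "AAAACX"
        assert c.genotype.count_X == 1

    def test_worked_slope_numbers(self):
        """End-to-end check of the published assay numbers: a 4:0:1
        ratio with S_ABC 0.349 and a control 5-copy slope of 0.431 must
        come out as AAAACX with S_Ctrl recomputed to ~0.359."""
        dna = 10.0
        m = DqPCRMeasurement(
            locus_id="L", conc_A=4 * 0.349 * dna, conc_B=0.0,
            conc_C=1 * 0.349 * dna, conc_ctrl=0.431 * 5 * dna, dna_conc=dna,
        )
        c = call_genotype(m, PANEL)
        assert str(c.genotype) == "AAAACX"
        assert c.S_ABC == pytest.approx(0.349, abs=1e-6)
        assert c.S_Ctrl == pytest.approx(0.359, abs=1e-3)
        assert abs(c.S_Ctrl - c.S_ABC) <= PANEL.slope_tol

    def test_equal_proportions_flagged_without_reference(self):
        c = call_genotype(_measurement("AABBCC"), PANEL)
        assert "ambiguous_scale" in c.flags

    def test_noiseless_round_trip_all_genotypes(self):
        """Noiseless measurements recover every genotype with total <= 8
        and X <= 2 exactly, X included, given the assay slope."""
        failures = []
        for total in range(1, 9):
            for a in range(total + 1):
                for b in range(total + 1 - a):
                    for c_ in range(total + 1 - a - b):
                        x = total - a - b - c_
                        if x > 2 or (a + b + c_) == 0:
                            continue
                        g = HomoeologGenotype(a, b, c_, x)
                        m = _measurement(str(g))
                        call = call_genotype(m, PANEL, reference_slope=S_TRUE)
                        if call.genotype != g:
                            failures.append((str(g), str(call.genotype)))
        assert not failures

    def test_noisy_accuracy_hexaploid(self):
        """>= 99% correct calls at 26,000 partitions and dilution-tuned
        loads over 1,000 simulated hexaploid measurements."""
        rng = np.random.default_rng(20240901)
        genos = ["AABBCC", "AABBBC", "AAABCC", "ABBBCC",
                 "AAAABC", "AABBBB", "AAABBB", "AAAACX"]
        ok = 0
        for i in range(1000):
            g = genos[i % len(genos)]
            m = _measurement(g, dna=300.0, rng=rng)
            call = call_genotype(m, PANEL, reference_slope=S_TRUE)
            ok += str(call.genotype) == g
        assert ok / 1000 >= 0.99


class TestJointCalling:
    def test_consensus_resolves_equal_proportions(self):
        """A 1:1:1 locus on its own could be ABC or AABBCC; other loci on
        the same DNA pin the per-copy slope and force the right scale."""
        ms = [
            _measurement("AABBCC", locus_id="L1"),
            _measurement("AABBBC", locus_id="L2"),
            _measurement("AAABCC", locus_id="L3"),
        ]
        calls = joint_call_sample(ms, PANEL)
        assert [str(c.genotype) for c in calls] == ["AABBCC", "AABBBC", "AAABCC"]
        assert not any("ambiguous_scale" in c.flags for c in calls)

    def test_consensus_resolves_reducible_ratio(self):
        # BBBBCC reduces to 2:1 — indistinguishable from BBC alone
        ms = [
            _measurement("BBBBCC", locus_id="L1"),
            _measurement("AABBBC", locus_id="L2"),
        ]
        calls = joint_call_sample(ms, PANEL)
        assert str(calls[0].genotype) == "BBBBCC"

    def test_triploid_locus_against_consensus(self):
        ms = [
            _measurement("ABC", locus_id="L1"),
            _measurement("AABBBC", locus_id="L2"),
            _measurement("AAABCC", locus_id="L3"),
        ]
        calls = joint_call_sample(ms, PANEL)
        assert str(calls[0].genotype) == "ABC"

    def test_single_locus_keeps_ambiguity_flag(self):
        calls = joint_call_sample([_measurement("AABBCC")], PANEL)
        assert "ambiguous_scale" in calls[0].flags
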