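"""Accuracy summaries, metric tables, agreement limits, signed-rank test."""

import itertools

import numpy as np
import pytest

from beamdvh.dvh import DVHCurve
from beamdvh.eud import default_registry, eud
from beamdvh.evaluation import (
    eud_errors,
    limits_of_agreement,
    paired_signed_rank,
    plan_metric_table,
    summarize,
    summarize_by_organ,
)
from conftest import random_quantile_curve


class TestEudErrors:
    def test_identical_curves_zero_error(self, registry, rng):
        curves = {
            ("P1", "brainstem"): random_quantile_curve(rng, sid="brainstem"),
            ("P2", "larynx"): random_quantile_curve(rng, sid="larynx"),
        }
        errors = eud_errors(curves, dict(curves), registry)
        assert all(e == 0.0 for e in errors.values())

    def test_uniform_shift_at_k1(self, rng):
        """A +2 Gy shift shows as exactly +2 Gy signed error at k = 1."""
        from beamdvh.eud import KEntry, KRegistry

        reg = KRegistry(entries={"larynx": KEntry(k=1.0)})
        true = random_quantile_curve(rng, sid="larynx")
        pred = DVHCurve(structure_id="larynx", doses=true.doses + 2.0, dv=true.dv)
        errors = eud_errors({("P1", "larynx"): pred}, {("P1", "larynx"): true}, reg)
        assert errors[("P1", "larynx")] == pytest.approx(2.0, rel=1e-12)

    def test_composition_oracle(self, registry, rng):
        """Errors equal independently composed eud() differences."""
        pred, true = {}, {}
        for p in range(5):
            key = (f"P{p}", "parotid_l")
            pred[key] = random_quantile_curve(rng, sid="parotid_l")
            true[key] = random_quantile_curve(rng, sid="parotid_l")
        signed = eud_errors(pred, true, registry, signed=True)
        absolute = eud_errors(pred, true, registry, signed=False)
        for key in pred:
            oracle = eud(pred[key], 3.9) - eud(true[key], 3.9)
            assert signed[key] == pytest.approx(oracle, rel=1e-12)
            assert absolute[key] == pytest.approx(abs(oracle), rel=1e-12)

    def test_unmatched_pairs_listed(self, registry, rng):
        a = {("P1", "larynx"): random_quantile_curve(rng, sid="larynx")}
        with pytest.raises(ValueError, match="P1"):
            eud_errors(a, {}, registry)


class TestSummarize:
    def test_constant_errors(self):
        s = summarize([1.0, 1.0, 1.0])
        assert (s.delta_gy, s.sigma_gy, s.n) == (1.0, 0.0, 3)

    def test_two_point_sd(self):
        s = summarize([0.0, 2.0])
        assert s.delta_gy == 1.0
        assert s.sigma_gy == pytest.approx(np.sqrt(2.0))

    def test_textbook_formula_oracle(self, rng):
        e = rng.standard_normal(500) * 3.0 + 0.5
        s = summarize(e)
        delta = e.sum() / e.size
        sigma = np.sqrt(((e - delta) ** 2).sum() / (e.size - 1))
        assert s.delta_gy == pytest.approx(delta, abs=1e-12)
        assert s.sigma_gy == pytest.approx(sigma, abs=1e-12)

    def test_order_invariance_and_shift(self, rng):
        e = list(rng.standard_normal(30))
        shuffled = list(np.random.default_rng(1).permutation(e))
        assert summarize(e).delta_gy == pytest.approx(summarize(shuffled).delta_gy)
        shifted = summarize([x + 5.0 for x in e])
        assert shifted.delta_gy == pytest.approx(summarize(e).delta_gy + 5.0)
        assert shifted.sigma_gy == pytest.approx(summarize(e).sigma_gy)

    def test_too_few_errors(self):
        with pytest.raises(ValueError):
            summarize([1.0])

    def test_by_organ_keeps_sides_separate(self, registry, rng):
        errors = {}
        for p in range(3):
            errors[(f"P{p}", "lens_l")] = 1.0
            errors[(f"P{p}", "lens_r")] = 2.0
        df = summarize_by_organ(errors)
        assert set(df.structure_id) == {"lens_l", "lens_r"}
        assert df.set_index("structure_id").loc["lens_l", "delta_gy"] == 1.0


class TestMetricTable:
    def test_uniform_organ(self, registry):
        c = DVHCurve(structure_id="larynx", doses=[60.0] * 4, dv=0.25, total_volume_cc=8.0)
        df = plan_metric_table({("P1", "larynx"): c}, registry)
        values = df.set_index("metric").value_gy
        for metric in ("D98", "Dmax", "Dmean", "D1cc", "EUD"):
            assert values[metric] == pytest.approx(60.0)

    def test_two_level_organ(self, registry):
        c = DVHCurve(structure_id="larynx", doses=[20, 20, 60, 60], dv=0.25, total_volume_cc=4.0)
        df = plan_metric_table({("P1", "larynx"): c}, registry).set_index("metric")
        assert df.loc["D1cc", "value_gy"] == 60.0
        assert df.loc["Dmean", "value_gy"] == 40.0

    def test_composition_oracle(self, registry, rng):
        from beamdvh.dvh import dose_at_relative_volume, max_dose, mean_dose

        curves = {
            (f"P{p}", "brainstem"): random_quantile_curve(rng, sid="brainstem")
            for p in range(4)
        }
        df = plan_metric_table(curves, registry, metrics=("D98", "Dmax", "Dmean", "EUD"))
        for (pid, sid), c in curves.items():
            sub = df[(df.patient_id == pid)].set_index("metric").value_gy
            assert sub["D98"] == pytest.approx(dose_at_relative_volume(c, 0.98))
            assert sub["Dmax"] == pytest.approx(max_dose(c))
            assert sub["Dmean"] == pytest.approx(mean_dose(c))
            assert sub["EUD"] == pytest.approx(eud(c, 9.8))

    def test_missing_volume_reported_not_fatal(self, registry, rng):
        c = random_quantile_curve(rng, sid="larynx")  # no total_volume_cc
        df = plan_metric_table({("P1", "larynx"): c}, registry)
        row = df[df.metric == "D1cc"].iloc[0]
        assert np.isnan(row.value_gy) and "volume" in row.error
        assert np.isfinite(df[df.metric == "Dmean"].iloc[0].value_gy)


class TestLimitsOfAgreement:
    def test_identical_vectors(self):
        loa = limits_of_agreement([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert loa == (0.0, 0.0, 0.0, 1.0)

    def test_symmetric_two_point(self):
        loa = limits_of_agreement([0.0, 2.0], [1.0, 1.0])
        assert loa.mean_diff == 0.0
        assert loa.upper == pytest.approx(1.96 * np.sqrt(2.0))
        assert loa.lower == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_nominal_coverage_monte_carlo(self):
        """~95% of normal differences fall inside mean ± 1.96 SD."""
        rng = np.random.default_rng(2024)
        a = rng.standard_normal(10_000)
        loa = limits_of_agreement(a, np.zeros_like(a))
        assert loa.frac_within == pytest.approx(0.95, abs=0.01)

    def test_antisymmetry(self, rng):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        ab = limits_of_agreement(a, b)
        ba = limits_of_agreement(b, a)
        assert ab.mean_diff == pytest.approx(-ba.mean_diff)
        assert ab.upper - ab.lower == pytest.approx(ba.upper - ba.lower)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            limits_of_agreement([1.0], [0.0])


def brute_force_signed_rank_p(diffs):
    """Independent enumeration oracle over all 2^n sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray([x for x in diffs if x != 0.0])
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    count = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return w_obs, count / total


class TestSignedRank:
    def test_constant_shift_exact_p(self):
        """All-positive differences, n = 8: two-sided exact p = 2/2^8."""
        b = np.arange(8.0)
        a = b + 3.0
        stat, p = paired_signed_rank(a, b)
        assert stat == 36.0  # sum of all ranks
        assert p == pytest.approx(2.0 / 256.0)

    def test_antisymmetric_differences_centered(self):
        d = np.array([-1.0, 1.0, -2.0, 2.0, -3.0, 3.0])
        stat, p = paired_signed_rank(d, np.zeros_like(d))
        assert stat == pytest.approx(10.5)  # half the total rank mass
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n", range(2, 13))
    def test_exact_path_matches_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        d = np.round(rng.standard_normal(n) * 3.0, 1)  # rounding creates ties
        d[d == 0.0] = 0.5
        stat, p = paired_signed_rank(d, np.zeros_like(d))
        stat_bf, p_bf = brute_force_signed_rank_p(d)
        assert stat == pytest.approx(stat_bf)
        assert p == pytest.approx(p_bf, abs=1e-12)

    def test_matches_scipy_exact_on_tie_free_data(self):
        from scipy.stats import wilcoxon

        rng = np.random.default_rng(7)
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        _, p = paired_signed_rank(a, b)
        ref = wilcoxon(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_path_matches_scipy(self):
        from scipy.stats import wilcoxon

        rng = np.random.default_rng(8)
        a = rng.standard_normal(40)
        b = a + rng.standard_normal(40) * 0.5 + 0.2
        _, p = paired_signed_rank(a, b)
        ref = wilcoxon(a, b, alternative="two-sided", method="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_all_zero_differences(self):
        with pytest.raises(ValueError, match="no informative"):
            paired_signed_rank([1.0, 2.0], [1.0, 2.0])
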