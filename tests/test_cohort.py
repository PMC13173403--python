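"""Wilcoxon signed-rank test, cohort summaries, model comparison, reports."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats

from segcal.cohort import (
    ModelComparison,
    compare_models,
    evaluate_patient,
    render_report,
    summarize_cohort,
    wilcoxon_signed_rank,
)
from segcal.volumes import (
    EnsemblePrediction,
    LabelVolume,
    ProbabilityVolume,
    StructureMetrics,
    VolumeGrid,
    write_metrics_table,
)


def enumeration_oracle_p(d):
    """Exhaustive 2^n two-sided p-value for differences d (no ties, no zeros):
    enumerate every sign assignment of the rank magnitudes and count tails."""
    d = np.asarray(d, dtype=float)
    n = d.size
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs or w >= total - w_obs:
            count += 1
    return count / 2**n


class TestWilcoxonSignedRank:
    def test_identical_vectors_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.p_value)
        assert res.n_used == 0

    def test_five_consistent_differences(self):
        # all differences positive with distinct magnitudes: W- = 0 and the
        # exact two-sided p is 2/2^5 = 0.0625
        a = [1.1, 2.3, 3.2, 4.9, 5.5]
        b = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = wilcoxon_signed_rank(a, b)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.0625)
        assert res.method == "exact"
        assert res.n_used == 5

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 13))
            d = rng.standard_normal(n)  # continuous: no ties, no zeros
            a = rng.standard_normal(n)
            res = wilcoxon_signed_rank(a + d, a)
            assert res.p_value == pytest.approx(enumeration_oracle_p(d), abs=1e-12)

    def test_matches_scipy_exact(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 18))
            a = rng.standard_normal(n)
            b = rng.standard_normal(n)
            res = wilcoxon_signed_rank(a, b)
            ref = scipy.stats.wilcoxon(a, b, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_swap_symmetry(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10)
        assert wilcoxon_signed_rank(a, b).p_value == pytest.approx(
            wilcoxon_signed_rank(b, a).p_value
        )

    def test_zero_differences_dropped(self):
        a = [1.0, 2.0, 3.5, 4.9, 5.0]
        b = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = wilcoxon_signed_rank(a, b)
        assert res.n_used == 2  # three zero differences removed

    def test_nan_pairs_dropped(self):
        a = [1.5, math.nan, 3.5, 4.5]
        b = [1.0, 2.0, math.nan, 4.0]
        res = wilcoxon_signed_rank(a, b)
        assert res.n_used == 2

    def test_large_n_uses_normal_approximation(self, rng):
        a = rng.standard_normal(40)
        b = a + rng.standard_normal(40) * 0.5
        res = wilcoxon_signed_rank(a, b)
        assert res.method == "approx"
        ref = scipy.stats.wilcoxon(
            a, b, alternative="two-sided", method="approx", correction=True
        )
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tied_magnitudes_match_enumeration_oracle(self, rng):
        # discretized differences produce tied |d|; mid-rank exact p must
        # agree with the explicit 2^n enumeration
        for _ in range(50):
            n = int(rng.integers(3, 11))
            d = rng.integers(1, 4, size=n) * rng.choice([-1.0, 1.0], size=n)
            res = wilcoxon_signed_rank(d, np.zeros(n))
            assert res.method == "exact"
            assert res.p_value == pytest.approx(enumeration_oracle_p(d), abs=1e-12)


class TestSummarizeCohort:
    def _records(self, values, metric="dsc"):
        return [
            StructureMetrics(f"p{i}", "A", "s", **{metric: v})
            for i, v in enumerate(values)
        ]

    def test_odd_n(self):
        df = summarize_cohort(self._records([0.2, 0.6, 1.0]))
        row = df[df.metric == "dsc"].iloc[0]
        assert row["median"] == pytest.approx(0.6)
        assert (row["min"], row["max"]) == (0.2, 1.0)

    def test_even_n_midpoint(self):
        df = summarize_cohort(self._records([0.2, 0.6]))
        assert df[df.metric == "dsc"].iloc[0]["median"] == pytest.approx(0.4)

    def test_single_value(self):
        df = summarize_cohort(self._records([0.7]))
        row = df[df.metric == "dsc"].iloc[0]
        assert row["median"] == 0.7 and row["min"] == 0.7 and row["max"] == 0.7

    def test_na_skipping_and_all_na(self):
        df = summarize_cohort(self._records([0.5, math.nan, 0.7]))
        row = df[df.metric == "dsc"].iloc[0]
        assert row["n"] == 2 and row["median"] == pytest.approx(0.6)
        ece_row = df[df.metric == "ece"].iloc[0]  # never populated
        assert ece_row["n"] == 0 and math.isnan(ece_row["median"])


class TestCompareModels:
    def _cohort(self, model, offsets):
        return [
            StructureMetrics(f"p{i}", model, "s", dsc=0.8 + off, mi=0.01 + off / 10)
            for i, off in enumerate(offsets)
        ]

    def test_identical_records_have_na_p(self):
        a = self._cohort("A", [0.0, 0.01, 0.02, 0.03, 0.04])
        with pytest.warns(UserWarning):
            comps = compare_models(a, a)
        for c in comps:
            assert math.isnan(c.p_value)
            assert not c.significant

    def test_constant_shift_gives_minimal_exact_p(self):
        a = self._cohort("A", [0.0, 0.011, 0.019, 0.032, 0.04])
        b = [
            StructureMetrics(
                r.patient_id, "B", "s", dsc=r.dsc + 0.05, mi=r.mi + 0.001
            )
            for r in a
        ]
        comps = {c.metric: c for c in compare_models(a, b)}
        assert comps["dsc"].p_value == pytest.approx(0.0625)  # floor at n = 5
        assert comps["dsc"].n_pairs == 5
        assert not comps["dsc"].significant  # 0.0625 >= 0.05

    def test_unmatched_patients_excluded(self):
        a = self._cohort("A", [0.0, 0.011, 0.019, 0.032])
        b = [
            StructureMetrics(f"p{i}", "B", "s", dsc=0.9 + i / 100)
            for i in (0, 1, 2, 7)  # p7 has no partner in A, p3 none in B
        ]
        comps = {c.metric: c for c in compare_models(a, b)}
        assert comps["dsc"].n_pairs == 3

    def test_na_pairs_reduce_n_for_that_metric_only(self):
        a = self._cohort("A", [0.0, 0.011, 0.019, 0.032, 0.04])
        b = [
            StructureMetrics(
                r.patient_id, "B", "s",
                dsc=r.dsc + 0.05,
                mi=math.nan if r.patient_id == "p0" else r.mi + 0.001,
            )
            for r in a
        ]
        comps = {c.metric: c for c in compare_models(a, b)}
        assert comps["dsc"].n_pairs == 5
        assert comps["mi"].n_pairs == 4  # mirrors uneven per-metric cohorts

    def test_no_shared_patients_warns_empty(self):
        a = self._cohort("A", [0.0, 0.01])
        b = [StructureMetrics("q0", "B", "s", dsc=0.9)]
        with pytest.warns(UserWarning, match="no shared patients"):
            assert compare_models(a, b) == []


class TestEvaluatePatient:
    @pytest.fixture
    def cube_patient(self):
        grid = VolumeGrid((20, 20, 20), (1.0, 1.0, 1.0))
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[4:10, 4:10, 4:10] = 1
        labels[13:17, 13:17, 13:17] = 2
        ref = LabelVolume(grid, labels, ("big", "small"))
        ensembles = {}
        for s in ref.structure_names:
            indicator = ProbabilityVolume(grid, ref.mask(s).astype(float))
            ensembles[s] = EnsemblePrediction(tuple(indicator for _ in range(5)))
        return ref, ensembles

    def test_perfect_indicator_identities(self, cube_patient):
        ref, ensembles = cube_patient
        records = evaluate_patient(ref, ensembles, patient_id="p0", model="M")
        assert len(records) == 2
        for r in records:
            assert r.dsc == 1.0
            assert r.nsd == 1.0
            assert r.mi == 0.0
            assert r.ens_var == 0.0
            assert r.ece == 0.0

    def test_missing_structure_yields_all_na(self, cube_patient):
        ref, ensembles = cube_patient
        del ensembles["small"]
        with pytest.warns(UserWarning, match="no prediction"):
            records = evaluate_patient(ref, ensembles)
        small = [r for r in records if r.structure == "small"][0]
        assert all(math.isnan(small.metric(m)) for m in
                   ("dsc", "nsd", "mi", "ens_var", "ece"))

    def test_rerun_is_byte_identical(self, cube_patient, tmp_path):
        ref, ensembles = cube_patient
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_metrics_table(evaluate_patient(ref, ensembles), p1)
        write_metrics_table(evaluate_patient(ref, ensembles), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestRenderReport:
    COMPS = [
        ModelComparison(
            structure="brainstem", metric="dsc",
            values_a=(0.9, 0.92), values_b=(0.91, 0.93), n_pairs=2,
            median_a=0.91, range_a=(0.9, 0.92),
            median_b=0.92, range_b=(0.91, 0.93),
            p_value=0.5, significant=False,
        ),
        ModelComparison(
            structure="brainstem", metric="mi",
            values_a=(0.02, 0.03), values_b=(0.01, 0.015), n_pairs=2,
            median_a=0.025, range_a=(0.02, 0.03),
            median_b=0.0125, range_b=(0.01, 0.015),
            p_value=0.001, significant=True,
        ),
    ]

    def test_empty_report(self, tmp_path):
        render_report([], tmp_path)
        assert (tmp_path / "report.csv").read_text().startswith("structure,metric")

    def test_populated_and_deterministic(self, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        render_report(self.COMPS, d1)
        render_report(self.COMPS, d2)
        assert (d1 / "report.csv").read_bytes() == (d2 / "report.csv").read_bytes()
        assert (d1 / "report.md").read_bytes() == (d2 / "report.md").read_bytes()
        md = (d1 / "report.md").read_text()
        assert "brainstem" in md
        assert "**0.001**" in md  # significant p bolded
        assert "0.91 (0.9–0.92)" in md
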