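import math

import numpy as np
import pandas as pd
import pytest

from lncflow.ripening import (
    CONTRASTS,
    de_test,
    expressed_set,
    nearest_mrna,
    pair_and_correlate,
    venn_partition,
)
from lncflow.synthetic_data import simulate_null_matrix

from conftest import make_transcript, random_transcript


def _stage_design(reps=2, stages=("MG", "BR")):
    rows = []
    for st in stages:
        for r in range(reps):
            rows.append({"sample": f"{st}_r{r + 1}", "tissue": ".", "stage": st})
    return pd.DataFrame(rows)


def _matrix(data, design):
    return pd.DataFrame(data, columns=list(design["sample"])).rename_axis(
        "transcript_id"
    )


class TestExpressedSet:
    def test_mean_above_floor_kept(self):
        d = _stage_design(reps=2, stages=("MG",))
        m = pd.DataFrame({"MG_r1": [12.0], "MG_r2": [9.0]}, index=["t1"])
        assert expressed_set(m, d, "MG") == {"t1"}

    def test_mean_exactly_ten_excluded(self):
        d = _stage_design(reps=2, stages=("MG",))
        m = pd.DataFrame({"MG_r1": [10.0], "MG_r2": [10.0]}, index=["t1"])
        assert expressed_set(m, d, "MG") == set()  # strict >

    def test_unknown_stage_errors(self):
        d = _stage_design()
        m = pd.DataFrame()
        with pytest.raises(ValueError, match="ripe"):
            expressed_set(m, d, "ripe")

    def test_recovers_planted_high_expression_sets(self, sim):
        for stage in ("MG", "BR", "BR+7"):
            got = expressed_set(sim.expression, sim.design, stage)
            truth_col = sim.truth[f"high_{stage}"]
            expected_novel = set(truth_col.index[truth_col])
            assert got & set(sim.truth.index) == expected_novel


class TestDeTest:
    def test_log2fc_with_pseudocount(self):
        d = _stage_design(reps=2)
        m = _matrix([[40.0, 40.0, 10.0, 10.0]], d)
        m.index = ["t1"]
        de = de_test(m, d, ("MG", "BR"))
        assert de.loc[0, "log2fc"] == pytest.approx(math.log2(41 / 11))
        assert de.loc[0, "log2fc"] == pytest.approx(1.898, abs=1e-3)

    def test_identical_replicates_null(self):
        d = _stage_design(reps=3)
        vals = [5.0, 7.0, 9.0]
        m = _matrix([vals + vals], d)
        m.index = ["t1"]
        de = de_test(m, d, ("MG", "BR"))
        assert de.loc[0, "log2fc"] == 0.0
        assert de.loc[0, "p"] == pytest.approx(1.0)

    def test_bh_hand_computation_via_external_p(self):
        d = _stage_design(reps=2)
        m = _matrix(np.ones((4, 4)), d)
        m.index = [f"t{i}" for i in range(4)]
        external = {"t0": 0.01, "t1": 0.02, "t2": 0.03, "t3": 0.04}
        de = de_test(m, d, ("MG", "BR"), external_p=external)
        assert list(de["q"]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bh_q_monotone_and_at_least_p(self):
        rng = np.random.default_rng(12)
        d = _stage_design(reps=2)
        n = 50
        m = _matrix(np.ones((n, 4)), d)
        m.index = [f"t{i}" for i in range(n)]
        external = {f"t{i}": float(p) for i, p in enumerate(rng.uniform(size=n))}
        de = de_test(m, d, ("MG", "BR"), external_p=external)
        assert (de["q"] >= de["p"] - 1e-12).all()
        by_p = de.sort_values("p")
        assert (np.diff(by_p["q"].values) >= -1e-12).all()

    def test_permutation_floor_at_3v3(self):
        """Exact 3v3 permutation p-values are multiples of 1/20, >= 0.1."""
        rng = np.random.default_rng(1)
        d = _stage_design(reps=3)
        m = _matrix(
            np.hstack([rng.uniform(30, 40, (20, 3)), rng.uniform(1, 2, (20, 3))]),
            d,
        )
        m.index = [f"t{i}" for i in range(20)]
        de = de_test(m, d, ("MG", "BR"), method="permutation")
        assert (de["p"] >= 0.1 - 1e-12).all()
        assert np.allclose(np.round(de["p"] * 20), de["p"] * 20)

    def test_too_few_replicates_error(self):
        d = _stage_design(reps=1)
        m = _matrix([[1.0, 2.0]], d)
        m.index = ["t1"]
        with pytest.raises(ValueError, match="replicates"):
            de_test(m, d, ("MG", "BR"))

    def test_significance_invariant(self):
        rng = np.random.default_rng(2)
        d = _stage_design(reps=3)
        m = _matrix(rng.uniform(1, 50, (30, 6)), d)
        m.index = [f"t{i}" for i in range(30)]
        de = de_test(m, d, ("MG", "BR"), method="ttest")
        expected = (de["log2fc"].abs() > 1) & (de["q"] < 0.05)
        assert (de["significant"] == expected).all()

    def test_null_fpr_controlled_both_methods(self):
        matrix, design = simulate_null_matrix(
            n_transcripts=400, reps=3, dispersion=0.3, seed=21
        )
        for method in ("permutation", "ttest"):
            de = de_test(matrix, design, ("MG", "BR"), method=method)
            fpr = (de["q"] < 0.05).mean()
            assert fpr <= 0.07, method

    def test_planted_de_recall_with_ttest(self):
        """Planted |log2FC| >= 2 at dispersion 0.1, n=3: recall >= 0.9.

        Uses the t-test route: the exact 3v3 permutation p-value floor (0.1)
        makes q < 0.05 unreachable for any test at this replicate number.
        """
        rng = np.random.default_rng(31)
        n = 200
        mg = 10.0 * np.exp(rng.normal(0, 0.1, (n, 3)))
        br = 40.0 * np.exp(rng.normal(0, 0.1, (n, 3)))
        d = _stage_design(reps=3)
        m = _matrix(np.hstack([mg, br]), d)
        m.index = [f"t{i}" for i in range(n)]
        de = de_test(m, d, ("MG", "BR"), method="ttest")
        assert de["significant"].mean() >= 0.9

    def test_recovers_planted_de_flags_noise_free_ttest(self, sim):
        novel_ids = set(sim.truth.index)
        for a, b in CONTRASTS:
            de = de_test(sim.expression, sim.design, (a, b), method="ttest")
            de = de.set_index("transcript_id")
            for tid in novel_ids:
                planted = sim.truth.loc[tid, f"de_{a}-vs-{b}"]
                assert bool(de.loc[tid, "significant"]) == bool(planted), (
                    tid, a, b,
                )


class TestVennPartition:
    def test_worked_example(self):
        v = venn_partition({"a", "b", "c"}, {"b", "c", "d"}, {"c"})
        assert v == {"A": 1, "B": 1, "C": 0, "AB": 1, "AC": 0, "BC": 0, "ABC": 1}

    def test_disjoint(self):
        v = venn_partition({"a"}, {"b"}, {"c"})
        assert v == {"A": 1, "B": 1, "C": 1, "AB": 0, "AC": 0, "BC": 0, "ABC": 0}

    def test_identical_sets_all_triple(self):
        s = {"x", "y"}
        v = venn_partition(s, s, s)
        assert v == {"A": 0, "B": 0, "C": 0, "AB": 0, "AC": 0, "BC": 0, "ABC": 2}

    def test_region_counts_sum_to_union(self):
        rng = np.random.default_rng(4)
        universe = [f"t{i}" for i in range(40)]
        for _ in range(50):
            a = set(rng.choice(universe, rng.integers(0, 30), replace=False))
            b = set(rng.choice(universe, rng.integers(0, 30), replace=False))
            c = set(rng.choice(universe, rng.integers(0, 30), replace=False))
            assert sum(venn_partition(a, b, c).values()) == len(a | b | c)


class TestNearestMrna:
    def test_worked_example(self):
        lnc = make_transcript("l", "chr1", [(5000, 5800)], "+")
        mrnas = [
            make_transcript("m1", "chr1", [(1000, 2500)], "+"),
            make_transcript("m2", "chr1", [(9000, 9500)], "+"),
        ]
        assert nearest_mrna(lnc, mrnas) == ("m1", 2500)

    def test_adjacent_half_open_distance_zero(self):
        lnc = make_transcript("l", "chr1", [(0, 100)], "+")
        m = make_transcript("m", "chr1", [(100, 200)], "+")
        assert nearest_mrna(lnc, [m]) == ("m", 0)

    def test_tie_broken_lexicographically(self):
        lnc = make_transcript("l", "chr1", [(1000, 1100)], "+")
        mrnas = [
            make_transcript("mB", "chr1", [(1200, 1300)], "+"),
            make_transcript("mA", "chr1", [(800, 900)], "+"),
        ]
        assert nearest_mrna(lnc, mrnas) == ("mA", 100)

    def test_no_same_chrom_candidate(self):
        lnc = make_transcript("l", "chr1", [(0, 100)], "+")
        m = make_transcript("m", "chr2", [(0, 100)], "+")
        assert nearest_mrna(lnc, [m]) == (None, None)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        mrnas = [random_transcript(rng, f"m{i}") for i in range(30)]
        for i in range(200):
            lnc = random_transcript(rng, f"l{i}")
            got_id, got_d = nearest_mrna(lnc, mrnas)
            gaps = sorted(
                (
                    max(0, m.interval.start - lnc.interval.end,
                        lnc.interval.start - m.interval.end),
                    m.transcript_id,
                )
                for m in mrnas
                if m.chrom == lnc.chrom
            )
            assert (got_d, got_id) == gaps[0]


class TestPairAndCorrelate:
    def _setup(self, lnc_vals, mrna_vals, reps=3):
        stages = ("MG", "BR", "BR+7")
        d = _stage_design(reps=reps, stages=stages)
        m = _matrix([lnc_vals, mrna_vals], d)
        m.index = ["lnc1", "m1"]
        lnc = {"lnc1": make_transcript("lnc1", "chr1", [(5000, 5500)], "+")}
        mrna = {"m1": make_transcript("m1", "chr1", [(1000, 2000)], "+")}
        return lnc, mrna, m, d

    def test_proportional_profiles_r_one(self):
        base = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0]
        lnc, mrna, m, d = self._setup([2 * v for v in base], base)
        pairs, _ = pair_and_correlate(
            ["lnc1"], ["m1"], lnc, mrna, m, d, pseudocount=0
        )
        assert pairs[0].pearson_r == pytest.approx(1.0)
        assert pairs[0].distance_bp == 3000

    def test_anti_proportional_profiles_r_minus_one(self):
        base = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0]
        lnc, mrna, m, d = self._setup([1 / v for v in base], base)
        pairs, _ = pair_and_correlate(
            ["lnc1"], ["m1"], lnc, mrna, m, d, pseudocount=0
        )
        assert pairs[0].pearson_r == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(1, 100, 9)
        y = rng.uniform(1, 100, 9)
        lnc, mrna, m, d = self._setup(list(x), list(y))
        pairs, _ = pair_and_correlate(["lnc1"], ["m1"], lnc, mrna, m, d)
        lx, ly = np.log2(x + 1), np.log2(y + 1)
        dx, dy = lx - lx.mean(), ly - ly.mean()
        expected = (dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum())
        assert pairs[0].pearson_r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_pair_kept_with_nan(self):
        lnc, mrna, m, d = self._setup([5.0] * 9, [1.0, 2, 3, 4, 5, 6, 7, 8, 9])
        pairs, _ = pair_and_correlate(["lnc1"], ["m1"], lnc, mrna, m, d)
        assert len(pairs) == 1 and math.isnan(pairs[0].pearson_r)

    def test_distance_threshold_excludes_far_pairs(self):
        base = list(range(1, 10))
        lnc, mrna, m, d = self._setup(base, base)
        mrna = {"m1": make_transcript("m1", "chr1", [(50_000, 51_000)], "+")}
        pairs, frac = pair_and_correlate(["lnc1"], ["m1"], lnc, mrna, m, d)
        assert pairs == []
        assert frac == 0.0  # 44.5 kb away: not within 30 kb either

    def test_proximity_fraction(self):
        stages = ("MG", "BR", "BR+7")
        d = _stage_design(reps=3, stages=stages)
        vals = [list(range(1, 10))] * 4
        m = _matrix(vals, d)
        m.index = ["l1", "l2", "m1", "m2"]
        lnc = {
            "l1": make_transcript("l1", "chr1", [(0, 100)], "+"),
            "l2": make_transcript("l2", "chr1", [(100_000, 100_100)], "+"),
        }
        mrna = {
            "m1": make_transcript("m1", "chr1", [(5000, 6000)], "+"),
            "m2": make_transcript("m2", "chr1", [(150_000, 151_000)], "+"),
        }
        pairs, frac = pair_and_correlate(
            ["l1", "l2"], ["m1", "m2"], lnc, mrna, m, d
        )
        # l1->m1 at 4900 (paired, <10kb); l2->m2 at 49900 (not paired, >30kb)
        assert [p.lnc_id for p in pairs] == ["l1"]
        assert frac == pytest.approx(0.5)
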