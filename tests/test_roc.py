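"""Matched-control ROC areas, group comparisons, expression tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trapsil.roc import (_permutation_p, benjamini_hochberg, compare_groups,
                         heatmap_matrix, matched_controls, roc_area,
                         significance_stars, site_scores, wilcoxon_expression)
from trapsil.features import point_track

from conftest import random_genome


def _sites_df(rows):
    return pd.DataFrame(rows, columns=["read_id", "vector", "phenotype", "chrom",
                                       "position", "strand", "status"])


class TestMatchedControls:
    def _sites(self, n=5, chrom="chrS1"):
        return _sites_df([[f"s{i}", "LV", "REP", chrom, 1_000 + i, "+", "mapped"]
                          for i in range(n)])

    def test_zero_controls_rejected(self):
        genome = {"chrS1": "ACGT" * 1_000}
        with pytest.raises(ValueError, match="n_controls"):
            matched_controls(self._sites(), genome, n_controls=0)

    def test_fixed_seed_reproduces_identical_sets(self):
        rng = np.random.default_rng(20)
        genome = random_genome(rng, {"chrS1": 20_000, "chrS2": 10_000})
        a = matched_controls(self._sites(), genome, seed=9)
        b = matched_controls(self._sites(), genome, seed=9)
        assert {k: v.controls for k, v in a.items()} == {
            k: v.controls for k, v in b.items()}

    def test_uniform_positions_pass_chi_square_goodness_of_fit(self):
        rng = np.random.default_rng(21)
        genome = random_genome(rng, {"chrS1": 100_000})
        sets = matched_controls(self._sites(n=1_000), genome, n_controls=10, seed=3)
        positions = np.array([p for cs in sets.values() for _, p, _ in cs.controls])
        observed, _ = np.histogram(positions, bins=10, range=(0, 100_000))
        p = stats.chisquare(observed).pvalue
        assert p > 0.001

    def test_msei_matched_controls_track_ttaa_distance(self):
        rng = np.random.default_rng(22)
        genome = random_genome(rng, {"chrS1": 50_000})
        from trapsil.features import distance_to_nearest
        from trapsil.roc import _ttaa_positions
        ttaa = _ttaa_positions(genome["chrS1"])
        sites = self._sites(n=5)
        sets = matched_controls(sites, genome, n_controls=5, mode="msei_matched",
                                seed=4, msei_tolerance=50)
        for _, s in sites.iterrows():
            own = distance_to_nearest(int(s["position"]), ttaa)
            for chrom, pos, _ in sets[s["read_id"]].controls:
                assert abs(distance_to_nearest(pos, ttaa) - own) <= 50

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            matched_controls(self._sites(), {"chrS1": "ACGT" * 100}, mode="fancy")


class TestRocArea:
    def test_all_sites_above_controls_scores_one(self):
        case = [10.0] * 20
        ctrl = [list(range(6))] * 20
        assert roc_area(case, ctrl) == 1.0

    def test_all_sites_below_controls_scores_zero(self):
        case = [0.0] * 20
        ctrl = [list(range(5, 11))] * 20
        assert roc_area(case, ctrl) == 0.0

    def test_all_values_identical_scores_half(self):
        assert roc_area([3.0] * 10, [[3.0, 3.0, 3.0]] * 10) == 0.5

    def test_hand_enumerated_mixed_case(self):
        # one site, value 3, controls {1,2,3,5}: b=2/4, t=1/4 -> 0.625
        assert roc_area([3.0], [[1.0, 2.0, 3.0, 5.0]]) == 0.625

    def test_antisymmetry_under_case_control_swap(self):
        rng = np.random.default_rng(30)
        case = rng.normal(size=50)
        ctrl = [rng.normal(size=1) for _ in range(50)]
        # with one control per site the swap is well-defined sitewise
        a = roc_area(case, ctrl)
        b = roc_area([c[0] for c in ctrl], [[v] for v in case])
        assert a + b == pytest.approx(1.0)

    def test_na_sites_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropped 1"):
            a = roc_area([1.0, np.nan], [[0.0], [0.0]])
        assert a == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_shared_control_pool_equals_mann_whitney_auc(self, seed):
        """When every site shares one control pool the matched-control area
        must equal the tie-corrected Mann-Whitney AUC U/(n*m)."""
        rng = np.random.default_rng(700 + seed)
        n, m = int(rng.integers(3, 30)), int(rng.integers(3, 30))
        # integer values force ties
        case = rng.integers(0, 6, size=n).astype(float)
        pool = rng.integers(0, 6, size=m).astype(float)
        got = roc_area(case, [pool] * n)
        u = stats.mannwhitneyu(case, pool, alternative="two-sided").statistic
        assert got == pytest.approx(u / (n * m))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(31)
        case = rng.normal(size=40)
        ctrl = [rng.normal(size=10) for _ in range(40)]
        a = roc_area(case, ctrl)
        f = lambda x: np.exp(3 * np.asarray(x)) + 1  # strictly increasing
        assert roc_area(f(case), [f(c) for c in ctrl]) == pytest.approx(a)

    def test_null_calibration_mean_near_half(self):
        rng = np.random.default_rng(32)
        areas = []
        for _ in range(200):
            case = rng.normal(size=50)
            ctrl = [rng.normal(size=10) for _ in range(50)]
            areas.append(roc_area(case, ctrl))
        areas = np.array(areas)
        se = areas.std(ddof=1) / math.sqrt(len(areas))
        assert abs(areas.mean() - 0.5) < 3 * se


class TestHeatmapMatrix:
    def test_identically_zero_feature_gives_half_everywhere(self):
        rng = np.random.default_rng(33)
        genome = random_genome(rng, {"chrS1": 50_000})
        sites = _sites_df([[f"s{i}", "LV", "REP", "chrS1", 1_000 * (i + 1), "+", "mapped"]
                           for i in range(10)])
        sets = matched_controls(sites, genome, seed=1)
        track = point_track("empty", {"chrS1": []})
        heat = heatmap_matrix({"LV-REP": sites}, {"empty": track}, [1_000, 10_000],
                              sets, sequences=genome)
        assert (heat["area"] == 0.5).all()

    def test_empty_group_yields_na_row(self):
        rng = np.random.default_rng(34)
        genome = random_genome(rng, {"chrS1": 10_000})
        track = point_track("m", {"chrS1": [(5, 1)]})
        heat = heatmap_matrix({"LV-REP": _sites_df([])}, {"m": track}, [1_000], {},
                              sequences=genome)
        assert heat["area"].isna().all() and (heat["n_sites"] == 0).all()

    def test_case_control_swap_antisymmetry(self):
        """Treating each site's first control as the case (and the case as
        its control) maps every area a to 1 - a."""
        rng = np.random.default_rng(35)
        case = rng.normal(size=30)
        ctrl = [rng.normal(size=1) for _ in range(30)]
        a = roc_area(case, ctrl)
        a_swapped = roc_area([c[0] for c in ctrl], [[v] for v in case])
        assert a_swapped == pytest.approx(1 - a)


class TestCompareGroups:
    def _planted(self, rng, n, effect, m=10):
        """Matched sets where the case value is shifted by `effect`."""
        case = rng.normal(size=n) + effect
        ctrl = [rng.normal(size=m) for _ in range(n)]
        return case, ctrl

    def test_identical_groups_permutation_p_near_one(self):
        rng = np.random.default_rng(40)
        case, ctrl = self._planted(rng, 30, 0.0)
        res = compare_groups(case, ctrl, case, ctrl, method="permutation", seed=2)
        assert res["p_perm"] > 0.99

    def test_planted_effect_detected_by_both_methods(self):
        rng = np.random.default_rng(41)
        ca, xa = self._planted(rng, 500, 1.0)
        cb, xb = self._planted(rng, 500, 0.0)
        res = compare_groups(ca, xa, cb, xb, seed=3)
        assert res["p_chi2"] < 0.01 and res["p_perm"] < 0.01
        assert res["area_a"] > res["area_b"]

    def test_permutation_on_toy_equals_exhaustive_enumeration(self):
        """6 sites total: the implementation's exact path must equal a direct
        enumeration over all label assignments written independently here."""
        sa = np.array([0.9, 0.8, 0.7])
        sb = np.array([0.3, 0.4, 0.2])
        got = _permutation_p(sa, sb, n_perm=10_000, seed=0)
        pooled = np.concatenate([sa, sb])
        obs = abs(sa.mean() - sb.mean())
        hits = total = 0
        for comb in itertools.combinations(range(6), 3):
            a = pooled[list(comb)]
            b = np.delete(pooled, list(comb))
            total += 1
            if abs(a.mean() - b.mean()) >= obs - 1e-12:
                hits += 1
        assert got == pytest.approx(hits / total)
        assert got == pytest.approx(2 / 20)

    def test_clogit_likelihood_ratio_null_uniformity(self):
        # under the null the LR p-value should not be anti-conservative
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(100):
            ca, xa = self._planted(rng, 40, 0.3)
            cb, xb = self._planted(rng, 40, 0.3)  # same effect: null interaction
            res = compare_groups(ca, xa, cb, xb, method="chi2_clogit",
                                 n_perm=200, seed=5)
            rejections += res["p_chi2"] < 0.05
        assert rejections <= 12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="usable site"):
            compare_groups([], [], [1.0], [[0.0]])


class TestParameterRecovery:
    def test_roc_area_monotone_in_planted_feature_effect(self):
        """Sweeping the planted log-odds of the feature term upward must
        push the REP-group area monotonically above 0.5."""
        from trapsil.synthetic_data import SynthConfig, gen_genome, gen_integrants
        from trapsil.features import quantify

        base = dict(genome_length=1_000_000, n_chromosomes=2, n_genes=40,
                    gene_size_range=(5_000, 40_000), n_sites=1_200,
                    baseline_p_rep=0.05, distance_decay_bp=0.0,
                    density_track="planted_mark", seed=311)
        cfg0 = SynthConfig(**base, feature_effect=0.0)
        bundle = gen_genome(cfg0)
        rng = np.random.default_rng(312)
        pts = {ch: [(int(p), 1) for p in rng.integers(0, len(seq), 60)]
               for ch, seq in bundle.sequences.items()}
        bundle.tracks["planted_mark"] = point_track("planted_mark", pts)
        track = bundle.tracks["planted_mark"]
        chrom_len = {c: len(s) for c, s in bundle.sequences.items()}
        ctrl_rng = np.random.default_rng(313)
        areas = []
        for effect in (0.0, 2.0, 4.0):
            cfg = SynthConfig(**base, feature_effect=effect)
            sites = gen_integrants(cfg, bundle)
            rep = sites[sites["phenotype"] == "REP"]
            case, ctrl = [], []
            for _, s in rep.iterrows():
                case.append(quantify(track, s["chrom"], int(s["position"]), 1_000,
                                     chrom_length=chrom_len[s["chrom"]]))
                cc = []
                for _ in range(10):
                    ch = ["chrS1", "chrS2"][ctrl_rng.integers(2)]
                    p = int(ctrl_rng.integers(0, chrom_len[ch]))
                    cc.append(quantify(track, ch, p, 1_000, chrom_length=chrom_len[ch]))
                ctrl.append(cc)
            areas.append(roc_area(case, ctrl))
        assert areas[0] == pytest.approx(0.5, abs=0.05)
        assert areas[0] < areas[1] < areas[2]


class TestWilcoxonExpression:
    def test_identical_samples_exact_p_is_one(self):
        groups = {"g1": [5.0, 5.0, 5.0], "g2": [5.0, 5.0, 5.0]}
        df = wilcoxon_expression(groups)
        assert df["p"].item() == 1.0 and df["method"].item() == "exact"

    def test_disjoint_triples_exact_enumeration(self):
        # {1,2,3} vs {4,5,6}: 2 of the 20 assignments are as extreme
        df = wilcoxon_expression({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert df["p"].item() == pytest.approx(0.1)

    def test_normal_approximation_close_to_exact_at_n8(self):
        rng = np.random.default_rng(43)
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(loc=0.5, size=8)
            exact = wilcoxon_expression({"a": x, "b": y})["p"].item()
            approx = wilcoxon_expression({"a": x, "b": y}, exact_max_n=0)["p"].item()
            # continuity-corrected normal approximation sits within ~0.015
            # of full enumeration at these sample sizes
            assert abs(exact - approx) < 0.015

    def test_empty_group_gives_na(self):
        df = wilcoxon_expression({"a": [1.0], "b": []})
        assert np.isnan(df["p"].item()) and df["method"].item() == "na"

    def test_three_groups_give_three_pairs(self):
        df = wilcoxon_expression({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert len(df) == 3


def test_significance_star_thresholds():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"
    assert significance_stars(0.2) == ""


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(44)
    p = rng.uniform(size=37)
    got = benjamini_hochberg(p)
    _, expect, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(got, expect)
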