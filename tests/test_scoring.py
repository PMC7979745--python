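"""Screen scoring: counting, normalization, the NB guide test, alpha-RRA
sliding windows with permutation p values, and group ECDF comparison."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crescreen import SimConfig, design, scoring, simulate
from crescreen.design import TargetRegion
from crescreen.scoring import CountMatrix


def _mini_library():
    return pd.DataFrame(
        {
            "guide_id": ["g1", "g2", "g3"],
            "region_id": "r0",
            "cut_site": [10, 20, 30],
            "protospacer": ["ACGTACGTACGTACGTACGT",
                            "TGCATGCATGCATGCATGCA",
                            "GGCCGGCCGGCCTTAAGGCC"],
            "ambiguous": False,
        }
    )


def _cm(day0, day16):
    samples = {}
    meta = []
    for i, col in enumerate(np.atleast_2d(np.asarray(day0).T)):
        samples[f"day0_rep{i + 1}"] = col
        meta.append({"sample": f"day0_rep{i + 1}", "timepoint": "day0", "replicate": i + 1})
    for i, col in enumerate(np.atleast_2d(np.asarray(day16).T)):
        samples[f"day16_rep{i + 1}"] = col
        meta.append({"sample": f"day16_rep{i + 1}", "timepoint": "day16", "replicate": i + 1})
    return CountMatrix(counts=pd.DataFrame(samples), meta=pd.DataFrame(meta))


class TestCountGuides:
    def test_identity_counting(self):
        lib = _mini_library()
        reads = list(lib["protospacer"]) * 3
        cm, unassigned = scoring.count_guides(
            {"day0_rep1": reads, "day16_rep1": reads}, lib
        )
        assert (cm.counts == 3).all().all()
        assert (unassigned == 0).all()

    def test_single_mismatch_is_unassigned(self):
        lib = _mini_library()
        read = "T" + lib["protospacer"][0][1:]
        cm, unassigned = scoring.count_guides(
            {"day0_rep1": [read], "day16_rep1": []}, lib
        )
        assert cm.counts["day0_rep1"].sum() == 0
        assert unassigned["day0_rep1"] == 1

    def test_totals_conserved(self, rng):
        lib = _mini_library()
        reads = ["ACGT" * 5, *lib["protospacer"], "TTTT" * 5]
        cm, unassigned = scoring.count_guides(
            {"day0_rep1": reads, "day16_rep1": reads}, lib
        )
        assert cm.counts["day0_rep1"].sum() + unassigned["day0_rep1"] == len(reads)

    def test_duplicate_protospacer_requires_flag(self):
        lib = _mini_library()
        lib.loc[1, "protospacer"] = lib.loc[0, "protospacer"]
        with pytest.raises(ValueError, match="duplicate"):
            scoring.count_guides({"day0_rep1": [], "day16_rep1": []}, lib)


class TestNormalize:
    def test_identical_samples_unit_factors(self):
        counts = np.tile([[10], [20], [30]], (1, 4))
        cm = _cm(counts[:, :2], counts[:, 2:])
        sf = scoring.normalize_counts(cm).size_factors
        assert np.allclose(sf, 1.0)

    def test_doubled_sample_doubles_factor(self):
        base = np.array([10, 20, 40, 80])
        cm = _cm(np.column_stack([base, 2 * base]), np.column_stack([base, base]))
        sf = scoring.normalize_counts(cm).size_factors
        assert sf["day0_rep2"] / sf["day0_rep1"] == pytest.approx(2.0)

    def test_matches_definition_on_random_matrix(self, rng):
        counts = rng.integers(1, 1000, size=(50, 4))
        cm = _cm(counts[:, :2], counts[:, 2:])
        sf = scoring.normalize_counts(cm).size_factors.to_numpy()
        # direct re-computation from the definition
        geo = np.exp(np.log(counts).mean(axis=1))
        expected = np.median(counts / geo[:, None], axis=0)
        assert np.allclose(sf, expected)

    def test_all_zero_sample_rejected(self):
        cm = _cm(np.array([[1, 0], [2, 0]]), np.array([[1, 1], [2, 2]]))
        with pytest.raises(ValueError, match="all-zero"):
            scoring.normalize_counts(cm)


class TestGuideDepletion:
    def test_no_change_gives_null_result(self):
        counts = np.array([[100, 100], [50, 50], [211, 211]])
        cm = _cm(counts, counts)
        gs = scoring.guide_depletion_test(cm)
        assert np.allclose(gs["log2fc"], 0)
        assert (gs["p_dep"] >= 0.5).all()

    def test_poisson_limit_matches_poisson_oracle(self):
        cfg = SimConfig(seed=5, nb_dispersion=0.0)
        lib = pd.DataFrame(
            {"guide_id": [f"g{i}" for i in range(2000)], "region_id": "r0",
             "cut_site": np.arange(2000)}
        )
        cm, _ = simulate.simulate_screen_counts(lib, cfg)
        gs = scoring.guide_depletion_test(cm)
        # oracle: identical Wald construction with the dispersion pinned to 0
        cmn = scoring.normalize_counts(cm)
        norm = cmn.normalized
        m0 = norm[cmn.samples("day0")].mean(axis=1).to_numpy()
        m16 = norm[cmn.samples("day16")].mean(axis=1).to_numpy()
        lfc = np.log2((m16 + 0.5) / (m0 + 0.5))
        se = np.sqrt((m0 / 2) / (m0 + 0.5) ** 2 + (m16 / 2) / (m16 + 0.5) ** 2) / np.log(2)
        p_oracle = 2 * stats.norm.sf(np.abs(lfc / se))
        assert np.abs(p_oracle - gs["p_two"].to_numpy()).max() <= 0.01

    def test_type_one_error_calibrated(self):
        fracs = []
        lib = pd.DataFrame(
            {"guide_id": [f"g{i}" for i in range(2000)], "region_id": "r0",
             "cut_site": np.arange(2000)}
        )
        for seed in range(20):
            cm, _ = simulate.simulate_screen_counts(lib, SimConfig(seed=seed))
            gs = scoring.guide_depletion_test(cm)
            fracs.append((gs["p_dep"] < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_single_replicate_falls_back_with_warning(self):
        counts = np.array([[100], [50], [211]])
        cm = _cm(counts, counts)
        with pytest.warns(UserWarning, match="single replicate"):
            gs = scoring.guide_depletion_test(cm)
        assert (gs["dispersion"] == 0).all()

    def test_scaling_one_sample_preserves_inference(self):
        """Scaling a sample's depth is absorbed by normalization: guide
        ranking is unchanged and p values move only marginally."""
        cfg = SimConfig(seed=3)
        lib = pd.DataFrame(
            {"guide_id": [f"g{i}" for i in range(500)], "region_id": "r0",
             "cut_site": np.arange(500)}
        )
        cm, _ = simulate.simulate_screen_counts(lib, cfg)
        gs = scoring.guide_depletion_test(cm)
        scaled_counts = cm.counts.copy()
        scaled_counts["day16_rep1"] *= 7
        cm2 = CountMatrix(counts=scaled_counts, meta=cm.meta)
        gs2 = scoring.guide_depletion_test(cm2)
        # pseudocount breaks exact ratio invariance at the 1e-3 level only
        assert np.allclose(gs["log2fc"], gs2["log2fc"], atol=0.01)
        rho = stats.spearmanr(gs["p_dep"], gs2["p_dep"]).statistic
        assert rho > 0.9999
        assert np.abs(gs["p_dep"] - gs2["p_dep"]).max() < 0.02


class TestWindows:
    def test_candidate_window_grid(self):
        wins = scoring.candidate_windows(0, 400)
        assert wins == [(0, 100), (50, 150), (100, 200), (150, 250),
                        (200, 300), (250, 350), (300, 400)]

    def test_rra_score_bounds_and_best_window(self):
        """The window holding the library's best-ranked guides attains the
        smallest RRA score in its region."""
        n = 100
        gs = pd.DataFrame(
            {
                "guide_id": [f"g{i}" for i in range(n)],
                "p_dep": np.linspace(0.001, 0.999, n),
                "log2fc": 0.0,
                "cut_site": np.arange(n) * 10 + 5,
            }
        )
        perc = scoring.rank_percentiles(gs)
        region = TargetRegion("r", "c", 0, 400)
        wdf = scoring.window_aggregate(
            region, gs, perc, n_perm=200, seed=0, exact_limit=0
        )
        assert ((wdf["rra_score"] >= 0) & (wdf["rra_score"] <= 1)).all()
        best_window = wdf.sort_values("rra_score").iloc[0]
        assert best_window["start"] == 0  # holds the lowest percentiles

    def test_improving_a_member_rank_never_hurts(self, rng):
        gate = 0.4
        for _ in range(200):
            m = int(rng.integers(2, 8))
            perc = np.sort(rng.random(m))
            base = scoring.rra_score(perc, gate)
            j = int(rng.integers(0, m))
            better = perc.copy()
            better[j] *= rng.random()
            assert scoring.rra_score(better, gate) <= base + 1e-12

    def test_permutation_p_matches_exhaustive_enumeration(self):
        pool = (np.arange(1, 31)) / 30.0
        gate = 0.5
        obs_sets = [pool[:4], pool[[0, 9, 19, 29]], pool[-4:]]
        for obs in obs_sets:
            score = scoring.rra_score(obs, gate)
            exact = scoring.window_permutation_p(
                score, 4, pool, gate, exact_limit=10**6
            )
            mc = scoring.window_permutation_p(
                score, 4, pool, gate, n_perm=20_000,
                rng=np.random.default_rng(1), exact_limit=0,
            )
            assert abs(exact - mc) <= 0.01

    def test_region_p_is_min_of_window_p(self, screen_setup):
        cfg = screen_setup["config"]
        lib = screen_setup["library"]
        cm, _ = simulate.simulate_screen_counts(lib, cfg)
        res = scoring.score_screen(
            cm, lib.guides, screen_setup["regions"], n_perm=200, seed=0
        )
        wins = res["windows"]
        for _, row in res["regions"].iterrows():
            if row["n_windows"] == 0:
                assert row["p_region"] == 1.0
                continue
            grp = wins[wins["region_id"] == row["region_id"]]
            assert row["p_region"] == pytest.approx(grp["p_window"].min())


class TestPipelineRecovery:
    def test_planted_region_ranks_first(self, screen_setup):
        cfg = screen_setup["config"]
        lib = screen_setup["library"]
        regions = screen_setup["regions"]
        hits = 0
        for seed in range(20):
            cm, _ = simulate.simulate_screen_counts(lib, replace(cfg, seed=seed))
            res = scoring.score_screen(cm, lib.guides, regions, n_perm=200, seed=seed)
            ranked = res["regions"].sort_values(
                "depletion_score", ascending=False
            ).reset_index(drop=True)
            rank = int(ranked.index[ranked["region_id"] == "region_0000"][0]) + 1
            hits += rank <= max(1, int(0.05 * len(ranked)))
        assert hits >= 18  # >= 90% of seeds

    def test_null_region_rank_is_unremarkable(self, screen_setup):
        cfg = replace(screen_setup["config"], planted_effects={})
        lib = screen_setup["library"]
        regions = screen_setup["regions"]
        ranks = []
        for seed in range(20):
            cm, _ = simulate.simulate_screen_counts(lib, replace(cfg, seed=seed))
            res = scoring.score_screen(cm, lib.guides, regions, n_perm=200, seed=seed)
            ranked = res["regions"].sort_values(
                "depletion_score", ascending=False
            ).reset_index(drop=True)
            ranks.append(int(ranked.index[ranked["region_id"] == "region_0000"][0]) + 1)
        # mean rank of 20 uniform draws over 1..20 is 10.5 +- ~1.3
        assert 6.0 <= np.mean(ranks) <= 15.0
        assert len(set(ranks)) > 3


class TestGroupComparison:
    def test_self_comparison_zero_distance(self, rng):
        vals = rng.random(50)
        _, ks = scoring.group_depletion_comparison({"a": vals, "b": vals})
        assert ks["ks_d"].iloc[0] == 0.0

    def test_ks_matches_bruteforce_sup_difference(self, rng):
        a = rng.uniform(0, 1, 200)
        b = rng.uniform(0, 0.5, 200)
        _, ks = scoring.group_depletion_comparison({"a": a, "b": b})
        grid = np.unique(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert ks["ks_d"].iloc[0] == pytest.approx(np.abs(ecdf_a - ecdf_b).max())

    def test_planted_essentials_separate_from_insensitive(self, screen_setup):
        cfg = screen_setup["config"]
        lib = screen_setup["library"]
        cm, truth = simulate.simulate_screen_counts(lib, cfg)
        gs = scoring.guide_depletion_test(cm).merge(truth, on="guide_id")
        groups = {
            "essential": gs.loc[gs["true_log2fc"] < 0, "p_dep"],
            "insensitive": gs.loc[gs["true_log2fc"] == 0, "p_dep"],
        }
        _, ks = scoring.group_depletion_comparison(groups)
        assert ks["p"].iloc[0] < 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 5"):
            scoring.group_depletion_comparison({"a": [0.1] * 5, "b": [0.2] * 3})
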