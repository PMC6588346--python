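"""Phenotype calculation, Mann-Whitney null, gene aggregation, hit calling."""

import itertools
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

import facscreen as fs
from facscreen.stats import StatsError
from conftest import make_counts


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive enumeration of the Mann-Whitney U null.


@lru_cache(maxsize=None)
def exact_u_distribution(n: int, m: int) -> np.ndarray:
    """counts[u] = number of labelings of ranks 1..n+m giving U_x = u."""
    counts = np.zeros(n * m + 1, dtype=np.int64)
    base = n * (n + 1) // 2
    for combo in itertools.combinations(range(1, n + m + 1), n):
        counts[sum(combo) - base] += 1
    return counts


def enumeration_p(x, y) -> Fraction:
    """Two-sided exact p by brute-force enumeration (tie-free data only).

    Returned as an exact rational so agreement can be checked without
    floating-point slack.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    u = sum((xi > y).sum() for xi in x)
    dist = exact_u_distribution(len(x), len(y))
    total = int(dist.sum())
    lo = Fraction(int(dist[: u + 1].sum()), total)
    hi = Fraction(int(dist[u:].sum()), total)
    return min(Fraction(1), 2 * min(lo, hi))


def matches_enumeration_exactly(p: float, x, y) -> bool:
    """True when the float p is the enumeration rational to the last ulp.

    Distinct attainable p-values are spaced at least 1/C(n+m,n)^2 apart,
    orders of magnitude above float rounding error, so snapping the float
    back to the nearest rational with the null's denominator is an exact
    comparison.
    """
    denominator = comb(len(x) + len(y), len(x))
    return Fraction(p).limit_denominator(2 * denominator) == \
        enumeration_p(x, y)


class TestMannWhitney:
    def test_complete_separation_five_vs_ten(self):
        p = fs.mann_whitney_p(np.arange(1, 6), np.arange(6, 16))
        assert p == 2 / comb(15, 5)
        assert matches_enumeration_exactly(p, np.arange(1, 6),
                                           np.arange(6, 16))

    def test_interleaved_pair_clamps_to_one(self):
        assert fs.mann_whitney_p([1, 4], [2, 3]) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsError):
            fs.mann_whitney_p([], [1.0])
        with pytest.raises(StatsError):
            fs.mann_whitney_p([1.0], [])

    @pytest.mark.parametrize("m", [5, 6, 7, 8])
    def test_matches_enumeration_for_random_tie_free_inputs(self, m):
        rng = np.random.default_rng(100 + m)
        for _ in range(60):
            pooled = rng.permutation(5 + m).astype(float)
            x, y = pooled[:5], pooled[5:]
            assert matches_enumeration_exactly(fs.mann_whitney_p(x, y), x, y)

    def test_large_samples_fall_back_to_normal_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=5), rng.normal(size=100)  # C(105,5) > 2e5
        p = fs.mann_whitney_p(x, y)
        assert 0 < p <= 1

    def test_floor_applied(self):
        x = np.arange(200.0)
        y = np.arange(300.0, 600.0)
        assert fs.mann_whitney_p(x, y, p_floor=1e-16) == 1e-16

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_two_sided_p_invariant_under_sign_flip(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=5), rng.normal(size=7)
        assert fs.mann_whitney_p(x, y) == pytest.approx(
            fs.mann_whitney_p(-x, -y), rel=1e-12)


class TestSgrnaPhenotypes:
    def test_equal_counts_give_zero(self, toy_design):
        hi, lo = make_counts(toy_design, 100, 100)
        ph = fs.sgrna_phenotypes(hi, lo, toy_design)
        assert np.allclose(ph.value, 0.0)

    def test_fourfold_abundance_gives_two(self, toy_design):
        """One sgRNA at 4x relative abundance in high vs low -> log2 4 = 2;
        controls sit at 0 so centering does not move it."""
        n = toy_design.n_sgrnas
        hi = np.full(n, 99)
        lo = np.full(n, 99)
        hi[0], lo[0] = 399, 99  # post-pseudocount 400 vs 100
        hi[1], lo[1] = 99, 399  # keeps the two bin totals equal
        cfg = fs.StatsConfig(center_on_controls=False)
        ph = fs.sgrna_phenotypes(*make_counts(toy_design, hi, lo),
                                 toy_design, cfg)
        # identical totals, so depth terms cancel
        assert ph.value.iloc[0] == pytest.approx(2.0, abs=1e-9)
        assert ph.value.iloc[1] == pytest.approx(-2.0, abs=1e-9)

    def test_centering_subtracts_control_median(self, toy_design):
        n = toy_design.n_sgrnas
        hi = np.full(n, 10)
        ctrl_mask = toy_design.df.is_control.to_numpy()
        hi[ctrl_mask] = 20       # controls shifted up
        hi[0] = 80
        cfg_raw = fs.StatsConfig(center_on_controls=False)
        cfg_cen = fs.StatsConfig(center_on_controls=True)
        raw = fs.sgrna_phenotypes(*make_counts(toy_design, hi, 10),
                                  toy_design, cfg_raw)
        cen = fs.sgrna_phenotypes(*make_counts(toy_design, hi, 10),
                                  toy_design, cfg_cen)
        ctrl_median = np.median(raw.value[ctrl_mask])
        assert np.allclose(cen.value, raw.value - ctrl_median)

    def test_arm_mismatch_rejected(self, toy_design):
        hi, _ = make_counts(toy_design, 10, 10, arm="tm")
        _, lo = make_counts(toy_design, 10, 10, arm="tm_ceapin")
        with pytest.raises(StatsError, match="arm mismatch"):
            fs.sgrna_phenotypes(hi, lo, toy_design)

    def test_centering_requires_controls(self, toy_design):
        targeted = fs.LibraryDesign(
            toy_design.df[~toy_design.df.is_control].drop(
                columns="is_control"))
        hi, lo = make_counts(targeted, 10, 10)
        with pytest.raises(StatsError, match="negative-control"):
            fs.sgrna_phenotypes(hi, lo, targeted)

    def test_min_reads_filter(self, toy_design):
        n = toy_design.n_sgrnas
        hi = np.full(n, 50)
        lo = np.full(n, 50)
        hi[0], lo[0] = 2, 1
        cfg = fs.StatsConfig(min_reads=10)
        ph = fs.sgrna_phenotypes(*make_counts(toy_design, hi, lo),
                                 toy_design, cfg)
        assert not ph.passed_filter.iloc[0]
        assert ph.passed_filter.iloc[1:].all()

    @given(st.integers(2, 1000))
    @settings(max_examples=25, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_depth_invariance(self, toy_design, scale):
        """Rescaling both bins by any constant (pseudocount alongside)
        leaves every phenotype unchanged."""
        rng = np.random.default_rng(42)
        hi = rng.integers(1, 500, toy_design.n_sgrnas)
        lo = rng.integers(1, 500, toy_design.n_sgrnas)
        ph1 = fs.sgrna_phenotypes(*make_counts(toy_design, hi, lo),
                                  toy_design, fs.StatsConfig(pseudocount=1.0))
        ph2 = fs.sgrna_phenotypes(
            *make_counts(toy_design, hi * scale, lo * scale),
            toy_design, fs.StatsConfig(pseudocount=float(scale)))
        assert np.allclose(ph1.value, ph2.value)


class TestGeneStats:
    def test_score_formula(self):
        """rho=1, sigma=0.25, p=0.01 -> |4 * (-2)| = 8 > tau=7 -> hit."""
        from facscreen.stats import _score
        score = _score(np.array([1.0]), 0.25, np.array([0.01]), 1e-16)
        assert score[0] == pytest.approx(8.0, abs=1e-12)
        assert score[0] > 7.0

    def test_p_one_or_rho_zero_scores_zero(self):
        from facscreen.stats import _score
        assert _score(np.array([5.0]), 0.3, np.array([1.0]), 1e-16)[0] == 0.0
        assert _score(np.array([0.0]), 0.3, np.array([1e-5]), 1e-16)[0] == 0.0

    def test_identical_bins_all_zero_no_hits(self, toy_design):
        hi, lo = make_counts(toy_design, 100, 100)
        _, gs = fs.analyze_arm(hi, lo, toy_design)
        assert np.allclose(gs.rho, 0.0)
        assert np.allclose(gs.score, 0.0)
        assert not gs.hit.any()

    def test_swapping_bins_negates_rho_preserves_p_and_score(
            self, toy_design):
        rng = np.random.default_rng(9)
        hi = rng.integers(50, 500, toy_design.n_sgrnas)
        lo = rng.integers(50, 500, toy_design.n_sgrnas)
        h, l = make_counts(toy_design, hi, lo)
        swapped_h, swapped_l = make_counts(toy_design, lo, hi)
        _, gs1 = fs.analyze_arm(h, l, toy_design)
        _, gs2 = fs.analyze_arm(swapped_h, swapped_l, toy_design)
        assert np.allclose(gs1.rho, -gs2.rho)
        assert np.allclose(gs1.p, gs2.p)
        assert np.allclose(gs1.score, gs2.score)
        assert (gs1.hit == gs2.hit).all()

    def test_depth_rescaling_leaves_gene_stats_unchanged(self, toy_design):
        rng = np.random.default_rng(10)
        hi = rng.integers(50, 500, toy_design.n_sgrnas)
        lo = rng.integers(50, 500, toy_design.n_sgrnas)
        _, gs1 = fs.analyze_arm(*make_counts(toy_design, hi, lo), toy_design,
                                fs.StatsConfig(pseudocount=1.0))
        _, gs2 = fs.analyze_arm(*make_counts(toy_design, hi * 7, lo * 7),
                                toy_design, fs.StatsConfig(pseudocount=7.0))
        pd.testing.assert_frame_equal(gs1, gs2)

    def test_permuting_gene_labels_permutes_stats(self, toy_design):
        """Swapping the two genes' sgRNA blocks swaps their statistics."""
        rng = np.random.default_rng(11)
        hi = rng.integers(50, 500, toy_design.n_sgrnas)
        lo = rng.integers(50, 500, toy_design.n_sgrnas)
        _, gs1 = fs.analyze_arm(*make_counts(toy_design, hi, lo), toy_design)
        df = toy_design.df.copy()
        df["target"] = df["target"].map(
            {"g0": "g1", "g1": "g0"}).fillna(df["target"])
        df["tss"] = df["target"]
        relabeled = fs.LibraryDesign(df.drop(columns="is_control"))
        _, gs2 = fs.analyze_arm(*make_counts(relabeled, hi, lo), relabeled)
        a = gs1.set_index("gene")
        b = gs2.set_index("gene")
        for stat in ("rho", "p", "score"):
            assert a.loc["g0", stat] == pytest.approx(b.loc["g1", stat])
            assert a.loc["g1", stat] == pytest.approx(b.loc["g0", stat])

    def test_fully_filtered_gene_flagged_not_hit(self, toy_design):
        n = toy_design.n_sgrnas
        hi = np.full(n, 100)
        lo = np.full(n, 120)
        g0 = toy_design.df.target.to_numpy() == "g0"
        hi[g0] = 0
        lo[g0] = 0
        cfg = fs.StatsConfig(min_reads=5)
        _, gs = fs.analyze_arm(*make_counts(toy_design, hi, lo), toy_design,
                               cfg)
        row = gs.set_index("gene").loc["g0"]
        assert row.n_used == 0 and not row.hit and row.score == 0.0

    def test_sigma_zero_with_nonzero_rho_is_degenerate(self, toy_design):
        ph = pd.DataFrame({
            "arm": "tm",
            "sgrna_id": toy_design.sgrna_ids,
            "value": np.where(toy_design.df.is_control, 0.0, 1.0),
            "passed_filter": True,
            "is_control": toy_design.df.is_control.to_numpy(),
        })
        cfg = fs.StatsConfig(sd_mode="all_genes")  # both genes rho=1 -> sd 0
        with pytest.raises(StatsError, match="degenerate"):
            fs.gene_stats(ph, toy_design, cfg, include_pseudogenes=False)


class TestPseudogenes:
    def test_partition_sizes_and_determinism(self):
        ids = [f"c{i}" for i in range(12)]
        groups = fs.control_pseudogenes(ids, 5, seed=3)
        assert len(groups) == 2
        members = [m for g in groups.values() for m in g]
        assert len(members) == len(set(members)) == 10  # disjoint, 2 dropped
        assert groups == fs.control_pseudogenes(ids, 5, seed=3)

    def test_null_pseudogene_rho_centered_on_zero(self, small_design,
                                                  small_params):
        """On centered null data the pseudogene phenotypes average ~0."""
        rhos = []
        for seed in range(8):
            small_params.seed = seed
            counts, _ = fs.simulate_screen(small_design, fs.EffectSpec.null(),
                                           small_params)
            _, gs = fs.analyze_arm(counts[("tm", "high")],
                                   counts[("tm", "low")], small_design)
            rhos.extend(gs.loc[gs.control, "rho"])
        assert abs(np.mean(rhos)) < 0.05
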