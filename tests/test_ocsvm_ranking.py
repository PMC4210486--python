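"""Signed-distance ranking, GC baseline, Spearman stability machinery."""

import itertools

import numpy as np
import pytest
from scipy.stats import wilcoxon

from alienscan.errors import ParameterError, ValidationError
from alienscan.feature_extraction import (
    FeatureMatrix,
    FeatureSpec,
    build_feature_matrix,
    get_spec,
    standardize,
)
from alienscan.ocsvm_ranking import (
    DEFAULT_NU,
    RULE_OF_THUMB,
    SvmParams,
    default_gamma_grid,
    default_nu_grid,
    gc_baseline_rank,
    neighbor_stability,
    rank_genes,
    rank_segments,
    resolve_gamma,
    spearman_rho,
    stability_sweep,
)
from alienscan.sequence_io import Segment
from alienscan.synthetic_data import generate_benchmark

from conftest import make_family


def spearman_oracle(a, b):
    """Brute-force Spearman for tie-free rankings: 1 - 6*sum(d^2)/(n(n^2-1))."""
    n = len(a)
    rank_a = sorted(range(n), key=lambda i: a[i])
    rank_b = sorted(range(n), key=lambda i: b[i])
    pos_a = {i: r for r, i in enumerate(rank_a)}
    pos_b = {i: r for r, i in enumerate(rank_b)}
    d2 = sum((pos_a[i] - pos_b[i]) ** 2 for i in range(n))
    return 1 - 6 * d2 / (n * (n**2 - 1))


def _standardized_matrix(values, dim=None):
    """Wrap a raw array as a standardized FeatureMatrix with an ad-hoc spec."""
    values = np.asarray(values, dtype=float)
    spec = FeatureSpec("custom", None, values.shape[1])
    ids = [f"g{i}" for i in range(values.shape[0])]
    return FeatureMatrix(spec, ids, values, standardized=True)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

class TestParams:
    def test_rule_of_thumb_gc(self):
        assert resolve_gamma(get_spec("gc"), RULE_OF_THUMB) == 0.5

    def test_rule_of_thumb_tetra(self):
        assert resolve_gamma(get_spec("tetra"), RULE_OF_THUMB) == 1 / 512

    def test_numeric_passthrough(self):
        assert resolve_gamma(get_spec("di"), 0.01) == 0.01

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ParameterError):
            resolve_gamma(get_spec("di"), -1.0)
        with pytest.raises(ParameterError):
            SvmParams(nu=0.2, gamma=0.0)

    def test_invalid_nu_rejected(self):
        for nu in (0.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                SvmParams(nu=nu)

    def test_shipped_defaults(self):
        p = SvmParams()
        assert p.nu == DEFAULT_NU == 0.2
        assert p.gamma == RULE_OF_THUMB

    def test_nu_grid_spacing(self):
        grid = default_nu_grid()
        assert len(grid) == 1000
        assert grid[0] == pytest.approx(0.001)
        assert grid[-1] == 1.0
        assert np.allclose(np.diff(grid), 0.001, atol=1e-12)

    def test_gamma_grid_values(self):
        grid = default_gamma_grid(get_spec("tetra"))
        assert grid == [1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.1, 1.0, 10.0, 100.0, 1 / 512]


# ---------------------------------------------------------------------------
# rank_genes
# ---------------------------------------------------------------------------

class TestRankGenes:
    def test_requires_standardized(self, toy_family):
        fm = build_feature_matrix(toy_family, get_spec("mono"))
        with pytest.raises(ValidationError):
            rank_genes(fm)

    def test_duplicated_rows_equal_scores_adjacent_ranks(self, rng):
        X = rng.normal(size=(20, 3))
        X[7] = X[3]  # duplicate row
        fm = _standardized_matrix(X)
        r = rank_genes(fm, SvmParams(nu=0.3, gamma=0.2))
        pos3, pos7 = r.ranked_gene_ids.index("g3"), r.ranked_gene_ids.index("g7")
        assert abs(pos3 - pos7) == 1
        assert r.signed_distance[pos3] == pytest.approx(r.signed_distance[pos7], abs=1e-9)

    def test_far_outliers_take_top_ranks_parzen_oracle(self, rng):
        gamma = 0.5
        inliers = rng.normal(scale=0.5, size=(95, 2))
        outliers = rng.normal(loc=6.0, scale=0.5, size=(5, 2))
        X = np.vstack([inliers, outliers])
        fm = _standardized_matrix(X)
        r = rank_genes(fm, SvmParams(nu=0.2, gamma=gamma))
        top5 = set(r.ranked_gene_ids[:5])
        # Parzen window oracle: lowest kernel density = most atypical
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
        density = np.exp(-gamma * d2).sum(axis=1)
        lowest = {f"g{i}" for i in np.argsort(density)[:5]}
        assert top5 == lowest == {f"g{i}" for i in range(95, 100)}

    def test_distances_ascending_with_rank(self, rng):
        fm = _standardized_matrix(rng.normal(size=(30, 4)))
        r = rank_genes(fm, SvmParams(nu=0.2, gamma=0.1))
        assert np.all(np.diff(r.signed_distance) >= 0)
        assert r.signed_distance.min() < 0  # some genes fall outside the boundary

    def test_row_permutation_equivariance(self, rng):
        X = rng.normal(size=(40, 5))
        fm = _standardized_matrix(X)
        r1 = rank_genes(fm, SvmParams(nu=0.25, gamma=0.1))
        perm = rng.permutation(40)
        fm2 = FeatureMatrix(fm.spec, [f"g{i}" for i in perm], X[perm], standardized=True)
        r2 = rank_genes(fm2, SvmParams(nu=0.25, gamma=0.1))
        d1 = dict(zip(r1.ranked_gene_ids, r1.signed_distance))
        d2 = dict(zip(r2.ranked_gene_ids, r2.signed_distance))
        assert all(abs(d1[g] - d2[g]) < 1e-9 for g in d1)
        # the induced rankings are identical
        order2 = [g for g in r2.ranked_gene_ids]
        assert spearman_rho([d1[g] for g in order2], [d2[g] for g in order2]) == 1.0


# ---------------------------------------------------------------------------
# GC baseline
# ---------------------------------------------------------------------------

def _family_with_gc(gc_values):
    seqs = []
    for gc in gc_values:
        n = 20
        g = round(gc * n)
        seqs.append("G" * g + "A" * (n - g))
    return make_family(seqs)


class TestGcBaseline:
    def test_symmetric_deviations_top_two(self):
        ds = _family_with_gc([0.30, 0.50, 0.50, 0.50, 0.70])
        r = gc_baseline_rank(ds)
        assert set(r.ranked_gene_ids[:2]) == {"g1", "g5"}

    def test_all_identical_gc_ingest_order(self):
        ds = _family_with_gc([0.5, 0.5, 0.5, 0.5])
        r = gc_baseline_rank(ds)
        assert r.ranked_gene_ids == ["g1", "g2", "g3", "g4"]

    def test_matches_brute_force_sort(self):
        gcs = [0.1, 0.4, 0.5, 0.6, 0.65]
        ds = _family_with_gc(gcs)
        r = gc_baseline_rank(ds)
        med = np.median(gcs)
        # brute-force oracle: stable sort by decreasing |gc - median|
        oracle = [f"g{i+1}" for i in
                  sorted(range(5), key=lambda i: (-abs(gcs[i] - med), i))]
        assert r.ranked_gene_ids == oracle
        assert np.all(np.diff(r.signed_distance) >= 0)


# ---------------------------------------------------------------------------
# Spearman / stability
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_identical_permutations(self):
        p = list(range(10))
        assert spearman_rho(p, p) == 1.0

    def test_reversal(self):
        p = list(range(10))
        assert spearman_rho(p, p[::-1]) == -1.0

    def test_single_adjacent_swap(self):
        assert spearman_rho([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(0.8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            spearman_rho([1, 2, 3], [1, 2])

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_matches_oracle_on_all_permutations(self, n):
        identity = list(range(n))
        for perm in itertools.permutations(range(n)):
            assert spearman_rho(identity, list(perm)) == pytest.approx(
                spearman_oracle(identity, list(perm))
            )

    def test_matches_oracle_on_permutation_pairs(self):
        perms = list(itertools.permutations(range(4)))
        for a in perms:
            for b in perms:
                assert spearman_rho(list(a), list(b)) == pytest.approx(
                    spearman_oracle(list(a), list(b))
                )


class TestNeighborStability:
    def test_identical_rankings_give_one(self):
        v = np.arange(8.0)
        rho = neighbor_stability([v, v.copy(), v.copy()])
        assert np.allclose(rho, 1.0)  # boundaries use their single neighbour

    def test_reversed_middle_gives_minus_one(self):
        v = np.arange(8.0)
        rho = neighbor_stability([v, v[::-1].copy(), v.copy()])
        assert rho[1] == pytest.approx(-1.0)
        assert rho[0] == pytest.approx(-1.0)  # boundary: its only neighbour reversed

    def test_missing_points_recorded_not_fatal(self):
        v = np.arange(6.0)
        rho = neighbor_stability([v, None, v.copy()])
        assert np.isnan(rho[1])
        assert np.isnan(rho[0]) and np.isnan(rho[2])  # only neighbour missing


class TestStabilitySweep:
    def test_shapes_and_coverage(self, rng):
        fm = _standardized_matrix(rng.normal(size=(25, 3)))
        nu_grid = np.array([0.1, 0.2, 0.3, 0.4])
        profiles = stability_sweep(fm, gamma_grid=[0.1, 1.0], nu_grid=nu_grid)
        assert [p.gamma for p in profiles] == [0.1, 1.0]
        for p in profiles:
            assert p.rho.shape == (4,)
            assert 0.0 <= p.coverage <= 1.0

    def test_order_independent(self, rng):
        fm = _standardized_matrix(rng.normal(size=(20, 3)))
        nu_grid = np.array([0.2, 0.3, 0.4])
        a = stability_sweep(fm, gamma_grid=[0.05, 0.5], nu_grid=nu_grid)
        b = stability_sweep(fm, gamma_grid=[0.5, 0.05], nu_grid=nu_grid)
        by_gamma_a = {p.gamma: p.rho for p in a}
        by_gamma_b = {p.gamma: p.rho for p in b}
        for g in (0.05, 0.5):
            assert np.allclose(by_gamma_a[g], by_gamma_b[g], equal_nan=True)

    def test_rule_of_thumb_high_nu_more_stable_than_large_gamma_small_nu(self):
        """Qualitative stability trend: the 1/(2D) rule at large nu beats
        gamma=100 at small nu, consistently across synthetic families."""
        high = np.array([0.899, 0.900, 0.901])
        low = np.array([0.049, 0.050, 0.051])
        rot_vals, big_vals = [], []
        for s in range(10):
            fams = generate_benchmark(2, 1.0, 40, seed=100 + s)
            fm = standardize(build_feature_matrix(fams[0], get_spec("di")))
            rot = resolve_gamma(fm.spec, RULE_OF_THUMB)
            rho_rot = stability_sweep(fm, gamma_grid=[rot], nu_grid=high)[0].rho[1]
            rho_big = stability_sweep(fm, gamma_grid=[100.0], nu_grid=low)[0].rho[1]
            rot_vals.append(rho_rot)
            big_vals.append(rho_big)
        stat = wilcoxon(rot_vals, big_vals, alternative="greater")
        assert stat.pvalue < 0.05


# ---------------------------------------------------------------------------
# Segment ranking
# ---------------------------------------------------------------------------

def _segments_from(seq, window, step, genome="G"):
    from alienscan.sequence_io import sliding_window

    return sliding_window(seq, window, step, source_genome=genome)


class TestRankSegments:
    def test_self_mode_equals_rank_genes(self, rng):
        fams = generate_benchmark(2, 1.0, 6, seed=2)
        genome = "".join(g.seq for g in fams[0].genes)
        segs = _segments_from(genome, 300, 300)
        spec = get_spec("tetra")
        params = SvmParams(nu=0.2, gamma=0.01)
        r_self = rank_segments(segs, "self", spec, params)
        # oracle: encode the segments as a matrix and rank directly
        from alienscan.feature_extraction import encode

        X = np.vstack([encode(s.seq, spec) for s in segs])
        fm = standardize(
            FeatureMatrix(spec, [s.segment_id for s in segs], X)
        )
        r_direct = rank_genes(fm, params)
        assert r_self.ranked_gene_ids == r_direct.ranked_gene_ids
        assert np.allclose(r_self.signed_distance, r_direct.signed_distance, atol=1e-9)

    def test_centroid_like_segment_ranks_last(self):
        # unimodal background around a balanced composition: a segment at
        # the compositional centroid is the most typical (ranks last),
        # confirmed by a Parzen density oracle on the standardized rows
        ds = make_family(
            ["ATGCATGCATGC", "ATGCATGCATGA", "ATGCATGCATGG",
             "ATGCATGCATCC", "TTGCATGCATGC", "AAGCATGCATGC"]
        )
        segs = [
            Segment("balanced", "t", 0, 12, "ATGCATGCATGC"),
            Segment("extremeAT", "t", 0, 12, "ATATATATATAT"),
            Segment("extremeGC", "t", 0, 12, "GCGCGCGCGCGC"),
        ]
        spec = get_spec("mono")
        gamma = 0.5
        r = rank_segments(segs, ds, spec, SvmParams(nu=0.5, gamma=gamma))
        assert r.ranked_gene_ids[-1] == "balanced"
        # density oracle agrees on which segment is most typical
        from alienscan.feature_extraction import apply_standardization, encode

        bg = standardize(build_feature_matrix(ds, spec))
        seg_rows = apply_standardization(
            np.vstack([encode(s.seq, spec) for s in segs]), bg.center, bg.scale
        )
        d2 = ((seg_rows[:, None, :] - bg.values[None, :, :]) ** 2).sum(-1)
        density = np.exp(-gamma * d2).sum(axis=1)
        assert segs[int(np.argmax(density))].segment_id == "balanced"

    def test_alien_segment_tops_family_background(self):
        fams = generate_benchmark(2, 1.0, 30, seed=11)
        family, alien_family = fams
        genome = "".join(g.seq for g in family.genes[:5])
        segs = _segments_from(genome, 500, 500)
        alien_seq = "".join(g.seq for g in alien_family.genes[:2])[:500]
        segs = segs + [Segment("alien", "t", 0, 500, alien_seq)]
        r = rank_segments(segs, family, get_spec("tetra"), SvmParams())
        assert r.ranked_gene_ids[0] == "alien"

    def test_background_too_small(self):
        ds = make_family(["ATATATATATAT"] * 3)
        segs = [Segment("s", "t", 0, 12, "ATGCATGCATGC")]
        with pytest.raises(Exception):
            rank_segments(segs, ds, get_spec("mono"), SvmParams())
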