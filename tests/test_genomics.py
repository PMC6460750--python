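import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import orchard_gblup as og
from orchard_gblup.genomics import (
    EmptyFilterError,
    FilterThresholds,
    GenotypeMatrix,
    LDDecayCurve,
    pairwise_r2,
)


def make_geno(dosages, chrom=None, pos=None, qa=None, qb=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = [f"i{k}" for k in range(n)]
    markers = [f"m{k}" for k in range(m)]
    meta = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["chr1"] * m,
            "pos": pos if pos is not None else np.arange(1, m + 1) * 100,
            "qa": qa if qa is not None else np.ones(m),
            "qb": qb if qb is not None else np.ones(m),
        },
        index=markers,
    )
    return GenotypeMatrix(ids, markers, dosages, meta)


class TestGenotypeMatrix:
    def test_rejects_bad_dosage(self):
        with pytest.raises(ValueError, match="0/1/2"):
            make_geno([[0, 3]])

    def test_maf_and_callrate_from_observed(self):
        g = make_geno([[0, np.nan], [1, 2], [2, 2], [np.nan, 2]])
        assert g.call_rate() == pytest.approx([0.75, 0.75])
        assert g.allele_frequency() == pytest.approx([0.5, 1.0])
        assert g.maf() == pytest.approx([0.5, 0.0])


class TestFilterMarkers:
    def test_maf_rule(self):
        # 100 individuals: MAF 0.005 fails the "> 0.01" rule
        d = np.zeros((100, 2))
        d[0, 0] = 1  # MAF 0.005
        d[:50, 1] = 1  # MAF 0.25
        g = make_geno(d)
        out, rep = og.filter_markers(g)
        assert rep.removed["maf"] == 1
        assert out.marker_ids == ["m1"]

    def test_call_rate_rule(self):
        d = np.ones((10, 2))
        d[::2, 1] = 0  # polymorphic survivor
        d[:5, 0] = np.nan  # call rate 0.5 fails "> 0.6"
        d[5:, 0] = [0, 1, 0, 1, 0]
        g = make_geno(d)
        out, rep = og.filter_markers(g)
        assert rep.removed["call_rate"] == 1
        assert "m0" not in out.marker_ids

    def test_hand_enumerated_toy(self):
        # 10 markers: 1 fails qa, 1 fails qb, 1 fails MAF, 1 fails call rate,
        # and m9 duplicates m8 (r2 = 1, pruned) -> 5 survivors
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(40, 10)).astype(float)
        base[:, 9] = base[:, 8]  # duplicate column -> r2 = 1
        base[:20, 3] = np.nan  # call rate 0.5
        base[:, 2] = 0.0
        base[0, 2] = 1.0  # MAF 1/80 = 0.0125 > 0.01 ... make it fail:
        base[:, 2] = 0.0  # monomorphic -> MAF 0 fails
        qa = np.ones(10); qa[0] = 0.4
        qb = np.ones(10); qb[1] = 0.1
        g = make_geno(base, qa=qa, qb=qb)
        out, rep = og.filter_markers(g)
        assert rep.n_input == 10
        assert rep.removed["quality_a"] == 1
        assert rep.removed["quality_b"] == 1
        assert rep.removed["maf"] == 1
        assert rep.removed["call_rate"] == 1
        assert rep.removed["ld"] == 1
        assert rep.n_pass == 5
        assert set(out.marker_ids) == {"m4", "m5", "m6", "m7", "m8"}

    def test_per_marker_rules_order_independent(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(30, 20)).astype(float)
        qa = rng.uniform(size=20)
        qb = rng.uniform(size=20)
        g = make_geno(d, qa=qa, qb=qb)
        t = FilterThresholds(ld_r2=1.1 if False else 1.0)  # disable pruning via r2=1 cap
        # survivors from applying the four per-marker rules in any order match
        keep_ref = (qa > t.quality_a) & (qb > t.quality_b) & (g.maf() > t.maf) & (
            g.call_rate() > t.call_rate
        )
        out, rep = og.filter_markers(g, t)
        got = np.isin(g.marker_ids, out.marker_ids)
        # LD pruning with threshold 1.0 removes only exact duplicates
        dup_removed = keep_ref & ~got
        assert rep.removed["ld"] == dup_removed.sum()
        assert not (got & ~keep_ref).any()

    def test_all_removed_errors(self):
        g = make_geno([[0, 0], [0, 0]])  # monomorphic: MAF rule removes all
        with pytest.raises(EmptyFilterError):
            og.filter_markers(g)


class TestImputeEM:
    def test_no_missing_unchanged(self):
        d = np.array([[0.0, 1], [2, 1], [1, 0]])
        g = make_geno(d)
        out = og.impute_em(g)
        assert np.array_equal(out.dosages, d)
        assert out.imputation_converged

    def test_constant_column_fixed_point(self):
        d = np.array([[2.0, 0], [2, 1], [np.nan, 2], [2, 1]])
        out = og.impute_em(make_geno(d))
        assert out.dosages[2, 0] == pytest.approx(2.0, abs=1e-6)

    def test_observed_entries_never_move(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(30, 40)).astype(float)
        mask = rng.uniform(size=d.shape) < 0.1
        dm = d.copy()
        dm[mask] = np.nan
        out = og.impute_em(make_geno(dm))
        assert np.array_equal(out.dosages[~mask], d[~mask])
        assert np.all((out.dosages >= 0) & (out.dosages <= 2))

    def test_all_missing_marker_rejected(self):
        d = np.array([[np.nan, 1.0], [np.nan, 2.0]])
        with pytest.raises(ValueError, match="no observed"):
            og.impute_em(make_geno(d))

    def test_beats_mean_imputation_with_structure(self, small_population):
        pop = small_population
        D = pop.complete_dosages
        rng = np.random.default_rng(42)
        mask = rng.uniform(size=D.shape) < 0.1
        dm = D.copy()
        dm[mask] = np.nan
        g = GenotypeMatrix(
            pop.genotypes.individual_ids, pop.genotypes.marker_ids, dm,
            pop.genotypes.marker_meta,
        )
        out = og.impute_em(g)
        em = np.sqrt(np.mean((out.dosages[mask] - D[mask]) ** 2))
        cm = np.where(np.isnan(dm), np.nanmean(dm, axis=0)[None, :], dm)
        mean_rmse = np.sqrt(np.mean((cm[mask] - D[mask]) ** 2))
        assert em < mean_rmse


class TestComputeG:
    def test_mean_diag_is_one(self, small_population):
        g = og.impute_em(small_population.genotypes)
        G = og.compute_G(g)
        assert np.diag(G.values).mean() == pytest.approx(1.0, abs=1e-12)

    def test_identical_rows(self):
        d = np.array([[0.0, 2, 1], [0, 2, 1], [2, 0, 1], [1, 1, 2]])
        G = og.compute_G(make_geno(d)).to_frame()
        assert G.loc["i0", "i0"] == pytest.approx(G.loc["i0", "i1"])
        assert G.loc["i1", "i1"] == pytest.approx(G.loc["i0", "i1"])

    def test_hand_worked_three_by_two(self):
        # M = [[0,2],[1,1],[2,0]]: column means 1, Z = [[-1,1],[0,0],[1,-1]]
        # ZZ' = [[2,0,-2],[0,0,0],[-2,0,2]], trace 4, scale = 4/3
        M = np.array([[0.0, 2], [1, 1], [2, 0]])
        G = og.compute_G(make_geno(M)).values
        expect = np.array([[2, 0, -2], [0, 0, 0], [-2, 0, 2]]) / (4.0 / 3.0)
        assert G == pytest.approx(expect, abs=1e-12)

    def test_monomorphic_marker_leaves_G_unchanged(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(12, 30)).astype(float)
        G1 = og.compute_G(make_geno(d)).values
        d2 = np.column_stack([d, np.full(12, 2.0)])
        G2 = og.compute_G(make_geno(d2)).values
        assert G1 == pytest.approx(G2, abs=1e-12)

    def test_missing_rejected(self):
        d = np.array([[0.0, np.nan], [1, 1], [2, 0]])
        with pytest.raises(ValueError, match="impute"):
            og.compute_G(make_geno(d))

    def test_monomorphic_only_rejected(self):
        d = np.tile([[2.0, 0.0]], (4, 1))
        with pytest.raises(ValueError, match="polymorphic"):
            og.compute_G(make_geno(d))


class TestCompositeR2:
    def test_identical_columns(self):
        d = np.array([[0.0, 0], [1, 1], [2, 2], [1, 1]])
        g = make_geno(d)
        assert og.composite_r2(g, "m0", "m1") == pytest.approx(1.0)

    def test_allele_flip_invariance(self):
        d = np.array([[0.0, 2], [1, 1], [2, 0], [1, 1], [0, 2]])
        g = make_geno(d)
        assert og.composite_r2(g, "m0", "m1") == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, size=(25, 2)).astype(float)
        g = make_geno(d)
        assert og.composite_r2(g, "m0", "m1") == pytest.approx(
            og.composite_r2(g, "m1", "m0"), rel=1e-12
        )

    def test_zero_variance_is_nan_not_zero(self):
        d = np.array([[1.0, 0], [1, 1], [1, 2]])
        g = make_geno(d)
        assert np.isnan(og.composite_r2(g, "m0", "m1"))

    def test_null_bias_small(self):
        rng = np.random.default_rng(5)
        n = 10_000
        d = rng.binomial(2, 0.5, size=(n, 2)).astype(float)
        g = make_geno(d)
        # independent markers: E[r2] ~ 1/n
        assert og.composite_r2(g, "m0", "m1") < 0.001

    def test_pairwise_matches_scalar(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, size=(40, 5)).astype(float)
        d[rng.uniform(size=d.shape) < 0.15] = np.nan
        g = make_geno(d)
        R = pairwise_r2(d)
        for i in range(5):
            for j in range(5):
                expect = og.composite_r2(g, f"m{i}", f"m{j}")
                if np.isnan(expect):
                    assert np.isnan(R[i, j]) or i == j
                else:
                    assert R[i, j] == pytest.approx(expect, abs=1e-10)


class TestLDDecay:
    def test_interpolation_arithmetic(self):
        curve = LDDecayCurve([0, 2000, 4000], [0.50, 0.19], [10, 10])
        # midpoints 1 kb and 3 kb; interpolate 0.2 between them
        d = curve.decay_distance_at(0.2)
        assert 1000 < d < 3000
        assert d == pytest.approx(1000 + 2000 * (0.5 - 0.2) / (0.5 - 0.19))
        exact = LDDecayCurve([0, 2000, 4000], [0.50, 0.20], [10, 10])
        assert exact.decay_distance_at(0.2) == pytest.approx(3000)

    def test_perfect_ld_not_reached(self):
        d = np.tile([[0.0], [1], [2], [1]], (1, 6))
        pos = np.array([1, 500, 1500, 2500, 4000, 6000])
        g = make_geno(d, pos=pos)
        curve = og.ld_decay(g, max_distance_bp=8000, bin_width_bp=1000)
        assert np.nanmax(curve.mean_r2) == pytest.approx(1.0)
        assert curve.decay_distance_at(0.2) is None

    def test_no_pairs_errors(self):
        d = np.array([[0.0, 1], [1, 2], [2, 0]])
        g = make_geno(d, chrom=["chr1", "chr2"])
        with pytest.raises(ValueError, match="no intra-chromosome"):
            og.ld_decay(g, max_distance_bp=1000)

    def test_curve_frame_shape(self, small_population):
        g = og.impute_em(small_population.genotypes)
        curve = og.ld_decay(g, max_distance_bp=20_000, bin_width_bp=2000)
        df = curve.to_frame()
        assert list(df.columns) == ["bin_start", "bin_end", "mean_r2", "n_pairs"]
        ok = df["n_pairs"] > 0
        assert ((df.loc[ok, "mean_r2"] >= 0) & (df.loc[ok, "mean_r2"] <= 1)).all()


class TestSpectralDecomposition:
    def test_eigenvalue_sum_is_trace(self, small_population):
        g = og.impute_em(small_population.genotypes)
        G = og.compute_G(g)
        _, w = og.spectral_decomposition(G)
        assert w.sum() == pytest.approx(np.trace(G.values), abs=1e-8)

    def test_identity_degenerate(self):
        K = og.RelationshipMatrix([f"x{i}" for i in range(5)], np.eye(5), kind="G")
        scores, w = og.spectral_decomposition(K, 3)
        assert w == pytest.approx(np.ones(5))

    def test_asymmetric_rejected(self):
        K = og.RelationshipMatrix(["a", "b"], np.eye(2), kind="G")
        K.values = np.array([[1.0, 0.5], [0.1, 1.0]])  # break it after validation
        with pytest.raises(ValueError, match="symmetric"):
            og.spectral_decomposition(K)

    def test_orchards_separate(self, small_population):
        g = og.impute_em(small_population.genotypes)
        G = og.compute_G(g)
        scores, _ = og.spectral_decomposition(G, 2)
        labels = small_population.orchard_labels.loc[scores.index]
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression().fit(scores.to_numpy(), labels)
        assert clf.score(scores.to_numpy(), labels) > 0.9


@given(st.integers(2, 40), st.integers(2, 12), st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_property_G_scaling(n, m, seed):
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(n, m)).astype(float)
    if (d.var(axis=0) > 0).sum() < 2:
        return
    G = og.compute_G(make_geno(d))
    assert np.diag(G.values).mean() == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(G.values, G.values.T)
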