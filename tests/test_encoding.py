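import numpy as np
import pytest

from conftest import random_dataset
from traitpred.core import GenotypeMatrix, TraitVector
from traitpred.encoding import (
    EncodingError,
    traditional_encoding,
    fit_pure,
    fit_hybrid,
    fit_pairwise_hybrid,
    apply_encoding,
    apply_pair_encoding,
    product_epistasis,
)


def dataset(codes, traits):
    codes = np.atleast_2d(np.asarray(codes, dtype=np.int16).T).T
    if codes.shape[1] > codes.shape[0] and len(np.asarray(traits)) == codes.shape[1]:
        codes = codes.T
    n, m = codes.shape
    g = GenotypeMatrix([f"S{i}" for i in range(n)],
                       [f"M{j}" for j in range(m)], codes)
    t = TraitVector(g.sample_ids, traits)
    return g, t


def brute_force_class_means(codes_col, y, grand):
    out = []
    for c in (0, 1, 2):
        vals = [y[i] for i in range(len(y)) if codes_col[i] == c]
        out.append(np.asarray(vals).mean() if vals else grand)
    return out


class TestTraditional:
    def test_identity_scheme(self):
        g, _ = dataset([[0], [1], [2]], [0, 0, 1])
        table = traditional_encoding("{0,1,2}")
        X = apply_encoding(g, table)
        assert X.values.ravel().tolist() == [0.0, 1.0, 2.0]

    def test_shifted_scheme(self):
        g, _ = dataset([[0], [1], [2]], [0, 0, 1])
        X = apply_encoding(g, traditional_encoding("{-1,0,1}"))
        assert X.values.ravel().tolist() == [-1.0, 0.0, 1.0]

    def test_unknown_scheme(self):
        with pytest.raises(EncodingError, match="unknown scheme"):
            traditional_encoding("{0,1}")

    def test_heterozygote_products_differ_between_schemes(self):
        # the interaction of two heterozygotes is 1 under {0,1,2}, 0 under {-1,0,1}
        g, _ = dataset(np.array([[1, 1]]), [0.0])
        for scheme, expected in [("{0,1,2}", 1.0), ("{-1,0,1}", 0.0)]:
            X = apply_encoding(g, traditional_encoding(scheme))
            P = product_epistasis(X, [("M0", "M1")])
            assert P.values[0, 0] == expected

    def test_product_collapses_zero_combinations(self):
        # (0,1) and (0,2) both multiply to 0 under the dosage scheme
        g, _ = dataset(np.array([[0, 1], [0, 2]]), [0.0, 1.0])
        X = apply_encoding(g, traditional_encoding("{0,1,2}"))
        P = product_epistasis(X, [("M0", "M1")])
        assert P.values.ravel().tolist() == [0.0, 0.0]


class TestFitSingle:
    def test_pure_worked_example(self):
        g, t = dataset([[0], [0], [1], [2], [2]], [2, 4, 6, 8, 10])
        table = fit_pure(g, t)
        assert table.values[0].tolist() == [3.0, 6.0, 9.0]

    def test_hybrid_worked_example(self):
        g, t = dataset([[0], [0], [1], [2], [2]], [2, 4, 7, 8, 10])
        table = fit_hybrid(g, t)
        assert table.values[0].tolist() == [3.0, 6.2, 9.0]
        # pure would give the class mean 7.0 for the heterozygote instead
        assert fit_pure(g, t).values[0, 1] == 7.0

    def test_constant_trait_encodes_constant(self):
        g, t = dataset([[0], [1], [2]], [5.0, 5.0, 5.0])
        for fit in (fit_pure, fit_hybrid):
            assert np.all(fit(g, t).values == 5.0)

    def test_unseen_class_gets_grand_mean(self):
        g, t = dataset([[0], [0], [1], [1]], [1, 2, 3, 4])
        table = fit_pure(g, t)
        assert table.values[0, 2] == 2.5

    def test_degenerate_all_heterozygous(self):
        g, t = dataset([[1], [1], [1]], [1.0, 2.0, 3.0])
        table = fit_hybrid(g, t)
        assert table.values[0].tolist() == [2.0, 2.0, 2.0]

    @pytest.mark.parametrize("fit", [fit_pure, fit_hybrid])
    def test_brute_force_oracle(self, rng, fit):
        for _ in range(30):
            n = int(rng.integers(3, 31))
            m = int(rng.integers(1, 11))
            g, t = random_dataset(rng, n, m)
            table = fit(g, t)
            grand = t.values.mean()
            for j in range(m):
                expected = brute_force_class_means(g.codes[:, j], t.values, grand)
                if fit is fit_hybrid:
                    expected[1] = grand
                assert table.values[j].tolist() == pytest.approx(expected, abs=0)


class TestInvariants:
    def test_sample_permutation_invariance(self, rng):
        g, t = random_dataset(rng, 25, 5)
        perm = rng.permutation(25)
        g2 = GenotypeMatrix([g.sample_ids[i] for i in perm], g.marker_ids,
                            g.codes[perm])
        t2 = TraitVector(g2.sample_ids, t.values[perm])
        for fit in (fit_pure, fit_hybrid):
            assert np.allclose(fit(g, t).values, fit(g2, t2).values)

    def test_label_swap_covariance(self, rng):
        g, t = random_dataset(rng, 25, 4)
        swapped = g.codes.copy()
        swapped[:, 0] = 2 - swapped[:, 0]
        g2 = GenotypeMatrix(g.sample_ids, g.marker_ids, swapped)
        a, b = fit_hybrid(g, t), fit_hybrid(g2, t)
        assert a.values[0, 0] == b.values[0, 2]
        assert a.values[0, 2] == b.values[0, 0]
        assert a.values[0, 1] == b.values[0, 1]

    def test_trait_affine_equivariance(self, rng):
        g, t = random_dataset(rng, 20, 4)
        a, b = 2.5, -1.0
        t2 = TraitVector(t.sample_ids, a * t.values + b)
        for fit in (fit_pure, fit_hybrid):
            assert np.allclose(fit(g, t2).values, a * fit(g, t).values + b)
        pairs = [("M0", "M1"), ("M2", "M3")]
        pt, pt2 = (fit_pairwise_hybrid(g, t, pairs),
                   fit_pairwise_hybrid(g, t2, pairs))
        assert np.allclose(pt2.grids, a * pt.grids + b)

    def test_pure_hybrid_agree_on_homozygotes(self, rng):
        g, t = random_dataset(rng, 30, 6)
        p, h = fit_pure(g, t), fit_hybrid(g, t)
        assert np.array_equal(p.values[:, [0, 2]], h.values[:, [0, 2]])


class TestPairwise:
    def six_sample_case(self):
        codes = np.array([[0, 0], [0, 0], [2, 0], [0, 2], [2, 2], [1, 1]],
                         dtype=np.int16)
        traits = [1.0, 3.0, 5.0, 7.0, 9.0, 11.0]
        return dataset(codes, traits)

    def test_worked_grid(self):
        g, t = self.six_sample_case()
        table = fit_pairwise_hybrid(g, t, [("M0", "M1")])
        grid = table.grids[0]
        assert grid[0, 0] == 2.0
        assert grid[2, 0] == 5.0
        assert grid[0, 2] == 7.0
        assert grid[2, 2] == 9.0
        assert grid[1, 0] == 3.0  # marginal over marker i given j=0
        assert grid[0, 1] == pytest.approx(11.0 / 3.0)
        assert grid[2, 1] == 7.0
        assert grid[1, 2] == 8.0
        assert grid[1, 1] == 6.0  # grand mean

    def test_constant_trait(self):
        g, t = dataset(np.array([[0, 1], [2, 0], [1, 2]]), [4.0, 4.0, 4.0])
        table = fit_pairwise_hybrid(g, t, [("M0", "M1")])
        assert np.all(table.grids == 4.0)

    def test_empty_corner_falls_back(self):
        g, t = dataset(np.array([[0, 0], [2, 2]]), [1.0, 3.0])
        table = fit_pairwise_hybrid(g, t, [("M0", "M1")])
        assert table.grids[0][0, 2] == 2.0  # no sample at (0,2): grand mean

    def test_self_pair_rejected(self):
        g, t = dataset(np.array([[0, 1]]), [1.0])
        with pytest.raises(EncodingError, match="twice"):
            fit_pairwise_hybrid(g, t, [("M0", "M0")])

    def test_marginal_identities_vs_single_marker(self, rng):
        # edge cells must equal the single-marker hybrid encodings exactly
        for _ in range(20):
            g, t = random_dataset(rng, int(rng.integers(4, 25)), 4)
            single = fit_hybrid(g, t)
            pairs = [("M0", "M1"), ("M1", "M3"), ("M0", "M2")]
            table = fit_pairwise_hybrid(g, t, pairs)
            idx = {m: i for i, m in enumerate(g.marker_ids)}
            for (mi, mj), grid in zip(table.pairs, table.grids):
                for c in (0, 2):
                    assert grid[1, c] == single.values[idx[mj], c]
                    assert grid[c, 1] == single.values[idx[mi], c]
                assert grid[1, 1] == single.values[idx[mi], 1]

    def test_apply_pair_encoding(self):
        g, t = self.six_sample_case()
        table = fit_pairwise_hybrid(g, t, [("M0", "M1")])
        X = apply_pair_encoding(g, table)
        assert X.feature_ids == ["M0:M1"]
        assert X.values[0, 0] == 2.0  # sample with codes (0,0)
        assert X.values[5, 0] == 6.0  # heterozygote pair -> centre cell

    def test_empty_pair_list(self):
        g, t = self.six_sample_case()
        table = fit_pairwise_hybrid(g, t, [])
        X = apply_pair_encoding(g, table)
        assert X.n_features == 0


class TestApply:
    def test_lookup(self):
        g, t = dataset([[0], [1], [2]], [0.0, 0.0, 0.0])
        table = fit_hybrid(*dataset([[0], [0], [1], [2], [2]],
                                    [2, 4, 7, 8, 10]))
        X = apply_encoding(g, table)
        assert X.values.ravel().tolist() == [3.0, 6.2, 9.0]

    def test_missing_marker_errors(self):
        g, _ = dataset([[0]], [0.0])
        other_g, other_t = dataset([[1]], [1.0])
        table = fit_pure(other_g, other_t)
        g2 = GenotypeMatrix(["S0"], ["other"], np.array([[0]], dtype=np.int16))
        with pytest.raises(EncodingError, match="other"):
            apply_encoding(g2, table)
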