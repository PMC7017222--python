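"""PCA, membership-function and RW ranking behaviour.

The eigendecomposition is cross-checked against a brute-force oracle that
solves the 3×3 characteristic polynomial by hand (trace / principal-minor /
determinant coefficients, numpy.roots) and recovers eigenvectors from SVD
null spaces — a fully independent route from numpy.linalg.eigh.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from heatscreen import (
    DegenerateRangeError,
    DegenerateVarianceError,
    DomainError,
    IndexMatrix,
    ShapeError,
    contribution_weights,
    cumulative_contribution,
    membership_normalize,
    pca_fit,
    rw_score,
    screen_herd,
)


def _matrix(values, directions=None, ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return IndexMatrix(
        cow_ids=ids or tuple(f"c{i:02d}" for i in range(n)),
        index_names=tuple(f"ix{j}" for j in range(p)),
        values=values,
        directions=directions or {},
    )


def char_poly_eig3(C):
    """Brute-force eigensolve of a symmetric 3×3 via its characteristic
    polynomial: λ³ − tr·λ² + m2·λ − det, minors expanded by hand."""
    tr = C[0, 0] + C[1, 1] + C[2, 2]
    m2 = (
        C[0, 0] * C[1, 1] - C[0, 1] * C[1, 0]
        + C[0, 0] * C[2, 2] - C[0, 2] * C[2, 0]
        + C[1, 1] * C[2, 2] - C[1, 2] * C[2, 1]
    )
    det = (
        C[0, 0] * (C[1, 1] * C[2, 2] - C[1, 2] * C[2, 1])
        - C[0, 1] * (C[1, 0] * C[2, 2] - C[1, 2] * C[2, 0])
        + C[0, 2] * (C[1, 0] * C[2, 1] - C[1, 1] * C[2, 0])
    )
    lams = np.sort(np.real(np.roots([1.0, -tr, m2, -det])))[::-1]
    vecs = []
    for lam in lams:
        _, s, vt = np.linalg.svd(C - lam * np.eye(3))
        vecs.append(vt[-1])  # null-space direction
    return lams, np.column_stack(vecs)


class TestPcaFit:
    def test_matches_char_poly_oracle(self, rng):
        data = _matrix(rng.normal(size=(40, 3)) @ rng.normal(size=(3, 3)))
        model = pca_fit(data)
        Z = (data.values - data.values.mean(0)) / data.values.std(0, ddof=1)
        C = np.corrcoef(data.values, rowvar=False)
        lams, vecs = char_poly_eig3(C)
        np.testing.assert_allclose(model.eigenvalues, lams, atol=1e-8)
        for j in range(3):
            cos = abs(vecs[:, j] @ model.loadings[:, j])
            assert cos == pytest.approx(1.0, abs=1e-8)
        # scores are the standardized data projected on the loadings
        np.testing.assert_allclose(model.scores, Z @ model.loadings, atol=1e-10)

    def test_perfectly_correlated_pair(self):
        x = np.linspace(0, 1, 10)
        model = pca_fit(_matrix(np.column_stack([x, 2 * x + 1])))
        np.testing.assert_allclose(model.contribution_rates, [1.0, 0.0], atol=1e-12)

    def test_uncorrelated_indexes_share_contribution(self, rng):
        data = _matrix(rng.standard_normal((4000, 3)))
        model = pca_fit(data)
        np.testing.assert_allclose(model.contribution_rates, [1 / 3] * 3, atol=0.05)

    def test_contribution_rates_sum_to_one(self, rng):
        model = pca_fit(_matrix(rng.normal(size=(15, 4))))
        assert model.contribution_rates.sum() == pytest.approx(1.0, abs=1e-9)
        cum = model.cumulative_contribution
        assert np.all(np.diff(cum) >= -1e-12)
        assert cum[-1] == pytest.approx(1.0, abs=1e-9)

    def test_eigenvalues_descending_nonnegative(self, rng):
        model = pca_fit(_matrix(rng.normal(size=(20, 3))))
        assert np.all(model.eigenvalues >= 0)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_constant_column_names_offender(self, rng):
        vals = rng.normal(size=(10, 3))
        vals[:, 1] = 5.0
        with pytest.raises(DegenerateVarianceError, match="ix1"):
            pca_fit(_matrix(vals))

    def test_sign_convention_burden_loadings_negative(self, rng):
        data = _matrix(rng.normal(size=(30, 3)))
        model = pca_fit(data)
        for j in range(model.loadings.shape[1]):
            assert model.loadings[:, j].sum() <= 0  # all indexes higher-is-worse

    def test_higher_is_better_direction_flips_orientation(self, rng):
        vals = rng.normal(size=(30, 2))
        worse = pca_fit(_matrix(vals))
        better = pca_fit(
            _matrix(vals, directions={"ix0": "higher_is_better",
                                      "ix1": "higher_is_better"})
        )
        np.testing.assert_allclose(worse.scores, -better.scores, atol=1e-12)


class TestMembership:
    def test_linear_map_endpoints(self):
        np.testing.assert_allclose(
            membership_normalize([0.0, 5.0, 10.0]), [0.0, 0.5, 1.0]
        )

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateRangeError):
            membership_normalize([2.0, 2.0, 2.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.lists(
            st.floats(min_value=-1e4, max_value=1e4),
            min_size=3, max_size=20, unique=True,
        ),
        a=st.floats(min_value=0.01, max_value=100.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_positive_affine_invariance(self, x, a, b):
        x = np.asarray(x)
        assume(np.ptp(x) > 1e-2)          # keep the map numerically stable
        assume(np.ptp(a * x + b) > 0.0)   # transform must not collapse range
        np.testing.assert_allclose(
            membership_normalize(a * x + b), membership_normalize(x),
            atol=1e-7,
        )

    def test_range_and_extremes(self, rng):
        r = membership_normalize(rng.normal(size=50))
        assert r.min() == 0.0 and r.max() == 1.0
        assert np.all((r >= 0) & (r <= 1))


class TestWeightsAndRw:
    def test_published_contribution_rates(self):
        # renormalising the first two rates of the 71.22/26.90/1.88 split
        w = contribution_weights([0.7122, 0.2690])
        np.testing.assert_allclose(w, [0.7122 / 0.9812, 0.2690 / 0.9812])
        np.testing.assert_allclose(w, [0.72585, 0.27415], atol=5e-6)

    @pytest.mark.parametrize(
        "p, expected",
        [([0.4], [1.0]), ([0.2, 0.2, 0.2], [1 / 3, 1 / 3, 1 / 3])],
    )
    def test_weight_examples(self, p, expected):
        np.testing.assert_allclose(contribution_weights(p), expected)

    def test_weights_sum_to_one(self, rng):
        w = contribution_weights(rng.uniform(0.01, 1.0, 5))
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("bad", [[], [0.5, 0.0], [0.5, -0.1]])
    def test_invalid_rates_rejected(self, bad):
        with pytest.raises(DomainError):
            contribution_weights(bad)

    def test_cumulative_contribution(self):
        np.testing.assert_allclose(
            cumulative_contribution([0.7, 0.2, 0.1]), [0.7, 0.9, 1.0]
        )

    @pytest.mark.parametrize(
        "row, w, expected",
        [
            ([1.0, 1.0], [0.6, 0.4], 1.0),
            ([0.0, 0.0], [0.6, 0.4], 0.0),
            ([1.0, 0.0], [0.7, 0.3], 0.7),
        ],
    )
    def test_rw_convex_combination(self, row, w, expected):
        assert rw_score([row], w)[0] == pytest.approx(expected)

    def test_rw_shape_error(self):
        with pytest.raises(ShapeError):
            rw_score([[0.5, 0.5]], [1.0, 0.0, 0.0])

    def test_rw_monotone_in_membership(self, rng):
        R = rng.uniform(size=(8, 3))
        W = contribution_weights([0.6, 0.3, 0.1])
        base = rw_score(R, W)
        R2 = R.copy()
        R2[4, 1] = min(1.0, R2[4, 1] + 0.2)
        bumped = rw_score(R2, W)
        assert bumped[4] >= base[4]
        np.testing.assert_allclose(np.delete(bumped, 4), np.delete(base, 4))

    def test_rw_in_unit_interval(self, rng):
        rw = rw_score(rng.uniform(size=(30, 2)), contribution_weights([0.7, 0.3]))
        assert np.all((rw >= 0) & (rw <= 1))


class TestScreenHerd:
    def test_dominant_cow_ranks_first(self, rng):
        vals = rng.uniform(1, 2, size=(10, 3)) + 5
        vals[3] = 0.1  # best (lowest burden) on every index
        ranking = screen_herd(_matrix(vals), k=2)
        assert ranking.rank[3] == 1
        assert ranking.group[3] == "HT"

    def test_rank_is_permutation_groups_disjoint(self, rng):
        ranking = screen_herd(_matrix(rng.normal(size=(12, 3))), k=3)
        assert sorted(ranking.rank) == list(range(1, 13))
        assert (ranking.group == "HT").sum() == 3
        assert (ranking.group == "NHT").sum() == 3
        assert not np.any((ranking.group == "HT") & (ranking.group == "NHT"))

    def test_duplicating_every_cow_preserves_rw(self, rng):
        vals = rng.normal(size=(9, 3))
        ids = tuple(f"c{i}" for i in range(9))
        single = screen_herd(_matrix(vals, ids=ids), k=2)
        doubled = screen_herd(
            _matrix(np.vstack([vals, vals]),
                    ids=ids + tuple(f"d{i}" for i in range(9))),
            k=2,
        )
        np.testing.assert_allclose(doubled.rw[:9], single.rw, atol=1e-9)

    def test_affine_invariance_of_full_ranking(self, rng):
        vals = rng.normal(size=(20, 3))
        base = screen_herd(_matrix(vals), k=3)
        scales = np.array([3.0, 0.2, 11.0])
        shifts = np.array([-4.0, 100.0, 0.5])
        transformed = screen_herd(_matrix(vals * scales + shifts), k=3)
        np.testing.assert_array_equal(base.rank, transformed.rank)
        np.testing.assert_allclose(base.rw, transformed.rw, atol=1e-9)

    def test_tie_break_by_cow_id_is_deterministic(self):
        # two identical cows: the lexicographically smaller id ranks first
        # (rows 2/3 break collinearity so the second PC keeps some spread)
        vals = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 7.0], [5.0, 1.0]])
        ranking = screen_herd(_matrix(vals, ids=("b", "a", "c", "d")), k=1)
        ra = dict(zip(ranking.cow_ids, ranking.rank))
        assert abs(ra["a"] - ra["b"]) == 1
        assert ra["a"] < ra["b"]

    @pytest.mark.parametrize("k", [0, 7])
    def test_bad_k_rejected(self, rng, k):
        with pytest.raises(DomainError):
            screen_herd(_matrix(rng.normal(size=(12, 3))), k=k)

    def test_recovers_planted_classes(self, herd):
        from heatscreen import index_matrix_from_phenotypes

        matrix = index_matrix_from_phenotypes(herd.phenotypes)
        ranking = screen_herd(matrix, k=3)
        df = ranking.to_frame().merge(herd.truth, on="cow_id")
        assert (df.loc[df.group == "HT", "true_class"] == "tolerant").all()
        assert (df.loc[df.group == "NHT", "true_class"] == "intolerant").all()


class TestIndexMatrixValidation:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(DomainError, match="unique"):
            _matrix(np.eye(3), ids=("a", "a", "b"))

    def test_missing_cells_rejected(self):
        vals = np.ones((4, 2))
        vals[1, 0] = np.nan
        with pytest.raises(DomainError):
            _matrix(vals)

    def test_from_frame_roundtrip(self):
        df = pd.DataFrame(
            {"cow_id": ["x", "y", "z"], "rt": [38.6, 39.1, 39.8],
             "rr": [55.0, 80.0, 103.0]}
        )
        m = IndexMatrix.from_frame(df)
        assert m.cow_ids == ("x", "y", "z")
        assert m.index_names == ("rt", "rr")
        np.testing.assert_allclose(m.values[:, 0], df["rt"])
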