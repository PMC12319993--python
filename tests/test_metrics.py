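"""Reliability statistics against brute-force and closed-form oracles."""

import numpy as np
import pytest

from fcreliab import (
    DistanceMatrix,
    ValidationError,
    classify_icc,
    discriminability,
    distance_matrix,
    edgewise_icc,
    fingerprinting,
    i2c2,
    i2c2_from_squared_distances,
    icc_a1,
    mean_icc,
)
from fcreliab.metrics import fc_data_array, i2c2_components
from fcreliab.synthetic import VarianceSpec, generate_fc_dataset

from conftest import make_fc_set, random_distance_matrix


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive, loop-based)


def anova_icc_oracle(table):
    """ICC(2,1) from explicit sums of squares, scalar arithmetic only."""
    table = np.asarray(table, float)
    n, k = table.shape
    grand = table.sum() / (n * k)
    SSR = sum(k * (row.mean() - grand) ** 2 for row in table)
    SSC = sum(n * (col.mean() - grand) ** 2 for col in table.T)
    SST = sum((x - grand) ** 2 for x in table.ravel())
    SSE = SST - SSR - SSC
    MSR = SSR / (n - 1)
    MSC = SSC / (k - 1)
    MSE = SSE / ((n - 1) * (k - 1))
    return (MSR - MSE) / (MSR + (k - 1) * MSE + k * (MSC - MSE) / n)


def discr_oracle(d, mode):
    """Exhaustive triple-loop discriminability with half-credit ties."""
    subjects = d.subjects
    fracs = []
    for s in subjects:
        rows = d.rows_of(s)
        for ai, anchor in enumerate(rows):
            for bi, target in enumerate(rows):
                if ai == bi:
                    continue
                w = d.values[anchor, target]
                comparisons = []
                for o in subjects:
                    if o == s:
                        continue
                    orows = d.rows_of(o)
                    if mode == "cross_scan":
                        comparisons.append(d.values[anchor, orows[bi]])
                    else:
                        comparisons.extend(d.values[anchor, r] for r in orows)
                hits = sum(
                    1.0 if c > w else (0.5 if c == w else 0.0)
                    for c in comparisons
                )
                fracs.append(hits / len(comparisons))
    return float(np.mean(np.array(fracs)))


def fingerprint_oracle(d):
    subjects = d.subjects
    accs = []
    for a, b in [(0, 1), (1, 0)]:
        wins = 0
        for s in subjects:
            w = d.values[d.rows_of(s)[a], d.rows_of(s)[b]]
            others = [
                d.values[d.rows_of(s)[a], d.rows_of(o)[b]]
                for o in subjects
                if o != s
            ]
            wins += all(w < x for x in others)
        accs.append(wins / len(subjects))
    return sum(accs) / 2


# ---------------------------------------------------------------------------
# Distance matrix


class TestDistanceMatrix:
    def test_identical_matrices_have_zero_distance(self):
        X = np.tile(np.arange(6.0).reshape(1, 1, 2, 3), (3, 2, 1, 1))
        d = distance_matrix(make_fc_set(X))
        np.testing.assert_allclose(d.values, 0)

    def test_three_four_five(self):
        X = np.zeros((3, 2, 1, 2))
        X[0, 1] = [[3.0, 4.0]]
        d = distance_matrix(make_fc_set(X))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_matches_pairwise_loop_oracle(self, rng):
        X = rng.normal(size=(2, 2, 3, 3))
        d = distance_matrix(make_fc_set(X))
        flat = X.reshape(4, -1)
        for i in range(4):
            for j in range(4):
                expected = np.sqrt(((flat[i] - flat[j]) ** 2).sum())
                assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_invalid_matrices_rejected(self):
        idx = [("a", 1), ("a", 2)]
        with pytest.raises(ValidationError, match="symmetric"):
            DistanceMatrix(values=[[0, 1], [2, 0]], index=idx)
        with pytest.raises(ValidationError, match="diagonal"):
            DistanceMatrix(values=[[1, 1], [1, 0]], index=idx)
        with pytest.raises(ValidationError, match="same number"):
            DistanceMatrix(
                values=np.zeros((3, 3)),
                index=[("a", 1), ("a", 2), ("b", 1)],
            )


# ---------------------------------------------------------------------------
# ICC


class TestIcc:
    def test_perfect_reliability(self):
        table = np.repeat(np.arange(4.0)[:, None], 2, axis=1)
        assert icc_a1(table)[0] == pytest.approx(1.0)

    def test_degenerate_constant_table_is_nan(self):
        assert np.isnan(icc_a1(np.ones((4, 2)))[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.normal(size=(4, 2))
        assert icc_a1(table)[0] == pytest.approx(
            anova_icc_oracle(table), abs=1e-10
        )

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(123)
        table = rng.normal(size=(6, 3)) + rng.normal(size=(6, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 3),
                "rater": np.tile(np.arange(3), 6),
                "score": table.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        )
        icc2 = ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].item()
        assert icc_a1(table)[0] == pytest.approx(icc2, abs=1e-8)

    def test_edgewise_icc_keeps_grid_and_masks_nan(self):
        X = np.random.default_rng(0).normal(size=(5, 2, 3, 4))
        fcs = make_fc_set(X)
        icc = edgewise_icc(fcs)
        assert icc.shape == (3, 4)
        vals = X.reshape(5, 2, 12)
        for e in range(12):
            assert icc.ravel()[e] == pytest.approx(
                anova_icc_oracle(vals[:, :, e]), abs=1e-10
            )


class TestMeanIcc:
    def test_constant_matrix(self):
        per_vertex, roi = mean_icc(np.full((3, 4), 0.7))
        np.testing.assert_allclose(per_vertex, 0.7)
        assert roi == pytest.approx(0.7)

    def test_two_level_average(self):
        per_vertex, roi = mean_icc(np.array([[0.2, 0.4], [0.6, 0.8]]))
        np.testing.assert_allclose(per_vertex, [0.3, 0.7])
        assert roi == pytest.approx(0.5)

    def test_equals_flat_mean_without_nans(self, rng):
        m = rng.uniform(size=(7, 5))
        assert mean_icc(m)[1] == pytest.approx(m.mean())

    def test_all_nan_row_gives_nan_vertex(self):
        m = np.array([[np.nan, np.nan], [0.5, 0.5]])
        per_vertex, roi = mean_icc(m)
        assert np.isnan(per_vertex[0]) and roi == pytest.approx(0.5)


@pytest.mark.parametrize(
    "value, label",
    [
        (0.1, "poor"),
        (0.2, "fair"),
        (0.39, "fair"),
        (0.4, "moderate"),
        (0.453, "moderate"),
        (0.6, "good"),
        (0.79, "good"),
        (0.8, "excellent"),
        (0.95, "excellent"),
        (-0.3, "poor"),
        (np.nan, "undefined"),
    ],
)
def test_icc_quality_bins(value, label):
    assert classify_icc(value) == label


# ---------------------------------------------------------------------------
# I2C2


class TestI2c2:
    def test_identical_scans_within_subject_give_one(self):
        base = np.random.default_rng(0).normal(size=(4, 1, 2, 3))
        X = np.tile(base, (1, 2, 1, 1))
        assert i2c2(make_fc_set(X)) == pytest.approx(1.0)

    def test_pure_noise_is_near_zero(self):
        spec = VarianceSpec(
            n_subjects=80, n_vertices=20, n_parcels=20,
            sigma2_between=0.0, sigma2_within=1.0, seed=4,
        )
        ds = generate_fc_dataset(spec)
        value = i2c2(ds.condition_scans("movie"))
        assert abs(value) < 0.05

    def test_components_match_direct_formula(self, rng):
        X = rng.normal(size=(5, 3, 7))
        comp = i2c2_components(X)
        n, J, V = X.shape
        grand = X.mean(axis=(0, 1))
        ko = sum(
            ((X[i, j] - grand) ** 2).sum() for i in range(n) for j in range(J)
        ) / (n * J - 1)
        subj = X.mean(axis=1)
        ku = sum(
            ((X[i, j] - subj[i]) ** 2).sum() for i in range(n) for j in range(J)
        ) / (n * (J - 1))
        assert comp.trace_Ko == pytest.approx(ko, rel=1e-12)
        assert comp.trace_Ku == pytest.approx(ku, rel=1e-12)

    def test_distance_identity_matches_direct(self, rng):
        X = rng.normal(size=(6, 2, 4, 3))
        fcs = make_fc_set(X)
        direct = i2c2(fcs)
        d = distance_matrix(fcs)
        groups = np.repeat(np.arange(6), 2)
        from_d = i2c2_from_squared_distances(d.values**2, groups)
        assert from_d == pytest.approx(direct, abs=1e-10)

    def test_degenerate_data_is_an_error(self):
        X = np.zeros((3, 2, 1, 1))
        with pytest.raises(ValidationError, match="degenerate"):
            i2c2(make_fc_set(X))


# ---------------------------------------------------------------------------
# Discriminability / fingerprinting


class TestDiscriminability:
    def test_perfectly_separated_subjects_score_one(self):
        X = np.tile(
            (10 * np.arange(4))[:, None, None, None], (1, 2, 1, 2)
        ).astype(float)
        d = distance_matrix(make_fc_set(X))
        assert discriminability(d) == 1.0
        assert discriminability(d, "all") == 1.0

    def test_all_equal_distances_score_half(self):
        M = 6
        D = np.ones((M, M)) - np.eye(M)
        idx = [(f"s{i}", j) for i in range(3) for j in (1, 2)]
        d = DistanceMatrix(values=D, index=idx)
        assert discriminability(d) == pytest.approx(0.5)
        assert discriminability(d, "all") == pytest.approx(0.5)

    @pytest.mark.parametrize("mode", ["cross_scan", "all"])
    @pytest.mark.parametrize("quantize", [None, 2])
    def test_matches_triple_loop_oracle(self, rng, mode, quantize):
        for _ in range(10):
            n = int(rng.integers(3, 8))
            d = random_distance_matrix(rng, n, quantize=quantize)
            assert discriminability(d, mode) == pytest.approx(
                discr_oracle(d, mode), abs=0
            )

    def test_three_scan_all_mode_matches_oracle(self, rng):
        d = random_distance_matrix(rng, 4, n_scans=3)
        assert discriminability(d, "all") == discr_oracle(d, "all")
        with pytest.raises(ValidationError, match="exactly 2"):
            discriminability(d, "cross_scan")

    def test_fewer_than_two_subjects_is_an_error(self, rng):
        d = random_distance_matrix(rng, 1)
        with pytest.raises(ValidationError, match="2 subjects"):
            discriminability(d)


class TestFingerprinting:
    def test_distinct_noiseless_subjects_score_one(self):
        X = np.tile(
            (5 * np.arange(3))[:, None, None, None], (1, 2, 1, 2)
        ).astype(float)
        d = distance_matrix(make_fc_set(X))
        assert fingerprinting(d) == 1.0

    def test_ties_fail_strictly(self):
        M = 6
        D = np.ones((M, M)) - np.eye(M)
        idx = [(f"s{i}", j) for i in range(3) for j in (1, 2)]
        assert fingerprinting(DistanceMatrix(values=D, index=idx)) == 0.0

    def test_hand_enumerated_three_subject_table(self):
        # scan1 x scan2 cross-distances; sub c's own match (6) is beaten by 5
        cross = np.array(
            [
                [1.0, 4.0, 9.0],
                [7.0, 2.0, 8.0],
                [6.0, 5.0, 6.5],
            ]
        )
        D = np.zeros((6, 6))
        for i in range(3):
            for j in range(3):
                D[2 * i, 2 * j + 1] = cross[i, j]
                D[2 * j + 1, 2 * i] = cross[i, j]
        # make same-scan distances large so only cross-scan matters
        for i in range(3):
            for j in range(3):
                if i != j:
                    D[2 * i, 2 * j] = D[2 * j, 2 * i] = 50.0
                    D[2 * i + 1, 2 * j + 1] = D[2 * j + 1, 2 * i + 1] = 50.0
        idx = [(s, j) for s in "abc" for j in (1, 2)]
        d = DistanceMatrix(values=D, index=idx)
        # forward: a wins (1<4,9), b wins (2<7,8), c loses (6.5 > 5)
        assert fingerprinting(d, "forward") == pytest.approx(2 / 3)
        assert fingerprinting(d) == pytest.approx(
            fingerprint_oracle(d)
        )

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            d = random_distance_matrix(rng, int(rng.integers(3, 9)))
            assert fingerprinting(d) == fingerprint_oracle(d)

    def test_wrong_scan_count_is_an_error(self, rng):
        d = random_distance_matrix(rng, 4, n_scans=3)
        with pytest.raises(ValidationError, match="exactly 2"):
            fingerprinting(d)


# ---------------------------------------------------------------------------
# Shared properties


def test_monotone_transform_invariance(rng):
    d = random_distance_matrix(rng, 6)
    transformed = DistanceMatrix(
        values=np.sqrt(d.values) * 3, index=list(d.index)
    )
    for mode in ("cross_scan", "all"):
        assert discriminability(d, mode) == pytest.approx(
            discriminability(transformed, mode)
        )
    assert fingerprinting(d) == pytest.approx(fingerprinting(transformed))


def test_subject_relabelling_leaves_scalars_unchanged(rng):
    X = rng.normal(size=(6, 2, 3, 3))
    fcs = make_fc_set(X)
    perm = rng.permutation(6)
    shuffled = make_fc_set(X[perm])
    d1, d2 = distance_matrix(fcs), distance_matrix(shuffled)
    assert i2c2(fcs) == pytest.approx(i2c2(shuffled), abs=1e-12)
    assert discriminability(d1) == pytest.approx(discriminability(d2), abs=1e-12)
    assert fingerprinting(d1) == pytest.approx(fingerprinting(d2), abs=1e-12)
    assert mean_icc(edgewise_icc(fcs))[1] == pytest.approx(
        mean_icc(edgewise_icc(shuffled))[1], abs=1e-12
    )


def test_vanishing_within_noise_drives_all_measures_to_one():
    spec = VarianceSpec(
        n_subjects=6, n_vertices=4, n_parcels=5,
        sigma2_between=1.0, sigma2_within=0.0, seed=9,
    )
    ds = generate_fc_dataset(spec)
    fcs = ds.condition_scans("movie")
    d = distance_matrix(fcs)
    assert mean_icc(edgewise_icc(fcs))[1] == pytest.approx(1.0)
    assert i2c2(fcs) == pytest.approx(1.0)
    assert discriminability(d) == 1.0
    assert fingerprinting(d) == 1.0
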