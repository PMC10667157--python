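"""Metric suite: worked examples, invariants, and brute-force oracle checks."""

import numpy as np
import pytest

from fatseg import metrics as M

rng = np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# independent direct-definition oracles (kept deliberately naive)

def brute_accuracy(p, t):
    return sum(int(a == b) for a, b in zip(p.ravel(), t.ravel())) / p.size


def brute_dice(p, t, lab):
    P = {i for i, v in enumerate(p.ravel()) if v == lab}
    T = {i for i, v in enumerate(t.ravel()) if v == lab}
    if not P and not T:
        return 1.0
    return 2 * len(P & T) / (len(P) + len(T))


def brute_mpe(e):
    return sum(e) / len(e)


def brute_sd(e):
    m = sum(e) / len(e)
    return (sum((x - m) ** 2 for x in e) / len(e)) ** 0.5


def brute_rmspe(e):
    return (sum(x * x for x in e) / len(e)) ** 0.5


def brute_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x) ** 0.5
    dy = sum((b - my) ** 2 for b in y) ** 0.5
    return num / (dx * dy)


def brute_pw2(x, y):
    s = sum(y) / len(y)
    xs = sorted(v / s for v in x)
    ys = sorted(v / s for v in y)
    return (sum((a - b) ** 2 for a, b in zip(xs, ys)) / len(xs)) ** 0.5


def brute_kurtosis(e):
    n = len(e)
    m = sum(e) / n
    c2 = sum((x - m) ** 2 for x in e) / n
    c4 = sum((x - m) ** 4 for x in e) / n
    return c4 / c2**2 - 3.0


def brute_icc_absolute(a, b):
    """ICC(2,1) from the explicit two-way ANOVA table."""
    n, k = len(a), 2
    x = [[ai, bi] for ai, bi in zip(a, b)]
    grand = sum(sum(r) for r in x) / (n * k)
    rm = [sum(r) / k for r in x]
    cm = [sum(a) / n, sum(b) / n]
    ss_rows = k * sum((m - grand) ** 2 for m in rm)
    ss_cols = n * sum((m - grand) ** 2 for m in cm)
    ss_tot = sum((v - grand) ** 2 for r in x for v in r)
    ss_err = ss_tot - ss_rows - ss_cols
    msr, msc = ss_rows / (n - 1), ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def brute_cv(a, b):
    terms = []
    for ai, bi in zip(a, b):
        m = (ai + bi) / 2
        sd = (((ai - m) ** 2 + (bi - m) ** 2) / 1) ** 0.5  # sample SD of 2 values
        terms.append((sd / m) ** 2)
    return (sum(terms) / len(terms)) ** 0.5


# ---------------------------------------------------------------------------

class TestSegmentationScores:
    def test_identity_is_perfect(self):
        t = rng.integers(0, 3, size=(20, 20)).astype(np.uint8)
        s = M.segmentation_scores(t, t)
        assert s.accuracy == 1.0 and s.dice_sat == 1.0 and s.dice_vat == 1.0

    def test_disjoint_sat_sets_give_zero_dice(self):
        p = np.zeros((4, 4), dtype=np.uint8)
        t = np.zeros((4, 4), dtype=np.uint8)
        p[0, :2] = 1
        t[1, :2] = 1
        assert M.segmentation_scores(p, t).dice_sat == 0.0

    def test_hand_enumerated_overlap(self):
        # |P| = 4, |T| = 6, overlap 3 -> Dice 0.6
        p = np.zeros(12, dtype=np.uint8)
        t = np.zeros(12, dtype=np.uint8)
        p[:4] = 1
        t[1:7] = 1
        assert M.segmentation_scores(p, t).dice_sat == pytest.approx(2 * 3 / (4 + 6))

    def test_dice_symmetric(self):
        p = rng.integers(0, 3, size=(15, 15)).astype(np.uint8)
        t = rng.integers(0, 3, size=(15, 15)).astype(np.uint8)
        assert M.dice_coefficient(p, t, 1) == M.dice_coefficient(t, p, 1)

    def test_shape_and_label_validation(self):
        with pytest.raises(ValueError, match="shape"):
            M.segmentation_scores(np.zeros((2, 2), dtype=int), np.zeros((3, 3), dtype=int))
        with pytest.raises(ValueError, match="labels"):
            M.segmentation_scores(np.full((2, 2), 5), np.zeros((2, 2), dtype=int))


class TestErrorMetrics:
    def test_relative_error_examples(self):
        assert M.relative_errors([2.0], [2.0]) == pytest.approx([0.0])
        np.testing.assert_allclose(M.relative_errors([1.1, 2.2], [1.0, 2.0]), 0.1)
        assert M.relative_errors([2.1], [2.0]) == pytest.approx([0.05])
        with pytest.raises(ValueError, match="positive"):
            M.relative_errors([1.0], [0.0])

    def test_rmspe_decomposition_identity(self):
        for _ in range(20):
            e = rng.normal(0, 0.05, size=rng.integers(3, 40))
            assert M.rmspe(e) ** 2 == pytest.approx(M.mpe(e) ** 2 + M.sd_rel(e) ** 2, abs=1e-12)

    def test_zero_errors(self):
        e = np.zeros(3)
        assert M.mpe(e) == 0 and M.sd_rel(e) == 0 and M.rmspe(e) == 0

    def test_pearson_on_affine_data(self):
        t = rng.uniform(1, 5, size=10)
        assert M.pearson_r(2.0 * t + 1.0, t) == pytest.approx(1.0)
        assert M.pearson_r(-0.5 * t + 3.0, t) == pytest.approx(-1.0)

    def test_pw2_identity_shift_permutation(self):
        x = rng.uniform(1, 4, size=9)
        assert M.pw2_rel(x, x) == pytest.approx(0.0)
        assert M.pw2_rel(rng.permutation(x), x) == pytest.approx(0.0, abs=1e-12)
        # pure shift after normalisation: W2 equals the shift
        y = np.full(6, 2.0)
        assert M.pw2_rel(y + 0.5, y) == pytest.approx(0.25)  # shift 0.5 / mean 2.0

    def test_excess_kurtosis_closed_forms(self):
        signs = rng.choice([-1.0, 1.0], size=64)
        signs[: 32] = -1.0
        signs[32:] = 1.0  # exactly balanced two-point distribution
        assert M.excess_kurtosis(signs) == pytest.approx(-2.0)
        big = rng.standard_normal(10_000)
        assert abs(M.excess_kurtosis(big)) < 0.15

    def test_outlier_raises_kurtosis_monotonically(self):
        base = rng.normal(0, 1, size=50)
        vals = [M.excess_kurtosis(np.append(base, mag)) for mag in (5, 10, 20)]
        assert vals[0] < vals[1] < vals[2]


class TestReliability:
    def test_icc_and_cv_on_identical_pairs(self):
        a = rng.uniform(1, 5, size=8)
        assert M.icc(a, a) == pytest.approx(1.0)
        assert M.cv(a, a) == pytest.approx(0.0)

    def test_absolute_agreement_penalises_offset(self):
        a = rng.uniform(1, 5, size=12)
        b = a + 3.0
        assert M.icc(a, b, form="absolute") < M.icc(a, b, form="consistency")

    def test_four_pair_anova_oracle(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [1.2, 1.9, 3.3, 4.4]
        assert M.icc(a, b) == pytest.approx(brute_icc_absolute(a, b), abs=1e-12)

    def test_icc_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        a = rng.uniform(1, 6, size=15)
        b = a + rng.normal(0.2, 0.3, size=15)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 2),
            "rater": np.tile(["A", "B"], 15),
            "score": np.column_stack([a, b]).ravel(),
        })
        table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc_a1 = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert M.icc(a, b) == pytest.approx(icc_a1, abs=1e-9)


class TestBlandAltman:
    def test_identical_vectors(self):
        v = rng.uniform(1, 3, size=6)
        ba = M.bland_altman(v, v)
        assert ba.mu == 0 and ba.lower == 0 and ba.upper == 0

    def test_constant_offset(self):
        v = rng.uniform(1, 3, size=6)
        ba = M.bland_altman(1.05 * v, v)
        assert ba.mu == pytest.approx(0.05)
        assert ba.upper - ba.lower == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_coverage(self):
        true = np.full(4000, 2.0)
        pred = true * (1 + rng.normal(0, 0.03, size=4000))
        ba = M.bland_altman(pred, true)
        rel = (pred - true) / true
        frac = np.mean((rel >= ba.lower) & (rel <= ba.upper))
        assert 0.93 < frac < 0.97


class TestOracleEquivalence:
    """Every metric agrees with its naive direct-definition implementation."""

    @pytest.mark.parametrize("trial", range(10))
    def test_random_inputs(self, trial):
        r = np.random.default_rng(100 + trial)
        t = r.integers(0, 3, size=(10, 10)).astype(np.uint8)
        p = r.integers(0, 3, size=(10, 10)).astype(np.uint8)
        s = M.segmentation_scores(p, t)
        assert s.accuracy == pytest.approx(brute_accuracy(p, t), abs=1e-10)
        assert s.dice_sat == pytest.approx(brute_dice(p, t, 1), abs=1e-10)
        assert s.dice_vat == pytest.approx(brute_dice(p, t, 2), abs=1e-10)

        true = r.uniform(1, 5, size=10)
        pred = true * (1 + r.normal(0, 0.1, size=10))
        e = list(M.relative_errors(pred, true))
        assert M.mpe(e) == pytest.approx(brute_mpe(e), abs=1e-10)
        assert M.sd_rel(e) == pytest.approx(brute_sd(e), abs=1e-10)
        assert M.rmspe(e) == pytest.approx(brute_rmspe(e), abs=1e-10)
        assert M.pearson_r(pred, true) == pytest.approx(brute_pearson(pred, true), abs=1e-10)
        assert M.pw2_rel(pred, true) == pytest.approx(brute_pw2(pred, true), abs=1e-10)
        assert M.excess_kurtosis(e) == pytest.approx(brute_kurtosis(e), abs=1e-10)
        assert M.icc(pred, true) == pytest.approx(brute_icc_absolute(pred, true), abs=1e-10)
        assert M.cv(pred, true) == pytest.approx(brute_cv(pred, true), abs=1e-10)


class TestPropertyInvariants:
    """Metric invariants over generated inputs."""

    from hypothesis import given, settings, strategies as st

    errors = st.lists(st.floats(-0.5, 0.5, allow_nan=False), min_size=2, max_size=40)
    volumes = st.lists(st.floats(0.5, 20.0, allow_nan=False), min_size=2, max_size=40)

    @given(e=errors)
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_rmspe_decomposition_holds_everywhere(self, e):
        assert M.rmspe(e) ** 2 == pytest.approx(M.mpe(e) ** 2 + M.sd_rel(e) ** 2, abs=1e-12)

    @given(v=volumes, seed=st.integers(0, 2**16))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_pw2_permutation_invariance(self, v, seed):
        x = np.asarray(v)
        y = x * 1.07
        perm = np.random.default_rng(seed).permutation(len(x))
        assert M.pw2_rel(y[perm], x) == pytest.approx(M.pw2_rel(y, x), abs=1e-12)

    @given(v=volumes)
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bland_altman_limits_bracket_mu(self, v):
        x = np.asarray(v)
        ba = M.bland_altman(x * 1.03, x)
        assert ba.lower <= ba.mu <= ba.upper
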