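import numpy as np
import pytest

from dmhprep.background import CorrectedIntensities, correct_background
from dmhprep.exceptions import FitError, InputError
from dmhprep.normalization import (
    MAArray,
    composite_weight,
    compute_ma,
    fit_loess,
    local_polynomial_fit,
    normalize,
    stack_m_values,
)
from dmhprep.restriction import ControlProbeSet


def corrected(R, G, array_id="arr"):
    n = len(R)
    return CorrectedIntensities(
        array_id=array_id,
        probe_ids=np.array([f"p{i}" for i in range(n)]),
        R=np.asarray(R, float),
        G=np.asarray(G, float),
        method_id="none",
    )


def ma_from(A, M, probe_ids=None, array_id="arr"):
    A = np.asarray(A, float)
    M = np.asarray(M, float)
    ids = np.array(probe_ids if probe_ids is not None else [f"p{i}" for i in range(len(A))])
    return MAArray(array_id=array_id, probe_ids=ids, M=M, A=A)


class TestComputeMA:
    def test_equal_channels_give_zero_m(self):
        ma = compute_ma(corrected([100.0], [100.0]))
        assert ma.M[0] == 0
        assert ma.A[0] == pytest.approx(np.log2(100), abs=1e-12)

    def test_powers_of_two(self):
        ma = compute_ma(corrected([4.0], [1.0]))
        assert ma.M[0] == pytest.approx(2.0) and ma.A[0] == pytest.approx(1.0)

    def test_non_positive_intensity_gives_missing_pair(self):
        ma = compute_ma(corrected([-20.0, 5.0, 3.0], [50.0, 0.0, 3.0]))
        assert np.isnan(ma.M[0]) and np.isnan(ma.A[0])
        assert np.isnan(ma.M[1]) and np.isnan(ma.A[1])
        assert ma.M[2] == 0


class TestFitLoess:
    def test_reproduces_exact_line(self, rng):
        A = np.sort(rng.uniform(5, 15, 400))
        M = 0.5 * A + 1.0
        curve = fit_loess(A, M, span=0.4, degree=1)
        grid = np.linspace(A.min(), A.max(), 100)
        np.testing.assert_allclose(curve(grid), 0.5 * grid + 1.0, atol=1e-8)

    def test_constant_data_gives_constant_curve(self, rng):
        A = rng.uniform(0, 10, 100)
        curve = fit_loess(A, np.full(100, 3.25), span=0.5, degree=1)
        np.testing.assert_allclose(curve(np.linspace(0, 10, 50)), 3.25, atol=1e-10)

    def test_recovers_smooth_signal_against_independent_implementation(self, rng):
        n = 2000
        A = np.sort(rng.uniform(0, 2 * np.pi, n))
        M = np.sin(A) + rng.normal(0, 0.05, n)
        # span chosen so the local-linear curvature bias (~ h^2 |sin''| / 2)
        # stays well inside the 0.05 recovery band
        curve = fit_loess(A, M, span=0.1, degree=1)
        lo, hi = np.quantile(A, [0.1, 0.9])
        grid = np.linspace(lo, hi, 200)
        assert np.max(np.abs(curve(grid) - np.sin(grid))) < 0.05
        # independent quadratic-time local-regression oracle at same span
        idx = np.linspace(0, n - 1, 300).astype(int)
        oracle = local_polynomial_fit(A[idx], M[idx], span=0.1, degree=1)
        inner = (A[idx] >= lo) & (A[idx] <= hi)
        assert np.max(np.abs(curve(A[idx])[inner] - oracle[inner])) < 0.05

    def test_boundary_value_extension(self, rng):
        A = np.sort(rng.uniform(0, 10, 100))
        curve = fit_loess(A, 2.0 * A, span=0.5)
        assert curve(-50.0) == pytest.approx(curve(A.min()))
        assert curve(50.0) == pytest.approx(curve(A.max()))

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_loess(np.arange(5.0), np.arange(5.0))

    def test_quadratic_degree_beats_linear_on_curvature(self, rng):
        A = np.sort(rng.uniform(-2, 2, 300))
        M = A**2
        c2 = fit_loess(A, M, span=0.6, degree=2)
        grid = np.linspace(-1.5, 1.5, 50)
        np.testing.assert_allclose(c2(grid), grid**2, atol=0.05)


class TestCompositeWeight:
    def test_minimum_gets_zero(self):
        assert composite_weight(1.0, [1.0, 2.0, 3.0]) == 0.0

    def test_strict_count(self):
        assert composite_weight(4.0, [1.0, 2.0, 3.0, 4.0]) == 0.75

    def test_above_maximum_gets_one(self):
        assert composite_weight(9.0, [1.0, 2.0, 3.0]) == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(InputError):
            composite_weight(1.0, [])


def _biased_ma(rng, n=2000, n_controls=200, bias=lambda A: 0.8 - 0.12 * (A - 10)):
    """Array whose biological probes carry a planted M-on-A trend and
    whose control probes sit at M = 0 + noise + the same trend."""
    A = rng.uniform(6, 14, n)
    M = bias(A) + rng.normal(0, 0.3, n)
    ids = np.array([f"ctl_{i}" if i < n_controls else f"bio_{i}" for i in range(n)])
    ma = ma_from(A, M, probe_ids=ids)
    controls = ControlProbeSet(probe_ids=frozenset(ids[:n_controls]))
    return ma, controls


class TestNormalize:
    def test_none_is_identity(self, rng):
        ma, controls = _biased_ma(rng)
        out = normalize(ma, "none")
        np.testing.assert_array_equal(out.M, ma.M)

    def test_global_removes_planted_trend(self, rng):
        ma, _ = _biased_ma(rng)
        out = normalize(ma, "global")
        trend = fit_loess(out.A, out.M, span=0.3)
        lo, hi = np.nanquantile(ma.A, [0.05, 0.95])
        grid = np.linspace(lo, hi, 100)
        assert np.max(np.abs(trend(grid))) < 0.02

    def test_control_centering_per_decile(self, rng):
        ma, controls = _biased_ma(rng)
        out = normalize(ma, "control", controls=controls)
        is_ctrl = np.isin(out.probe_ids, list(controls.probe_ids))
        A, M = out.A[is_ctrl], out.M[is_ctrl]
        deciles = np.quantile(A, np.linspace(0, 1, 11))
        for lo, hi in zip(deciles[:-1], deciles[1:]):
            sel = (A >= lo) & (A <= hi)
            se = M[sel].std(ddof=1) / np.sqrt(sel.sum())
            assert abs(M[sel].mean()) < 2 * se

    def test_constant_control_m_centered_to_zero(self, rng):
        A = rng.uniform(0, 10, 200)
        M = np.full(200, 0.7)
        ids = np.array([f"c{i}" for i in range(200)])
        ma = ma_from(A, M, probe_ids=ids)
        controls = ControlProbeSet(probe_ids=frozenset(ids))
        out = normalize(ma, "control", controls=controls)
        np.testing.assert_allclose(out.M, 0.0, atol=1e-6)

    def test_composite_equals_global_when_curves_coincide(self, rng):
        ma, _ = _biased_ma(rng, n=500)
        all_controls = ControlProbeSet(probe_ids=frozenset(ma.probe_ids))
        got = normalize(ma, "composite", controls=all_controls)
        want = normalize(ma, "global")
        np.testing.assert_allclose(got.M, want.M, atol=1e-10)

    def test_composite_lies_between_the_two_curves(self, rng):
        ma, controls = _biased_ma(rng, n=1500, n_controls=300)
        present = ma.present
        f_all = fit_loess(ma.A[present], ma.M[present], span=0.3)
        is_ctrl = np.isin(ma.probe_ids, list(controls.probe_ids)) & present
        f_ctrl = fit_loess(ma.A[is_ctrl], ma.M[is_ctrl], span=0.3)
        out = normalize(ma, "composite", controls=controls)
        g = ma.M[present] - out.M[present]
        lo = np.minimum(f_all(ma.A[present]), f_ctrl(ma.A[present]))
        hi = np.maximum(f_all(ma.A[present]), f_ctrl(ma.A[present]))
        assert np.all(g >= lo - 1e-9) and np.all(g <= hi + 1e-9)

    def test_global_normalization_approximately_idempotent(self, rng):
        # LOESS is not a projection, so exact idempotence is impossible on
        # noisy data: the second pass re-smooths noise and moves each M by
        # O(sigma / sqrt(span * n)).  Require the second-pass change to be
        # far smaller than the first-pass change and small absolutely.
        ma, _ = _biased_ma(rng)
        once = normalize(ma, "global")
        twice = normalize(once, "global")
        first_change = np.sqrt(np.nanmean((once.M - ma.M) ** 2))
        second_change = np.sqrt(np.nanmean((twice.M - once.M) ** 2))
        assert second_change < 0.05 * first_change
        assert second_change < 0.01

    def test_methods_agree_on_trend_free_data(self, rng):
        A = rng.uniform(5, 15, 400)
        ids = np.array([f"c{i}" if i < 100 else f"b{i}" for i in range(400)])
        ma = ma_from(A, np.zeros(400), probe_ids=ids)
        controls = ControlProbeSet(probe_ids=frozenset(ids[:100]))
        for method in ("none", "global", "control", "composite"):
            out = normalize(ma, method, controls=controls)
            np.testing.assert_allclose(out.M, 0.0, atol=1e-9)

    def test_missing_cells_pass_through(self, rng):
        ma, controls = _biased_ma(rng, n=600)
        ma.M[5] = np.nan
        ma.A[5] = np.nan
        out = normalize(ma, "global")
        assert np.isnan(out.M[5]) and np.isnan(out.A[5])
        assert np.isfinite(out.M[6])

    def test_too_few_controls_error_names_count(self, rng):
        ma, _ = _biased_ma(rng, n=100, n_controls=5)
        controls = ControlProbeSet(probe_ids=frozenset(f"ctl_{i}" for i in range(5)))
        with pytest.raises(FitError, match="5 control probes"):
            normalize(ma, "control", controls=controls)

    def test_unknown_method_rejected(self, rng):
        ma, _ = _biased_ma(rng, n=100)
        with pytest.raises(InputError):
            normalize(ma, "quantile")


def test_stack_m_values_aligns_arrays(small_dataset):
    mas = [compute_ma(correct_background(a, "subtract")) for a in small_dataset["arrays"]]
    m = stack_m_values(mas)
    assert m.shape == (len(small_dataset["annotation"]), len(small_dataset["arrays"]))
    assert list(m.columns) == [a.array_id for a in small_dataset["arrays"]]
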