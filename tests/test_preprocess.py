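"""Pre-treatment operators against explicit least-squares oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirseed.preprocess import (PreprocessPipeline, PreprocessStep,
                                cultivar_chain, detrend, emsc,
                                endophyte_chain, fit_apply_pipeline,
                                mean_center_apply, mean_center_fit, msc,
                                savgol, snv)

RNG = np.random.default_rng(7)


def lstsq_fit(basis, row):
    """Normal-equations oracle for a least-squares fit."""
    coef = np.linalg.solve(basis.T @ basis, basis.T @ row)
    return basis @ coef


class TestDetrend:
    def test_removes_exact_polynomials(self):
        i = np.arange(30, dtype=float)
        assert np.allclose(detrend(2.0 * i + 1.0, order=1), 0.0, atol=1e-10)
        assert np.allclose(detrend(0.5 * i**2 - i + 3, order=2), 0.0,
                           atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        row = RNG.normal(size=20)
        i = np.arange(20, dtype=float)
        basis = np.column_stack([np.ones(20), i])
        expected = row - lstsq_fit(basis, row)
        np.testing.assert_allclose(detrend(row, order=1)[0], expected,
                                   atol=1e-8)

    def test_idempotent(self):
        X = RNG.normal(size=(4, 25))
        once = detrend(X, order=2)
        np.testing.assert_allclose(detrend(once, order=2), once, atol=1e-10)

    def test_order_at_least_n_points_rejected(self):
        with pytest.raises(ValueError):
            detrend(np.ones((1, 5)), order=5)


class TestSNV:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0]))[0],
                                   [-1.0, 0.0, 1.0], atol=1e-12)

    def test_rows_standardised(self):
        X = RNG.normal(2.0, 3.0, size=(5, 40))
        out = snv(X)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_rejected_by_index(self):
        X = RNG.normal(size=(3, 10))
        X[1] = 4.2
        with pytest.raises(ValueError, match=r"\[1\]"):
            snv(X)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        X = np.random.default_rng(seed).normal(size=(3, 15))
        once = snv(X)
        np.testing.assert_allclose(snv(once), once, atol=1e-10)


class TestMSC:
    def test_reference_row_unchanged(self):
        ref = RNG.normal(0.5, 0.2, 30)
        np.testing.assert_allclose(msc(ref, ref)[0], ref, atol=1e-10)

    def test_affine_distortion_inverted(self):
        ref = RNG.normal(0.5, 0.2, 30)
        np.testing.assert_allclose(msc(2.0 * ref + 3.0, ref)[0], ref,
                                   atol=1e-9)

    def test_matches_2x2_normal_equations(self):
        ref = RNG.normal(0.5, 0.2, 25)
        row = RNG.normal(0.5, 0.3, 25)
        design = np.column_stack([np.ones(25), ref])
        b, a = np.linalg.solve(design.T @ design, design.T @ row)
        np.testing.assert_allclose(msc(row, ref)[0], (row - b) / a,
                                   atol=1e-9)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            msc(RNG.normal(size=10), np.ones(10))


class TestEMSC:
    def test_recovers_reference_under_quadratic_baseline(self):
        ref = np.sin(np.linspace(0, 3, 50)) + 2.0
        i = np.linspace(-1, 1, 50)
        row = ref + 0.3 * i**2 - 0.2 * i + 0.1
        np.testing.assert_allclose(emsc(row, ref, order=2)[0], ref,
                                   atol=1e-9)

    def test_order_zero_with_centered_reference_equals_msc(self):
        ref = RNG.normal(0.0, 0.2, 40)
        ref -= ref.mean()
        X = RNG.normal(0.5, 0.3, size=(3, 40))
        np.testing.assert_allclose(emsc(X, ref, order=0), msc(X, ref),
                                   atol=1e-8)

    def test_residual_orthogonal_to_design(self):
        ref = np.cos(np.linspace(0, 4, 30)) + 1.5
        row = RNG.normal(0.5, 0.3, 30)
        out = emsc(row, ref, order=2)[0]
        # reconstruct the fit residual: row = a*(out) + baseline with
        # residual orthogonal to [ref, polynomial basis]
        t = np.linspace(-1, 1, 30)
        basis = np.polynomial.legendre.legvander(t, 2)
        design = np.column_stack([ref, basis])
        coef, *_ = np.linalg.lstsq(design, row, rcond=None)
        resid = row - design @ coef
        np.testing.assert_allclose(design.T @ resid, 0.0, atol=1e-8)

    def test_collinear_reference_rejected(self):
        t = np.linspace(-1, 1, 20)
        with pytest.raises(ValueError, match="collinear"):
            emsc(RNG.normal(size=20), 1.0 + 2.0 * t, order=2)


class TestSavGol:
    def test_first_derivative_of_quadratic(self):
        i = np.arange(40, dtype=float)
        q = 0.3 * i**2 - 2.0 * i + 5.0
        out = savgol(q, window=15, polyorder=2, deriv=1)[0]
        np.testing.assert_allclose(out, 0.6 * i - 2.0, atol=1e-8)

    def test_second_derivative_of_quadratic_is_constant(self):
        i = np.arange(40, dtype=float)
        out = savgol(0.3 * i**2 + i, window=15, polyorder=2, deriv=2)[0]
        np.testing.assert_allclose(out, 0.6, atol=1e-8)

    def test_constant_row_derivative_zero(self):
        out = savgol(np.full(30, 2.5), window=15, polyorder=2, deriv=1)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_deriv0_fixes_low_degree_polynomials_on_interior(self):
        i = np.arange(50, dtype=float)
        q = 0.1 * i**2 - i + 2
        out = savgol(q, window=15, polyorder=2, deriv=0)[0]
        np.testing.assert_allclose(out[7:-7], q[7:-7], atol=1e-8)

    def test_interior_matches_local_polyfit_oracle(self):
        row = RNG.normal(size=41)
        out = savgol(row, window=15, polyorder=2, deriv=1)[0]
        pos = 20
        t = np.arange(-7, 8, dtype=float)
        coef = np.polynomial.polynomial.polyfit(t, row[pos - 7:pos + 8], 2)
        assert out[pos] == pytest.approx(coef[1], abs=1e-8)

    @pytest.mark.parametrize("window,polyorder", [(14, 2), (3, 4), (99, 2)])
    def test_bad_window_rejected(self, window, polyorder):
        with pytest.raises(ValueError):
            savgol(np.ones((1, 30)), window=window, polyorder=polyorder,
                   deriv=1)


class TestMeanCenter:
    def test_calibration_columns_centred_and_idempotent(self):
        X = RNG.normal(3.0, 1.0, size=(8, 12))
        means = mean_center_fit(X)
        centred = mean_center_apply(X, means)
        np.testing.assert_allclose(centred.mean(axis=0), 0.0, atol=1e-12)
        again = mean_center_apply(centred, mean_center_fit(centred))
        np.testing.assert_allclose(again, centred, atol=1e-12)

    def test_validation_uses_calibration_means(self):
        means = np.arange(5, dtype=float)
        np.testing.assert_allclose(
            mean_center_apply(np.zeros((1, 5)), means)[0], -means)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mean_center_apply(np.zeros((1, 5)), np.zeros(4))


class TestPipeline:
    def test_empty_pipeline_is_identity(self):
        X = RNG.normal(size=(3, 20))
        pipe = PreprocessPipeline()
        out, _ = fit_apply_pipeline(pipe, X)
        np.testing.assert_array_equal(out, X)

    def test_named_chains_have_documented_steps(self):
        kinds = [s.kind for s in cultivar_chain().steps]
        assert kinds == ["detrend", "msc", "savgol", "mean_center"]
        assert cultivar_chain().steps[2].params["deriv"] == 2
        kinds = [s.kind for s in endophyte_chain().steps]
        assert kinds == ["detrend", "snv", "savgol", "mean_center"]
        assert endophyte_chain().steps[2].params["deriv"] == 1

    def test_validation_transformed_with_calibration_state(self):
        Xc = RNG.normal(0.5, 0.1, size=(10, 30))
        Xv = RNG.normal(0.5, 0.1, size=(4, 30))
        pipe = cultivar_chain()
        out_c, out_v = fit_apply_pipeline(pipe, Xc, Xv)
        # calibration output exactly centred (final step fitted on cal)
        np.testing.assert_allclose(out_c.mean(axis=0), 0.0, atol=1e-10)
        # validation transformed with cal state: replay by hand
        msc_ref = pipe.steps[1].fitted_state["reference"]
        means = pipe.steps[3].fitted_state["means"]
        manual = mean_center_apply(
            savgol(msc(detrend(Xv, 1), msc_ref), 15, 2, 2), means)
        np.testing.assert_allclose(out_v, manual, atol=1e-10)

    def test_endophyte_chain_centres_calibration(self):
        Xc = RNG.normal(0.5, 0.1, size=(12, 40))
        out, _ = fit_apply_pipeline(endophyte_chain(), Xc)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)

    def test_unfitted_pipeline_rejected_on_new_data(self):
        pipe = cultivar_chain()
        with pytest.raises(RuntimeError, match="fitted"):
            pipe.transform(RNG.normal(size=(2, 20)))

    def test_row_permutation_equivariance(self):
        X = RNG.normal(0.5, 0.1, size=(6, 25))
        pipe = cultivar_chain()
        out = pipe.fit_transform(X)
        perm = np.array([3, 1, 5, 0, 4, 2])
        out_perm = pipe.transform(X[perm])
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)

    def test_serialisation_round_trip(self):
        X = RNG.normal(0.5, 0.1, size=(5, 20))
        pipe = endophyte_chain()
        pipe.fit_transform(X)
        back = PreprocessPipeline.from_dict(pipe.to_dict())
        Xnew = RNG.normal(0.5, 0.1, size=(2, 20))
        np.testing.assert_allclose(back.transform(Xnew),
                                   pipe.transform(Xnew), atol=1e-12)

    def test_shapes_preserved_by_all_operators(self):
        X = RNG.normal(0.5, 0.1, size=(4, 30))
        ref = X.mean(axis=0)
        for out in (detrend(X), snv(X), msc(X, ref), emsc(X, ref, 2),
                    savgol(X), mean_center_apply(X, mean_center_fit(X))):
            assert out.shape == X.shape
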