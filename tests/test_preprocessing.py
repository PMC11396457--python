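import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from saffronir import (
    PreprocessPipeline,
    SpectraSet,
    WavelengthGrid,
    build_method_pipeline,
    detrend,
    first_difference,
    savgol,
    snv,
)
from saffronir.preprocess import METHOD_STEPS, MeanCenterStep, MSCStep


def make_set(matrix, lam=None):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    lam = np.arange(1000.0, 1000.0 + matrix.shape[1]) if lam is None else lam
    ids = [f"S{i}" for i in range(matrix.shape[0])]
    return SpectraSet(ids, WavelengthGrid(lam), matrix)


class TestSNV:
    def test_three_point_row(self):
        out = snv(make_set([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0])

    def test_normalized_row_unchanged(self):
        row = np.array([-1.0, 0.0, 1.0])  # zero mean, unit sample SD
        out = snv(make_set([row]))
        np.testing.assert_allclose(out.absorbance[0], row, atol=1e-12)

    def test_constant_row_names_sample(self):
        with pytest.raises(ValueError, match="S1"):
            snv(make_set([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))

    @given(
        X=hnp.arrays(
            float,
            (10, 50),
            elements=st.floats(-10, 10, allow_nan=False, width=64),
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_row_identities(self, X):
        X = X + np.linspace(0, 1, 50)  # ensure non-constant rows
        out = snv(make_set(X)).absorbance
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestMSC:
    def test_reference_is_column_mean(self, small_spectra):
        step = MSCStep().fit(small_spectra)
        np.testing.assert_allclose(
            step.fitted_state["reference"], small_spectra.absorbance.mean(axis=0)
        )

    def test_reference_of_scaled_pair(self):
        ref = np.sin(np.linspace(0, 3, 20)) + 2.0
        s = make_set([ref, 2 * ref])
        step = MSCStep().fit(s)
        np.testing.assert_allclose(step.fitted_state["reference"], 1.5 * ref)

    def test_exact_inversion_of_scatter_model(self):
        ref = np.sin(np.linspace(0, 3, 30)) + 2.0
        s = make_set([ref, 5.0 + 2.0 * ref, -0.3 + 0.7 * ref])
        step = MSCStep().fit(make_set([ref, ref]))
        out = step.apply(s).absorbance
        for row in out:
            np.testing.assert_allclose(row, ref, atol=1e-9)

    def test_single_sample_fit_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            MSCStep().fit(make_set([[1.0, 2.0, 3.0]]))

    def test_unfitted_apply_rejected(self, small_spectra):
        with pytest.raises(RuntimeError, match="before fitting"):
            MSCStep().apply(small_spectra)

    def test_scatter_noise_reduced(self, rng):
        # gain/offset corrupted copies of one clean spectrum: MSC should
        # shrink the RMSE to the clean spectrum by at least 5x
        lam = np.arange(1000.0, 1200.0)
        clean = 0.5 + 0.3 * np.exp(-0.5 * ((lam - 1100) / 20) ** 2)
        gains = rng.uniform(0.7, 1.3, size=20)
        offs = rng.uniform(-0.1, 0.1, size=20)
        X = gains[:, None] * clean + offs[:, None]
        s = make_set(X, lam)
        out = MSCStep().fit(s).apply(s).absorbance
        rmse_pre = np.sqrt(np.mean((X - clean) ** 2))
        rmse_post = np.sqrt(np.mean((out - clean) ** 2))
        assert rmse_post < rmse_pre / 5


class TestDetrend:
    def test_annihilates_quadratic(self):
        lam = np.arange(1000.0, 1100.0)
        row = 3.0 - 0.01 * lam + 2e-5 * lam**2
        out = detrend(make_set([row], lam), order=2)
        np.testing.assert_allclose(out.absorbance, 0.0, atol=1e-9)

    def test_order_zero_is_mean_removal(self, small_spectra):
        out = detrend(small_spectra, order=0).absorbance
        expected = small_spectra.absorbance - small_spectra.absorbance.mean(
            axis=1, keepdims=True
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_residual_orthogonal_to_basis(self, rng):
        lam = np.arange(1000.0, 1150.0)
        row = rng.normal(size=lam.size)
        resid = detrend(make_set([row], lam), order=3).absorbance[0]
        V = np.vander((lam - lam.mean()) / 75.0, 4)
        assert np.max(np.abs(resid @ V)) < 1e-8

    def test_excessive_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            detrend(make_set([[1.0, 2.0, 3.0]]), order=3)


class TestSavgol:
    def test_center_weights_quadratic_window5(self):
        # classic smoothing weights [-3, 12, 17, 12, -3]/35 recovered by
        # filtering unit impulses
        impulses = make_set(np.eye(9))
        out = savgol(impulses, window=5, polyorder=2, deriv=0)
        np.testing.assert_allclose(
            out.absorbance[2:7, 4], np.array([-3, 12, 17, 12, -3]) / 35, atol=1e-12
        )

    def test_polynomial_exactness(self):
        lam = np.arange(1000.0, 1050.0)
        row = 1.0 + 0.02 * (lam - 1000) - 3e-4 * (lam - 1000) ** 2
        out = savgol(make_set([row], lam), window=11, polyorder=2, deriv=0)
        np.testing.assert_allclose(out.absorbance[0], row, atol=1e-8)

    def test_linear_derivative_is_slope(self):
        lam = np.arange(1000.0, 1050.0, 0.5)  # step 0.5 nm checks delta scaling
        b = 0.004
        out = savgol(make_set([0.2 + b * lam], lam), window=11, polyorder=2, deriv=1)
        np.testing.assert_allclose(out.absorbance[0], b, atol=1e-10)

    @pytest.mark.parametrize(
        "kwargs", [dict(window=4), dict(window=5, polyorder=5), dict(window=1)]
    )
    def test_invalid_params_rejected(self, small_spectra, kwargs):
        with pytest.raises(ValueError):
            savgol(small_spectra, **{"polyorder": 2, **kwargs})


class TestFirstDifference:
    def test_constant_row_zeros(self):
        out = first_difference(make_set([[2.0] * 10]))
        np.testing.assert_allclose(out.absorbance, 0.0)
        assert out.n_wavelengths == 9

    def test_linear_row_slope(self):
        lam = np.arange(1000.0, 1020.0, 2.0)
        out = first_difference(make_set([0.1 + 0.03 * lam], lam))
        np.testing.assert_allclose(out.absorbance[0], 0.03, atol=1e-12)
        np.testing.assert_allclose(out.grid.values, lam[:-1] + 1.0)

    def test_matches_brute_force(self, small_spectra):
        out = first_difference(small_spectra).absorbance
        X, lam = small_spectra.absorbance, small_spectra.grid.values
        brute = (X[:, 1:] - X[:, :-1]) / (lam[1:] - lam[:-1])
        np.testing.assert_allclose(out, brute)

    def test_too_narrow_input_rejected(self):
        s = SpectraSet(["a"], WavelengthGrid([1000.0, 1001.0]), [[1.0, 2.0]])
        with pytest.raises(ValueError, match="at least 3"):
            first_difference(s)


class TestMeanCenter:
    def test_calibration_columns_zero(self, small_spectra):
        step = MeanCenterStep().fit(small_spectra)
        out = step.apply(small_spectra).absorbance
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)

    def test_calibration_means_reused_on_new_data(self, small_spectra, rng):
        step = MeanCenterStep().fit(small_spectra)
        other = small_spectra.with_absorbance(
            small_spectra.absorbance + rng.normal(1.0, 0.1, small_spectra.absorbance.shape)
        )
        out = step.apply(other).absorbance
        assert np.abs(out.mean(axis=0)).max() > 0.1  # not re-centred on new data

    def test_grid_mismatch_rejected(self, small_spectra):
        step = MeanCenterStep().fit(small_spectra)
        from saffronir import crop_band

        with pytest.raises(ValueError, match="grid"):
            step.apply(crop_band(small_spectra, 1100, 2000))


class TestMethodPipelines:
    def test_method2_structure(self):
        p = build_method_pipeline("method2")
        kinds = [s.kind for s in p.steps]
        assert kinds == ["MSC", "SG", "SG", "MEAN_CENTER"]
        assert p.steps[1].params["deriv"] == 0 and p.steps[2].params["deriv"] == 1

    def test_method3_has_no_scatter_reference(self):
        p = build_method_pipeline("method3")
        assert len(p.steps) == 3
        assert all(s.kind != "MSC" and s.kind != "SNV" for s in p.steps)

    def test_method1_order_matches_catalog(self):
        p = build_method_pipeline("method1")
        assert [s.kind for s in p.steps] == ["SNV", "DT", "SG", "SG", "MEAN_CENTER"]
        assert tuple(METHOD_STEPS) == ("method1", "method2", "method3")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method9"):
            build_method_pipeline("method9")


class TestPipelineFitApply:
    @pytest.mark.parametrize("method", ["method1", "method2", "method3"])
    def test_calibration_block_centered(self, tiny_dataset, method):
        spectra, _, _ = tiny_dataset
        p = build_method_pipeline(method)
        cal_t, _ = p.fit_apply(spectra)
        np.testing.assert_allclose(cal_t.absorbance.mean(axis=0), 0.0, atol=1e-10)

    def test_deterministic_reapplication(self, tiny_dataset):
        spectra, _, _ = tiny_dataset
        p = build_method_pipeline("method2")
        cal_t, _ = p.fit_apply(spectra)
        again = p.apply(spectra)
        np.testing.assert_array_equal(cal_t.absorbance, again.absorbance)

    def test_unfitted_pipeline_rejected(self, small_spectra):
        p = build_method_pipeline("method2", sg_window=5)
        with pytest.raises(RuntimeError, match="unfitted"):
            p.apply(small_spectra)

    def test_fitted_state_independent_of_prediction_rows(self, tiny_dataset, rng):
        spectra, _, _ = tiny_dataset
        cal = spectra.subset(spectra.sample_ids[:80])
        pred = spectra.subset(spectra.sample_ids[80:])
        pred_perturbed = pred.with_absorbance(pred.absorbance + rng.normal(0, 1, pred.absorbance.shape))

        p1 = build_method_pipeline("method2")
        p1.fit_apply(cal, [pred])
        p2 = build_method_pipeline("method2")
        p2.fit_apply(cal, [pred_perturbed])
        for s1, s2 in zip(p1.steps, p2.steps):
            if s1.fitted_state is not None:
                np.testing.assert_array_equal(
                    s1.fitted_state["reference" if s1.kind == "MSC" else "column_means"],
                    s2.fitted_state["reference" if s2.kind == "MSC" else "column_means"],
                )

    def test_serialization_bit_identical(self, tiny_dataset, tmp_path):
        spectra, _, _ = tiny_dataset
        p = build_method_pipeline("method2")
        cal_t, _ = p.fit_apply(spectra)
        back = PreprocessPipeline.from_json(p.to_json(tmp_path / "p.json"))
        assert back.name == "method2"
        np.testing.assert_array_equal(back.apply(spectra).absorbance, cal_t.absorbance)
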