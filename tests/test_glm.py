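"""Design construction, OLS fitting, contrasts and collinearity checks."""

import numpy as np
import pandas as pd
import pytest

from memtrace import glm
from memtrace.simulate import (NoiseSpec, PatternSpec, TaskDesign,
                               simulate_bold)
from memtrace.simulate.bold import default_grid_shape


def single_event_table(onset=0.0, duration=1.0, cond="a"):
    return pd.DataFrame({"onset": [onset], "duration": [duration],
                         "trial_type": [cond]})


class TestBuildDesign:
    def test_hrf_regressor_peaks_five_to_six_seconds(self):
        """Oracle: sample the convolved response on a fine grid; the Glover
        response to a brief event must peak ~5-6 s after onset."""
        fine = np.arange(0, 32, 0.1)
        reg = glm.hrf_regressor([0.0], [1.0], [1.0], fine)
        peak = fine[np.argmax(reg)]
        assert 4.0 < peak < 7.0
        coarse = glm.build_design(single_event_table(), None, 2.0, 16)
        assert coarse["a"].to_numpy().argmax() * 2.0 == pytest.approx(peak, abs=2.0)

    def test_no_events_leaves_nuisance_only(self):
        events = pd.DataFrame({"onset": [], "duration": [], "trial_type": []})
        X = glm.build_design(events, pd.DataFrame({"c0": np.zeros(60) + np.arange(60)}),
                             2.0, 60)
        assert X.attrs["event_columns"] == []
        assert "intercept" in X.columns and "c0" in X.columns
        assert any(c.startswith("drift_") for c in X.columns)

    def test_model_variants_select_epochs(self, assoc_factors):
        sub = assoc_factors[assoc_factors["run"] == 1]
        ev_fb = glm.label_association_events(sub, "recall_confidence_feedback")
        ev_enc = glm.label_association_events(sub, "recall_confidence_encoding")
        assert (ev_fb["epoch"] == "feedback").any()
        assert not (ev_fb["epoch"] == "encoding").any()
        assert (ev_enc["epoch"] == "encoding").any()
        assert not (ev_enc["epoch"] == "feedback").any()
        # recall conditions split by accuracy x confidence in both variants
        recall_types = set(ev_fb.loc[ev_fb["epoch"] == "recall", "trial_type"])
        assert recall_types <= {
            "recall_Error_ConfidenceLow", "recall_Error_ConfidenceHigh",
            "recall_Correct_ConfidenceLow", "recall_Correct_ConfidenceHigh"}

    def test_design_deterministic(self, assoc_factors):
        sub = assoc_factors[assoc_factors["run"] == 1]
        ev = glm.label_association_events(sub, "recall_confidence_feedback")
        X1 = glm.build_design(ev, None, 2.0, 200)
        X2 = glm.build_design(ev, None, 2.0, 200)
        assert list(X1.columns) == list(X2.columns)
        assert np.array_equal(X1.to_numpy(), X2.to_numpy())


@pytest.fixture(scope="module")
def noise_free_fit(design, localizer_schedule, pattern):
    sub = localizer_schedule[localizer_schedule["run"] == 1]
    vol, truth = simulate_bold(
        sub, pattern, NoiseSpec(sigma=0.0, n_drift=0, n_confounds=0, seed=0),
        design)
    events = glm.label_localizer_events(sub)
    X = glm.build_design(events, None, design.tr, vol.n_frames)
    return vol, X, glm.fit_glm(vol, X), truth


class TestFitGlm:
    def test_noise_free_betas_recover_injected_pattern(self, noise_free_fit, pattern):
        _, _, fit, _ = noise_free_fit
        rec = fit.beta_map("face_correctrejection")[pattern.roi_mask]
        rel = np.abs(rec - pattern.face_pattern) / np.abs(pattern.face_pattern)
        assert rel.max() < 1e-8

    def test_orthogonal_confound_leaves_betas_unchanged(self, design,
                                                        localizer_schedule,
                                                        pattern):
        sub = localizer_schedule[localizer_schedule["run"] == 1]
        vol, _ = simulate_bold(
            sub, pattern, NoiseSpec(sigma=0.0, n_drift=0, n_confounds=0, seed=0),
            design)
        events = glm.label_localizer_events(sub)
        X0 = glm.build_design(events, None, design.tr, vol.n_frames)
        fit0 = glm.fit_glm(vol, X0)
        # orthogonalize a random confound against every existing column
        rng = np.random.default_rng(1)
        raw = rng.standard_normal(vol.n_frames)
        base = X0.to_numpy()
        resid = raw - base @ np.linalg.lstsq(base, raw, rcond=None)[0]
        X1 = glm.build_design(events, pd.DataFrame({"orth": resid}),
                              design.tr, vol.n_frames)
        fit1 = glm.fit_glm(vol, X1)
        for col in X0.attrs["event_columns"]:
            assert np.allclose(fit0.beta_map(col), fit1.beta_map(col), atol=1e-10)

    def test_rank_deficient_design_raises_with_columns(self, noise_free_fit):
        vol, X, _, _ = noise_free_fit
        bad = X.copy()
        bad["dup"] = bad["face_correctrejection"]
        with pytest.raises(glm.SingularDesignError):
            glm.fit_glm(vol, bad)

    def test_ar1_noise_betas_unbiased(self, design, localizer_schedule, pattern):
        """Simulation oracle: across replicates, OLS betas under AR(1) noise
        center on the injected amplitude."""
        sub = localizer_schedule[localizer_schedule["run"] == 1]
        events = glm.label_localizer_events(sub)
        errs = []
        for rep in range(60):
            vol, _ = simulate_bold(
                sub, pattern,
                NoiseSpec(sigma=0.5, ar_coefficient=0.4, n_drift=0,
                          n_confounds=0, seed=1000 + rep), design)
            X = glm.build_design(events, None, design.tr, vol.n_frames)
            fit = glm.fit_glm(vol, X)
            rec = fit.beta_map("face_correctrejection")[pattern.roi_mask]
            errs.append((rec - pattern.face_pattern).mean())
        errs = np.array(errs)
        ci_half = 3 * errs.std(ddof=1) / np.sqrt(len(errs))
        assert abs(errs.mean()) < ci_half


class TestContrast:
    def test_zero_weights_zero_everywhere(self, noise_free_fit):
        _, _, fit, _ = noise_free_fit
        con = glm.contrast(fit, {"face_correctrejection": 0.0})
        assert np.all(con.effect == 0) and np.all(con.t == 0)

    def test_negation_antisymmetric(self, noise_free_fit):
        _, _, fit, _ = noise_free_fit
        w = {"face_correctrejection": 1, "house_correctrejection": -1}
        con = glm.contrast(fit, w)
        neg = glm.contrast(fit, {k: -v for k, v in w.items()})
        assert np.array_equal(con.effect, -neg.effect)
        assert np.allclose(con.t, -neg.t)

    def test_linearity_on_effect_maps(self, noise_free_fit):
        _, _, fit, _ = noise_free_fit
        w1 = {"face_correctrejection": 1.0}
        w2 = {"house_correctrejection": -0.5}
        both = glm.contrast(fit, {**w1, **w2})
        assert np.allclose(both.effect,
                           glm.contrast(fit, w1).effect + glm.contrast(fit, w2).effect)

    def test_planted_activation_localized(self, design, localizer_schedule,
                                          pattern):
        sub = localizer_schedule[localizer_schedule["run"] == 1]
        vol, _ = simulate_bold(
            sub, pattern, NoiseSpec(sigma=0.02, n_drift=0, n_confounds=0, seed=5),
            design)
        events = glm.label_localizer_events(sub)
        X = glm.build_design(events, None, design.tr, vol.n_frames)
        con = glm.contrast(glm.fit_glm(vol, X), {"face_correctrejection": 1})
        inside = con.effect[pattern.roi_mask].mean()
        outside = np.abs(con.effect[~pattern.roi_mask]).max()
        assert inside > 10 * outside

    def test_missing_column_raises(self, noise_free_fit):
        _, _, fit, _ = noise_free_fit
        with pytest.raises(KeyError):
            glm.contrast(fit, {"nonexistent": 1.0})

    def test_t_to_z_preserves_tail_probability(self):
        from scipy import stats
        t = np.array([-6.0, -1.3, 0.0, 0.7, 2.2, 9.0])
        df = 29
        z = glm.t_to_z(t, df)
        assert np.allclose(stats.norm.sf(np.abs(z)),
                           stats.t.sf(np.abs(t), df), rtol=1e-10)
        assert np.all(np.sign(z) == np.sign(t))

    def test_r_squared_definition(self, noise_free_fit):
        _, _, fit, _ = noise_free_fit
        con = glm.contrast(fit, {"face_correctrejection": 1})
        assert np.all((con.r_squared >= 0) & (con.r_squared <= 1))
        assert np.allclose(con.r_squared, con.t**2 / (con.t**2 + con.df))


class TestCollinearity:
    def test_orthogonal_regressors_unit_vif(self):
        n = 100
        t = np.arange(n)
        X = pd.DataFrame({"a": np.sin(2 * np.pi * t / n),
                          "b": np.cos(2 * np.pi * t / n),
                          "c": np.sin(4 * np.pi * t / n)},
                         index=t * 2.0)
        X.attrs["event_columns"] = ["a", "b", "c"]
        diag = glm.collinearity_diagnostics(X)
        assert np.allclose(diag["vif"], 1.0)
        assert (diag["flag"] == "none").all()

    def test_duplicated_regressor_infinite_vif(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(80)
        X = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.standard_normal(80)})
        X.attrs["event_columns"] = ["a", "b", "c"]
        diag = glm.collinearity_diagnostics(X).set_index("regressor")
        assert np.isinf(diag.loc["a", "vif"]) and diag.loc["a", "flag"] == "high"
        assert diag.loc["a", "max_abs_r"] == pytest.approx(1.0)

    def test_vif_matches_independent_definition(self):
        """Definitional oracle: VIF_j = 1/(1-R^2_j) from a separate OLS fit
        using statsmodels on each column."""
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        base = rng.standard_normal((120, 3))
        mixed = base @ np.array([[1, 0.4, 0.1], [0, 1, 0.6], [0, 0, 1.0]])
        X = pd.DataFrame(mixed, columns=["a", "b", "c"])
        X.attrs["event_columns"] = ["a", "b", "c"]
        diag = glm.collinearity_diagnostics(X).set_index("regressor")
        for j, name in enumerate(["a", "b", "c"]):
            others = sm.add_constant(np.delete(mixed, j, axis=1))
            r2 = sm.OLS(mixed[:, j], others).fit().rsquared
            assert diag.loc[name, "vif"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-8)
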