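"""Design-matrix construction, OLS engine, contrasts, conjunction, ROI."""

import numpy as np
import pandas as pd
import pytest

import moralsv as m
from moralsv import glm
from moralsv.errors import ValidationError


def events_frame(onsets, svs, task="moral", duration=0.0):
    return pd.DataFrame(
        {
            "onset": np.asarray(onsets, float),
            "duration": duration,
            "trial_type": task,
            "sv": np.asarray(svs, float),
        }
    )


class TestBuildDesign:
    def test_zero_events_gives_drift_and_intercept_only(self):
        design = glm.build_design(events_frame([], []), tr=2.0, n_scans=50)
        assert design.names == ["drift_1", "drift_2", "intercept"]
        assert design.full_rank

    def test_constant_sv_centers_to_zero_column(self):
        design = glm.build_design(
            events_frame([10.0, 30.0, 50.0], [4.0, 4.0, 4.0]), tr=2.0, n_scans=60
        )
        assert np.linalg.norm(design.frame["moral_sv"]) < 1e-10
        assert np.linalg.norm(design.frame["moral_onset"]) > 1.0

    def test_modulator_column_equals_direct_convolution(self):
        """Two sticks: the modulator column equals a hand-summed shifted-HRF
        superposition weighted by the centered SVs."""
        tr, n_scans, oversample = 2.0, 80, 16
        onsets = [8.0, 100.0]
        svs = [3.0, 7.0]
        design = glm.build_design(events_frame(onsets, svs), tr=tr, n_scans=n_scans,
                                  oversample=oversample)
        dt = tr / oversample
        hrf = glm.double_gamma_hrf(dt)
        centered = np.asarray(svs) - np.mean(svs)
        expected = np.zeros(n_scans)
        scan_times = np.arange(n_scans) * tr
        for onset, weight in zip(onsets, centered):
            for i, t in enumerate(scan_times):
                lag = t - np.floor(onset / dt) * dt
                j = int(round(lag / dt))
                if 0 <= j < len(hrf):
                    expected[i] += weight * hrf[j]
        np.testing.assert_allclose(design.frame["moral_sv"], expected, atol=1e-10)

    def test_onset_beyond_horizon_rejected(self):
        with pytest.raises(ValidationError):
            glm.build_design(events_frame([500.0], [1.0]), tr=2.0, n_scans=50)


@pytest.fixture(scope="module")
def design():
    rng = np.random.default_rng(0)
    events = events_frame(np.sort(rng.uniform(5, 180, 40)), rng.normal(5, 2, 40))
    return glm.build_design(events, tr=2.0, n_scans=100)


@pytest.fixture(scope="module")
def injected_result(agent, financial_design, moral_design):
    from moralsv import synthetic

    datasets = [
        m.simulate_choices(agent, financial_design, seed=41),
        m.simulate_choices(agent, moral_design, seed=43),
    ]
    truth = synthetic.BoldTruthConfig(
        clusters=[
            synthetic.TruthCluster("mor", (2, 2, 2), 1.5, "moral_sv", 1.0),
        ],
        noise_sd=0.5,
    )
    bold = m.simulate_bold(datasets, truth, seed=47, shape=(8, 8, 8))
    bold_design = glm.build_design(bold.events, tr=bold.tr, n_scans=bold.n_scans)
    return glm.fit_glm(bold, bold_design), truth


class TestFitGlm:
    def test_noiseless_identity(self, design):
        rng = np.random.default_rng(1)
        true_b = rng.normal(size=(design.matrix.shape[1], 4))
        data = (design.matrix @ true_b).T.reshape(2, 2, 1, -1)
        result = glm.fit_glm(data, design)
        np.testing.assert_allclose(
            result.betas.reshape(len(design.names), -1), true_b, atol=1e-10
        )

    def test_betas_match_normal_equations(self, design):
        """Vectorized engine equals the closed-form (X'X)^-1 X'y solution."""
        rng = np.random.default_rng(2)
        data = rng.normal(size=(3, 3, 2, 100))
        result = glm.fit_glm(data, design)
        x = design.matrix
        closed = np.linalg.solve(x.T @ x, x.T @ data.reshape(-1, 100).T)
        np.testing.assert_allclose(
            result.betas.reshape(len(design.names), -1), closed, atol=1e-8
        )

    def test_t_statistics_match_statsmodels(self, design):
        """Independent cross-check of the t engine on a single voxel."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        y = design.matrix @ rng.normal(size=design.matrix.shape[1]) + rng.normal(size=100)
        result = glm.fit_glm(y.reshape(1, 1, 1, -1), design)
        ref = sm.OLS(y, design.matrix).fit()
        idx = design.names.index("moral_sv")
        t_mine = result.t_map({"moral_sv": 1.0})[0, 0, 0]
        assert t_mine == pytest.approx(ref.tvalues[idx], rel=1e-8)
        assert result.residual_df == int(ref.df_resid)

    def test_zero_variance_voxel_masked(self, design):
        data = np.zeros((2, 1, 1, 100))
        data[0, 0, 0] = design.frame["intercept"] * 7.0  # exact fit, zero residual
        result = glm.fit_glm(data, design)
        t = result.t_map({"moral_sv": 1.0})
        assert np.isnan(t[0, 0, 0]) and np.isnan(t[1, 0, 0])

    def test_time_mismatch_rejected(self, design):
        with pytest.raises(ValidationError):
            glm.fit_glm(np.zeros((2, 2, 2, 55)), design)


class TestContrasts:
    def test_domain_contrast_isolates_injected_cluster(self, injected_result):
        res, truth = injected_result
        t_map = m.contrast_sv_domains(res, pair=("moral_sv", "financial_sv"))
        cluster = truth.clusters[0].voxels((8, 8, 8))
        inside = np.mean([t_map[v] for v in cluster])
        outside_mask = np.ones((8, 8, 8), bool)
        for v in cluster:
            outside_mask[v] = False
        assert inside > 5.0
        assert abs(np.nanmean(t_map[outside_mask])) < 0.5

    def test_negating_column_equals_negating_weight(self, injected_result):
        res, _ = injected_result
        a = m.contrast_sv_domains(res, pair=("-moral_sv", "financial_sv"))
        b = -res.t_map({"moral_sv": 1.0, "financial_sv": 1.0})
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_contrast_linearity(self, injected_result):
        res, _ = injected_result
        combined = res.t_map({"moral_sv": 1.0, "financial_sv": -1.0})
        # the effect (numerator) is linear; check via beta maps
        eff = res.beta_map("moral_sv") - res.beta_map("financial_sv")
        var_scale = res.contrast_vector({"moral_sv": 1.0, "financial_sv": -1.0})
        scale = float(var_scale @ res.xtx_inv @ var_scale)
        np.testing.assert_allclose(combined, eff / np.sqrt(res.sigma2 * scale), atol=1e-10)

    def test_unknown_regressor_rejected(self, injected_result):
        res, _ = injected_result
        with pytest.raises(ValidationError):
            m.contrast_sv_domains(res, pair=("moral_sv", "banana"))


class TestConjunction:
    def test_equal_maps_reduce_to_single_threshold(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=(6, 6, 6))
        np.testing.assert_array_equal(m.conjunction(t, t, 1.5), t > 1.5)

    def test_minus_infinity_threshold_keeps_everything(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=(4, 4, 4))
        assert m.conjunction(t, t, -np.inf).all()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            m.conjunction(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)), 3.0)


class TestRoi:
    def test_constant_map_returns_value(self):
        roi = m.RoiSpec(center=(5, 5, 5), radius_mm=8.0, voxel_size_mm=3.0)
        assert m.roi_mean(np.full((10, 10, 10), 4.2), roi) == pytest.approx(4.2)

    def test_tiny_radius_is_single_voxel(self):
        data = np.zeros((6, 6, 6))
        data[2, 3, 4] = 9.0
        roi = m.RoiSpec(center=(2, 3, 4), radius_mm=1.0, voxel_size_mm=3.0)
        assert m.roi_mean(data, roi) == pytest.approx(9.0)

    def test_sphere_voxel_count_matches_lattice_enumeration(self):
        """8 mm sphere on a 3 mm grid against brute-force lattice counting."""
        shape = (12, 12, 12)
        center, radius, vs = (6, 6, 6), 8.0, 3.0
        roi = m.RoiSpec(center=center, radius_mm=radius, voxel_size_mm=vs)
        brute = sum(
            1
            for i in range(shape[0])
            for j in range(shape[1])
            for k in range(shape[2])
            if ((i - center[0]) ** 2 + (j - center[1]) ** 2 + (k - center[2]) ** 2)
            * vs**2
            <= radius**2
        )
        assert roi.mask(shape).sum() == brute
        assert brute > 1  # genuinely multi-voxel at this radius

    def test_empty_sphere_rejected(self):
        roi = m.RoiSpec(center=(50, 50, 50), radius_mm=2.0, voxel_size_mm=3.0)
        with pytest.raises(ValidationError):
            m.roi_mean(np.zeros((5, 5, 5)), roi)
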