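"""Cohort generator: marginals, copula dependence, rendering."""

import numpy as np
import pytest
from scipy import stats as sps

from hepamri.phantom import (
    CONTINUOUS_VARIABLES,
    VARIABLES,
    AnimalRecord,
    GroupSpec,
    NoiseModel,
    cohort_to_frame,
    default_dependence,
    default_group_specs,
    default_layout,
    nearest_psd_correlation,
    render_animal,
    sample_cohort,
    simulate_observers,
    spearman_to_latent,
)


class TestGroupSpec:
    def test_defaults_validate(self):
        control, model = default_group_specs()
        assert control.n == model.n == 10
        assert control.param_means["MD"] == pytest.approx(1.76e-3)

    def test_bad_pmf_rejected(self):
        control, _ = default_group_specs()
        with pytest.raises(ValueError, match="pmf"):
            GroupSpec(
                name="control", n=10,
                param_means=control.param_means,
                param_sds=control.param_sds,
                score_dist={"I_score": (0.5, 0.6)},
            )

    def test_asymmetric_dependence_rejected(self):
        control, _ = default_group_specs()
        dep = np.eye(len(VARIABLES))
        dep[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            GroupSpec(
                name="control", n=10,
                param_means=control.param_means,
                param_sds=control.param_sds,
                score_dist=control.score_dist,
                dependence=dep,
            )


class TestDependence:
    def test_default_dependence_is_valid_copula_target(self):
        dep = default_dependence()
        latent = spearman_to_latent(dep)
        np.fill_diagonal(latent, 1.0)
        assert np.linalg.eigvalsh(latent).min() >= -1e-8
        np.testing.assert_allclose(np.diag(dep), 1.0)
        np.testing.assert_allclose(dep, dep.T, atol=1e-12)

    def test_default_dependence_preserves_sign_pattern(self):
        """The PSD completion shrinks the specified block toward
        feasibility but must keep the signs and a usable magnitude of
        the strong reference associations."""
        dep = default_dependence()
        from hepamri.phantom import _MR_REF_SPEARMAN

        block = dep[0:6, 6:14]
        strong = np.abs(_MR_REF_SPEARMAN) > 0.5
        assert np.all(np.sign(block[strong]) == np.sign(_MR_REF_SPEARMAN[strong]))
        assert np.all(np.abs(block[strong]) > 0.25)

    def test_nearest_psd_projection_is_psd_and_unit_diag(self):
        m = np.array([[1.0, 0.95, -0.9], [0.95, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        out = nearest_psd_correlation(m)
        assert np.linalg.eigvalsh(out).min() >= -1e-10
        np.testing.assert_allclose(np.diag(out), 1.0)


class TestSampling:
    def test_deterministic_given_seed(self):
        control, model = default_group_specs()
        a = cohort_to_frame(sample_cohort(control, model, 123))
        b = cohort_to_frame(sample_cohort(control, model, 123))
        c = cohort_to_frame(sample_cohort(control, model, 124))
        assert a.equals(b)
        assert not a.equals(c)

    def test_group_sizes_and_columns(self):
        control, model = default_group_specs(8, 12)
        frame = cohort_to_frame(sample_cohort(control, model, 7))
        assert (frame["group"] == "control").sum() == 8
        assert (frame["group"] == "model").sum() == 12
        for v in VARIABLES:
            assert v in frame.columns

    def test_marginal_recovery_large_n(self):
        """With many animals the sample means/SDs approach the group
        specification."""
        control, model = default_group_specs(4000, 4000)
        frame = cohort_to_frame(sample_cohort(control, model, 42))
        ctrl = frame[frame["group"] == "control"]
        for var in ("PF", "MD", "R2star", "MDA"):
            mu = control.param_means[var]
            sd = control.param_sds[var]
            assert ctrl[var].mean() == pytest.approx(mu, abs=0.08 * sd + 1e-12)
            assert ctrl[var].std(ddof=1) == pytest.approx(sd, rel=0.08)

    def test_rank_correlation_targets_recovered(self):
        """Pooled Spearman correlations track the dependence targets."""
        control, model = default_group_specs(3000, 3000)
        frame = cohort_to_frame(sample_cohort(control, model, 11))
        ctrl = frame[frame["group"] == "control"]
        dep = control.dependence
        for mr, ref in (("R2star", "SOD"), ("PF", "MDA"), ("MD", "ALT")):
            target = dep[VARIABLES.index(mr), VARIABLES.index(ref)]
            got = sps.spearmanr(ctrl[mr], ctrl[ref]).statistic
            assert got == pytest.approx(target, abs=0.06)

    def test_clip_and_identifiability_floor(self):
        control, model = default_group_specs(500, 500)
        frame = cohort_to_frame(sample_cohort(control, model, 5))
        assert (frame["Dfast"] >= 5.0 * frame["Dslow"] - 1e-15).all()
        assert (frame["SOD"] >= 1.0).all()
        assert frame["FA"].between(0.0, 0.999).all()

    def test_control_scores_all_zero_model_scores_spread(self):
        control, model = default_group_specs(200, 200)
        frame = cohort_to_frame(sample_cohort(control, model, 31))
        ctrl = frame[frame["group"] == "control"]
        modl = frame[frame["group"] == "model"]
        assert (ctrl["I_score"] == 0).all() and (ctrl["F_score"] == 0).all()
        assert set(modl["I_score"]) == {0, 1, 2}
        # pmf (0.4, 0.4, 0.2) for inflammation
        assert (modl["I_score"] == 0).mean() == pytest.approx(0.4, abs=0.1)


class TestLayout:
    def test_default_layout_properties(self, layout):
        assert layout.grid_shape == (40, 40, 5)
        assert layout.vessel_mask.sum() > 0
        assert not np.any(layout.vessel_mask & ~layout.liver_mask)
        assert layout.liver_mask.any(axis=(0, 1)).sum() >= 3

    def test_vessel_outside_liver_rejected(self):
        liver = np.zeros((10, 10, 3), dtype=bool)
        liver[2:8, 2:8, :] = True
        vessel = np.zeros_like(liver)
        vessel[0, 0, 0] = True
        from hepamri.phantom import PhantomLayout

        with pytest.raises(ValueError, match="subset"):
            PhantomLayout(liver, vessel)


def _record():
    return AnimalRecord(
        id="control-01", group="control",
        mr={"Dslow": 1.29e-3, "Dfast": 32.33e-3, "PF": 30.44,
            "MD": 1.76e-3, "FA": 0.36, "R2star": 88.89},
        biochem={"ALT": 34.5}, histology={"I_score": 0},
    )


class TestRendering:
    def test_series_shapes_and_determinism(self, layout):
        noise = NoiseModel("rician", 50.0, seed=9)
        s1 = render_animal(_record(), layout, noise)
        s2 = render_animal(_record(), layout, noise)
        assert s1["ivim"].data.shape == (40, 40, 5, 11)
        assert s1["dti"].data.shape == (40, 40, 5, 13)
        assert s1["megre"].data.shape == (40, 40, 5, 9)
        for k in ("ivim", "dti", "megre"):
            np.testing.assert_array_equal(s1[k].data, s2[k].data)

    def test_different_animals_get_different_fields(self, layout):
        noise = NoiseModel("none", seed=9)
        rec2 = AnimalRecord(
            id="control-02", group="control", mr=_record().mr,
            biochem={}, histology={},
        )
        a = render_animal(_record(), layout, noise)["ivim"].data
        b = render_animal(rec2, layout, noise)["ivim"].data
        assert not np.array_equal(a, b)

    def test_noise_free_background_is_zero(self, layout):
        s = render_animal(_record(), layout, NoiseModel("none", seed=3))
        bg = ~layout.liver_mask
        assert np.all(s["ivim"].data[bg] == 0.0)

    def test_rician_background_is_rayleigh(self, layout):
        """Background magnitude noise has mean sigma*sqrt(pi/2)."""
        snr = 50.0
        s = render_animal(_record(), layout, NoiseModel("rician", snr, 3))
        bg = s["megre"].data[~layout.liver_mask]
        sigma = 100.0 / snr
        assert bg.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.05)

    def test_restricted_render_matches_on_rendered_voxels(self, layout):
        """Restricting the render to a submask reproduces the exact same
        voxel values there (same per-animal parameter stream)."""
        noise = NoiseModel("none", seed=17)
        full = render_animal(_record(), layout, noise)
        sub = layout.liver_mask.copy()
        restricted = render_animal(_record(), layout, noise, restrict_mask=sub)
        np.testing.assert_array_equal(
            full["ivim"].data[layout.liver_mask],
            restricted["ivim"].data[layout.liver_mask],
        )

    def test_snr_matches_request_at_b0(self, layout):
        snr = 25.0
        s = render_animal(_record(), layout, NoiseModel("gaussian", snr, 21))
        clean = render_animal(_record(), layout, NoiseModel("none", 50, 21))
        resid = (s["ivim"].data - clean["ivim"].data)[layout.liver_mask][:, 0]
        assert resid.std() == pytest.approx(100.0 / snr, rel=0.05)

    def test_within_animal_cv_near_five_percent(self, layout):
        s = render_animal(_record(), layout, NoiseModel("none", seed=4))
        b0 = s["megre"].data[layout.parenchyma_mask][:, 0]
        # S0 is constant; the first-echo spread reflects the R2* field
        te0 = 2.57e-3
        r2s = -np.log(b0 / 100.0) / te0
        assert r2s.std() / r2s.mean() == pytest.approx(0.05, abs=0.015)


def test_simulate_observers_zero_jitter_identical(layout):
    obs1, obs2 = simulate_observers(layout, 0.0, seed=5)
    assert obs1 == obs2
    obs1b, obs2b = simulate_observers(layout, 3.0, seed=5)
    assert obs1b == obs1  # placement independent of jitter level
    assert obs2b != obs1b
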