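"""Phantom generator: signal models, noise, geometry, reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penumbra.images import mirror
from penumbra.phantom import (
    PhantomSpec,
    add_rician_noise,
    coil_profile,
    compartment_masks,
    generate_subject,
    signal_dwi,
    signal_msme,
    signal_sodium,
    subject_timepoints,
)

from conftest import noiseless_spec


class TestSignalModels:
    @pytest.mark.parametrize(
        "func,kwargs,expected",
        [
            # b=0 and adc=0 leave the signal at S0; analytic point 1000*e^-1
            (signal_dwi, dict(s0=500.0, adc=1e-3, b=0.0), 500.0),
            (signal_dwi, dict(s0=500.0, adc=0.0, b=1079.0), 500.0),
            (signal_dwi, dict(s0=1000.0, adc=1.0e-3, b=1000.0), 1000.0 * np.exp(-1)),
            # TE=0 and T2=inf leave the spin echo at S0; 1000*e^-1 at TE=T2
            (signal_msme, dict(s0=750.0, t2_ms=50.0, te_ms=0.0), 750.0),
            (signal_msme, dict(s0=750.0, t2_ms=np.inf, te_ms=176.0), 750.0),
            (signal_msme, dict(s0=1000.0, t2_ms=50.0, te_ms=50.0), 1000.0 * np.exp(-1)),
        ],
    )
    def test_closed_form_points(self, func, kwargs, expected):
        assert func(**kwargs) == pytest.approx(expected, rel=1e-12)

    def test_sodium_drift_and_attenuation(self):
        # zero drift -> constant in time
        s_early = signal_sodium(100.0, 7.0, 2.9, t_minutes=15.0, t_ref_minutes=15.0)
        s_late = signal_sodium(100.0, 7.0, 2.9, t_minutes=80.0, t_ref_minutes=15.0)
        assert s_early == pytest.approx(s_late)
        # te=0 -> no T2* attenuation
        assert signal_sodium(88.0, 5.0, te_ms=0.0) == pytest.approx(88.0)
        # attenuation over the tissue T2* range at the protocol TE of 2.9 ms
        for t2star, factor in [(5.0, np.exp(-0.58)), (9.0, np.exp(-2.9 / 9.0))]:
            assert signal_sodium(100.0, t2star, 2.9) == pytest.approx(100.0 * factor)
        # drift is linear in time in normalized units per hour
        s = signal_sodium(100.0, 7.0, 0.0, t_minutes=75.0, drift_rate_pct_per_h=20.0,
                          t_ref_minutes=15.0)
        assert s == pytest.approx(120.0)

    @pytest.mark.parametrize(
        "func,kwargs",
        [
            (signal_dwi, dict(s0=100.0, adc=-1e-3, b=530.0)),
            (signal_dwi, dict(s0=100.0, adc=1e-3, b=-1.0)),
            (signal_msme, dict(s0=100.0, t2_ms=-50.0, te_ms=11.0)),
            (signal_sodium, dict(concentration_rel=100.0, t2star_ms=0.0)),
        ],
    )
    def test_invalid_inputs_rejected(self, func, kwargs):
        with pytest.raises(ValueError):
            func(**kwargs)

    @given(
        s0=st.floats(1.0, 1e4),
        adc=st.floats(0.0, 3e-3),
        b=st.floats(0.0, 2000.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_dwi_signal_bounded(self, s0, adc, b):
        s = signal_dwi(s0, adc, b)
        assert 0.0 < s <= s0


class TestRicianNoise:
    def test_sigma_zero_is_identity(self, rng):
        img = rng.random((16, 16))
        assert np.array_equal(add_rician_noise(img, 0.0, rng), img)

    def test_output_nonnegative(self, rng):
        img = rng.normal(size=(32, 32))
        assert (add_rician_noise(np.abs(img), 2.0, rng) >= 0).all()

    def test_zero_signal_floor_matches_rayleigh_mean(self, rng):
        # magnitude of pure complex noise is Rayleigh with mean sigma*sqrt(pi/2)
        sigma = 3.0
        out = add_rician_noise(np.zeros(200_000), sigma, rng)
        assert out.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.01)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            add_rician_noise(np.zeros(4), -1.0, rng)


class TestGeometry:
    def test_lesion_mask_algebra(self, default_spec):
        m = compartment_masks(default_spec)
        assert not (m["core"] & m["penumbra"]).any()
        assert np.array_equal(m["core"] | m["penumbra"], m["hypoperfused"])
        assert (m["hypoperfused"] <= m["ipsi_hemisphere"]).all()
        assert (m["core"] <= m["brain"]).all()

    def test_hypoperfused_territory_is_connected(self, default_spec):
        from scipy import ndimage

        _, n = ndimage.label(compartment_masks(default_spec)["hypoperfused"])
        assert n == 1

    def test_coil_profile_mirror_symmetric(self, default_spec):
        coil = coil_profile(default_spec)
        assert np.array_equal(coil, mirror(coil, default_spec.midline_axis))
        assert (coil > 0).all()

    def test_spec_validation_rejects_bad_specs(self):
        with pytest.raises(ValueError):
            PhantomSpec(grid_shape=(4, 4)).validate()
        with pytest.raises(ValueError):
            PhantomSpec(cpu_radius_vox=-1.0).validate()
        spec = PhantomSpec()
        spec.noise_sigma["dwi"] = -0.1
        with pytest.raises(ValueError):
            spec.validate()
        # caudate putamen moved across the midline: core leaves the
        # hypoperfused (ipsilateral) territory
        with pytest.raises(ValueError):
            PhantomSpec(cpu_center_vox=(20.0, 32.0)).validate()


class TestGenerateSubject:
    def test_protocol_frames(self, subject1):
        data, _ = subject1
        dwi = data["pre"]["dwi"]
        assert sorted(set(dwi.frame_meta["b_value"])) == [0.0, 530.0, 1079.0]
        assert dwi.frame_meta["b_value"].count(0.0) == 5
        assert dwi.n_frames == 5 + 2 * 3
        msme = data["pre"]["msme"]
        assert msme.n_frames == 16
        assert msme.frame_meta["te_ms"][0] == 11.0
        assert msme.frame_meta["te_ms"][-1] == 176.0
        sod = data["pre"]["sodium"]
        assert sod.n_frames == 9
        assert sod.frame_meta["time_min"][0] == 15.0
        assert sod.frame_meta["time_min"][-1] == 80.0
        # sodium time series exists only before reperfusion
        assert data["post"]["sodium"].n_frames == 1
        assert data["h24"]["sodium"].n_frames == 1

    def test_noiseless_voxels_follow_closed_form(self, noiseless_subject):
        data, gt = noiseless_subject
        spec = gt.spec
        dwi = data["pre"]["dwi"]
        adc = gt.true_map("adc", "pre")
        b = np.asarray(dwi.frame_meta["b_value"])
        s0 = spec.baseline["s0_dwi"]
        for k in (0, 5, 8):  # a b=0, a b=530 and a b=1079 frame
            expected = signal_dwi(s0, adc, b[k])
            assert np.allclose(dwi.frames[..., k], expected, rtol=1e-12)

    def test_seed_reproducibility(self, default_spec):
        d1, g1 = generate_subject(default_spec, 0)
        d2, g2 = generate_subject(default_spec, 0)
        assert np.array_equal(d1["pre"]["dwi"].frames, d2["pre"]["dwi"].frames)
        assert g1.ratios == g2.ratios
        other = generate_subject(PhantomSpec(seed=2), 0)[0]
        assert not np.array_equal(
            d1["pre"]["dwi"].frames, other["pre"]["dwi"].frames
        )

    def test_core_sodium_increases_at_drift_rate(self, subject1):
        # Fig-7 dynamics: subcortical sodium climbs ~20 % of the
        # contralateral level per hour over the 15-80 min window
        data, gt = subject1
        sod = data["pre"]["sodium"]
        t_h = np.asarray(sod.frame_meta["time_min"]) / 60.0
        core_means = sod.frames[gt.masks["core"]].mean(axis=0)
        contra_means = sod.frames[gt.masks["core_mirror"]].mean(axis=0)
        norm = 100.0 * core_means / contra_means
        slope = np.polyfit(t_h, norm, 1)[0]
        assert slope == pytest.approx(20.0, abs=2.0)

    def test_negative_subject_index_rejected(self, default_spec):
        with pytest.raises(ValueError):
            generate_subject(default_spec, -1)

    def test_sham_phantom_is_mirror_symmetric_on_average(self):
        spec = noiseless_spec().sham()
        data, gt = generate_subject(spec, 0, timepoints=("pre",))
        img = data["pre"]["dwi"].frames[..., 0]
        left = img[gt.masks["core_mirror"]].mean()
        right = img[gt.masks["core"]].mean()
        assert right / left == pytest.approx(1.0, abs=1e-12)

    def test_multislice_grid_supported(self):
        spec = PhantomSpec(grid_shape=(64, 64, 3), voxel_size_mm=(0.5, 0.5, 2.0),
                           seed=2)
        data, gt = generate_subject(spec, 0, timepoints=("pre",))
        assert data["pre"]["dwi"].frames.shape == (64, 64, 3, 11)
        assert gt.masks["core"].shape == (64, 64, 3)
        # slices replicate the 2-D geometry
        assert np.array_equal(gt.masks["core"][..., 0], gt.masks["core"][..., 2])

    def test_dropout_schedule(self, default_spec):
        # subjects 4,5,6,8 (1-based) miss the 24 h scan
        assert subject_timepoints(default_spec, 0) == ("pre", "post", "h24")
        assert subject_timepoints(default_spec, 3) == ("pre", "post")
        assert subject_timepoints(default_spec, 7) == ("pre", "post")
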