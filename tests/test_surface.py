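"""Surface detection, alternating sequential filtering, and Rq estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octdent import (
    SurfaceProfile,
    asf_waviness,
    compute_rq,
    detect_surface,
    roughness_volume,
)
from octdent.phantom import PhantomConfig, make_phantom, preset


# ---------------------------------------------------------------------------
# brute-force sliding-window morphology oracle
# ---------------------------------------------------------------------------

def _slide(f, k, op):
    half = k // 2
    padded = np.concatenate([np.full(half, f[0]), f, np.full(half, f[-1])])
    return np.array([op(padded[i : i + k]) for i in range(len(f))])


def _oracle_waviness(f, k):
    erode = lambda x: _slide(x, k, np.min)
    dilate = lambda x: _slide(x, k, np.max)
    opening = lambda x: dilate(erode(x))
    closing = lambda x: erode(dilate(x))
    return 0.5 * (closing(opening(f)) + opening(closing(f)))


def _profile(heights, spacing=1.0):
    heights = np.asarray(heights, dtype=float)
    return SurfaceProfile(heights, np.ones(len(heights), bool), spacing)


class TestDetectSurface:
    def test_flat_sharp_interface_found_exactly(self):
        img = np.zeros((16, 200))
        img[:, 100:] = 1.0
        prof = detect_surface(img, axial_spacing_um=2.0)
        assert prof.valid.all()
        np.testing.assert_allclose(prof.height_um, 200.0)

    def test_phantom_truth_recovered_with_speckle(self, small_phantom):
        vol, truth = small_phantom
        errs = []
        for b in range(vol.n_bscans):
            prof = detect_surface(vol.bscan(b), vol.axial_spacing_um)
            errs.append((prof.height_um - truth.surface_um[b])[prof.valid])
        err_px = np.abs(np.concatenate(errs)) / vol.axial_spacing_um
        assert np.mean(err_px) <= 1.0

    def test_all_noise_image_fully_masked_with_warning(self):
        rng = np.random.default_rng(0)
        img = rng.exponential(1e-4, size=(32, 200))
        with pytest.warns(UserWarning, match="surface not found"):
            prof = detect_surface(img, axial_spacing_um=1.5)
        assert prof.n_valid == 0
        assert prof.warning is not None

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            detect_surface(np.empty((0, 0)), axial_spacing_um=1.5)


class TestAsfWaviness:
    def test_constant_profile_unchanged(self):
        prof = _profile(np.full(200, 7.5))
        np.testing.assert_allclose(asf_waviness(prof, 21.0), 7.5)

    def test_monotone_ramp_preserved_in_interior(self):
        ramp = np.linspace(0.0, 50.0, 300)
        wav = asf_waviness(_profile(ramp), 21.0)
        np.testing.assert_allclose(wav[30:-30], ramp[30:-30], atol=1e-12)

    def test_spikes_removed_from_sinusoid(self):
        """10-um bright spikes vanish under a 70 um SE (open-close order,
        the right branch for one-sided artifacts); the smooth sinusoidal
        form survives.  Two intrinsic flat-element error floors bound what
        any opening/closing composition can do — crest clipping
        A(1 - cos(pi SE/P)) and on-slope spike leakage ~ slope x spike
        width — so the period is chosen to keep both below 1 um."""
        x = np.arange(3000, dtype=float)
        clean = 20.0 * np.sin(2 * np.pi * x / 1500.0)
        spiky = clean.copy()
        for pos in range(50, 3000, 100):
            spiky[pos : pos + 10] += 15.0  # 10-um-wide spikes
        wav = asf_waviness(_profile(spiky), 70.0, composition="open-close")
        assert np.max(np.abs(wav[80:-80] - clean[80:-80])) < 1.0

    def test_average_matches_oracle_on_spiky_sinusoid(self):
        x = np.arange(600, dtype=float)
        spiky = 20.0 * np.sin(2 * np.pi * x / 500.0)
        spiky[100:110] += 15.0
        np.testing.assert_allclose(
            asf_waviness(_profile(spiky), 70.0), _oracle_waviness(spiky, 71), atol=1e-10
        )

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([5, 9, 15]))
    def test_matches_brute_force_oracle(self, seed, se_px):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=80).cumsum()  # rough random walk
        wav = asf_waviness(_profile(f), float(se_px))
        np.testing.assert_allclose(wav, _oracle_waviness(f, se_px), atol=1e-10)

    @settings(deadline=None, max_examples=15)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetric_in_profile_sign(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=120).cumsum()
        w_pos = asf_waviness(_profile(f), 11.0)
        w_neg = asf_waviness(_profile(-f), 11.0)
        np.testing.assert_allclose(w_neg, -w_pos, atol=1e-10)

    def test_masked_gaps_bridged(self):
        f = np.linspace(0, 30, 120)
        valid = np.ones(120, bool)
        valid[40:50] = False
        prof = SurfaceProfile(np.where(valid, f, np.nan), valid, 1.0)
        wav = asf_waviness(prof, 9.0)
        assert np.all(np.isfinite(wav))

    def test_se_longer_than_profile_rejected(self):
        with pytest.raises(ValueError, match="longer than the profile"):
            asf_waviness(_profile(np.zeros(20)), 100.0)


class TestComputeRq:
    def test_zero_residual_gives_zero(self):
        prof = _profile(np.full(50, 3.0))
        res = compute_rq(prof, np.full(50, 3.0))
        assert res.rq_um == 0.0

    def test_symmetric_residual(self):
        a = 2.5
        heights = np.tile([a, -a], 25).astype(float)
        res = compute_rq(_profile(heights), np.zeros(50))
        assert res.rq_um == pytest.approx(a)

    def test_too_few_ascans_rejected(self):
        prof = _profile(np.zeros(5))
        with pytest.raises(ValueError, match="at least 10"):
            compute_rq(prof, np.zeros(5))

    @settings(deadline=None, max_examples=15)
    @given(st.floats(-500.0, 500.0))
    def test_rq_invariant_to_height_offset(self, offset):
        rng = np.random.default_rng(7)
        f = rng.normal(size=200).cumsum()
        prof0, prof1 = _profile(f), _profile(f + offset)
        rq0 = compute_rq(prof0, asf_waviness(prof0, 15.0)).rq_um
        rq1 = compute_rq(prof1, asf_waviness(prof1, 15.0)).rq_um
        assert rq1 == pytest.approx(rq0, abs=1e-9)


class TestRoughnessVolume:
    def test_preset_roughness_recovered(self):
        """Stage-2 caries preset (sigma_r = 6.6 um): mean Rq within 10%."""
        rqs = []
        for seed in range(4):
            vol, _ = make_phantom(preset("caries_stage2", seed=seed, n_bscans=4))
            _, summary = roughness_volume(vol)
            rqs.append(summary["mean"])
        assert np.mean(rqs) == pytest.approx(6.6, rel=0.10)

    def test_single_bscan_ci_flagged_undefined(self):
        vol, _ = make_phantom(PhantomConfig(n_bscans=1, n_ascans=256, seed=2))
        _, summary = roughness_volume(vol)
        assert summary["n"] == 1
        assert np.isnan(summary["ci_low"]) and np.isnan(summary["ci_high"])

    def test_short_se_leaks_less_waviness(self, small_phantom):
        """A short SE tracks the form better than a long one, so less of
        the waviness ends up in the residual."""
        vol, _ = small_phantom
        _, s_short = roughness_volume(vol, se_um=70.0)
        _, s_long = roughness_volume(vol, se_um=230.0)
        assert s_short["mean"] <= s_long["mean"]
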