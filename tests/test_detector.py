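import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strandscan import (
    SamParams,
    angle_to_likelihood,
    extract_signature,
    generate_scene,
    noise_free_config,
    sam_classify,
    separable_config,
    spectral_angle,
)
from strandscan.detector import (
    SpectralSignature,
    read_signatures_csv,
    read_signatures_json,
    write_signatures_csv,
    write_signatures_json,
)
from strandscan.pipeline import SignatureConfig, signatures_from_truth
from tests.conftest import make_raster


class TestExtractSignature:
    def test_single_pixel(self):
        values = np.arange(8 * 4 * 4, dtype=float).reshape(8, 4, 4)
        sig = extract_signature(make_raster(values), [(1, 2)], "w")
        np.testing.assert_allclose(sig.mean, values[:, 1, 2])
        np.testing.assert_allclose(sig.min, values[:, 1, 2])
        np.testing.assert_allclose(sig.max, values[:, 1, 2])
        np.testing.assert_allclose(sig.sd, 0.0)
        assert sig.n_pixels == 1

    def test_two_pixel_arithmetic(self):
        values = np.zeros((8, 2, 2))
        values[:, 0, 0] = 10.0
        values[:, 0, 1] = 30.0
        sig = extract_signature(make_raster(values), [(0, 0), (0, 1)], "w")
        np.testing.assert_allclose(sig.mean, 20.0)
        np.testing.assert_allclose(sig.min, 10.0)
        np.testing.assert_allclose(sig.max, 30.0)

    def test_forty_random_pixels_match_bruteforce_stats(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 80, (8, 20, 20))
        pixels = [tuple(p) for p in rng.integers(0, 20, size=(40, 2))]
        sig = extract_signature(make_raster(values), pixels, "w")
        for b in range(8):
            samples = [values[b, r, c] for r, c in pixels]
            assert sig.mean[b] == pytest.approx(sum(samples) / 40, rel=1e-6)
            assert sig.min[b] == pytest.approx(min(samples))
            assert sig.max[b] == pytest.approx(max(samples))
            mean = sum(samples) / 40
            var = sum((s - mean) ** 2 for s in samples) / 40
            assert sig.sd[b] == pytest.approx(math.sqrt(var), rel=1e-6)

    def test_all_nodata_rejected(self):
        values = np.full((8, 2, 2), np.nan)
        with pytest.raises(ValueError, match="nodata"):
            extract_signature(make_raster(values), [(0, 0)], "w")

    def test_stat_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpectralSignature("x", "target", mean=[1.0], min=[2.0], max=[3.0],
                              sd=[0.0], n_pixels=1)


class TestSpectralAngle:
    def test_identity_and_scale_invariance(self):
        assert spectral_angle([1, 2, 3], [1, 2, 3]) == 0.0
        assert spectral_angle([1, 2, 3], [2, 4, 6]) == pytest.approx(0.0, abs=1e-7)

    def test_closed_form_45_degrees(self):
        assert spectral_angle([1, 0], [1, 1]) == pytest.approx(0.785398, abs=1e-6)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            spectral_angle([0, 0], [1, 1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.lists(st.floats(0.01, 100), min_size=3, max_size=8),
        scale=st.floats(0.01, 50),
    )
    def test_symmetric_and_rescale_invariant(self, a, scale):
        rng = np.random.default_rng(len(a))
        b = rng.uniform(0.01, 100, len(a))
        t1 = spectral_angle(a, b)
        assert t1 == pytest.approx(spectral_angle(b, a), abs=1e-9)
        assert t1 == pytest.approx(spectral_angle(np.array(a) * scale, b), abs=1e-6)
        assert 0 <= t1 <= math.pi


class TestAngleToLikelihood:
    def test_boundaries_and_midpoint(self):
        assert angle_to_likelihood(0.0, 0.1) == 100.0
        assert angle_to_likelihood(0.1, 0.1) == 0.0
        assert angle_to_likelihood(0.2, 0.1) == 0.0
        assert angle_to_likelihood(0.05, 0.1) == pytest.approx(50.0)

    def test_strictly_decreasing_inside_threshold(self):
        angles = np.linspace(0, 0.1, 50)
        liks = angle_to_likelihood(angles, 0.1)
        assert (np.diff(liks) < 0).all()


def brute_force_sam(raster, signatures, params, mask=None):
    """Exhaustive per-pixel reimplementation of the candidate rule."""
    targets = [s for s in signatures if s.role == "target"]
    exclusions = [s for s in signatures if s.role == "exclusion"]
    found = []
    h, w = raster.shape
    for r in range(h):
        for c in range(w):
            if mask is not None and not mask[r, c]:
                continue
            x = raster.values[:, r, c].astype(float)
            if not np.isfinite(x).all() or np.linalg.norm(x) == 0:
                continue
            t_angles = [spectral_angle(x, s.mean) for s in targets]
            best = min(t_angles)
            if best > params.max_angle_rad:
                continue
            if exclusions:
                e_best = min(spectral_angle(x, s.mean) for s in exclusions)
                if not best < e_best:
                    continue
            found.append((r, c, targets[int(np.argmin(t_angles))].label, best))
    return found


class TestSamClassify:
    def test_exact_match_recovery_noise_free(self):
        cfg = noise_free_config(seed=2, n_whales=5)
        ms, _, truth = generate_scene(cfg)
        target = np.asarray(cfg.whale_spectra["orange"], float)
        sig = SpectralSignature("whale", "target", target, target, target,
                                np.zeros(8), n_pixels=1)
        cands = sam_classify(ms, [sig], SamParams(max_angle_rad=0.10))
        whale_pixels = {(r, c) for w in truth.whales for r, c in w.footprint}
        assert {(c.row, c.col) for c in cands} == whale_pixels
        assert all(c.likelihood == pytest.approx(100.0) for c in cands)

    def test_exclusion_signature_removes_closer_pixels(self):
        values = np.ones((8, 2, 2))
        cloudish = np.array([60, 62, 63, 63, 62, 61, 60, 58], float)
        whalish = np.array([30, 32, 38, 48, 55, 56, 60, 48], float)
        values[:, 0, 0] = cloudish * 1.01
        values[:, 0, 1] = whalish
        r = make_raster(values)
        sigs = [
            SpectralSignature("whale", "target", whalish, whalish, whalish,
                              np.zeros(8), 1),
            SpectralSignature("cloud", "exclusion", cloudish, cloudish, cloudish,
                              np.zeros(8), 1),
        ]
        cands = sam_classify(r, sigs, SamParams(max_angle_rad=0.5))
        coords = {(c.row, c.col) for c in cands}
        assert (0, 1) in coords and (0, 0) not in coords

    def test_matches_bruteforce_on_noisy_scene(self):
        cfg = separable_config(seed=6, n_whales=5, rows=50, cols=50)
        ms, _, truth = generate_scene(cfg)
        sigs = signatures_from_truth(ms, truth, SignatureConfig(n_whales=2))
        params = SamParams(max_angle_rad=0.15)
        cands = sam_classify(ms, sigs, params)
        oracle = brute_force_sam(ms, sigs, params)
        assert [(c.row, c.col, c.label) for c in cands] == [
            (r, c, lab) for r, c, lab, _ in oracle
        ]

    def test_threshold_nesting(self, default_scene):
        _, ms, _, truth = default_scene
        sigs = signatures_from_truth(ms, truth, SignatureConfig(n_whales=3))
        cands = sam_classify(ms, sigs, SamParams(max_angle_rad=0.2))
        all_px = {(c.row, c.col) for c in cands}
        ge40 = {(c.row, c.col) for c in cands if c.likelihood >= 40}
        ge65 = {(c.row, c.col) for c in cands if c.likelihood >= 65}
        assert ge65 <= ge40 <= all_px

    def test_mask_never_adds_candidates(self, default_scene):
        _, ms, _, truth = default_scene
        sigs = signatures_from_truth(ms, truth, SignatureConfig(n_whales=3))
        params = SamParams(max_angle_rad=0.2)
        unmasked = {(c.row, c.col) for c in sam_classify(ms, sigs, params)}
        rng = np.random.default_rng(0)
        mask = rng.random(ms.shape) > 0.5
        masked = {(c.row, c.col) for c in sam_classify(ms, sigs, params, mask)}
        assert masked <= unmasked

    def test_requires_target_signature(self, default_scene):
        _, ms, _, _ = default_scene
        s = SpectralSignature("c", "exclusion", np.ones(8), np.ones(8),
                              np.ones(8), np.zeros(8), 1)
        with pytest.raises(ValueError, match="target"):
            sam_classify(ms, [s])

    def test_band_mismatch_rejected(self, default_scene):
        _, ms, _, _ = default_scene
        s = SpectralSignature("w", "target", np.ones(3), np.ones(3),
                              np.ones(3), np.zeros(3), 1)
        with pytest.raises(ValueError, match="bands"):
            sam_classify(ms, [s])


class TestSignatureIO:
    def _sigs(self):
        rng = np.random.default_rng(1)
        out = []
        for i, role in enumerate(["target", "exclusion"]):
            lo = rng.uniform(0, 10, 8)
            hi = lo + rng.uniform(0, 10, 8)
            out.append(SpectralSignature(
                label=f"s{i}", role=role, mean=(lo + hi) / 2, min=lo, max=hi,
                sd=rng.uniform(0, 3, 8), n_pixels=5,
                source_pixels=[(i, j) for j in range(5)],
            ))
        return out

    def test_csv_roundtrip(self, tmp_path):
        sigs = self._sigs()
        write_signatures_csv(sigs, tmp_path / "s.csv")
        back = read_signatures_csv(tmp_path / "s.csv")
        for a, b in zip(sigs, back):
            assert a.label == b.label and a.role == b.role
            np.testing.assert_allclose(a.mean, b.mean, rtol=1e-12)
            np.testing.assert_allclose(a.sd, b.sd, rtol=1e-12)

    def test_json_roundtrip(self, tmp_path):
        sigs = self._sigs()
        write_signatures_json(sigs, tmp_path / "s.json")
        back = read_signatures_json(tmp_path / "s.json")
        for a, b in zip(sigs, back):
            np.testing.assert_allclose(a.max, b.max, rtol=1e-12)
            assert a.source_pixels == b.source_pixels
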