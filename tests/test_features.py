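"""Feature extractors vs independent naive implementations, plus the
invariances the descriptors are chosen for (rotation for Zernike magnitudes,
transpose for angle-averaged Haralick) and the fixed 550-d fusion layout."""

import math

import numpy as np
import pytest

from histocompare import features as F
from histocompare import synthetic as syn


# ---------------------------------------------------------------------------
# naive oracles (straight double-sum / enumeration implementations)
# ---------------------------------------------------------------------------

def naive_zernike(gray, n_max=8):
    h, w = gray.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = min(h, w) / 2.0
    pairs = [(n, m) for n in range(n_max + 1) for m in range(n + 1)
             if (n - m) % 2 == 0]
    alpha = 0
    for y in range(h):
        for x in range(w):
            if math.hypot((y - cy) / radius, (x - cx) / radius) <= 1.0:
                alpha += 1
    out = []
    for n, m in pairs:
        z = 0.0 + 0.0j
        for y in range(h):
            for x in range(w):
                rho = math.hypot((y - cy) / radius, (x - cx) / radius)
                if rho > 1.0:
                    continue
                theta = math.atan2(y - cy, x - cx)
                r = 0.0
                for s in range((n - m) // 2 + 1):
                    r += ((-1) ** s * math.factorial(n - s)
                          / (math.factorial(s)
                             * math.factorial((n + m) // 2 - s)
                             * math.factorial((n - m) // 2 - s))) * rho ** (n - 2 * s)
                z += gray[y, x] * r * np.exp(-1j * m * theta)
        out.append(abs((n + 1) / alpha * z))
    return np.array(out)


def naive_glcm(gq, levels, d, angle_deg, symmetric=True, normalized=True):
    h, w = gq.shape
    a = math.radians(angle_deg)
    dc = round(d * math.cos(a))
    dr = -round(d * math.sin(a))
    P = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                P[gq[r, c], gq[r2, c2]] += 1
    if symmetric:
        P = P + P.T
    if normalized and P.sum() > 0:
        P = P / P.sum()
    return P


def naive_haralick(P):
    L = P.shape[0]
    eps = 1e-12
    px = [sum(P[i][j] for j in range(L)) for i in range(L)]
    py = [sum(P[i][j] for i in range(L)) for j in range(L)]
    mx = sum(i * px[i] for i in range(L))
    my = sum(j * py[j] for j in range(L))
    sx = math.sqrt(sum((i - mx) ** 2 * px[i] for i in range(L)))
    sy = math.sqrt(sum((j - my) ** 2 * py[j] for j in range(L)))
    psum = [0.0] * (2 * L - 1)
    pdiff = [0.0] * L
    for i in range(L):
        for j in range(L):
            psum[i + j] += P[i][j]
            pdiff[abs(i - j)] += P[i][j]
    f = [0.0] * 13
    f[0] = sum(P[i][j] ** 2 for i in range(L) for j in range(L))
    f[1] = sum(k ** 2 * pdiff[k] for k in range(L))
    f[2] = 0.0 if sx * sy <= eps else (
        sum(i * j * P[i][j] for i in range(L) for j in range(L)) - mx * my) / (sx * sy)
    f[3] = sum((i - mx) ** 2 * P[i][j] for i in range(L) for j in range(L))
    f[4] = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    f[5] = sum(k * psum[k] for k in range(2 * L - 1))
    f[6] = sum((k - f[5]) ** 2 * psum[k] for k in range(2 * L - 1))
    f[7] = -sum(q * math.log2(q + eps) for q in psum)
    f[8] = -sum(P[i][j] * math.log2(P[i][j] + eps) for i in range(L) for j in range(L))
    mdiff = sum(k * pdiff[k] for k in range(L))
    f[9] = sum((k - mdiff) ** 2 * pdiff[k] for k in range(L))
    f[10] = -sum(q * math.log2(q + eps) for q in pdiff)
    hxy = f[8]
    hxy1 = -sum(P[i][j] * math.log2(px[i] * py[j] + eps)
                for i in range(L) for j in range(L))
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j] + eps)
                for i in range(L) for j in range(L))
    hx = -sum(q * math.log2(q + eps) for q in px)
    hy = -sum(q * math.log2(q + eps) for q in py)
    f[11] = 0.0 if max(hx, hy) <= eps else (hxy - hxy1) / max(hx, hy)
    f[12] = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
    return np.array(f)


def naive_histogram(px, bins=8):
    hist = np.zeros((bins, bins, bins))
    for row in px.reshape(-1, 3):
        idx = tuple(min(int(v) * bins // 256, bins - 1) for v in row)
        hist[idx] += 1
    return hist.ravel() / hist.sum()


# ---------------------------------------------------------------------------
# Zernike
# ---------------------------------------------------------------------------

class TestZernike:
    def test_25_moments_for_orders_0_to_8(self, rng):
        res = F.zernike_moments(rng.random((16, 16)))
        assert len(res.magnitudes) == 25
        assert len(F.zernike_index_list(8)) == 25
        assert res.index_list[0] == (0, 0)
        assert res.index_list[-1] == (8, 8)

    def test_matches_naive_double_sum(self, rng):
        gray = rng.integers(0, 256, (16, 16)).astype(float)
        got = F.zernike_moments(gray).magnitudes
        want = naive_zernike(gray)
        assert np.allclose(got, want, atol=1e-8)

    def test_z00_is_disk_mean(self, rng):
        gray = rng.integers(0, 256, (16, 16)).astype(float)
        res = F.zernike_moments(gray)
        h, w = gray.shape
        cy, cx = (h - 1) / 2, (w - 1) / 2
        yy, xx = np.mgrid[0:h, 0:w]
        inside = np.hypot((yy - cy) / 8, (xx - cx) / 8) <= 1
        assert np.isclose(res.magnitudes[0], gray[inside].sum() / inside.sum(),
                          atol=1e-10)

    def test_rotation_invariance_of_magnitudes(self):
        for seed in range(20):
            patch, _ = syn.generate_image(syn.default_malignant_spec(),
                                          (64, 64), seed=seed)
            g = F.rgb_to_gray(patch.pixels)
            base = F.zernike_moments(g).magnitudes
            for k in (1, 2, 3):
                rot = F.zernike_moments(np.rot90(g, k)).magnitudes
                rel = np.abs(rot - base) / np.maximum(np.abs(base), 1e-9)
                assert rel.max() <= 1e-2

    def test_zero_image_gives_zero_vector(self):
        res = F.zernike_moments(np.zeros((16, 16)))
        assert (res.magnitudes == 0).all()

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            F.zernike_moments(np.zeros((4, 4)))


# ---------------------------------------------------------------------------
# GLCM / Haralick
# ---------------------------------------------------------------------------

class TestGLCM:
    def test_two_pair_example(self):
        P = F.glcm(np.array([[0, 0], [1, 1]]), levels=2, d=1, angle=0.0)
        assert P[0, 0] == pytest.approx(0.5)
        assert P[1, 1] == pytest.approx(0.5)
        assert P[0, 1] == P[1, 0] == 0.0

    def test_constant_image_single_entry(self):
        P = F.glcm(np.full((6, 6), 3), levels=8, d=1, angle=0.0)
        assert P[3, 3] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("d,angle", [(1, 0.0), (1, 45.0), (2, 90.0),
                                         (4, 135.0), (1, 225.0)])
    def test_normalized_sums_to_one(self, rng, d, angle):
        gq = F.quantize_gray(rng.integers(0, 256, (16, 16)).astype(float), 8)
        P = F.glcm(gq, 8, d, angle)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)
        assert (P >= 0).all()

    def test_matches_naive_enumeration(self, rng):
        gq = F.quantize_gray(rng.integers(0, 256, (16, 16)).astype(float), 8)
        for d in (1, 2):
            for angle in (0.0, 45.0, 90.0, 135.0, 180.0, 270.0):
                assert np.allclose(F.glcm(gq, 8, d, angle),
                                   naive_glcm(gq, 8, d, angle), atol=1e-12)

    def test_matches_skimage_convention(self, rng):
        """Independent library cross-check.  skimage measures angles with the
        row axis pointing down (its angle t is this module's -t), so with
        symmetric accumulation the diagonal angles map as t <-> 180 - t."""
        from skimage.feature import graycomatrix

        gq = F.quantize_gray(rng.integers(0, 256, (16, 16)).astype(float), 8)
        for mine_deg, theirs_rad in [(0, 0), (45, 3 * np.pi / 4),
                                     (90, np.pi / 2), (135, np.pi / 4)]:
            sk = graycomatrix(gq.astype(np.uint8), [1], [theirs_rad], levels=8,
                              symmetric=True, normed=True)[:, :, 0, 0]
            assert np.allclose(F.glcm(gq, 8, 1, mine_deg), sk, atol=1e-12)

    def test_oversized_displacement_rejected(self):
        with pytest.raises(ValueError):
            F.glcm(np.zeros((4, 4), int), levels=2, d=5, angle=0.0)


class TestHaralick:
    def test_output_length_13(self, rng):
        assert F.haralick_features(rng.integers(0, 256, (32, 32)).astype(float)).shape == (13,)

    def test_constant_image(self):
        f = F.haralick_features(np.full((32, 32), 128.0))
        assert f[1] == pytest.approx(0.0)   # contrast
        assert f[0] == pytest.approx(1.0)   # angular second moment

    def test_checkerboard_matches_naive_per_angle_mean(self):
        board = np.indices((8, 8)).sum(axis=0) % 2  # two-level checkerboard
        angles = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)
        want = np.mean([naive_haralick(naive_glcm(board, 2, 1, a))
                        for a in angles], axis=0)
        got = np.mean([F.haralick_from_glcm(F.glcm(board, 2, 1, a))
                       for a in angles], axis=0)
        assert np.allclose(got, want, atol=1e-10)

    def test_full_feature_matches_naive(self, rng):
        gray = rng.integers(0, 256, (16, 16)).astype(float)
        spec = F.GLCMSpec(levels=8, distances=(1, 2))
        gq = F.quantize_gray(gray, 8)
        want = np.mean([naive_haralick(naive_glcm(gq, 8, d, a))
                        for d in (1, 2) for a in spec.angles], axis=0)
        assert np.allclose(F.haralick_features(gray, spec), want, atol=1e-8)

    def test_transpose_invariance_of_angle_mean(self, rng):
        gray = rng.integers(0, 256, (32, 32)).astype(float)
        f1 = F.haralick_features(gray)
        f2 = F.haralick_features(gray.T)
        assert np.allclose(f1, f2, atol=1e-8)


# ---------------------------------------------------------------------------
# color histogram and fusion
# ---------------------------------------------------------------------------

class TestColorHistogram:
    def test_length_512(self, rng):
        px = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        assert F.color_histogram(px).shape == (512,)

    def test_all_black_mass_in_first_bin(self):
        h = F.color_histogram(np.zeros((4, 4, 3), np.uint8))
        assert h[0] == 1.0
        assert h[1:].sum() == 0.0

    def test_black_and_white_split(self):
        px = np.array([[[0, 0, 0], [255, 255, 255]]], np.uint8)
        h = F.color_histogram(px)
        assert h[0] == pytest.approx(0.5)
        assert h[-1] == pytest.approx(0.5)
        assert h.sum() == pytest.approx(1.0)

    def test_matches_naive(self, rng):
        px = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        assert np.allclose(F.color_histogram(px), naive_histogram(px), atol=1e-12)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            F.color_histogram(np.zeros((4, 4), np.uint8))


class TestFusion:
    def test_length_550_and_layout_recovery(self, rng):
        z = rng.random(25)
        h = rng.random(13)
        c = rng.random(512)
        v = F.fuse(z, h, c)
        assert v.shape == (550,)
        assert np.array_equal(v[F.ZERNIKE_SLICE], z)
        assert np.array_equal(v[F.HARALICK_SLICE], h)
        assert np.array_equal(v[F.HISTOGRAM_SLICE], c)

    def test_zero_components_give_zero_vector(self):
        v = F.fuse(np.zeros(25), np.zeros(13), np.zeros(512))
        assert v.shape == (550,) and (v == 0).all()

    def test_wrong_lengths_rejected(self):
        with pytest.raises(ValueError):
            F.fuse(np.zeros(24), np.zeros(13), np.zeros(512))

    def test_extract_features_end_to_end(self, tissue_image):
        v = F.extract_features(tissue_image[0].pixels)
        assert v.shape == (550,)
        assert np.isfinite(v).all()
        assert len(F.feature_column_names()) == 550
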