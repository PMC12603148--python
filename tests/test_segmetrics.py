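"""Segmentation metric suite vs exhaustive brute-force references."""

from __future__ import annotations

import numpy as np
import pytest

from lucent.segmetrics import assd, overlap_metrics, seg_report, surface_voxels


# ----------------------------------------------------------------- oracles
def brute_overlap(pred, gt):
    """Exhaustive voxel-by-voxel tally (independent of the implementation)."""
    tp = fp = fn = tn = 0
    for p, g in zip(pred.ravel(), gt.ravel()):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif g:
            fn += 1
        else:
            tn += 1
    P, G = tp + fp, tp + fn
    union = tp + fp + fn
    out = {
        "dsc": 100.0 * 2 * tp / (P + G),
        "voe": 100.0 * (1 - tp / union),
        "rvd": 100.0 * abs(P - G) / G,
        "miou": 0.5 * (tp / union + tn / (tn + fp + fn)),
        "precision": 100.0 * tp / P if P else float("nan"),
        "fnr": 100.0 * fn / G,
        "fpr": 100.0 * fp / (tn + fp),
    }
    return out


def brute_surface(mask):
    pts = []
    nx, ny, nz = mask.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                                   (0, 0, 1), (0, 0, -1)):
                    a, b, c = i + di, j + dj, k + dk
                    if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) \
                            or not mask[a, b, c]:
                        pts.append((i, j, k))
                        break
    return np.array(pts, dtype=float)


def brute_assd(pred, gt, spacing):
    sp = brute_surface(pred) * spacing
    sg = brute_surface(gt) * spacing
    d1 = [min(np.linalg.norm(a - b) for b in sg) for a in sp]
    d2 = [min(np.linalg.norm(b - a) for a in sp) for b in sg]
    return (sum(d1) + sum(d2)) / (len(d1) + len(d2))


def random_pair(rng, p=0.3):
    while True:
        a = rng.random((8, 8, 8)) < p
        b = rng.random((8, 8, 8)) < p
        if a.any() and b.any():
            return a, b


# ------------------------------------------------------------------- tests
class TestOverlapMetrics:
    def test_identity_masks_are_perfect(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        dsc, voe, rvd, miou, prec, fnr, fpr = overlap_metrics(m, m)
        assert (dsc, voe, rvd, prec, fnr, fpr) == (100.0, 0.0, 0.0, 100.0, 0.0, 0.0)
        assert miou == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[0], b[3] = True, True
        dsc, voe, *_ = overlap_metrics(a, b)
        assert dsc == 0.0 and voe == 100.0

    def test_hand_counted_example(self):
        # 4x4x1 grid; |P| = |G| = 4, |P & G| = 2
        p = np.zeros((4, 4, 1), bool)
        g = np.zeros((4, 4, 1), bool)
        p[0, 0] = p[0, 1] = p[1, 0] = p[1, 1] = True
        g[1, 0] = g[1, 1] = g[2, 0] = g[2, 1] = True
        dsc, voe, rvd, miou, prec, fnr, fpr = overlap_metrics(p, g)
        assert dsc == pytest.approx(50.0)
        assert voe == pytest.approx(100 * (1 - 2 / 6))
        assert rvd == 0.0
        assert prec == pytest.approx(50.0)
        assert fnr == pytest.approx(50.0)
        assert fpr == pytest.approx(100 * 2 / 12)  # 12 background voxels

    def test_both_empty_warns_perfect(self):
        e = np.zeros((3, 3, 3), bool)
        with pytest.warns(UserWarning):
            dsc, *_ = overlap_metrics(e, e)
        assert dsc == 100.0

    def test_empty_gt_nonempty_pred_raises(self):
        e = np.zeros((3, 3, 3), bool)
        p = e.copy()
        p[0, 0, 0] = True
        with pytest.raises(ValueError, match="RVD"):
            overlap_metrics(p, e)

    def test_oracle_equivalence_100_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b = random_pair(rng)
            dsc, voe, rvd, miou, prec, fnr, fpr = overlap_metrics(a, b)
            ref = brute_overlap(a, b)
            for got, want in [(dsc, ref["dsc"]), (voe, ref["voe"]),
                              (rvd, ref["rvd"]), (miou, ref["miou"]),
                              (prec, ref["precision"]), (fnr, ref["fnr"]),
                              (fpr, ref["fpr"])]:
                assert got == pytest.approx(want, rel=1e-10)

    def test_symmetry_and_identities(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = random_pair(rng)
            m1 = overlap_metrics(a, b)
            m2 = overlap_metrics(b, a)
            assert m1[0] == pytest.approx(m2[0])   # DSC symmetric
            assert m1[1] == pytest.approx(m2[1])   # VOE symmetric
            iou = 1 - m1[1] / 100
            assert m1[0] / 100 == pytest.approx(2 * iou / (1 + iou), rel=1e-12)


class TestSurfaceAndASSD:
    def test_solid_block_surface_count(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        assert len(surface_voxels(m)) == 26  # all but the center voxel

    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert np.array_equal(surface_voxels(m), [[1.0, 1.0, 1.0]])

    def test_border_voxels_are_surface(self):
        m = np.ones((3, 3, 3), bool)
        assert len(surface_voxels(m)) == 26  # border counts as background

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            surface_voxels(np.zeros((2, 2, 2), bool))

    def test_identity_assd_zero(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        assert assd(m, m) == 0.0

    def test_parallel_planes_distance(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[:, :, 0] = True
        b[:, :, 3] = True
        assert assd(a, b) == pytest.approx(3.0)

    def test_assd_linear_in_spacing(self):
        rng = np.random.default_rng(9)
        a, b = random_pair(rng)
        assert assd(a, b, (2.0, 2.0, 2.0)) == pytest.approx(2 * assd(a, b), rel=1e-12)

    def test_assd_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a, b = random_pair(rng, p=0.2)
            assert assd(a, b) == pytest.approx(brute_assd(a, b, 1.0), rel=1e-10)

    def test_assd_bounded_by_hausdorff(self):
        from scipy.spatial import cKDTree

        rng = np.random.default_rng(13)
        for _ in range(10):
            a, b = random_pair(rng)
            sa, sb = surface_voxels(a), surface_voxels(b)
            h = max(cKDTree(sb).query(sa)[0].max(), cKDTree(sa).query(sb)[0].max())
            assert assd(a, b) <= h + 1e-12


class TestSegReport:
    def test_identity_row(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        r = seg_report(m, m)
        assert r.dsc_pct == 100.0 and r.assd_mm == 0.0 and r.miou_frac == 1.0

    def test_fields_match_componentwise_recomputation(self):
        rng = np.random.default_rng(17)
        a, b = random_pair(rng)
        r = seg_report(a, b)
        ref = brute_overlap(a, b)
        assert r.dsc_pct == pytest.approx(ref["dsc"], rel=1e-10)
        assert r.fpr_pct == pytest.approx(ref["fpr"], rel=1e-10)
        assert r.assd_mm == pytest.approx(brute_assd(a, b, 1.0), rel=1e-10)
        assert np.isfinite(r.rvd_signed_pct)
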