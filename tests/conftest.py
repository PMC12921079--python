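import numpy as np
import pytest

from cardiopet import PhantomSpec, generate_static_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, blur-free, aligned phantom: PET equals the uptake map."""
    spec = PhantomSpec(psf_fwhm_mm=0.0, noise_scale=0.0, seed=11)
    return generate_static_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """Phantom under the default imaging conditions (6 mm PSF, noise)."""
    return generate_static_phantom(PhantomSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# Independent brute-force oracles.  These deliberately use naive loops and
# set enumeration so they share no code path with the package.


def brute_overlap(pred, ref):
    p = {tuple(v) for v in np.argwhere(np.asarray(pred, bool))}
    r = {tuple(v) for v in np.argwhere(np.asarray(ref, bool))}
    inter = len(p & r)
    dice = 2 * inter / (len(p) + len(r)) if (p or r) else 1.0
    jac = inter / len(p | r) if (p or r) else 1.0
    sens = inter / len(r) if r else (1.0 if not p else 0.0)
    return dice, jac, sens


def brute_surface_voxels(mask):
    mask = np.asarray(mask, bool)
    out = np.zeros_like(mask)
    nx, ny, nz = mask.shape
    for i, j, k in np.argwhere(mask):
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            a, b, c = i + di, j + dj, k + dk
            if not (0 <= a < nx and 0 <= b < ny and 0 <= c < nz) or not mask[a, b, c]:
                out[i, j, k] = True
                break
    return out


def brute_mean_surface_distance(pred, ref, spacing):
    sp = np.asarray(spacing, float)
    pts_p = np.argwhere(brute_surface_voxels(pred)) * sp
    pts_r = np.argwhere(brute_surface_voxels(ref)) * sp
    d_pr = np.mean([min(np.linalg.norm(p - q) for q in pts_r) for p in pts_p])
    d_rp = np.mean([min(np.linalg.norm(q - p) for p in pts_p) for q in pts_r])
    return 0.5 * (d_pr + d_rp)


def brute_dilate(mask, radius_mm, spacing):
    mask = np.asarray(mask, bool)
    sp = np.asarray(spacing, float)
    centers = np.argwhere(mask) * sp
    out = np.zeros_like(mask)
    for idx in np.ndindex(mask.shape):
        pos = np.asarray(idx) * sp
        if centers.size and np.min(np.linalg.norm(centers - pos, axis=1)) <= radius_mm + 1e-9:
            out[idx] = True
    return out


def brute_resample_nn(labels, src_spacing, src_origin, tgt_shape, tgt_spacing, tgt_origin):
    out = np.zeros(tgt_shape, dtype=np.asarray(labels).dtype)
    for idx in np.ndindex(tuple(tgt_shape)):
        pos = np.asarray(tgt_origin) + np.asarray(idx) * np.asarray(tgt_spacing)
        src = np.rint((pos - np.asarray(src_origin)) / np.asarray(src_spacing)).astype(int)
        if all(0 <= s < n for s, n in zip(src, labels.shape)):
            out[idx] = labels[tuple(src)]
    return out
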