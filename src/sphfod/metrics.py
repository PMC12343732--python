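"""Evaluation metrics for FOD fields: MSE, ACC, SSIM, PSNR, angular error, PMR.

Voxel-wise metrics operate on ``(V, K)`` stacks of SH coefficients; grid-aware
metrics (SSIM) require a :class:`FODField` with a 3D voxel layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.spatial import ConvexHull

from . import sphharm

__all__ = [
    "FODField",
    "PeakSet",
    "MetricReport",
    "sh_mse",
    "acc",
    "ssim_per_channel",
    "psnr",
    "extract_peaks",
    "angular_error",
    "principal_peak_angles",
    "peak_match_rate",
    "metric_maps",
    "evaluate_voxels",
    "evaluate_field",
]


@dataclass(frozen=True)
class FODField:
    """A 3D grid of SH coefficient vectors with a binary mask and affine."""

    data: np.ndarray  # (X, Y, Z, K)
    mask: np.ndarray  # (X, Y, Z) boolean
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError(f"field data must be 4D (x, y, z, K), got {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match field grid")

    @property
    def n_coeffs(self) -> int:
        return self.data.shape[-1]

    def masked_coeffs(self) -> np.ndarray:
        """(V, K) stack of the in-mask voxels."""
        return self.data[self.mask.astype(bool)]


@dataclass(frozen=True)
class PeakSet:
    """FOD maxima: unit directions with amplitudes, sorted descending."""

    directions: np.ndarray  # (P, 3)
    amplitudes: np.ndarray  # (P,)

    def __len__(self) -> int:
        return self.directions.shape[0]

    @property
    def principal(self) -> np.ndarray | None:
        return self.directions[0] if len(self) else None


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    gt = np.atleast_2d(np.asarray(gt, dtype=float))
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return pred, gt


def sh_mse(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean over voxels of the squared SH-coefficient distance ||p_i - t_i||^2."""
    pred, gt = _check_pair(pred, gt)
    return float(np.mean(np.sum((pred - gt) ** 2, axis=-1)))


def acc(
    pred: np.ndarray,
    gt: np.ndarray,
    sampling: sphharm.SphereSampling | None = None,
) -> np.ndarray:
    """Per-voxel angular correlation: cosine similarity of FOD amplitudes.

    With ``sampling`` the cosine is computed between amplitude vectors on the
    given grid (the plain discrete form).  Without it, the exact dense-grid
    limit is used: for an orthonormal band-limited basis the amplitude inner
    product converges to the SH coefficient inner product, which is also
    exactly rotation invariant.  Zero-norm voxels yield NaN.
    """
    pred, gt = _check_pair(pred, gt)
    if sampling is not None:
        pred = sphharm.isft(pred, sampling)
        gt = sphharm.isft(gt, sampling)
    num = np.sum(pred * gt, axis=-1)
    den = np.linalg.norm(pred, axis=-1) * np.linalg.norm(gt, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    return out


def _ssim_3d(x: np.ndarray, y: np.ndarray, data_range: float, win: int = 7) -> float:
    """Uniform-window SSIM on a 3D volume (sample-covariance convention)."""
    if min(x.shape) < win:
        raise ValueError(f"volume side {min(x.shape)} smaller than window {win}")
    if data_range == 0:
        return 1.0 if np.array_equal(x, y) else 0.0
    NP = win**3
    cov_norm = NP / (NP - 1)
    K1, K2 = 0.01, 0.03
    C1, C2 = (K1 * data_range) ** 2, (K2 * data_range) ** 2
    ux = uniform_filter(x, win)
    uy = uniform_filter(y, win)
    uxx = uniform_filter(x * x, win)
    uyy = uniform_filter(y * y, win)
    uxy = uniform_filter(x * y, win)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    S = ((2 * ux * uy + C1) * (2 * vxy + C2)) / (
        (ux * ux + uy * uy + C1) * (vx + vy + C2)
    )
    pad = (win - 1) // 2
    core = S[pad:-pad, pad:-pad, pad:-pad]
    return float(core.mean())


def ssim_per_channel(pred: FODField, gt: FODField, win: int = 7) -> float:
    """3D SSIM computed per SH channel and averaged over channels.

    Each channel's data range is the ground-truth channel's max - min; voxels
    outside the mask are zeroed first.  Channels where both volumes are
    constant score 1.0 by convention.
    """
    if pred.data.shape != gt.data.shape:
        raise ValueError("field shapes differ")
    m = gt.mask.astype(bool)[..., None]
    p = np.where(m, pred.data, 0.0)
    g = np.where(m, gt.data, 0.0)
    vals = []
    for c in range(gt.n_coeffs):
        rng_c = float(g[..., c].max() - g[..., c].min())
        vals.append(_ssim_3d(p[..., c], g[..., c], rng_c, win))
    return float(np.mean(vals))


def psnr(pred: np.ndarray, gt: np.ndarray) -> float:
    """10 log10(data_range^2 / element-wise MSE), range = max |gt| coefficient."""
    pred, gt = _check_pair(pred, gt)
    mse = float(np.mean((pred - gt) ** 2))
    data_range = float(np.max(np.abs(gt)))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(data_range**2 / mse))


# ---------------------------------------------------------------------------
# peak extraction

_NEIGHBOR_CACHE: dict[int, np.ndarray] = {}


def _neighbor_index(sampling: sphharm.SphereSampling) -> np.ndarray:
    """(N, max_degree) neighbor indices from the convex-hull triangulation,
    padded with each point's own index."""
    key = id(sampling)
    if key in _NEIGHBOR_CACHE:
        return _NEIGHBOR_CACHE[key]
    hull = ConvexHull(sampling.dirs)
    nbrs: list[set[int]] = [set() for _ in range(sampling.n_points)]
    for a, b, c in hull.simplices:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    width = max(len(s) for s in nbrs)
    out = np.empty((sampling.n_points, width), dtype=np.int64)
    for i, s in enumerate(nbrs):
        row = sorted(s)
        out[i] = row + [i] * (width - len(row))
    _NEIGHBOR_CACHE[key] = out
    return out


def _tangent_frames(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent bases for a batch of unit vectors (V, 3)."""
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (v.shape[0], 1))
    near_x = np.abs(v[:, 0]) > 0.9
    ref[near_x] = [0.0, 1.0, 0.0]
    e1 = np.cross(v, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(v, e1)
    return e1, e2


def refine_directions(
    coeffs: np.ndarray, v0: np.ndarray, lmax: int, n_iter: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Newton ascent of the SH sums near starting directions.

    ``coeffs`` is (V, K), ``v0`` is (V, 3); one local maximum is refined per
    row.  Central finite differences with a shrinking step give the gradient
    and Hessian in the tangent plane; the Newton step is clipped and falls
    back to a gradient step when the Hessian is not negative definite.
    Returns the refined unit directions and their amplitudes.
    """
    coeffs = np.atleast_2d(coeffs)
    v = np.atleast_2d(np.asarray(v0, dtype=float)).copy()
    V = v.shape[0]
    hs = np.geomspace(1e-3, 1e-6, n_iter)
    # tangent-plane stencil offsets: center, +-e1, +-e2, four diagonals
    offs = np.array(
        [[0, 0], [1, 0], [-1, 0], [0, 1], [0, -1], [1, 1], [1, -1], [-1, 1], [-1, -1]],
        dtype=float,
    )
    for h in hs:
        e1, e2 = _tangent_frames(v)
        pts = (
            v[:, None, :]
            + h * offs[None, :, 0, None] * e1[:, None, :]
            + h * offs[None, :, 1, None] * e2[:, None, :]
        )  # (V, 9, 3)
        pts /= np.linalg.norm(pts, axis=2, keepdims=True)
        Y = sphharm.build_basis(pts.reshape(-1, 3), lmax).reshape(V, 9, -1)
        f = np.einsum("vsk,vk->vs", Y, coeffs)
        g1 = (f[:, 1] - f[:, 2]) / (2 * h)
        g2 = (f[:, 3] - f[:, 4]) / (2 * h)
        h11 = (f[:, 1] - 2 * f[:, 0] + f[:, 2]) / h**2
        h22 = (f[:, 3] - 2 * f[:, 0] + f[:, 4]) / h**2
        h12 = (f[:, 5] - f[:, 6] - f[:, 7] + f[:, 8]) / (4 * h**2)
        det = h11 * h22 - h12**2
        neg_def = (det > 0) & (h11 < 0)
        s1 = np.where(neg_def, -(h22 * g1 - h12 * g2) / np.where(det == 0, 1, det), 0.01 * g1)
        s2 = np.where(neg_def, -(h11 * g2 - h12 * g1) / np.where(det == 0, 1, det), 0.01 * g2)
        norm = np.sqrt(s1**2 + s2**2)
        scale = np.where(norm > 0.1, 0.1 / np.maximum(norm, 1e-300), 1.0)
        v = v + (s1 * scale)[:, None] * e1 + (s2 * scale)[:, None] * e2
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    amp = np.einsum(
        "vk,vk->v", sphharm.build_basis(v, lmax), coeffs
    )
    return v, amp


def _refine_direction(coeffs: np.ndarray, v0: np.ndarray, lmax: int) -> tuple[np.ndarray, float]:
    v, a = refine_directions(coeffs[None, :], v0[None, :], lmax)
    return v[0], float(a[0])


def extract_peaks(
    fod_sh: np.ndarray,
    sampling: sphharm.SphereSampling,
    rel_amp_threshold: float = 0.3,
    min_separation_deg: float = 25.0,
    max_peaks: int = 3,
    refine: bool = True,
) -> PeakSet:
    """Local maxima of the FOD over the sampling's neighbor graph.

    Candidates below ``rel_amp_threshold`` times the global maximum are
    dropped; surviving maxima are deduplicated antipodally and greedily
    suppressed within ``min_separation_deg``, then (optionally) refined by
    continuous maximization and sorted by descending amplitude.
    """
    fod_sh = np.asarray(fod_sh, dtype=float)
    amp = sampling.U @ fod_sh
    gmax = amp.max()
    if gmax <= 0:
        return PeakSet(np.empty((0, 3)), np.empty(0))
    nbr = _neighbor_index(sampling)
    is_max = amp >= amp[nbr].max(axis=1)
    cand = np.nonzero(is_max & (amp >= rel_amp_threshold * gmax) & (amp > 0))[0]
    cand = cand[np.argsort(amp[cand])[::-1]]
    min_cos = np.cos(np.deg2rad(min_separation_deg))
    kept_dirs: list[np.ndarray] = []
    kept_amps: list[float] = []
    for i in cand:
        v = sampling.dirs[i]
        # antipodal metric handles both +/-v duplicates and close neighbors
        if any(abs(v @ u) >= min_cos for u in kept_dirs):
            continue
        a = float(amp[i])
        if refine:
            v, a = _refine_direction(fod_sh, v, sampling.lmax)
            if any(abs(v @ u) >= min_cos for u in kept_dirs):
                continue
        kept_dirs.append(v)
        kept_amps.append(a)
        if len(kept_dirs) >= max_peaks:
            break
    if not kept_dirs:
        return PeakSet(np.empty((0, 3)), np.empty(0))
    order = np.argsort(kept_amps)[::-1]
    return PeakSet(
        np.asarray(kept_dirs)[order], np.asarray(kept_amps)[order]
    )


def angular_error(pred_peaks: PeakSet, gt_peaks: PeakSet) -> float:
    """Antipodally symmetric angle (degrees) between the principal peaks."""
    if len(pred_peaks) == 0 or len(gt_peaks) == 0:
        return float("nan")
    c = abs(float(pred_peaks.principal @ gt_peaks.principal))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def principal_peak_angles(
    pred: np.ndarray,
    gt: np.ndarray,
    sampling: sphharm.SphereSampling,
    rel_amp_threshold: float = 0.3,
    min_separation_deg: float = 25.0,
    refine: bool = True,
) -> np.ndarray:
    """Per-voxel principal-peak angular error in degrees (NaN = invalid voxel).

    The principal peak is the global maximum of the reconstructed FOD, located
    on the sampling grid and (by default) refined off-grid, so the whole batch
    vectorizes.  Voxels whose maximum amplitude is non-positive in either
    field are invalid (NaN).
    """
    pred, gt = _check_pair(pred, gt)
    out = np.full(pred.shape[0], np.nan)

    def principal(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        amp = stack @ sampling.U.T
        idx = np.argmax(amp, axis=1)
        vmax = amp[np.arange(stack.shape[0]), idx]
        dirs = sampling.dirs[idx]
        if refine:
            dirs, vref = refine_directions(stack, dirs, sampling.lmax)
            vmax = np.maximum(vmax, vref)
        return dirs, vmax

    dp, mp = principal(pred)
    dg, mg = principal(gt)
    valid = (mp > 0) & (mg > 0)
    cosang = np.abs(np.einsum("vk,vk->v", dp, dg))
    out[valid] = np.degrees(np.arccos(np.clip(cosang[valid], -1.0, 1.0)))
    return out


def peak_match_rate(angles_deg: np.ndarray, threshold_deg: float = 20.0) -> float:
    """Fraction of valid voxels with principal-peak error below the threshold."""
    angles_deg = np.asarray(angles_deg, dtype=float)
    valid = np.isfinite(angles_deg)
    if not np.any(valid):
        raise ValueError("no valid voxels (no peaks found in either field)")
    return float(np.mean(angles_deg[valid] < threshold_deg))


@dataclass
class MetricReport:
    """Global scalar metrics plus FOD-wise summaries (mean +/- sd)."""

    mse: float
    psnr: float
    ssim: float | None
    acc_mean: float
    acc_sd: float
    ae_mean: float
    ae_sd: float
    pmr: float
    n_voxels: int
    n_invalid: int

    def to_dict(self) -> dict:
        return {
            "global_scalar": {"MSE": self.mse, "SSIM": self.ssim, "PSNR_dB": self.psnr},
            "fod_wise": {
                "ACC": {"mean": self.acc_mean, "sd": self.acc_sd},
                "mean_angular_error_deg": {"mean": self.ae_mean, "sd": self.ae_sd},
                "peak_match_rate_20deg": self.pmr,
            },
            "n_voxels": self.n_voxels,
            "n_invalid": self.n_invalid,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def evaluate_voxels(
    pred: np.ndarray,
    gt: np.ndarray,
    peak_sampling: sphharm.SphereSampling | None = None,
    pmr_threshold_deg: float = 20.0,
    refine_peaks: bool = True,
    ssim: float | None = None,
) -> MetricReport:
    """Compute the full metric panel on (V, K) coefficient stacks."""
    pred, gt = _check_pair(pred, gt)
    if peak_sampling is None:
        peak_sampling = sphharm.make_sampling(2562, "icosphere", lmax=8)
    accs = acc(pred, gt)
    angles = principal_peak_angles(pred, gt, peak_sampling, refine=refine_peaks)
    valid = np.isfinite(angles)
    return MetricReport(
        mse=sh_mse(pred, gt),
        psnr=psnr(pred, gt),
        ssim=ssim,
        acc_mean=float(np.nanmean(accs)),
        acc_sd=float(np.nanstd(accs)),
        ae_mean=float(np.mean(angles[valid])) if valid.any() else float("nan"),
        ae_sd=float(np.std(angles[valid])) if valid.any() else float("nan"),
        pmr=peak_match_rate(angles, pmr_threshold_deg),
        n_voxels=pred.shape[0],
        n_invalid=int(np.sum(~valid)),
    )


def metric_maps(
    pred: FODField,
    gt: FODField,
    peak_sampling: sphharm.SphereSampling | None = None,
    refine_peaks: bool = True,
) -> dict[str, np.ndarray]:
    """Per-voxel 3D maps of ACC and principal-peak angular error (degrees).

    Voxels outside the mask (and invalid voxels) hold NaN.
    """
    if peak_sampling is None:
        peak_sampling = sphharm.make_sampling(2562, "icosphere", lmax=8)
    m = gt.mask.astype(bool)
    p, g = pred.data[m], gt.data[m]
    out = {}
    for name, values in (
        ("acc", acc(p, g)),
        ("angular_error_deg", principal_peak_angles(p, g, peak_sampling,
                                                    refine=refine_peaks)),
    ):
        vol = np.full(m.shape, np.nan)
        vol[m] = values
        out[name] = vol
    return out


def evaluate_field(
    pred: FODField,
    gt: FODField,
    peak_sampling: sphharm.SphereSampling | None = None,
    pmr_threshold_deg: float = 20.0,
    refine_peaks: bool = True,
) -> MetricReport:
    """Metric panel on 3D fields (adds channel-wise SSIM over the grid)."""
    if pred.data.shape != gt.data.shape:
        raise ValueError("field shapes differ")
    if not np.array_equal(pred.mask, gt.mask):
        raise ValueError("field masks differ")
    if not np.any(gt.mask):
        raise ValueError("empty mask")
    s = ssim_per_channel(pred, gt) if min(gt.mask.shape) >= 7 else None
    return evaluate_voxels(
        pred.masked_coeffs(),
        gt.masked_coeffs(),
        peak_sampling,
        pmr_threshold_deg,
        refine_peaks,
        ssim=s,
    )
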