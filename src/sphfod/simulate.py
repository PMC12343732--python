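"""Synthetic multi-shell dMRI phantom with planted fiber configurations.

Generates (noisy DWI, ground-truth FOD) voxel pairs on a reduced three-shell
protocol (19/26/38 directions at b = 400/1000/2600 s/mm^2 by default).  The
per-fiber signal kernel is an axially symmetric diffusion tensor; ground-truth
FODs are band-limited projections of weighted orientation deltas, and the
forward signal is their spherical convolution with the kernel's zonal profile
(Funk-Hecke), corrupted by Rician noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sphharm

__all__ = [
    "Protocol",
    "FiberConfig",
    "SyntheticVoxel",
    "PhantomDataset",
    "protocol_reduced",
    "tensor_signal",
    "zonal_response",
    "delta_fod_sh",
    "watson_zonal",
    "fiber_fod_sh",
    "sh_convolve",
    "add_rician_noise",
    "generate_phantom",
    "fit_per_shell_sh",
    "D_PAR_DEFAULT",
    "D_PERP_DEFAULT",
    "D_PERP_NEONATAL",
]

# default diffusivities in mm^2/s; the neonatal preset lowers anisotropy
D_PAR_DEFAULT = 1.7e-3
D_PERP_DEFAULT = 0.4e-3
D_PERP_NEONATAL = 0.7e-3

FULL_SHELL_COUNTS = (64, 88, 128)
SHELL_BVALUES = (400.0, 1000.0, 2600.0)


@dataclass(frozen=True)
class Protocol:
    """Multi-shell gradient scheme: list of (b-value, directions) pairs."""

    bvalues: tuple[float, ...]
    directions: tuple[np.ndarray, ...]

    @property
    def counts(self) -> tuple[int, ...]:
        return tuple(d.shape[0] for d in self.directions)

    @property
    def n_shells(self) -> int:
        return len(self.bvalues)

    @property
    def total_directions(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class FiberConfig:
    """Planted fiber population: unit directions and positive weights."""

    directions: np.ndarray  # (F, 3)
    weights: np.ndarray  # (F,)
    d_par: float = D_PAR_DEFAULT
    d_perp: float = D_PERP_DEFAULT
    s0: float = 1.0

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if d.shape[0] == 0:
            raise ValueError("fiber list is empty")
        if d.shape[0] != w.shape[0]:
            raise ValueError("directions and weights length mismatch")
        if np.any(w <= 0):
            raise ValueError("fiber weights must be positive")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError(f"fiber weights must sum to 1, got {w.sum()}")
        object.__setattr__(self, "directions", d / np.linalg.norm(d, axis=1, keepdims=True))
        object.__setattr__(self, "weights", w)

    @property
    def n_fibers(self) -> int:
        return self.directions.shape[0]


@dataclass(frozen=True)
class SyntheticVoxel:
    fiber_config: FiberConfig
    fod_sh: np.ndarray  # (K,) ground truth
    dwi: tuple[np.ndarray, ...]  # per-shell amplitudes
    noisy: bool
    seed: int


@dataclass(frozen=True)
class PhantomDataset:
    """Voxel collection with train/val/test split indices."""

    protocol: Protocol
    voxels: list[SyntheticVoxel]
    splits: dict[str, np.ndarray]
    lmax: int
    snr: float
    seed: int

    def __len__(self) -> int:
        return len(self.voxels)

    def fod_sh(self, split: str | None = None) -> np.ndarray:
        idx = self.splits[split] if split else np.arange(len(self.voxels))
        return np.stack([self.voxels[i].fod_sh for i in idx])

    def dwi(self, split: str | None = None) -> list[np.ndarray]:
        idx = self.splits[split] if split else np.arange(len(self.voxels))
        return [
            np.stack([self.voxels[i].dwi[s] for i in idx])
            for s in range(self.protocol.n_shells)
        ]


def protocol_reduced(
    full_counts: tuple[int, ...] = FULL_SHELL_COUNTS,
    fraction: float = 0.30,
    bvalues: tuple[float, ...] = SHELL_BVALUES,
) -> Protocol:
    """Reduced protocol keeping ``floor(fraction * n)`` directions per shell.

    The default reproduces the 19/26/38-direction scheme (83 total).  Each
    shell's directions are a deterministic well-spread (Fibonacci) set rotated
    to a shell-specific offset so shells do not share directions.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    counts = tuple(int(np.floor(fraction * n)) for n in full_counts)
    if any(c < 6 for c in counts):
        raise ValueError(f"reduced shell counts {counts} fall below the sanity floor of 6")
    dirs = []
    for i, c in enumerate(counts):
        pts = sphharm.fibonacci_sphere(c)
        # fixed per-shell rotation (golden-angle about z then tilt) for variety
        a = 2.399963229728653 * (i + 1)
        ca, sa = np.cos(a), np.sin(a)
        Rz = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
        b = 0.61803398875 * (i + 1)
        cb, sb = np.cos(b), np.sin(b)
        Rx = np.array([[1.0, 0.0, 0.0], [0.0, cb, -sb], [0.0, sb, cb]])
        dirs.append(pts @ (Rx @ Rz).T)
    return Protocol(bvalues=tuple(bvalues[: len(counts)]), directions=tuple(dirs))


def tensor_signal(
    b: float | np.ndarray,
    g: np.ndarray,
    v: np.ndarray,
    d_par: float = D_PAR_DEFAULT,
    d_perp: float = D_PERP_DEFAULT,
) -> np.ndarray:
    """Axially symmetric tensor kernel: exp(-b (d_perp + (d_par-d_perp)(g.v)^2))."""
    if np.any(np.asarray(b) < 0):
        raise ValueError("b-value must be non-negative")
    if d_par < d_perp or d_perp < 0:
        raise ValueError("need d_par >= d_perp >= 0")
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    dot = g @ v if g.ndim > 1 else float(np.dot(g, v))
    return np.exp(-np.asarray(b) * (d_perp + (d_par - d_perp) * np.square(dot)))


def zonal_response(
    b: float,
    d_par: float = D_PAR_DEFAULT,
    d_perp: float = D_PERP_DEFAULT,
    lmax: int = 8,
    quad_order: int = 64,
) -> np.ndarray:
    """Zonal SH coefficients r_l of the tensor kernel, one per even degree.

    r_l = 2*pi * Integral_{-1}^{1} k(t) * Pbar_l(t) dt with Pbar_l the
    orthonormal zonal harmonic sqrt((2l+1)/(4*pi)) * P_l, computed by
    Gauss-Legendre quadrature.
    """
    if b < 0:
        raise ValueError("b-value must be non-negative")
    t, w = np.polynomial.legendre.leggauss(max(int(quad_order), 64))
    k = np.exp(-b * (d_perp + (d_par - d_perp) * t**2))
    degrees = sphharm.sh_degrees(lmax)
    out = np.empty(len(degrees))
    for i, l in enumerate(degrees):
        Pl = np.polynomial.legendre.Legendre.basis(l)(t)
        Pbar = np.sqrt((2 * l + 1) / (4.0 * np.pi)) * Pl
        out[i] = 2.0 * np.pi * np.sum(w * k * Pbar)
    return out


def delta_fod_sh(fibers: FiberConfig, lmax: int = 8) -> np.ndarray:
    """Band-limited projection of the weighted orientation deltas.

    Coefficients are sum_i w_i * Y_k(v_i) so that the represented spherical
    function integrates to sum_i w_i = 1.
    """
    Y = sphharm.build_basis(fibers.directions, lmax)
    return fibers.weights @ Y


def watson_zonal(kappa: float, lmax: int = 8, quad_order: int = 128) -> np.ndarray:
    """Zonal SH coefficients of a unit-integral Watson density exp(kappa t^2).

    A smooth antipodally symmetric fiber kernel; kappa -> infinity approaches
    the delta projection.  Normalized so the represented density integrates
    to 1 on the sphere.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    t, w = np.polynomial.legendre.leggauss(max(int(quad_order), 64))
    k = np.exp(kappa * (t**2 - 1.0))  # -1 offset for numerical range only
    degrees = sphharm.sh_degrees(lmax)
    out = np.empty(len(degrees))
    for i, l in enumerate(degrees):
        Pbar = np.sqrt((2 * l + 1) / (4.0 * np.pi)) * np.polynomial.legendre.Legendre.basis(l)(t)
        out[i] = 2.0 * np.pi * np.sum(w * k * Pbar)
    return out / (out[0] * np.sqrt(4.0 * np.pi))


def fiber_fod_sh(fibers: FiberConfig, kernel_zonal: np.ndarray, lmax: int = 8) -> np.ndarray:
    """FOD of weighted fiber kernels: per-fiber deltas convolved with a zonal
    kernel (Funk-Hecke), so peaks stay at the fiber directions but the
    spectrum matches the kernel."""
    return sh_convolve(delta_fod_sh(fibers, lmax), kernel_zonal, lmax)


def sh_convolve(fod_sh: np.ndarray, r_l: np.ndarray, lmax: int = 8) -> np.ndarray:
    """Spherical convolution with a zonal kernel in the SH domain (Funk-Hecke).

    ``s_lm = sqrt(4*pi/(2l+1)) * r_l * f_lm``.
    """
    fod_sh = np.asarray(fod_sh)
    degrees = sphharm.sh_degrees(lmax)
    if fod_sh.shape[-1] != sphharm.n_coeffs(lmax) or len(r_l) != len(degrees):
        raise ValueError("coefficient lengths inconsistent with lmax")
    ldeg = sphharm.degree_of_index(lmax)
    scale = np.empty(fod_sh.shape[-1])
    for i, l in enumerate(degrees):
        scale[ldeg == l] = np.sqrt(4.0 * np.pi / (2 * l + 1)) * r_l[i]
    return fod_sh * scale


def add_rician_noise(
    amplitudes: np.ndarray, sigma: float, rng: np.random.Generator | int
) -> np.ndarray:
    """Magnitude-MR noise: sqrt((s + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    amplitudes = np.asarray(amplitudes, dtype=float)
    if sigma == 0:
        return amplitudes.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n1 = rng.normal(0.0, sigma, amplitudes.shape)
    n2 = rng.normal(0.0, sigma, amplitudes.shape)
    return np.sqrt((amplitudes + n1) ** 2 + n2**2)


def _sample_watson(rng: np.random.Generator, axis: np.ndarray, kappa: float) -> np.ndarray:
    """One draw from a Watson distribution around ``axis`` (rejection sampling)."""
    while True:
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        t = float(v @ axis)
        if rng.random() < np.exp(kappa * (t * t - 1.0)):
            return v


def _sample_fibers(
    rng: np.random.Generator,
    n_fibers: int,
    min_angle_deg: float,
    max_angle_deg: float,
    d_par: float,
    d_perp: float,
    max_tries: int = 200,
    orientation_axes: np.ndarray | None = None,
    orientation_kappa: float = 25.0,
) -> FiberConfig:
    """Draw fibers with pairwise crossing-angle bounds.

    Orientations are uniform on the sphere by default; with
    ``orientation_axes`` each fiber is drawn from a Watson lobe around one of
    the given axes (tract-like clustering).
    """
    lo = np.cos(np.deg2rad(min_angle_deg))
    hi = np.cos(np.deg2rad(max_angle_deg))
    for _ in range(max_tries):
        if orientation_axes is None:
            v = rng.standard_normal((n_fibers, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
        else:
            picks = rng.choice(len(orientation_axes), size=n_fibers, replace=False) \
                if n_fibers <= len(orientation_axes) else \
                rng.choice(len(orientation_axes), size=n_fibers)
            v = np.stack([
                _sample_watson(rng, orientation_axes[p], orientation_kappa)
                for p in picks
            ])
        ok = True
        for i in range(n_fibers):
            for j in range(i + 1, n_fibers):
                c = abs(float(v[i] @ v[j]))  # antipodally symmetric angle
                if not (hi <= c <= lo):
                    ok = False
        if ok:
            break
    else:
        raise RuntimeError("could not sample a fiber configuration within angle bounds")
    # weights: Dirichlet-ish but bounded away from 0 so every fiber is resolvable
    w = 0.3 + rng.random(n_fibers)
    w = w / w.sum()
    return FiberConfig(directions=v, weights=w, d_par=d_par, d_perp=d_perp)


def generate_phantom(
    n_voxels: int,
    protocol: Protocol | None = None,
    snr: float = 20.0,
    seed: int = 0,
    lmax: int = 8,
    fiber_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2),
    crossing_angle_range: tuple[float, float] = (40.0, 90.0),
    d_par: float = D_PAR_DEFAULT,
    d_perp: float = D_PERP_DEFAULT,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    noisy: bool = True,
    fod_kernel: str = "watson",
    watson_kappa: float = 15.0,
    n_orientation_axes: int | None = None,
    orientation_kappa: float = 25.0,
) -> PhantomDataset:
    """Generate a reproducible voxel phantom with train/val/test splits.

    ``fiber_fractions`` are the proportions of 1-, 2- and 3-fiber voxels;
    ``snr`` is s0/sigma on the b=0 amplitude (``snr = inf`` or ``noisy=False``
    disables noise).  Ground-truth FODs are mixtures of fiber kernels:
    ``fod_kernel='watson'`` (default) uses a smooth Watson lobe per fiber,
    emulating the spectral decay of deconvolution-based FODs;
    ``fod_kernel='delta'`` uses the raw band-limited delta projection.  The
    DWI forward model always uses the delta fiber geometry, so the signal is
    independent of the ground-truth smoothing.

    Fiber orientations are uniform on the sphere by default.  With
    ``n_orientation_axes`` set, orientations cluster in Watson lobes
    (concentration ``orientation_kappa``) around that many random axes,
    mimicking the anatomically coherent tract orientations of real data.
    """
    if n_voxels <= 0:
        raise ValueError("n_voxels must be positive")
    if protocol is None:
        protocol = protocol_reduced()
    rng = np.random.default_rng(seed)
    # separate stream so noise draws do not perturb the fiber configurations
    noise_rng = np.random.default_rng((seed, 0x5EED))
    fracs = np.asarray(fiber_fractions, dtype=float)
    fracs = fracs / fracs.sum()
    sigma = 0.0 if (not noisy or not np.isfinite(snr)) else 1.0 / snr
    responses = [
        zonal_response(b, d_par, d_perp, lmax=lmax) for b in protocol.bvalues
    ]
    if fod_kernel == "watson":
        kernel = watson_zonal(watson_kappa, lmax)
    elif fod_kernel == "delta":
        kernel = None
    else:
        raise ValueError(f"unknown fod_kernel {fod_kernel!r}")
    if n_orientation_axes is not None:
        # well-separated tract axes: icosahedral axes (pairwise 63.4 degrees)
        # under a seed-dependent random rotation, truncated to the requested count
        t = (1.0 + np.sqrt(5.0)) / 2.0
        ico_axes = np.array(
            [[1, t, 0], [-1, t, 0], [0, 1, t], [0, -1, t], [t, 0, 1], [-t, 0, 1]],
            dtype=float,
        )
        ico_axes /= np.linalg.norm(ico_axes, axis=1, keepdims=True)
        if not 1 <= n_orientation_axes <= 6:
            raise ValueError("n_orientation_axes must be in 1..6")
        axes = ico_axes[:n_orientation_axes] @ sphharm.random_rotation(rng).T
    else:
        axes = None
    voxels: list[SyntheticVoxel] = []
    n_fiber_choices = rng.choice(3, size=n_voxels, p=fracs) + 1
    for i in range(n_voxels):
        fibers = _sample_fibers(
            rng, int(n_fiber_choices[i]), *crossing_angle_range, d_par, d_perp,
            orientation_axes=axes, orientation_kappa=orientation_kappa,
        )
        fod = delta_fod_sh(fibers, lmax)
        dwi = []
        for s in range(protocol.n_shells):
            # the signal always follows the exact (delta-fiber) forward model
            sig_sh = sh_convolve(fod, responses[s], lmax)
            amp = sphharm.build_basis(protocol.directions[s], lmax) @ sig_sh
            if sigma > 0:
                amp = add_rician_noise(amp, sigma, noise_rng)
            dwi.append(amp)
        gt = fod if kernel is None else sh_convolve(fod, kernel, lmax)
        voxels.append(
            SyntheticVoxel(
                fiber_config=fibers,
                fod_sh=gt,
                dwi=tuple(dwi),
                noisy=sigma > 0,
                seed=seed,
            )
        )
    perm = rng.permutation(n_voxels)
    n_train = int(round(split_fractions[0] * n_voxels))
    n_val = int(round(split_fractions[1] * n_voxels))
    splits = {
        "train": np.sort(perm[:n_train]),
        "val": np.sort(perm[n_train : n_train + n_val]),
        "test": np.sort(perm[n_train + n_val :]),
    }
    return PhantomDataset(
        protocol=protocol, voxels=voxels, splits=splits, lmax=lmax, snr=snr, seed=seed
    )


def fit_per_shell_sh(
    dwi: list[np.ndarray] | tuple[np.ndarray, ...],
    protocol: Protocol,
    lmax: int = 8,
    ridge: float = 1e-3,
    min_dirs: int = 6,
    regularizer: str = "ridge",
) -> np.ndarray:
    """Least-squares SH fit per shell -> (..., n_shells, K) coefficient stack.

    Shells with fewer directions than ``K`` are fit with the regularized
    minimum-norm solution (default identity ridge 1e-3; ``ridge=0`` gives the
    plain pseudo-inverse).  ``regularizer='laplace_beltrami'`` weights the
    penalty by ``(l(l+1))^2``, shrinking the poorly determined high degrees
    harder — the standard smoothness prior for under-sampled shells.  Shells
    are ordered by ascending b-value.
    """
    if len(dwi) != protocol.n_shells:
        raise ValueError("one amplitude array per shell required")
    order = np.argsort(protocol.bvalues)
    K = sphharm.n_coeffs(lmax)
    out = []
    for s in order:
        n = protocol.counts[s]
        if n < min_dirs:
            raise ValueError(
                f"shell b={protocol.bvalues[s]:g} has {n} directions (< {min_dirs})"
            )
        amp = np.asarray(dwi[s], dtype=float)
        if amp.shape[-1] != n:
            raise ValueError(
                f"shell b={protocol.bvalues[s]:g}: {amp.shape[-1]} amplitudes != {n} directions"
            )
        Y = sphharm.build_basis(protocol.directions[s], lmax)
        if ridge > 0:
            if regularizer == "ridge":
                P = np.eye(K)
            elif regularizer == "laplace_beltrami":
                ldeg = sphharm.degree_of_index(lmax)
                P = np.diag((ldeg * (ldeg + 1.0)) ** 2) + 1e-3 * np.eye(K)
            else:
                raise ValueError(f"unknown regularizer {regularizer!r}")
            A = np.linalg.solve(Y.T @ Y + ridge * P, Y.T)
        else:
            A = np.linalg.pinv(Y)  # minimum-norm when underdetermined
        out.append(amp @ A.T)
    return np.stack(out, axis=-2)
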