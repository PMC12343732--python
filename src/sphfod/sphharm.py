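"""Real symmetric spherical-harmonic basis and spherical Fourier transforms.

The basis is the real, even-degree, orthonormal spherical-harmonic set in the
ordering used by MRtrix3 FOD images: coefficients are stored by ascending
degree ``l`` (even only), and within each degree by ascending order ``m``
from ``-l`` to ``l``.  For ``m < 0`` the function is ``sqrt(2) * Im(Y_l^|m|)``,
for ``m = 0`` it is ``Y_l^0``, and for ``m > 0`` it is ``sqrt(2) * Re(Y_l^m)``,
with ``Y_l^m`` the orthonormal complex spherical harmonics (Condon-Shortley
phase included).  Directions are 3D Cartesian unit vectors; the polar angle is
measured from +z and the azimuth from +x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "n_coeffs",
    "sh_degrees",
    "index_table",
    "degree_of_index",
    "build_basis",
    "SphereSampling",
    "make_sampling",
    "fibonacci_sphere",
    "icosphere",
    "sft",
    "isft",
    "SHRotation",
    "rotation_operator",
    "random_rotation",
    "write_dirs",
    "read_dirs",
]


def n_coeffs(lmax: int) -> int:
    """Number of even-degree real SH basis functions up to ``lmax``.

    ``K = (lmax/2 + 1) * (lmax + 1)``; for ``lmax = 8`` this is 45.
    """
    _check_lmax(lmax)
    return (lmax // 2 + 1) * (lmax + 1)


def sh_degrees(lmax: int) -> np.ndarray:
    """Even degrees 0, 2, ..., lmax."""
    _check_lmax(lmax)
    return np.arange(0, lmax + 1, 2)


def index_table(lmax: int) -> np.ndarray:
    """(K, 2) array mapping flat coefficient index to (l, m)."""
    _check_lmax(lmax)
    out = []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            out.append((l, m))
    return np.asarray(out, dtype=int)


def degree_of_index(lmax: int) -> np.ndarray:
    """Length-K vector giving the degree ``l`` of each flat index."""
    return index_table(lmax)[:, 0]


def _check_lmax(lmax: int) -> None:
    if lmax < 0 or lmax % 2 != 0:
        raise ValueError(f"lmax must be an even non-negative integer, got {lmax}")


def _check_unit(dirs: np.ndarray, tol: float = 1e-6) -> None:
    norms = np.linalg.norm(dirs, axis=-1)
    bad = np.nonzero(np.abs(norms - 1.0) > tol)[0]
    if bad.size:
        raise ValueError(
            f"direction row {bad[0]} is not unit-norm (|v| = {norms[bad[0]]:.6g})"
        )


def cart_to_sph(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian unit vectors -> (polar theta from +z, azimuth phi from +x)."""
    dirs = np.asarray(dirs, dtype=float)
    theta = np.arccos(np.clip(dirs[..., 2], -1.0, 1.0))
    phi = np.arctan2(dirs[..., 1], dirs[..., 0])
    return theta, phi


def build_basis(dirs: np.ndarray, lmax: int) -> np.ndarray:
    """Evaluate the real symmetric SH basis at unit directions.

    Parameters
    ----------
    dirs : (N, 3) array of unit vectors.
    lmax : even band limit.

    Returns
    -------
    (N, K) matrix ``U`` with ``K = n_coeffs(lmax)``; column ``k`` is basis
    function ``k`` evaluated at every direction.
    """
    _check_lmax(lmax)
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    if dirs.shape[-1] != 3:
        raise ValueError(f"dirs must have shape (N, 3), got {dirs.shape}")
    _check_unit(dirs)
    theta, phi = cart_to_sph(dirs)
    cols = []
    for l in range(0, lmax + 1, 2):
        # complex orthonormal SH for m = 0..l evaluated at all points
        y = {m: sph_harm_y(l, m, theta, phi) for m in range(0, l + 1)}
        for m in range(-l, l + 1):
            if m < 0:
                cols.append(np.sqrt(2.0) * y[-m].imag)
            elif m == 0:
                cols.append(y[0].real)
            else:
                cols.append(np.sqrt(2.0) * y[m].real)
    return np.stack(cols, axis=-1)


@dataclass(frozen=True)
class SphereSampling:
    """A fixed sphere discretization shared by nonlinearities, loss and metrics.

    Attributes
    ----------
    dirs : (N, 3) unit vectors.
    U : (N, K) inverse-SFT matrix (basis at ``dirs``).
    U_pinv : (K, N) least-squares forward-SFT matrix.
    lmax : band limit of the basis.
    quad_weights : optional (N,) positive weights summing to 4*pi.
    """

    dirs: np.ndarray
    U: np.ndarray
    U_pinv: np.ndarray
    lmax: int
    quad_weights: np.ndarray | None = field(default=None)

    @property
    def n_points(self) -> int:
        return self.dirs.shape[0]

    @property
    def n_coeffs(self) -> int:
        return self.U.shape[1]


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic well-spread point set (golden-angle spiral)."""
    if n_points < 1:
        raise ValueError("n_points must be positive")
    i = np.arange(n_points, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def icosphere(n_subdiv: int = 3) -> np.ndarray:
    """Vertices of a subdivided icosahedron (42, 162, 642, 2562, ... points)."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(n_subdiv):
        verts_list = [v for v in verts]
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key in midpoint_cache:
                return midpoint_cache[key]
            v = verts_list[a] + verts_list[b]
            v = v / np.linalg.norm(v)
            verts_list.append(v)
            midpoint_cache[key] = len(verts_list) - 1
            return midpoint_cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces)
    return verts


def make_sampling(
    n_points: int = 724,
    scheme: str = "fibonacci",
    lmax: int = 8,
    ridge: float = 0.0,
) -> SphereSampling:
    """Build a deterministic :class:`SphereSampling`.

    ``scheme='fibonacci'`` honours ``n_points`` exactly (must be even);
    ``scheme='icosphere'`` rounds up to the next subdivision level (42, 162,
    642, 2562, ...).  Both point sets are antipodally symmetric, so the
    least-squares SFT annihilates odd functions exactly.  ``ridge`` adds
    Tikhonov regularization to the SFT matrix (default 0: plain Moore-Penrose
    pseudo-inverse).
    """
    K = n_coeffs(lmax)
    if n_points < K:
        raise ValueError(
            f"n_points = {n_points} underdetermines the SFT (need >= {K} for lmax={lmax})"
        )
    if n_points < 2 * K:
        raise ValueError(
            f"n_points = {n_points} < 2K = {2 * K}: the least-squares SFT would be "
            "ill-conditioned on an antipodally symmetric sampling"
        )
    if scheme == "fibonacci":
        if n_points % 2:
            raise ValueError("fibonacci sampling requires an even n_points "
                             "(points are antipodally paired)")
        half = fibonacci_sphere(n_points // 2)
        dirs = np.concatenate([half, -half])
    elif scheme == "icosphere":
        n_subdiv = 0
        while 10 * 4**n_subdiv + 2 < n_points:
            n_subdiv += 1
        dirs = icosphere(n_subdiv)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    U = build_basis(dirs, lmax)
    if np.linalg.cond(U) > 1e6:
        raise ValueError(
            f"sampling with {dirs.shape[0]} points is too ill-conditioned for "
            f"lmax = {lmax}; use more points"
        )
    if ridge > 0:
        U_pinv = np.linalg.solve(U.T @ U + ridge * np.eye(K), U.T)
    else:
        U_pinv = np.linalg.pinv(U)
    w = np.full(dirs.shape[0], 4.0 * np.pi / dirs.shape[0])
    return SphereSampling(dirs=dirs, U=U, U_pinv=U_pinv, lmax=lmax, quad_weights=w)


def isft(coeffs: np.ndarray, sampling: SphereSampling) -> np.ndarray:
    """SH coefficients -> amplitudes at the sampling points (``U @ c``).

    ``coeffs`` may be (..., K); the transform maps the trailing axis.
    """
    coeffs = np.asarray(coeffs)
    if coeffs.shape[-1] != sampling.n_coeffs:
        raise ValueError(
            f"coefficient length {coeffs.shape[-1]} != basis size {sampling.n_coeffs}"
        )
    return coeffs @ sampling.U.T


def sft(amplitudes: np.ndarray, sampling: SphereSampling) -> np.ndarray:
    """Amplitudes at the sampling points -> least-squares SH coefficients."""
    amplitudes = np.asarray(amplitudes)
    if amplitudes.shape[-1] != sampling.n_points:
        raise ValueError(
            f"amplitude length {amplitudes.shape[-1]} != sampling size {sampling.n_points}"
        )
    return amplitudes @ sampling.U_pinv.T


@dataclass(frozen=True)
class SHRotation:
    """Block-diagonal rotation operator on even-degree real SH coefficients.

    ``D @ c`` are the coefficients of the rotated function
    ``f'(x) = f(R^T x)`` when ``c`` are the coefficients of ``f``.
    """

    R: np.ndarray
    D: np.ndarray
    lmax: int

    def apply(self, coeffs: np.ndarray) -> np.ndarray:
        return np.asarray(coeffs) @ self.D.T

    def blocks(self) -> list[np.ndarray]:
        out, k = [], 0
        for l in sh_degrees(self.lmax):
            out.append(self.D[k : k + 2 * l + 1, k : k + 2 * l + 1])
            k += 2 * l + 1
        return out


# dense grid reused for the per-degree least-squares construction
_ROT_GRID_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def rotation_operator(R: np.ndarray, lmax: int) -> SHRotation:
    """Construct the SH-domain operator for a 3x3 rotation matrix.

    Built numerically per degree: on a dense well-spread grid ``X`` the block
    ``D_l`` solves ``Y_l(X) D_l^T = Y_l(X R)`` in the least-squares sense,
    which is exact up to the band limit.  Rotations only mix coefficients
    within a degree, so ``D`` is block-diagonal with orthogonal blocks.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"R must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
        raise ValueError("R is not orthogonal (R^T R != I within 1e-10)")
    if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ValueError("R must be a proper rotation (det = +1)")
    _check_lmax(lmax)
    if lmax not in _ROT_GRID_CACHE:
        grid = fibonacci_sphere(max(40 * (lmax + 1), 400))
        _ROT_GRID_CACHE[lmax] = (grid, build_basis(grid, lmax))
    grid, Y = _ROT_GRID_CACHE[lmax]
    # f'(x) = f(R^T x): evaluate the basis at R^T-rotated grid points.
    Yrot = build_basis(grid @ R, lmax)
    K = n_coeffs(lmax)
    D = np.zeros((K, K))
    k = 0
    for l in sh_degrees(lmax):
        w = 2 * l + 1
        block, *_ = np.linalg.lstsq(Y[:, k : k + w], Yrot[:, k : k + w], rcond=None)
        D[k : k + w, k : k + w] = block
        k += w
    return SHRotation(R=R, D=D, lmax=lmax)


def write_dirs(path, dirs: np.ndarray) -> None:
    """Serialize a point set as plain text, one ``x y z`` triple per line."""
    np.savetxt(path, np.atleast_2d(dirs), fmt="%.17g")


def read_dirs(path) -> np.ndarray:
    dirs = np.atleast_2d(np.loadtxt(path))
    if dirs.shape[1] != 3:
        raise ValueError(f"expected 3 columns (x y z), got {dirs.shape[1]}")
    return dirs


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-uniform random rotation matrix (QR of a Gaussian matrix)."""
    A = rng.standard_normal((3, 3))
    Q, Rq = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(Rq))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
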