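"""NIfTI / FSL-gradient readers and writers, phantom serialization, manifests."""

from __future__ import annotations

import hashlib
import os
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import yaml

from . import __version__, simulate, sphharm
from .metrics import FODField

__all__ = [
    "DWIDataset",
    "read_dwi",
    "read_gradients",
    "write_sh_image",
    "read_sh_image",
    "write_phantom",
    "load_phantom_dwi",
    "fit_dataset_sh",
    "write_manifest",
]

SHELL_TOLERANCE = 50.0  # s/mm^2 grouping tolerance for b-values


@dataclass(frozen=True)
class DWIDataset:
    """4D diffusion volume with gradient table, mask and affine."""

    data: np.ndarray  # (X, Y, Z, V)
    bvals: np.ndarray  # (V,)
    bvecs: np.ndarray  # (V, 3)
    mask: np.ndarray  # (X, Y, Z) boolean
    affine: np.ndarray

    def __post_init__(self):
        v = self.data.shape[-1]
        if len(self.bvals) != v or self.bvecs.shape != (v, 3):
            raise ValueError(
                f"volume/gradient count mismatch: {v} volumes, "
                f"{len(self.bvals)} bvals, {self.bvecs.shape[0]} bvecs"
            )

    def shell_groups(self) -> dict[float, np.ndarray]:
        """Disjoint volume-index groups keyed by rounded shell b-value.

        b-values within ``SHELL_TOLERANCE`` collapse to one shell; the b=0
        group (key 0.0) holds non-diffusion-weighted volumes.
        """
        groups: dict[float, list[int]] = {}
        centers: list[float] = []
        for i, b in enumerate(self.bvals):
            for c in centers:
                if abs(b - c) <= SHELL_TOLERANCE:
                    groups[c].append(i)
                    break
            else:
                centers.append(float(b))
                groups[float(b)] = [i]
        out = {}
        for c in sorted(groups):
            key = 0.0 if c <= SHELL_TOLERANCE else c
            out[key] = np.asarray(groups[c])
        return out

    def to_protocol(self) -> simulate.Protocol:
        """Weighted shells (b > 0) as a Protocol, ascending b-value."""
        groups = self.shell_groups()
        bvals = [b for b in groups if b > 0]
        return simulate.Protocol(
            bvalues=tuple(bvals),
            directions=tuple(self.bvecs[groups[b]] for b in bvals),
        )


def read_gradients(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """FSL-format gradient table: whitespace bvals, 3xV (or Vx3) bvecs."""
    bvals = np.loadtxt(bval_path).reshape(-1)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise ValueError(f"bvec file must be 3xV or Vx3, got shape {bvecs.shape}")
    if bvecs.shape[0] == 3:  # FSL 3xV (the ambiguous 3x3 is read as FSL too)
        bvecs = bvecs.T
    else:
        warnings.warn("bvec file is Vx3; the FSL convention is 3xV", stacklevel=2)
    if len(bvals) != bvecs.shape[0]:
        raise ValueError(
            f"gradient count mismatch: {len(bvals)} bvals vs {bvecs.shape[0]} bvecs"
        )
    weighted = bvals > SHELL_TOLERANCE
    norms = np.linalg.norm(bvecs[weighted], axis=1)
    bad = np.nonzero(np.abs(norms - 1.0) > 1e-3)[0]
    if bad.size:
        i = np.nonzero(weighted)[0][bad[0]]
        raise ValueError(f"bvec {i} is not unit-norm (|v| = {norms[bad[0]]:.4f})")
    return bvals, bvecs


def read_dwi(dwi_path, bval_path, bvec_path, mask_path=None) -> DWIDataset:
    """Load a 4D DWI NIfTI with its FSL gradient table and optional mask."""
    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"DWI volume must be 4D, got {data.ndim}D")
    bvals, bvecs = read_gradients(bval_path, bvec_path)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask grid does not match DWI grid")
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return DWIDataset(data=data, bvals=bvals, bvecs=bvecs, mask=mask,
                      affine=np.asarray(img.affine))


def write_sh_image(field: FODField, path, n_coeffs: int = 45) -> None:
    """Write an SH coefficient field as a 4D NIfTI (one volume per coefficient)."""
    if field.data.shape[-1] != n_coeffs:
        raise ValueError(
            f"expected {n_coeffs} coefficient channels, got {field.data.shape[-1]}"
        )
    img = nib.Nifti1Image(field.data.astype(np.float64), field.affine)
    nib.save(img, str(path))


def read_sh_image(path, mask_path=None, n_coeffs: int = 45) -> FODField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != n_coeffs:
        raise ValueError(
            f"SH image must be 4D with {n_coeffs} volumes, got shape {data.shape}"
        )
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.any(data != 0, axis=-1)
    return FODField(data=data, mask=mask, affine=np.asarray(img.affine))


def _grid_shape(n_voxels: int) -> tuple[int, int, int]:
    nx = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    ny = int(np.ceil(np.sqrt(n_voxels / nx)))
    nz = int(np.ceil(n_voxels / (nx * ny)))
    return nx, ny, nz


def write_phantom(dataset: simulate.PhantomDataset, outdir) -> dict[str, str]:
    """Serialize a phantom: 4D DWI (one leading b=0 volume), bvals/bvecs,
    mask, ground-truth SH image and a YAML manifest of splits/parameters."""
    os.makedirs(outdir, exist_ok=True)
    n = len(dataset)
    shape = _grid_shape(n)
    nvol = 1 + dataset.protocol.total_directions  # synthetic b=0 first
    flat_dwi = np.zeros((np.prod(shape), nvol))
    flat_fod = np.zeros((np.prod(shape), sphharm.n_coeffs(dataset.lmax)))
    s0 = np.array([v.fiber_config.s0 for v in dataset.voxels])
    if dataset.snr and np.isfinite(dataset.snr) and dataset.voxels[0].noisy:
        s0 = simulate.add_rician_noise(s0, 1.0 / dataset.snr, dataset.seed + 1)
    flat_dwi[:n, 0] = s0
    col = 1
    for s in range(dataset.protocol.n_shells):
        block = np.stack([v.dwi[s] for v in dataset.voxels])
        flat_dwi[:n, col : col + block.shape[1]] = block
        col += block.shape[1]
    flat_fod[:n] = np.stack([v.fod_sh for v in dataset.voxels])
    mask = np.zeros(np.prod(shape), dtype=np.uint8)
    mask[:n] = 1
    affine = np.eye(4)
    paths = {
        "dwi": os.path.join(outdir, "dwi.nii.gz"),
        "bvals": os.path.join(outdir, "bvals"),
        "bvecs": os.path.join(outdir, "bvecs"),
        "mask": os.path.join(outdir, "mask.nii.gz"),
        "fod_gt": os.path.join(outdir, "fod_gt.nii.gz"),
        "manifest": os.path.join(outdir, "phantom.yaml"),
    }
    nib.save(nib.Nifti1Image(flat_dwi.reshape(*shape, nvol), affine), paths["dwi"])
    nib.save(nib.Nifti1Image(mask.reshape(shape), affine), paths["mask"])
    nib.save(
        nib.Nifti1Image(flat_fod.reshape(*shape, -1), affine), paths["fod_gt"]
    )
    bvals = np.concatenate(
        [[0.0]] + [
            np.full(c, b)
            for b, c in zip(dataset.protocol.bvalues, dataset.protocol.counts)
        ]
    )
    bvecs = np.concatenate([np.zeros((1, 3))] + list(dataset.protocol.directions))
    np.savetxt(paths["bvals"], bvals[None, :], fmt="%g")
    np.savetxt(paths["bvecs"], bvecs.T, fmt="%.10f")
    meta = {
        "n_voxels": n,
        "grid_shape": list(shape),
        "lmax": dataset.lmax,
        "snr": float(dataset.snr),
        "seed": dataset.seed,
        "shells": [
            {"bvalue": float(b), "n_dirs": int(c)}
            for b, c in zip(dataset.protocol.bvalues, dataset.protocol.counts)
        ],
        "splits": {k: np.asarray(v).tolist() for k, v in dataset.splits.items()},
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(meta, fh)
    return paths


def load_phantom_dwi(outdir) -> tuple[DWIDataset, dict]:
    """Read back a phantom directory written by :func:`write_phantom`."""
    ds = read_dwi(
        os.path.join(outdir, "dwi.nii.gz"),
        os.path.join(outdir, "bvals"),
        os.path.join(outdir, "bvecs"),
        os.path.join(outdir, "mask.nii.gz"),
    )
    with open(os.path.join(outdir, "phantom.yaml")) as fh:
        meta = yaml.safe_load(fh)
    return ds, meta


def fit_dataset_sh(ds: DWIDataset, lmax: int = 8, ridge: float = 1e-3) -> np.ndarray:
    """Per-shell SH fit of the masked voxels -> (V, n_shells, K) stack.

    b=0 volumes are excluded from the fit; shells are ordered by ascending
    b-value.
    """
    protocol = ds.to_protocol()
    groups = ds.shell_groups()
    vox = ds.data[ds.mask.astype(bool)]
    dwi = [vox[:, groups[b]] for b in protocol.bvalues]
    return simulate.fit_per_shell_sh(dwi, protocol, lmax=lmax, ridge=ridge)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(outdir, command: str, seed, config: dict,
                   inputs: list | None = None, outputs: list | None = None) -> str:
    """Write the per-run YAML manifest required to re-run a CLI command."""
    manifest = {
        "command": command,
        "seed": seed,
        "package_version": __version__,
        "config": config,
        "inputs": {str(p): _digest(p) for p in (inputs or []) if os.path.exists(str(p))},
        "outputs": [str(p) for p in (outputs or [])],
    }
    path = os.path.join(outdir, f"manifest_{command}.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return path
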