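"""File interfaces: NIfTI-1 volumes (via nibabel), FSL-style bvals/bvecs
text files, a JSON scheme descriptor with the explicit axis/bisector
partition, and YAML phantom manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .dki_core import AcquisitionScheme, make_199_scheme

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_bvals_bvecs",
    "read_bvals_bvecs",
    "scheme_to_json",
    "scheme_from_json",
    "scheme_from_bvals_bvecs",
    "write_manifest",
]

AFFINE_TOL_MM = 1e-4


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_nifti(path, array, voxel_size_mm, *, dtype=np.float32) -> None:
    """Write a 3D/4D array as NIfTI-1 with a diagonal voxel-size affine."""
    img = nib.Nifti1Image(np.asarray(array).astype(dtype), _affine(voxel_size_mm))
    img.header.set_zooms(tuple(voxel_size_mm) + (1.0,) * (array.ndim - 3))
    nib.save(img, str(path))


def load_nifti(path):
    """Read a NIfTI file; returns (data array, voxel size mm, affine)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.dataobj), tuple(float(z) for z in zooms), img.affine


def check_same_geometry(affine_a, affine_b, tol: float = AFFINE_TOL_MM) -> None:
    if np.abs(np.asarray(affine_a) - np.asarray(affine_b)).max() > tol:
        raise ValueError("images do not share an affine within tolerance")


def write_bvals_bvecs(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    """FSL convention: bvals on one row; bvecs as three rows (x, y, z)."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    # Full precision: the scheme certification checks direction moments to
    # 1e-10, which truncated components would fail.
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.17g")


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError("bvals/bvecs sizes do not match")
    return bvals, bvecs


def scheme_from_bvals_bvecs(bval_path, bvec_path) -> AcquisitionScheme:
    """Reconstruct a 1-9-9 scheme from FSL files.

    Expects acquisition order b=0 first, then the 9 directions at b1 and the
    same 9 at b2, each shell ordered axes-first; the moment-condition check
    at construction rejects direction sets for which the 1/15-2/15 weighting
    is not exact.
    """
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if bvals.size != 19 or bvals[0] != 0:
        raise ValueError("expected 19 volumes with a leading b=0")
    b1 = float(bvals[1])
    b2 = float(bvals[10])
    if not np.allclose(bvals[1:10], b1) or not np.allclose(bvals[10:], b2):
        raise ValueError("expected two 9-volume shells")
    dirs1, dirs2 = bvecs[1:10], bvecs[10:]
    if not np.allclose(dirs1, dirs2, atol=1e-6):
        raise ValueError("the two shells must share directions")
    dirs1 = dirs1 / np.linalg.norm(dirs1, axis=1, keepdims=True)
    return make_199_scheme(b1, b2, axes=dirs1[:3], bisectors=dirs1[3:])


def scheme_to_json(scheme: AcquisitionScheme, path) -> None:
    doc = {
        "b0": 0.0,
        "b1": scheme.b1,
        "b2": scheme.b2,
        "axes": scheme.axes.tolist(),
        "bisectors": scheme.bisectors.tolist(),
        "axis_weight": scheme.AXIS_WEIGHT,
        "bisector_weight": scheme.BISECTOR_WEIGHT,
        "delta_ms": scheme.delta_ms,
        "Delta_ms": scheme.Delta_ms,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def scheme_from_json(path) -> AcquisitionScheme:
    doc = json.loads(Path(path).read_text())
    return make_199_scheme(
        doc["b1"],
        doc["b2"],
        axes=doc["axes"],
        bisectors=doc["bisectors"],
        delta_ms=doc.get("delta_ms"),
        Delta_ms=doc.get("Delta_ms"),
    )


def write_manifest(path, spec) -> None:
    """YAML manifest of a phantom spec (geometry, tissue params, noise)."""
    doc = {
        "shape": list(spec.shape),
        "voxel_size_mm": list(spec.voxel_size_mm),
        "snr": spec.snr,
        "s0": spec.s0,
        "seed": spec.seed,
        "ring_scale": spec.ring_scale,
        "brain": {"center": list(spec.brain.center),
                  "semi_axes": list(spec.brain.semi_axes)},
        "lesion_core": {"center": list(spec.lesion_core.center),
                        "semi_axes": list(spec.lesion_core.semi_axes)},
        "regions": {
            name: {"md": p.md, "mkt": p.mkt} for name, p in spec.regions.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
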