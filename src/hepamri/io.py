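"""File formats: NIfTI series, FSL-style gradient tables, sidecars.

Volumes are written as NIfTI-1, RAS-oriented, with voxel sizes from the
acquisition protocols stored in the header (geometry is carried as
metadata only; nothing downstream uses it computationally).  Gradient
tables follow the FSL dialect: ``.bval`` one space-separated row,
``.bvec`` three rows by N columns with zero columns for b=0 volumes.
Echo times travel in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import ImageSeries, PhantomLayout
from .schemes import BValueScheme, EchoScheme, GradientScheme

__all__ = [
    "VOXEL_SIZES_MM",
    "write_nifti",
    "read_nifti",
    "write_bval_bvec",
    "read_bval",
    "read_bvec",
    "write_echo_times",
    "read_echo_times",
    "write_series",
    "read_series",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: Header voxel sizes (mm) per series kind, from the acquisition protocols.
VOXEL_SIZES_MM: dict[str, tuple[float, float, float]] = {
    "ivim": (1.9, 1.9, 4.0),
    "dti": (1.4, 1.4, 4.0),
    "megre": (2.0, 1.6, 4.0),
}


def _affine(voxel_sizes: tuple[float, float, float]) -> np.ndarray:
    return np.diag(list(voxel_sizes) + [1.0])


def write_nifti(
    data: np.ndarray, path: str | Path,
    voxel_sizes: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_sizes))
    nib.save(img, path)
    return path


def read_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_bval_bvec(
    path_stem: str | Path,
    bvals: np.ndarray,
    bvecs: np.ndarray | None = None,
) -> tuple[Path, Path | None]:
    """Write FSL .bval (one row) and optionally .bvec (3 rows x N)."""
    stem = Path(path_stem)
    bval_path = stem.with_suffix(".bval")
    bval_path.write_text(" ".join(f"{v:g}" for v in np.asarray(bvals)) + "\n")
    bvec_path = None
    if bvecs is not None:
        bvecs = np.asarray(bvecs, dtype=float)
        if bvecs.shape[0] != 3:
            raise ValueError(".bvec must be written as 3 rows x N columns")
        bvec_path = stem.with_suffix(".bvec")
        lines = [" ".join(f"{v:.10f}" for v in row) for row in bvecs]
        bvec_path.write_text("\n".join(lines) + "\n")
    return bval_path, bvec_path


def read_bval(path: str | Path) -> np.ndarray:
    return np.asarray(Path(path).read_text().split(), dtype=float)


def read_bvec(path: str | Path, unit_tol: float = 0.01) -> np.ndarray:
    """Read an FSL .bvec table (3 rows x N).

    Nonzero columns off unit norm by at most ``unit_tol`` (1% default)
    are renormalized; larger deviations are rejected.
    """
    rows = [np.asarray(line.split(), dtype=float)
            for line in Path(path).read_text().splitlines() if line.strip()]
    if len(rows) != 3:
        raise ValueError(f"{path}: .bvec must have exactly 3 rows")
    vec = np.stack(rows)
    norms = np.linalg.norm(vec, axis=0)
    nz = norms > 1e-12
    off = np.abs(norms[nz] - 1.0)
    if np.any(off > unit_tol):
        raise ValueError(
            f"{path}: gradient column deviates from unit norm by more than "
            f"{unit_tol:.0%}"
        )
    vec[:, nz] = vec[:, nz] / norms[nz]
    return vec


def write_echo_times(te_ms: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"EchoTimesMs": list(map(float, te_ms))}, indent=1))
    return path


def read_echo_times(path: str | Path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text())["EchoTimesMs"], dtype=float)


def write_series(series: ImageSeries, out_dir: str | Path, stem: str) -> dict:
    """Write one series: 4-D NIfTI plus its scheme sidecars.

    Returns a manifest fragment mapping role -> written file name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vox = VOXEL_SIZES_MM.get(series.kind, (1.0, 1.0, 1.0))
    nii = out_dir / f"{stem}.nii"
    write_nifti(series.data, nii, vox)
    manifest = {"kind": series.kind, "image": nii.name}
    scheme = series.scheme
    if isinstance(scheme, BValueScheme):
        bval, _ = write_bval_bvec(out_dir / stem, scheme.b)
        manifest["bval"] = bval.name
    elif isinstance(scheme, GradientScheme):
        bvals = np.concatenate([[scheme.b_low],
                                np.full(len(scheme) - 1, scheme.b_high)])
        bvecs = np.concatenate(
            [np.zeros((3, 1)), scheme.directions.T], axis=1
        )
        bval, bvec = write_bval_bvec(out_dir / stem, bvals, bvecs)
        manifest["bval"] = bval.name
        manifest["bvec"] = bvec.name
    elif isinstance(scheme, EchoScheme):
        te = write_echo_times(scheme.te_ms, out_dir / f"{stem}_te.json")
        manifest["echo_times"] = te.name
    return manifest


def read_series(
    image_path: str | Path,
    kind: str,
    bval_path: str | Path | None = None,
    bvec_path: str | Path | None = None,
    te_path: str | Path | None = None,
    liver_mask: np.ndarray | None = None,
    vessel_mask: np.ndarray | None = None,
) -> ImageSeries:
    """Load a 4-D series and attach its validated scheme.

    Rejects length mismatches between the 4th dimension and the sidecar,
    naming the offending file.
    """
    data = read_nifti(image_path)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4-D series")
    nvol = data.shape[3]
    if kind == "ivim":
        if bval_path is None:
            raise ValueError("IVIM series needs a .bval sidecar")
        b = read_bval(bval_path)
        if b.size != nvol:
            raise ValueError(
                f"{bval_path}: {b.size} b values for {nvol} volumes"
            )
        scheme: BValueScheme | GradientScheme | EchoScheme = BValueScheme(b)
    elif kind == "dti":
        if bval_path is None or bvec_path is None:
            raise ValueError("DTI series needs .bval and .bvec sidecars")
        b = read_bval(bval_path)
        vec = read_bvec(bvec_path)
        if b.size != nvol or vec.shape[1] != nvol:
            raise ValueError(
                f"{bval_path}/{bvec_path}: sidecar length does not match "
                f"{nvol} volumes"
            )
        weighted = b > 0
        if (~weighted).sum() != 1 or not np.all(b[weighted] == b[weighted][0]):
            raise ValueError(
                f"{bval_path}: expected one b=0 volume plus a single shell"
            )
        scheme = GradientScheme(
            directions=vec[:, weighted].T, b_low=0.0,
            b_high=float(b[weighted][0]),
        )
        order = np.concatenate([np.flatnonzero(~weighted),
                                np.flatnonzero(weighted)])
        data = data[..., order]
    elif kind == "megre":
        if te_path is None:
            raise ValueError("gradient-echo series needs an echo-time sidecar")
        te = read_echo_times(te_path)
        if te.size != nvol:
            raise ValueError(f"{te_path}: {te.size} echoes for {nvol} volumes")
        scheme = EchoScheme(te)
    else:
        raise ValueError(f"unknown series kind {kind!r}")
    shape = data.shape[:3]
    liver = (np.ones(shape, dtype=bool) if liver_mask is None
             else np.asarray(liver_mask, dtype=bool))
    vessel = (np.zeros(shape, dtype=bool) if vessel_mask is None
              else np.asarray(vessel_mask, dtype=bool))
    return ImageSeries(kind, data, scheme, liver, vessel)


def write_cohort_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "group" not in frame.columns:
        raise ValueError(f"{path}: cohort table needs a 'group' column")
    return frame


def write_masks(layout: PhantomLayout, out_dir: str | Path, stem: str = "mask") -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    liver = out_dir / f"{stem}_liver.nii"
    vessel = out_dir / f"{stem}_vessel.nii"
    write_nifti(layout.liver_mask.astype(np.uint8), liver)
    write_nifti(layout.vessel_mask.astype(np.uint8), vessel)
    return {"liver_mask": liver.name, "vessel_mask": vessel.name}
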