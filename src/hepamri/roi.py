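"""Six-ROI sampling protocol on parametric liver maps.

Six circular regions of interest are placed on the three central liver
slices (two per slice), entirely inside the liver, away from vessels, and
pairwise non-overlapping; each disc covers 12 +/- 2 pixels.  The animal-
level value of a parametric map is the mean of the six per-ROI means.
Manual placement by a reader is emulated by constrained seeded random
placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROISpec",
    "ROISet",
    "disc_pixels",
    "place_rois",
    "jitter_rois",
    "extract_roi_means",
    "DEFAULT_RADIUS_PX",
]

#: Disc radius (pixels) whose rasterization covers 13 pixels on a square
#: grid, inside the 12 +/- 2 protocol target.
DEFAULT_RADIUS_PX: float = 2.0

PIXEL_TARGET: tuple[int, int] = (10, 14)  # 12 +/- 2


def disc_pixels(center: tuple[int, int], radius: float) -> np.ndarray:
    """In-plane pixel coordinates with center distance <= radius, (n, 2)."""
    r_int = int(np.floor(radius))
    offs = np.arange(-r_int, r_int + 1)
    dx, dy = np.meshgrid(offs, offs, indexing="ij")
    keep = dx**2 + dy**2 <= radius**2
    return np.stack([center[0] + dx[keep], center[1] + dy[keep]], axis=1)


@dataclass(frozen=True)
class ROISpec:
    """One circular ROI: slice index, in-plane center and radius."""

    slice_index: int
    center: tuple[int, int]
    radius: float = DEFAULT_RADIUS_PX

    @property
    def pixels(self) -> np.ndarray:
        return disc_pixels(self.center, self.radius)

    @property
    def pixel_count(self) -> int:
        return int(self.pixels.shape[0])


@dataclass(frozen=True)
class ROISet:
    """Exactly six ROIs distributed two-per-slice over three slices."""

    rois: tuple[ROISpec, ...]

    def __post_init__(self) -> None:
        if len(self.rois) != 6:
            raise ValueError("an ROI set holds exactly six ROIs")
        slices = sorted({r.slice_index for r in self.rois})
        if len(slices) != 3:
            raise ValueError("ROIs must cover exactly three distinct slices")

    def __iter__(self):
        return iter(self.rois)

    def to_dict(self) -> list[dict]:
        return [
            {
                "slice": int(r.slice_index),
                "center": [int(r.center[0]), int(r.center[1])],
                "radius": float(r.radius),
                "pixels": [[int(a), int(b)] for a, b in r.pixels],
            }
            for r in self.rois
        ]

    @classmethod
    def from_dict(cls, items: list[dict]) -> "ROISet":
        return cls(
            tuple(
                ROISpec(d["slice"], (d["center"][0], d["center"][1]), d["radius"])
                for d in items
            )
        )


def _roi_ok(
    roi: ROISpec,
    liver_mask: np.ndarray,
    vessel_mask: np.ndarray,
    placed: list[ROISpec],
) -> bool:
    px = roi.pixels
    if (px < 0).any() or (px[:, 0] >= liver_mask.shape[0]).any() or (
        px[:, 1] >= liver_mask.shape[1]
    ).any():
        return False
    sl_liver = liver_mask[:, :, roi.slice_index]
    sl_vessel = vessel_mask[:, :, roi.slice_index]
    if not sl_liver[px[:, 0], px[:, 1]].all():
        return False
    if sl_vessel[px[:, 0], px[:, 1]].any():
        return False
    for other in placed:
        if other.slice_index != roi.slice_index:
            continue
        d = np.hypot(
            roi.center[0] - other.center[0], roi.center[1] - other.center[1]
        )
        if d <= roi.radius + other.radius:
            return False
    return True


def central_slices(liver_mask: np.ndarray, n: int = 3) -> list[int]:
    """The n central slices among those where the liver mask is nonempty."""
    occupied = [z for z in range(liver_mask.shape[2]) if liver_mask[:, :, z].any()]
    if len(occupied) < n:
        raise ValueError("liver mask nonempty on fewer than 3 slices")
    mid = len(occupied) // 2
    lo = mid - n // 2
    return occupied[lo : lo + n]


def place_rois(
    liver_mask: np.ndarray,
    vessel_mask: np.ndarray,
    seed: int,
    radius: float = DEFAULT_RADIUS_PX,
    max_tries: int = 2000,
) -> ROISet:
    """Seeded constrained placement of the six-ROI protocol.

    Deterministic for a fixed seed.  Raises if the constraints cannot be
    satisfied within the retry budget.
    """
    rng = np.random.default_rng(seed)
    slices = central_slices(liver_mask)
    placed: list[ROISpec] = []
    for z in slices:
        cand = np.argwhere(liver_mask[:, :, z] & ~vessel_mask[:, :, z])
        got = 0
        for _ in range(max_tries):
            c = cand[rng.integers(len(cand))]
            roi = ROISpec(z, (int(c[0]), int(c[1])), radius)
            if _roi_ok(roi, liver_mask, vessel_mask, placed):
                placed.append(roi)
                got += 1
                if got == 2:
                    break
        if got < 2:
            raise RuntimeError(
                f"could not place 2 ROIs on slice {z} within {max_tries} tries"
            )
    return ROISet(tuple(placed))


def jitter_rois(
    rois: ROISet,
    liver_mask: np.ndarray,
    vessel_mask: np.ndarray,
    jitter_px: float,
    seed: int,
    max_tries: int = 200,
) -> ROISet:
    """Displace each ROI center by at most jitter_px, keeping it valid.

    Used to emulate a second reader.  jitter_px = 0 returns an identical
    set.  Raises if no valid displaced position exists for some ROI.
    """
    if jitter_px < 0:
        raise ValueError("jitter_px must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[ROISpec] = []
    for roi in rois:
        if jitter_px == 0:
            out.append(roi)
            continue
        ok = False
        for _ in range(max_tries):
            d = rng.integers(-int(jitter_px), int(jitter_px) + 1, size=2)
            if np.hypot(*d) > jitter_px:
                continue
            moved = ROISpec(
                roi.slice_index,
                (roi.center[0] + int(d[0]), roi.center[1] + int(d[1])),
                roi.radius,
            )
            # second reader's ROIs need not avoid each other's copies,
            # but must stay in liver and out of vessels
            if _roi_ok(moved, liver_mask, vessel_mask, []):
                out.append(moved)
                ok = True
                break
        if not ok:
            raise RuntimeError("jitter pushed an ROI out of the liver mask")
    return ROISet(tuple(out))


def extract_roi_means(
    param_map: np.ndarray, rois: ROISet
) -> tuple[float, list[float]]:
    """Animal-level value: mean over the six per-ROI means.

    Invalid (NaN) voxels are excluded within each ROI; an ROI with no
    valid voxel is dropped (the animal value then averages the rest) and
    an all-invalid set raises.
    """
    per_roi: list[float] = []
    for roi in rois:
        px = roi.pixels
        vals = param_map[px[:, 0], px[:, 1], roi.slice_index]
        vals = vals[np.isfinite(vals)]
        per_roi.append(float(vals.mean()) if vals.size else np.nan)
    finite = [v for v in per_roi if np.isfinite(v)]
    if not finite:
        raise ValueError("all ROIs contain only invalid voxels")
    return float(np.mean(finite)), per_roi
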