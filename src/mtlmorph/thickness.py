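"""Landmark-based local thickness of binary gray-matter segmentations.

Thickness at an anatomical landmark (the "dot") is defined as the diameter of
the sphere that (i) overlaps the dot, (ii) is fully contained in the
foreground of the segmentation, and (iii) has the maximum possible radius.
Two landmark locations are placed per subregion along the anterior-posterior
axis and their diameters averaged into a single per-subregion thickness.

The sphere search is discrete: candidate centers are foreground voxel
centers, each carrying radius ``d - h/2`` where ``d`` is the Euclidean
distance (in mm, honoring anisotropic spacing) from the center to the nearest
background voxel center (positions outside the grid count as background) and
``h`` is the smallest axis spacing.  The half-voxel margin guarantees that
every voxel center inside the closed ball is foreground, and makes the
measurement exact for axis-aligned slabs with an odd number of foreground
planes.  The discretization error is bounded by one voxel.

An inadmissible landmark (no containing sphere reaches the dot) yields an
*invalid* fit rather than an exception, so cohort-level pipelines degrade to
missing values the way damaged-tissue locations do in practice.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

#: The seven medial temporal lobe subregions measured, in report order:
#: entorhinal cortex, Brodmann areas 35/36 (perirhinal cortex),
#: parahippocampal cortex, subiculum, CA1, and the stratum radiatum
#: lacunosum moleculare ("dark band") of the cornu ammonis.
SUBREGIONS: tuple[str, ...] = ("ERC", "BA35", "BA36", "PHC", "SUB", "CA1", "SRLM")

#: Default search neighborhood around the dot, matching the ~5-10 mm
#: gray-matter patch segmented around each landmark.
DEFAULT_SEARCH_RADIUS_MM: float = 10.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class BinaryMask:
    """A 3D binary segmentation on a regular grid.

    Parameters
    ----------
    values
        3D array; nonzero voxels are foreground.
    spacing
        Voxel spacing in mm per axis, strictly positive.
    origin
        Physical mm coordinate of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got {arr.ndim}D")
        object.__setattr__(self, "values", arr.astype(bool, copy=False))
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(not math.isfinite(s) or s <= 0 for s in sp):
            raise ValueError(f"spacing must be three finite positive values, got {self.spacing}")
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Physical mm coordinates of voxel centers, shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def contains_point(self, point: Sequence[float]) -> bool:
        """Whether a physical point lies inside the grid's voxel volume."""
        p = np.asarray(point, dtype=float)
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.spacing)
        hi = lo + np.asarray(self.shape) * np.asarray(self.spacing)
        return bool(np.all(p >= lo) and np.all(p <= hi))


@dataclasses.dataclass(frozen=True)
class Landmark:
    """An anatomical measurement location: a subregion label, a location
    index along the anterior-posterior axis (1 = anterior, 2 = posterior)
    and a physical mm coordinate."""

    subregion: str
    location_index: int
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.subregion not in SUBREGIONS:
            raise ValueError(f"unknown subregion {self.subregion!r}; expected one of {SUBREGIONS}")
        if self.location_index not in (1, 2):
            raise ValueError(f"location_index must be 1 or 2, got {self.location_index}")
        object.__setattr__(self, "position", tuple(float(x) for x in self.position))


@dataclasses.dataclass(frozen=True)
class SphereFit:
    """Result of the maximal-sphere search at one landmark."""

    center: tuple[float, float, float] | None
    radius: float
    valid: bool

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius if self.valid else math.nan

    @staticmethod
    def invalid() -> "SphereFit":
        return SphereFit(center=None, radius=math.nan, valid=False)


@dataclasses.dataclass(frozen=True)
class SubregionThickness:
    """Per-subregion thickness: one diameter per measurable location and
    their arithmetic mean.  ``mean_mm`` is NaN when no location produced a
    valid fit."""

    subregion: str
    location_diameters: dict[int, float]  # location_index -> diameter mm (NaN if invalid)
    mean_mm: float
    n_locations_used: int


# ---------------------------------------------------------------------------
# Distance transform
# ---------------------------------------------------------------------------


def distance_to_background(mask: BinaryMask) -> np.ndarray:
    """Euclidean distance (mm) from each foreground voxel center to the
    nearest background voxel center.

    Positions outside the grid are background by convention, so a foreground
    voxel on the grid boundary is one spacing away from background.
    Background voxels carry 0.
    """
    if not mask.values.any():
        raise ValueError("mask has no foreground voxels")
    # One layer of zero padding realizes the out-of-grid-is-background
    # convention exactly: the nearest exterior voxel center always lies in
    # the first exterior shell.
    padded = np.pad(mask.values, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded, sampling=mask.spacing)
    return dist[1:-1, 1:-1, 1:-1]


# ---------------------------------------------------------------------------
# Maximal-sphere fit
# ---------------------------------------------------------------------------


def fit_max_sphere(
    mask: BinaryMask,
    dot: Landmark | Sequence[float],
    search_radius_mm: float | None = DEFAULT_SEARCH_RADIUS_MM,
) -> SphereFit:
    """Fit the maximum-radius sphere that overlaps the dot and is fully
    contained in the foreground.

    Candidate centers are foreground voxel centers (optionally within
    ``search_radius_mm`` of the dot).  A candidate with center ``c`` carries
    radius ``r(c) = d(c) - h/2`` (``d`` the distance-to-background map, ``h``
    the smallest axis spacing) and is admissible when ``|c - dot| <= r(c)``,
    i.e. the dot lies in the closed ball.  The fit maximizes ``r`` over
    admissible candidates; ties are broken by distance to the dot, then by
    lexicographic voxel index.  Returns an invalid fit (not an exception)
    when no candidate is admissible.
    """
    position = dot.position if isinstance(dot, Landmark) else tuple(float(x) for x in dot)
    if not mask.values.any():
        raise ValueError("mask has no foreground voxels")
    if not mask.contains_point(position):
        raise ValueError(f"dot {position} lies outside the grid's physical bounds")

    dist = distance_to_background(mask)
    h = min(mask.spacing)
    fg_idx = np.argwhere(mask.values)
    centers = mask.voxel_centers(fg_idx)
    radii = dist[tuple(fg_idx.T)] - 0.5 * h
    d_dot = np.linalg.norm(centers - np.asarray(position), axis=1)

    keep = np.ones(len(fg_idx), dtype=bool)
    if search_radius_mm is not None:
        keep &= d_dot <= search_radius_mm
    # Half-voxel slack absorbs float round-off at exact-tangency boundaries.
    keep &= d_dot <= radii + 1e-9
    if not keep.any():
        return SphereFit.invalid()

    fg_idx, centers, radii, d_dot = fg_idx[keep], centers[keep], radii[keep], d_dot[keep]
    flat = np.ravel_multi_index(tuple(fg_idx.T), mask.shape)
    order = np.lexsort((flat, d_dot, -radii))  # last key is primary
    best = order[0]
    return SphereFit(center=tuple(centers[best]), radius=float(radii[best]), valid=True)


def measure_subregion(
    mask: BinaryMask,
    landmarks: Sequence[Landmark],
    search_radius_mm: float | None = DEFAULT_SEARCH_RADIUS_MM,
) -> SubregionThickness:
    """Measure one subregion from its 1-2 landmark locations.

    Invalid fits count as missing; the subregion mean is the arithmetic mean
    over the locations that produced a valid fit.
    """
    if len(landmarks) == 0:
        raise ValueError("at least one landmark is required")
    labels = {lm.subregion for lm in landmarks}
    if len(labels) != 1:
        raise ValueError(f"landmarks span multiple subregions: {sorted(labels)}")
    if len(landmarks) > 2:
        raise ValueError("a subregion has at most two landmark locations")

    diameters: dict[int, float] = {}
    for lm in landmarks:
        fit = fit_max_sphere(mask, lm, search_radius_mm)
        diameters[lm.location_index] = fit.diameter
    present = [d for d in diameters.values() if not math.isnan(d)]
    mean = float(np.mean(present)) if present else math.nan
    return SubregionThickness(
        subregion=landmarks[0].subregion,
        location_diameters=diameters,
        mean_mm=mean,
        n_locations_used=len(present),
    )


def measure_specimen(
    mask: BinaryMask,
    landmarks: Sequence[Landmark],
    search_radius_mm: float | None = DEFAULT_SEARCH_RADIUS_MM,
) -> pd.DataFrame:
    """Measure every subregion present among ``landmarks``.

    Returns one row per subregion in canonical order with the per-location
    diameters retained (columns ``loc1_mm``, ``loc2_mm``) alongside the
    subregion mean, supporting separate anterior/posterior analyses.
    """
    seen: set[tuple[str, int]] = set()
    for lm in landmarks:
        key = (lm.subregion, lm.location_index)
        if key in seen:
            raise ValueError(f"duplicate landmark for {key}")
        seen.add(key)

    rows = []
    by_region: dict[str, list[Landmark]] = {}
    for lm in landmarks:
        by_region.setdefault(lm.subregion, []).append(lm)
    for sub in SUBREGIONS:
        if sub not in by_region:
            continue
        st = measure_subregion(mask, by_region[sub], search_radius_mm)
        rows.append(
            {
                "subregion": sub,
                "loc1_mm": st.location_diameters.get(1, math.nan),
                "loc2_mm": st.location_diameters.get(2, math.nan),
                "thickness_mm": st.mean_mm,
                "n_locations": st.n_locations_used,
            }
        )
    return pd.DataFrame(rows, columns=["subregion", "loc1_mm", "loc2_mm", "thickness_mm", "n_locations"])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_mask(path) -> BinaryMask:
    """Load a NIfTI-1 segmentation: any nonzero voxel is foreground, spacing
    comes from the header zooms and the origin from the affine translation.
    The affine is assumed axis-aligned (no rotation)."""
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj) != 0
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return BinaryMask(values=values, spacing=spacing, origin=origin)


def write_mask(mask: BinaryMask, path) -> None:
    """Write a mask as NIfTI-1 with spacing on the affine diagonal."""
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_landmarks(path) -> dict[str, list[Landmark]]:
    """Read a landmark table (columns: specimen_id, subregion,
    location_index, x_mm, y_mm, z_mm) into per-specimen landmark lists."""
    df = pd.read_csv(path)
    required = {"specimen_id", "subregion", "location_index", "x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV is missing columns: {sorted(missing)}")
    out: dict[str, list[Landmark]] = {}
    for _, row in df.iterrows():
        lm = Landmark(
            subregion=str(row["subregion"]),
            location_index=int(row["location_index"]),
            position=(row["x_mm"], row["y_mm"], row["z_mm"]),
        )
        out.setdefault(str(row["specimen_id"]), []).append(lm)
    return out


def write_landmarks(landmarks: dict[str, Iterable[Landmark]], path) -> None:
    rows = [
        {
            "specimen_id": sid,
            "subregion": lm.subregion,
            "location_index": lm.location_index,
            "x_mm": lm.position[0],
            "y_mm": lm.position[1],
            "z_mm": lm.position[2],
        }
        for sid, lms in landmarks.items()
        for lm in lms
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
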