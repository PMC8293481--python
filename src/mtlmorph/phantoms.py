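"""Synthetic inputs with known ground truth.

Two generators make the whole pipeline testable without any specimen data:

* :func:`make_phantom` voxelizes simple analytic geometries (axis-aligned
  slab, tilted slab, spherical shell) whose local thickness is known in
  closed form, places landmark dots strictly inside the foreground, and can
  carve axis-aligned box "tears" emulating tissue damage.
* :func:`simulate_cohort` draws donor cohorts with a known statistical
  structure: latent per-lesion severities from a multivariate normal with a
  configurable comorbidity correlation, ordinal regional scores by
  thresholding the latents onto the five-point scale, and subregional
  thickness as a linear function of composite scores, age and sex plus
  Gaussian noise, with independent per-location missingness.

All randomness flows from a single integer seed through one
:class:`numpy.random.Generator` stream.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import COMPOSITE_REGIONS, LESIONS, SCORE_VALUES, composite_column, score_column
from .thickness import SUBREGIONS, BinaryMask, Landmark

GEOMETRIES: tuple[str, ...] = ("slab", "tilted_slab", "spherical_shell")

#: Cut points on the latent (standard-normal-ish) scale mapping a latent
#: severity onto the ordinal scale {0, 0.5, 1, 2, 3}; chosen to produce a
#: right-skewed score distribution typical of semi-quantitative ratings.
DEFAULT_CUTPOINTS: tuple[float, ...] = (0.2, 0.8, 1.5, 2.3)

#: Latent mean severity per lesion; orders the lesions by prevalence
#: (tau nearly ubiquitous, alpha-synuclein rare).
DEFAULT_LATENT_MEANS: dict[str, float] = {
    "tau": 1.4,
    "amyloid_beta": 0.5,
    "TDP43": -0.6,
    "alpha_synuclein": -1.2,
}

#: Baseline (pathology-free) thickness per subregion, mm.  SRLM is the thin
#: hypointense "dark band"; the cortical subregions sit near 2.3-2.9 mm.
DEFAULT_BASELINES: dict[str, float] = {
    "ERC": 2.6,
    "BA35": 2.8,
    "BA36": 2.9,
    "PHC": 2.4,
    "SUB": 2.2,
    "CA1": 1.5,
    "SRLM": 0.5,
}

#: Default thickness slopes (mm per unit composite score; negative =
#: thinning).  Tau thins the early Braak-stage regions; TDP-43 thins the
#: MTL diffusely; amyloid-beta and alpha-synuclein have no direct effect.
DEFAULT_EFFECT_SIZES: dict[str, dict[str, float]] = {
    "tau": {"ERC": -0.25, "BA35": -0.30, "CA1": -0.20, "SRLM": -0.10},
    "TDP43": {s: -0.30 for s in SUBREGIONS},
    "amyloid_beta": {},
    "alpha_synuclein": {},
}


def default_comorbidity_corr() -> np.ndarray:
    """Modest positive comorbidity among the four lesions (tau-amyloid
    strongest), ordered as :data:`mtlmorph.cohort.LESIONS`."""
    c = np.full((4, 4), 0.2)
    np.fill_diagonal(c, 1.0)
    i = {l: k for k, l in enumerate(LESIONS)}
    c[i["tau"], i["amyloid_beta"]] = c[i["amyloid_beta"], i["tau"]] = 0.4
    c[i["tau"], i["TDP43"]] = c[i["TDP43"], i["tau"]] = 0.3
    return c


# ---------------------------------------------------------------------------
# Phantom masks
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Tear:
    """Axis-aligned box of background carved from the foreground, emulating
    a tissue tear: physical center (mm) and edge lengths (mm)."""

    center: tuple[float, float, float]
    size: tuple[float, float, float]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Specification of a synthetic specimen mask.

    geometry_params by geometry:

    * ``slab`` / ``tilted_slab``: ``thickness_mm`` and optional ``normal``
      (default +z for ``slab``, an oblique direction for ``tilted_slab``).
    * ``spherical_shell``: ``inner_radius_mm``, ``outer_radius_mm``.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2)
    geometry: str = "slab"
    geometry_params: dict = dataclasses.field(default_factory=lambda: {"thickness_mm": 2.2})
    defects: tuple[Tear, ...] = ()
    subregions: tuple[str, ...] = SUBREGIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}; expected one of {GEOMETRIES}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        extent = min(n * s for n, s in zip(self.shape, self.spacing))
        if self.geometry in ("slab", "tilted_slab"):
            t = self.geometry_params.get("thickness_mm")
            if t is None or t <= 0:
                raise ValueError("slab thickness_mm must be > 0")
            if t >= extent:
                raise ValueError(
                    f"slab thickness {t} mm exceeds the grid physical extent {extent} mm"
                )
        else:
            a = self.geometry_params.get("inner_radius_mm")
            b = self.geometry_params.get("outer_radius_mm")
            if a is None or b is None or not (b > a >= 0):
                raise ValueError("shell requires outer_radius_mm > inner_radius_mm >= 0")
        unknown = set(self.subregions) - set(SUBREGIONS)
        if unknown:
            raise ValueError(f"unknown subregions {sorted(unknown)}")
        object.__setattr__(self, "defects", tuple(self.defects))
        object.__setattr__(self, "subregions", tuple(self.subregions))


def _grid_center(shape, spacing) -> np.ndarray:
    # Center voxel's center: a true voxel center when the shape is odd.
    return np.array([(n - 1) // 2 for n in shape], dtype=float) * np.asarray(spacing)


def _slab_frame(geometry: str, params: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if "normal" in params:
        n = np.asarray(params["normal"], dtype=float)
    elif geometry == "slab":
        n = np.array([0.0, 0.0, 1.0])
    else:
        n = np.array([1.0, 1.0, 2.0])
    n = n / np.linalg.norm(n)
    # Two tangent vectors completing an orthonormal frame.
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return n, e1, e2


def _point_to_box_distance(point: np.ndarray, tear: Tear) -> float:
    lo = np.asarray(tear.center) - 0.5 * np.asarray(tear.size)
    hi = np.asarray(tear.center) + 0.5 * np.asarray(tear.size)
    d = np.maximum(np.maximum(lo - point, point - hi), 0.0)
    return float(np.linalg.norm(d))


def make_phantom(
    spec: PhantomSpec,
) -> tuple[BinaryMask, list[Landmark], dict[tuple[str, int], float]]:
    """Voxelize a phantom, place two landmarks per requested subregion and
    return the analytic local thickness at each landmark.

    A voxel is foreground exactly when its center lies inside the analytic
    geometry (and outside every tear box).  Landmarks sit on the medial
    surface of the geometry (slab center plane, shell mid-radius), strictly
    inside the foreground and away from tears and the grid boundary, so the
    analytic thickness (slab plate thickness, shell width) holds at each dot.
    """
    spacing = np.asarray(spec.spacing, dtype=float)
    shape = tuple(int(n) for n in spec.shape)
    idx = np.indices(shape, dtype=float)
    coords = np.stack([idx[a] * spacing[a] for a in range(3)], axis=-1)
    center = _grid_center(shape, spacing)

    if spec.geometry in ("slab", "tilted_slab"):
        thickness = float(spec.geometry_params["thickness_mm"])
        normal, e1, e2 = _slab_frame(spec.geometry, spec.geometry_params)
        signed = (coords - center) @ normal
        fg = np.abs(signed) <= thickness / 2.0
    else:
        a = float(spec.geometry_params["inner_radius_mm"])
        b = float(spec.geometry_params["outer_radius_mm"])
        thickness = b - a
        r = np.linalg.norm(coords - center, axis=-1)
        fg = (r >= a) & (r <= b)

    if not fg.any():
        raise ValueError(
            f"{spec.geometry} with params {spec.geometry_params} is too thin to "
            f"contain any voxel center at spacing {spec.spacing}"
        )

    for tear in spec.defects:
        lo = np.asarray(tear.center) - 0.5 * np.asarray(tear.size)
        hi = np.asarray(tear.center) + 0.5 * np.asarray(tear.size)
        inside = np.all((coords >= lo) & (coords <= hi), axis=-1)
        fg = fg & ~inside

    mask = BinaryMask(values=fg, spacing=tuple(spacing), origin=(0.0, 0.0, 0.0))
    rng = np.random.default_rng(spec.seed)

    # Keep dots far enough from tears and the grid edge that the maximal
    # ball containing the dot cannot touch either.
    safety = max(thickness, float(spacing.max()))
    landmarks: list[Landmark] = []
    truth: dict[tuple[str, int], float] = {}
    half_extent = 0.5 * (np.asarray(shape) - 1) * spacing

    def _candidate_point() -> np.ndarray:
        if spec.geometry in ("slab", "tilted_slab"):
            lim = float(min(half_extent)) - (thickness / 2.0 + 2.0 * float(spacing.max()))
            lim = max(lim, 0.0) / math.sqrt(2.0)
            u, v = rng.uniform(-lim, lim, size=2)
            return center + u * e1 + v * e2
        w = rng.normal(size=3)
        w /= np.linalg.norm(w)
        r_mid = float(spec.geometry_params.get("landmark_radius_mm", (a + b) / 2.0))
        return center + r_mid * w

    def _acceptable(p: np.ndarray) -> bool:
        vox = np.round((p - np.asarray(mask.origin)) / spacing).astype(int)
        if np.any(vox < 0) or np.any(vox >= np.asarray(shape)):
            return False
        if not mask.values[tuple(vox)]:
            return False
        if any(_point_to_box_distance(p, t) < safety for t in spec.defects):
            return False
        border = vox * spacing
        far_side = (np.asarray(shape) - 1 - vox) * spacing
        return bool(np.all(border >= safety) and np.all(far_side >= safety))

    for sub in spec.subregions:
        for loc in (1, 2):
            point = None
            for _ in range(1000):
                cand = _candidate_point()
                if _acceptable(cand):
                    point = cand
                    break
            if point is None:
                raise ValueError(
                    f"could not place a landmark for {sub} location {loc}: geometry "
                    "leaves no admissible interior point away from tears and edges"
                )
            landmarks.append(Landmark(subregion=sub, location_index=loc, position=tuple(point)))
            truth[(sub, loc)] = thickness

    return mask, landmarks, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CohortSimSpec:
    """Specification of a simulated donor cohort.

    ``effect_sizes`` maps lesion -> subregion -> slope in mm thickness
    change per unit composite score (negative values thin the region).
    ``comorbidity_corr`` is the 4x4 correlation among the latent lesion
    severities in :data:`mtlmorph.cohort.LESIONS` order.  ``noise_sd`` is
    donor-level measurement noise (mm); each of the two per-subregion
    locations additionally jitters by ``location_jitter_sd`` and goes
    missing independently with probability ``missing_rate``.
    """

    n_donors: int = 58
    effect_sizes: dict = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_EFFECT_SIZES.items()}
    )
    comorbidity_corr: np.ndarray = dataclasses.field(default_factory=default_comorbidity_corr)
    age_effect: float = -0.01
    sex_effect: float = 0.05
    noise_sd: float = 0.4
    missing_rate: float = 0.05
    seed: int = 0
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    latent_means: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_LATENT_MEANS))
    baselines: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_BASELINES))
    region_jitter_sd: float = 0.25
    location_jitter_sd: float = 0.1
    age_mean: float = 75.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (44.0, 97.0)
    pct_male: float = 0.603

    def __post_init__(self) -> None:
        if self.n_donors < 4:
            raise ValueError("n_donors must be >= 4 (partial correlation undefined below)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        corr = np.asarray(self.comorbidity_corr, dtype=float)
        if corr.shape != (len(LESIONS), len(LESIONS)):
            raise ValueError(f"comorbidity_corr must be {len(LESIONS)}x{len(LESIONS)}")
        if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
            raise ValueError("comorbidity_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError("comorbidity_corr is not positive semi-definite")
        object.__setattr__(self, "comorbidity_corr", corr)
        if len(self.cutpoints) != 4 or list(self.cutpoints) != sorted(self.cutpoints):
            raise ValueError("cutpoints must be four increasing values")


def _threshold_scores(latent: np.ndarray, cutpoints: Sequence[float]) -> np.ndarray:
    """Map latent severities onto the ordinal scale {0, 0.5, 1, 2, 3}."""
    levels = np.searchsorted(np.asarray(cutpoints), latent, side="right")
    return np.asarray(SCORE_VALUES)[levels]


def _mvn_factor(corr: np.ndarray) -> np.ndarray:
    # eigh-based factor tolerates exactly-semi-definite matrices.
    w, v = np.linalg.eigh(corr)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw a cohort of ``spec.n_donors`` donors.

    Per donor: latent lesion severities ~ MVN(latent_means,
    comorbidity_corr); each composite region's ordinal score thresholds the
    lesion latent plus an independent regional jitter; thickness per
    subregion is baseline + sum(slope x composite) + age_effect x (age -
    age_mean) + sex_effect x male + N(0, noise_sd), realized at two
    locations that each jitter slightly and go missing independently.
    A/B/C staging scores threshold the amyloid (A, C) and tau (B) latents.
    Byte-identical output for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_donors
    factor = _mvn_factor(spec.comorbidity_corr)
    mu = np.array([spec.latent_means[l] for l in LESIONS])
    latents = mu + rng.standard_normal((n, len(LESIONS))) @ factor.T

    df = pd.DataFrame({"donor_id": [f"D{i + 1:03d}" for i in range(n)]})
    df["age"] = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), *spec.age_range).round(1)
    df["sex"] = np.where(rng.random(n) < spec.pct_male, "male", "female")
    df["hemisphere"] = np.where(rng.random(n) < 0.5, "left", "right")

    for j, lesion in enumerate(LESIONS):
        for region in COMPOSITE_REGIONS:
            z = latents[:, j] + rng.normal(0.0, spec.region_jitter_sd, size=n)
            df[score_column(lesion, region)] = _threshold_scores(z, spec.cutpoints)
        df[composite_column(lesion)] = df[
            [score_column(lesion, r) for r in COMPOSITE_REGIONS]
        ].mean(axis=1)

    i = {l: k for k, l in enumerate(LESIONS)}
    stage = lambda z, cuts: np.searchsorted(np.asarray(cuts), z, side="right").astype(float)
    df["A_score"] = stage(latents[:, i["amyloid_beta"]], (-0.65, 0.26, 0.50))
    b = stage(latents[:, i["tau"]] + rng.normal(0.0, 0.3, size=n), (-0.72, 0.16, 0.72))
    b[rng.random(n) < 0.05] = np.nan  # Braak stage occasionally unassessable
    df["B_score"] = b
    df["C_score"] = stage(
        latents[:, i["amyloid_beta"]] + rng.normal(0.0, 0.3, size=n), (0.13, 0.59, 0.70)
    )

    male = (df["sex"] == "male").to_numpy(dtype=float)
    age_centered = df["age"].to_numpy(dtype=float) - spec.age_mean
    for sub in SUBREGIONS:
        mean = np.full(n, spec.baselines[sub])
        for lesion in LESIONS:
            slope = spec.effect_sizes.get(lesion, {}).get(sub, 0.0)
            mean = mean + slope * df[composite_column(lesion)].to_numpy()
        mean = mean + spec.age_effect * age_centered + spec.sex_effect * male
        value = mean + rng.normal(0.0, spec.noise_sd, size=n)
        locs = {}
        for loc in (1, 2):
            v = value + rng.normal(0.0, spec.location_jitter_sd, size=n)
            v[rng.random(n) < spec.missing_rate] = np.nan
            locs[loc] = np.clip(v, 0.05, None)
        df[f"thickness_{sub}_loc1"] = locs[1]
        df[f"thickness_{sub}_loc2"] = locs[2]
        stacked = np.column_stack([locs[1], locs[2]])
        n_present = (~np.isnan(stacked)).sum(axis=1)
        df[f"thickness_{sub}"] = np.where(
            n_present > 0, np.nansum(stacked, axis=1) / np.maximum(n_present, 1), np.nan
        )

    df.attrs["provenance"] = {"source": "simulated", "seed": spec.seed}
    return df


# ---------------------------------------------------------------------------
# Spec (de)serialization
# ---------------------------------------------------------------------------


def spec_to_json(spec: PhantomSpec | CohortSimSpec) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return {"__type__": type(o).__name__, **dataclasses.asdict(o)}
        raise TypeError(f"cannot serialize {type(o)}")

    return json.dumps({"__type__": type(spec).__name__, **dataclasses.asdict(spec)}, default=default, indent=2)


def spec_from_json(text: str) -> PhantomSpec | CohortSimSpec:
    raw = json.loads(text)
    kind = raw.pop("__type__", None)
    if kind == "PhantomSpec":
        raw["defects"] = tuple(
            Tear(center=tuple(d["center"]), size=tuple(d["size"])) for d in raw.get("defects", ())
        )
        for key in ("shape", "spacing", "subregions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return PhantomSpec(**raw)
    if kind == "CohortSimSpec":
        for key in ("cutpoints", "age_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "comorbidity_corr" in raw:
            raw["comorbidity_corr"] = np.asarray(raw["comorbidity_corr"], dtype=float)
        return CohortSimSpec(**raw)
    raise ValueError(f"unknown spec type {kind!r}")
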