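"""Donor-level pathology data: ordinal scores, composite MTL scores and
subset definitions.

Each sampled region carries a semi-quantitative burden rating per lesion on
the five-point ordinal scale none/rare/mild/moderate/severe = 0/0.5/1/2/3.
The composite MTL score for a lesion is the mean of the CA1/SUB, ERC and
dentate-gyrus regional ratings, so composites live on thirds of the scale
(e.g. ratings 2, 3, 2 give 2.33).  Donors also carry A/B/C neuropathologic
staging scores (amyloid, tau/Braak, neuritic plaque; each 0-3), age, sex and
the hemisphere that was imaged.

A cohort is a tidy :class:`pandas.DataFrame`, one row per donor, with score
columns named ``{lesion}_{region}``, composite columns ``mtl_{lesion}`` and
thickness columns ``thickness_{subregion}`` (see :data:`SCORE_VALUES`,
:data:`LESIONS`, :data:`COMPOSITE_REGIONS`).  Simulation provenance travels
in ``DataFrame.attrs['provenance']``.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .thickness import SUBREGIONS

#: The four lesions scored per region.
LESIONS: tuple[str, ...] = ("tau", "amyloid_beta", "TDP43", "alpha_synuclein")

#: Regions entering the composite MTL score (CA1/subiculum, entorhinal
#: cortex, dentate gyrus), as column-name-safe labels.
COMPOSITE_REGIONS: tuple[str, ...] = ("CA1_SUB", "ERC", "DG")

#: The five-point semi-quantitative scale.
SCORE_VALUES: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0)

#: Canonical cohort subsets.
SUBSETS: tuple[str, ...] = ("full", "A_negative", "A_negative_and_TDP_low")

#: Composite TDP-43 threshold below which a donor counts as TDP-low; chosen
#: at the natural gap between composite scores of 0-0.17 and >= 0.67.
TDP_LOW_CUTOFF: float = 0.5


def score_column(lesion: str, region: str) -> str:
    return f"{lesion}_{region}"


def composite_column(lesion: str) -> str:
    return f"mtl_{lesion}"


def thickness_column(subregion: str) -> str:
    return f"thickness_{subregion}"


def _get(record: Mapping, key: str):
    try:
        return record[key]
    except KeyError:
        return math.nan


def composite_mtl_score(record: Mapping, lesion: str, strict: bool = False) -> float:
    """Composite MTL score for one lesion: the mean of the CA1/SUB, ERC and
    dentate-gyrus regional ratings.

    Missing regional ratings are skipped and the mean taken over the present
    ones (``strict=True`` instead returns NaN when any region is missing).
    NaN when no region is available.
    """
    if lesion not in LESIONS:
        raise ValueError(f"unknown lesion {lesion!r}; expected one of {LESIONS}")
    vals = [float(_get(record, score_column(lesion, r))) for r in COMPOSITE_REGIONS]
    present = [v for v in vals if not math.isnan(v)]
    if not present or (strict and len(present) < len(vals)):
        return math.nan
    return float(np.mean(present))


def add_composite_scores(table: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Return a copy of the cohort with one ``mtl_{lesion}`` column per lesion."""
    out = table.copy()
    for lesion in LESIONS:
        out[composite_column(lesion)] = [
            composite_mtl_score(row, lesion, strict=strict) for _, row in table.iterrows()
        ]
    out.attrs = dict(table.attrs)
    return out


def is_amyloid_negative(record: Mapping) -> bool:
    """Amyloid-beta negative (A-): staging A-score of 0 or 1."""
    a = _get(record, "A_score")
    if a is None or (isinstance(a, float) and math.isnan(a)):
        raise ValueError("A_score is missing; amyloid-negative status undefined")
    return float(a) in (0.0, 1.0)


def is_tdp_low(record: Mapping) -> bool:
    """Low/absent TDP-43: composite MTL TDP-43 score strictly below 0.5."""
    score = record.get(composite_column("TDP43")) if hasattr(record, "get") else None
    if score is None or (isinstance(score, float) and math.isnan(score)):
        score = composite_mtl_score(record, "TDP43")
    if math.isnan(score):
        raise ValueError("composite TDP-43 score is missing; TDP-low status undefined")
    return float(score) < TDP_LOW_CUTOFF


def apply_subset(table: pd.DataFrame, subset: str) -> pd.DataFrame:
    """Filter a cohort to one of the canonical subsets."""
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; expected one of {SUBSETS}")
    if subset == "full":
        return table
    keep = table.apply(is_amyloid_negative, axis=1)
    if subset == "A_negative_and_TDP_low":
        keep &= table.apply(is_tdp_low, axis=1)
    out = table[keep]
    out.attrs = dict(table.attrs)
    return out


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------


def _pct(count: int, n: int) -> float:
    return round(100.0 * count / n, 1)


def summarize_cohort(table: pd.DataFrame, subset: str = "full") -> dict:
    """Demographic and pathology summary of a cohort subset.

    Percentages are computed on non-missing values and rounded to one
    decimal; score means/SDs to two decimals.  The per-lesion block reports
    the composite mean +/- SD, its observed range, and the percentage (and
    count) of donors with a composite score above zero.
    """
    sub = apply_subset(table, subset)
    if len(sub) == 0:
        raise ValueError(f"cohort subset {subset!r} is empty")
    sub = add_composite_scores(sub) if composite_column("tau") not in sub.columns else sub
    n = len(sub)

    age = sub["age"].astype(float)
    male = (sub["sex"] == "male").sum()
    summary: dict = {
        "subset": subset,
        "n": int(n),
        "n_male": int(male),
        "pct_male": _pct(int(male), n),
        "age": {
            "median": float(age.median()),
            "min": float(age.min()),
            "max": float(age.max()),
            "mean": round(float(age.mean()), 1),
            "sd": round(float(age.std(ddof=1)), 1),
        },
        "lesions": {},
        "stages": {},
    }
    for lesion in LESIONS:
        scores = sub[composite_column(lesion)].astype(float)
        nonmiss = scores.dropna()
        positive = int((nonmiss > 0).sum())
        summary["lesions"][lesion] = {
            "mean": round(float(nonmiss.mean()), 2),
            "sd": round(float(nonmiss.std(ddof=1)), 2),
            "min": round(float(nonmiss.min()), 2),
            "max": round(float(nonmiss.max()), 2),
            "n_nonmissing": int(len(nonmiss)),
            "n_positive": positive,
            "pct_positive": _pct(positive, len(nonmiss)),
        }
    for stage in ("A_score", "B_score", "C_score"):
        if stage not in sub.columns:
            continue
        vals = sub[stage].astype(float)
        nonmiss = vals.dropna()
        dist = {}
        for level in (0, 1, 2, 3):
            count = int((nonmiss == level).sum())
            dist[str(level)] = {"n": count, "pct": _pct(count, len(nonmiss)) if len(nonmiss) else 0.0}
        dist["missing"] = int(vals.isna().sum())
        summary["stages"][stage] = dist
    return summary


def format_summary(summary: dict) -> str:
    """Render a summary dict as a plain-text demographics table."""
    lines = [
        f"Cohort summary ({summary['subset']})",
        f"  Number of donors: {summary['n']}",
        f"  Sex (% male): {summary['pct_male']} ({summary['n_male']})",
        (
            f"  Age (years): median {summary['age']['median']:.1f}"
            f" (range {summary['age']['min']:.0f}-{summary['age']['max']:.0f}),"
            f" mean {summary['age']['mean']} +/- {summary['age']['sd']}"
        ),
    ]
    for lesion, s in summary["lesions"].items():
        lines.append(
            f"  MTL {lesion}: mean {s['mean']} +/- {s['sd']}"
            f" (range {s['min']}-{s['max']});"
            f" % score > 0: {s['pct_positive']}% ({s['n_positive']})"
            f" [n = {s['n_nonmissing']}]"
        )
    for stage, dist in summary["stages"].items():
        parts = [f"{lvl}: {d['pct']}% ({d['n']})" for lvl, d in dist.items() if lvl != "missing"]
        if dist.get("missing"):
            parts.append(f"missing: {dist['missing']}")
        lines.append(f"  {stage}: " + ", ".join(parts))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (one row per donor, empty fields for missing)."""
    df = pd.read_csv(path)
    if "donor_id" not in df.columns:
        raise ValueError("cohort CSV must have a donor_id column")
    if df["donor_id"].duplicated().any():
        dups = df.loc[df["donor_id"].duplicated(), "donor_id"].tolist()
        raise ValueError(f"duplicate donor_id values: {dups}")
    df["donor_id"] = df["donor_id"].astype(str)
    return df


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="")
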