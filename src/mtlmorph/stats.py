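"""Partial Spearman correlation with covariates, significance tiers,
interaction and stratified analyses.

The partial Spearman correlation between x and y given covariates Z is the
Pearson partial correlation of the rank-transformed variables: all columns
are ranked (average ranks on ties) on the complete-case subset, the rank
correlation matrix R is inverted, and

    r_xy.Z = -P_xy / sqrt(P_xx * P_yy),   P = R^{-1}.

The two-sided p-value refers t = r * sqrt((n - 2 - k) / (1 - r^2)) to a
Student t distribution with n - 2 - k degrees of freedom, k the number of
covariates — the conventions of the standard partial-rank-correlation
implementations.  An equivalent route (residualize the x- and y-ranks on
the covariate ranks and correlate the residuals) is used as an independent
oracle in the test suite.

Interaction analyses fit ordinary least squares on ranks, with the
interaction column the product of mean-centered ranks, and t-test the
product term.  Results carry the significance tier markers
('' / 'a' p<0.10 / '*' p<0.05 / '**' p<0.01 / '***' p<0.001); no
multiple-comparison adjustment is applied by default (Holm is available
behind a flag for reuse).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import LESIONS, SUBSETS, apply_subset, composite_column, thickness_column
from .thickness import SUBREGIONS

#: Default conditioning variables: donor age, sex and imaged hemisphere.
DEFAULT_COVARIATES: tuple[str, ...] = ("age", "sex_code", "hemisphere_code")

CONDITIONING_MODES: tuple[str, ...] = ("covariates_only", "covariates_plus_other_pathologies")


@dataclasses.dataclass(frozen=True)
class PartialCorrResult:
    """One partial-correlation cell: the estimate, its two-sided p, the
    complete-case n, the conditioning set and the significance tier."""

    estimate: float
    p_two_sided: float
    n: int
    conditioning_set: tuple[str, ...]
    tier: str


@dataclasses.dataclass(frozen=True)
class AnalysisSpec:
    """One correlation-table analysis.

    ``conditioning='covariates_plus_other_pathologies'`` additionally
    conditions each lesion on the other three composite scores (all
    pathologies in the same model); ``covariates_only`` conditions on age,
    sex and hemisphere alone.
    """

    name: str = "analysis"
    exposures: tuple[str, ...] = LESIONS
    outcomes: tuple[str, ...] = SUBREGIONS
    conditioning: str = "covariates_plus_other_pathologies"
    subset: str = "full"
    stratify_by: str | None = None
    per_location: bool = False

    def __post_init__(self) -> None:
        if self.conditioning not in CONDITIONING_MODES:
            raise ValueError(f"conditioning must be one of {CONDITIONING_MODES}")
        if self.subset not in SUBSETS:
            raise ValueError(f"subset must be one of {SUBSETS}")
        unknown = set(self.exposures) - set(LESIONS)
        if unknown:
            raise ValueError(f"unknown exposures {sorted(unknown)}")
        object.__setattr__(self, "exposures", tuple(self.exposures))
        object.__setattr__(self, "outcomes", tuple(self.outcomes))


# ---------------------------------------------------------------------------
# Core computations
# ---------------------------------------------------------------------------


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Average ranks (ties share their mean rank); missing values are kept
    as NaN and excluded from ranking."""
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    if mask.sum() == 0:
        raise ValueError("cannot rank an all-missing vector")
    if mask.sum() < 2:
        raise ValueError("ranking requires at least two non-missing values")
    out = np.full(arr.shape, np.nan)
    out[mask] = sps.rankdata(arr[mask], method="average")
    return out


def tier(p: float) -> str:
    """Significance marker: '***' p<0.001, '**' p<0.01, '*' p<0.05,
    'a' (trend) p<0.10, '' otherwise.  Thresholds are strict."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "a"
    return ""


def _complete_cases(columns: list[np.ndarray]) -> np.ndarray:
    stacked = np.column_stack(columns)
    return ~np.isnan(stacked).any(axis=1)


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Sequence[Sequence[float]] | np.ndarray | pd.DataFrame | None = None,
    covariate_names: Sequence[str] | None = None,
) -> PartialCorrResult:
    """Partial Spearman correlation of x and y given covariates.

    Complete cases across x, y and every covariate are used; all variables
    are rank-transformed on that subset and the partial correlation is read
    off the precision matrix of the rank correlation matrix.  With no
    covariates this is the ordinary Spearman coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov_cols: list[np.ndarray] = []
        names: list[str] = []
    elif isinstance(covariates, pd.DataFrame):
        names = [str(c) for c in covariates.columns]
        cov_cols = [covariates[c].to_numpy(dtype=float) for c in covariates.columns]
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov_cols = [cov[:, j] for j in range(cov.shape[1])]
        names = list(covariate_names or [f"z{j}" for j in range(len(cov_cols))])
    k = len(cov_cols)

    keep = _complete_cases([x, y, *cov_cols])
    n = int(keep.sum())
    if n < k + 3:
        raise ValueError(f"only {n} complete cases; need at least k + 3 = {k + 3}")

    ranks = np.column_stack([rank_transform(c[keep]) for c in (x, y, *cov_cols)])
    sd = ranks.std(axis=0)
    if np.any(sd == 0):
        const = [name for name, s in zip(["x", "y", *names], sd) if s == 0]
        raise ValueError(f"constant variable(s) after ranking: {const}")
    corr = np.corrcoef(ranks, rowvar=False)
    dof = n - 2 - k
    if abs(corr[0, 1]) >= 1.0 - 1e-14:
        # perfectly rank-correlated x and y make the matrix singular
        warnings.warn("|partial correlation| = 1; p reported as smallest positive value")
        return PartialCorrResult(
            estimate=float(np.sign(corr[0, 1])),
            p_two_sided=float(np.nextafter(0.0, 1.0)),
            n=n,
            conditioning_set=tuple(names),
            tier=tier(float(np.nextafter(0.0, 1.0))),
        )
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"singular rank correlation matrix; collinear variables among {['x', 'y', *names]}"
        ) from exc
    if not np.all(np.isfinite(prec)) or np.linalg.cond(corr) > 1e12:
        raise ValueError(
            f"near-singular rank correlation matrix; collinear variables among {['x', 'y', *names]}"
        )
    r = float(np.clip(-prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1]), -1.0, 1.0))

    if abs(r) >= 1.0 - 1e-15:
        warnings.warn("|partial correlation| = 1; p reported as smallest positive value")
        p = float(np.nextafter(0.0, 1.0))
    else:
        t = r * math.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return PartialCorrResult(
        estimate=r, p_two_sided=p, n=n, conditioning_set=tuple(names), tier=tier(p)
    )


# ---------------------------------------------------------------------------
# Cohort-level analyses
# ---------------------------------------------------------------------------


def encode_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Add numeric sex (male=1) and hemisphere (right=1) codings.  Any fixed
    binary coding leaves rank-based partial correlations unchanged."""
    out = table.copy()
    out["sex_code"] = (table["sex"] == "male").astype(float)
    out["hemisphere_code"] = (table["hemisphere"] == "right").astype(float)
    out.attrs = dict(table.attrs)
    return out


def _outcome_columns(spec: AnalysisSpec) -> list[tuple[str, str]]:
    if spec.per_location:
        return [
            (f"{sub} (loc {loc})", f"{thickness_column(sub)}_loc{loc}")
            for sub in spec.outcomes
            for loc in (1, 2)
        ]
    return [(sub, thickness_column(sub)) for sub in spec.outcomes]


def correlation_matrix(
    table: pd.DataFrame,
    spec: AnalysisSpec,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    listwise: bool = False,
    holm: bool = False,
) -> pd.DataFrame:
    """Partial Spearman correlations of lesion composites with subregional
    thickness: one row per (exposure, outcome) cell.

    Complete cases are determined per cell by default (each subregion keeps
    its own n, as thickness availability differs by subregion);
    ``listwise=True`` instead restricts every cell to rows complete across
    all analysis columns.  Cells with too few complete cases are reported
    absent with a reason rather than raised.  ``holm=True`` applies a Holm
    step-down adjustment across the table's p-values (off by default: no
    multiple-comparison correction).
    """
    sub_table = apply_subset(table, spec.subset)
    if len(sub_table) == 0:
        raise ValueError(f"subset {spec.subset!r} is empty")
    if "sex_code" not in sub_table.columns:
        sub_table = encode_covariates(sub_table)

    outcome_cols = _outcome_columns(spec)
    if listwise:
        all_cols = (
            [composite_column(l) for l in LESIONS if spec.conditioning != "covariates_only" or l in spec.exposures]
            + [c for _, c in outcome_cols]
            + list(covariates)
        )
        keep = sub_table[all_cols].notna().all(axis=1)
        sub_table = sub_table[keep]

    rows = []
    for lesion in spec.exposures:
        for label, ycol in outcome_cols:
            cond_names = list(covariates)
            if spec.conditioning == "covariates_plus_other_pathologies":
                cond_names += [composite_column(l) for l in LESIONS if l != lesion]
            cell: dict = {"exposure": lesion, "outcome": label}
            try:
                res = partial_spearman(
                    sub_table[composite_column(lesion)],
                    sub_table[ycol],
                    sub_table[cond_names],
                )
                cell.update(
                    estimate=res.estimate,
                    p=res.p_two_sided,
                    n=res.n,
                    tier=res.tier,
                    reason="",
                )
            except ValueError as exc:
                cell.update(estimate=np.nan, p=np.nan, n=0, tier="", reason=str(exc))
            cell["conditioning_set"] = ";".join(cond_names)
            rows.append(cell)
    out = pd.DataFrame(rows)
    if holm:
        ok = out["p"].notna()
        adj = _holm(out.loc[ok, "p"].to_numpy())
        out.loc[ok, "p_holm"] = adj
    out.attrs["analysis"] = dataclasses.asdict(spec)
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank_i, idx in enumerate(order):
        running = max(running, (m - rank_i) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclasses.dataclass(frozen=True)
class InteractionResult:
    """t-test of a rank-scale product term in an OLS fit on ranks."""

    coefficient: float
    t: float
    p_two_sided: float
    n: int


def interaction_test(
    table: pd.DataFrame,
    outcome: str,
    x1: str,
    x2: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> InteractionResult:
    """Test an x1-by-x2 interaction on an outcome, on the rank scale.

    Outcome ranks are regressed (OLS) on the ranks of x1, x2, their
    product of mean-centered ranks, and the covariate ranks; the returned
    p is the two-sided t-test of the product term.
    """
    cols = [outcome, x1, x2, *covariates]
    data = table[cols].to_numpy(dtype=float)
    keep = ~np.isnan(data).any(axis=1)
    data = data[keep]
    n = data.shape[0]
    n_terms = 4 + len(covariates)  # intercept, x1, x2, product, covariates
    if n < n_terms + 2:
        raise ValueError(f"only {n} complete cases; need at least {n_terms + 2}")

    ranks = np.column_stack([rank_transform(data[:, j]) for j in range(data.shape[1])])
    y = ranks[:, 0]
    r1 = ranks[:, 1] - ranks[:, 1].mean()
    r2 = ranks[:, 2] - ranks[:, 2].mean()
    X = np.column_stack([np.ones(n), ranks[:, 1], ranks[:, 2], r1 * r2, ranks[:, 3:]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"collinear design for interaction {x1} x {x2} on {outcome}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * xtx_inv[3, 3])
    t = float(beta[3] / se)
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return InteractionResult(coefficient=float(beta[3]), t=t, p_two_sided=p, n=n)


def stratified_matrix(
    table: pd.DataFrame,
    spec: AnalysisSpec,
    strata: str = "sex",
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> dict[str, pd.DataFrame]:
    """Run the correlation matrix separately within each level of a
    stratification variable (which is dropped from the conditioning set)."""
    strata_code = {"sex": "sex_code", "hemisphere": "hemisphere_code"}.get(strata, strata)
    reduced = tuple(c for c in covariates if c not in (strata, strata_code))
    if "sex_code" not in table.columns:
        table = encode_covariates(table)
    out: dict[str, pd.DataFrame] = {}
    for level in sorted(table[strata].dropna().unique()):
        stratum = table[table[strata] == level]
        stratum.attrs = dict(table.attrs)
        out[str(level)] = correlation_matrix(stratum, spec, covariates=reduced)
    return out


# ---------------------------------------------------------------------------
# Formatting
# ---------------------------------------------------------------------------


def matrix_to_wide(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format results into a lesions-by-subregions table with a
    leading sample-size row, mirroring the usual report layout."""
    outcomes = list(dict.fromkeys(results["outcome"]))
    wide = {}
    n_row = {}
    for outcome in outcomes:
        cells = results[results["outcome"] == outcome]
        n_row[outcome] = int(cells["n"].max())
        col = {}
        for _, row in cells.iterrows():
            if math.isnan(row["estimate"]):
                col[row["exposure"]] = "-"
            else:
                col[row["exposure"]] = f"{row['estimate']:.2f}{row['tier']}"
        wide[outcome] = col
    table = pd.DataFrame(wide)
    table.loc["Sample size"] = pd.Series(n_row)
    order = ["Sample size"] + [e for e in dict.fromkeys(results["exposure"])]
    return table.reindex(order)


def matrix_to_markdown(results: pd.DataFrame, title: str = "") -> str:
    wide = matrix_to_wide(results)
    lines = []
    if title:
        lines += [f"### {title}", ""]
    header = "| | " + " | ".join(wide.columns) + " |"
    sep = "|" + "---|" * (len(wide.columns) + 1)
    lines += [header, sep]
    for idx, row in wide.iterrows():
        cells = []
        for v in row:
            text = str(v)
            if isinstance(v, str) and v.endswith("*"):  # significant at p < 0.05
                estimate = v.rstrip("*")
                escaped_marks = "\\*" * (len(v) - len(estimate))
                text = f"**{estimate}{escaped_marks}**"
            cells.append(text)
        lines.append(f"| {idx} | " + " | ".join(cells) + " |")
    lines.append("")
    lines.append("a p<0.10; * p<0.05; ** p<0.01; *** p<0.001; corrected for " "age, sex and hemisphere.")
    return "\n".join(lines)
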