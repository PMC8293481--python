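"""End-to-end orchestration: specimens (real or simulated) -> thickness
table -> join with donor cohort -> summaries and correlation tables.

A :class:`RunConfig` selects exactly one input mode:

* ``simulate`` — draw a cohort (with per-location thickness) from a
  :class:`~mtlmorph.phantoms.CohortSimSpec`;
* ``files`` — read NIfTI masks and a landmark CSV, measure every specimen
  with the maximal-sphere method, and join the resulting thickness table to
  a cohort CSV on ``donor_id``.

The result bundle (thickness CSV, cohort summaries, one correlation table
per analysis, provenance record) is deterministic given the seed; the log
file is the only output that carries timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import cohort as cohort_mod
from . import phantoms, stats, thickness

logger = logging.getLogger("mtlmorph")

DEFAULT_ANALYSES: tuple[stats.AnalysisSpec, ...] = (
    stats.AnalysisSpec(
        name="full_all_pathologies",
        conditioning="covariates_plus_other_pathologies",
        subset="full",
    ),
    stats.AnalysisSpec(
        name="tau_A_negative",
        exposures=("tau",),
        conditioning="covariates_only",
        subset="A_negative",
    ),
    stats.AnalysisSpec(
        name="tau_A_negative_TDP_low",
        exposures=("tau",),
        conditioning="covariates_only",
        subset="A_negative_and_TDP_low",
    ),
)


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; exactly one input mode.

    In simulate mode ``seed`` overrides the cohort spec's seed so one
    integer reproduces the whole run.
    """

    mode: str = "simulate"
    outdir: str | Path = "results"
    seed: int = 0
    cohort_spec: phantoms.CohortSimSpec | None = None
    mask_dir: str | Path | None = None
    landmarks_csv: str | Path | None = None
    cohort_csv: str | Path | None = None
    analyses: tuple[stats.AnalysisSpec, ...] = DEFAULT_ANALYSES
    search_radius_mm: float = thickness.DEFAULT_SEARCH_RADIUS_MM
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if self.mode == "files":
            missing = [
                name
                for name, val in (
                    ("mask_dir", self.mask_dir),
                    ("landmarks_csv", self.landmarks_csv),
                    ("cohort_csv", self.cohort_csv),
                )
                if val is None
            ]
            if missing:
                raise ValueError(f"files mode requires {missing}")
        self.analyses = tuple(self.analyses)

    @staticmethod
    def from_json(path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "cohort_spec" in raw and raw["cohort_spec"] is not None:
            raw["cohort_spec"] = phantoms.spec_from_json(
                json.dumps({"__type__": "CohortSimSpec", **raw["cohort_spec"]})
            )
        if "analyses" in raw:
            raw["analyses"] = tuple(stats.AnalysisSpec(**a) for a in raw["analyses"])
        return RunConfig(**raw)

    def canonical_dict(self) -> dict:
        """Config as plain JSON-serializable data, excluding the output
        location (so the same analysis into two directories hashes alike)."""
        d: dict = {"mode": self.mode, "seed": self.seed, "log_level": self.log_level}
        if self.cohort_spec is not None:
            d["cohort_spec"] = json.loads(phantoms.spec_to_json(self.cohort_spec))
        for key in ("mask_dir", "landmarks_csv", "cohort_csv"):
            val = getattr(self, key)
            if val is not None:
                d[key] = str(val)
        d["analyses"] = [dataclasses.asdict(a) for a in self.analyses]
        d["search_radius_mm"] = self.search_radius_mm
        return d


def _setup_logging(outdir: Path, level: str) -> logging.Handler:
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level.upper())
    return handler


def measure_specimens(
    mask_dir, landmarks_csv, search_radius_mm: float = thickness.DEFAULT_SEARCH_RADIUS_MM
) -> pd.DataFrame:
    """Measure every specimen found in a mask directory.

    Masks are NIfTI files named ``{specimen_id}.nii`` or ``.nii.gz``; the
    landmark CSV supplies the dots.  Returns one wide row per specimen with
    per-subregion means and the per-location diameters retained.
    """
    mask_dir = Path(mask_dir)
    all_landmarks = thickness.read_landmarks(landmarks_csv)
    rows = []
    for specimen_id in sorted(all_landmarks):
        candidates = [mask_dir / f"{specimen_id}.nii.gz", mask_dir / f"{specimen_id}.nii"]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise FileNotFoundError(f"no mask for specimen {specimen_id!r} in {mask_dir}")
        mask = thickness.read_mask(path)
        per_sub = thickness.measure_specimen(mask, all_landmarks[specimen_id], search_radius_mm)
        row: dict = {"donor_id": specimen_id}
        for _, r in per_sub.iterrows():
            row[f"thickness_{r['subregion']}"] = r["thickness_mm"]
            row[f"thickness_{r['subregion']}_loc1"] = r["loc1_mm"]
            row[f"thickness_{r['subregion']}_loc2"] = r["loc2_mm"]
        rows.append(row)
        logger.info("measured specimen %s (%d subregions)", specimen_id, len(per_sub))
    return pd.DataFrame(rows)


def _thickness_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("thickness_")]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured pipeline and return the bundle's file paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir, config.log_level)
    try:
        return _run(config, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path) -> dict[str, Path]:
    paths: dict[str, Path] = {}

    if config.mode == "simulate":
        spec = config.cohort_spec or phantoms.CohortSimSpec()
        spec = dataclasses.replace(spec, seed=config.seed)
        logger.info("simulating cohort: n=%d seed=%d", spec.n_donors, spec.seed)
        table = phantoms.simulate_cohort(spec)
    else:
        measured = measure_specimens(config.mask_dir, config.landmarks_csv, config.search_radius_mm)
        donors = cohort_mod.read_cohort(config.cohort_csv)
        overlap = set(measured["donor_id"]) & set(donors["donor_id"])
        if not overlap:
            raise ValueError(
                "no overlapping donor ids between thickness and cohort tables; "
                f"thickness ids: {sorted(measured['donor_id'])[:5]}..."
            )
        orphans = sorted(set(measured["donor_id"]) - overlap)
        if orphans:
            logger.warning("dropping specimens without cohort rows: %s", orphans)
        table = donors.merge(measured, on="donor_id", how="inner")

    table = cohort_mod.add_composite_scores(table) if "mtl_tau" not in table.columns else table
    table = stats.encode_covariates(table)

    thick_cols = ["donor_id"] + _thickness_columns(table)
    paths["thickness"] = outdir / "thickness.csv"
    table[thick_cols].to_csv(paths["thickness"], index=False, float_format="%.6f")

    paths["cohort"] = outdir / "cohort.csv"
    cohort_mod.write_cohort(table.drop(columns=["sex_code", "hemisphere_code"]), paths["cohort"])

    summaries = {}
    for subset in ("full", "A_negative"):
        try:
            summaries[subset] = cohort_mod.summarize_cohort(table, subset)
        except ValueError as exc:
            logger.warning("summary for subset %s skipped: %s", subset, exc)
    paths["summary"] = outdir / "cohort_summary.json"
    paths["summary"].write_text(json.dumps(summaries, indent=2, sort_keys=True))
    paths["summary_txt"] = outdir / "cohort_summary.txt"
    paths["summary_txt"].write_text(
        "\n\n".join(cohort_mod.format_summary(s) for s in summaries.values()) + "\n"
    )

    cell_ns: dict[str, dict] = {}
    for analysis in config.analyses:
        results = stats.correlation_matrix(table, analysis)
        csv_path = outdir / f"correlations_{analysis.name}.csv"
        results.to_csv(csv_path, index=False, float_format="%.6g")
        md_path = outdir / f"correlations_{analysis.name}.md"
        md_path.write_text(stats.matrix_to_markdown(results, title=analysis.name) + "\n")
        paths[f"correlations_{analysis.name}"] = csv_path
        paths[f"correlations_{analysis.name}_md"] = md_path
        cell_ns[analysis.name] = {
            f"{r['exposure']}|{r['outcome']}": int(r["n"]) for _, r in results.iterrows()
        }
        logger.info("analysis %s: %d cells", analysis.name, len(results))

    provenance = {
        "config": config.canonical_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.canonical_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_donors": int(len(table)),
        "cell_sample_sizes": cell_ns,
        "flags": {
            "complete_cases": "per_cell",
            "tie_handling": "average_ranks",
            "multiple_comparison_correction": "none",
            "composite_missing_regions": "average_present",
        },
    }
    paths["provenance"] = outdir / "provenance.json"
    paths["provenance"].write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return paths
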