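"""End-to-end orchestration: validate -> summarize -> fit -> stats -> report.

Stages communicate only through documented plain-text contracts (the long
plants table in, CSV/JSON out), so runs are diffable and idempotent:
re-running on identical inputs rewrites byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables
from .group_stats import pooled_group_compare
from .isotope_metrics import (
    DELTA_KEYS,
    DeltaValue,
    derived_to_frame,
    grand_means,
    plant_fractionation,
    plants_from_frame,
    summaries_to_frame,
    treatment_summary,
)
from .rayleigh import fit_rayleigh, uptake_epsilon
from .isotope_metrics import solution_after_uptake

__all__ = ["PipelineConfig", "ValidationReport", "validate_table", "run_pipeline"]

log = logging.getLogger("cdisoflux")

#: Column names and dtype kinds of the long plants table.
PLANTS_SCHEMA = {
    "treatment_id": "object",
    "replicate_id": "object",
    "hydro_fe": "bool",
    "hydro_zn": "bool",
    "foliar_fe": "bool",
    "foliar_zn": "bool",
    "organ": "object",
    "dry_mass_g": "number",
    "conc_mg_per_kg": "number",
    "delta114_permil": "number",
    "two_sd_permil": "number",
}


@dataclass(frozen=True)
class ValidationReport:
    table: str
    n_rows: int
    violations: tuple[tuple[object, str, str], ...]  # (row label, column, message)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_table(source: "str | Path | pd.DataFrame", schema: str = "plants") -> ValidationReport:
    """Check a table against a named schema; never coerces silently.

    The ``plants`` schema checks column presence, numeric ranges
    (delta within +-5 permil, conc >= 0, masses > 0) and uniqueness of
    (treatment, replicate, organ). Every violation is reported with its row
    label.
    """
    if schema != "plants":
        raise ValueError(f"unknown schema {schema!r}")
    name = schema
    if isinstance(source, (str, Path)):
        name = str(source)
        df = pd.read_csv(source)
    else:
        df = source
    violations: list[tuple[object, str, str]] = []
    for col in PLANTS_SCHEMA:
        if col not in df.columns:
            violations.append(("-", col, "missing column"))
    if violations:
        return ValidationReport(name, len(df), tuple(violations))

    def flag(mask: pd.Series, col: str, message: str) -> None:
        for idx in df.index[mask.fillna(True)]:
            violations.append((idx, col, message))

    flag(~df["organ"].isin(("root", "stem", "leaf")), "organ", "organ must be root/stem/leaf")
    flag(~(df["dry_mass_g"] > 0), "dry_mass_g", "dry mass must be > 0 g")
    flag(~(df["conc_mg_per_kg"] >= 0), "conc_mg_per_kg", "concentration must be >= 0 mg/kg")
    flag(df["delta114_permil"].abs() > 5, "delta114_permil", "delta outside +-5 permil")
    flag(~(df["two_sd_permil"] >= 0), "two_sd_permil", "2sd must be >= 0")
    dup = df.duplicated(subset=["treatment_id", "replicate_id", "organ"], keep=False)
    flag(dup, "organ", "duplicate (treatment, replicate, organ) row")
    return ValidationReport(name, len(df), tuple(violations))


@dataclass(frozen=True)
class PipelineConfig:
    """File paths and physical parameters of one pipeline run."""

    plants_csv: str | Path
    out_dir: str | Path
    delta_sol: float = tables.DELTA_SOLUTION.value
    delta_sol_2sd: float = tables.DELTA_SOLUTION.two_sd
    solution_cd_ug: float = tables.RESERVOIR_CD_UG
    uptake_fraction: float = tables.MEAN_UPTAKE_FRACTION
    round_display: int | None = None  # None = full precision
    stats_variables: tuple[str, ...] = ("total_cd_ug", "tf_percent", "f_shoot", "d_shoot_tot")
    stats_factors: tuple[str, ...] = ("hydro_fe", "hydro_zn")

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["plants_csv"] = str(self.plants_csv)
        d["out_dir"] = str(self.out_dir)
        d["stats_variables"] = list(self.stats_variables)
        d["stats_factors"] = list(self.stats_factors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("stats_variables", "stats_factors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _write_csv(df: pd.DataFrame, path: Path, round_display: int | None) -> None:
    if round_display is not None:
        df = df.round(round_display)
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def _write_json(obj: object, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis over a plants table and write the report bundle.

    Outputs under ``config.out_dir``: plant_derived.csv,
    treatment_summary.csv, rayleigh_fits.json (leaf and shoot sinks),
    uptake.csv (reservoir reconstruction per treatment), stats.json and a
    merged report.json. Returns the report dict.

    Raises ``ValueError`` with column-level diagnostics when the input table
    violates the plants schema.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = validate_table(config.plants_csv, "plants")
    log.info("validate: %s rows, %d violations", report.n_rows, len(report.violations))
    if not report.ok:
        lines = "; ".join(f"row {r} [{c}]: {m}" for r, c, m in report.violations[:20])
        raise ValueError(f"schema violations in {report.table}: {lines}")
    df = pd.read_csv(config.plants_csv)
    if df.empty:
        raise ValueError("input plants table is empty")
    plants = plants_from_frame(df)
    delta_sol = DeltaValue(config.delta_sol, config.delta_sol_2sd)

    # per-plant mass balance and fractionation
    per_plant = [plant_fractionation(p, delta_sol) for p in plants]
    derived_frame = derived_to_frame([d for d, _, _ in per_plant])
    for key in DELTA_KEYS:
        derived_frame[f"d_{key}"] = [
            ds[key].value if key in ds else np.nan for _, ds, _ in per_plant
        ]
    derived_frame["eps_seq_mob"] = [e for _, _, e in per_plant]
    derived_frame = derived_frame.sort_values(["treatment_id", "replicate_id"]).reset_index(
        drop=True
    )
    _write_csv(derived_frame, out / "plant_derived.csv", config.round_display)
    log.info("plant_derived: %d plants", len(derived_frame))

    # treatment averages and grand means
    summaries = treatment_summary(plants, delta_sol)
    summary_frame = summaries_to_frame(summaries)
    _write_csv(summary_frame, out / "treatment_summary.csv", config.round_display)
    means = grand_means(summary_frame).to_dict()
    log.info("treatment_summary: %d treatments", len(summary_frame))

    # forced-origin Rayleigh fits on per-plant points, both sinks
    fits = {}
    for sink, f_col, d_col in (
        ("leaf", "f_leaf", "d_leaf_tot"),
        ("shoot", "f_shoot", "d_shoot_tot"),
    ):
        pts = derived_frame[[f_col, d_col]].dropna()
        fit = fit_rayleigh(list(pts.itertuples(index=False, name=None)), sink=sink)
        fits[sink] = {
            "epsilon_permil": fit.epsilon,
            "epsilon_magnitude_permil": fit.epsilon_magnitude,
            "n_points": fit.n_points,
            "residual_sd_permil": fit.residual_sd,
        }
    _write_json(fits, out / "rayleigh_fits.json")

    # reservoir reconstruction per treatment at the configured uptake fraction
    f_rem = 1.0 - config.uptake_fraction
    uptake_rows = []
    for s in sorted(summaries, key=lambda s: s.treatment_id):
        d_tot_sol = s.deltas["tot_sol"].value
        delta_final = solution_after_uptake(
            config.delta_sol, config.delta_sol + d_tot_sol, f_rem
        )
        eps = uptake_epsilon(config.delta_sol, delta_final, f_rem)
        uptake_rows.append(
            {
                "treatment_id": s.treatment_id,
                "d_tot_sol": d_tot_sol,
                "f_remaining": f_rem,
                "delta_final": delta_final,
                "eps_uptake": eps,
                "eps_uptake_magnitude": abs(eps),
            }
        )
    uptake_frame = pd.DataFrame(uptake_rows)
    _write_csv(uptake_frame, out / "uptake.csv", config.round_display)

    # pooled nonparametric comparisons
    stats_out = []
    for factor in config.stats_factors:
        for variable in config.stats_variables:
            try:
                cmp_res = pooled_group_compare(derived_frame, factor, variable)
            except ValueError as exc:
                log.warning("stats %s/%s skipped: %s", variable, factor, exc)
                continue
            stats_out.append(
                {
                    "variable": cmp_res.variable,
                    "factor": cmp_res.factor,
                    "group_sizes": list(cmp_res.group_sizes),
                    "H": cmp_res.h_statistic,
                    "p_value": cmp_res.p_value,
                    "method": cmp_res.method,
                    "significant": cmp_res.significant,
                }
            )
    _write_json(stats_out, out / "stats.json")

    report_dict = {
        "config": config.to_dict(),
        "n_plants": int(len(derived_frame)),
        "n_treatments": int(len(summary_frame)),
        "grand_means": {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in means.items()},
        "rayleigh": fits,
        "uptake": {
            "mean_eps_uptake_magnitude": float(uptake_frame["eps_uptake_magnitude"].mean()),
            "delta_final_range": [
                float(uptake_frame["delta_final"].min()),
                float(uptake_frame["delta_final"].max()),
            ],
        },
        "stats": stats_out,
    }
    _write_json(report_dict, out / "report.json")
    log.info("report written to %s", out / "report.json")
    return report_dict
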