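"""Run orchestration: one reproducible validation report.

``run_validation_report`` ties the pieces together — simulate a cohort (or
load user tables), apply the filters, run both analysis arms, and write
delimited-text tables, exclusion ledgers, a plain-text log, a YAML run
manifest and a machine-readable JSON summary. The JSON summary is
byte-identical across runs with the same configuration and seed.

Printed precisions follow the reporting conventions of the tables the
pipeline emulates: match rates to one decimal, sensitivity/specificity to
integer percent, likelihood ratios and odds ratios to two decimals. Full
precision is kept everywhere internally and in the JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import StudyBundle, generate_cohort
from .config import CohortConfig, ConfigurationError, FilterThresholds
from .diet import DEFAULT_WINDOW_GRID, DietValidation
from .ingest import StudyTables, load_study
from .pa import PAValidation

logger = logging.getLogger(__name__)


def fmt_match_rate(value: float) -> str:
    """Match rates print to one decimal percent."""
    return "--" if pd.isna(value) else f"{value:.1f}"


def fmt_sens_spec(value: float) -> str:
    """Sensitivity/specificity print to integer percent."""
    return "--" if pd.isna(value) else f"{value:.0f}"


def fmt_ratio(value: float) -> str:
    """Likelihood and odds ratios print to two decimals."""
    return "--" if pd.isna(value) else f"{value:.2f}"


@dataclass
class RunConfig:
    """One reproducible run: either a simulate block or input paths.

    Exactly one of ``simulate``/``inputs`` must be set. ``arms`` selects
    the analyses; ``subgroups`` names participant attributes for the diet
    chi-square tests.
    """

    simulate: CohortConfig | None = None
    inputs: dict | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    arms: tuple[str, ...] = ("diet", "pa")
    grid: tuple[int, ...] = DEFAULT_WINDOW_GRID
    subgroups: tuple[str, ...] = ("gender", "race", "pell")
    outdir: str | Path = "emaval_report"
    seed: int | None = None

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError("exactly one of simulate / inputs must be given")
        unknown = set(self.arms) - {"diet", "pa"}
        if unknown:
            raise ConfigurationError(f"unknown arms: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None, outdir=None, arms=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.get("simulate")
        if sim is not None:
            if seed is not None:
                sim = {**sim, "seed": seed}
            sim = CohortConfig.from_dict(sim)
        thresholds = FilterThresholds.from_dict(raw.get("thresholds", {}))
        analysis = raw.get("analysis", {})
        grid = tuple(analysis.get("grid", DEFAULT_WINDOW_GRID))
        kw = dict(
            simulate=sim,
            inputs=raw.get("inputs"),
            thresholds=thresholds,
            grid=grid,
            subgroups=tuple(analysis.get("subgroups", ("gender", "race", "pell"))),
            outdir=outdir or raw.get("outdir", "emaval_report"),
            seed=seed if seed is not None else raw.get("seed"),
        )
        if arms:
            kw["arms"] = tuple(arms)
        elif "arms" in analysis:
            kw["arms"] = tuple(analysis["arms"])
        return cls(**kw)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Timestamp):
        return obj.isoformat()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _clean(obj):
    """Round floats and replace NaN with None for a stable JSON summary."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return None if np.isnan(obj) else round(float(obj), 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _df_records(df: pd.DataFrame) -> list[dict]:
    out = []
    for _, row in df.iterrows():
        rec = {}
        for k, v in row.items():
            if isinstance(v, pd.Timestamp):
                v = v.isoformat()
            rec[str(k)] = v
        out.append(rec)
    return out


def run_validation_report(config: RunConfig) -> dict:
    """Execute the configured run and write the result bundle.

    Returns the machine-readable summary (also written to
    ``summary.json``). A failure inside one arm is recorded in the summary
    and the other arm still completes; configuration or load errors raise.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("emaval")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"arms": {}, "errors": {}}
    try:
        if config.simulate is not None:
            sim_cfg = config.simulate
            if config.seed is not None and sim_cfg.seed != config.seed:
                sim_cfg = CohortConfig.from_dict({**sim_cfg.to_dict(), "seed": config.seed})
            logger.info("simulating cohort: %d participants x %d days", sim_cfg.n_participants, sim_cfg.n_days)
            bundle: StudyBundle = generate_cohort(sim_cfg)
            data_dir = outdir / "data"
            bundle.write(data_dir)
            tables: StudyTables = load_study(data_dir)
            summary["source"] = {"simulated": True, "seed": sim_cfg.seed,
                                 "n_participants": sim_cfg.n_participants, "n_days": sim_cfg.n_days}
        else:
            tables = load_study(config.inputs)
            summary["source"] = {"simulated": False}
        summary["n_prompts"] = int(len(tables.prompts))
        summary["n_recall_instances"] = int(len(tables.recalls))
        summary["n_rejected_records"] = int(len(tables.rejections))

        if "diet" in config.arms:
            try:
                logger.info("diet arm: filtering and matching")
                model = DietValidation.from_tables(
                    tables, thresholds=config.thresholds, grid=config.grid
                )
                res = model.fit(subgroups=config.subgroups if tables.participants is not None else ())
                res.day_match.per_group.to_csv(outdir / "diet_day_match.csv", index=False)
                res.day_match.per_day.to_csv(outdir / "diet_day_audit.csv", index=False)
                res.ppv_curve.to_csv(outdir / "diet_window_ppv.csv", index=False)
                res.sens_spec.to_csv(outdir / "diet_window_sens_spec.csv", index=False)
                res.day_ledger.to_csv(outdir / "diet_exclusions.csv", index=False)
                if res.mixed_or is not None:
                    res.mixed_or.to_csv(outdir / "diet_mixed_or.csv", index=False)
                for attr, tab in res.subgroups.items():
                    tab.to_csv(outdir / f"diet_chisq_{attr}.csv", index=False)
                (outdir / "diet_summary.txt").write_text(res.summary() + "\n")
                logger.info("diet arm: %d paired days analysed", len(res.days))
                summary["arms"]["diet"] = {
                    "n_days": int(len(res.days)),
                    "n_excluded_days": int(len(res.day_ledger)),
                    "day_match": _df_records(res.day_match.per_group),
                    "mixed_or": _df_records(res.mixed_or) if res.mixed_or is not None else [],
                    "subgroup_chisq": {a: _df_records(t) for a, t in res.subgroups.items()},
                }
            except Exception as exc:  # partial-arm failure: record, continue
                logger.exception("diet arm failed")
                summary["errors"]["diet"] = f"{type(exc).__name__}: {exc}"

        if "pa" in config.arms:
            try:
                logger.info("activity arm: filtering and agreement")
                model = PAValidation.from_tables(tables, thresholds=config.thresholds)
                res = model.fit()
                res.crosstab.to_csv(outdir / "pa_crosstab.csv")
                res.agreement.to_csv(outdir / "pa_agreement.csv", index=False)
                res.mixed_or.to_csv(outdir / "pa_mixed_or.csv", index=False)
                res.ks.to_csv(outdir / "pa_ks.csv", index=False)
                res.occasion_ledger.to_csv(outdir / "pa_exclusions.csv", index=False)
                res.participant_means.to_csv(outdir / "pa_participant_means.csv")
                res.inversions.to_csv(outdir / "pa_inversions.csv", index=False)
                if res.logcount is not None:
                    res.logcount.contrasts.to_csv(outdir / "pa_logcount_contrasts.csv", index=False)
                (outdir / "pa_summary.txt").write_text(res.summary() + "\n")
                logger.info("activity arm: %d occasions analysed", len(res.occasions))
                summary["arms"]["pa"] = {
                    "n_occasions": int(len(res.occasions)),
                    "n_excluded_prompts": int(len(res.occasion_ledger)),
                    "crosstab": res.crosstab.to_numpy().tolist(),
                    "agreement": _df_records(res.agreement),
                    "mixed_or": _df_records(res.mixed_or),
                    "ks": _df_records(res.ks),
                    "logcount_contrasts": (
                        _df_records(res.logcount.contrasts) if res.logcount is not None else []
                    ),
                    "inversions": _df_records(res.inversions),
                }
            except Exception as exc:
                logger.exception("activity arm failed")
                summary["errors"]["pa"] = f"{type(exc).__name__}: {exc}"
    finally:
        root.removeHandler(handler)
        handler.close()

    summary = _clean(summary)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    manifest = {
        "seed": config.seed,
        "arms": list(config.arms),
        "thresholds": config.thresholds.to_dict(),
        "grid": [int(w) for w in config.grid],
        "simulate": config.simulate.to_dict() if config.simulate is not None else None,
        "inputs": {k: str(v) for k, v in config.inputs.items()} if config.inputs else None,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return summary
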