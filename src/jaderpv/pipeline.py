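"""Config-driven orchestration of the full analysis.

A run loads (or simulates) a JADER-schema database, builds the complete-case
analysis dataset, and emits the three result tables plus onset histograms:

* ``table1_counts.csv`` — reported cases, reporting ratios and crude RORs per
  drug / drug group, under both the all-reports and complete-case
  denominators;
* ``table2_adjusted_ror.csv`` — adjusted RORs (logistic model) for the whole
  data and per-drug subsets;
* ``table3_tto.csv`` — time-to-onset quartiles, Weibull parameters and hazard
  classification per drug / drug group;
* ``histograms/<drug>.csv`` (optionally ``.png``) — day-binned onset counts;
* ``manifest.json`` — inputs, seed, versions and row counts at each filter
  step.

Machine CSVs keep full precision; rendered rounding (ratios to 1-2 decimals,
RORs to 2) is left to presentation layers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .adjusted_model import run_adjusted_analysis
from .disproportionality import ror_table
from .report_store import (
    CaseDefinition,
    ReportDatabase,
    SJS_TEN,
    build_analysis_dataset,
    load_database,
    write_analysis_dataset,
    write_database,
)
from .synthetic_data import SimConfig, generate_database, paperlike_config
from .time_to_onset import (
    classify_hazard,
    compute_durations,
    fit_weibull,
    onset_histogram,
    summarize,
)

log = logging.getLogger(__name__)

#: Drug-group definitions shipped as defaults (names as published).
ACE_INHIBITORS: tuple[str, ...] = (
    "imidapril hydrochloride",
    "enalapril maleate",
    "temocapril hydrochloride",
    "lisinopril hydrate",
    "perindopril erbumine",
    "alacepril",
)
CORTICOSTEROIDS: tuple[str, ...] = (
    "dexamethasone",
    "dexamethasone sodium phosphate",
    "dexamethasone acetate",
    "triamcinolone acetonide",
    "prednisolone",
    "prednisolone acetate",
    "betamethasone",
    "betamethasone/d-chlorpheniramine maleate mixture",
    "betamethasone valerate/gentamicin sulfate",
    "methylprednisolone",
    "methylprednisolone sodium succinate",
)

DEFAULT_DRUGS: tuple[str, ...] = (
    "allopurinol",
    "loxoprofen",
    "acetaminophen",
    "carbamazepine",
    "lamotrigine",
)


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Exactly one of ``inputs`` (paths to the four tables) or ``simulate``
    (an inline generator configuration) must be provided.
    """

    outdir: str | Path = "run"
    inputs: dict[str, str] | None = None
    schema_config: str | dict | None = None
    simulate: SimConfig | None = None
    case_pts: tuple[str, ...] = tuple(sorted(SJS_TEN.pt_codes))
    case_label: str = "SJS/TEN"
    drugs: tuple[str, ...] = DEFAULT_DRUGS
    drug_groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "ACE inhibitors": ACE_INHIBITORS,
            "corticosteroids": CORTICOSTEROIDS,
        }
    )
    year_range: tuple[int, int] = (2004, 2015)
    run_signal: bool = True
    run_adjusted: bool = True
    run_tto: bool = True
    tto_min_n: int = 10
    histogram_png: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.case_pts:
            raise ValueError("case definition PT list must be non-empty")
        if not (self.run_signal or self.run_adjusted or self.run_tto):
            raise ValueError("at least one analysis must be enabled")
        if self.inputs is None and self.simulate is None:
            raise ValueError("provide either input paths or a simulate block")

    @property
    def case_definition(self) -> CaseDefinition:
        return CaseDefinition(frozenset(self.case_pts), self.case_label)

    def drug_sets(self) -> dict[str, tuple[str, ...]]:
        sets: dict[str, tuple[str, ...]] = {d: (d,) for d in self.drugs}
        sets.update(self.drug_groups)
        return sets

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw["simulate"]
            raw["simulate"] = (
                paperlike_config() if sim == "paperlike" else SimConfig.from_dict(sim)
            )
        if "drug_groups" in raw:
            raw["drug_groups"] = {
                k: tuple(v) for k, v in raw["drug_groups"].items()
            }
        for key in ("case_pts", "drugs", "year_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _obtain_database(config: RunConfig, outdir: Path) -> tuple[ReportDatabase, dict]:
    meta: dict = {}
    if config.simulate is not None:
        sim = config.simulate
        if config.seed is not None:
            sim.rng_seed = config.seed
        db, truth = generate_database(sim)
        write_database(db, outdir / "simulated_input")
        truth.to_json(outdir / "simulated_input" / "truth.json")
        meta["source"] = "simulated"
        meta["rng_seed"] = sim.rng_seed
        meta["n_simulated_reports"] = truth.n_reports
    else:
        db = load_database(config.inputs, config.schema_config)
        meta["source"] = {k: str(v) for k, v in config.inputs.items()}
    return db, meta


def run(config: RunConfig) -> Path:
    """Execute the configured analyses; returns the run directory.

    Any stage failure aborts with the stage name; outputs already written by
    earlier stages are retained for inspection.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": __version__, "seed": config.seed}
    stage = "load"
    try:
        db, source_meta = _obtain_database(config, outdir)
        manifest["input"] = source_meta
        manifest["counts"] = {
            "raw_reports": db.n_reports,
            "drug_rows": len(db.drug),
            "reac_rows": len(db.reac),
        }

        stage = "dataset"
        case_def = config.case_definition
        ds_all = build_analysis_dataset(
            db, case_def, year_range=config.year_range, drop_incomplete=False
        )
        ds = build_analysis_dataset(db, case_def, year_range=config.year_range)
        write_analysis_dataset(ds, outdir / "analysis_dataset.csv")
        manifest["counts"]["complete_case_reports"] = int(ds.attrs["n_complete"])
        manifest["counts"]["cases_complete"] = int(ds.attrs["n_cases"])
        manifest["case_definition"] = sorted(case_def.pt_codes)
        drug_sets = config.drug_sets()

        if config.run_signal:
            stage = "signal"
            t_complete = ror_table(ds, drug_sets, denominator_label="complete_case")
            t_raw = ror_table(ds_all, drug_sets, denominator_label="all_reports")
            overall = pd.DataFrame(
                [
                    {
                        "drug": "(database)",
                        "denominator": lbl,
                        "reported_cases": int(d["is_case"].sum()),
                        "drug_total": len(d),
                        "reporting_ratio_pct": 100.0 * d["is_case"].mean(),
                    }
                    for lbl, d in (("all_reports", ds_all), ("complete_case", ds))
                ]
            )
            table1 = pd.concat([overall, t_raw, t_complete], ignore_index=True)
            table1.to_csv(outdir / "table1_counts.csv", index=False)
            manifest["counts"]["table1_rows"] = len(table1)

        if config.run_adjusted:
            stage = "adjust"
            blocks = run_adjusted_analysis(
                ds, drug_sets, base_year=config.year_range[0]
            )
            table2 = pd.concat(
                [blk.assign(block=name) for name, blk in blocks.items()],
                ignore_index=True,
            )
            cols = ["block"] + [c for c in table2.columns if c != "block"]
            table2[cols].to_csv(outdir / "table2_adjusted_ror.csv", index=False)
            manifest["counts"]["table2_blocks"] = len(blocks)

        if config.run_tto:
            stage = "tto"
            hist_dir = outdir / "histograms"
            hist_dir.mkdir(exist_ok=True)
            rows = []
            tto_excl: dict[str, dict] = {}
            for label, names in drug_sets.items():
                dur, excl = compute_durations(db, names, case_def)
                tto_excl[label] = excl
                if dur.empty:
                    log.warning("time-to-onset: no complete durations for %s", label)
                    continue
                t = dur["duration_days"].to_numpy()
                summ = summarize(t)
                row = dict(
                    drug=label, n=summ.n, median=summ.median,
                    lower_quartile=summ.lower_quartile,
                    upper_quartile=summ.upper_quartile,
                    minimum=summ.minimum, maximum=summ.maximum,
                )
                if summ.n >= config.tto_min_n:
                    fit = fit_weibull(t, min_n=config.tto_min_n)
                    row.update(
                        alpha=fit.scale, alpha_ci_low=fit.scale_ci[0],
                        alpha_ci_high=fit.scale_ci[1],
                        beta=fit.shape, beta_ci_low=fit.shape_ci[0],
                        beta_ci_high=fit.shape_ci[1],
                        hazard_class=classify_hazard(fit).value,
                    )
                else:
                    log.warning(
                        "time-to-onset: %s has n=%d < %d; Weibull fit skipped",
                        label, summ.n, config.tto_min_n,
                    )
                rows.append(row)
                hist = onset_histogram(t)
                safe = label.replace("/", "_").replace(" ", "_")
                hist.to_csv(hist_dir / f"{safe}.csv", index=False)
                if config.histogram_png:
                    _plot_histogram(hist, label, hist_dir / f"{safe}.png")
            table3 = pd.DataFrame(rows)
            table3.to_csv(outdir / "table3_tto.csv", index=False)
            manifest["counts"]["table3_rows"] = len(table3)
            manifest["tto_exclusions"] = tto_excl
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    manifest["filter_steps"] = {
        "raw_reports": manifest["counts"]["raw_reports"],
        "complete_case_reports": manifest["counts"].get(
            "complete_case_reports", manifest["counts"]["raw_reports"]
        ),
    }
    versions = {}
    for mod in ("numpy", "pandas", "scipy"):
        versions[mod] = __import__(mod).__version__
    manifest["library_versions"] = versions
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def _plot_histogram(hist: pd.DataFrame, label: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    body = hist.iloc[:-1]
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.bar(body["day"].astype(int), body["count"], width=1.0, align="edge",
           color="#4878a8", edgecolor="white")
    ax.set_xlabel("days from first prescription to onset")
    ax.set_ylabel("reports")
    ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
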