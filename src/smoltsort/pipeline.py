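"""End-to-end analysis: validate -> transform -> fit -> thresholds ->
classify -> summarize -> test.

The pipeline is a pure function of (cohort file, run configuration, seed):
per treatment it fits 1-3 component mixtures to fork length (raw mm, all
fish, milt males included) and to each log10 maturation marker (males),
selects the best fit by BIC, converts fits to mode-intersection
thresholds, classifies every fish, summarises proportions and runs the
equality-of-proportions battery.  Mature (milt) males are included in the
mixture fits — they anchor the upper modes — even though the study
censors them from its mean comparisons.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (Cohort, MATURATION_MARKERS, log10_markers, read_cohort)
from .mixture import EMOptions, FitError, ModelSelection, select_model
from .thresholds import ThresholdSet, thresholds_from_selection
from .classify import classify_cohort, summarize_calls
from .proportions import table3_battery

__all__ = ["RunConfig", "AnalysisReport", "PipelineError", "run_analysis",
           "write_report"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage and offending metric."""

    def __init__(self, stage: str, metric: str, message: str):
        self.stage = stage
        self.metric = metric
        super().__init__(f"[{stage}] {metric}: {message}")


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings (all tunables of the pipeline in one place)."""

    seed: int = 0
    k_max: int = 3
    em_tol: float = 1e-8
    em_max_iter: int = 500
    em_restarts: int = 10
    var_floor_frac: float = 1e-3
    male_residual_rule: str = "or"  # "or" (default) | "and"
    yates_correction: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


@dataclass
class AnalysisReport:
    """All pipeline outputs plus reproducibility metadata."""

    threshold_table: pd.DataFrame
    proportions: pd.DataFrame
    test_battery: pd.DataFrame
    classifications: pd.DataFrame
    selections: dict[tuple[str, str], ModelSelection]
    thresholds: dict[str, dict[str, ThresholdSet]]
    fork_thresholds: dict[str, float]
    exclusions: pd.DataFrame
    run_metadata: dict


def _fit_seed(seed: int, treatment: str, metric: str) -> int:
    return (seed * 1000003 + zlib.crc32(f"{treatment}/{metric}".encode())) % (2**31)


def _fit_metric(values: np.ndarray, treatment: str, metric: str,
                cfg: RunConfig) -> Optional[ModelSelection]:
    """BIC selection with k capped by sample size; None if unfittable."""
    k_max = min(cfg.k_max, len(values) // 10)
    if k_max < 1:
        return None
    opts = EMOptions(tol=cfg.em_tol, max_iter=cfg.em_max_iter,
                     n_restarts=cfg.em_restarts,
                     seed=_fit_seed(cfg.seed, treatment, metric),
                     var_floor_frac=cfg.var_floor_frac)
    return select_model(values, k_max=k_max, options=opts, metric=metric,
                        treatment=treatment)


def run_analysis(cohort: Union[Cohort, str, Path],
                 config: Union[RunConfig, str, Path, None] = None
                 ) -> AnalysisReport:
    """Run the full analysis and return an :class:`AnalysisReport`."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    cfg = config or RunConfig()
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort)
    warnings: list[str] = []

    tables, exclusions = log10_markers(cohort, MATURATION_MARKERS)
    for row in exclusions.itertuples():
        if row.n_excluded:
            warnings.append(f"{row.treatment}/{row.marker}: excluded "
                            f"{row.n_excluded} non-positive value(s) before "
                            "log10 transform")

    df = cohort.data
    treatments = sorted(df["treatment"].unique())
    selections: dict[tuple[str, str], ModelSelection] = {}
    thresholds: dict[str, dict[str, ThresholdSet]] = {}
    fork_thresholds: dict[str, float] = {}
    rows = []

    for t in treatments:
        # fork length: all fish of the treatment, raw scale
        fl = df.loc[df["treatment"] == t, "fork_length_mm"].to_numpy(float)
        try:
            sel = _fit_metric(fl, t, "fork_length", cfg)
        except FitError as e:
            raise PipelineError("fit", f"{t}/fork_length", str(e)) from e
        if sel is None:
            raise PipelineError("fit", f"{t}/fork_length",
                                "too few fish to fit")
        ts = thresholds_from_selection(sel, scale="raw")
        if not ts.usable:
            raise PipelineError(
                "thresholds", f"{t}/fork_length",
                "fork length selected a unimodal fit; no migration "
                "threshold can be derived")
        selections[(t, "fork_length")] = sel
        fork_thresholds[t] = ts.threshold1
        rows.append(_threshold_row(t, "fork_length", sel, ts, len(fl)))
        if ts.fallback1 or ts.fallback2:
            warnings.append(f"{t}/fork_length: fallback threshold")

        thresholds[t] = {}
        n_males = int(((df["treatment"] == t) & (df["sex"] == "male")).sum())
        for m in MATURATION_MARKERS:
            vals = tables.get((t, m), np.empty(0))
            if n_males == 0 or len(vals) == 0:
                continue
            try:
                sel = _fit_metric(vals, t, m, cfg)
            except FitError as e:
                raise PipelineError("fit", f"{t}/{m}", str(e)) from e
            if sel is None:
                warnings.append(f"{t}/{m}: too few values to fit; marker "
                                "unusable")
                continue
            orientation = "inverted" if m == "amh" else "standard"
            ts = thresholds_from_selection(sel, orientation=orientation,
                                           scale="log10")
            selections[(t, m)] = sel
            thresholds[t][m] = ts
            rows.append(_threshold_row(t, m, sel, ts, len(vals)))
            if ts.fallback1 or ts.fallback2:
                warnings.append(f"{t}/{m}: fallback threshold")

    threshold_table = pd.DataFrame(rows, columns=[
        "treatment", "metric", "n", "bic_fmm1", "bic_fmm2", "bic_fmm3",
        "best_fit", "threshold1", "threshold2", "orientation", "fallback"])

    calls = classify_cohort(cohort, thresholds, fork_thresholds,
                            male_residual_rule=cfg.male_residual_rule)
    n_unknown = int((calls["maturation_status"] == "unknown").sum())
    if n_unknown:
        warnings.append(f"{n_unknown} male(s) with unknown maturation status "
                        "(no usable marker)")

    proportions = summarize_calls(calls, cohort)
    battery = table3_battery(calls, cohort,
                             correction_policy=cfg.yates_correction)

    cfg_yaml = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    metadata = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "smoltsort_version": __version__,
        "n_fish": len(cohort),
        "provenance": cohort.provenance,
        "warnings": warnings,
    }
    return AnalysisReport(threshold_table=threshold_table,
                          proportions=proportions, test_battery=battery,
                          classifications=calls, selections=selections,
                          thresholds=thresholds,
                          fork_thresholds=fork_thresholds,
                          exclusions=exclusions, run_metadata=metadata)


def _threshold_row(treatment: str, metric: str, sel: ModelSelection,
                   ts: ThresholdSet, n: int) -> dict:
    def get_bic(k):
        f = sel.fits.get(k)
        return np.nan if f is None else f.bic
    return {
        "treatment": treatment, "metric": metric, "n": n,
        "bic_fmm1": get_bic(1), "bic_fmm2": get_bic(2), "bic_fmm3": get_bic(3),
        "best_fit": f"fmm {sel.best_k}",
        "threshold1": np.nan if ts.threshold1 is None else ts.threshold1,
        "threshold2": np.nan if ts.threshold2 is None else ts.threshold2,
        "orientation": ts.orientation,
        "fallback": bool(ts.fallback1 or ts.fallback2),
    }


# --------------------------------------------------------------------------
# report writing

def _fmt_threshold(metric: str, value: float) -> str:
    if np.isnan(value):
        return "NA"
    if metric == "fork_length":
        return f"{value:.1f}"
    if metric == "gsi":
        return f"{value:.3f}"
    return f"{value:.2f}"


def write_report(report: AnalysisReport, outdir: str | Path) -> list[Path]:
    """Write thresholds.csv, classifications.csv, proportions.csv,
    tests.csv and report.md; returns the paths written.

    Output is byte-identical for identical inputs and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def save(df: pd.DataFrame, name: str):
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.12g", lineterminator="\n")
        paths.append(p)

    save(report.threshold_table, "thresholds.csv")
    save(report.classifications, "classifications.csv")
    save(report.proportions, "proportions.csv")
    save(report.test_battery, "tests.csv")

    md = ["# smoltsort analysis report", ""]
    meta = report.run_metadata
    md += [f"- seed: {meta['seed']}",
           f"- fish: {meta['n_fish']}",
           f"- input: {meta['provenance']}",
           f"- config sha256: {meta['config_sha256']}",
           ""]
    md += ["## Threshold values (measurement scale)", "",
           "| Treatment | Metric | Best fit | Threshold 1 | Threshold 2 |",
           "|---|---|---|---|---|"]
    for r in report.threshold_table.itertuples():
        md.append(f"| {r.treatment} | {r.metric} | {r.best_fit} | "
                  f"{_fmt_threshold(r.metric, r.threshold1)} | "
                  f"{_fmt_threshold(r.metric, r.threshold2)} |")
    md += ["", "## Status proportions", "",
           "| Table | Treatment | Sex | Status | Count | % |",
           "|---|---|---|---|---|---|"]
    for r in report.proportions.itertuples():
        md.append(f"| {r.table} | {r.treatment} | {r.sex} | {r.status} | "
                  f"{r.count} | {100 * r.proportion:.1f} |")
    md += ["", "## Equality-of-proportions tests", "",
           "| Comparison | X2 | df | N | p | Result |",
           "|---|---|---|---|---|---|"]
    for r in report.test_battery.itertuples():
        x2 = "NA" if np.isnan(r.X2) else f"{r.X2:.3f}"
        p = "NA" if np.isnan(r.p) else ("< 0.001" if r.p < 0.001
                                        else f"{r.p:.4f}")
        md.append(f"| {r.comparison} | {x2} | {r.df} | {r.N} | {p} | "
                  f"{r.result} |")
    if meta["warnings"]:
        md += ["", "## Warnings", ""] + [f"- {w}" for w in meta["warnings"]]
    md.append("")
    p = outdir / "report.md"
    p.write_text("\n".join(md))
    paths.append(p)
    return paths
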