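"""Maturation and migration gating rules.

Males are classified from the maturation-marker panel against the
per-treatment thresholds: a milt-expressing fish is *mature*
unconditionally; otherwise a fish is *maturing* if at least one usable,
present marker is past its gate (value above threshold1 for standard
markers; below threshold1 for *amh*, whose expression falls at maturation
onset), *immature* if at least one usable marker was evaluated and none
gated, and *unknown* when no usable marker is available.  Gate comparisons
are strict: a value exactly at the threshold stays in the lower/immature
mode.  Only the lowest threshold classifies — upper modes of trimodal fits
(e.g. *igf3* threshold2) never affect the call.

Migration is sex-specific: females are residuals solely by failing the
fork-length threshold (none show maturation signs); males are residuals by
failing the fork-length threshold OR by being maturing/mature — precocious
maturation predicts freshwater residency at any size.  An ``and`` variant
(small AND maturing) is available for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, FishRecord, MATURATION_MARKERS
from .thresholds import ThresholdSet

__all__ = [
    "MATURATION_STATUSES",
    "MIGRATION_STATUSES",
    "MaturationCall",
    "MigrationCall",
    "compute_gsi",
    "classify_male_maturation",
    "classify_migration",
    "classify_cohort",
    "summarize_calls",
]

MATURATION_STATUSES = ("immature", "maturing", "mature", "unknown")
MIGRATION_STATUSES = ("migrant", "residual")


@dataclass(frozen=True)
class MaturationCall:
    """Per-male maturation status with per-marker evidence.

    ``evidence`` maps each of the six maturation markers to a verdict:
    "above" / "below" / "at_threshold" (relative to threshold1),
    "missing" (no value) or "unusable" (unimodal fit, no threshold).
    """

    fish_id: str
    status: str
    evidence: Mapping[str, str]
    n_markers_used: int


@dataclass(frozen=True)
class MigrationCall:
    """Predicted post-release status.

    ``basis`` records the clause(s) that decided a residual call
    ("length_only", "maturation_only" or "both"); for migrants it records
    which clauses were consulted ("length_only" for females, "both" for
    males).  ``maturation_unknown`` flags males whose maturation status
    could not be determined and who were treated as immature by this rule.
    """

    fish_id: str
    status: str
    basis: str
    maturation_unknown: bool = False


def compute_gsi(gonad_weight: float, body_weight: float) -> float:
    """Gonadosomatic index: 100 * gonad weight / body weight, in percent."""
    if not gonad_weight > 0:
        raise ValueError(f"gonad_weight must be > 0, got {gonad_weight!r}")
    if not body_weight > 0:
        raise ValueError(f"body_weight must be > 0, got {body_weight!r}")
    return 100.0 * gonad_weight / body_weight


def classify_male_maturation(record: FishRecord,
                             thresholds: Mapping[str, ThresholdSet]) -> MaturationCall:
    """Apply the maturation gating rules to one male.

    ``thresholds`` maps marker name to the marker's :class:`ThresholdSet`
    for the record's treatment; markers without an entry are unusable.
    """
    if record.sex != "male":
        raise ValueError(f"maturation is classified for males only, got sex="
                         f"{record.sex!r} for fish {record.fish_id!r}")
    evidence: dict[str, str] = {}
    gated = False
    n_used = 0
    for marker in MATURATION_MARKERS:
        ts = thresholds.get(marker)
        if ts is not None and ts.treatment and ts.treatment != record.treatment:
            raise ValueError(
                f"threshold for {marker!r} belongs to treatment "
                f"{ts.treatment!r}, record is {record.treatment!r}")
        value = record.marker_value(marker)
        if ts is None or not ts.usable:
            evidence[marker] = "unusable"
            continue
        if value is None:
            evidence[marker] = "missing"
            continue
        n_used += 1
        if value > ts.threshold1:
            evidence[marker] = "above"
        elif value < ts.threshold1:
            evidence[marker] = "below"
        else:
            evidence[marker] = "at_threshold"
        if ts.orientation == "inverted":
            gated = gated or value < ts.threshold1
        else:
            gated = gated or value > ts.threshold1

    if record.milt_expressed:
        status = "mature"
    elif n_used == 0:
        status = "unknown"
    elif gated:
        status = "maturing"
    else:
        status = "immature"
    return MaturationCall(fish_id=record.fish_id, status=status,
                          evidence=evidence, n_markers_used=n_used)


def classify_migration(record: FishRecord, fl_threshold: float,
                       maturation: Optional[MaturationCall] = None,
                       male_residual_rule: str = "or") -> MigrationCall:
    """Predict migrant vs residual for one fish.

    ``fl_threshold`` is the fork-length threshold (mm) of the record's
    treatment.  Females need no maturation call; males with an unknown
    maturation status are treated as immature for this rule and flagged.
    """
    if male_residual_rule not in ("or", "and"):
        raise ValueError(f"invalid male_residual_rule {male_residual_rule!r}")
    small = record.fork_length < fl_threshold
    if record.sex == "female":
        return MigrationCall(fish_id=record.fish_id,
                             status="residual" if small else "migrant",
                             basis="length_only")

    if maturation is None:
        raise ValueError("males require a maturation call")
    unknown = maturation.status == "unknown"
    mat = maturation.status in ("maturing", "mature")
    if male_residual_rule == "or":
        residual = small or mat
    else:
        residual = small and mat
    if residual:
        basis = "both" if (small and mat) else ("length_only" if small
                                                else "maturation_only")
    else:
        basis = "both"
    return MigrationCall(fish_id=record.fish_id,
                         status="residual" if residual else "migrant",
                         basis=basis, maturation_unknown=unknown)


def classify_cohort(cohort: Cohort,
                    thresholds_by_treatment: Mapping[str, Mapping[str, ThresholdSet]],
                    fl_thresholds: Mapping[str, float],
                    male_residual_rule: str = "or") -> pd.DataFrame:
    """Classify every fish; returns one tidy row per fish.

    Females carry maturation_status "immature" (all females are visually
    immature at sampling; the marker panel applies to males only).
    """
    rows = []
    for rec in cohort.records:
        if rec.treatment not in fl_thresholds:
            raise ValueError(f"no fork-length threshold for treatment "
                             f"{rec.treatment!r}")
        if rec.sex == "male":
            mat = classify_male_maturation(
                rec, thresholds_by_treatment.get(rec.treatment, {}))
            mig = classify_migration(rec, fl_thresholds[rec.treatment], mat,
                                     male_residual_rule)
            mat_status, n_used = mat.status, mat.n_markers_used
            evidence = ";".join(f"{m}:{v}" for m, v in mat.evidence.items())
        else:
            mig = classify_migration(rec, fl_thresholds[rec.treatment])
            mat_status, n_used, evidence = "immature", 0, ""
        rows.append({
            "fish_id": rec.fish_id,
            "treatment": rec.treatment,
            "sex": rec.sex,
            "maturation_status": mat_status,
            "migration_status": mig.status,
            "basis": mig.basis,
            "maturation_unknown": mig.maturation_unknown,
            "n_markers_used": n_used,
            "evidence": evidence,
        })
    return pd.DataFrame(rows)


def _phenotype_categories(cohort: Cohort) -> pd.Series:
    """Visual category per fish: milt expression overrides to 'mature'."""
    df = cohort.data
    return pd.Series(np.where(df["milt_expressed"], "mature",
                              df["smolt_phenotype"]), index=df.index)


def summarize_calls(calls: pd.DataFrame,
                    cohort: Optional[Cohort] = None) -> pd.DataFrame:
    """Per-stratum status counts and proportions.

    Emits one row per (table, treatment, sex, status) where ``table`` is
    "maturation" (males only), "migration" (per sex, plus sexes combined
    as sex="all"), and — when a cohort is supplied — "phenotype" (visual
    categories with milt males as their own "mature" category).
    Proportions sum to one within each (table, treatment, sex) stratum;
    empty strata are simply absent.
    """
    rows = []

    def tally(table: str, treatment: str, sex: str, statuses: pd.Series):
        n = len(statuses)
        if n == 0:
            return
        counts = statuses.value_counts()
        for status, cnt in counts.sort_index().items():
            rows.append({"table": table, "treatment": treatment, "sex": sex,
                         "status": status, "count": int(cnt),
                         "proportion": cnt / n, "n_stratum": n})

    for treatment in sorted(calls["treatment"].unique()):
        sub = calls[calls["treatment"] == treatment]
        tally("maturation", treatment, "male",
              sub.loc[sub["sex"] == "male", "maturation_status"])
        for sex in ("male", "female"):
            tally("migration", treatment, sex,
                  sub.loc[sub["sex"] == sex, "migration_status"])
        tally("migration", treatment, "all", sub["migration_status"])

    if cohort is not None:
        pheno = _phenotype_categories(cohort)
        df = cohort.data
        for treatment in sorted(df["treatment"].unique()):
            mask = df["treatment"] == treatment
            for sex in ("male", "female"):
                tally("phenotype", treatment, sex,
                      pheno[mask & (df["sex"] == sex)])
            tally("phenotype", treatment, "all", pheno[mask])

    return pd.DataFrame(rows, columns=["table", "treatment", "sex", "status",
                                       "count", "proportion", "n_stratum"])
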