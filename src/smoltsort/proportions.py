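"""Pearson chi-square tests for equality of two proportions (2x2 tables).

The uncorrected statistic is N(ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]; the
Yates continuity correction replaces |ad - bc| with max(|ad - bc| - N/2, 0).
The p-value comes from the chi-square distribution with one degree of
freedom.  The battery runner reproduces the study-style comparison table:
treatment-vs-treatment and sex-vs-sex comparisons of phenotype, maturation
and predicted-residual proportions, each reported with its counts, the
statistic, N, p and a direction at the alpha = 0.05 convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .classify import _phenotype_categories

__all__ = [
    "ContingencyTable2x2",
    "ProportionTestResult",
    "chi2_2x2",
    "proportion_pct",
    "relative_increase_pct",
    "ComparisonSpec",
    "default_battery",
    "table3_battery",
]

ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: group 1 (a successes, b failures), group 2 (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"count {name} must be a non-negative "
                                 f"integer, got {v!r}")
        if self.total == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ProportionTestResult:
    statistic: float
    df: int
    p_value: float
    corrected: bool
    N: int


def chi2_2x2(table: ContingencyTable2x2,
             corrected: bool = True) -> ProportionTestResult:
    """Pearson chi-square test for equality of two proportions."""
    a, b, c, d = table.a, table.b, table.c, table.d
    margins = {"row 1 (a+b)": a + b, "row 2 (c+d)": c + d,
               "column 1 (a+c)": a + c, "column 2 (b+d)": b + d}
    for name, m in margins.items():
        if m == 0:
            raise ValueError(f"degenerate margin: {name} is zero")
    n = table.total
    diff = abs(a * d - b * c)
    if corrected:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff * diff / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(stats.chi2.sf(stat, df=1))
    return ProportionTestResult(statistic=float(stat), df=1, p_value=p,
                                corrected=corrected, N=n)


def proportion_pct(k: int, n: int) -> float:
    """A count as a percentage of its total."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 100.0 * k / n


def relative_increase_pct(k_ref: int, n_ref: int, k_new: int, n_new: int) -> float:
    """Relative change of proportion k_new/n_new over k_ref/n_ref, in %."""
    return 100.0 * ((k_new / n_new) / (k_ref / n_ref) - 1.0)


# --------------------------------------------------------------------------
# battery

@dataclass(frozen=True)
class ComparisonSpec:
    """One battery row: two groups compared on one category's proportion."""

    label: str
    table: str        # "phenotype" | "maturation" | "residual"
    category: str     # category counted as "success"
    group1: tuple[str, str]  # (treatment, sex); sex may be "all"
    group2: tuple[str, str]
    corrected: Optional[bool] = None  # None -> battery-level policy


def default_battery() -> list[ComparisonSpec]:
    """The standard 17-row comparison battery."""
    rows: list[ComparisonSpec] = []
    for t in ("S1", "S2"):
        for cat in ("parr", "transitional", "smolt"):
            rows.append(ComparisonSpec(
                f"{t} male {cat} vs. {t} female {cat}", "phenotype", cat,
                (t, "male"), (t, "female")))
    rows.append(ComparisonSpec("S1 mature male vs. S2 mature male",
                               "phenotype", "mature", ("S1", "all"), ("S2", "all")))
    for cat in ("parr", "transitional", "smolt"):
        rows.append(ComparisonSpec(f"S1 {cat} vs. S2 {cat}", "phenotype", cat,
                                   ("S1", "all"), ("S2", "all")))
    for cat in ("immature", "maturing"):
        rows.append(ComparisonSpec(f"S1 {cat} males vs. S2 {cat} males",
                                   "maturation", cat,
                                   ("S1", "male"), ("S2", "male")))
    for t in ("S1", "S2"):
        rows.append(ComparisonSpec(f"{t} male residuals vs. {t} female residuals",
                                   "residual", "residual",
                                   (t, "male"), (t, "female")))
    for sex in ("male", "female"):
        rows.append(ComparisonSpec(f"S1 {sex} residuals vs. S2 {sex} residuals",
                                   "residual", "residual",
                                   ("S1", sex), ("S2", sex)))
    rows.append(ComparisonSpec("S1 residuals vs. S2 residuals", "residual",
                               "residual", ("S1", "all"), ("S2", "all")))
    return rows


def _category_series(table: str, calls: pd.DataFrame,
                     cohort: Cohort) -> pd.DataFrame:
    """(treatment, sex, category) per fish for one comparison table."""
    if table == "phenotype":
        df = cohort.data
        return pd.DataFrame({"treatment": df["treatment"], "sex": df["sex"],
                             "category": _phenotype_categories(cohort)})
    if table == "maturation":
        sub = calls[calls["sex"] == "male"]
        return pd.DataFrame({"treatment": sub["treatment"], "sex": sub["sex"],
                             "category": sub["maturation_status"]})
    if table == "residual":
        return pd.DataFrame({"treatment": calls["treatment"],
                             "sex": calls["sex"],
                             "category": calls["migration_status"]})
    raise ValueError(f"unknown comparison table {table!r}")


def table3_battery(calls: pd.DataFrame, cohort: Cohort,
                   correction_policy: bool | Mapping[str, bool] = True,
                   comparisons: Optional[Sequence[ComparisonSpec]] = None
                   ) -> pd.DataFrame:
    """Run the equality-of-proportions battery on classified data.

    ``correction_policy`` is either one boolean for every row or a mapping
    from row label to boolean (rows absent from the mapping use the Yates
    correction); an explicit ``corrected`` on a :class:`ComparisonSpec`
    always wins.  Rows with an empty group or a degenerate margin are
    emitted with a not-computable marker rather than dropped.
    """
    comparisons = list(comparisons) if comparisons is not None else default_battery()
    out = []
    for spec in comparisons:
        data = _category_series(spec.table, calls, cohort)
        counts = []
        for treatment, sex in (spec.group1, spec.group2):
            mask = data["treatment"] == treatment
            if sex != "all":
                mask &= data["sex"] == sex
            grp = data.loc[mask, "category"]
            counts.append((int((grp == spec.category).sum()), int(len(grp))))
        (a, n1), (c, n2) = counts
        if spec.corrected is not None:
            corrected = spec.corrected
        elif isinstance(correction_policy, Mapping):
            corrected = bool(correction_policy.get(spec.label, True))
        else:
            corrected = bool(correction_policy)
        row = {"comparison": spec.label, "a": a, "b": n1 - a, "c": c,
               "d": n2 - c, "corrected": corrected, "X2": np.nan, "df": 1,
               "N": n1 + n2, "p": np.nan, "result": "not_computable"}
        try:
            res = chi2_2x2(ContingencyTable2x2(a, n1 - a, c, n2 - c), corrected)
        except ValueError:
            out.append(row)
            continue
        row["X2"], row["p"] = res.statistic, res.p_value
        if res.p_value >= ALPHA:
            row["result"] = "NS"
        else:
            row["result"] = "greater" if a / n1 > c / n2 else "less"
        out.append(row)
    return pd.DataFrame(out, columns=["comparison", "a", "b", "c", "d",
                                      "corrected", "X2", "df", "N", "p",
                                      "result"])
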