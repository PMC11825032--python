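"""Reading, validation and preprocessing of per-fish cohort tables.

A cohort is one sampling event's worth of fish: every row is a single fish
with its morphology (fork length, body weight), visually scored smolt
phenotype, milt-expression flag and an optional maturation-marker panel
(pituitary *fshb*/*lhb* and testis *amh*/*igf3* relative mRNA expression,
gonadosomatic index GSI, plasma 11-ketotestosterone).  Files are plain CSV,
UTF-8, one header row, "." decimal, empty cell = missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TREATMENTS",
    "SEXES",
    "PHENOTYPES",
    "MATURATION_MARKERS",
    "MARKER_COLUMNS",
    "COLUMNS",
    "SchemaError",
    "CohortValidationError",
    "ValidationOptions",
    "FishRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "log10_markers",
]

TREATMENTS = ("S1", "S2")
SEXES = ("male", "female")
PHENOTYPES = ("parr", "transitional", "smolt")

#: The six maturation parameters used for male gating (fork length never is).
MATURATION_MARKERS = ("fshb", "lhb", "amh", "igf3", "gsi", "kt11")

#: Marker name -> CSV column holding its values.
MARKER_COLUMNS: Mapping[str, str] = {
    "fshb": "fshb",
    "lhb": "lhb",
    "amh": "amh",
    "igf3": "igf3",
    "gsi": "gsi_pct",
    "kt11": "kt11",
}

MANDATORY_COLUMNS = (
    "fish_id",
    "release_year",
    "treatment",
    "sex",
    "fork_length_mm",
    "body_weight_g",
    "smolt_phenotype",
    "milt_expressed",
)

OPTIONAL_COLUMNS = (
    "gill_atpase",
    "gonad_weight_g",
    "fshb",
    "lhb",
    "amh",
    "igf3",
    "kt11",
    "gsi_pct",
)

COLUMNS = MANDATORY_COLUMNS[:6] + ("gill_atpase", "smolt_phenotype",
                                   "milt_expressed", "gonad_weight_g",
                                   "fshb", "lhb", "amh", "igf3", "kt11",
                                   "gsi_pct")

_FLOAT_COLUMNS = (
    "fork_length_mm",
    "body_weight_g",
    "gill_atpase",
    "gonad_weight_g",
    "fshb",
    "lhb",
    "amh",
    "igf3",
    "kt11",
    "gsi_pct",
)

#: Gonad-derived fields that must be absent for females.
_FEMALE_FORBIDDEN = ("gonad_weight_g", "gsi_pct", "amh", "igf3")


class SchemaError(ValueError):
    """A structural problem with the file (missing column, bad header)."""


class CohortValidationError(ValueError):
    """One or more rows violate a hard cohort invariant.

    ``problems`` is a list of ``(row_number, message)`` pairs, where
    ``row_number`` is the 1-based data-row index (header excluded).
    """

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {r}: {m}" for r, m in problems[:25])
        extra = "" if len(problems) <= 25 else f" (+{len(problems) - 25} more)"
        super().__init__(f"cohort validation failed: {lines}{extra}")


@dataclass(frozen=True)
class ValidationOptions:
    """Validation options for :func:`read_cohort`.

    derive_gsi
        Fill ``gsi_pct`` from 100 * gonad_weight / body_weight when absent.
    gsi_rtol
        Relative tolerance for agreement between a stored ``gsi_pct`` and
        the value implied by the weights.
    """

    derive_gsi: bool = True
    gsi_rtol: float = 1e-6


@dataclass(frozen=True)
class FishRecord:
    """One sampled fish; optional fields are ``None`` when not measured."""

    fish_id: str
    release_year: int
    treatment: str
    sex: str
    fork_length: float
    body_weight: float
    smolt_phenotype: str
    milt_expressed: bool
    gill_atpase: Optional[float] = None
    gonad_weight: Optional[float] = None
    fshb: Optional[float] = None
    lhb: Optional[float] = None
    amh: Optional[float] = None
    igf3: Optional[float] = None
    kt11: Optional[float] = None
    gsi: Optional[float] = None

    def marker_value(self, marker: str) -> Optional[float]:
        if marker not in MATURATION_MARKERS:
            raise ValueError(f"unknown maturation marker {marker!r}")
        return getattr(self, marker)


@dataclass
class Cohort:
    """A validated cohort table plus its provenance tag."""

    data: pd.DataFrame
    provenance: str = "unknown"

    def __len__(self) -> int:
        return len(self.data)

    @property
    def records(self) -> list[FishRecord]:
        return [_record_from_row(row) for row in self.data.itertuples(index=False)]

    def treatment_counts(self) -> dict[str, int]:
        return self.data["treatment"].value_counts().to_dict()


def _opt(value: float) -> Optional[float]:
    return None if value is None or (isinstance(value, float) and math.isnan(value)) else float(value)


def _record_from_row(row) -> FishRecord:
    return FishRecord(
        fish_id=str(row.fish_id),
        release_year=int(row.release_year),
        treatment=row.treatment,
        sex=row.sex,
        fork_length=float(row.fork_length_mm),
        body_weight=float(row.body_weight_g),
        smolt_phenotype=row.smolt_phenotype,
        milt_expressed=bool(row.milt_expressed),
        gill_atpase=_opt(row.gill_atpase),
        gonad_weight=_opt(row.gonad_weight_g),
        fshb=_opt(row.fshb),
        lhb=_opt(row.lhb),
        amh=_opt(row.amh),
        igf3=_opt(row.igf3),
        kt11=_opt(row.kt11),
        gsi=_opt(row.gsi_pct),
    )


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _parse_bool(cell: str, rownum: int, problems: list) -> bool:
    key = str(cell).strip().lower()
    if key not in _BOOL_MAP:
        problems.append((rownum, f"unparseable boolean milt_expressed value {cell!r}"))
        return False
    return _BOOL_MAP[key]


def read_cohort(path: str | Path,
                schema_config: ValidationOptions | None = None) -> Cohort:
    """Read and validate a cohort CSV.

    Rows violating hard invariants are reported with 1-based data-row
    indices in a single :class:`CohortValidationError`; missing optional
    cells are preserved as missing (NaN), never coerced to zero.
    """
    opts = schema_config or ValidationOptions()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in OPTIONAL_COLUMNS:
        if col not in raw.columns:
            raw[col] = ""

    problems: list[tuple[int, str]] = []
    n = len(raw)
    out = pd.DataFrame(index=range(n))
    out["fish_id"] = raw["fish_id"].str.strip()

    # integer year
    years = np.full(n, -1, dtype=np.int64)
    for i, cell in enumerate(raw["release_year"]):
        try:
            years[i] = int(str(cell).strip())
        except ValueError:
            problems.append((i + 1, f"unparseable release_year {cell!r}"))
    out["release_year"] = years

    for col, allowed in (("treatment", TREATMENTS), ("sex", SEXES),
                         ("smolt_phenotype", PHENOTYPES)):
        vals = raw[col].str.strip()
        for i, v in enumerate(vals):
            if v not in allowed:
                problems.append((i + 1, f"invalid {col} value {v!r}"))
        out[col] = vals

    out["milt_expressed"] = [
        _parse_bool(c, i + 1, problems) for i, c in enumerate(raw["milt_expressed"])
    ]

    for col in _FLOAT_COLUMNS:
        vals = np.full(n, np.nan)
        for i, cell in enumerate(raw[col]):
            s = str(cell).strip()
            if s == "":
                continue
            try:
                v = float(s)
            except ValueError:
                problems.append((i + 1, f"unparseable numeric cell {col}={cell!r}"))
                continue
            if not math.isfinite(v):
                problems.append((i + 1, f"non-finite value {col}={cell!r}"))
                continue
            vals[i] = v
        out[col] = vals

    # duplicate ids
    dup = out["fish_id"].duplicated(keep=False)
    if dup.any():
        for i in np.flatnonzero(dup.to_numpy()):
            problems.append((int(i) + 1, f"duplicate fish_id {out['fish_id'].iloc[i]!r}"))

    _validate_invariants(out, opts, problems)

    if problems:
        problems.sort(key=lambda p: p[0])
        raise CohortValidationError(problems)

    for t in sorted(set(out["treatment"])):
        if (out["treatment"] == t).sum() == 0:  # pragma: no cover - defensive
            raise CohortValidationError([(0, f"no records for treatment {t}")])

    out = out[list(COLUMNS)]
    return Cohort(data=out.reset_index(drop=True), provenance=str(path))


def _validate_invariants(df: pd.DataFrame, opts: ValidationOptions,
                         problems: list[tuple[int, str]]) -> None:
    for i in range(len(df)):
        rownum = i + 1
        fl = df["fork_length_mm"].iloc[i]
        bw = df["body_weight_g"].iloc[i]
        if math.isnan(fl) or fl <= 0:
            problems.append((rownum, "fork_length_mm must be present and > 0"))
        if math.isnan(bw) or bw <= 0:
            problems.append((rownum, "body_weight_g must be present and > 0"))

        if df["sex"].iloc[i] == "female":
            if df["milt_expressed"].iloc[i]:
                problems.append((rownum, "invariant violated: female with milt_expressed=true"))
            for col in _FEMALE_FORBIDDEN:
                if not math.isnan(df[col].iloc[i]):
                    problems.append(
                        (rownum, f"invariant violated: female with gonad marker {col} present"))

        # negative marker / gonad values are never legal; zeros are tolerated
        # at I/O time and excluded only at the log10 transform.
        for col in ("gonad_weight_g", "fshb", "lhb", "amh", "igf3", "kt11", "gsi_pct"):
            v = df[col].iloc[i]
            if not math.isnan(v) and v < 0:
                problems.append((rownum, f"negative {col} value {v!r}"))

        gw = df["gonad_weight_g"].iloc[i]
        gsi = df["gsi_pct"].iloc[i]
        if not math.isnan(gw) and not math.isnan(bw) and bw > 0:
            implied = 100.0 * gw / bw
            if math.isnan(gsi):
                if opts.derive_gsi:
                    df.loc[df.index[i], "gsi_pct"] = implied
            elif implied > 0 and abs(gsi - implied) > opts.gsi_rtol * max(abs(implied), 1e-300):
                problems.append(
                    (rownum,
                     f"gsi_pct={gsi!r} disagrees with 100*gonad_weight/body_weight={implied!r}"))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to CSV (full float precision; empty = missing)."""
    df = cohort.data.copy()
    cols = list(MANDATORY_COLUMNS[:6]) + ["gill_atpase", "smolt_phenotype",
                                          "milt_expressed", "gonad_weight_g",
                                          "fshb", "lhb", "amh", "igf3",
                                          "kt11", "gsi_pct"]
    out = pd.DataFrame()
    for col in cols:
        if col == "milt_expressed":
            out[col] = np.where(df[col], "true", "false")
        elif col in _FLOAT_COLUMNS:
            out[col] = [("" if math.isnan(v) else repr(float(v))) for v in df[col]]
        else:
            out[col] = df[col].astype(str)
    out.to_csv(path, index=False, lineterminator="\n")


def log10_markers(cohort: Cohort,
                  markers: Iterable[str]) -> tuple[dict[tuple[str, str], np.ndarray],
                                                   pd.DataFrame]:
    """log10-transform maturation-marker values, per (treatment, marker).

    Returns a table of usable transformed values keyed by
    ``(treatment, marker)`` together with an exclusion report counting, per
    key, how many present values were excluded because they were not
    strictly positive.  Missing values simply do not enter the table.  Fork
    length is not a maturation marker and is never transformed (mixtures on
    fork length are fitted on the raw millimetre scale).
    """
    markers = list(markers)
    for m in markers:
        if m not in MATURATION_MARKERS:
            raise ValueError(
                f"unknown marker {m!r}; expected one of {MATURATION_MARKERS}")

    tables: dict[tuple[str, str], np.ndarray] = {}
    rows = []
    df = cohort.data
    for treatment in sorted(set(df["treatment"])):
        sub = df[df["treatment"] == treatment]
        for m in markers:
            vals = sub[MARKER_COLUMNS[m]].to_numpy(dtype=float)
            present = vals[~np.isnan(vals)]
            usable = present[present > 0]
            tables[(treatment, m)] = np.log10(usable)
            rows.append({
                "treatment": treatment,
                "marker": m,
                "n_present": int(present.size),
                "n_used": int(usable.size),
                "n_excluded": int(present.size - usable.size),
            })
    report = pd.DataFrame(rows, columns=["treatment", "marker", "n_present",
                                         "n_used", "n_excluded"])
    return tables, report
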