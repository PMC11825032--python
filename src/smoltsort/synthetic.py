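"""Synthetic cohort generator with known mixture structure and truth labels.

The study's raw per-fish data are not public, so this module generates
cohorts carrying the statistical structure the analysis assumes: per
treatment, every metric follows a 1-, 2- or 3-component Gaussian mixture
(log10 scale for maturation markers, raw millimetres for fork length)
whose weighted-density intersections are known analytically.  The default
configuration places those generating intersections exactly at the
published threshold values (fork length 146.6 / 147.6 mm, GSI 0.051/0.627
and 0.056/0.962 %, 11KT 0.88/23.08 and 0.97/15.81 ng/ml, and so on), so
threshold recovery can be measured against exact ground truth.

Each male carries a latent maturation stage (immature / maturing / mature)
which routes it into marker components coherently: mature (milt) males
occupy top modes, advanced maturing males spill into upper GSI/11KT/igf3
modes, and testis transcripts are unmeasurable in spermiating fish.
Missingness mimics the study design: gill ATPase on a subset of later
years, testis mRNA in the first two release years only, mature-male GSI
absent in the last two years.  The recorded "truth" maturation and
migration labels are the gating rules evaluated with the generating
thresholds, so a pipeline whose fitted thresholds equal the generating
ones reproduces the truth exactly.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, MATURATION_MARKERS
from .mixture import Component
from .thresholds import ThresholdSet, component_intersection
from .classify import classify_cohort, summarize_calls

__all__ = [
    "STAGES",
    "MarkerSpec",
    "StageRouting",
    "ForkRouting",
    "SyntheticConfig",
    "LabeledCohort",
    "default_paper_config",
    "generate_cohort",
    "truth_summary",
    "pair_lower_mean",
]

STAGES = ("immature", "maturing", "mature")

_METRICS = ("fork_length",) + MATURATION_MARKERS


class ConfigError(ValueError):
    """An invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class MarkerSpec:
    """Generating mixture for one metric within one treatment."""

    marker: str
    scale: str  # "raw" | "log10"
    components: tuple[tuple[float, float, float], ...]  # (weight, mean, sd)
    orientation: str = "standard"

    def __post_init__(self):
        if len(self.components) > 3:
            raise ConfigError(
                f"{self.marker}: {len(self.components)} components; the "
                "pipeline supports at most 3")
        if not self.components:
            raise ConfigError(f"{self.marker}: needs at least one component")
        w = sum(c[0] for c in self.components)
        if abs(w - 1.0) > 1e-12:
            raise ConfigError(f"{self.marker}: weights sum to {w!r}, not 1")
        means = [c[1] for c in self.components]
        if sorted(means) != means:
            raise ConfigError(f"{self.marker}: components must be ordered "
                              "by ascending mean")
        if any(c[2] <= 0 for c in self.components):
            raise ConfigError(f"{self.marker}: all sds must be positive")
        if self.orientation == "inverted" and self.marker != "amh":
            raise ConfigError("inverted orientation is reserved for amh")

    @property
    def k(self) -> int:
        return len(self.components)

    def as_components(self) -> tuple[Component, ...]:
        return tuple(Component(weight=w, mean=m, sd=s)
                     for w, m, s in self.components)

    def intersections(self) -> tuple[float, ...]:
        comps = self.as_components()
        return tuple(component_intersection(comps[i], comps[i + 1])
                     for i in range(len(comps) - 1))


@dataclass(frozen=True)
class StageRouting:
    """P(component | latent stage) for one marker; None = not measurable."""

    immature: Optional[tuple[float, ...]]
    maturing: Optional[tuple[float, ...]]
    mature: Optional[tuple[float, ...]]

    def row(self, stage: int) -> Optional[tuple[float, ...]]:
        return (self.immature, self.maturing, self.mature)[stage]


@dataclass(frozen=True)
class ForkRouting:
    """P(lower fork-length component) by sex / male stage."""

    female_lower: float
    immature_lower: float
    maturing_lower: float = 0.1
    mature_lower: float = 0.0


@dataclass
class SyntheticConfig:
    """Full description of a synthetic paired-release study."""

    seed: int = 0
    years: tuple[int, ...] = (2011, 2012, 2013, 2014, 2015)
    n_per_treatment: dict[str, int] = field(default_factory=dict)
    male_fraction: dict[str, float] = field(default_factory=dict)
    #: (immature, maturing, mature) probabilities for males; the mature
    #: entry is the milt-expression rate.
    stage_probs: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    markers: dict[str, dict[str, MarkerSpec]] = field(default_factory=dict)
    routing: dict[str, dict[str, StageRouting]] = field(default_factory=dict)
    fork_routing: dict[str, ForkRouting] = field(default_factory=dict)
    #: zero-centred additive mean shift per year, on the analysis scale.
    year_effects: dict[str, tuple[float, ...]] = field(default_factory=dict)
    #: marker -> treatment -> per-year missingness rate.
    missingness: dict[str, dict[str, tuple[float, ...]]] = field(default_factory=dict)
    #: years in which mature-male GSI is structurally absent.
    mature_gsi_missing_years: tuple[int, ...] = (2014, 2015)
    #: (parr, transitional, smolt) probabilities for non-milt fish.
    phenotype_probs: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    gill: dict[str, tuple[float, float]] = field(default_factory=dict)
    condition_factor: tuple[float, float] = (1.10, 0.07)

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(sorted(self.n_per_treatment))

    def validate(self) -> None:
        if not self.n_per_treatment:
            raise ConfigError("no treatments configured")
        for t, n in self.n_per_treatment.items():
            if n <= 0:
                raise ConfigError(f"n_per_treatment[{t}] must be > 0")
        for t in self.treatments:
            probs = self.stage_probs[t]
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigError(f"stage_probs[{t}] must be a distribution")
            if not 0 <= self.male_fraction[t] <= 1:
                raise ConfigError(f"male_fraction[{t}] out of [0, 1]")
            for marker, spec in self.markers[t].items():
                if marker == "fork_length":
                    continue  # routed by sex/stage, not by StageRouting
                route = self.routing[t][marker]
                implied = self._implied_weights(t, marker)
                configured = np.array([c[0] for c in spec.components])
                if not np.allclose(implied, configured, atol=1e-9):
                    raise ConfigError(
                        f"routing for ({t}, {marker}) implies occupancy "
                        f"{implied.round(6).tolist()}, configured weights are "
                        f"{configured.round(6).tolist()}")
                for stage in range(3):
                    row = route.row(stage)
                    if row is not None and (len(row) != spec.k
                                            or abs(sum(row) - 1.0) > 1e-9):
                        raise ConfigError(
                            f"routing row for ({t}, {marker}, "
                            f"{STAGES[stage]}) is not a distribution over "
                            f"{spec.k} components")
        for marker, per_t in self.missingness.items():
            for t, rates in per_t.items():
                if len(rates) != len(self.years) or not all(
                        0 <= r <= 1 for r in rates):
                    raise ConfigError(f"missingness[{marker}][{t}] must give "
                                      "one rate in [0,1] per year")

    def _implied_weights(self, treatment: str, marker: str) -> np.ndarray:
        """Marginal component occupancy implied by stages and routing."""
        spec = self.markers[treatment][marker]
        route = self.routing[treatment][marker]
        probs = self.stage_probs[treatment]
        w = np.zeros(spec.k)
        mass = 0.0
        for stage in range(3):
            row = route.row(stage)
            if row is None:
                continue
            w += probs[stage] * np.asarray(row)
            mass += probs[stage]
        return w / mass

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "years": list(self.years),
            "n_per_treatment": dict(self.n_per_treatment),
            "male_fraction": dict(self.male_fraction),
            "stage_probs": {t: list(v) for t, v in self.stage_probs.items()},
            "markers": {
                t: {m: {"scale": s.scale, "orientation": s.orientation,
                        "components": [list(c) for c in s.components]}
                    for m, s in per_t.items()}
                for t, per_t in self.markers.items()},
            "routing": {
                t: {m: {stage: (None if r.row(i) is None else list(r.row(i)))
                        for i, stage in enumerate(STAGES)}
                    for m, r in per_t.items()}
                for t, per_t in self.routing.items()},
            "fork_routing": {t: asdict(r) for t, r in self.fork_routing.items()},
            "year_effects": {m: list(v) for m, v in self.year_effects.items()},
            "missingness": {m: {t: list(v) for t, v in per_t.items()}
                            for m, per_t in self.missingness.items()},
            "mature_gsi_missing_years": list(self.mature_gsi_missing_years),
            "phenotype_probs": {t: list(v) for t, v in self.phenotype_probs.items()},
            "gill": {t: list(v) for t, v in self.gill.items()},
            "condition_factor": list(self.condition_factor),
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        cfg = cls(
            seed=int(d.get("seed", 0)),
            years=tuple(d["years"]),
            n_per_treatment={t: int(n) for t, n in d["n_per_treatment"].items()},
            male_fraction={t: float(v) for t, v in d["male_fraction"].items()},
            stage_probs={t: tuple(v) for t, v in d["stage_probs"].items()},
            markers={t: {m: MarkerSpec(marker=m, scale=s["scale"],
                                       orientation=s.get("orientation", "standard"),
                                       components=tuple(tuple(c) for c in s["components"]))
                         for m, s in per_t.items()}
                     for t, per_t in d["markers"].items()},
            routing={t: {m: StageRouting(
                            immature=None if r["immature"] is None else tuple(r["immature"]),
                            maturing=None if r["maturing"] is None else tuple(r["maturing"]),
                            mature=None if r["mature"] is None else tuple(r["mature"]))
                         for m, r in per_t.items()}
                     for t, per_t in d["routing"].items()},
            fork_routing={t: ForkRouting(**r) for t, r in d["fork_routing"].items()},
            year_effects={m: tuple(v) for m, v in d["year_effects"].items()},
            missingness={m: {t: tuple(v) for t, v in per_t.items()}
                         for m, per_t in d["missingness"].items()},
            mature_gsi_missing_years=tuple(d.get("mature_gsi_missing_years", ())),
            phenotype_probs={t: tuple(v) for t, v in d["phenotype_probs"].items()},
            gill={t: tuple(v) for t, v in d["gill"].items()},
            condition_factor=tuple(d.get("condition_factor", (1.10, 0.07))),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class LabeledCohort:
    """A generated cohort plus ground truth and generating thresholds."""

    cohort: Cohort
    truth: pd.DataFrame
    thresholds: dict[str, dict[str, ThresholdSet]]
    fork_thresholds: dict[str, float]
    config: SyntheticConfig


# --------------------------------------------------------------------------
# default configuration

def pair_lower_mean(target: float, mu_high: float, w_low: float,
                    w_high: float, sd: float) -> float:
    """Lower mean of an equal-sd pair whose intersection equals ``target``.

    For equal sds the weighted-density intersection is
    t = (mu_low + mu_high)/2 + sd^2 * ln(w_low/w_high) / (mu_high - mu_low),
    which solves in closed form for the separation d = mu_high - mu_low.
    """
    a = mu_high - target
    if a <= 0:
        raise ConfigError("mu_high must exceed the target intersection")
    disc = a * a + 2.0 * sd * sd * math.log(w_low / w_high)
    if disc <= 0:
        raise ConfigError("no equal-sd pair with this intersection exists "
                          "(weight imbalance too extreme for the separation)")
    return mu_high - (a + math.sqrt(disc))


def _solve_pair(t1: float, mu_high: float, w: Sequence[float],
                sd: float) -> tuple[float, float]:
    mu_low = pair_lower_mean(t1, mu_high, w[0], w[1], sd)
    return mu_low, mu_high


def _solve_triple(t1: float, t2: float, mu_top: float, w: Sequence[float],
                  sd: float) -> tuple[float, float, float]:
    mu_mid = pair_lower_mean(t2, mu_top, w[1], w[2], sd)
    if not t1 < mu_mid < t2:
        raise ConfigError("middle component mean fell outside (t1, t2)")
    mu_low = pair_lower_mean(t1, mu_mid, w[0], w[1], sd)
    return mu_low, mu_mid, mu_top


def pair_upper_mean(target: float, mu_low: float, w_low: float,
                    w_high: float, sd_low: float, sd_high: float) -> float:
    """Upper mean (possibly with its own sd) whose weighted density equals
    the lower component's at ``target``; inverse of the intersection."""
    z = (target - mu_low) / sd_low
    arg = 2.0 * math.log(w_high * sd_low / (w_low * sd_high)) + z * z
    if arg <= 0:
        raise ConfigError("no upper component places the intersection at "
                          "the target with these weights/sds")
    return target + sd_high * math.sqrt(arg)


def _solve_triple_centered(t1: float, t2: float, w: Sequence[float],
                           sd: float, sd_top: Optional[float] = None
                           ) -> tuple[tuple[float, float, float],
                                      tuple[float, float, float]]:
    """Means/sds for a trimodal spec with the middle mode centred between
    its two thresholds (balanced valleys on both sides).  ``sd_top`` lets
    the upper mode be tighter than the rest."""
    sd_top = sd if sd_top is None else sd_top
    mu_mid = 0.5 * (t1 + t2)
    mu_top = pair_upper_mean(t2, mu_mid, w[1], w[2], sd, sd_top)
    mu_low = pair_lower_mean(t1, mu_mid, w[0], w[1], sd)
    return (mu_low, mu_mid, mu_top), (sd, sd, sd_top)


def _spec(marker, scale, weights, means, sd, orientation="standard"):
    sds = (sd,) * len(weights) if np.isscalar(sd) else tuple(sd)
    return MarkerSpec(marker=marker, scale=scale,
                      components=tuple((float(w), float(m), float(s))
                                       for w, m, s in zip(weights, means, sds)),
                      orientation=orientation)


def default_paper_config(n_per_treatment: int = 1500,
                         seed: int = 0) -> SyntheticConfig:
    """The default study-shaped configuration.

    Latent male stage probabilities are S1 immature/maturing/mature =
    0.718/0.280/0.002 and S2 = 0.631/0.280/0.089 (milt rates 3/1496 and
    133/1497 at study scale); component means are solved so that every
    generating intersection equals the published threshold exactly.
    """
    L = math.log10
    stage = {"S1": (0.718, 0.280, 0.002), "S2": (0.631, 0.280, 0.089)}
    male_frac = {"S1": 0.5, "S2": 0.5}

    markers: dict[str, dict[str, MarkerSpec]] = {"S1": {}, "S2": {}}
    routing: dict[str, dict[str, StageRouting]] = {"S1": {}, "S2": {}}
    fork_specs: dict[str, MarkerSpec] = {}
    fork_routing = {"S1": ForkRouting(female_lower=0.206, immature_lower=0.206),
                    "S2": ForkRouting(female_lower=0.2281, immature_lower=0.2281)}

    def norm(w):
        w = np.asarray(w, dtype=float)
        return tuple(w / w.sum())

    # fork length: bimodal, raw mm, fitted on all fish of a treatment.
    fork_targets = {"S1": (146.6, 172.0, 8.5), "S2": (147.6, 176.0, 8.5)}
    for t, (thr, mu_hi, sd) in fork_targets.items():
        fr = fork_routing[t]
        p = stage[t]
        w_low = (0.5 * fr.female_lower
                 + 0.5 * (p[0] * fr.immature_lower + p[1] * fr.maturing_lower
                          + p[2] * fr.mature_lower))
        w = norm([w_low, 1.0 - w_low])
        means = _solve_pair(thr, mu_hi, w, sd)
        fork_specs[t] = _spec("fork_length", "raw", w, means, sd)

    def add(t, marker, spec, imm, mat, mature):
        markers[t][marker] = spec
        routing[t][marker] = StageRouting(immature=imm, maturing=mat,
                                          mature=mature)

    for t in ("S1", "S2"):
        p = stage[t]
        # trimodal GSI / 11KT: advanced maturing males reach the top mode
        # alongside milt males (a larger share for S1, whose milt rate is
        # far too small to populate a mode on its own).
        f_up = {"S1": 0.25, "S2": 0.15}[t]
        w3 = norm([p[0], p[1] * (1 - f_up), p[1] * f_up + p[2]])
        r3 = (0.0, 1.0 - f_up, f_up)
        gsi_t = {"S1": (L(0.051), L(0.627)), "S2": (L(0.056), L(0.962))}[t]
        means, sds = _solve_triple_centered(gsi_t[0], gsi_t[1], w3, 0.14)
        add(t, "gsi", _spec("gsi", "log10", w3, means, sds),
            (1.0, 0.0, 0.0), r3, (0.0, 0.0, 1.0))
        kt_t = {"S1": (L(0.88), L(23.08)), "S2": (L(0.97), L(15.81))}[t]
        means, sds = _solve_triple_centered(kt_t[0], kt_t[1], w3, 0.15)
        add(t, "kt11", _spec("kt11", "log10", w3, means, sds),
            (1.0, 0.0, 0.0), r3, (0.0, 0.0, 1.0))
        # trimodal igf3, unmeasurable in spermiating (milt) males; 30% of
        # maturing males sit in the upper mode.
        f_ig = 0.35
        wig = norm([p[0], p[1] * (1 - f_ig), p[1] * f_ig])
        ig_t = {"S1": (L(6.2), L(14.8), 1.30), "S2": (L(6.2), L(16.6), 1.35)}[t]
        add(t, "igf3", _spec("igf3", "log10", wig,
                             _solve_triple(ig_t[0], ig_t[1], ig_t[2], wig, 0.06),
                             0.06),
            (1.0, 0.0, 0.0), (0.0, 1.0 - f_ig, f_ig), None)

    # pituitary fshb: S1 unimodal (uninformative), S2 bimodal at 270.
    add("S1", "fshb", _spec("fshb", "log10", (1.0,), (2.30,), 0.30),
        (1.0,), (1.0,), (1.0,))
    w = norm([stage["S2"][0], stage["S2"][1] + stage["S2"][2]])
    add("S2", "fshb", _spec("fshb", "log10", w,
                            _solve_pair(L(270.0), 2.95, w, 0.20), 0.20),
        (1.0, 0.0), (0.0, 1.0), (0.0, 1.0))

    # pituitary lhb: S1 bimodal at 44.7; S2 trimodal at 94.9 / 11306.5 with
    # the top mode holding milt males.
    w = norm([stage["S1"][0], stage["S1"][1] + stage["S1"][2]])
    add("S1", "lhb", _spec("lhb", "log10", w,
                           _solve_pair(L(44.7), 2.10, w, 0.18), 0.18),
        (1.0, 0.0), (0.0, 1.0), (0.0, 1.0))
    w = norm(stage["S2"])
    # the mature (milt) mode saturates high and is modelled tighter than
    # the immature/maturing modes
    means, sds = _solve_triple_centered(L(94.9), L(11306.5), w, 0.25,
                                        sd_top=0.12)
    add("S2", "lhb", _spec("lhb", "log10", w, means, sds),
        (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

    # testis amh: falls with maturation onset (inverted); S1 unimodal,
    # S2 bimodal at 2.7; unmeasurable in milt males.
    add("S1", "amh", _spec("amh", "log10", (1.0,), (0.50,), 0.25, "inverted"),
        (1.0,), (1.0,), None)
    p = stage["S2"]
    w = norm([p[1], p[0]])  # ascending mean: maturing (low) then immature
    add("S2", "amh", _spec("amh", "log10", w,
                           _solve_pair(L(2.7), 0.85, w, 0.18), 0.18, "inverted"),
        (0.0, 1.0), (1.0, 0.0), None)

    years = (2011, 2012, 2013, 2014, 2015)
    # between-year shifts stay well below the within-mode sd so that pooled
    # fits see modes, not year substructure
    year_effects = {"fork_length": (-2.0, -1.0, 0.0, 1.0, 2.0)}
    for m in MATURATION_MARKERS:
        year_effects[m] = (-0.03, -0.015, 0.0, 0.015, 0.03)
    year_effects["igf3"] = (-0.012, -0.006, 0.0, 0.006, 0.012)

    # study-shaped missingness: testis mRNA in the first two years only,
    # gill ATPase on 200 of ~600 fish in 2012-2015 and never in 2011.
    missingness: dict[str, dict[str, tuple[float, ...]]] = {}
    for m, rates in {
        "fshb": (0.03,) * 5,
        "lhb": (0.03,) * 5,
        "amh": (0.03, 0.03, 1.0, 1.0, 1.0),
        "igf3": (0.03, 0.03, 1.0, 1.0, 1.0),
        "kt11": (0.03,) * 5,
        "gsi": (0.01,) * 5,
        "gill_atpase": (1.0, 2 / 3, 2 / 3, 2 / 3, 2 / 3),
    }.items():
        missingness[m] = {"S1": rates, "S2": rates}

    cfg = SyntheticConfig(
        seed=seed,
        years=years,
        n_per_treatment={"S1": n_per_treatment, "S2": n_per_treatment},
        male_fraction=male_frac,
        stage_probs=stage,
        markers=markers,
        routing=routing,
        fork_routing=fork_routing,
        year_effects=year_effects,
        missingness=missingness,
        mature_gsi_missing_years=(2014, 2015),
        phenotype_probs={"S1": (0.123, 0.568, 0.309),
                         "S2": (0.040, 0.612, 0.348)},
        gill={"S1": (4.0, 1.2), "S2": (4.5, 1.2)},
    )
    # fork specs ride along in the marker tables under their own key
    for t in ("S1", "S2"):
        cfg.markers[t]["fork_length"] = fork_specs[t]
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# generation

def _stream(seed: int, name: str) -> np.random.Generator:
    """A named, seed-derived random stream (stable across config changes)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _categorical(rng: np.random.Generator, probs: np.ndarray,
                 n: int) -> np.ndarray:
    u = rng.random(n)
    return (u[:, None] >= np.cumsum(probs)[None, :-1]).sum(axis=1)


def generating_thresholds(config: SyntheticConfig
                          ) -> tuple[dict[str, dict[str, ThresholdSet]],
                                     dict[str, float]]:
    """Analytic intersections of the generating components, as ThresholdSets."""
    marker_ts: dict[str, dict[str, ThresholdSet]] = {}
    fork_ts: dict[str, float] = {}
    for t in config.treatments:
        marker_ts[t] = {}
        for m, spec in config.markers[t].items():
            cuts = spec.intersections()
            if m == "fork_length":
                fork_ts[t] = cuts[0] if cuts else math.nan
                continue
            back = (lambda v: 10.0 ** v) if spec.scale == "log10" else (lambda v: v)
            t1 = back(cuts[0]) if len(cuts) >= 1 else None
            t2 = back(cuts[1]) if len(cuts) >= 2 else None
            marker_ts[t][m] = ThresholdSet(metric=m, treatment=t,
                                           scale=spec.scale, threshold1=t1,
                                           threshold2=t2,
                                           orientation=spec.orientation)
    return marker_ts, fork_ts


def generate_cohort(config: SyntheticConfig) -> LabeledCohort:
    """Generate a labelled cohort; byte-identical output for a given seed."""
    config.validate()
    seed = config.seed
    years = np.asarray(config.years)
    n_years = len(years)
    frames = []
    truth_frames = []

    for t in config.treatments:
        n = config.n_per_treatment[t]
        base = n // n_years
        counts = np.full(n_years, base)
        counts[: n - base * n_years] += 1
        year_idx = np.repeat(np.arange(n_years), counts)

        rs = _stream(seed, f"{t}/structure")
        male = rs.random(n) < config.male_fraction[t]
        stage = np.zeros(n, dtype=int)
        stage[male] = _categorical(rs, np.asarray(config.stage_probs[t]),
                                   int(male.sum()))
        milt = male & (stage == 2)

        # fork length -----------------------------------------------------
        spec = config.markers[t]["fork_length"]
        fr = config.fork_routing[t]
        p_low = np.where(~male, fr.female_lower,
                         np.choose(stage, [fr.immature_lower,
                                           fr.maturing_lower,
                                           fr.mature_lower]))
        rf = _stream(seed, f"{t}/fork_length")
        if len(spec.components) == 1:
            fork_comp = np.zeros(n, dtype=int)
            rf.random(n)  # keep the stream aligned with the bimodal case
        else:
            fork_comp = (rf.random(n) >= p_low).astype(int)
        mu = np.array([c[1] for c in spec.components])
        sd = np.array([c[2] for c in spec.components])
        shift = np.asarray(config.year_effects.get("fork_length", (0.0,) * n_years))
        fork = rf.normal(mu[fork_comp] + shift[year_idx], sd[fork_comp])
        fork = np.maximum(fork, 30.0)  # physical floor, never binds in practice

        rw = _stream(seed, f"{t}/body_weight")
        k_mean, k_sd = config.condition_factor
        K = np.maximum(rw.normal(k_mean, k_sd, n), 0.5)
        weight = K * (fork / 10.0) ** 3 / 100.0

        rp = _stream(seed, f"{t}/phenotype")
        pheno_idx = _categorical(rp, np.asarray(config.phenotype_probs[t]), n)
        phenotype = np.array(["parr", "transitional", "smolt"])[pheno_idx]
        phenotype[milt] = "transitional"  # milt males are their own category

        rg = _stream(seed, f"{t}/gill_atpase")
        g_mean, g_sd = config.gill[t]
        gill = np.maximum(rg.normal(g_mean, g_sd, n), 0.05)
        g_rates = np.asarray(config.missingness.get(
            "gill_atpase", {}).get(t, (0.0,) * n_years))
        gill_missing = rg.random(n) < g_rates[year_idx]
        gill = np.where(gill_missing, np.nan, gill)

        # maturation markers (males only) ----------------------------------
        values: dict[str, np.ndarray] = {}
        comps: dict[str, np.ndarray] = {}
        for m in MATURATION_MARKERS:
            spec = config.markers[t][m]
            route = config.routing[t][m]
            rm = _stream(seed, f"{t}/{m}")
            comp = np.full(n, -1, dtype=int)
            val = np.full(n, np.nan)
            mu = np.array([c[1] for c in spec.components])
            sd = np.array([c[2] for c in spec.components])
            shift = np.asarray(config.year_effects.get(m, (0.0,) * n_years))
            u_comp = rm.random(n)
            z = rm.standard_normal(n)
            u_miss = rm.random(n)
            for s in range(3):
                row = route.row(s)
                sel = male & (stage == s)
                if row is None or not sel.any():
                    continue
                cum = np.cumsum(np.asarray(row))[:-1]
                comp[sel] = (u_comp[sel, None] >= cum[None, :]).sum(axis=1)
                val[sel] = mu[comp[sel]] + shift[year_idx[sel]] + sd[comp[sel]] * z[sel]
            if spec.scale == "log10":
                val = 10.0 ** val
            # missingness, applied after generation
            rates = np.asarray(config.missingness.get(m, {}).get(t, (0.0,) * n_years))
            miss = u_miss < rates[year_idx]
            if m == "gsi":
                miss |= milt & np.isin(years[year_idx],
                                       config.mature_gsi_missing_years)
            val[miss] = np.nan
            values[m] = val
            comps[m] = comp

        gsi = values["gsi"]
        gonad_weight = gsi * weight / 100.0

        ids = np.array([f"{t}-{years[yi]}-{i:05d}"
                        for i, yi in enumerate(year_idx)])
        frames.append(pd.DataFrame({
            "fish_id": ids,
            "release_year": years[year_idx],
            "treatment": t,
            "sex": np.where(male, "male", "female"),
            "fork_length_mm": fork,
            "body_weight_g": weight,
            "gill_atpase": gill,
            "smolt_phenotype": phenotype,
            "milt_expressed": milt,
            "gonad_weight_g": gonad_weight,
            "fshb": values["fshb"],
            "lhb": values["lhb"],
            "amh": values["amh"],
            "igf3": values["igf3"],
            "kt11": values["kt11"],
            "gsi_pct": gsi,
        }))
        tdf = pd.DataFrame({
            "fish_id": ids,
            "treatment": t,
            "sex": np.where(male, "male", "female"),
            "stage": np.array(STAGES)[stage],
            "fork_length_component": fork_comp,
        })
        tdf.loc[~male, "stage"] = "immature"
        for m in MATURATION_MARKERS:
            tdf[f"{m}_component"] = comps[m]
        truth_frames.append(tdf)

    data = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    cohort = Cohort(data=data, provenance=f"synthetic:seed={seed}")

    marker_ts, fork_ts = generating_thresholds(config)
    calls = classify_cohort(cohort, marker_ts, fork_ts)
    truth = truth.merge(
        calls[["fish_id", "maturation_status", "migration_status"]]
        .rename(columns={"maturation_status": "true_maturation",
                         "migration_status": "true_migration"}),
        on="fish_id", validate="one_to_one")
    return LabeledCohort(cohort=cohort, truth=truth, thresholds=marker_ts,
                         fork_thresholds=fork_ts, config=config)


def truth_summary(labeled: LabeledCohort) -> pd.DataFrame:
    """True status proportions by treatment and sex (tidy table)."""
    calls_like = labeled.truth.rename(
        columns={"true_maturation": "maturation_status",
                 "true_migration": "migration_status"})
    return summarize_calls(calls_like[["fish_id", "treatment", "sex",
                                       "maturation_status",
                                       "migration_status"]])
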