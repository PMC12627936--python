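"""Model parameterization: types, validation, file I/O and synthesis.

The parameter file is a single structured YAML document (versioned header,
human-diffable) so that a published supplementary parameter list can be
transcribed into it verbatim.  Every scalar or vector may carry an optional
distribution tag used by the probabilistic sensitivity analysis; untagged
values are treated as fixed.
"""

from __future__ import annotations

import copy
import enum
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

SCHEMA_VERSION = 1

__all__ = [
    "ControlState",
    "DistributionSpec",
    "Utilities",
    "AgeAdjustmentBand",
    "Costs",
    "ParameterSet",
    "LifeTable",
    "SchemaError",
    "ValidationError",
    "load_parameters",
    "write_parameters",
    "validate_parameters",
    "default_parameters",
    "random_plausible_parameters",
    "load_life_table",
    "write_life_table",
    "default_life_table",
    "weekly_mortality",
]


class SchemaError(ValueError):
    """A parameter file does not conform to the documented schema."""


class ValidationError(ValueError):
    """A parameter set violates one or more of its invariants."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class ControlState(enum.IntEnum):
    """The five mutually exclusive health states of the weekly model.

    ``DEAD`` is absorbing; asthma-specific death is reachable only from
    ``EXACERBATION`` (background mortality applies from every alive state).
    """

    CONTROLLED = 0
    PARTIALLY_CONTROLLED = 1
    UNCONTROLLED = 2
    EXACERBATION = 3
    DEAD = 4


#: The three symptom-control states, in occupancy-vector order.
CONTROL_STATES = (
    ControlState.CONTROLLED,
    ControlState.PARTIALLY_CONTROLLED,
    ControlState.UNCONTROLLED,
)

_STATE_KEYS = {
    ControlState.CONTROLLED: "controlled",
    ControlState.PARTIALLY_CONTROLLED: "partially_controlled",
    ControlState.UNCONTROLLED: "uncontrolled",
    ControlState.EXACERBATION: "exacerbation",
}
_KEY_STATES = {v: k for k, v in _STATE_KEYS.items()}


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution attached to a parameter for the PSA.

    ``mean`` is the deterministic point value; ``fixed`` tags return it
    exactly when sampled.  Supported families follow standard
    decision-model conventions: ``beta`` (probabilities and utilities),
    ``gamma`` (costs), ``lognormal`` (odds ratios), ``dirichlet``
    (probability vectors) and ``fixed``.
    """

    family: str
    params: tuple[float, ...]
    mean: float | tuple[float, ...] | None = None

    _FAMILIES = ("fixed", "beta", "gamma", "lognormal", "dirichlet")

    def validate(self, name: str = "distribution") -> list[str]:
        v: list[str] = []
        if self.family not in self._FAMILIES:
            return [f"{name}: unknown family {self.family!r}"]
        p = self.params
        if self.family == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                v.append(f"{name}: beta requires two shape parameters > 0, got {p}")
            elif self.mean is not None and not 0 <= float(self.mean) <= 1:
                v.append(f"{name}: beta mean {self.mean} outside [0, 1]")
        elif self.family == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                v.append(f"{name}: gamma requires shape > 0 and scale > 0, got {p}")
            elif self.mean is not None and float(self.mean) < 0:
                v.append(f"{name}: gamma mean {self.mean} outside [0, inf)")
        elif self.family == "lognormal":
            if len(p) != 2 or not math.isfinite(p[0]) or p[1] <= 0:
                v.append(
                    f"{name}: lognormal requires finite log-scale and shape > 0, got {p}"
                )
            elif self.mean is not None and float(self.mean) <= 0:
                v.append(f"{name}: lognormal mean {self.mean} outside (0, inf)")
        elif self.family == "dirichlet":
            if len(p) < 2 or any(c <= 0 for c in p):
                v.append(f"{name}: dirichlet requires concentrations > 0, got {p}")
            elif self.mean is not None:
                m = np.asarray(self.mean, dtype=float)
                if abs(float(m.sum()) - 1.0) > 1e-9:
                    v.append(f"{name}: dirichlet mean must sum to 1, got {m.tolist()}")
        return v

    def sample(self, rng: np.random.Generator):
        """Draw one value (scalar, or vector for dirichlet)."""
        if self.family == "fixed":
            return self.mean
        if self.family == "beta":
            return float(rng.beta(self.params[0], self.params[1]))
        if self.family == "gamma":
            return float(rng.gamma(self.params[0], self.params[1]))
        if self.family == "lognormal":
            return float(rng.lognormal(self.params[0], self.params[1]))
        if self.family == "dirichlet":
            return rng.dirichlet(np.asarray(self.params, dtype=float))
        raise ValueError(f"unknown family {self.family!r}")


@dataclass
class Utilities:
    """Per-state EQ-5D-style utilities; exacerbation split by admission."""

    controlled: float
    partially_controlled: float
    uncontrolled: float
    exacerbation_admitted: float
    exacerbation_nonadmitted: float


@dataclass(frozen=True)
class AgeAdjustmentBand:
    """Multiplicative utility decrement applying from ``age_from`` upward."""

    age_from: int
    female: float
    male: float


@dataclass
class Costs:
    """Unit costs, 2022 GBP, NHS/PSS perspective.

    ``maintenance_weekly`` is the weekly maintenance-therapy cost at full
    adherence, pre-weighted across treatment steps.  ``rescue_weekly`` is
    indexed by alive state (controlled, partially controlled, uncontrolled,
    exacerbation).  Exacerbation costs are per episode.
    """

    maintenance_weekly: float
    outpatient_visit: float
    rescue_weekly: np.ndarray
    exacerbation_nonadmitted: float
    exacerbation_admitted: float

    def __post_init__(self):
        self.rescue_weekly = np.asarray(self.rescue_weekly, dtype=float)


@dataclass
class ParameterSet:
    """Every numeric input of the model, with optional distribution tags.

    Vector fields indexed over control states use the order
    (controlled, partially controlled, uncontrolled).
    ``full_adherence_transitions`` is a 3x4 array of weekly *move*
    probabilities from each control state to (controlled, partially
    controlled, uncontrolled, exacerbation); the diagonal is zero and the
    residual mass in each row is the probability of staying put, resolved
    at transition-matrix construction.
    """

    initial_distribution: np.ndarray
    full_adherence_transitions: np.ndarray
    exacerbation_recovery: np.ndarray
    zero_adherence_odds_ratios: np.ndarray
    exacerbation_case_fatality: float
    admitted_fraction: float
    utilities: Utilities
    utility_age_adjustment: list[AgeAdjustmentBand]
    costs: Costs
    outpatient_interval_weeks: np.ndarray
    discount_rate_annual: float = 0.035
    horizon_years: float = 20.0
    cycles_per_year: int = 52
    cohort_start_age: float = 40.0
    sex_mix_female: float = 0.5
    distributions: dict[str, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self):
        self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
        self.full_adherence_transitions = np.asarray(
            self.full_adherence_transitions, dtype=float
        )
        self.exacerbation_recovery = np.asarray(self.exacerbation_recovery, dtype=float)
        self.zero_adherence_odds_ratios = np.asarray(
            self.zero_adherence_odds_ratios, dtype=float
        )
        self.outpatient_interval_weeks = np.asarray(
            self.outpatient_interval_weeks, dtype=float
        )

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def utility_adjustment(self, age: float) -> float:
        """Sex-mix-weighted multiplicative utility adjustment at ``age``."""
        factor_f = factor_m = 1.0
        for band in self.utility_age_adjustment:
            if age >= band.age_from:
                factor_f, factor_m = band.female, band.male
        return self.sex_mix_female * factor_f + (1.0 - self.sex_mix_female) * factor_m


# ---------------------------------------------------------------------------
# Path addressing (used by distribution tags and the PSA sampler)
# ---------------------------------------------------------------------------

_INDEX_RE = re.compile(r"\[([0-9]+(?:\s*,\s*[0-9]+)*)\]$")


def _split_path(path: str) -> tuple[list[str], tuple[int, ...] | None]:
    idx = None
    m = _INDEX_RE.search(path)
    if m:
        idx = tuple(int(s) for s in m.group(1).split(","))
        path = path[: m.start()]
    return path.split("."), idx


def get_by_path(p: ParameterSet, path: str):
    """Resolve a dotted/indexed path like ``costs.rescue_weekly[2]``."""
    attrs, idx = _split_path(path)
    obj = p
    for a in attrs:
        obj = getattr(obj, a)
    if idx is not None:
        obj = obj[idx if len(idx) > 1 else idx[0]]
    return obj


def set_by_path(p: ParameterSet, path: str, value) -> None:
    attrs, idx = _split_path(path)
    obj = p
    for a in attrs[:-1]:
        obj = getattr(obj, a)
    if idx is None:
        current = getattr(obj, attrs[-1])
        if isinstance(current, np.ndarray):
            value = np.asarray(value, dtype=float).reshape(current.shape)
        setattr(obj, attrs[-1], value)
    else:
        arr = getattr(obj, attrs[-1])
        arr[idx if len(idx) > 1 else idx[0]] = value


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_prob(v: list[str], name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        v.append(f"{name} = {value} outside [0, 1]")


def validate_parameters(p: ParameterSet) -> list[str]:
    """Return a description of every violated invariant (empty iff valid).

    Reports, never raises: each entry names the field, the offending value
    and the rule broken.
    """
    v: list[str] = []

    init = p.initial_distribution
    if init.shape != (3,):
        v.append(f"initial_distribution has shape {init.shape}, expected (3,)")
    else:
        for i, st in enumerate(CONTROL_STATES):
            _check_prob(v, f"initial_distribution[{_STATE_KEYS[st]}]", init[i])
        if abs(float(init.sum()) - 1.0) > 1e-9:
            v.append(
                f"initial_distribution sums to {float(init.sum())!r}, must sum to 1"
            )

    trans = p.full_adherence_transitions
    if trans.shape != (3, 4):
        v.append(
            f"full_adherence_transitions has shape {trans.shape}, expected (3, 4)"
        )
    else:
        for i, origin in enumerate(CONTROL_STATES):
            for j in range(4):
                dest = _STATE_KEYS[ControlState(j)]
                _check_prob(
                    v,
                    f"full_adherence_transitions[{_STATE_KEYS[origin]}->{dest}]",
                    trans[i, j],
                )
            if trans[i, i] != 0.0:
                v.append(
                    f"full_adherence_transitions[{_STATE_KEYS[origin]}] has a nonzero "
                    f"self-transition {trans[i, i]}; stay probability is the residual"
                )
            row_sum = float(trans[i].sum())
            if row_sum > 1.0 + 1e-12:
                v.append(
                    f"full_adherence_transitions[{_STATE_KEYS[origin]}] move "
                    f"probabilities sum to {row_sum} > 1"
                )

    rec = p.exacerbation_recovery
    if rec.shape != (3,):
        v.append(f"exacerbation_recovery has shape {rec.shape}, expected (3,)")
    else:
        for i, st in enumerate(CONTROL_STATES):
            _check_prob(v, f"exacerbation_recovery[{_STATE_KEYS[st]}]", rec[i])
        if abs(float(rec.sum()) - 1.0) > 1e-9:
            v.append(
                f"exacerbation_recovery sums to {float(rec.sum())!r}, must sum to 1"
            )

    ors = p.zero_adherence_odds_ratios
    if ors.shape != (3,):
        v.append(f"zero_adherence_odds_ratios has shape {ors.shape}, expected (3,)")
    else:
        for i, st in enumerate(CONTROL_STATES):
            if not ors[i] > 0:
                v.append(
                    f"zero_adherence_odds_ratios[{_STATE_KEYS[st]}] = {ors[i]} "
                    "must be > 0"
                )

    _check_prob(v, "exacerbation_case_fatality", p.exacerbation_case_fatality)
    _check_prob(v, "admitted_fraction", p.admitted_fraction)
    _check_prob(v, "sex_mix_female", p.sex_mix_female)

    for name in (
        "controlled",
        "partially_controlled",
        "uncontrolled",
        "exacerbation_admitted",
        "exacerbation_nonadmitted",
    ):
        u = getattr(p.utilities, name)
        if not -1.0 <= u <= 1.0:
            v.append(f"utilities.{name} = {u} outside [-1, 1]")

    ages = [b.age_from for b in p.utility_age_adjustment]
    if ages != sorted(ages):
        v.append(f"utility_age_adjustment ages {ages} not sorted")
    for b in p.utility_age_adjustment:
        if b.female < 0 or b.male < 0:
            v.append(
                f"utility_age_adjustment band at age {b.age_from} has a negative factor"
            )

    for name in (
        "maintenance_weekly",
        "outpatient_visit",
        "exacerbation_nonadmitted",
        "exacerbation_admitted",
    ):
        c = getattr(p.costs, name)
        if c < 0:
            v.append(f"costs.{name} = {c} must be >= 0")
    if p.costs.rescue_weekly.shape != (4,):
        v.append(
            f"costs.rescue_weekly has shape {p.costs.rescue_weekly.shape}, "
            "expected (4,)"
        )
    else:
        for j in range(4):
            if p.costs.rescue_weekly[j] < 0:
                v.append(
                    f"costs.rescue_weekly[{_STATE_KEYS[ControlState(j)]}] = "
                    f"{p.costs.rescue_weekly[j]} must be >= 0"
                )

    if p.outpatient_interval_weeks.shape != (3,):
        v.append(
            f"outpatient_interval_weeks has shape {p.outpatient_interval_weeks.shape},"
            " expected (3,)"
        )
    else:
        for i, st in enumerate(CONTROL_STATES):
            if not p.outpatient_interval_weeks[i] > 0:
                v.append(
                    f"outpatient_interval_weeks[{_STATE_KEYS[st]}] = "
                    f"{p.outpatient_interval_weeks[i]} must be > 0"
                )

    if not 0.0 <= p.discount_rate_annual < 1.0:
        v.append(f"discount_rate_annual = {p.discount_rate_annual} outside [0, 1)")
    if not p.horizon_years > 0:
        v.append(f"horizon_years = {p.horizon_years} must be > 0")
    if not (isinstance(p.cycles_per_year, (int, np.integer)) and p.cycles_per_year >= 1):
        v.append(f"cycles_per_year = {p.cycles_per_year} must be a positive integer")
    if p.cohort_start_age < 0:
        v.append(f"cohort_start_age = {p.cohort_start_age} must be >= 0")

    for path, spec in p.distributions.items():
        v.extend(spec.validate(f"distributions[{path}]"))
        try:
            get_by_path(p, path)
        except (AttributeError, IndexError, TypeError):
            v.append(f"distributions[{path}] does not address a parameter field")

    return v


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

def default_parameters(tagged: bool = True) -> ParameterSet:
    """The parameter fixture shipped with the package.

    Provenance of each value:

    * printed in the source publication: initial distribution
      (0.205 / 0.394 / 0.401 over controlled / partially controlled /
      uncontrolled), admitted fraction 0.39, 3.5%/yr discounting, 20-year
      horizon, weekly cycles, outpatient intervals (6-monthly / 3-monthly /
      monthly);
    * documented plausible stand-ins (replaceable by transcribing the
      deposited supplementary parameter list): weekly transition
      probabilities, odds ratios, case fatality, utilities, unit costs,
      cohort start age 40 and 50/50 sex mix.
    """
    p = ParameterSet(
        # paper: 20.5% controlled / 39.4% partly / 40.1% uncontrolled
        initial_distribution=np.array([0.205, 0.394, 0.401]),
        # stand-in weekly move probabilities at full adherence; diagonal
        # (stay) is the residual.  Order: C, PC, U, exacerbation.
        full_adherence_transitions=np.array(
            [
                [0.000, 0.089, 0.005, 0.002],
                [0.075, 0.000, 0.045, 0.006],
                [0.015, 0.090, 0.000, 0.015],
            ]
        ),
        # stand-in: post-exacerbation return mostly to poorer control
        exacerbation_recovery=np.array([0.15, 0.35, 0.50]),
        # stand-in OR for exacerbation entry at zero adherence vs full
        zero_adherence_odds_ratios=np.array([2.5, 2.5, 2.5]),
        # stand-in weekly probability of asthma death while in exacerbation
        exacerbation_case_fatality=0.010,
        admitted_fraction=0.39,  # paper: 39% admitted / 61% non-admitted
        # stand-in EQ-5D-style utilities
        utilities=Utilities(
            controlled=0.89,
            partially_controlled=0.80,
            uncontrolled=0.68,
            exacerbation_admitted=0.33,
            exacerbation_nonadmitted=0.57,
        ),
        # stand-in multiplicative age/sex decrements (population-norm style)
        utility_age_adjustment=[
            AgeAdjustmentBand(0, 1.000, 1.000),
            AgeAdjustmentBand(40, 0.970, 0.965),
            AgeAdjustmentBand(50, 0.940, 0.935),
            AgeAdjustmentBand(60, 0.905, 0.895),
            AgeAdjustmentBand(70, 0.855, 0.845),
            AgeAdjustmentBand(80, 0.790, 0.780),
        ],
        # stand-in 2022 GBP unit costs
        costs=Costs(
            maintenance_weekly=9.0,
            outpatient_visit=160.0,
            rescue_weekly=np.array([0.5, 1.2, 2.5, 3.0]),
            exacerbation_nonadmitted=250.0,
            exacerbation_admitted=3500.0,
        ),
        # paper: 6-monthly / 3-monthly / monthly attendance by control state
        outpatient_interval_weeks=np.array([26.0, 13.0, 13.0 / 3.0]),
        discount_rate_annual=0.035,
        horizon_years=20.0,
        cycles_per_year=52,
        cohort_start_age=40.0,
        sex_mix_female=0.5,
    )
    if tagged:
        p.distributions = _default_distribution_tags(p)
    return p


def _beta_from_mean(mean: float, ess: float) -> DistributionSpec:
    return DistributionSpec("beta", (mean * ess, (1.0 - mean) * ess), mean)


def _gamma_from_mean(mean: float, cv: float = 0.2) -> DistributionSpec:
    shape = 1.0 / cv**2
    return DistributionSpec("gamma", (shape, mean / shape), mean)


def _default_distribution_tags(p: ParameterSet) -> dict[str, DistributionSpec]:
    """Conventional family choices: beta for probabilities and utilities,
    gamma for costs, lognormal for odds ratios, dirichlet for vectors."""
    tags: dict[str, DistributionSpec] = {}
    tags["initial_distribution"] = DistributionSpec(
        "dirichlet",
        tuple(1000.0 * x for x in p.initial_distribution),
        tuple(p.initial_distribution),
    )
    for i in range(3):
        for j in range(4):
            if i == j:
                continue
            mean = float(p.full_adherence_transitions[i, j])
            if mean > 0:
                tags[f"full_adherence_transitions[{i},{j}]"] = _beta_from_mean(
                    mean, 800.0
                )
    tags["exacerbation_recovery"] = DistributionSpec(
        "dirichlet",
        tuple(100.0 * x for x in p.exacerbation_recovery),
        tuple(p.exacerbation_recovery),
    )
    for i in range(3):
        orv = float(p.zero_adherence_odds_ratios[i])
        sigma = 0.18
        tags[f"zero_adherence_odds_ratios[{i}]"] = DistributionSpec(
            "lognormal", (math.log(orv) - sigma**2 / 2.0, sigma), orv
        )
    tags["exacerbation_case_fatality"] = _beta_from_mean(
        p.exacerbation_case_fatality, 1000.0
    )
    tags["admitted_fraction"] = _beta_from_mean(p.admitted_fraction, 1000.0)
    for name in (
        "controlled",
        "partially_controlled",
        "uncontrolled",
        "exacerbation_admitted",
        "exacerbation_nonadmitted",
    ):
        tags[f"utilities.{name}"] = _beta_from_mean(
            getattr(p.utilities, name), 400.0
        )
    for name in (
        "maintenance_weekly",
        "outpatient_visit",
        "exacerbation_nonadmitted",
        "exacerbation_admitted",
    ):
        tags[f"costs.{name}"] = _gamma_from_mean(getattr(p.costs, name))
    for j in range(4):
        tags[f"costs.rescue_weekly[{j}]"] = _gamma_from_mean(
            float(p.costs.rescue_weekly[j])
        )
    return tags


def random_plausible_parameters(seed: int, tagged: bool = True) -> ParameterSet:
    """A valid ParameterSet with values drawn from documented plausible
    ranges; identical seed gives identical output (property-test generator).
    """
    rng = np.random.default_rng(seed)
    init = rng.dirichlet(np.array([2.0, 4.0, 4.0]))

    trans = np.zeros((3, 4))
    for i in range(3):
        # keep total move mass comfortably below 1
        dests = [j for j in range(4) if j != i]
        mass = rng.uniform(0.02, 0.35)
        w = rng.dirichlet(np.ones(len(dests)))
        for j, wj in zip(dests, w):
            trans[i, j] = mass * wj
        # exacerbation entry kept in a low weekly range
        trans[i, 3] = rng.uniform(5e-4, 0.03)

    rec = rng.dirichlet(np.array([2.0, 3.0, 3.0]))
    ors = rng.uniform(1.2, 4.0, size=3)
    case_fatality = rng.uniform(1e-3, 0.03)
    admitted = rng.uniform(0.2, 0.6)

    u_c = rng.uniform(0.80, 0.95)
    u_pc = rng.uniform(0.65, u_c)
    u_u = rng.uniform(0.50, u_pc)
    u_ea = rng.uniform(0.15, 0.45)
    u_en = rng.uniform(u_ea, 0.70)

    p = ParameterSet(
        initial_distribution=init,
        full_adherence_transitions=trans,
        exacerbation_recovery=rec,
        zero_adherence_odds_ratios=ors,
        exacerbation_case_fatality=float(case_fatality),
        admitted_fraction=float(admitted),
        utilities=Utilities(
            controlled=float(u_c),
            partially_controlled=float(u_pc),
            uncontrolled=float(u_u),
            exacerbation_admitted=float(u_ea),
            exacerbation_nonadmitted=float(u_en),
        ),
        utility_age_adjustment=[
            AgeAdjustmentBand(0, 1.0, 1.0),
            AgeAdjustmentBand(60, float(rng.uniform(0.85, 1.0)), float(rng.uniform(0.85, 1.0))),
        ],
        costs=Costs(
            maintenance_weekly=float(rng.uniform(2.0, 30.0)),
            outpatient_visit=float(rng.uniform(50.0, 300.0)),
            rescue_weekly=rng.uniform(0.1, 5.0, size=4),
            exacerbation_nonadmitted=float(rng.uniform(50.0, 500.0)),
            exacerbation_admitted=float(rng.uniform(1000.0, 6000.0)),
        ),
        outpatient_interval_weeks=np.array([26.0, 13.0, 13.0 / 3.0]),
        discount_rate_annual=0.035,
        horizon_years=float(rng.choice([5.0, 10.0, 20.0])),
        cycles_per_year=52,
        cohort_start_age=float(rng.uniform(25.0, 60.0)),
        sex_mix_female=float(rng.uniform(0.3, 0.7)),
    )
    if tagged:
        p.distributions = _default_distribution_tags(p)
    return p


# ---------------------------------------------------------------------------
# Parameter file I/O (YAML schema)
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = (
    "initial_distribution",
    "full_adherence_transitions",
    "exacerbation_recovery",
    "zero_adherence_odds_ratios",
    "exacerbation_case_fatality",
    "admitted_fraction",
    "utilities",
    "costs",
)

_OPTIONAL_DEFAULTS = {
    "outpatient_interval_weeks": [26.0, 13.0, 13.0 / 3.0],
    "discount_rate_annual": 0.035,
    "horizon_years": 20.0,
    "cycles_per_year": 52,
    "cohort_start_age": 40.0,
    "sex_mix_female": 0.5,
}


def _transitions_to_mapping(trans: np.ndarray) -> dict:
    out = {}
    for i, origin in enumerate(CONTROL_STATES):
        row = {}
        for j in range(4):
            if j == i:
                continue
            row[_STATE_KEYS[ControlState(j)]] = float(trans[i, j])
        out[_STATE_KEYS[origin]] = row
    return out


def _transitions_from_mapping(mapping: dict) -> np.ndarray:
    trans = np.zeros((3, 4))
    for i, origin in enumerate(CONTROL_STATES):
        key = _STATE_KEYS[origin]
        if key not in mapping:
            raise SchemaError(f"full_adherence_transitions missing origin {key!r}")
        for dest_key, value in mapping[key].items():
            if dest_key not in _KEY_STATES:
                raise SchemaError(
                    f"full_adherence_transitions[{key}] has unknown destination "
                    f"{dest_key!r}"
                )
            trans[i, int(_KEY_STATES[dest_key])] = float(value)
    return trans


def write_parameters(p: ParameterSet, path: str | Path) -> None:
    """Write a ParameterSet to the YAML parameter file format (UTF-8, LF)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "initial_distribution": [float(x) for x in p.initial_distribution],
        "full_adherence_transitions": _transitions_to_mapping(
            p.full_adherence_transitions
        ),
        "exacerbation_recovery": [float(x) for x in p.exacerbation_recovery],
        "zero_adherence_odds_ratios": [
            float(x) for x in p.zero_adherence_odds_ratios
        ],
        "exacerbation_case_fatality": float(p.exacerbation_case_fatality),
        "admitted_fraction": float(p.admitted_fraction),
        "utilities": {
            k: float(getattr(p.utilities, k))
            for k in (
                "controlled",
                "partially_controlled",
                "uncontrolled",
                "exacerbation_admitted",
                "exacerbation_nonadmitted",
            )
        },
        "utility_age_adjustment": [
            {"age_from": int(b.age_from), "female": float(b.female), "male": float(b.male)}
            for b in p.utility_age_adjustment
        ],
        "costs": {
            "maintenance_weekly": float(p.costs.maintenance_weekly),
            "outpatient_visit": float(p.costs.outpatient_visit),
            "rescue_weekly": [float(x) for x in p.costs.rescue_weekly],
            "exacerbation_nonadmitted": float(p.costs.exacerbation_nonadmitted),
            "exacerbation_admitted": float(p.costs.exacerbation_admitted),
        },
        "outpatient_interval_weeks": [float(x) for x in p.outpatient_interval_weeks],
        "discount_rate_annual": float(p.discount_rate_annual),
        "horizon_years": float(p.horizon_years),
        "cycles_per_year": int(p.cycles_per_year),
        "cohort_start_age": float(p.cohort_start_age),
        "sex_mix_female": float(p.sex_mix_female),
    }
    if p.distributions:
        doc["distributions"] = {
            path_: {
                "family": spec.family,
                "params": [float(x) for x in spec.params],
                "mean": (
                    [float(x) for x in spec.mean]
                    if isinstance(spec.mean, (tuple, list, np.ndarray))
                    else (None if spec.mean is None else float(spec.mean))
                ),
            }
            for path_, spec in p.distributions.items()
        }
    text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)
    Path(path).write_text(text, encoding="utf-8", newline="\n")


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter file.

    Raises :class:`SchemaError` for a missing/unknown field and
    :class:`ValidationError` (listing *every* violation) for invariant
    breaches.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"parameter file not found: {path}")
    doc = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise SchemaError(f"parameter file {path} is not a mapping")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
        )
    missing = [k for k in _REQUIRED_KEYS if k not in doc]
    if missing:
        raise SchemaError(f"parameter file missing required fields: {missing}")

    util = doc["utilities"]
    for k in (
        "controlled",
        "partially_controlled",
        "uncontrolled",
        "exacerbation_admitted",
        "exacerbation_nonadmitted",
    ):
        if k not in util:
            raise SchemaError(f"utilities missing required field {k!r}")
    cost = doc["costs"]
    for k in (
        "maintenance_weekly",
        "outpatient_visit",
        "rescue_weekly",
        "exacerbation_nonadmitted",
        "exacerbation_admitted",
    ):
        if k not in cost:
            raise SchemaError(f"costs missing required field {k!r}")

    bands = [
        AgeAdjustmentBand(int(b["age_from"]), float(b["female"]), float(b["male"]))
        for b in doc.get("utility_age_adjustment", [{"age_from": 0, "female": 1.0, "male": 1.0}])
    ]

    distributions: dict[str, DistributionSpec] = {}
    for path_, d in (doc.get("distributions") or {}).items():
        mean = d.get("mean")
        if isinstance(mean, list):
            mean = tuple(float(x) for x in mean)
        elif mean is not None:
            mean = float(mean)
        distributions[str(path_)] = DistributionSpec(
            str(d["family"]), tuple(float(x) for x in d["params"]), mean
        )

    p = ParameterSet(
        initial_distribution=np.asarray(doc["initial_distribution"], dtype=float),
        full_adherence_transitions=_transitions_from_mapping(
            doc["full_adherence_transitions"]
        ),
        exacerbation_recovery=np.asarray(doc["exacerbation_recovery"], dtype=float),
        zero_adherence_odds_ratios=np.asarray(
            doc["zero_adherence_odds_ratios"], dtype=float
        ),
        exacerbation_case_fatality=float(doc["exacerbation_case_fatality"]),
        admitted_fraction=float(doc["admitted_fraction"]),
        utilities=Utilities(**{k: float(v) for k, v in util.items()}),
        utility_age_adjustment=bands,
        costs=Costs(
            maintenance_weekly=float(cost["maintenance_weekly"]),
            outpatient_visit=float(cost["outpatient_visit"]),
            rescue_weekly=np.asarray(cost["rescue_weekly"], dtype=float),
            exacerbation_nonadmitted=float(cost["exacerbation_nonadmitted"]),
            exacerbation_admitted=float(cost["exacerbation_admitted"]),
        ),
        outpatient_interval_weeks=np.asarray(
            doc.get(
                "outpatient_interval_weeks",
                _OPTIONAL_DEFAULTS["outpatient_interval_weeks"],
            ),
            dtype=float,
        ),
        discount_rate_annual=float(
            doc.get("discount_rate_annual", _OPTIONAL_DEFAULTS["discount_rate_annual"])
        ),
        horizon_years=float(
            doc.get("horizon_years", _OPTIONAL_DEFAULTS["horizon_years"])
        ),
        cycles_per_year=int(
            doc.get("cycles_per_year", _OPTIONAL_DEFAULTS["cycles_per_year"])
        ),
        cohort_start_age=float(
            doc.get("cohort_start_age", _OPTIONAL_DEFAULTS["cohort_start_age"])
        ),
        sex_mix_female=float(
            doc.get("sex_mix_female", _OPTIONAL_DEFAULTS["sex_mix_female"])
        ),
        distributions=distributions,
    )
    violations = validate_parameters(p)
    if violations:
        raise ValidationError(violations)
    return p


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

@dataclass
class LifeTable:
    """Age-indexed annual all-cause mortality probabilities, by sex.

    Ages are strictly increasing and contiguous; lookups beyond the last
    age carry the last row forward.  Tables loaded without a sex column
    use the same probabilities for both sexes.
    """

    ages: np.ndarray
    qx_female: np.ndarray
    qx_male: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx_female = np.asarray(self.qx_female, dtype=float)
        self.qx_male = np.asarray(self.qx_male, dtype=float)
        problems = self._problems()
        if problems:
            raise ValidationError(problems)

    def _problems(self) -> list[str]:
        v = []
        if len(self.ages) == 0:
            return ["life table is empty"]
        diffs = np.diff(self.ages)
        if np.any(diffs <= 0):
            v.append(f"life table ages not strictly increasing: {self.ages.tolist()}")
        elif np.any(diffs != 1):
            v.append(f"life table ages not contiguous: {self.ages.tolist()}")
        for name, qx in (("qx_female", self.qx_female), ("qx_male", self.qx_male)):
            if qx.shape != self.ages.shape:
                v.append(f"life table {name} length mismatch")
            elif np.any((qx < 0) | (qx > 1)):
                v.append(f"life table {name} has probabilities outside [0, 1]")
        return v

    def annual_mortality(self, age: float, sex_mix_female: float = 0.5) -> float:
        """Sex-mix-weighted annual mortality for the row covering ``age``."""
        idx = int(np.clip(int(age) - int(self.ages[0]), 0, len(self.ages) - 1))
        return float(
            sex_mix_female * self.qx_female[idx]
            + (1.0 - sex_mix_female) * self.qx_male[idx]
        )


def weekly_mortality(
    lt: LifeTable,
    age: float,
    cycles_per_year: int = 52,
    sex_mix_female: float = 0.5,
) -> float:
    """Per-cycle mortality via the complement-power (constant-hazard) rule:
    ``1 - (1 - q_annual)**(1/cycles_per_year)``.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    q = lt.annual_mortality(age, sex_mix_female)
    return 1.0 - (1.0 - q) ** (1.0 / cycles_per_year)


def _split_delimited(line: str) -> list[str]:
    for sep in (",", "\t", ";"):
        if sep in line:
            return [tok.strip() for tok in line.split(sep)]
    return line.split()


def load_life_table(path: str | Path) -> LifeTable:
    """Read a delimited life table with columns ``age``, ``qx`` and an
    optional ``sex`` column (``female``/``male``, or ``f``/``m``).

    Parsed with Python's exact float conversion so writes round-trip
    bit-exactly.
    """
    path = Path(path)
    lines = [
        ln
        for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise SchemaError(f"life table {path} is empty")
    header = [c.lower() for c in _split_delimited(lines[0])]
    if "age" not in header or "qx" not in header:
        raise SchemaError(
            f"life table {path} must have columns age, qx[, sex]; got {header}"
        )
    i_age, i_qx = header.index("age"), header.index("qx")
    i_sex = header.index("sex") if "sex" in header else None

    rows: list[tuple[int, float, str]] = []
    for ln in lines[1:]:
        toks = _split_delimited(ln)
        sex = toks[i_sex].lower()[:1] if i_sex is not None else ""
        rows.append((int(float(toks[i_age])), float(toks[i_qx]), sex))

    if i_sex is not None:
        fem = [(a, q) for a, q, s in rows if s == "f"]
        mal = [(a, q) for a, q, s in rows if s == "m"]
        if not fem or not mal or [a for a, _ in fem] != [a for a, _ in mal]:
            raise SchemaError(
                f"life table {path}: female and male rows must cover the same ages"
            )
        return LifeTable(
            ages=np.array([a for a, _ in fem]),
            qx_female=np.array([q for _, q in fem]),
            qx_male=np.array([q for _, q in mal]),
        )
    qx = np.array([q for _, q, _ in rows])
    return LifeTable(ages=np.array([a for a, _, _ in rows]), qx_female=qx, qx_male=qx.copy())


def write_life_table(lt: LifeTable, path: str | Path) -> None:
    lines = ["age,qx,sex"]
    for sex, qx in (("female", lt.qx_female), ("male", lt.qx_male)):
        for a, q in zip(lt.ages, qx):
            lines.append(f"{int(a)},{float(q)!r},{sex}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def default_life_table(max_age: int = 109) -> LifeTable:
    """Synthetic national-style life table (Gompertz hazard, stand-in for
    published ONS tables): ``q(age) = min(0.7, A * exp(B * age))`` with a
    small female survival advantage."""
    ages = np.arange(0, max_age + 1)
    a_f, a_m, b = 1.7e-5, 2.3e-5, 0.0978
    qf = np.minimum(0.7, a_f * np.exp(b * ages))
    qm = np.minimum(0.7, a_m * np.exp(b * ages))
    return LifeTable(ages=ages, qx_female=qf, qx_male=qm)
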