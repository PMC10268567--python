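"""Model inputs: validated parameter containers, probability conversions and
probabilistic-sensitivity distributions.

The model prices three managements of recurrent anterior male urethral
stricture — the Optilume paclitaxel drug-coated balloon, endoscopic
management (dilation / DVIU) and urethroplasty — from the NHS England
perspective at 2019/20 prices.  Trial-reported cumulative recurrence risks
are converted to per-cycle (monthly) probabilities under a constant-hazard
assumption, and median waiting times to retreatment are converted to
per-cycle exit probabilities of a geometric waiting-time distribution.

Parameter uncertainty is described by moment-matched beta distributions for
probabilities/proportions and gamma distributions for costs; where no
confidence interval is available the standard error is taken as 25% of the
mean.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy import stats

#: Mean calendar month length in days (365.25 / 12).
DAYS_PER_MONTH = 365.25 / 12

#: Valid treatment arms, in the order (intervention, base-case comparator,
#: scenario comparator).
ARMS = ("optilume", "endoscopic", "urethroplasty")


class ParameterValidationError(ValueError):
    """Raised when a parameter set violates one or more input contracts.

    ``problems`` lists every offending field so a config can be fixed in
    one pass.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid parameters:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


# ---------------------------------------------------------------------------
# Probability / cost conversions
# ---------------------------------------------------------------------------

def rate_to_probability(cumulative_risk: float, horizon_months: float) -> float:
    """Convert a cumulative risk over ``horizon_months`` to a per-month
    probability under a constant hazard.

    Solves ``1 - (1 - p)**horizon_months = cumulative_risk`` for ``p``.
    E.g. the 88.1% 12-month recurrence risk after endoscopic management
    maps to a 16.3% monthly probability.
    """
    if not 0.0 <= cumulative_risk < 1.0:
        raise ParameterValidationError(
            [f"cumulative_risk must be in [0, 1); got {cumulative_risk!r}"]
        )
    if horizon_months < 1:
        raise ParameterValidationError(
            [f"horizon_months must be >= 1; got {horizon_months!r}"]
        )
    return 1.0 - (1.0 - cumulative_risk) ** (1.0 / horizon_months)


def probability_to_rate(monthly_p: float, horizon_months: float) -> float:
    """Exact inverse of :func:`rate_to_probability`:
    ``1 - (1 - monthly_p)**horizon_months``."""
    if not 0.0 <= monthly_p < 1.0:
        raise ParameterValidationError(
            [f"monthly_p must be in [0, 1); got {monthly_p!r}"]
        )
    if horizon_months < 1:
        raise ParameterValidationError(
            [f"horizon_months must be >= 1; got {horizon_months!r}"]
        )
    return 1.0 - (1.0 - monthly_p) ** horizon_months


def median_to_exit_probability(
    median_days: float, days_per_month: float = DAYS_PER_MONTH
) -> float:
    """Per-cycle exit probability of a geometric waiting time whose
    continuous-equivalent median is ``median_days``.

    Solves ``(1 - p) ** (median_days / days_per_month) = 0.5``, i.e.
    ``p = 1 - 0.5 ** (days_per_month / median_days)``.
    """
    if median_days <= 0 or days_per_month <= 0:
        raise ParameterValidationError(
            [
                "median_days and days_per_month must be > 0; got "
                f"{median_days!r}, {days_per_month!r}"
            ]
        )
    return 1.0 - 0.5 ** (days_per_month / median_days)


def exit_probability_to_median(
    exit_p: float, days_per_month: float = DAYS_PER_MONTH
) -> float:
    """Inverse of :func:`median_to_exit_probability` (used when sensitivity
    analyses vary the derived exit probability directly)."""
    if not 0.0 < exit_p < 1.0:
        raise ParameterValidationError([f"exit_p must be in (0, 1); got {exit_p!r}"])
    return days_per_month * math.log(0.5) / math.log(1.0 - exit_p)


def episode_cost(
    base_cost: float, ae_cost: float, extras: Iterable[float] = ()
) -> float:
    """One-off cost of a procedure episode: procedure + adverse-event cost
    (+ any extras such as pre-dilation)."""
    components = [base_cost, ae_cost, *extras]
    bad = [c for c in components if c < 0]
    if bad:
        raise ParameterValidationError(
            [f"episode cost components must be >= 0; got {bad}"]
        )
    return float(sum(components))


def weighted_adverse_event_cost(
    events: Iterable[tuple[float, float]]
) -> float:
    """Expected 30-day adverse-event cost per procedure:
    sum of (proportion experiencing event) x (unit cost of treating it)."""
    total = 0.0
    problems = []
    for i, (p, c) in enumerate(events):
        if not 0.0 <= p <= 1.0:
            problems.append(f"event {i}: probability {p!r} outside [0, 1]")
        if c < 0:
            problems.append(f"event {i}: unit cost {c!r} is negative")
        total += p * c
    if problems:
        raise ParameterValidationError(problems)
    return total


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class TransitionInputs:
    """Per-cycle transition inputs (probabilities and waiting-time medians)."""

    monthly_p_recur_endo: float
    monthly_p_recur_optilume: float
    monthly_p_recur_urethroplasty: float
    p_treated_after_recurrence: float
    split_urethroplasty_after_endo_or_optilume: float
    split_repeat_endo_or_optilume: float
    split_repeat_urethroplasty_after_urethroplasty: float
    split_endo_or_optilume_after_urethroplasty: float
    median_days_to_treatment_endo_optilume: float
    median_days_to_treatment_urethroplasty: float
    monthly_p_death: float = 0.0

    def validate(self) -> list[str]:
        problems = []
        prob_fields = [
            "monthly_p_recur_endo",
            "monthly_p_recur_optilume",
            "monthly_p_recur_urethroplasty",
            "p_treated_after_recurrence",
            "split_urethroplasty_after_endo_or_optilume",
            "split_repeat_endo_or_optilume",
            "split_repeat_urethroplasty_after_urethroplasty",
            "split_endo_or_optilume_after_urethroplasty",
            "monthly_p_death",
        ]
        for name in prob_fields:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}: probability {v!r} outside [0, 1]")
        for a, b in (
            (
                "split_urethroplasty_after_endo_or_optilume",
                "split_repeat_endo_or_optilume",
            ),
            (
                "split_repeat_urethroplasty_after_urethroplasty",
                "split_endo_or_optilume_after_urethroplasty",
            ),
        ):
            s = getattr(self, a) + getattr(self, b)
            if abs(s - 1.0) > 1e-9:
                problems.append(f"{a} + {b} must sum to 1; got {s!r}")
        for name in (
            "median_days_to_treatment_endo_optilume",
            "median_days_to_treatment_urethroplasty",
        ):
            if getattr(self, name) <= 0:
                problems.append(f"{name}: must be > 0; got {getattr(self, name)!r}")
        return problems


@dataclass
class CostInputs:
    """Episode, device and health-state costs (GBP, 2019/20 prices)."""

    cost_endo_procedure: float
    cost_urethroplasty_procedure: float
    cost_optilume_incl_device: float
    cost_optilume_excl_device: float
    cost_optilume_device: float
    cost_predilation: float
    ae_cost_optilume: float
    ae_cost_endo: float
    ae_cost_urethroplasty: float
    training_per_patient_optilume: float
    monthly_cost_cured: float
    monthly_cost_recurrence: float

    def validate(self) -> list[str]:
        problems = []
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                problems.append(f"{f.name}: cost {v!r} is negative")
        # Device + procedure-only components must reconstruct the bundled
        # price to printed (whole-pound) rounding.
        diff = self.cost_optilume_incl_device - (
            self.cost_optilume_excl_device + self.cost_optilume_device
        )
        if abs(diff) > 1.0:
            problems.append(
                "cost_optilume_incl_device must equal excl_device + device "
                f"within £1; difference is {diff:.2f}"
            )
        return problems


@dataclass
class EngineSettings:
    """Cohort-engine settings: horizon, cycle length, discounting, exit mode."""

    horizon_cycles: int = 60
    cycle_length_months: float = 1.0
    annual_discount_rate_costs: float = 0.035
    starting_age: float = 59
    days_per_month: float = DAYS_PER_MONTH
    recurrence_exit_mode: str = "geometric"
    include_predilation: bool = False

    def validate(self) -> list[str]:
        problems = []
        if self.horizon_cycles < 1:
            problems.append(f"horizon_cycles must be >= 1; got {self.horizon_cycles!r}")
        if self.annual_discount_rate_costs < 0:
            problems.append(
                "annual_discount_rate_costs must be >= 0; got "
                f"{self.annual_discount_rate_costs!r}"
            )
        if self.cycle_length_months <= 0:
            problems.append(
                f"cycle_length_months must be > 0; got {self.cycle_length_months!r}"
            )
        if self.days_per_month <= 0:
            problems.append(f"days_per_month must be > 0; got {self.days_per_month!r}")
        if self.recurrence_exit_mode not in ("geometric", "fixed_tunnel"):
            problems.append(
                "recurrence_exit_mode must be 'geometric' or 'fixed_tunnel'; "
                f"got {self.recurrence_exit_mode!r}"
            )
        return problems


@dataclass
class DistributionSpec:
    """Moment-matched sampling distribution for one uncertain parameter.

    ``beta`` for quantities in [0, 1], ``gamma`` for non-negative costs,
    ``fixed`` for degenerate parameters.  ``shape`` holds (alpha, beta) for
    the beta family and (k, theta) for the gamma family.
    """

    parameter_name: str
    family: str  # "beta" | "gamma" | "fixed"
    mean: float
    se: float
    shape: tuple[float, float] = (0.0, 0.0)

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(self.shape[0], self.shape[1], size=size)
        if self.family == "gamma":
            return rng.gamma(self.shape[0], self.shape[1], size=size)
        if size is None:
            return self.mean
        return np.full(size, self.mean)

    def ppf(self, q: float) -> float:
        if self.family == "beta":
            return float(stats.beta.ppf(q, self.shape[0], self.shape[1]))
        if self.family == "gamma":
            return float(stats.gamma.ppf(q, self.shape[0], scale=self.shape[1]))
        return self.mean


def build_distribution(
    name: str,
    mean: float,
    kind: str,
    ci: tuple[float, float] | None = None,
) -> DistributionSpec:
    """Build a moment-matched :class:`DistributionSpec`.

    ``kind`` is ``"probability"`` (beta) or ``"cost"`` (gamma).  The standard
    error comes from a 95% confidence interval when supplied, otherwise from
    the 25%-of-mean rule.  A zero mean yields a degenerate ``fixed`` spec.
    """
    if kind not in ("probability", "cost"):
        raise ParameterValidationError([f"{name}: unknown distribution kind {kind!r}"])
    if kind == "probability" and not 0.0 <= mean <= 1.0:
        raise ParameterValidationError(
            [f"{name}: probability mean {mean!r} outside [0, 1]"]
        )
    if kind == "cost" and mean < 0:
        raise ParameterValidationError([f"{name}: cost mean {mean!r} is negative"])
    se = (ci[1] - ci[0]) / (2 * 1.959963984540054) if ci is not None else 0.25 * mean
    if mean == 0 or se == 0:
        return DistributionSpec(name, "fixed", mean, 0.0)
    if kind == "probability":
        var = se * se
        if var >= mean * (1.0 - mean):
            raise ParameterValidationError(
                [f"{name}: se {se!r} too large for a beta with mean {mean!r}"]
            )
        nu = mean * (1.0 - mean) / var - 1.0
        return DistributionSpec(name, "beta", mean, se, (mean * nu, (1.0 - mean) * nu))
    # gamma, matched on (mean, se): k = (mean/se)^2, theta = se^2/mean
    return DistributionSpec(
        name, "gamma", mean, se, ((mean / se) ** 2, se * se / mean)
    )


def fixed_distribution(name: str, value: float) -> DistributionSpec:
    """A degenerate spec for parameters held fixed in sensitivity analyses."""
    return DistributionSpec(name, "fixed", value, 0.0)


@dataclass
class ParameterSet:
    """Complete, validated model configuration."""

    transitions: TransitionInputs
    costs: CostInputs
    engine: EngineSettings
    distributions: list[DistributionSpec] = field(default_factory=list)

    def validate(self) -> None:
        problems = (
            self.transitions.validate()
            + self.costs.validate()
            + self.engine.validate()
        )
        if problems:
            raise ParameterValidationError(problems)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Config loading
# ---------------------------------------------------------------------------

_TRANSITION_KEYS = [f.name for f in fields(TransitionInputs)]
_COST_KEYS = [f.name for f in fields(CostInputs)]
_ENGINE_KEYS = [f.name for f in fields(EngineSettings)]
#: monthly_p_death and engine settings default if omitted from a config.
_OPTIONAL_KEYS = {"monthly_p_death", *_ENGINE_KEYS}
REQUIRED_KEYS = [
    k for k in _TRANSITION_KEYS + _COST_KEYS if k not in _OPTIONAL_KEYS
]


def load_parameters(config_source) -> ParameterSet:
    """Load and validate a flat key-value config (YAML path or mapping).

    Raises :class:`ParameterValidationError` naming every missing, unknown
    or out-of-range field.  Distributions for the probabilistic and
    deterministic sensitivity analyses are attached automatically.
    """
    if isinstance(config_source, (str, Path)):
        with open(config_source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(config_source)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParameterValidationError(
            [f"config must be a flat mapping; got {type(raw).__name__}"]
        )

    problems = []
    known = set(_TRANSITION_KEYS) | set(_COST_KEYS) | set(_ENGINE_KEYS)
    for key in raw:
        if key not in known:
            problems.append(f"unknown config key: {key}")
    for key in REQUIRED_KEYS:
        if key not in raw:
            problems.append(f"missing required field: {key}")
    if problems:
        raise ParameterValidationError(problems)

    def pick(keys, cls):
        return cls(**{k: raw[k] for k in keys if k in raw})

    pset = ParameterSet(
        transitions=pick(_TRANSITION_KEYS, TransitionInputs),
        costs=pick(_COST_KEYS, CostInputs),
        engine=pick(_ENGINE_KEYS, EngineSettings),
    )
    pset.validate()
    pset.distributions = build_default_distributions(pset)
    return pset


def default_parameters() -> ParameterSet:
    """The packaged default configuration (trial recurrence risks, NHS
    reference costs, 60 monthly cycles, 3.5% annual discounting)."""
    ref = resources.files("stricture_econ").joinpath("data/defaults.yaml")
    with resources.as_file(ref) as path:
        return load_parameters(path)


# ---------------------------------------------------------------------------
# Uncertain-parameter registry (shared by the PSA and the DSA)
# ---------------------------------------------------------------------------
#
# Probabilities and proportions are sampled from betas; complementary split
# pairs are sampled once with the complement set to one minus the draw, so
# each pair keeps summing to 1.  Waiting-time medians enter the sensitivity
# analyses through their derived per-cycle exit probabilities.  Costs are
# sampled from gammas; the bundled Optilume price rescales its device and
# procedure-only components to preserve the accounting identity.  Discount
# rate, horizon and background mortality are held fixed.

def _set_split_eo(pset, v):
    pset.transitions.split_urethroplasty_after_endo_or_optilume = v
    pset.transitions.split_repeat_endo_or_optilume = 1.0 - v


def _set_split_u(pset, v):
    pset.transitions.split_repeat_urethroplasty_after_urethroplasty = v
    pset.transitions.split_endo_or_optilume_after_urethroplasty = 1.0 - v


def _set_exit_eo(pset, v):
    pset.transitions.median_days_to_treatment_endo_optilume = (
        exit_probability_to_median(v, pset.engine.days_per_month)
    )


def _set_exit_u(pset, v):
    pset.transitions.median_days_to_treatment_urethroplasty = (
        exit_probability_to_median(v, pset.engine.days_per_month)
    )


def _get_exit_eo(pset):
    return median_to_exit_probability(
        pset.transitions.median_days_to_treatment_endo_optilume,
        pset.engine.days_per_month,
    )


def _get_exit_u(pset):
    return median_to_exit_probability(
        pset.transitions.median_days_to_treatment_urethroplasty,
        pset.engine.days_per_month,
    )


def _set_optilume_incl(pset, v):
    c = pset.costs
    scale = v / c.cost_optilume_incl_device if c.cost_optilume_incl_device else 1.0
    c.cost_optilume_device *= scale
    c.cost_optilume_incl_device = v
    c.cost_optilume_excl_device = v - c.cost_optilume_device


def _t_get(name):
    return lambda pset: getattr(pset.transitions, name)


def _t_set(name):
    return lambda pset, v: setattr(pset.transitions, name, v)


def _c_get(name):
    return lambda pset: getattr(pset.costs, name)


def _c_set(name):
    return lambda pset, v: setattr(pset.costs, name, v)


#: name -> (kind, getter, setter). Order fixes the draw order in the PSA.
UNCERTAIN_PARAMETERS: dict[str, tuple] = {
    "monthly_p_recur_endo": (
        "probability", _t_get("monthly_p_recur_endo"), _t_set("monthly_p_recur_endo"),
    ),
    "monthly_p_recur_optilume": (
        "probability",
        _t_get("monthly_p_recur_optilume"),
        _t_set("monthly_p_recur_optilume"),
    ),
    "monthly_p_recur_urethroplasty": (
        "probability",
        _t_get("monthly_p_recur_urethroplasty"),
        _t_set("monthly_p_recur_urethroplasty"),
    ),
    "p_treated_after_recurrence": (
        "probability",
        _t_get("p_treated_after_recurrence"),
        _t_set("p_treated_after_recurrence"),
    ),
    "split_urethroplasty_after_endo_or_optilume": (
        "probability",
        _t_get("split_urethroplasty_after_endo_or_optilume"),
        _set_split_eo,
    ),
    "split_repeat_urethroplasty_after_urethroplasty": (
        "probability",
        _t_get("split_repeat_urethroplasty_after_urethroplasty"),
        _set_split_u,
    ),
    "exit_p_recurrence_endo_optilume": ("probability", _get_exit_eo, _set_exit_eo),
    "exit_p_recurrence_urethroplasty": ("probability", _get_exit_u, _set_exit_u),
    "cost_endo_procedure": (
        "cost", _c_get("cost_endo_procedure"), _c_set("cost_endo_procedure"),
    ),
    "cost_urethroplasty_procedure": (
        "cost",
        _c_get("cost_urethroplasty_procedure"),
        _c_set("cost_urethroplasty_procedure"),
    ),
    "cost_optilume_incl_device": (
        "cost", _c_get("cost_optilume_incl_device"), _set_optilume_incl,
    ),
    "ae_cost_optilume": ("cost", _c_get("ae_cost_optilume"), _c_set("ae_cost_optilume")),
    "ae_cost_endo": ("cost", _c_get("ae_cost_endo"), _c_set("ae_cost_endo")),
    "ae_cost_urethroplasty": (
        "cost", _c_get("ae_cost_urethroplasty"), _c_set("ae_cost_urethroplasty"),
    ),
    "training_per_patient_optilume": (
        "cost",
        _c_get("training_per_patient_optilume"),
        _c_set("training_per_patient_optilume"),
    ),
    "monthly_cost_cured": (
        "cost", _c_get("monthly_cost_cured"), _c_set("monthly_cost_cured"),
    ),
    "monthly_cost_recurrence": (
        "cost", _c_get("monthly_cost_recurrence"), _c_set("monthly_cost_recurrence"),
    ),
}


def build_default_distributions(
    pset: ParameterSet, se_scale: float = 1.0
) -> list[DistributionSpec]:
    """Distributions for every uncertain parameter (SE = 25% of mean,
    scaled by ``se_scale``), plus fixed specs for the settings held
    constant in sensitivity analyses."""
    z = 1.959963984540054
    specs = []
    for name, (kind, get, _set) in UNCERTAIN_PARAMETERS.items():
        mean = get(pset)
        if se_scale == 1.0:
            spec = build_distribution(name, mean, kind)
        else:
            se = 0.25 * mean * se_scale
            spec = build_distribution(name, mean, kind, ci=(mean - z * se, mean + z * se))
        specs.append(spec)
    specs.append(
        fixed_distribution(
            "annual_discount_rate_costs", pset.engine.annual_discount_rate_costs
        )
    )
    specs.append(fixed_distribution("horizon_cycles", pset.engine.horizon_cycles))
    specs.append(
        fixed_distribution("monthly_p_death", pset.transitions.monthly_p_death)
    )
    return specs


def apply_parameter_value(pset: ParameterSet, name: str, value: float) -> None:
    """Set one uncertain parameter on ``pset`` (complement splits and
    derived medians handled consistently)."""
    if name not in UNCERTAIN_PARAMETERS:
        raise KeyError(f"unknown uncertain parameter: {name}")
    UNCERTAIN_PARAMETERS[name][2](pset, value)


def get_parameter_value(pset: ParameterSet, name: str) -> float:
    if name not in UNCERTAIN_PARAMETERS:
        raise KeyError(f"unknown uncertain parameter: {name}")
    return UNCERTAIN_PARAMETERS[name][1](pset)
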