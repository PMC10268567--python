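"""Synthetic individual-level data with the statistical structure the
cohort model assumes.

Two purposes: (a) an independent patient-level microsimulation oracle that
samples paths from the same monthly transition kernel the cohort engine
builds — never the engine's trace — so the two routes can be compared; and
(b) simulated trial arms with geometric (discrete, constant-hazard)
time-to-recurrence, matching the model's monthly-cycle assumption exactly,
for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .parameters import ParameterSet, ParameterValidationError

# ---------------------------------------------------------------------------
# Simulated trial arms
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTrialArm:
    """Per-patient recurrence month (1-based), NaN when censored at the
    follow-up horizon."""

    n: int
    horizon_months: int
    recurrence_month: np.ndarray  # float array; NaN = censored
    seed: int

    def to_frame(self) -> pd.DataFrame:
        censored = np.isnan(self.recurrence_month)
        return pd.DataFrame(
            {
                "patient_id": np.arange(self.n),
                "event_month": np.where(censored, self.horizon_months,
                                        self.recurrence_month).astype(int),
                "censored": censored,
            }
        )


def simulate_trial_arm(
    monthly_p: float, n: int, horizon_months: int, seed: int
) -> SimulatedTrialArm:
    """Draw each patient's recurrence month geometrically with per-month
    probability ``monthly_p``, censoring beyond ``horizon_months``."""
    if not 0.0 <= monthly_p < 1.0:
        raise ParameterValidationError(
            [f"monthly_p must be in [0, 1); got {monthly_p!r}"]
        )
    if n < 1 or horizon_months < 1:
        raise ParameterValidationError(
            [f"n and horizon_months must be >= 1; got {n!r}, {horizon_months!r}"]
        )
    rng = np.random.default_rng(seed)
    if monthly_p == 0.0:
        months = np.full(n, np.nan)
    else:
        months = rng.geometric(monthly_p, size=n).astype(float)
        months[months > horizon_months] = np.nan
    return SimulatedTrialArm(
        n=n, horizon_months=horizon_months, recurrence_month=months, seed=seed
    )


def estimate_cumulative_risk(arm: SimulatedTrialArm, at_month: int) -> float:
    """Observed fraction of patients with a recurrence by ``at_month``."""
    if at_month > arm.horizon_months:
        raise ParameterValidationError(
            [f"at_month {at_month!r} beyond follow-up horizon {arm.horizon_months!r}"]
        )
    with np.errstate(invalid="ignore"):
        return float(np.nansum(arm.recurrence_month <= at_month) / arm.n)


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------

@dataclass
class MicrosimResult:
    """Patient-level discounted cost over the horizon."""

    n_patients: int
    arm: str
    seed: int
    costs: np.ndarray  # per-patient discounted total
    category_costs: pd.DataFrame  # per-patient, six categories

    @property
    def mean(self) -> float:
        return float(self.costs.mean())

    @property
    def se(self) -> float:
        return float(self.costs.std(ddof=1) / np.sqrt(self.n_patients))

    def category_mean_se(self) -> pd.DataFrame:
        m = self.category_costs.mean(axis=0)
        se = self.category_costs.std(axis=0, ddof=1) / np.sqrt(self.n_patients)
        return pd.DataFrame({"mean": m, "se": se})


def microsim_cohort(
    params: ParameterSet, arm: str, n_patients: int, seed: int
) -> MicrosimResult:
    """Simulate each patient's monthly state path by direct categorical
    sampling from the arm's transition matrix, accruing exactly the costs
    the cohort engine accrues (initial episode and training at cycle 0
    undiscounted; discounted state costs from cycle 1; discounted
    retreatment episode costs on the retreatment transitions)."""
    if n_patients < 1:
        raise ParameterValidationError([f"n_patients must be >= 1; got {n_patients!r}"])
    matrix = engine.build_transition_matrix(params, arm)
    ss = matrix.states
    eng_ = params.engine
    n_cycles = eng_.horizon_cycles
    rng = np.random.default_rng(seed)

    cum = np.cumsum(matrix.probs, axis=1)
    cum[:, -1] = 1.0  # guard rounding
    df_t = engine.discount_factor(
        np.arange(n_cycles + 1), eng_.annual_discount_rate_costs,
        eng_.cycle_length_months,
    )

    cat_idx = {c: k for k, c in enumerate(engine.CATEGORIES)}
    cat = np.zeros((n_patients, len(engine.CATEGORIES)))
    cat[:, cat_idx["initial_procedure"]] = engine.initial_episode_cost(params, arm)
    if arm == "optilume":
        cat[:, cat_idx["training"]] = params.costs.training_per_patient_optilume

    event_cost = np.zeros_like(matrix.probs)
    event_cat = np.full(matrix.probs.shape, -1, dtype=int)
    for (i, j), (category, cost) in matrix.transition_costs.items():
        event_cost[i, j] = cost
        event_cat[i, j] = cat_idx[category]

    cured = np.zeros(ss.n_states, dtype=bool)
    cured[ss.cured_states] = True
    recur = np.zeros(ss.n_states, dtype=bool)
    recur[ss.recurrence_states] = True

    state = np.zeros(n_patients, dtype=int)  # all start in initial treatment
    c_cured = params.costs.monthly_cost_cured
    c_rec = params.costs.monthly_cost_recurrence
    for t in range(n_cycles):
        u = rng.random(n_patients)
        nxt = (u[:, None] >= cum[state]).sum(axis=1)
        ec = event_cost[state, nxt]
        has_event = ec > 0
        if has_event.any():
            idx = event_cat[state[has_event], nxt[has_event]]
            np.add.at(
                cat, (np.flatnonzero(has_event), idx), ec[has_event] * df_t[t + 1]
            )
        state = nxt
        cat[cured[state], cat_idx["cured_state"]] += c_cured * df_t[t + 1]
        cat[recur[state], cat_idx["recurrence_state"]] += c_rec * df_t[t + 1]

    category_costs = pd.DataFrame(cat, columns=list(engine.CATEGORIES))
    return MicrosimResult(
        n_patients=n_patients,
        arm=arm,
        seed=seed,
        costs=cat.sum(axis=1),
        category_costs=category_costs,
    )


# ---------------------------------------------------------------------------
# Random parameter sets for property testing
# ---------------------------------------------------------------------------

def random_parameter_set(seed: int) -> ParameterSet:
    """A randomized but always-valid :class:`ParameterSet`: probabilities in
    (0, 0.5), costs in (0, 10000), complementary splits summing to 1."""
    from .parameters import load_parameters

    rng = np.random.default_rng(seed)
    prob = lambda: float(rng.uniform(1e-4, 0.5))
    cost = lambda: float(rng.uniform(1.0, 10_000.0))
    split_eo = prob()
    split_u = prob()
    device = float(rng.uniform(1.0, 5_000.0))
    excl = float(rng.uniform(1.0, 5_000.0))
    cfg = {
        "monthly_p_recur_endo": prob(),
        "monthly_p_recur_optilume": prob(),
        "monthly_p_recur_urethroplasty": prob(),
        "p_treated_after_recurrence": prob(),
        "split_urethroplasty_after_endo_or_optilume": split_eo,
        "split_repeat_endo_or_optilume": 1.0 - split_eo,
        "split_repeat_urethroplasty_after_urethroplasty": split_u,
        "split_endo_or_optilume_after_urethroplasty": 1.0 - split_u,
        "median_days_to_treatment_endo_optilume": float(rng.uniform(10, 200)),
        "median_days_to_treatment_urethroplasty": float(rng.uniform(10, 300)),
        "monthly_p_death": float(rng.uniform(0.0, 0.02)),
        "cost_endo_procedure": cost(),
        "cost_urethroplasty_procedure": cost(),
        "cost_optilume_incl_device": device + excl,
        "cost_optilume_excl_device": excl,
        "cost_optilume_device": device,
        "cost_predilation": float(rng.uniform(0.0, 100.0)),
        "ae_cost_optilume": float(rng.uniform(0.0, 500.0)),
        "ae_cost_endo": float(rng.uniform(0.0, 500.0)),
        "ae_cost_urethroplasty": float(rng.uniform(0.0, 500.0)),
        "training_per_patient_optilume": float(rng.uniform(0.0, 100.0)),
        "monthly_cost_cured": float(rng.uniform(0.0, 200.0)),
        "monthly_cost_recurrence": float(rng.uniform(0.0, 200.0)),
        "horizon_cycles": int(rng.integers(12, 120)),
        "annual_discount_rate_costs": float(rng.uniform(0.0, 0.06)),
    }
    return load_parameters(cfg)
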