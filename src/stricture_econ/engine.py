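"""Cohort Markov engine: state space, transition matrix, trace and costs.

A closed cohort enters the model in an initial-treatment state, moves to a
treatment-dependent cured state after one monthly cycle, and from there can
recur.  Treated recurrences wait in a queue state (its per-cycle exit
probability calibrated to the median time to retreatment), then receive
either a repeat endoscopic-class procedure or a urethroplasty, landing in
the cured state of the new treatment; untreated recurrences remain in an
untreated-recurrence state until death or the end of the horizon.  Death is
reachable from every alive state and is absorbing.

Procedure costs are transition rewards (charged on the retreatment flow);
cured- and recurrence-state costs are state rewards; all costs after cycle 0
are discounted at an annual rate applied per monthly cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    ARMS,
    ParameterSet,
    episode_cost,
    median_to_exit_probability,
)

#: Cost categories, in presentation order.
CATEGORIES = (
    "initial_procedure",
    "repeat_endoscopic",
    "repeat_urethroplasty",
    "training",
    "cured_state",
    "recurrence_state",
)


class ModelStructureError(RuntimeError):
    """Raised when a built transition structure violates its invariants."""


# ---------------------------------------------------------------------------
# Episode cost assembly
# ---------------------------------------------------------------------------

def initial_episode_cost(params: ParameterSet, arm: str) -> float:
    """Procedure + adverse-event (+ optional pre-dilation) cost of the
    episode that starts the given arm."""
    c = params.costs
    if arm == "optilume":
        extras = [c.cost_predilation] if params.engine.include_predilation else []
        return episode_cost(c.cost_optilume_incl_device, c.ae_cost_optilume, extras)
    if arm == "endoscopic":
        return episode_cost(c.cost_endo_procedure, c.ae_cost_endo)
    if arm == "urethroplasty":
        return episode_cost(c.cost_urethroplasty_procedure, c.ae_cost_urethroplasty)
    raise ModelStructureError(f"unknown arm: {arm!r}")


def repeat_endoscopic_class_cost(params: ParameterSet, arm: str) -> float:
    """Cost of a repeat endoscopic-class retreatment.  In the Optilume arm a
    repeat endoscopic procedure is another Optilume treatment at full
    device-inclusive cost; in the comparator arms it is a plain endoscopic
    episode."""
    if arm == "optilume":
        return initial_episode_cost(params, "optilume")
    if arm in ("endoscopic", "urethroplasty"):
        return initial_episode_cost(params, "endoscopic")
    raise ModelStructureError(f"unknown arm: {arm!r}")


# ---------------------------------------------------------------------------
# State space
# ---------------------------------------------------------------------------

@dataclass
class StateSpace:
    """Ordered, labelled health states for one arm.

    The recurrence queues are single memoryless states under the default
    ``geometric`` exit mode, or chains of tunnel sub-states (one per cycle
    of the rounded median wait) under ``fixed_tunnel``.
    """

    labels: list[str]
    initial: int
    cured_endo_optilume: int
    cured_urethroplasty: int
    recurrence_endo_optilume: list[int]
    recurrence_urethroplasty: list[int]
    recurrence_untreated: int
    dead: int

    @property
    def n_states(self) -> int:
        return len(self.labels)

    @property
    def cured_states(self) -> list[int]:
        return [self.cured_endo_optilume, self.cured_urethroplasty]

    @property
    def recurrence_states(self) -> list[int]:
        return (
            self.recurrence_endo_optilume
            + self.recurrence_urethroplasty
            + [self.recurrence_untreated]
        )


def build_state_space(params: ParameterSet, arm: str) -> StateSpace:
    if arm not in ARMS:
        raise ModelStructureError(f"unknown arm: {arm!r}")
    eng = params.engine
    if eng.recurrence_exit_mode == "fixed_tunnel":
        t = params.transitions
        n_eo = max(
            1, round(t.median_days_to_treatment_endo_optilume / eng.days_per_month)
        )
        n_u = max(
            1, round(t.median_days_to_treatment_urethroplasty / eng.days_per_month)
        )
    else:
        n_eo = n_u = 1
    labels = [f"initial_treatment({arm})", "cured_after_endo_or_optilume",
              "cured_after_urethroplasty"]
    rec_eo = []
    for i in range(n_eo):
        rec_eo.append(len(labels))
        suffix = f"[{i + 1}/{n_eo}]" if n_eo > 1 else ""
        labels.append(f"recurrence_awaiting_after_endo_or_optilume{suffix}")
    rec_u = []
    for i in range(n_u):
        rec_u.append(len(labels))
        suffix = f"[{i + 1}/{n_u}]" if n_u > 1 else ""
        labels.append(f"recurrence_awaiting_after_urethroplasty{suffix}")
    untreated = len(labels)
    labels.append("recurrence_untreated")
    dead = len(labels)
    labels.append("dead")
    return StateSpace(
        labels=labels,
        initial=0,
        cured_endo_optilume=1,
        cured_urethroplasty=2,
        recurrence_endo_optilume=rec_eo,
        recurrence_urethroplasty=rec_u,
        recurrence_untreated=untreated,
        dead=dead,
    )


# ---------------------------------------------------------------------------
# Transition matrix
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """Row-stochastic per-cycle transition matrix with transition-attached
    procedure costs ``(from_state, to_state) -> (category, cost)``."""

    arm: str
    states: StateSpace
    probs: np.ndarray
    transition_costs: dict[tuple[int, int], tuple[str, float]] = field(
        default_factory=dict
    )

    def validate(self) -> None:
        p = self.probs
        if p.shape != (self.states.n_states, self.states.n_states):
            raise ModelStructureError("transition matrix shape mismatch")
        if (p < -1e-15).any() or (p > 1 + 1e-15).any():
            raise ModelStructureError("transition probabilities outside [0, 1]")
        bad = np.where(np.abs(p.sum(axis=1) - 1.0) > 1e-12)[0]
        if bad.size:
            names = ", ".join(self.states.labels[i] for i in bad)
            raise ModelStructureError(f"rows do not sum to 1: {names}")
        d = self.states.dead
        unit = np.zeros(self.states.n_states)
        unit[d] = 1.0
        if not np.array_equal(self.probs[d], unit):
            raise ModelStructureError("dead state is not absorbing")


def build_transition_matrix(params: ParameterSet, arm: str) -> TransitionMatrix:
    """Arm-specific per-cycle transition structure.

    Death competes proportionally with every other exit: the monthly death
    probability is applied first and the remaining mass follows the alive
    transition kernel.  Recurrence risk from a cured state depends on the
    last treatment received: the arm's own monthly probability after an
    endoscopic-class procedure, the urethroplasty monthly probability after
    a urethroplasty.
    """
    params.validate()
    ss = build_state_space(params, arm)
    t, eng = params.transitions, params.engine
    pd_ = t.monthly_p_death

    p_arm = {
        "optilume": t.monthly_p_recur_optilume,
        "endoscopic": t.monthly_p_recur_endo,
        "urethroplasty": t.monthly_p_recur_urethroplasty,
    }[arm]
    p_u = t.monthly_p_recur_urethroplasty
    treat = t.p_treated_after_recurrence

    if eng.recurrence_exit_mode == "fixed_tunnel":
        exit_eo = exit_u = 1.0  # advance one tunnel sub-state per cycle
    else:
        exit_eo = median_to_exit_probability(
            t.median_days_to_treatment_endo_optilume, eng.days_per_month
        )
        exit_u = median_to_exit_probability(
            t.median_days_to_treatment_urethroplasty, eng.days_per_month
        )

    n = ss.n_states
    M = np.zeros((n, n))

    def alive_row(i: int, moves: dict[int, float]) -> None:
        for j, p in moves.items():
            M[i, j] += (1.0 - pd_) * p
        M[i, ss.dead] += pd_

    # initial treatment -> cured state of the arm's treatment class
    first_cured = (
        ss.cured_urethroplasty if arm == "urethroplasty" else ss.cured_endo_optilume
    )
    alive_row(ss.initial, {first_cured: 1.0})

    # cured states: stay, or recur (90% to the treated queue, 10% untreated)
    alive_row(
        ss.cured_endo_optilume,
        {
            ss.cured_endo_optilume: 1.0 - p_arm,
            ss.recurrence_endo_optilume[0]: p_arm * treat,
            ss.recurrence_untreated: p_arm * (1.0 - treat),
        },
    )
    alive_row(
        ss.cured_urethroplasty,
        {
            ss.cured_urethroplasty: 1.0 - p_u,
            ss.recurrence_urethroplasty[0]: p_u * treat,
            ss.recurrence_untreated: p_u * (1.0 - treat),
        },
    )

    costs: dict[tuple[int, int], tuple[str, float]] = {}
    c_repeat = repeat_endoscopic_class_cost(params, arm)
    c_ure = initial_episode_cost(params, "urethroplasty")

    def queue_rows(chain, exit_p, split_to_ure):
        # walk the queue; the terminal exit splits between retreatments
        for k, i in enumerate(chain):
            last = k == len(chain) - 1
            nxt = None if last else chain[k + 1]
            moves = {}
            if not last:
                moves[nxt] = exit_p
                if exit_p < 1.0:
                    moves[i] = 1.0 - exit_p
            else:
                moves[ss.cured_urethroplasty] = exit_p * split_to_ure
                moves[ss.cured_endo_optilume] = exit_p * (1.0 - split_to_ure)
                if exit_p < 1.0:
                    moves[i] = 1.0 - exit_p
                costs[(i, ss.cured_urethroplasty)] = ("repeat_urethroplasty", c_ure)
                costs[(i, ss.cured_endo_optilume)] = ("repeat_endoscopic", c_repeat)
            alive_row(i, moves)

    queue_rows(
        ss.recurrence_endo_optilume,
        exit_eo,
        t.split_urethroplasty_after_endo_or_optilume,
    )
    queue_rows(
        ss.recurrence_urethroplasty,
        exit_u,
        t.split_repeat_urethroplasty_after_urethroplasty,
    )

    alive_row(ss.recurrence_untreated, {ss.recurrence_untreated: 1.0})
    M[ss.dead, ss.dead] = 1.0

    tm = TransitionMatrix(arm=arm, states=ss, probs=M, transition_costs=costs)
    tm.validate()
    return tm


# ---------------------------------------------------------------------------
# Cohort trace
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Per-cycle state-occupancy proportions for a cohort of size 1
    (rows: cycles 0..n, columns: states)."""

    occupancy: np.ndarray
    states: StateSpace | None = None

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_tidy(self) -> pd.DataFrame:
        labels = (
            self.states.labels
            if self.states is not None
            else [f"state_{j}" for j in range(self.occupancy.shape[1])]
        )
        df = pd.DataFrame(self.occupancy, columns=labels)
        df.insert(0, "cycle", np.arange(len(df)))
        return df.melt(id_vars="cycle", var_name="state", value_name="proportion")


def run_cohort(matrix, n_cycles: int) -> CohortTrace:
    """Iterate the cohort forward: ``occupancy[t+1] = occupancy[t] @ P``.

    ``matrix`` may be a :class:`TransitionMatrix` or a bare row-stochastic
    ndarray (useful for toy kernels in tests).  All mass starts in the first
    state (the initial-treatment state).
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1; got {n_cycles!r}")
    if isinstance(matrix, TransitionMatrix):
        P = matrix.probs
        states = matrix.states
    else:
        P = np.asarray(matrix, dtype=float)
        states = None
    n = P.shape[0]
    if P.shape != (n, n):
        raise ValueError("transition matrix must be square")
    occ = np.zeros((n_cycles + 1, n))
    occ[0, 0] = 1.0
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ P
    return CohortTrace(occupancy=occ, states=states)


def discount_factor(cycle: int, annual_rate: float, cycle_length_months: float = 1.0):
    """Present-value factor ``(1 + r)^(-cycle * months / 12)``; cycle 0 is
    undiscounted."""
    cycle = np.asarray(cycle)
    if (cycle < 0).any():
        raise ValueError("cycle must be >= 0")
    return (1.0 + annual_rate) ** (-(cycle * cycle_length_months) / 12.0)


# ---------------------------------------------------------------------------
# Cost accrual
# ---------------------------------------------------------------------------

@dataclass
class CostLedger:
    """Discounted cost per cycle per category (rows: cycles, columns:
    the six presentation categories)."""

    per_cycle: pd.DataFrame
    arm: str

    def totals(self) -> pd.Series:
        return self.per_cycle.sum(axis=0)

    def grand_total(self) -> float:
        return float(self.per_cycle.values.sum())

    def to_tidy(self) -> pd.DataFrame:
        df = self.per_cycle.copy()
        df.insert(0, "cycle", df.index)
        return df.melt(id_vars="cycle", var_name="category", value_name="cost")


def accrue_costs(
    trace: CohortTrace, matrix: TransitionMatrix, params: ParameterSet
) -> CostLedger:
    """Accrue discounted costs along a trace.

    Cycle 0 charges the initial episode (and, in the Optilume arm, the
    one-off training cost) undiscounted.  For each later cycle t, state
    costs are occupancy(t) x monthly state cost x df(t) and retreatment
    event costs are flow(t-1 -> t) x episode cost x df(t).  No state cost
    accrues during the initial-treatment cycle.
    """
    ss = matrix.states
    if trace.states is not None and trace.states.labels != ss.labels:
        raise ModelStructureError("trace and matrix state spaces differ")
    occ = trace.occupancy
    if occ.shape[1] != ss.n_states:
        raise ModelStructureError("trace width does not match the state space")
    n_cycles = trace.n_cycles
    eng = params.engine
    df_t = discount_factor(
        np.arange(n_cycles + 1), eng.annual_discount_rate_costs,
        eng.cycle_length_months,
    )

    per_cycle = np.zeros((n_cycles + 1, len(CATEGORIES)))
    cat_idx = {c: k for k, c in enumerate(CATEGORIES)}

    per_cycle[0, cat_idx["initial_procedure"]] = initial_episode_cost(
        params, matrix.arm
    )
    if matrix.arm == "optilume":
        per_cycle[0, cat_idx["training"]] = params.costs.training_per_patient_optilume

    cured_cols = ss.cured_states
    rec_cols = ss.recurrence_states
    c_cured = params.costs.monthly_cost_cured
    c_rec = params.costs.monthly_cost_recurrence
    for t in range(1, n_cycles + 1):
        per_cycle[t, cat_idx["cured_state"]] = occ[t, cured_cols].sum() * c_cured * df_t[t]
        per_cycle[t, cat_idx["recurrence_state"]] = (
            occ[t, rec_cols].sum() * c_rec * df_t[t]
        )
        for (i, j), (category, cost) in matrix.transition_costs.items():
            flow = occ[t - 1, i] * matrix.probs[i, j]
            per_cycle[t, cat_idx[category]] += flow * cost * df_t[t]

    ledger = pd.DataFrame(per_cycle, columns=list(CATEGORIES))
    ledger.index.name = "cycle"
    return CostLedger(per_cycle=ledger, arm=matrix.arm)


def summarize(ledger: CostLedger) -> pd.Series:
    """Six category totals plus the grand total (full precision; rounding
    to whole GBP happens only at presentation)."""
    totals = ledger.totals()
    totals["total"] = ledger.grand_total()
    return totals


def run_arm(params: ParameterSet, arm: str) -> CostLedger:
    """Convenience: build the arm's matrix, run the cohort over the
    configured horizon and accrue costs."""
    matrix = build_transition_matrix(params, arm)
    trace = run_cohort(matrix, params.engine.horizon_cycles)
    return accrue_costs(trace, matrix, params)
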