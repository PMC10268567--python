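"""Base-case comparison, urethroplasty scenario, probabilistic and
deterministic sensitivity analyses.

The primary outcome is the incremental mean discounted cost per patient
(intervention minus comparator) over the model horizon; a negative
incremental cost means the intervention is cost saving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import engine
from .parameters import (
    ParameterSet,
    apply_parameter_value,
)

TOTAL_ROW = "total"


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass
class ComparisonResult:
    """Six category totals + grand total per arm, with incrementals
    (intervention minus comparator)."""

    intervention: str
    comparator: str
    table: pd.DataFrame  # rows: categories + total; cols: arms + incremental

    @property
    def incremental_total(self) -> float:
        return float(self.table.loc[TOTAL_ROW, "incremental"])

    def arm_total(self, arm: str) -> float:
        return float(self.table.loc[TOTAL_ROW, arm])

    def to_json_dict(self) -> dict:
        return {
            "intervention": self.intervention,
            "comparator": self.comparator,
            "rows": {
                row: {col: float(v) for col, v in self.table.loc[row].items()}
                for row in self.table.index
            },
        }

    def to_markdown(self) -> str:
        """Presentation table, rounded to whole GBP (half away from zero)."""
        rounded = self.table.map(_round_half_away)
        lines = ["| Category | " + " | ".join(self.table.columns) + " |"]
        lines.append("|" + "---|" * (len(self.table.columns) + 1))
        for row in rounded.index:
            cells = " | ".join(f"£{v}" for v in rounded.loc[row])
            lines.append(f"| {row} | {cells} |")
        return "\n".join(lines)


def compare_arms(
    params: ParameterSet, intervention: str, comparator: str
) -> ComparisonResult:
    """Run two arms through the engine at identical settings and tabulate
    per-category and total incremental costs."""
    led_i = engine.run_arm(params, intervention)
    led_c = engine.run_arm(params, comparator)
    t_i = engine.summarize(led_i)
    t_c = engine.summarize(led_c)
    table = pd.DataFrame({intervention: t_i, comparator: t_c})
    table["incremental"] = table[intervention] - table[comparator]
    table = table.rename(index={"total": TOTAL_ROW})
    return ComparisonResult(intervention, comparator, table)


def base_case(params: ParameterSet) -> ComparisonResult:
    """Optilume versus endoscopic management."""
    return compare_arms(params, "optilume", "endoscopic")


def scenario_urethroplasty(params: ParameterSet) -> ComparisonResult:
    """Optilume versus urethroplasty: the comparator cohort starts with a
    urethroplasty episode, recurs at the urethroplasty monthly probability
    and on retreatment splits 12% repeat urethroplasty / 88% endoscopic
    (priced as plain endoscopic episodes — no device).  Optilume inputs are
    unchanged."""
    return compare_arms(params, "optilume", "urethroplasty")


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    n_iterations: int
    seed: int
    incremental_draws: np.ndarray
    parameter_draws: pd.DataFrame
    base_incremental: float

    @property
    def fraction_cost_saving(self) -> float:
        return float(np.mean(self.incremental_draws < 0))

    def histogram(self, bins: int = 20) -> pd.DataFrame:
        counts, edges = np.histogram(self.incremental_draws, bins=bins)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )


def run_psa(
    params: ParameterSet, n_iterations: int = 1000, seed: int | None = None
) -> PSAResult:
    """Monte Carlo propagation of parameter uncertainty.

    Every non-degenerate parameter distribution is sampled independently per
    iteration (complementary split pairs as one draw and its complement);
    the base-case comparison is rerun per draw and the incremental total
    recorded.  A seed is mandatory so draws are reproducible.
    """
    if seed is None:
        raise ValueError("run_psa requires an explicit seed for reproducibility")
    if n_iterations < 1:
        raise ValueError(f"n_iterations must be >= 1; got {n_iterations!r}")
    params.validate()
    rng = np.random.default_rng(seed)
    sampled = [s for s in params.distributions if s.family != "fixed"]
    draws = {
        s.parameter_name: np.asarray(s.sample(rng, n_iterations)) for s in sampled
    }
    base = base_case(params).incremental_total

    incrementals = np.empty(n_iterations)
    for it in range(n_iterations):
        p = params.copy()
        for name, values in draws.items():
            apply_parameter_value(p, name, float(values[it]))
        incrementals[it] = base_case(p).incremental_total
    return PSAResult(
        n_iterations=n_iterations,
        seed=seed,
        incremental_draws=incrementals,
        parameter_draws=pd.DataFrame(draws),
        base_incremental=base,
    )


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class DSAResult:
    table: pd.DataFrame  # one row per parameter, tornado-ordered
    base_incremental: float


def run_dsa(params: ParameterSet) -> DSAResult:
    """One-way sensitivity analysis: each uncertain parameter is set in turn
    to the 2.5th and 97.5th percentile of its distribution (all others at
    their means), the base-case comparison rerun, and parameters ordered by
    the absolute range of the incremental cost (tornado order).  Degenerate
    (fixed) parameters have zero range and sort last."""
    params.validate()
    base = base_case(params).incremental_total
    rows = []
    for spec in params.distributions:
        if spec.family == "fixed":
            low = high = spec.mean
            inc_low = inc_high = base
        else:
            low, high = spec.ppf(0.025), spec.ppf(0.975)
            p = params.copy()
            apply_parameter_value(p, spec.parameter_name, low)
            inc_low = base_case(p).incremental_total
            p = params.copy()
            apply_parameter_value(p, spec.parameter_name, high)
            inc_high = base_case(p).incremental_total
        rows.append(
            {
                "parameter": spec.parameter_name,
                "low_value": low,
                "high_value": high,
                "incremental_at_low": inc_low,
                "incremental_at_high": inc_high,
                "range": abs(inc_high - inc_low),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["range", "parameter"], ascending=[False, True], kind="mergesort"
    )
    table = table.reset_index(drop=True)
    return DSAResult(table=table, base_incremental=base)


def sign_flip_parameters(dsa: DSAResult) -> list[str]:
    """Parameters whose low/high incremental costs disagree in sign with
    each other or with the base case (i.e. varying the parameter alone can
    reverse the cost-saving conclusion)."""
    base_sign = np.sign(dsa.base_incremental)
    flips = []
    for _, row in dsa.table.iterrows():
        lo, hi = row["incremental_at_low"], row["incremental_at_high"]
        if lo * hi < 0 or np.sign(lo) != base_sign or np.sign(hi) != base_sign:
            flips.append(row["parameter"])
    return flips
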