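"""Five-state monthly Markov cohort model of the diagnostic pathway.

States: Symptomatic-Undiagnosed, Diagnosed-Untreated, Treatment-Initiated,
Progressive-Disease and Death (absorbing).  Only the forward transitions of
the published model exist — symptomatic patients are diagnosed, diagnosed
patients start treatment, treated patients may progress or die, progressive
patients may die — and each transition probability may be stratified by
symptom type, delay interval, stage, molecular subtype or treatment type,
falling back to the overall value when a stratified one is not listed.

The engine provides the deterministic cohort trace (occupancy of each state
at the start of every monthly cycle), a Monte-Carlo microsimulation oracle
for it, maximum-likelihood calibration of the transition table from
per-patient monthly state histories, discounted life-year / QALY / cost
accumulation, and counterfactual scenario comparison.

Note a structural property worth keeping in mind when reading
counterfactual output: the pre-diagnosis states carry no death hazard, so a
slower symptomatic-to-diagnosed transition mechanically defers absorption.
The survival harm of delay enters the analysis through stage migration and
the stratified post-treatment hazards, not through diagnosis timing itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import params

__all__ = [
    "STATES",
    "TransitionTable",
    "CohortTrace",
    "EconomicParams",
    "Scenario",
    "Outcomes",
    "build_matrix",
    "run_trace",
    "mle_transitions",
    "accumulate",
    "counterfactual",
    "microsim",
    "default_table",
]

STATES = params.STATES
DEATH = STATES.index("Death")
_IDX = {s: i for i, s in enumerate(STATES)}
OVERALL = ("overall", "overall")


@dataclass
class TransitionTable:
    """Stratified monthly transition probabilities.

    ``entries[(from, to)]`` maps a ``(stratum_key, stratum_value)`` pair to
    a monthly probability; the ``("overall", "overall")`` entry is the
    unstratified fallback.  Absent entries are *missing*, never zero.
    """

    entries: dict[tuple[str, str], dict[tuple[str, str], float]] = field(
        default_factory=dict
    )

    def set(self, frm: str, to: str, p: float, key="overall", value="overall"):
        if frm not in _IDX or to not in _IDX:
            raise KeyError(f"unknown state in transition {frm} -> {to}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability {p} outside [0, 1]")
        self.entries.setdefault((frm, to), {})[(key, value)] = float(p)

    def lookup(self, frm: str, to: str, stratum: dict | None) -> float | None:
        """Stratified value under the priority order, else overall, else None."""
        cell = self.entries.get((frm, to))
        if cell is None:
            return None
        if stratum:
            extra = sorted(set(stratum) - set(params.STRATUM_PRIORITY))
            for key in (*params.STRATUM_PRIORITY, *extra):
                if key in stratum and (key, stratum[key]) in cell:
                    return cell[(key, stratum[key])]
        return cell.get(OVERALL)

    def merged(self, fallback: "TransitionTable") -> "TransitionTable":
        """New table where missing entries are filled from ``fallback``."""
        out = TransitionTable()
        for src in (fallback, self):
            for edge, cell in src.entries.items():
                for strat, p in cell.items():
                    out.entries.setdefault(edge, {})[strat] = p
        return out

    def to_csv(self, path) -> None:
        rows = [
            {"from": f, "to": t, "stratum_key": k, "stratum_value": v, "probability": p}
            for (f, t), cell in self.entries.items()
            for (k, v), p in cell.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TransitionTable":
        table = cls()
        for _, row in pd.read_csv(path).iterrows():
            table.set(
                row["from"], row["to"], float(row["probability"]),
                key=row["stratum_key"], value=row["stratum_value"],
            )
        return table


def default_table() -> TransitionTable:
    """The published transition table."""
    table = TransitionTable()
    for (frm, to), cell in params.TRANSITIONS.items():
        for (key, value), p in cell.items():
            table.set(frm, to, p, key=key, value=value)
    return table


def build_matrix(table: TransitionTable, stratum: dict | None = None) -> np.ndarray:
    """Assemble the 5x5 row-stochastic monthly matrix for one stratum.

    Off-diagonal entries come from the table (stratified values override
    the overall ones); each diagonal is one minus the listed exits; the
    Death row is the identity row.
    """
    mat = np.zeros((5, 5))
    for (frm, to), _ in table.entries.items():
        p = table.lookup(frm, to, stratum)
        if p is None:
            raise KeyError(f"no probability available for {frm} -> {to}")
        mat[_IDX[frm], _IDX[to]] = p
    for i, state in enumerate(STATES):
        if i == DEATH:
            mat[i] = 0.0
            mat[i, i] = 1.0
            continue
        exits = mat[i].sum() - mat[i, i]
        if exits > 1.0 + 1e-12:
            raise ValueError(
                f"outgoing probabilities from {state} sum to {exits:.3f} > 1 "
                f"in stratum {stratum!r}"
            )
        mat[i, i] = 1.0 - exits
    return mat


@dataclass
class CohortTrace:
    """State occupancancy at the start of cycles 0..cycles (rows sum to 1)."""

    occupancy: np.ndarray
    cycles: int

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.shape != (self.cycles + 1, 5):
            raise ValueError("occupancy must have cycles+1 rows and 5 columns")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("trace rows must each sum to 1")
        if np.any(np.diff(occ[:, DEATH]) < -1e-12):
            raise ValueError("Death occupancy must be nondecreasing")
        self.occupancy = occ

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.cycles + 1))
        return df


def run_trace(
    matrix: np.ndarray, initial_occupancy, cycles: int = params.HORIZON_CYCLES
) -> CohortTrace:
    """Propagate a cohort through ``cycles`` monthly steps."""
    init = np.asarray(initial_occupancy, dtype=float)
    if init.shape != (5,) or abs(init.sum() - 1.0) > 1e-9 or np.any(init < 0):
        raise ValueError("initial occupancy must be a nonnegative 5-vector summing to 1")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    occ = np.empty((cycles + 1, 5))
    occ[0] = init
    for t in range(1, cycles + 1):
        occ[t] = occ[t - 1] @ matrix
    return CohortTrace(occupancy=occ, cycles=cycles)


def mle_transitions(
    event_histories: "list[list[str]]",
    strata: "list[dict] | None" = None,
) -> TransitionTable:
    """Maximum-likelihood transition probabilities from state histories.

    Each history is a per-patient sequence of monthly states.  The MLE of a
    monthly transition probability is the transition count divided by the
    person-months at risk in the origin state; estimates are produced
    overall and, when per-patient ``strata`` mappings are supplied, within
    each (key, value) stratum.  States with zero exposure yield no entry
    (missing, not zero).
    """
    if not event_histories:
        raise ValueError("no event histories supplied")
    if strata is not None and len(strata) != len(event_histories):
        raise ValueError("strata must align with event_histories")

    def tally(histories):
        exposure = np.zeros(5)
        counts = np.zeros((5, 5))
        for hist in histories:
            for a, b in zip(hist, hist[1:]):
                exposure[_IDX[a]] += 1
                counts[_IDX[a], _IDX[b]] += 1
        return exposure, counts

    table = TransitionTable()

    def add(histories, key, value):
        exposure, counts = tally(histories)
        for i, frm in enumerate(STATES):
            if exposure[i] == 0 or i == DEATH:
                continue
            for j, to in enumerate(STATES):
                if i != j and counts[i, j] > 0:
                    table.set(frm, to, counts[i, j] / exposure[i], key, value)

    add(event_histories, "overall", "overall")
    if strata is not None:
        groups: dict[tuple[str, str], list] = {}
        for hist, st in zip(event_histories, strata):
            for key, value in st.items():
                groups.setdefault((key, str(value)), []).append(hist)
        for (key, value), hists in groups.items():
            add(hists, key, value)
    return table


@dataclass
class EconomicParams:
    """Cycle convention, discounting, utilities and phase costs."""

    cycle_length_months: float = float(params.CYCLE_LENGTH_MONTHS)
    horizon_cycles: int = params.HORIZON_CYCLES
    discount_rate: float = params.ANNUAL_DISCOUNT_RATE
    utilities: dict = field(default_factory=lambda: dict(params.UTILITIES))
    costs: dict = field(default_factory=lambda: dict(params.COSTS_SAR))

    def __post_init__(self):
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount rate must lie in [0, 1)")
        for state, u in self.utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility for {state} outside [0, 1]")

    def discount_factor(self, cycle: int) -> float:
        """Exact compounding of the annual rate: (1 + r)^(-t/12)."""
        return (1.0 + self.discount_rate) ** (-cycle / 12.0)

    def initial_treatment_cost(self, stage_at_dx: str = "II") -> float:
        """Resolve the initial-treatment cost range by stage (linear I..IV)."""
        low, high = self.costs["initial_treatment"]
        frac = ("I", "II", "III", "IV").index(stage_at_dx) / 3.0
        return low + frac * (high - low)


class Outcomes(NamedTuple):
    life_years: float
    qalys: float
    discounted_cost: float


def accumulate(
    trace: CohortTrace,
    econ: EconomicParams,
    matrix: np.ndarray | None = None,
    stage_at_dx: str = "II",
) -> Outcomes:
    """Discounted life-years, QALYs and costs over a cohort trace.

    Membership is counted at cycle start with no half-cycle correction:
    cycle ``t`` contributes ``occupancy[t] / 12`` discounted by
    ``(1.035)^(-t/12)``.  Per-cycle costs apply to time in the treatment
    (continuing care) and progressive-disease states; one-off phase costs
    (diagnostic work-up, initial treatment, terminal care) apply to state
    *entries*, computed exactly from the transition matrix when supplied
    and otherwise approximated by nonnegative occupancy increments.
    """
    if trace.cycles != econ.horizon_cycles:
        raise ValueError(
            f"trace horizon {trace.cycles} != economic horizon {econ.horizon_cycles}"
        )
    occ = trace.occupancy
    d = np.array([econ.discount_factor(t) for t in range(trace.cycles)])
    alive = [i for i in range(5) if i != DEATH]
    months = econ.cycle_length_months / 12.0

    life_years = float((occ[:-1, alive].sum(axis=1) * d).sum() * months)
    weights = np.array([econ.utilities.get(s, 0.0) for s in STATES])
    qalys = float(((occ[:-1] @ weights) * d).sum() * months)

    if matrix is not None:
        inflow = np.empty((trace.cycles, 5))
        off = matrix.copy()
        np.fill_diagonal(off, 0.0)
        for t in range(trace.cycles):
            inflow[t] = occ[t] @ off
    else:
        inflow = np.clip(np.diff(occ, axis=0), 0.0, None)
    d_in = np.array([econ.discount_factor(t + 1) for t in range(trace.cycles)])

    per_cycle = (
        econ.costs["continuing_care"] * occ[:-1, _IDX["Treatment-Initiated"]]
        + econ.costs["progressive_disease"] * occ[:-1, _IDX["Progressive-Disease"]]
    )
    entry = (
        econ.costs["diagnostic"] * inflow[:, _IDX["Diagnosed-Untreated"]]
        + econ.initial_treatment_cost(stage_at_dx)
        * inflow[:, _IDX["Treatment-Initiated"]]
        + econ.costs["terminal_care"] * inflow[:, DEATH]
    )
    cost = float((per_cycle * d).sum() + (entry * d_in).sum())
    return Outcomes(life_years=life_years, qalys=qalys, discounted_cost=cost)


@dataclass
class Scenario:
    """One counterfactual arm: a stratum and an optional starting mix."""

    name: str
    stratum: dict = field(default_factory=dict)
    initial_occupancy: tuple = (1.0, 0.0, 0.0, 0.0, 0.0)
    cycles: int = params.HORIZON_CYCLES
    stage_at_dx: str = "II"
    migration_prob: float | None = None


def counterfactual(
    table: TransitionTable,
    econ: EconomicParams,
    scenario_a: Scenario,
    scenario_b: Scenario,
) -> dict:
    """Outcome differences (scenario_a minus scenario_b).

    Returns deltas in discounted life-years, QALYs and cost, in the death
    probability at the horizon, and — when both scenarios carry a
    ``migration_prob`` (typically evaluated from a migration curve at the
    scenario's delay) — in stage-migration probability.
    """
    if scenario_a.cycles != scenario_b.cycles:
        raise ValueError("scenarios must share the same horizon")

    def run(sc: Scenario):
        mat = build_matrix(table, sc.stratum)
        trace = run_trace(mat, sc.initial_occupancy, sc.cycles)
        out = accumulate(trace, econ, matrix=mat, stage_at_dx=sc.stage_at_dx)
        return trace, out

    trace_a, out_a = run(scenario_a)
    trace_b, out_b = run(scenario_b)
    deltas = {
        "life_years": out_a.life_years - out_b.life_years,
        "qalys": out_a.qalys - out_b.qalys,
        "discounted_cost": out_a.discounted_cost - out_b.discounted_cost,
        "death_prob": float(
            trace_a.occupancy[-1, DEATH] - trace_b.occupancy[-1, DEATH]
        ),
    }
    if scenario_a.migration_prob is not None and scenario_b.migration_prob is not None:
        deltas["migration_prob"] = scenario_a.migration_prob - scenario_b.migration_prob
    return deltas


@dataclass
class MicrosimResult:
    """Monte-Carlo occupancy estimates with binomial standard errors."""

    occupancy: np.ndarray
    se: np.ndarray
    n: int
    paths: np.ndarray | None = None


def microsim(
    matrix: np.ndarray,
    n: int,
    cycles: int = params.HORIZON_CYCLES,
    seed: int = 0,
    initial_state: int = 0,
    keep_paths: bool = False,
) -> MicrosimResult:
    """Simulate ``n`` independent patient paths through the chain.

    Serves as the stochastic oracle for :func:`run_trace`: occupancy
    estimates converge to the deterministic trace at the binomial rate.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(matrix, axis=1)
    states = np.full(n, initial_state, dtype=np.int64)
    paths = np.empty((cycles + 1, n), dtype=np.int8) if keep_paths else None
    occ = np.empty((cycles + 1, 5))
    occ[0] = np.bincount(states, minlength=5) / n
    if keep_paths:
        paths[0] = states
    for t in range(1, cycles + 1):
        u = rng.random(n)
        states = (u[:, None] >= cum[states]).sum(axis=1)
        occ[t] = np.bincount(states, minlength=5) / n
        if keep_paths:
            paths[t] = states
    se = np.sqrt(occ * (1.0 - occ) / n)
    return MicrosimResult(
        occupancy=occ, se=se, n=n,
        paths=paths.T if keep_paths else None,
    )
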