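"""Causal diagram utilities and product-method mediation decomposition.

The analysis rests on a directed acyclic graph in which diagnostic delay
affects survival directly and through three causally ordered mediators —
stage migration (primary), treatment intensity (secondary) and surgical
complications (tertiary) — while age, BMI, comorbidity, family history and
molecular subtype confound the delay–survival relationship.

Two tasks live here:

* **adjustment**: enumerate every inclusion-minimal backdoor adjustment set
  for an (exposure, outcome) pair, verified by d-separation in the graph
  with the exposure's outgoing edges removed;
* **mediation**: decompose the total delay effect into per-pathway indirect
  effects with the product method (exposure→mediator coefficient times
  mediator→outcome coefficient from linear working models on the
  log-hazard / linear-predictor scale), with seeded percentile-bootstrap
  confidence intervals.

The working models are ordinary least squares, so the decomposition is
exactly additive: direct + sum of indirect effects equals the total effect
by construction.  The log-hazard working scale is a modelling choice; on a
non-collapsible scale such as the hazard ratio the same shares would not
add exactly, which every decomposition result records as a caveat.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from . import params

__all__ = [
    "Dag",
    "MediationDecomposition",
    "build_dag",
    "study_dag",
    "backdoor_sets",
    "decompose",
    "residual_direct",
    "dag_to_edgelist",
    "dag_from_edgelist",
]

#: Nodes of the study diagram.
STUDY_NODES = (
    "delay",
    "stage_migration",
    "treatment_intensity",
    "complications",
    "survival",
    "age",
    "bmi",
    "comorbidity",
    "family_history",
    "subtype",
)

#: Edges of the study diagram: the direct path, the three mediated paths
#: (causally ordered stage -> treatment -> complications), and the five
#: confounders of both delay and survival.
STUDY_EDGES: tuple[tuple[str, str], ...] = (
    ("delay", "survival"),
    ("delay", "stage_migration"),
    ("stage_migration", "survival"),
    ("delay", "treatment_intensity"),
    ("treatment_intensity", "survival"),
    ("delay", "complications"),
    ("complications", "survival"),
    ("stage_migration", "treatment_intensity"),
    ("treatment_intensity", "complications"),
) + tuple(
    (c, v)
    for c in ("age", "bmi", "comorbidity", "family_history", "subtype")
    for v in ("delay", "survival")
)


@dataclass(frozen=True)
class Dag:
    """A validated acyclic causal diagram."""

    graph: nx.DiGraph

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(self.graph.edges)


def build_dag(edges, nodes=()) -> Dag:
    """Build and validate a DAG from an edge list (plus isolated nodes)."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"graph contains a cycle: {cycle}")
    return Dag(graph=g)


def study_dag() -> Dag:
    """The study's causal diagram (10 nodes)."""
    return build_dag(STUDY_EDGES, nodes=STUDY_NODES)


def backdoor_sets(dag: Dag, exposure, outcome) -> list[tuple]:
    """All inclusion-minimal sufficient backdoor adjustment sets.

    A candidate set (never containing descendants of the exposure) is
    sufficient when it d-separates exposure and outcome in the *backdoor
    graph*, i.e. the diagram with the exposure's outgoing edges removed.
    Sets are returned sorted, smallest first then lexicographically, so the
    enumeration is deterministic.
    """
    g = dag.graph
    if exposure not in g or outcome not in g:
        raise KeyError("exposure and outcome must be nodes of the DAG")
    if exposure == outcome:
        raise ValueError("exposure and outcome must differ")
    backdoor = g.copy()
    backdoor.remove_edges_from(list(g.out_edges(exposure)))
    forbidden = nx.descendants(g, exposure) | {exposure, outcome}
    candidates = sorted(set(g.nodes) - forbidden)
    minimal: list[tuple] = []
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            if any(set(m) <= set(combo) for m in minimal):
                continue
            if nx.is_d_separator(backdoor, {exposure}, {outcome}, set(combo)):
                minimal.append(combo)
    return sorted(minimal, key=lambda s: (len(s), s))


@dataclass
class MediationDecomposition:
    """Product-method split of a total effect into pathway contributions.

    Effects live on the linear working scale (log-hazard); ``proportions``
    are each pathway's share of the total, and ``ci`` holds per-pathway
    percentile bootstrap intervals keyed like ``indirect``.
    """

    total_effect: float
    indirect: dict[str, float]
    direct: float
    proportions: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n_boot: int
    seed: int
    mode: str = "sequential"
    caveat: str = (
        "effects decomposed on a linear (log-hazard) working scale; shares "
        "are not transportable to non-collapsible scales such as hazard ratios"
    )

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _ols_coefs(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares coefficients with an implicit intercept column."""
    design = np.column_stack([np.ones(len(X)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta[1:]


def _product_method(
    y, x, M: np.ndarray, C: np.ndarray | None, mode: str
) -> tuple[float, np.ndarray, float]:
    """One product-method pass: (total, indirect per mediator, direct)."""
    conf = C if C is not None else np.empty((len(x), 0))
    k = M.shape[1]
    a = np.empty(k)
    for j in range(k):
        if mode == "parallel" and j > 0:
            design = np.column_stack([x, M[:, :j], conf])
        else:
            design = np.column_stack([x, conf])
        a[j] = _ols_coefs(M[:, j], design)[0]
    full = _ols_coefs(y, np.column_stack([x, M, conf]))
    direct, b = full[0], full[1:k + 1]
    # In sequential mode the omitted-variable identity makes this total
    # exactly direct + sum(a*b); computing it from its own regression keeps
    # the additivity check a genuine numerical identity.
    total = _ols_coefs(y, np.column_stack([x, conf]))[0]
    return float(total), a * b, float(direct)


def decompose(
    cohort: pd.DataFrame,
    mediator_spec: dict | None = None,
    n_boot: int = params.N_BOOTSTRAP,
    seed: int = 0,
    mode: str = "sequential",
    ci_level: float = 0.95,
    max_mediator_levels: int = 10,
) -> MediationDecomposition:
    """Product-method mediation decomposition with percentile bootstrap.

    Parameters
    ----------
    cohort
        Patient table holding the exposure, mediator and outcome columns.
    mediator_spec
        Mapping with keys ``exposure``, ``mediators`` (ordered list),
        ``outcome`` and optionally ``confounders``.  Defaults to the
        mediation-cohort column names.
    n_boot
        Bootstrap replications (1,000 by default).
    mode
        ``"sequential"`` (default) uses the marginal exposure→mediator
        coefficient, so each indirect term captures every path entering the
        outcome through that mediator and the split is exactly additive.
        ``"parallel"`` conditions each mediator model on the earlier
        mediators instead, attributing only the direct exposure→mediator
        path; additivity then holds only approximately.

    Raises
    ------
    ValueError
        If the total effect is numerically zero (shares undefined) or a
        mediator is not binary/ordinal (more distinct levels than
        ``max_mediator_levels``).
    """
    if mediator_spec is None:
        mediator_spec = {
            "exposure": "exposure",
            "mediators": ["stage_migration", "treatment_intensity", "complications"],
            "outcome": "outcome",
        }
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if mode not in ("sequential", "parallel"):
        raise ValueError(f"unknown mode {mode!r}")
    exposure = mediator_spec["exposure"]
    mediators = list(mediator_spec["mediators"])
    outcome = mediator_spec["outcome"]
    confounders = list(mediator_spec.get("confounders", []))

    x = cohort[exposure].to_numpy(dtype=float)
    y = cohort[outcome].to_numpy(dtype=float)
    M = cohort[mediators].to_numpy(dtype=float)
    C = cohort[confounders].to_numpy(dtype=float) if confounders else None
    for name, col in zip(mediators, M.T):
        if len(np.unique(col)) > max_mediator_levels:
            raise ValueError(
                f"mediator {name!r} is not binary/ordinal "
                f"(> {max_mediator_levels} distinct levels)"
            )

    total, indirect, direct = _product_method(y, x, M, C, mode)
    if abs(total) < 1e-12:
        raise ValueError("total effect is numerically zero; shares undefined")

    rng = np.random.default_rng(seed)
    n = len(x)
    stats = np.empty((n_boot, len(mediators) + 2))
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        t_b, ind_b, d_b = _product_method(
            y[idx], x[idx], M[idx], C[idx] if C is not None else None, mode
        )
        if abs(t_b) < 1e-12:
            t_b = np.nan
        stats[r, :len(mediators)] = ind_b / t_b
        stats[r, len(mediators)] = d_b / t_b
        stats[r, -1] = t_b

    lo, hi = (1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100
    names = mediators + ["direct"]
    point = list(indirect / total) + [direct / total]
    ci = {
        name: tuple(np.nanpercentile(stats[:, j], [lo, hi]))
        for j, name in enumerate(names)
    }
    ci["total_effect"] = tuple(np.nanpercentile(stats[:, -1], [lo, hi]))
    return MediationDecomposition(
        total_effect=total,
        indirect=dict(zip(mediators, (float(v) for v in indirect))),
        direct=direct,
        proportions=dict(zip(names, (float(p) for p in point))),
        ci=ci,
        n_boot=n_boot,
        seed=seed,
        mode=mode,
    )


def residual_direct(proportions_mediated) -> float:
    """Direct-effect share left after the mediated shares: ``1 - sum``."""
    props = [float(p) for p in proportions_mediated]
    if any(not 0.0 <= p <= 1.0 for p in props):
        raise ValueError("proportions must lie in [0, 1]")
    s = sum(props)
    if s > 1.0 + 1e-9:
        raise ValueError(f"mediated proportions sum to {s} > 1")
    return 1.0 - s


def dag_to_edgelist(dag: Dag, path) -> None:
    """Serialise as one ``parent child`` pair per line."""
    with open(path, "w") as fh:
        for u, v in sorted(dag.edges):
            fh.write(f"{u} {v}\n")


def dag_from_edgelist(path) -> Dag:
    """Read a ``parent child`` per-line edge list."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                u, v = line.split()
                edges.append((u, v))
    return build_dag(edges)
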