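"""Testable implications, violation-driven DAG edits, and estimand plans.

A DAG's testable implications are the vanishing / non-vanishing partial
regression coefficients entailed by its d-separation structure.  When data
contradict an implication (per the Bayes-factor test), an analyst who trusts
the data over the hypothesized structure edits the DAG:

confounder motif (implications, all expected nonzero):
    b_YX.C violated  -> delete X -> Y
    b_YC.X violated  -> delete C -> Y
    b_XC   violated  -> delete C -> X

collider motif (six implications; three expected zero, three nonzero):
    b_YX.C   (zero)    violated -> add    X -> Y
    b_YW.C   (zero)    violated -> add    W -> Y
    b_WX     (zero)    violated -> add    W -> X   (direction fixed by
                                                    domain/temporal knowledge)
    b_CW.XY  (nonzero) violated -> delete W -> C
    b_CX.WY  (nonzero) violated -> delete X -> C
    b_YC.WX  (nonzero) violated -> delete C -> Y

Adaptation is one-shot: all implications are tested on the same dataset, the
edits are applied together, and the causal-effect estimands are re-derived
on the modified DAG via path tracing with per-edge single-door adjustment
sets.  Each edge coefficient is then estimated as the posterior mean of the
corresponding Bayesian ridge regression, so ACE = DE + IE holds by
construction on the estimates as well.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .bayes_test import BfResult, RegressionSpec, check_implication, fit_bayes_linreg
from .graphs import Dag, Edge, Node, directed_paths, single_door_set
from .scm import CONFOUNDER_DAG, COLLIDER_DAG, EffectTriple, SampleMatrix

__all__ = [
    "Implication",
    "ViolationPattern",
    "EstimandPlan",
    "confounder_implications",
    "collider_implications",
    "implications_for",
    "apply_edits",
    "evaluate_implications",
    "estimand_plan",
    "estimate_effects",
    "confounder_case_table",
    "all_patterns",
]

MOTIFS = ("confounder", "collider")


@dataclass(frozen=True)
class Implication:
    """One testable implication: a regression coefficient and its expected state."""

    spec: RegressionSpec
    expected: str  # "zero" | "nonzero"
    label: str

    def __post_init__(self) -> None:
        if self.expected not in ("zero", "nonzero"):
            raise ValueError("expected must be 'zero' or 'nonzero'")


@dataclass(frozen=True)
class ViolationPattern:
    """The ordered subset of implication labels flagged violated."""

    violated: tuple[str, ...]

    def __init__(self, violated=()):
        object.__setattr__(self, "violated", tuple(violated))
        if len(set(self.violated)) != len(self.violated):
            raise ValueError("duplicate labels in violation pattern")

    def __contains__(self, label: str) -> bool:
        return label in self.violated

    def __bool__(self) -> bool:
        return bool(self.violated)

    def as_key(self) -> str:
        """Canonical string form, used in result tables ("" when empty)."""
        return ";".join(self.violated)


def confounder_implications() -> tuple[Implication, ...]:
    """The three implications of the confounder DAG, all expected nonzero.

    The marginal X~C coefficient is used instead of the Y-adjusted one to
    avoid opening the collider Y on C -> Y <- X.
    """
    return (
        Implication(RegressionSpec("Y", "X", frozenset({"C"})), "nonzero", "b_YX.C"),
        Implication(RegressionSpec("Y", "C", frozenset({"X"})), "nonzero", "b_YC.X"),
        Implication(RegressionSpec("X", "C", frozenset()), "nonzero", "b_XC"),
    )


def collider_implications() -> tuple[Implication, ...]:
    """The six implications of the collider DAG.

    The candidate implication b_WX.C != 0 is omitted: whenever b_WX = 0
    holds its violation is equivalent to the b_CW.XY check, and whenever
    b_WX = 0 is violated it holds automatically, so it carries no
    information.
    """
    return (
        Implication(RegressionSpec("Y", "X", frozenset({"C"})), "zero", "b_YX.C"),
        Implication(RegressionSpec("Y", "W", frozenset({"C"})), "zero", "b_YW.C"),
        Implication(
            RegressionSpec("C", "W", frozenset({"X", "Y"})), "nonzero", "b_CW.XY"
        ),
        Implication(RegressionSpec("W", "X", frozenset()), "zero", "b_WX"),
        Implication(
            RegressionSpec("C", "X", frozenset({"W", "Y"})), "nonzero", "b_CX.WY"
        ),
        Implication(
            RegressionSpec("Y", "C", frozenset({"W", "X"})), "nonzero", "b_YC.WX"
        ),
    )


def implications_for(motif: str) -> tuple[Implication, ...]:
    if motif == "confounder":
        return confounder_implications()
    if motif == "collider":
        return collider_implications()
    raise ValueError(f"unknown motif {motif!r}")


# label -> (action, edge)
_CONFOUNDER_EDITS: dict[str, tuple[str, Edge]] = {
    "b_YX.C": ("delete", ("X", "Y")),
    "b_YC.X": ("delete", ("C", "Y")),
    "b_XC": ("delete", ("C", "X")),
}
_COLLIDER_EDITS: dict[str, tuple[str, Edge]] = {
    "b_YX.C": ("add", ("X", "Y")),
    "b_YW.C": ("add", ("W", "Y")),
    "b_WX": ("add", ("W", "X")),
    "b_CW.XY": ("delete", ("W", "C")),
    "b_CX.WY": ("delete", ("X", "C")),
    "b_YC.WX": ("delete", ("C", "Y")),
}


def apply_edits(motif: str, pattern: ViolationPattern) -> Dag:
    """Modified DAG after applying the motif's edit rule for each violation.

    Edits are set-based on disjoint edges, hence order-independent; the
    empty pattern returns the original motif DAG unchanged.
    """
    if motif == "confounder":
        dag, edits = CONFOUNDER_DAG, _CONFOUNDER_EDITS
    elif motif == "collider":
        dag, edits = COLLIDER_DAG, _COLLIDER_EDITS
    else:
        raise ValueError(f"unknown motif {motif!r}")
    for label in pattern.violated:
        if label not in edits:
            raise KeyError(f"unknown implication label {label!r} for {motif}")
        action, (u, v) = edits[label]
        dag = dag.without_edge(u, v) if action == "delete" else dag.with_edge(u, v)
    return dag


def evaluate_implications(
    data: SampleMatrix,
    implications: tuple[Implication, ...],
    prior_sd: float = 1.0,
    cache: dict | None = None,
) -> tuple[ViolationPattern, dict[str, BfResult]]:
    """Bayes-factor test of every implication on one dataset."""
    cache = {} if cache is None else cache
    violated: list[str] = []
    details: dict[str, BfResult] = {}
    for imp in implications:
        is_violated, detail = check_implication(
            data, imp.spec, imp.expected, prior_sd, cache
        )
        details[imp.label] = detail
        if is_violated:
            violated.append(imp.label)
    return ViolationPattern(violated), details


@dataclass(frozen=True)
class EstimandPlan:
    """How to assemble ACE/DE/IE estimates on a (possibly modified) DAG.

    ``ace_terms`` lists, per directed x->y path, the traversed edges with
    the single-door adjustment set identifying each edge coefficient.
    ``de_term`` is the direct edge's entry when x -> y is present.  When any
    needed edge coefficient lacks a single-door set among the observables,
    ``identifiable`` is False and no estimate is defined.
    """

    modified_dag: Dag
    x: Node
    y: Node
    ace_terms: tuple[tuple[tuple[tuple[Edge, frozenset[Node] | None], ...]], ...]
    de_term: tuple[Edge, frozenset[Node] | None] | None
    identifiable: bool


def estimand_plan(modified: Dag, x: Node, y: Node) -> EstimandPlan:
    """Path-tracing estimand of ACE/DE/IE on ``modified``.

    ACE is the sum over directed x->y paths of products of edge
    coefficients, each identified by its minimal single-door set; DE is the
    direct-edge coefficient (0 when the edge is absent); IE = ACE - DE.
    """
    modified._require(x, y)
    terms = []
    identifiable = True
    sd_cache: dict[Edge, frozenset[Node] | None] = {}

    def door(edge: Edge) -> frozenset[Node] | None:
        if edge not in sd_cache:
            sd_cache[edge] = single_door_set(modified, edge)
        return sd_cache[edge]

    for path in directed_paths(modified, x, y):
        entries = []
        for edge in path.edges():
            z = door(edge)
            if z is None:
                identifiable = False
            entries.append((edge, z))
        terms.append(tuple(entries))
    de_term = None
    if modified.has_edge(x, y):
        de_term = (((x, y)), door((x, y)))
    return EstimandPlan(
        modified_dag=modified,
        x=x,
        y=y,
        ace_terms=tuple(terms),
        de_term=de_term,
        identifiable=identifiable,
    )


def estimate_effects(
    data: SampleMatrix,
    plan: EstimandPlan,
    prior_sd: float = 1.0,
    cache: dict | None = None,
) -> EffectTriple:
    """Plug posterior-mean edge coefficients into the plan.

    Components the plan declares structurally zero (no directed path / no
    direct edge) are exactly 0, not estimated.
    """
    if not plan.identifiable:
        raise ValueError("plan is not identifiable; no estimate defined")
    cache = {} if cache is None else cache

    def edge_estimate(edge: Edge, z: frozenset[Node]) -> float:
        parent, child = edge
        spec = RegressionSpec(child, parent, z)
        fit = fit_bayes_linreg(data, spec, prior_sd, cache)
        return fit.coefficient(parent)[0]

    ace = 0.0
    for entries in plan.ace_terms:
        prod = 1.0
        for edge, z in entries:
            prod *= edge_estimate(edge, z)
        ace += prod
    de = 0.0
    if plan.de_term is not None:
        de = edge_estimate(*plan.de_term)
    return EffectTriple(ace=ace, de=de, ie=ace - de)


# The eight confounder violation cases, spelled out as the symbolic estimand
# an analyst following the edit rules would write down.  ACE and DE always
# coincide and IE is always 0 for this motif.  Used only to cross-validate
# the generic plan engine.
_CONFOUNDER_CASES: dict[frozenset[str], str] = {
    frozenset(): "beta_YX|C",
    frozenset({"b_YX.C"}): "0",
    frozenset({"b_YC.X"}): "beta_YX",
    frozenset({"b_XC"}): "beta_YX",
    frozenset({"b_YX.C", "b_YC.X"}): "0",
    frozenset({"b_YX.C", "b_XC"}): "0",
    frozenset({"b_YC.X", "b_XC"}): "beta_YX",
    frozenset({"b_YX.C", "b_YC.X", "b_XC"}): "0",
}


def confounder_case_table(pattern: ViolationPattern) -> dict[str, str]:
    """Symbolic ACE/DE/IE estimand for each of the 2^3 confounder patterns."""
    key = frozenset(pattern.violated)
    if key not in _CONFOUNDER_CASES:
        raise KeyError(f"not a confounder violation pattern: {pattern.violated}")
    ace = _CONFOUNDER_CASES[key]
    return {"ace": ace, "de": ace, "ie": "0"}


def all_patterns(motif: str) -> list[ViolationPattern]:
    """Every violation pattern of the motif (including the empty one)."""
    labels = [imp.label for imp in implications_for(motif)]
    out = []
    for k in range(len(labels) + 1):
        for combo in itertools.combinations(labels, k):
            out.append(ViolationPattern(combo))
    return out
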