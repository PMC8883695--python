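"""Monte Carlo estimation of the causal false-positive risk and induced bias.

One *replicate* mimics an analyst holding the true DAG: draw a dataset from
the true SCM, Bayes-factor-test every testable implication, edit the DAG
wherever an implication is violated, and compute the average / direct /
indirect effect of treatment X on outcome Y from the (possibly modified)
DAG.  A replicate with at least one violation has rejected the true model.

Across replicates this yields

* the causal false-positive risk (FPR): the fraction of replicates with a
  nonempty violation pattern, and
* the Monte Carlo means of the adaptively-selected ACE/DE/IE estimates,
  whose drift away from the true path-tracing effects is the bias induced
  by falsely rejecting the true model.

The settings grid mirrors the published study design: balanced and
unbalanced coefficient patterns for each motif, sample sizes between 10 and
100 per variable, standard-normal errors.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .adaptation import (
    EstimandPlan,
    ViolationPattern,
    apply_edits,
    estimand_plan,
    estimate_effects,
    evaluate_implications,
    implications_for,
)
from .scm import EffectTriple, LinearSCM, collider_model, confounder_model, simulate, true_effects, zscore

__all__ = [
    "StudySetting",
    "ReplicateRecord",
    "StudyResult",
    "model_for",
    "run_replicate",
    "run_study",
    "settings_registry",
    "bias_summary",
    "run_over_sample_sizes",
    "results_to_frame",
]

TREATMENT = "X"
OUTCOME = "Y"


@dataclass(frozen=True)
class StudySetting:
    """One cell of the simulation grid."""

    motif: str
    alpha: float
    beta: float
    gamma: float
    n: int
    reps: int
    master_seed: int
    standardize: bool = False
    prior_sd: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.motif not in ("confounder", "collider"):
            raise ValueError(f"unknown motif {self.motif!r}")
        if self.n < 2:
            raise ValueError("sample size must be at least 2")
        if self.reps < 1:
            raise ValueError("replicate count must be >= 1")
        if not 0 <= int(self.master_seed) < 2**63:
            raise ValueError("master_seed must be a non-negative integer")
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")


@dataclass(frozen=True)
class ReplicateRecord:
    """Outcome of a single simulated analysis."""

    index: int
    pattern: ViolationPattern
    effects: EffectTriple | None   # None when the modified DAG is unidentifiable
    bf01: dict[str, float]

    @property
    def rejected_true_model(self) -> bool:
        return bool(self.pattern)


@dataclass(frozen=True)
class StudyResult:
    """Aggregate over all replicates of one setting."""

    setting: StudySetting
    fpr: float
    mean_ace: float
    mean_de: float
    mean_ie: float
    se_ace: float
    se_de: float
    se_ie: float
    true_ace: float
    true_de: float
    true_ie: float
    pattern_frequencies: dict[str, int]
    undefined_count: int

    @property
    def reps(self) -> int:
        return self.setting.reps


def model_for(setting: StudySetting) -> LinearSCM:
    builder = confounder_model if setting.motif == "confounder" else collider_model
    return builder(setting.alpha, setting.beta, setting.gamma)


def _replicate_rng(master_seed: int, index: int) -> np.random.Generator:
    # Counter-based derivation: any single replicate is reproducible alone.
    return np.random.default_rng(
        np.random.SeedSequence(int(master_seed), spawn_key=(int(index),))
    )


def run_replicate(
    setting: StudySetting,
    replicate_index: int,
    _model: LinearSCM | None = None,
    _implications=None,
    _plan_cache: dict | None = None,
) -> ReplicateRecord:
    """simulate -> test implications -> edit DAG -> recompute effects.

    Deterministic given ``(setting.master_seed, replicate_index)``.  The
    underscore arguments let :func:`run_study` share per-setting immutables
    across replicates; results are identical without them.
    """
    model = _model if _model is not None else model_for(setting)
    implications = (
        _implications if _implications is not None else implications_for(setting.motif)
    )
    rng = _replicate_rng(setting.master_seed, replicate_index)
    data = simulate(model, setting.n, rng)
    if setting.standardize:
        data = zscore(data)
    fit_cache: dict = {}
    pattern, details = evaluate_implications(
        data, implications, setting.prior_sd, fit_cache
    )
    plan = _plan_for(setting.motif, pattern, _plan_cache)
    effects = None
    if plan.identifiable:
        effects = estimate_effects(data, plan, setting.prior_sd, fit_cache)
    return ReplicateRecord(
        index=replicate_index,
        pattern=pattern,
        effects=effects,
        bf01={label: d.bf01 for label, d in details.items()},
    )


def _plan_for(
    motif: str, pattern: ViolationPattern, plan_cache: dict | None
) -> EstimandPlan:
    key = (motif, pattern.as_key())
    if plan_cache is not None and key in plan_cache:
        return plan_cache[key]
    plan = estimand_plan(apply_edits(motif, pattern), TREATMENT, OUTCOME)
    if plan_cache is not None:
        plan_cache[key] = plan
    return plan


def run_study(
    setting: StudySetting,
    keep_replicates: bool = False,
) -> StudyResult | tuple[StudyResult, list[ReplicateRecord]]:
    """Run all replicates of one setting and aggregate.

    FPR is the number of replicates with at least one violated implication
    divided by the total number of replicates.  Effect means average over
    all replicates with defined (identifiable) effects; structurally zero
    estimands enter as exact 0.  MC standard errors accompany each mean.
    """
    model = model_for(setting)
    implications = implications_for(setting.motif)
    plan_cache: dict = {}
    records: list[ReplicateRecord] = []
    for i in range(setting.reps):
        records.append(
            run_replicate(
                setting,
                i,
                _model=model,
                _implications=implications,
                _plan_cache=plan_cache,
            )
        )
    truth = true_effects(model, TREATMENT, OUTCOME)
    defined = [r.effects for r in records if r.effects is not None]
    undefined_count = setting.reps - len(defined)
    ace = np.array([e.ace for e in defined])
    de = np.array([e.de for e in defined])
    ie = np.array([e.ie for e in defined])

    def mean_se(v: np.ndarray) -> tuple[float, float]:
        if v.size == 0:
            return math.nan, math.nan
        se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else math.nan
        return float(v.mean()), se

    (m_ace, s_ace), (m_de, s_de), (m_ie, s_ie) = map(mean_se, (ace, de, ie))
    freqs = Counter(r.pattern.as_key() for r in records)
    result = StudyResult(
        setting=setting,
        fpr=sum(1 for r in records if r.rejected_true_model) / setting.reps,
        mean_ace=m_ace,
        mean_de=m_de,
        mean_ie=m_ie,
        se_ace=s_ace,
        se_de=s_de,
        se_ie=s_ie,
        true_ace=truth.ace,
        true_de=truth.de,
        true_ie=truth.ie,
        pattern_frequencies=dict(freqs),
        undefined_count=undefined_count,
    )
    if keep_replicates:
        return result, records
    return result


# Coefficient grids as printed in the study design: (label, alpha, beta, gamma).
_CONFOUNDER_GRID: tuple[tuple[str, float, float, float], ...] = tuple(
    [
        (name, a, bg, bg)
        for a in (0.25, 0.5)
        for name, bg in (
            ("Weak Confounder", 0.125),
            ("Balanced Confounder", 0.25),
            ("Strong Confounder", 0.5),
            ("Very strong Confounder", 1.0),
        )
    ]
    + [
        ("Unbalanced Confounder", a, b, g)
        for a in (0.25, 0.5)
        for b, g in ((0.25, 0.75), (0.75, 0.25), (0.1, 0.9), (0.9, 0.1))
    ]
)

_COLLIDER_GRID: tuple[tuple[str, float, float, float], ...] = tuple(
    [
        ("Balanced", ab, ab, g)
        for g in (0.25, 0.5, 1.0)
        for ab in (0.25, 0.5, 1.0)
    ]
    + [
        ("Unbalanced", a, b, g)
        for g in (0.25, 0.5, 1.0)
        for a, b in ((1 / 3, 2 / 3), (2 / 3, 1 / 3))
    ]
    + [
        ("Unbalanced", a, b, g)
        for g in (0.25, 0.5, 1.0)
        for a, b in ((0.1, 0.9), (0.9, 0.1))
    ]
)


def settings_registry(
    motif: str,
    n: int = 100,
    reps: int = 2000,
    master_seed: int = 0,
    standardize: bool = False,
    prior_sd: float = 1.0,
) -> list[StudySetting]:
    """The published coefficient grid for one motif as StudySettings.

    16 confounder settings and 21 collider settings; each setting receives a
    distinct sub-seed derived from ``master_seed``.
    """
    if motif == "confounder":
        grid = _CONFOUNDER_GRID
    elif motif == "collider":
        grid = _COLLIDER_GRID
    else:
        raise ValueError(f"unknown motif {motif!r}")
    children = np.random.SeedSequence(int(master_seed)).spawn(len(grid))
    out = []
    for (label, a, b, g), child in zip(grid, children):
        out.append(
            StudySetting(
                motif=motif,
                alpha=a,
                beta=b,
                gamma=g,
                n=n,
                reps=reps,
                master_seed=int(child.generate_state(1)[0] % 2**31),
                standardize=standardize,
                prior_sd=prior_sd,
                label=label,
            )
        )
    return out


def bias_summary(result: StudyResult) -> dict[str, dict[str, float | None]]:
    """Absolute and (where defined) relative bias of each effect mean."""
    out: dict[str, dict[str, float | None]] = {}
    for name in ("ace", "de", "ie"):
        mean = getattr(result, f"mean_{name}")
        true = getattr(result, f"true_{name}")
        absolute = mean - true
        relative = absolute / true if true != 0 else None
        out[name] = {"absolute": absolute, "relative": relative}
    return out


def run_over_sample_sizes(
    setting: StudySetting, n_grid: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)
) -> list[StudyResult]:
    """Repeat one coefficient setting across a sample-size grid."""
    return [run_study(replace(setting, n=n)) for n in n_grid]


def results_to_frame(results: list[StudyResult]) -> pd.DataFrame:
    """Tidy one-row-per-result table (setting fields, FPR, means, SEs, truths)."""
    rows = []
    for r in results:
        s = r.setting
        rows.append(
            {
                "motif": s.motif,
                "label": s.label,
                "alpha": s.alpha,
                "beta": s.beta,
                "gamma": s.gamma,
                "n": s.n,
                "reps": s.reps,
                "master_seed": s.master_seed,
                "standardize": s.standardize,
                "prior_sd": s.prior_sd,
                "fpr": r.fpr,
                "mean_ace": r.mean_ace,
                "se_ace": r.se_ace,
                "mean_de": r.mean_de,
                "se_de": r.se_de,
                "mean_ie": r.mean_ie,
                "se_ie": r.se_ie,
                "true_ace": r.true_ace,
                "true_de": r.true_de,
                "true_ie": r.true_ie,
                "undefined_count": r.undefined_count,
            }
        )
    return pd.DataFrame(rows)
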