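"""Interaction detection and Markov-blanket learning for a leaf outcome.

A candidate set ``S`` (size >= 2) is reported *interactive* when the
outcome's BDeu family score given ``S`` exceeds the score given every
proper subset of ``S`` (including the empty set) — a nonadditive joint
effect.  Singletons are reported when they beat the empty set.  The
blanket is then assembled by greedy forward selection over the reported
candidate sets (maximizing the outcome's family score) followed by
backward pruning, terminating at a local optimum.

Only the outcome's families are ever scored: the outcome is treated as a
leaf, so its Markov blanket is exactly its parent set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .bdeu import ScoreCache, family_score
from .schema_io import DiscreteDataset, VariableSchema

__all__ = [
    "InteractionResult",
    "MarkovBlanketResult",
    "enumerate_candidates",
    "detect_interactions",
    "learn_markov_blanket",
    "run_sweep",
]

# Candidate parent sets whose configuration count exceeds this are never
# scored: they could not carry usable counts at clinical sample sizes.
MAX_PARENT_CONFIGS = 1_000_000


@dataclass(frozen=True)
class InteractionResult:
    """A candidate variable set with its family score at one alpha."""

    variables: frozenset[str]
    log_score: float
    gain_over_best_subset: float
    classification: str  # "single" | "interactive"
    alpha: float
    horizon: int | None = None

    def __post_init__(self) -> None:
        if self.classification == "interactive" and len(self.variables) < 2:
            raise ValueError("interactive sets need >= 2 variables")

    def sort_key(self) -> tuple:
        return (-self.log_score, len(self.variables), tuple(sorted(self.variables)))


@dataclass
class MarkovBlanketResult:
    """Selected direct causal sets plus the remaining interactive sets."""

    direct_sets: list[InteractionResult]
    other_interactions: list[InteractionResult]
    horizon: int | None
    alpha: float
    log_score: float  # family score of the outcome given the learned parents

    @property
    def parent_set(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for item in self.direct_sets:
            out |= item.variables
        return out


def enumerate_candidates(
    predictors: Sequence[str] | VariableSchema, max_size: int
) -> Iterator[tuple[str, ...]]:
    """All predictor subsets of size 1..max_size, lexicographic order."""
    if max_size not in (1, 2, 3):
        raise ValueError("max_size must be 1, 2 or 3")
    if isinstance(predictors, VariableSchema):
        predictors = predictors.predictor_names
    for size in range(1, max_size + 1):
        yield from combinations(predictors, size)


def _check_outcome(data: DiscreteDataset, outcome: str) -> None:
    if data.n == 0:
        raise ValueError("empty dataset")
    if data.cardinality(outcome) != 2:
        raise ValueError(f"outcome {outcome!r} is not binary in this dataset")


def _configs(data: DiscreteDataset, variables: Iterable[str]) -> int:
    out = 1
    for v in variables:
        out *= data.cardinality(v)
    return out


def detect_interactions(
    data: DiscreteDataset,
    outcome: str,
    alpha: float,
    max_size: int = 3,
    horizon: int | None = None,
    cache: ScoreCache | None = None,
) -> list[InteractionResult]:
    """Rank singles and nonadditive sets by BDeu family score.

    Returns results sorted by score descending; ties broken by smaller
    set, then lexicographic names.  ``gain_over_best_subset`` is the score
    margin over the best proper subset (the empty set for singletons) and
    is strictly positive for every reported set.
    """
    _check_outcome(data, outcome)
    cache = cache if cache is not None else ScoreCache()
    predictors = tuple(c for c in data.columns if c not in data.schema.outcome_names)

    scores: dict[frozenset, float] = {
        frozenset(): family_score(data, outcome, (), alpha, cache).log_score
    }
    for cand in enumerate_candidates(predictors, max_size):
        if _configs(data, cand) > MAX_PARENT_CONFIGS:
            continue
        scores[frozenset(cand)] = family_score(data, outcome, cand, alpha, cache).log_score

    results: list[InteractionResult] = []
    for varset, score in scores.items():
        if not varset:
            continue
        members = sorted(varset)
        proper_subsets = [frozenset()] + [
            frozenset(c)
            for size in range(1, len(varset))
            for c in combinations(members, size)
        ]
        best_subset = max(scores[s] for s in proper_subsets if s in scores)
        gain = score - best_subset
        if gain <= 0:
            continue
        results.append(
            InteractionResult(
                variables=varset,
                log_score=score,
                gain_over_best_subset=gain,
                classification="single" if len(varset) == 1 else "interactive",
                alpha=alpha,
                horizon=horizon,
            )
        )
    results.sort(key=InteractionResult.sort_key)
    return results


def learn_markov_blanket(
    data: DiscreteDataset,
    outcome: str,
    alpha: float,
    max_size: int = 3,
    horizon: int | None = None,
    cache: ScoreCache | None = None,
    candidates: Sequence[InteractionResult] | None = None,
    log: list[str] | None = None,
) -> MarkovBlanketResult:
    """Greedy forward/backward selection of direct causal sets.

    Forward steps add the candidate set that most improves the outcome's
    family score (strict improvement required); backward passes drop any
    selected set whose removal does not lower the score (this also prunes
    sets made redundant by later additions).
    """
    _check_outcome(data, outcome)
    cache = cache if cache is not None else ScoreCache()
    if candidates is None:
        candidates = detect_interactions(
            data, outcome, alpha, max_size=max_size, horizon=horizon, cache=cache
        )

    def fam(vars_: frozenset) -> float:
        return family_score(data, outcome, vars_, alpha, cache).log_score

    selected: list[InteractionResult] = []
    cur_vars: frozenset = frozenset()
    cur_score = fam(cur_vars)
    if log is not None:
        log.append(f"start score={cur_score:.6f}")

    while True:
        best: InteractionResult | None = None
        best_score = cur_score
        for cand in candidates:
            if cand in selected:
                continue
            union = cur_vars | cand.variables
            if union == cur_vars or _configs(data, union) > MAX_PARENT_CONFIGS:
                continue
            s = fam(union)
            if s > best_score + 1e-12 or (
                best is not None
                and abs(s - best_score) <= 1e-12
                and cand.sort_key() < best.sort_key()
            ):
                best, best_score = cand, s
        if best is None:
            break
        selected.append(best)
        cur_vars |= best.variables
        if log is not None:
            log.append(
                f"add {sorted(best.variables)} score={best_score:.6f} (+{best_score - cur_score:.6f})"
            )
        cur_score = best_score

        # backward pruning after every acceptance
        pruned = True
        while pruned and len(selected) > 1:
            pruned = False
            for item in list(selected):
                rest = [s for s in selected if s is not item]
                union = frozenset().union(*(s.variables for s in rest)) if rest else frozenset()
                s = fam(union)
                if s >= cur_score - 1e-12:
                    selected = rest
                    cur_vars = union
                    if log is not None:
                        log.append(f"drop {sorted(item.variables)} score={s:.6f}")
                    cur_score = s
                    pruned = True
                    break

    selected.sort(key=InteractionResult.sort_key)
    others = [
        c
        for c in candidates
        if c.classification == "interactive" and all(c.variables != s.variables for s in selected)
    ]
    return MarkovBlanketResult(
        direct_sets=selected,
        other_interactions=others,
        horizon=horizon,
        alpha=alpha,
        log_score=cur_score,
    )


def run_sweep(
    data: DiscreteDataset,
    schema: VariableSchema | None = None,
    horizons: Sequence[int] = (5, 10, 15),
    alphas: Sequence[float] = (1, 120, 480),
    max_size: int = 3,
    log: list[str] | None = None,
) -> dict[tuple[int, float], MarkovBlanketResult]:
    """One blanket-learning run per (horizon, alpha) pair.

    Count tables are shared across alphas through a single cache, so the
    sweep costs one counting pass per horizon.  Deterministic given the
    data: there is no randomness in learning.
    """
    schema = schema or data.schema
    results: dict[tuple[int, float], MarkovBlanketResult] = {}
    for horizon in horizons:
        outcome = schema.outcome_for_horizon(horizon)
        if outcome not in data.columns:
            raise ValueError(f"outcome column {outcome!r} missing from dataset")
        cache = ScoreCache()
        for alpha in alphas:
            if log is not None:
                log.append(f"== horizon={horizon} alpha={alpha:g} ==")
            results[(horizon, float(alpha))] = learn_markov_blanket(
                data,
                outcome,
                float(alpha),
                max_size=max_size,
                horizon=horizon,
                cache=cache,
                log=log,
            )
    return results
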