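"""Ground-truth Bayesian networks and forward-sampled discrete cohorts.

Provides three builders:

* :func:`build_benchmark_spec` — a 17-predictor binary network whose leaf
  outcome ``T`` has parents ``X11..X15``; ``{X13, X14}`` act on ``T``
  through a pure (zero-marginal) XOR term, and ``{X8, X9}`` jointly drive
  the parent ``X11`` through an XOR so they form an interactive pair
  outside the blanket.  Used for structure-recovery benchmarks.
* :func:`build_null_spec` — same predictor graph, outcome independent of
  everything (null calibration).
* :func:`build_clinical_like_spec` — a cohort shaped like the packaged
  31-variable clinical schema with a planted direct single effect
  (``Stage``), a planted XOR pair (``{TNEG, HER2}``) and a planted
  one-configuration "jackpot" triple (``{ER, n_tnm_stage,
  Surgical_margins}``) on each horizon's outcome.

Sampling is ancestral in topological order (ties broken alphabetically)
from a single generator seeded once per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .schema_io import DiscreteDataset, Variable, VariableSchema, clinical_schema

__all__ = [
    "GroundTruthSpec",
    "SimulationConfig",
    "EffectConfig",
    "build_benchmark_spec",
    "build_null_spec",
    "build_clinical_like_spec",
    "simulate_cohort",
    "recovery_metrics",
]


@dataclass(frozen=True)
class GroundTruthSpec:
    """A DAG with CPTs, a designated outcome and its planted effect sets.

    ``cpts[v]`` has shape ``(q, r)`` where ``q`` is the product of the
    parent cardinalities (mixed-radix, first listed parent most
    significant) and ``r`` the category count of ``v``.
    """

    variables: tuple[tuple[str, tuple[str, ...]], ...]  # ordered (name, categories)
    parents: Mapping[str, tuple[str, ...]]
    cpts: Mapping[str, np.ndarray]
    target: str
    direct_singles: tuple[str, ...] = ()
    interactive_sets: tuple[frozenset, ...] = ()
    noise_variables: tuple[str, ...] = ()
    outcome_names: tuple[str, ...] = ()
    horizons: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.outcome_names:
            object.__setattr__(self, "outcome_names", (self.target,))
        if not self.horizons:
            object.__setattr__(self, "horizons", tuple(range(5, 5 + 5 * len(self.outcome_names), 5)))
        self.validate()

    # -- structure helpers -------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.variables)

    def categories(self, name: str) -> tuple[str, ...]:
        for n, cats in self.variables:
            if n == name:
                return cats
        raise KeyError(name)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        for child, pars in self.parents.items():
            g.add_edges_from((p, child) for p in pars)
        return g

    def validate(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ground-truth graph is cyclic")
        for name, cats in self.variables:
            pars = tuple(self.parents.get(name, ()))
            q = int(np.prod([len(self.categories(p)) for p in pars])) if pars else 1
            cpt = np.asarray(self.cpts[name], dtype=float)
            if cpt.shape != (q, len(cats)):
                raise ValueError(f"CPT shape mismatch for {name!r}: {cpt.shape} != {(q, len(cats))}")
            if np.abs(cpt.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError(f"CPT rows of {name!r} do not sum to 1")
        t_parents = set(self.parents.get(self.target, ()))
        planted = set(self.direct_singles)
        for s in self.interactive_sets:
            planted |= {v for v in s if v in t_parents}
        if planted != t_parents:
            raise ValueError("planted singles/interactions do not cover the target's parents")
        if t_parents & set(self.noise_variables):
            raise ValueError("noise variables cannot be parents of the target")

    def schema(self) -> VariableSchema:
        predictors = tuple(
            Variable(name=name, categories=cats)
            for name, cats in self.variables
            if name not in self.outcome_names
        )
        return VariableSchema(
            variables=predictors,
            outcome_names=self.outcome_names,
            horizons=self.horizons,
            outcome_categories=self.categories(self.outcome_names[0]),
        )


@dataclass(frozen=True)
class SimulationConfig:
    n: int
    seed: int
    spec: GroundTruthSpec

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")


# ---------------------------------------------------------------------------
# CPT construction helpers (binary nodes)


def _binary_cpt(parents_cards: Sequence[int], p_one: Callable[[tuple[int, ...]], float]) -> np.ndarray:
    q = int(np.prod(parents_cards)) if parents_cards else 1
    cpt = np.empty((q, 2), dtype=float)
    for j, config in enumerate(product(*[range(c) for c in parents_cards])) if parents_cards else [(0, ())]:
        p = float(p_one(tuple(config)))
        cpt[j] = (1.0 - p, p)
    return cpt


def _root_cpt(probs: Sequence[float]) -> np.ndarray:
    return np.asarray([list(probs)], dtype=float)


def build_benchmark_spec() -> GroundTruthSpec:
    """17 binary predictors plus a leaf outcome with parents X11..X15."""
    b = ("0", "1")
    names = [f"X{i}" for i in range(1, 18)] + ["T"]
    variables = tuple((n, b) for n in names)
    parents: dict[str, tuple[str, ...]] = {n: () for n in names}
    cpts: dict[str, np.ndarray] = {}

    root_p = {
        "X1": 0.55, "X2": 0.45, "X3": 0.5, "X4": 0.5, "X5": 0.5,
        "X6": 0.5, "X7": 0.5, "X8": 0.5, "X9": 0.5,
    }
    for name, p in root_p.items():
        cpts[name] = _root_cpt([1 - p, p])

    parents["X10"] = ("X7",)
    cpts["X10"] = _binary_cpt([2], lambda c: 0.3 + 0.4 * c[0])

    # {X8, X9} drive X11 through a pure XOR: an interactive pair outside
    # the outcome's parent set.
    parents["X11"] = ("X8", "X9")
    cpts["X11"] = _binary_cpt([2, 2], lambda c: 0.15 + 0.70 * (c[0] ^ c[1]))

    parents["X12"] = ("X1", "X2")
    cpts["X12"] = _binary_cpt([2, 2], lambda c: 0.20 + 0.30 * c[0] + 0.30 * c[1])

    # X13 and X14 each keep a 0.5 marginal so the XOR term on T has an
    # exactly zero marginal effect.
    parents["X13"] = ("X3", "X10")
    cpts["X13"] = _binary_cpt([2, 2], lambda c: 0.5 + 0.15 * c[0] - 0.15 * c[1])

    parents["X14"] = ("X4", "X5")
    cpts["X14"] = _binary_cpt([2, 2], lambda c: 0.5 + 0.15 * c[0] - 0.15 * c[1])

    parents["X15"] = ("X6", "X7")
    cpts["X15"] = _binary_cpt([2, 2], lambda c: 0.20 + 0.30 * c[0] + 0.30 * c[1])

    parents["X16"] = ("X11",)
    cpts["X16"] = _binary_cpt([2], lambda c: 0.3 + 0.4 * c[0])
    parents["X17"] = ("X15",)
    cpts["X17"] = _binary_cpt([2], lambda c: 0.3 + 0.4 * c[0])

    parents["T"] = ("X11", "X12", "X13", "X14", "X15")
    cpts["T"] = _binary_cpt(
        [2] * 5,
        lambda c: 0.04 + 0.24 * c[0] + 0.19 * c[1] + 0.19 * c[4] + 0.30 * (c[2] ^ c[3]),
    )

    return GroundTruthSpec(
        variables=variables,
        parents=parents,
        cpts=cpts,
        target="T",
        direct_singles=("X11", "X12", "X15"),
        interactive_sets=(frozenset({"X13", "X14"}), frozenset({"X8", "X9"})),
        noise_variables=tuple(f"X{i}" for i in list(range(1, 11)) + [16, 17]),
    )


def build_null_spec() -> GroundTruthSpec:
    """The benchmark predictor graph with an outcome independent of it."""
    base = build_benchmark_spec()
    parents = dict(base.parents)
    cpts = dict(base.cpts)
    parents["T"] = ()
    cpts["T"] = _root_cpt([0.8, 0.2])
    return GroundTruthSpec(
        variables=base.variables,
        parents=parents,
        cpts=cpts,
        target="T",
        direct_singles=(),
        interactive_sets=(),
        noise_variables=tuple(n for n in base.names if n != "T"),
    )


@dataclass(frozen=True)
class EffectConfig:
    """Planted effect sizes for the clinical-like cohort."""

    base_rates: tuple[float, float, float] = (0.04, 0.06, 0.08)  # per horizon
    stage_coeffs: tuple[float, float, float, float] = (0.0, 0.02, 0.06, 0.25)
    pair_effect: float = 0.28  # XOR(TNEG = Yes, HER2 = pos)
    triple_effect: float = 0.60  # jackpot configuration bonus
    jackpot: tuple[tuple[str, str], ...] = (
        ("ER", "Neg"),
        ("n_tnm_stage", "4"),
        ("Surgical_margins", "Residual tumor"),
    )


def build_clinical_like_spec(seed: int = 0, effects: EffectConfig | None = None) -> GroundTruthSpec:
    """Schema-shaped cohort spec with planted single, pair and triple effects.

    Predictors are independent roots (Dirichlet-drawn marginals, seeded);
    TNEG and HER2 are fixed at 0.5/0.5 so the planted XOR pair has zero
    marginal effect.  Every horizon's outcome shares the same parent set
    and effect structure, differing only in base rate.
    """
    effects = effects or EffectConfig()
    schema = clinical_schema()
    rng = np.random.default_rng(seed)

    variables: list[tuple[str, tuple[str, ...]]] = []
    parents: dict[str, tuple[str, ...]] = {}
    cpts: dict[str, np.ndarray] = {}
    # Planted-effect variables get fixed marginals so the jackpot cell
    # carries enough mass to be learnable (and the XOR pair stays
    # zero-marginal); everything else draws a seeded Dirichlet marginal.
    fixed_marginals: dict[str, tuple[float, ...]] = {
        "TNEG": (0.5, 0.5),
        "HER2": (0.5, 0.5),
        "ER": (0.40, 0.45, 0.15),
        "n_tnm_stage": (0.25, 0.15, 0.15, 0.10, 0.30, 0.05),
        "Surgical_margins": (0.40, 0.50, 0.10),
        "Stage": (0.30, 0.30, 0.25, 0.15),
    }
    for var in schema.variables:
        variables.append((var.name, var.categories))
        parents[var.name] = ()
        r = var.n_categories
        if var.name in fixed_marginals:
            probs = np.asarray(fixed_marginals[var.name], dtype=float)
        else:
            probs = rng.dirichlet(np.full(r, 5.0))
        cpts[var.name] = _root_cpt(probs)

    pair = ("TNEG", "HER2")
    triple_vars = tuple(name for name, _ in effects.jackpot)
    jackpot_idx = tuple(
        schema.categories(name).index(tok) for name, tok in effects.jackpot
    )
    tneg_yes = schema.categories("TNEG").index("Yes")
    her2_pos = schema.categories("HER2").index("pos")

    def clip(p: float) -> float:
        return min(max(p, 0.01), 0.97)

    # Effects are planted on separate horizons: a joint family over all
    # planted parents at once would have ~900 configurations — far beyond
    # what n in the thousands can support — so no learner could recover
    # it.  The 5-year outcome carries the jackpot triple, the 10-year
    # outcome the direct single plus the XOR pair, the 15-year outcome the
    # direct single alone.
    out5, out10, out15 = schema.outcome_names
    b5, b10, b15 = effects.base_rates

    variables.append((out5, schema.outcome_categories))
    parents[out5] = triple_vars
    cpts[out5] = _binary_cpt(
        [len(schema.categories(p)) for p in triple_vars],
        lambda c: clip(b5 + (effects.triple_effect if tuple(c) == jackpot_idx else 0.0)),
    )

    pair10 = ("Stage",) + pair
    variables.append((out10, schema.outcome_categories))
    parents[out10] = pair10
    cpts[out10] = _binary_cpt(
        [len(schema.categories(p)) for p in pair10],
        lambda c: clip(
            b10
            + effects.stage_coeffs[c[0]]
            + effects.pair_effect * int((c[1] == tneg_yes) ^ (c[2] == her2_pos))
        ),
    )

    variables.append((out15, schema.outcome_categories))
    parents[out15] = ("Stage",)
    cpts[out15] = _binary_cpt(
        [len(schema.categories("Stage"))],
        lambda c: clip(b15 + effects.stage_coeffs[c[0]]),
    )

    # The 10-year outcome is the designated target for the blanket
    # invariant (its parents are the planted single plus the XOR pair);
    # the jackpot triple is planted on the 5-year outcome.
    planted = set(triple_vars) | set(pair) | {"Stage"}
    return GroundTruthSpec(
        variables=tuple(variables),
        parents=parents,
        cpts=cpts,
        target=out10,
        direct_singles=("Stage",),
        interactive_sets=(frozenset(pair), frozenset(triple_vars)),
        noise_variables=tuple(
            n for n in schema.predictor_names if n not in planted
        ),
        outcome_names=schema.outcome_names,
        horizons=schema.horizons,
    )


def simulate_cohort(config: SimulationConfig) -> DiscreteDataset:
    """Forward-sample ``n`` records ancestrally from the spec's DAG."""
    spec = config.spec
    spec.validate()
    rng = np.random.default_rng(config.seed)
    order = list(nx.lexicographical_topological_sort(spec.graph()))
    n = config.n
    sampled: dict[str, np.ndarray] = {}
    for name in order:
        cats = spec.categories(name)
        pars = tuple(spec.parents.get(name, ()))
        cpt = np.asarray(spec.cpts[name], dtype=float)
        if pars:
            codes = np.zeros(n, dtype=np.int64)
            for p in pars:
                codes = codes * len(spec.categories(p)) + sampled[p]
            probs = cpt[codes]
        else:
            probs = np.broadcast_to(cpt[0], (n, len(cats)))
        u = rng.random(n)
        cum = np.cumsum(probs, axis=1)
        sampled[name] = np.minimum(
            (u[:, None] > cum).sum(axis=1), len(cats) - 1
        ).astype(np.int64)

    schema = clinical_schema() if set(spec.outcome_names) == {
        "metastasis_5yr", "metastasis_10yr", "metastasis_15yr"
    } else spec.schema()
    columns = tuple(schema.predictor_names) + tuple(spec.outcome_names)
    codes = (
        np.column_stack([sampled[c] for c in columns])
        if n
        else np.empty((0, len(columns)), dtype=np.int64)
    )
    cards = np.array([len(schema.categories(c)) for c in columns], dtype=np.int64)
    return DiscreteDataset(schema=schema, columns=columns, codes=codes, cards=cards)


def recovery_metrics(
    learned_direct: Iterable[str],
    learned_interactions: Iterable[frozenset],
    truth: GroundTruthSpec,
) -> dict[str, float]:
    """Set-level precision/recall against the planted ground truth.

    Direct risk factors are compared variable-by-variable against the
    target's parent set; interactive sets require an exact set match.
    """
    known = set(truth.names)
    learned_direct = set(learned_direct)
    learned_interactions = {frozenset(s) for s in learned_interactions}
    for v in learned_direct | set().union(*learned_interactions) if learned_interactions else learned_direct:
        if v not in known:
            raise KeyError(f"unknown variable name {v!r}")

    true_direct = set(truth.parents.get(truth.target, ()))
    true_sets = {frozenset(s) for s in truth.interactive_sets}

    def prec_rec(found: set, truth_set: set) -> tuple[float, float]:
        tp = len(found & truth_set)
        prec = tp / len(found) if found else (1.0 if not truth_set else 0.0)
        rec = tp / len(truth_set) if truth_set else 1.0
        return prec, rec

    dp, dr = prec_rec(learned_direct, true_direct)
    ip, ir = prec_rec(learned_interactions, true_sets)
    return {
        "direct_precision": dp,
        "direct_recall": dr,
        "interaction_precision": ip,
        "interaction_recall": ir,
    }
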