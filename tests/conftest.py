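from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pytest

from mbrisk.schema_io import DiscreteDataset, Variable, VariableSchema


def build_dataset(
    values: Mapping[str, Sequence[int]],
    cards: Mapping[str, int] | None = None,
    outcomes: tuple[str, ...] = ("T",),
) -> DiscreteDataset:
    """Assemble a DiscreteDataset from integer columns for tests.

    Any column named in ``outcomes`` becomes a binary outcome column; the
    rest become raw-categorical predictors with numbered category tokens.
    """
    cards = dict(cards or {})
    names = list(values)
    for name in names:
        col = list(values[name])
        cards.setdefault(name, max(2, (max(col) + 1) if col else 2))
    predictors = tuple(
        Variable(name=n, categories=tuple(str(i) for i in range(cards[n])))
        for n in names
        if n not in outcomes
    )
    present_outcomes = tuple(n for n in names if n in outcomes)
    schema = VariableSchema(
        variables=predictors,
        outcome_names=present_outcomes or ("T",),
        horizons=tuple(5 * (i + 1) for i in range(len(present_outcomes) or 1)),
        outcome_categories=("0", "1"),
    )
    columns = tuple(n for n in names if n not in outcomes) + present_outcomes
    n = len(next(iter(values.values()))) if values else 0
    codes = (
        np.column_stack([np.asarray(values[c], dtype=np.int64) for c in columns])
        if n
        else np.empty((0, len(columns)), dtype=np.int64)
    )
    return DiscreteDataset(
        schema=schema,
        columns=columns,
        codes=codes,
        cards=np.array([cards[c] for c in columns], dtype=np.int64),
    )


def random_tiny_dataset(rng: np.random.Generator) -> DiscreteDataset:
    """A random dataset with <= 3 parents, <= 3 categories, n <= 12."""
    n = int(rng.integers(1, 13))
    n_pred = int(rng.integers(1, 4))
    values = {}
    cards = {}
    for i in range(n_pred):
        card = int(rng.integers(2, 4))
        values[f"P{i}"] = rng.integers(0, card, size=n).tolist()
        cards[f"P{i}"] = card
    values["T"] = rng.integers(0, 2, size=n).tolist()
    cards["T"] = 2
    return build_dataset(values, cards)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
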