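"""Variable schema, dataset I/O and result serialization.

The packaged schema (:func:`clinical_schema`) describes a flat clinical table of
31 categorical predictors plus one binary metastasis outcome per follow-up
horizon (5, 10 and 15 years).  Datasets are plain CSV (RFC 4180, UTF-8,
header required); every cell is either a category token from the schema, a
raw number for binned-numeric variables, or the designated missing token,
which maps to an explicit extra "missing" category instead of dropping the
record.
"""

from __future__ import annotations

import io
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

MISSING_TOKEN = "NA"
MISSING_CATEGORY = "missing"

__all__ = [
    "Variable",
    "VariableSchema",
    "DiscreteDataset",
    "SchemaError",
    "DataValueError",
    "clinical_schema",
    "load_dataset",
    "write_dataset",
    "discretize_numeric",
    "write_report",
    "read_report",
]


class SchemaError(ValueError):
    """A dataset or schema document violates the schema contract."""


class DataValueError(ValueError):
    """A cell value cannot be mapped to any schema category."""


@dataclass(frozen=True)
class Variable:
    """One column: its name, ordered category tokens and optional binning."""

    name: str
    categories: tuple[str, ...]
    kind: str = "raw-categorical"  # or "binned-numeric"
    bin_edges: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise SchemaError(f"variable {self.name!r} needs >= 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise SchemaError(f"variable {self.name!r} has duplicate categories")
        if self.kind not in ("raw-categorical", "binned-numeric"):
            raise SchemaError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "binned-numeric":
            if self.bin_edges is None:
                raise SchemaError(f"variable {self.name!r}: binned-numeric needs bin_edges")
            edges = tuple(float(e) for e in self.bin_edges)
            if list(edges) != sorted(set(edges)):
                raise SchemaError(f"variable {self.name!r}: bin_edges must be strictly increasing")
            if len(edges) != len(self.categories):
                raise SchemaError(
                    f"variable {self.name!r}: one bin edge per category expected"
                )
        elif self.bin_edges is not None:
            raise SchemaError(f"variable {self.name!r}: bin_edges on a raw-categorical variable")

    @property
    def n_categories(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class VariableSchema:
    """Ordered predictor variables plus per-horizon binary outcome columns."""

    variables: tuple[Variable, ...]
    outcome_names: tuple[str, ...]
    horizons: tuple[int, ...]
    outcome_categories: tuple[str, ...] = ("no", "yes")
    missing_token: str = MISSING_TOKEN

    def __post_init__(self) -> None:
        if len(self.outcome_names) != len(self.horizons):
            raise SchemaError("one outcome column per horizon required")
        if len(self.outcome_categories) != 2:
            raise SchemaError("outcome variables must be binary")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names")
        if set(names) & set(self.outcome_names):
            raise SchemaError("outcome names collide with predictor names")

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    @property
    def column_names(self) -> tuple[str, ...]:
        return self.predictor_names + self.outcome_names

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def categories(self, column: str) -> tuple[str, ...]:
        if column in self.outcome_names:
            return self.outcome_categories
        return self.variable(column).categories

    def outcome_for_horizon(self, horizon: int) -> str:
        try:
            return self.outcome_names[self.horizons.index(horizon)]
        except ValueError:
            raise KeyError(f"no outcome column for horizon {horizon}") from None


@dataclass
class DiscreteDataset:
    """n records of category indices over the schema's columns.

    ``cards[j]`` is the effective cardinality of column ``j``: the schema
    category count, plus one when the missing token occurred in that column
    (the missing category takes the last index).
    """

    schema: VariableSchema
    columns: tuple[str, ...]
    codes: np.ndarray  # shape (n, len(columns)), integer dtype
    cards: np.ndarray  # shape (len(columns),)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.cards = np.asarray(self.cards, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.columns):
            raise SchemaError("codes shape does not match columns")
        if len(self.cards) != len(self.columns):
            raise SchemaError("cards length does not match columns")
        if self.n and (self.codes < 0).any():
            raise DataValueError("negative category index")
        if self.n and (self.codes >= self.cards[None, :]).any():
            raise DataValueError("category index out of range for its column")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(name)
        except ValueError:
            raise KeyError(name) from None

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self.column_index(name)]

    def cardinality(self, name: str) -> int:
        return int(self.cards[self.column_index(name)])

    def tokens(self, name: str) -> tuple[str, ...]:
        """Category tokens for a column, including ``missing`` if extended."""
        cats = self.schema.categories(name)
        if self.cardinality(name) == len(cats) + 1:
            cats = cats + (MISSING_CATEGORY,)
        return cats

    def to_frame(self) -> pd.DataFrame:
        """Decode indices back to tokens (missing as the missing token)."""
        out = {}
        for j, name in enumerate(self.columns):
            cats = self.schema.categories(name)
            lut = np.array(list(cats) + [self.schema.missing_token], dtype=object)
            out[name] = lut[np.minimum(self.codes[:, j], len(cats))]
        return pd.DataFrame(out, columns=list(self.columns))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiscreteDataset):
            return NotImplemented
        return (
            self.columns == other.columns
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.cards, other.cards)
        )


def discretize_numeric(raw_value: float, variable: Variable) -> int:
    """Bin a raw number: lower-inclusive / upper-exclusive, last bin open."""
    if variable.kind != "binned-numeric" or variable.bin_edges is None:
        raise SchemaError(f"variable {variable.name!r} is not binned-numeric")
    edges = variable.bin_edges
    if raw_value < edges[0]:
        raise DataValueError(
            f"value {raw_value!r} below the domain of {variable.name!r} (min {edges[0]})"
        )
    return bisect_right(edges, raw_value) - 1


def _schema_from_mapping(doc: Mapping) -> VariableSchema:
    variables = tuple(
        Variable(
            name=str(v["name"]),
            categories=tuple(str(c) for c in v["categories"]),
            kind=str(v.get("kind", "raw-categorical")),
            bin_edges=tuple(float(e) for e in v["bin_edges"]) if "bin_edges" in v else None,
        )
        for v in doc["variables"]
    )
    outcomes = doc["outcomes"]
    return VariableSchema(
        variables=variables,
        outcome_names=tuple(str(o["name"]) for o in outcomes),
        horizons=tuple(int(h) for h in doc["horizons"]),
        outcome_categories=tuple(str(c) for c in outcomes[0]["categories"]),
        missing_token=str(doc.get("missing_token", MISSING_TOKEN)),
    )


def read_schema(path: str | Path) -> VariableSchema:
    with open(path, "r", encoding="utf-8") as fh:
        return _schema_from_mapping(yaml.safe_load(fh))


def clinical_schema() -> VariableSchema:
    """The packaged 31-predictor clinical schema with 5/10/15-year outcomes."""
    text = resources.files("mbrisk.data").joinpath("clinical_schema.yaml").read_text("utf-8")
    schema = _schema_from_mapping(yaml.safe_load(text))
    assert len(schema.variables) == 31
    return schema


def _encode_column(values: pd.Series, name: str, schema: VariableSchema) -> tuple[np.ndarray, int]:
    cats = schema.categories(name)
    index = {tok: i for i, tok in enumerate(cats)}
    missing_idx = len(cats)
    codes = np.empty(len(values), dtype=np.int64)
    saw_missing = False
    var = None
    if name not in schema.outcome_names:
        var = schema.variable(name)
    for row, raw in enumerate(values):
        tok = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
        if tok in index:
            codes[row] = index[tok]
        elif tok == schema.missing_token or tok == "":
            codes[row] = missing_idx
            saw_missing = True
        elif var is not None and var.kind == "binned-numeric":
            try:
                codes[row] = discretize_numeric(float(tok), var)
            except (ValueError, DataValueError):
                raise DataValueError(
                    f"row {row}, column {name!r}: cannot map value {tok!r}"
                ) from None
        else:
            raise DataValueError(f"row {row}, column {name!r}: cannot map value {tok!r}")
    card = missing_idx + 1 if saw_missing else missing_idx
    return codes, card


def load_dataset(path: str | Path, schema: VariableSchema) -> DiscreteDataset:
    """Read a delimited patient table and encode it against the schema.

    All predictor columns must be present; outcome columns are included
    when present.  Column order is normalized to schema order.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in schema.predictor_names if c not in frame.columns]
    if missing_cols:
        raise SchemaError(f"missing schema columns: {missing_cols}")
    extra = [c for c in frame.columns if c not in schema.column_names]
    if extra:
        raise SchemaError(f"columns outside the schema: {extra}")
    columns = tuple(schema.predictor_names) + tuple(
        o for o in schema.outcome_names if o in frame.columns
    )
    codes = np.empty((len(frame), len(columns)), dtype=np.int64)
    cards = np.empty(len(columns), dtype=np.int64)
    for j, name in enumerate(columns):
        codes[:, j], cards[j] = _encode_column(frame[name], name, schema)
    return DiscreteDataset(schema=schema, columns=columns, codes=codes, cards=cards)


def write_dataset(data: DiscreteDataset, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result serialization.  One CSV row per reported set; a companion .txt file
# carries the human-readable summary.  Output is byte-identical across runs
# for identical inputs.

_REPORT_HEADER = "horizon,alpha,section,rank,variables,log_score,gain\n"


def _result_rows(results) -> list[dict]:
    rows = []
    for (horizon, alpha) in sorted(results):
        res = results[(horizon, alpha)]
        for section, items in (("direct", res.direct_sets), ("other", res.other_interactions)):
            for rank, item in enumerate(items, start=1):
                rows.append(
                    {
                        "horizon": horizon,
                        "alpha": alpha,
                        "section": section,
                        "rank": rank,
                        "variables": "|".join(sorted(item.variables)),
                        "log_score": f"{item.log_score:.6f}",
                        "gain": f"{item.gain_over_best_subset:.6f}",
                    }
                )
    return rows


def write_report(results, path: str | Path) -> None:
    """Write learned results as CSV plus a plain-text summary next to it.

    ``results`` maps ``(horizon, alpha)`` to a blanket-learning result (see
    :mod:`mbrisk.learner`).  Scores are fixed to 6 decimals; a uniform
    structure prior is assumed (scores are data likelihoods only).
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(_REPORT_HEADER)
    for row in _result_rows(results):
        buf.write(
            f"{row['horizon']},{row['alpha']:g},{row['section']},{row['rank']},"
            f"{row['variables']},{row['log_score']},{row['gain']}\n"
        )
    path.write_text(buf.getvalue(), encoding="utf-8")

    from .report import render_causal_set_report  # cycle-free at call time

    path.with_suffix(".txt").write_text(render_causal_set_report(results), encoding="utf-8")


def read_report(path: str | Path) -> list[dict]:
    """Read back a result CSV written by :func:`write_report`."""
    frame = pd.read_csv(path, dtype=str)
    rows = []
    for rec in frame.to_dict(orient="records"):
        rows.append(
            {
                "horizon": int(rec["horizon"]),
                "alpha": float(rec["alpha"]),
                "section": rec["section"],
                "rank": int(rec["rank"]),
                "variables": frozenset(rec["variables"].split("|")),
                "log_score": float(rec["log_score"]),
                "gain": float(rec["gain"]),
            }
        )
    return rows
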