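"""Partner-frequency tables, per-horizon counts and causal-set listings.

For quantitation, race and ethnicity are merged into one variable, as are
smoking and alcohol usage, and the two lymph-node columns; every other
name maps to itself (or to its display alias).  Percentages are rounded
half-away-from-zero at two decimals.

The packaged fixtures ``interactions_alpha{1,120,480}.csv`` are verbatim
transcriptions of published per-focus partner-count tables; each printed
row expands into ``n_times`` two-variable interaction records tagged with
the row's horizons, which re-tabulate to the printed totals and
percentages.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "InteractionRecord",
    "FrequencyTableRow",
    "merge_variables",
    "display_name",
    "tabulate_partner_frequencies",
    "count_focus_frequency",
    "render_causal_set_report",
    "render_frequency_table",
    "load_published_table",
    "load_published_interactions",
    "records_from_results",
    "PUBLISHED_ALPHAS",
]

PUBLISHED_ALPHAS = (1, 120, 480)

# Canonical merged names for quantitation.  Keys cover schema names and
# the display aliases used in the published tables.
_MERGE: dict[str, str] = {
    "Race": "Race/ethnicity",
    "race": "Race/ethnicity",
    "Ethnicity": "Race/ethnicity",
    "Race/ethnicity": "Race/ethnicity",
    "Smoking": "Smoking/alcohol",
    "Alcohol": "Smoking/alcohol",
    "Alcohol usage": "Smoking/alcohol",
    "Smoking/alcohol": "Smoking/alcohol",
    "Alcohol/smoking": "Smoking/alcohol",
    "Lymph_nodes_positive": "LN positive/status",
    "Lymph_node_status": "LN positive/status",
    "LN positive": "LN positive/status",
    "LN positive/status": "LN positive/status",
    "Re_excision": "Re_excision",
    "Re-excision": "Re_excision",
    "n_tnm_stage": "n-TNM",
    "n-TNM": "n-TNM",
    "t_tnm_stage": "t-TNM",
    "t-TNM": "t-TNM",
    "Age_at_diagnosis": "Age at DG",
    "Age at DG": "Age at DG",
    "Surgical_margins": "Surgical margins",
    "Surgical margins": "Surgical margins",
    "Invasive_tumor_location": "Invasive tumor location",
    "Invasive tumor location": "Invasive tumor location",
}

# Names that pass through unchanged.
_IDENTITY = {
    "Family history",
    "Menopausal_status",
    "Side",
    "TNEG",
    "ER",
    "ER_percent",
    "PR",
    "PR_percent",
    "P53",
    "HER2",
    "Stage",
    "Lymph_nodes_removed",
    "Histology",
    "Size",
    "Grade",
    "Invasive",
    "Histology2",
    "DCIS_level",
    "MRIs_60_surgery",
    "metastasis_5yr",
    "metastasis_10yr",
    "metastasis_15yr",
}

# Display aliases for rendering learned sets (no cross-variable merging).
_DISPLAY = {
    "n_tnm_stage": "n-TNM",
    "t_tnm_stage": "t-TNM",
    "Age_at_diagnosis": "Age at DG",
    "Surgical_margins": "Surgical margins",
    "Invasive_tumor_location": "Invasive tumor location",
    "Lymph_nodes_positive": "LN positive",
    "Lymph_node_status": "LN status",
}


def merge_variables(name: str) -> str:
    """Map a variable name to its merged quantitation name."""
    if name in _MERGE:
        return _MERGE[name]
    if name in _IDENTITY:
        return name
    raise KeyError(f"unknown variable name {name!r}")


def display_name(name: str) -> str:
    if name in _DISPLAY:
        return _DISPLAY[name]
    if name in _IDENTITY or name in _MERGE:
        return name
    raise KeyError(f"unknown variable name {name!r}")


@dataclass(frozen=True)
class InteractionRecord:
    """One learned (or transcribed) interactive set at a horizon and alpha."""

    variables: frozenset[str]
    horizon: int
    alpha: float

    def __post_init__(self) -> None:
        if len(self.variables) < 2:
            raise ValueError("interaction records need >= 2 variables")
        if self.horizon not in (5, 10, 15):
            raise ValueError(f"horizon must be 5, 10 or 15, got {self.horizon}")

    def merged_members(self) -> frozenset[str]:
        return frozenset(merge_variables(v) for v in self.variables)


@dataclass(frozen=True)
class FrequencyTableRow:
    focus: str
    partner: str
    n_times: int
    years: tuple[int, ...]
    total: int
    percent: float


def _round2(value: float) -> float:
    """Round half away from zero at 2 decimals (matches printed tables)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def tabulate_partner_frequencies(
    records: Iterable[InteractionRecord], focus: str, alpha: float
) -> list[FrequencyTableRow]:
    """Per-partner occurrence counts for one merged focus variable.

    Every record containing the focus contributes one partner occurrence
    per other merged member (a triple therefore adds two occurrences),
    tagged with the record's horizon.  Percentages are taken against the
    focus's total partner occurrences.  Row order is first-appearance
    order of partners.
    """
    focus = merge_variables(focus)
    partners: dict[str, list[int]] = {}
    for rec in records:
        if rec.alpha != alpha:
            continue
        members = rec.merged_members()
        if focus not in members:
            continue
        for member in sorted(members - {focus}):
            partners.setdefault(member, []).append(rec.horizon)
    total = sum(len(v) for v in partners.values())
    rows = []
    for partner, horizons in partners.items():
        rows.append(
            FrequencyTableRow(
                focus=focus,
                partner=partner,
                n_times=len(horizons),
                years=tuple(sorted(horizons)),
                total=total,
                percent=_round2(100.0 * len(horizons) / total),
            )
        )
    return rows


def count_focus_frequency(
    records: Iterable[InteractionRecord], focus: str, alpha: float, horizon: int
) -> int:
    """Number of records at (alpha, horizon) containing the merged focus."""
    focus = merge_variables(focus)
    return sum(
        1
        for rec in records
        if rec.alpha == alpha and rec.horizon == horizon and focus in rec.merged_members()
    )


# ---------------------------------------------------------------------------
# Packaged transcriptions


def load_published_table(alpha: int) -> list[dict]:
    """Verbatim rows of the published partner-count table for one alpha."""
    if alpha not in PUBLISHED_ALPHAS:
        raise KeyError(f"no published table for alpha {alpha}")
    text = resources.files("mbrisk.data").joinpath(f"interactions_alpha{alpha}.csv").read_text("utf-8")
    rows = []
    for rec in csv.DictReader(io.StringIO(text)):
        rows.append(
            {
                "focus": rec["focus"],
                "partner": rec["partner"],
                "n_times": int(rec["n_times"]),
                "years": tuple(int(tok) for tok in rec["years"].split(",")),
                "total": int(rec["total"]),
                "percent": float(rec["percent"]),
            }
        )
    return rows


def load_published_interactions(alpha: int) -> dict[str, list[InteractionRecord]]:
    """Expand the transcribed per-focus counts into interaction records.

    Each printed row becomes ``n_times`` two-variable records.  Where the
    printed year list is shorter than ``n_times`` the last year token is
    repeated (a few printed rows collapse repeated years); where longer,
    it is truncated.
    """
    out: dict[str, list[InteractionRecord]] = {}
    for row in load_published_table(alpha):
        focus = merge_variables(row["focus"])
        years = list(row["years"])
        if len(years) < row["n_times"]:
            years += [years[-1]] * (row["n_times"] - len(years))
        years = years[: row["n_times"]]
        out.setdefault(focus, []).extend(
            InteractionRecord(
                variables=frozenset({row["focus"], row["partner"]}),
                horizon=year,
                alpha=float(alpha),
            )
            for year in years
        )
    return out


def records_from_results(results: Mapping) -> list[InteractionRecord]:
    """Interaction records (|S| >= 2) from a (horizon, alpha) -> result map."""
    records = []
    for (horizon, alpha), res in sorted(results.items()):
        for item in list(res.direct_sets) + list(res.other_interactions):
            if len(item.variables) >= 2:
                records.append(
                    InteractionRecord(
                        variables=frozenset(item.variables),
                        horizon=int(horizon),
                        alpha=float(alpha),
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Rendering


def _render_set(variables: frozenset[str]) -> str:
    return " × ".join(display_name(v) for v in sorted(variables))


def render_causal_set_report(results: Mapping) -> str:
    """Human-readable causal-set listing, one section per (horizon, alpha).

    Scores are BDeu log marginal likelihoods under a uniform structure
    prior.
    """
    lines = [
        "Direct causal sets and interactive risk factors",
        "(BDeu scores; uniform structure prior — likelihood only)",
        "",
    ]
    for (horizon, alpha) in sorted(results):
        res = results[(horizon, alpha)]
        lines.append(f"[{horizon}-year metastasis, alpha = {alpha:g}]")
        lines.append("  direct causal sets:")
        if not res.direct_sets:
            lines.append("    (none)")
        for item in res.direct_sets:
            lines.append(f"    {_render_set(item.variables)}  score={item.log_score:.6f}")
        lines.append("  other interactive risk factors:")
        if not res.other_interactions:
            lines.append("    (none)")
        for item in res.other_interactions:
            lines.append(f"    {_render_set(item.variables)}  score={item.log_score:.6f}")
        lines.append("")
    return "\n".join(lines)


def render_frequency_table(rows: Sequence[FrequencyTableRow]) -> str:
    """Markdown rendering of a partner-frequency table."""
    out = ["| Variable | Interacts with | n Times | Years after DG | Total | % |",
           "|---|---|---|---|---|---|"]
    for row in rows:
        years = ", ".join(str(y) for y in row.years)
        out.append(
            f"| {row.focus} | {row.partner} | {row.n_times} | {years} "
            f"| {row.total} | {row.percent:.2f}% |"
        )
    return "\n".join(out)
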