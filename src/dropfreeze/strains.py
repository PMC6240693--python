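"""Strain metadata, taxonomy-rank assignment and panel-level summaries.

Holds the per-strain record (taxonomy, origin, growth media, freeze and
desiccation survival, INA status), the rank-assignment rule applied to
precomputed sequence-alignment statistics (no alignment is run here), the
habitat generalist/specialist rule, and the composition / survival summary
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "MEDIA",
    "E_VALUE_THRESHOLD_EXP",
    "E_VALUE_THRESHOLD_POWER10",
    "StrainRecord",
    "AlignmentStats",
    "assign_taxonomic_rank",
    "habitat_strategy",
    "composition_summary",
    "survival_summary",
]

MEDIA = ("ARW", "MWC", "f2_25", "f2_100")

# The reported e-value bound "< e^-189" is ambiguous between the natural
# constant and scientific notation; both readings are provided, with the
# literal exp(-189) as default.
E_VALUE_THRESHOLD_EXP = math.exp(-189)
E_VALUE_THRESHOLD_POWER10 = 1e-189

FREEZE_OUTCOMES = ("survived", "killed", "untested")
INA_STATUSES = ("confirmed", "screened_only", "negative", "untested")


@dataclass(frozen=True)
class StrainRecord:
    """One strain's metadata: the unit of all diversity/survival summaries."""

    strain_id: str
    source: str  # airborne | aquatic
    taxon: Mapping[str, str | None]  # keys: phylum, class, genus, species
    isolation_medium: str
    growth_by_medium: Mapping[str, bool]
    freeze_survival: str = "untested"
    desiccation: str = "untested"
    ina_status: str = "untested"

    def __post_init__(self) -> None:
        if self.source not in ("airborne", "aquatic"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.isolation_medium not in self.growth_by_medium or not self.growth_by_medium[self.isolation_medium]:
            raise ValueError(
                f"isolation medium {self.isolation_medium!r} must be among the "
                "media the strain grows in"
            )
        for name, value in (("freeze_survival", self.freeze_survival),
                            ("desiccation", self.desiccation)):
            if value not in FREEZE_OUTCOMES:
                raise ValueError(f"{name} must be one of {FREEZE_OUTCOMES}")
        if self.ina_status not in INA_STATUSES:
            raise ValueError(f"ina_status must be one of {INA_STATUSES}")


@dataclass(frozen=True)
class AlignmentStats:
    """Precomputed best-hit alignment statistics for one marker sequence."""

    identity_pct: float
    query_coverage_pct: float
    e_value: float
    marker: str = "ITS"

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct must lie in [0, 100]")
        if not 0.0 <= self.query_coverage_pct <= 100.0:
            raise ValueError("query_coverage_pct must lie in [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")
        if self.marker not in ("ITS", "18S", "23S"):
            raise ValueError(f"unknown marker {self.marker!r}")


def assign_taxonomic_rank(
    stats: AlignmentStats,
    e_value_threshold: float = E_VALUE_THRESHOLD_EXP,
) -> str:
    """Rank-assignment rule for a best database hit.

    Unassigned unless the hit covers at least 89 % of the query, with
    identity strictly above 89 % and e-value below the threshold; then
    species at identity >= 97 %, genus at >= 95 %, otherwise a higher rank.
    Monotone in identity at fixed coverage and e-value.
    """
    if (
        stats.query_coverage_pct < 89.0
        or stats.identity_pct <= 89.0
        or stats.e_value >= e_value_threshold
    ):
        return "unassigned"
    if stats.identity_pct >= 97.0:
        return "species"
    if stats.identity_pct >= 95.0:
        return "genus"
    return "higher_rank"


def habitat_strategy(growth_by_medium: Mapping[str, bool]) -> str:
    """Generalist (growth in >= 2 media), specialist (exactly 1) or unknown (0)."""
    if not growth_by_medium:
        raise ValueError("no media tested")
    n_positive = sum(bool(v) for v in growth_by_medium.values())
    if n_positive >= 2:
        return "generalist"
    if n_positive == 1:
        return "specialist"
    return "unknown"


def composition_summary(
    records: Sequence[StrainRecord],
    grouping: str | Callable[[StrainRecord], str],
) -> pd.DataFrame:
    """Counts and percentages (1-decimal) of records per group.

    ``grouping`` is a taxon rank name (looked up in ``record.taxon``), one
    of the record's own fields (e.g. ``ina_status``), or a callable.
    Percentages are of the full record set and sum to 100 up to rounding;
    denominators are reported explicitly in the ``total`` column.
    """
    if not records:
        raise ValueError("composition_summary needs at least one record")
    if callable(grouping):
        key = grouping
    elif grouping in ("phylum", "class", "genus", "species"):
        key = lambda r: str(r.taxon.get(grouping) or "unknown")
    else:
        key = lambda r: str(getattr(r, grouping))
    total = len(records)
    counts: dict[str, int] = {}
    for r in records:
        g = key(r)
        counts[g] = counts.get(g, 0) + 1
    rows = [
        {
            "group": g,
            "count": n,
            "total": total,
            "percent": round(100.0 * n / total, 1),
        }
        for g, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)


def survival_summary(
    records: Sequence[StrainRecord],
    stressor: str,
) -> pd.DataFrame:
    """Per-source survival proportions for a stressor.

    ``stressor`` is ``freezing`` or ``desiccation``; untested strains are
    excluded from the denominator and the headline percentage is rounded to
    the nearest integer.
    """
    field_name = {"freezing": "freeze_survival", "desiccation": "desiccation"}.get(
        stressor
    )
    if field_name is None:
        raise ValueError("stressor must be 'freezing' or 'desiccation'")
    rows = []
    for source in ("airborne", "aquatic"):
        tested = [
            r for r in records
            if r.source == source and getattr(r, field_name) != "untested"
        ]
        if not tested:
            continue
        survived = sum(getattr(r, field_name) == "survived" for r in tested)
        rows.append(
            {
                "source": source,
                "stressor": stressor,
                "survived": survived,
                "tested": len(tested),
                "percent": round(100.0 * survived / len(tested)),
            }
        )
    if not rows:
        raise ValueError(f"no strain was tested for {stressor}")
    return pd.DataFrame(rows)
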