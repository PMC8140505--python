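"""Polyphasic rank decisions: known species vs novel species/genus/family.

The engine combines five lines of evidence per candidate isolate — best
16S rRNA gene identity to a validly named species, dDDH, ANI, POCP, and
phylogenetic/phenotypic flags — into a single categorical call:

* known species: best 16S identity > 98.7%;
* new species: 16S identity < 98.7% AND dDDH < 70% AND (ANI < 95%, or
  ANI in the closed window [95%, 96%] with distinct morphology and
  physiology);
* new genus: additionally 16S identity < 95%, POCP < 50%, phenotype
  distinct from neighbor genera, and an independent clade on the tree;
* new family: additionally 16S identity < 90%, closest neighbor genera
  from at least two different families, and phenotype distinct from the
  neighbor families.

All numeric comparisons are strict as stated. The 98.7% boundary itself
is deliberately ambiguous: the assignment rule treats identity <= 98.7%
as a novelty candidate while the species clause demands < 98.7%, so an
evidence record sitting exactly on the boundary that satisfies no higher
rank is reported as ``ambiguous`` rather than silently resolved.

Phenotype distinctness and clade topology arrive as boolean INPUTS —
deriving them (BIOLOG profiles, microscopy, tree building) is outside
this package's scope; keeping them as flags keeps the rule engine total.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum

import pandas as pd

from .errors import IncompleteEvidenceError


class Rank(str, Enum):
    KNOWN_SPECIES = "known_species"
    NEW_SPECIES = "new_species"
    NEW_GENUS = "new_genus"
    NEW_FAMILY = "new_family"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Thresholds:
    """All delineation boundaries, overridable but defaulting to the
    conventional published values."""

    id16s_species: float = 0.987
    id16s_genus: float = 0.95
    id16s_family: float = 0.90
    ddh_species: float = 70.0
    ani_species: float = 95.0
    ani_exception_high: float = 96.0   # phenotype-backed ANI window top
    pocp_genus: float = 50.0
    min_neighbor_families: int = 2


@dataclass(frozen=True)
class TaxonEvidence:
    """Per-candidate metric bundle consumed by the decision rules."""

    id16s_best: float                    # fraction in [0, 1]
    ddh: float                           # percent
    ani: float                           # percent
    pocp: float                          # percent
    independent_clade: bool
    neighbor_families_count: int
    phenotype_distinct_species: bool
    phenotype_distinct_genus: bool
    phenotype_distinct_family: bool

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) is None:
                raise IncompleteEvidenceError(f"evidence field {f.name!r} is missing")
        if not 0 <= self.id16s_best <= 1:
            raise ValueError("id16s_best must be a fraction in [0, 1]")
        for name in ("ddh", "ani", "pocp"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percent in [0, 100]")
        if self.neighbor_families_count < 0:
            raise ValueError("neighbor_families_count must be >= 0")


@dataclass(frozen=True)
class RankDecision:
    rank: Rank
    satisfied_clauses: tuple[str, ...]
    failed_clauses: tuple[str, ...]


def delineate(
    e: TaxonEvidence, thresholds: Thresholds = Thresholds()
) -> RankDecision:
    """Apply the polyphasic rules to one evidence record and report the
    highest satisfied rank with a clause-level audit trail."""
    t = thresholds
    clauses = {
        "known.id16s": e.id16s_best > t.id16s_species,
        "species.id16s": e.id16s_best < t.id16s_species,
        "species.ddh": e.ddh < t.ddh_species,
        "species.ani": (
            e.ani < t.ani_species
            or (
                t.ani_species <= e.ani <= t.ani_exception_high
                and e.phenotype_distinct_species
            )
        ),
        "genus.id16s": e.id16s_best < t.id16s_genus,
        "genus.pocp": e.pocp < t.pocp_genus,
        "genus.phenotype": e.phenotype_distinct_genus,
        "genus.clade": e.independent_clade,
        "family.id16s": e.id16s_best < t.id16s_family,
        "family.neighbors": e.neighbor_families_count >= t.min_neighbor_families,
        "family.phenotype": e.phenotype_distinct_family,
    }
    is_species = (
        clauses["species.id16s"] and clauses["species.ddh"] and clauses["species.ani"]
    )
    is_genus = is_species and all(
        clauses[c] for c in ("genus.id16s", "genus.pocp", "genus.phenotype", "genus.clade")
    )
    is_family = is_genus and all(
        clauses[c] for c in ("family.id16s", "family.neighbors", "family.phenotype")
    )
    if clauses["known.id16s"]:
        rank = Rank.KNOWN_SPECIES
    elif is_family:
        rank = Rank.NEW_FAMILY
    elif is_genus:
        rank = Rank.NEW_GENUS
    elif is_species:
        rank = Rank.NEW_SPECIES
    else:
        rank = Rank.AMBIGUOUS
    return RankDecision(
        rank=rank,
        satisfied_clauses=tuple(k for k, v in clauses.items() if v),
        failed_clauses=tuple(k for k, v in clauses.items() if not v),
    )


def delineate_batch(
    evidence, thresholds: Thresholds = Thresholds()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Delineate a table of candidates.

    ``evidence`` is an iterable of TaxonEvidence or a DataFrame with one
    column per TaxonEvidence field (plus an optional index of candidate
    ids). Returns (per-candidate decision frame, counts per rank). Row
    failures are re-raised with the offending row's identity attached.
    """
    if isinstance(evidence, pd.DataFrame):
        field_names = [f.name for f in fields(TaxonEvidence)]
        records = []
        for idx, row in evidence.iterrows():
            kwargs = {}
            for name in field_names:
                if name not in row or pd.isna(row[name]):
                    raise IncompleteEvidenceError(
                        f"row {idx!r}: evidence field {name!r} is missing"
                    )
                kwargs[name] = row[name]
            records.append((idx, kwargs))
        items = []
        for idx, kwargs in records:
            try:
                items.append((idx, TaxonEvidence(**kwargs)))
            except (ValueError, IncompleteEvidenceError) as err:
                raise type(err)(f"row {idx!r}: {err}") from err
    else:
        items = list(enumerate(evidence))

    rows = []
    counts = {rank.value: 0 for rank in Rank}
    for idx, ev in items:
        try:
            decision = delineate(ev, thresholds)
        except (ValueError, IncompleteEvidenceError) as err:
            raise type(err)(f"row {idx!r}: {err}") from err
        counts[decision.rank.value] += 1
        rows.append(
            {
                "candidate": idx,
                "rank": decision.rank.value,
                "satisfied_clauses": ";".join(decision.satisfied_clauses),
                "failed_clauses": ";".join(decision.failed_clauses),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["candidate", "rank", "satisfied_clauses", "failed_clauses"]
    )
    return frame, counts
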