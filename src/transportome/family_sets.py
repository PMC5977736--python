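"""Family presence/absence across groups and specificity set analysis.

A family is *present* in a group when at least one species of that group
carries at least one counted member after all ingest filters (a
configurable minimum number of supporting species guards against
single-annotation artifacts). Comparing two disjoint group supersets —
canonically prokaryotes {bacteria, archaea} vs the four eukaryotic
groups — partitions the families observed in either superset into
superset-specific and shared sets: families lost in a lineage, families
that newly emerged there, and the common core.

A *marker screen* asks the converse question for a single family: which
species carry it at all. Screening a strongly lineage-restricted family
(the mitochondrial carrier family SLC25 is the canonical example) across
prokaryotes highlights candidate relatives of the eukaryotic organelle
ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ingest import AnnotationError, SpeciesMeta, Transportome
from .ontology import FamilyRegistry, TransporterClass

__all__ = [
    "FamilyPresence",
    "SpecificityPartition",
    "presence_matrix",
    "specificity_partition",
    "marker_screen",
    "PROKARYOTE_GROUPS",
    "EUKARYOTE_GROUPS",
]

# default two-way split of the standard six-group scheme
PROKARYOTE_GROUPS = frozenset({"bacteria", "archaea"})
EUKARYOTE_GROUPS = frozenset(
    {"primitive_eukaryotes", "algae_plants", "fungi", "animals"}
)


@dataclass
class FamilyPresence:
    """Boolean family × group matrix with supporting-species evidence."""

    families: list[str]
    groups: list[str]
    present: np.ndarray  # bool, shape (n_families, n_groups)
    supporting_species: dict[tuple[str, str], list[str]]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.present, index=self.families, columns=self.groups)

    def is_present(self, family_id: str, group: str) -> bool:
        return bool(self.frame().loc[family_id, group])

    def families_of(self, groups: Iterable[str]) -> set[str]:
        """Families present in at least one of the given groups."""
        frame = self.frame()
        cols = [g for g in groups if g in frame.columns]
        if not cols:
            return set()
        mask = frame[cols].any(axis=1)
        return set(frame.index[mask])


@dataclass(frozen=True)
class SpecificityPartition:
    """Disjoint split of observed families into a-only / b-only / shared."""

    partition_labels: tuple[str, str]
    a_only: frozenset[str]
    b_only: frozenset[str]
    shared: frozenset[str]

    def __post_init__(self) -> None:
        if (self.a_only & self.b_only) or (self.a_only & self.shared) or (
            self.b_only & self.shared
        ):
            raise ValueError("partition sets must be pairwise disjoint")

    @property
    def all_families(self) -> frozenset[str]:
        return self.a_only | self.b_only | self.shared


def presence_matrix(
    transportomes: Sequence[Transportome],
    meta: Sequence[SpeciesMeta],
    registry: FamilyRegistry,
    min_species: int = 1,
) -> FamilyPresence:
    """Build the family × group presence matrix from counted transportomes.

    ``min_species`` is the evidence threshold: a family is flagged present
    in a group only when at least that many species of the group carry it
    (default 1). Families absent everywhere are excluded; rows are sorted
    by family id, columns follow group order of first occurrence in
    ``meta``.
    """
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    group_of = {m.species_id: m.group_label for m in meta}
    missing = [t.species_id for t in transportomes if t.species_id not in group_of]
    if missing:
        raise AnnotationError(f"species without group label: {sorted(missing)}")

    groups: list[str] = []
    for m in meta:
        if m.group_label not in groups:
            groups.append(m.group_label)

    support: dict[tuple[str, str], list[str]] = {}
    for t in transportomes:
        registry.check_known(t.family_counts)
        group = group_of[t.species_id]
        for family_id, count in t.family_counts.items():
            if count >= 1:
                support.setdefault((family_id, group), []).append(t.species_id)

    support = {
        key: sorted(species)
        for key, species in support.items()
        if len(species) >= min_species
    }
    families = sorted({family_id for family_id, _ in support})
    present = np.zeros((len(families), len(groups)), dtype=bool)
    fam_index = {f: i for i, f in enumerate(families)}
    grp_index = {g: j for j, g in enumerate(groups)}
    for family_id, group in support:
        present[fam_index[family_id], grp_index[group]] = True
    return FamilyPresence(
        families=families, groups=groups, present=present, supporting_species=support
    )


def specificity_partition(
    p: FamilyPresence,
    superset_a: Iterable[str],
    superset_b: Iterable[str],
    registry: FamilyRegistry | None = None,
    class_filter: TransporterClass | None = None,
    labels: tuple[str, str] = ("a", "b"),
) -> SpecificityPartition:
    """Partition families observed in two disjoint group supersets.

    ``a_only`` holds families present somewhere in ``superset_a`` and
    nowhere in ``superset_b``; symmetrically for ``b_only``; ``shared``
    families occur in both. Families in neither superset are ignored.
    ``class_filter`` restricts the analysis to one transporter class and
    requires a registry for the family → class lookup.
    """
    set_a, set_b = set(superset_a), set(superset_b)
    if not set_a or not set_b:
        raise ValueError("both group supersets must be non-empty")
    overlap = set_a & set_b
    if overlap:
        raise ValueError(f"group supersets overlap: {sorted(overlap)}")

    in_a = p.families_of(set_a)
    in_b = p.families_of(set_b)
    if class_filter is not None:
        if registry is None:
            raise ValueError("class_filter requires a registry")
        in_a = {f for f in in_a if registry.transporter_class(f) is class_filter}
        in_b = {f for f in in_b if registry.transporter_class(f) is class_filter}

    return SpecificityPartition(
        partition_labels=labels,
        a_only=frozenset(in_a - in_b),
        b_only=frozenset(in_b - in_a),
        shared=frozenset(in_a & in_b),
    )


def marker_screen(
    transportomes: Sequence[Transportome],
    family_id: str,
    registry: FamilyRegistry,
) -> list[str]:
    """Sorted species ids carrying at least one member of ``family_id``."""
    registry.check_known([family_id])
    return sorted(
        t.species_id
        for t in transportomes
        if t.family_counts.get(family_id, 0) >= 1
    )
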