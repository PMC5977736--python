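"""Annotation-table ingest: parsing, filtering and transportome assembly.

Raw annotator output is protein-level and noisy in four characteristic
ways, each handled by a dedicated, individually idempotent step:

1. fragments and spurious short ORFs  → :func:`filter_short_proteins`
   (proteins shorter than 100 aa are excluded; the cutoff is strict, a
   100-aa protein is kept);
2. the same protein predicted into several families, and alternative
   isoforms of one gene annotated separately → :func:`deduplicate_hits`;
3. multi-subunit primary active transport systems (prokaryotic ABC
   importers encoded as operons, one gene per subunit) annotated as one
   record per subunit → :func:`collapse_complexes`, which merges them so
   each system counts as a single transporter;
4. family ids an active registry does not know → rejected at read time.

The end product is one :class:`Transportome` per species: a bag of counted
transporters per family.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Sequence

import pandas as pd

from .ontology import FamilyRegistry, TransporterClass

__all__ = [
    "ProteinAnnotation",
    "SpeciesMeta",
    "Transportome",
    "AnnotationError",
    "read_annotations",
    "read_species_meta",
    "write_annotations",
    "write_species_meta",
    "filter_short_proteins",
    "deduplicate_hits",
    "collapse_complexes",
    "build_transportomes",
    "apply_filters",
    "DEFAULT_MIN_LENGTH",
]

DEFAULT_MIN_LENGTH = 100


class AnnotationError(ValueError):
    """An annotation or metadata table violates the ingest contract."""


@dataclass(frozen=True)
class ProteinAnnotation:
    """One annotated transporter protein (pre-filtering granularity)."""

    species_id: str
    protein_id: str
    family_id: str
    gene_id: str | None = None
    length_aa: int | None = None
    complex_id: str | None = None

    def __post_init__(self) -> None:
        if self.length_aa is not None and self.length_aa < 1:
            raise AnnotationError(
                f"{self.species_id}/{self.protein_id}: length_aa must be >= 1, "
                f"got {self.length_aa}"
            )


@dataclass(frozen=True)
class SpeciesMeta:
    """Per-species metadata: group assignment and genome-scale context."""

    species_id: str
    group_label: str
    total_genes: int
    genome_size_mb: float | None = None

    def __post_init__(self) -> None:
        if self.total_genes < 1:
            raise AnnotationError(f"{self.species_id}: total_genes must be positive")
        if self.genome_size_mb is not None and self.genome_size_mb <= 0:
            raise AnnotationError(f"{self.species_id}: genome_size_mb must be positive")


@dataclass
class Transportome:
    """Post-filter transporter census of one species."""

    species_id: str
    family_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_transporters(self) -> int:
        return sum(self.family_counts.values())

    def class_counts(
        self, registry: FamilyRegistry, exclude_energizers: bool = True
    ) -> dict[TransporterClass, int]:
        """Counted transporters per class, optionally dropping energizer
        families (F/V/A-ATPases and ATP synthases)."""
        counts = {c: 0 for c in TransporterClass}
        for family_id, n in self.family_counts.items():
            fam = registry[family_id]
            if exclude_energizers and fam.is_energizer:
                continue
            counts[fam.transporter_class] += n
        return counts

    def energizer_count(self, registry: FamilyRegistry) -> int:
        return sum(
            n for f, n in self.family_counts.items() if registry.is_energizer(f)
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_ANNOT_REQUIRED = ("species_id", "protein_id", "family_id")
_ANNOT_OPTIONAL = ("gene_id", "length_aa", "complex_id")


def _opt_str(value) -> str | None:
    if value is None:
        return None
    text = str(value).strip()
    return text or None


def read_annotations(
    path: str | PathLike, registry: FamilyRegistry
) -> list[ProteinAnnotation]:
    """Read a tab-separated annotation table and validate family ids.

    Required columns: species_id, protein_id, family_id. Optional:
    gene_id, length_aa, complex_id (empty cells mean "unset"). Every
    family id must resolve in ``registry``; unknown ids are collected and
    reported in a single hard error.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOT_REQUIRED if c not in table.columns]
    if missing:
        raise AnnotationError(f"annotation file {path} lacks required columns: {missing}")

    records: list[ProteinAnnotation] = []
    for idx, row in enumerate(table.to_dict("records")):
        line = idx + 2  # header is line 1
        species = _opt_str(row["species_id"])
        protein = _opt_str(row["protein_id"])
        family = _opt_str(row["family_id"])
        if not (species and protein and family):
            raise AnnotationError(
                f"line {line} of {path}: species_id, protein_id and family_id are required"
            )
        raw_len = _opt_str(row.get("length_aa"))
        length: int | None = None
        if raw_len is not None:
            try:
                length = int(raw_len)
            except ValueError:
                raise AnnotationError(
                    f"line {line} of {path}: length_aa must be an integer, got {raw_len!r}"
                ) from None
        try:
            records.append(
                ProteinAnnotation(
                    species_id=species,
                    protein_id=protein,
                    family_id=family,
                    gene_id=_opt_str(row.get("gene_id")),
                    length_aa=length,
                    complex_id=_opt_str(row.get("complex_id")),
                )
            )
        except AnnotationError as exc:
            raise AnnotationError(f"line {line} of {path}: {exc}") from None

    registry.check_known(r.family_id for r in records)
    return records


def write_annotations(records: Iterable[ProteinAnnotation], path: str | PathLike) -> None:
    rows = [
        {
            "species_id": r.species_id,
            "protein_id": r.protein_id,
            "gene_id": r.gene_id or "",
            "family_id": r.family_id,
            "length_aa": "" if r.length_aa is None else r.length_aa,
            "complex_id": r.complex_id or "",
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["species_id", "protein_id", "gene_id", "family_id", "length_aa", "complex_id"],
    ).to_csv(path, sep="\t", index=False)


def read_species_meta(path: str | PathLike) -> list[SpeciesMeta]:
    """Read the tab-separated species metadata table."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("species_id", "group_label", "total_genes")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise AnnotationError(f"metadata file {path} lacks required columns: {missing}")
    records: list[SpeciesMeta] = []
    seen: set[str] = set()
    for idx, row in enumerate(table.to_dict("records")):
        species = _opt_str(row["species_id"])
        if species is None:
            raise AnnotationError(f"line {idx + 2} of {path}: species_id is required")
        if species in seen:
            raise AnnotationError(f"duplicate species_id {species!r} in {path}")
        seen.add(species)
        raw_size = _opt_str(row.get("genome_size_mb"))
        records.append(
            SpeciesMeta(
                species_id=species,
                group_label=str(row["group_label"]).strip(),
                total_genes=int(row["total_genes"]),
                genome_size_mb=float(raw_size) if raw_size is not None else None,
            )
        )
    return records


def write_species_meta(records: Iterable[SpeciesMeta], path: str | PathLike) -> None:
    rows = [
        {
            "species_id": m.species_id,
            "group_label": m.group_label,
            "genome_size_mb": "" if m.genome_size_mb is None else f"{m.genome_size_mb:.2f}",
            "total_genes": m.total_genes,
        }
        for m in records
    ]
    pd.DataFrame(
        rows, columns=["species_id", "group_label", "genome_size_mb", "total_genes"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_short_proteins(
    annots: Sequence[ProteinAnnotation],
    min_len: int = DEFAULT_MIN_LENGTH,
    report: list[dict] | None = None,
) -> list[ProteinAnnotation]:
    """Drop proteins shorter than ``min_len`` amino acids (strictly).

    Records without a known length are kept: the rule cannot be applied to
    them, and dropping silently would bias counts. Input order preserved.
    """
    kept: list[ProteinAnnotation] = []
    for r in annots:
        if r.length_aa is not None and r.length_aa < min_len:
            if report is not None:
                report.append(
                    {
                        "action": "drop_short",
                        "species_id": r.species_id,
                        "protein_id": r.protein_id,
                        "detail": f"length {r.length_aa} aa < {min_len}",
                    }
                )
            continue
        kept.append(r)
    return kept


def deduplicate_hits(
    annots: Sequence[ProteinAnnotation],
    report: list[dict] | None = None,
) -> list[ProteinAnnotation]:
    """Collapse multi-prediction hits and alternative isoforms.

    Deterministic stand-in for manual curation, applied in two passes:

    * records sharing (species_id, protein_id) — the same protein
      predicted into several families — keep the record with the
      lexicographically smallest family_id;
    * records sharing (species_id, gene_id) — alternative isoforms of one
      gene — keep the record with the lexicographically smallest
      protein_id.

    Both tie-breaks are order-insensitive, so the result does not depend
    on the row order of the input table. Removals are appended to
    ``report`` when given.
    """

    def log(r: ProteinAnnotation, action: str, kept: ProteinAnnotation) -> None:
        if report is not None:
            report.append(
                {
                    "action": action,
                    "species_id": r.species_id,
                    "protein_id": r.protein_id,
                    "detail": f"family {r.family_id}; kept {kept.protein_id}/{kept.family_id}",
                }
            )

    # pass 1: one record per protein
    by_protein: dict[tuple[str, str], ProteinAnnotation] = {}
    order: list[tuple[str, str]] = []
    for r in annots:
        key = (r.species_id, r.protein_id)
        if key not in by_protein:
            by_protein[key] = r
            order.append(key)
        else:
            best = min(by_protein[key], r, key=lambda a: a.family_id)
            worst = r if best is by_protein[key] else by_protein[key]
            log(worst, "drop_multi_hit", best)
            by_protein[key] = best

    # pass 2: one record per gene (records lacking gene_id are untouched)
    by_gene: dict[tuple[str, str], ProteinAnnotation] = {}
    result: list[ProteinAnnotation] = []
    positions: dict[tuple[str, str], int] = {}
    for key in order:
        r = by_protein[key]
        if r.gene_id is None:
            result.append(r)
            continue
        gkey = (r.species_id, r.gene_id)
        if gkey not in by_gene:
            by_gene[gkey] = r
            positions[gkey] = len(result)
            result.append(r)
        else:
            best = min(by_gene[gkey], r, key=lambda a: a.protein_id)
            worst = r if best is by_gene[gkey] else by_gene[gkey]
            log(worst, "drop_isoform", best)
            by_gene[gkey] = best
            result[positions[gkey]] = best
    return result


def collapse_complexes(
    annots: Sequence[ProteinAnnotation],
    registry: FamilyRegistry,
    report: list[dict] | None = None,
) -> list[ProteinAnnotation]:
    """Merge multi-subunit ATP-dependent systems into single transporters.

    Records of ATP-dependent families sharing a non-empty ``complex_id``
    within one species (operon-encoded ABC subunits, translocase
    components) are merged into one record — the system translocates
    substrate as a unit, so it must be counted once. The surviving record
    keeps the smallest protein_id of the group. Records without a
    complex_id, and non-ATP-dependent records, are untouched. A
    complex_id spanning several families is ambiguous and a hard error.
    """
    groups: dict[tuple[str, str], list[ProteinAnnotation]] = defaultdict(list)
    for r in annots:
        if (
            r.complex_id is not None
            and registry.transporter_class(r.family_id) is TransporterClass.ATP_DEPENDENT
        ):
            groups[(r.species_id, r.complex_id)].append(r)

    for (species, complex_id), members in groups.items():
        families = {m.family_id for m in members}
        if len(families) > 1:
            raise AnnotationError(
                f"complex {complex_id!r} in species {species!r} spans multiple "
                f"families {sorted(families)}: ambiguous transport system"
            )

    keeper: dict[tuple[str, str], ProteinAnnotation] = {
        key: min(members, key=lambda a: a.protein_id) for key, members in groups.items()
    }
    result: list[ProteinAnnotation] = []
    emitted: set[tuple[str, str]] = set()
    for r in annots:
        key = (r.species_id, r.complex_id) if r.complex_id is not None else None
        if key is None or key not in keeper:
            result.append(r)
            continue
        if key in emitted:
            if report is not None:
                report.append(
                    {
                        "action": "merge_subunit",
                        "species_id": r.species_id,
                        "protein_id": r.protein_id,
                        "detail": f"complex {r.complex_id}; kept {keeper[key].protein_id}",
                    }
                )
            continue
        emitted.add(key)
        result.append(keeper[key])
    return result


def build_transportomes(
    annots: Sequence[ProteinAnnotation], registry: FamilyRegistry
) -> list[Transportome]:
    """Count filtered records into one :class:`Transportome` per species.

    Species appear in order of first occurrence in ``annots``.
    """
    registry.check_known(r.family_id for r in annots)
    counts: dict[str, Counter] = {}
    for r in annots:
        counts.setdefault(r.species_id, Counter())[r.family_id] += 1
    return [
        Transportome(species_id=sp, family_counts=dict(sorted(c.items())))
        for sp, c in counts.items()
    ]


def apply_filters(
    annots: Sequence[ProteinAnnotation],
    registry: FamilyRegistry,
    min_len: int = DEFAULT_MIN_LENGTH,
    report: list[dict] | None = None,
) -> list[ProteinAnnotation]:
    """Run the full filter chain in its canonical order."""
    out = filter_short_proteins(annots, min_len=min_len, report=report)
    out = deduplicate_hits(out, report=report)
    out = collapse_complexes(out, registry, report=report)
    return out
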