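"""Per-species transportome composition and group-level statistics.

A transportome's composition is summarised two ways:

* **class fractions** — the percentage of counted transporters falling in
  each of the three classes, computed after removing energizer families
  (F/V/A-ATPases, ATP synthases) from both numerator and denominator by
  default; the three percentages sum to 100;
* **intra-genomic frequencies** — class counts normalised to the total
  number of genes in the genome, measuring what share of the gene
  repertoire each transport class occupies.

Groups of species (domains of life, or any custom grouping) are compared
treating each species as one independent biological replicate: unweighted
per-group means with t-based confidence intervals (99% by default) and
two-sided Student's t-tests, optionally repeated on arcsin-√ transformed
proportions as a normality robustness check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .ingest import SpeciesMeta, Transportome
from .ontology import FamilyRegistry, TransporterClass

__all__ = [
    "CompositionRecord",
    "GroupSummary",
    "CompositionError",
    "class_fractions",
    "intragenomic_frequencies",
    "group_summary",
    "arcsin_sqrt",
    "ttest_groups",
    "pearson",
    "CLASS_KEYS",
]

# canonical short keys for the three classes, in reporting order
CLASS_KEYS = ("adt", "st", "ic")
_KEY_TO_CLASS = {
    "adt": TransporterClass.ATP_DEPENDENT,
    "st": TransporterClass.SECONDARY,
    "ic": TransporterClass.ION_CHANNEL,
}


class CompositionError(ValueError):
    """Composition statistics were requested on degenerate input."""


@dataclass(frozen=True)
class CompositionRecord:
    """Class-level composition of one species' transportome.

    Percentages always sum to 100; frequencies are optional (set by
    :func:`intragenomic_frequencies` when metadata is available).
    """

    species_id: str
    pct_adt: float
    pct_st: float
    pct_ic: float
    freq_adt: float | None = None
    freq_st: float | None = None
    freq_ic: float | None = None
    n_excluded_energizers: int = 0

    def __post_init__(self) -> None:
        total = self.pct_adt + self.pct_st + self.pct_ic
        if abs(total - 100.0) > 1e-9:
            raise CompositionError(
                f"{self.species_id}: class percentages sum to {total!r}, not 100"
            )
        for key in CLASS_KEYS:
            freq = getattr(self, f"freq_{key}")
            if freq is not None and not 0.0 <= freq <= 1.0:
                raise CompositionError(
                    f"{self.species_id}: freq_{key}={freq!r} outside [0, 1]"
                )

    def percentages(self) -> tuple[float, float, float]:
        return (self.pct_adt, self.pct_st, self.pct_ic)


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD and t-based CI of class percentages over one group."""

    group_label: str
    n_species: int
    confidence: float
    mean: dict[str, float]
    sd: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]

    def mean_percentages(self) -> tuple[float, float, float]:
        return tuple(self.mean[k] for k in CLASS_KEYS)


def _class_counts(
    t: Transportome, registry: FamilyRegistry, exclude_energizers: bool
) -> tuple[dict[str, int], int]:
    by_class = t.class_counts(registry, exclude_energizers=exclude_energizers)
    counts = {key: by_class[_KEY_TO_CLASS[key]] for key in CLASS_KEYS}
    return counts, t.energizer_count(registry) if exclude_energizers else 0


def class_fractions(
    t: Transportome,
    registry: FamilyRegistry,
    exclude_energizers: bool = True,
) -> CompositionRecord:
    """Percentage of each transporter class in one transportome.

    With ``exclude_energizers`` (default) the F/V/A-ATPase and ATP
    synthase members are removed from both the ATP-dependent count and
    the denominator: they energise the rest of the transportome rather
    than translocating substrates on their own account.
    """
    counts, n_energizers = _class_counts(t, registry, exclude_energizers)
    total = sum(counts.values())
    if total == 0:
        raise CompositionError(
            f"species {t.species_id!r} has no counted transporters"
            + (" after energizer exclusion" if exclude_energizers else "")
        )
    pct = {key: 100.0 * counts[key] / total for key in CLASS_KEYS}
    return CompositionRecord(
        species_id=t.species_id,
        pct_adt=pct["adt"],
        pct_st=pct["st"],
        pct_ic=pct["ic"],
        n_excluded_energizers=n_energizers,
    )


def intragenomic_frequencies(
    t: Transportome,
    meta: SpeciesMeta,
    registry: FamilyRegistry,
    exclude_energizers: bool = True,
) -> CompositionRecord:
    """Class counts per total gene number, attached to the class fractions.

    The frequency of a class is its post-filter transporter count divided
    by the genome's total gene count — the share of the gene repertoire
    devoted to that transport class.
    """
    if meta.species_id != t.species_id:
        raise CompositionError(
            f"metadata species {meta.species_id!r} does not match transportome "
            f"{t.species_id!r}"
        )
    counts, _ = _class_counts(t, registry, exclude_energizers)
    if meta.total_genes < sum(counts.values()):
        raise CompositionError(
            f"{t.species_id}: total_genes={meta.total_genes} smaller than the "
            f"transportome ({sum(counts.values())})"
        )
    record = class_fractions(t, registry, exclude_energizers=exclude_energizers)
    return replace(
        record,
        freq_adt=counts["adt"] / meta.total_genes,
        freq_st=counts["st"] / meta.total_genes,
        freq_ic=counts["ic"] / meta.total_genes,
    )


def group_summary(
    records: Sequence[CompositionRecord],
    meta: Sequence[SpeciesMeta],
    confidence: float = 0.99,
) -> list[GroupSummary]:
    """Per-group mean, sample SD and symmetric t-based CI of class shares.

    Each species is one replicate; the CI uses the t distribution with
    n − 1 degrees of freedom. Groups appear in order of first occurrence
    in ``meta``; a group represented by a single species is an error (its
    CI is undefined).
    """
    if not 0.0 < confidence < 1.0:
        raise CompositionError(f"confidence must be in (0, 1), got {confidence}")
    group_of = {m.species_id: m.group_label for m in meta}
    missing = [r.species_id for r in records if r.species_id not in group_of]
    if missing:
        raise CompositionError(f"no metadata for species: {sorted(missing)}")

    by_group: dict[str, list[CompositionRecord]] = {}
    for m in meta:  # meta order defines group order
        by_group.setdefault(m.group_label, [])
    for r in records:
        by_group[group_of[r.species_id]].append(r)

    summaries: list[GroupSummary] = []
    for group, members in by_group.items():
        if not members:
            continue
        n = len(members)
        if n < 2:
            raise CompositionError(
                f"group {group!r} has a single species; confidence interval undefined"
            )
        tquant = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
        mean, sd, lo, hi = {}, {}, {}, {}
        for key in CLASS_KEYS:
            values = np.array([getattr(r, f"pct_{key}") for r in members], dtype=float)
            m_ = float(values.mean())
            s_ = float(values.std(ddof=1))
            half = tquant * s_ / math.sqrt(n)
            mean[key], sd[key] = m_, s_
            lo[key], hi[key] = m_ - half, m_ + half
        summaries.append(
            GroupSummary(
                group_label=group,
                n_species=n,
                confidence=confidence,
                mean=mean,
                sd=sd,
                ci_low=lo,
                ci_high=hi,
            )
        )
    return summaries


def arcsin_sqrt(p):
    """Variance-stabilising transform asin(√p) for proportions in [0, 1].

    Accepts scalars or arrays; strictly monotone, mapping [0, 1] onto
    [0, π/2], so group orderings of mean proportions are preserved.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise CompositionError("arcsin_sqrt requires proportions in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def ttest_groups(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float, float]:
    """Two-sided Student's t-test between two groups of species values.

    Pooled-variance Student's test by default (``welch=True`` switches to
    the unequal-variance form). Returns (t, df, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise CompositionError("each sample needs at least two observations")
    result = stats.ttest_ind(a, b, equal_var=not welch)
    return float(result.statistic), float(result.df), float(result.pvalue)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise CompositionError("x and y must have the same length")
    if len(x) < 3:
        raise CompositionError("Pearson correlation needs at least three points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CompositionError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)
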