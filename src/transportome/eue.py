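"""Energy-usage efficiency (EUE) of transportomes and inter-group ΔEUE.

The EUE of a transportome is the average ATP equivalent a single
substrate translocation costs, taken over the transportome's class
composition:

    EUE = (w_ADT · %ADT + w_ST · %ST + w_IC · %IC) / 100

with conservative per-event cost coefficients

* ATP-dependent transporters: **2 ATP** — ABC transporters and the other
  primary active families generally show a 1:2 substrate:ATP hydrolysis
  stoichiometry;
* secondary transporters: **0.5 ATP** — active carriers dissipate ion
  gradients built by ATPases pumping ≈2–3 ions per ATP, so even
  concentrative carriers average ≤ 0.5 ATP per substrate (equilibrative
  carriers cost nothing, making 0.5 conservative);
* ion channels: **0 ATP** — equilibrative diffusion.

EUE is a property of composition only: transporter expression and flux
do not enter, so two organisms with identical transportomes have
identical EUE regardless of activity levels. ΔEUE between two groups is
the difference of their mean EUEs (row − column in the matrix); a
negative ΔEUE means the row group's transportome is the more
energy-efficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import CLASS_KEYS, CompositionRecord, GroupSummary

__all__ = [
    "EUEWeights",
    "EUEResult",
    "eue",
    "eue_from_percentages",
    "delta_eue",
    "eue_matrix",
    "species_eue",
    "format_delta_matrix",
]

Percentages = Sequence[float]  # (pct_adt, pct_st, pct_ic)


@dataclass(frozen=True)
class EUEWeights:
    """Per-class ATP cost coefficients (ATP equivalents per transport event)."""

    atp_per_event_adt: float = 2.0
    atp_per_event_st: float = 0.5
    atp_per_event_ic: float = 0.0

    def __post_init__(self) -> None:
        w = self.as_tuple()
        if any(x < 0 for x in w):
            raise ValueError("EUE weights must be non-negative")
        if not (w[0] >= w[1] >= w[2]):
            warnings.warn(
                "EUE weights do not satisfy adt >= st >= ic; the efficiency "
                "ordering interpretation of ΔEUE no longer applies",
                stacklevel=2,
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.atp_per_event_adt, self.atp_per_event_st, self.atp_per_event_ic)


@dataclass
class EUEResult:
    """Per-species and per-group EUE plus the inter-group ΔEUE matrix.

    ``delta`` holds the full antisymmetric matrix ΔEUE[row, col] =
    EUE(row) − EUE(col) at full precision; ``format_delta_matrix``
    renders the conventional lower-triangular, 2-decimal presentation.
    """

    group_order: list[str]
    group_mean_eue: dict[str, float]
    delta: pd.DataFrame
    per_species_eue: dict[str, float] = field(default_factory=dict)

    def delta_entry(self, row_group: str, col_group: str) -> float:
        return float(self.delta.loc[row_group, col_group])


def _coerce_percentages(c: CompositionRecord | Percentages) -> tuple[float, float, float]:
    if isinstance(c, CompositionRecord):
        return c.percentages()
    triple = tuple(float(v) for v in c)
    if len(triple) != 3:
        raise ValueError("expected (pct_adt, pct_st, pct_ic)")
    return triple


def eue_from_percentages(percentages: Percentages, w: EUEWeights = EUEWeights()) -> float:
    """EUE of a raw (pct_adt, pct_st, pct_ic) triplet."""
    p = _coerce_percentages(percentages)
    wt = w.as_tuple()
    return sum(wi * pi for wi, pi in zip(wt, p)) / 100.0


def eue(c: CompositionRecord | Percentages, w: EUEWeights = EUEWeights()) -> float:
    """Average ATP cost per transport event of one composition.

    A convex combination of the class weights, hence always within
    [min(w), max(w)] — [0, 2] under the defaults.
    """
    return eue_from_percentages(_coerce_percentages(c), w)


def delta_eue(
    a: CompositionRecord | Percentages,
    b: CompositionRecord | Percentages,
    w: EUEWeights = EUEWeights(),
) -> float:
    """ΔEUE = EUE(a) − EUE(b); negative means ``a`` is more efficient.

    Linear in the composition difference, so the matrix built from it is
    antisymmetric and additive along any chain of groups.
    """
    return eue(a, w) - eue(b, w)


def species_eue(
    records: Sequence[CompositionRecord], w: EUEWeights = EUEWeights()
) -> dict[str, float]:
    """Per-species EUE keyed by species id."""
    return {r.species_id: eue(r, w) for r in records}


def eue_matrix(
    summaries: Sequence[GroupSummary],
    w: EUEWeights = EUEWeights(),
    order: Sequence[str] | None = None,
    per_species: Mapping[str, float] | None = None,
) -> EUEResult:
    """Inter-group ΔEUE matrix from group mean class percentages.

    Group EUE is the EUE of the group's unweighted mean composition
    (equivalently, by linearity, the mean of per-species EUEs). Entry
    (row, col) is EUE(row) − EUE(col); the diagonal is zero.
    """
    by_label = {s.group_label: s for s in summaries}
    order = list(order) if order is not None else [s.group_label for s in summaries]
    missing = [g for g in order if g not in by_label]
    if missing:
        raise ValueError(f"groups missing from summaries: {missing}")

    group_eue = {g: eue_from_percentages(by_label[g].mean_percentages(), w) for g in order}
    values = np.array([group_eue[g] for g in order], dtype=float)
    delta = pd.DataFrame(
        values[:, None] - values[None, :], index=order, columns=order
    )
    return EUEResult(
        group_order=order,
        group_mean_eue=group_eue,
        delta=delta,
        per_species_eue=dict(per_species) if per_species else {},
    )


def format_delta_matrix(result: EUEResult, decimals: int = 2) -> str:
    """Lower-triangular tab-separated rendering of the ΔEUE matrix.

    Entries above the diagonal are left blank; values are rounded to
    ``decimals`` (two, conventionally) with the sign preserved. Full
    precision stays available on :attr:`EUEResult.delta`.
    """
    lines = ["\t".join([""] + result.group_order)]
    for i, row in enumerate(result.group_order):
        cells = [row]
        for j, col in enumerate(result.group_order):
            if j > i:
                cells.append("")
            else:
                value = round(result.delta_entry(row, col), decimals)
                cells.append(f"{value + 0.0:.{decimals}f}")  # +0.0 avoids "-0.00"
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
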