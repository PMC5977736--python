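"""Transporter classification vocabulary and the family registry.

Three functional classes partition every membrane transporter counted by
the analysis:

* **ion channels** — pore-forming proteins enabling selective passive
  diffusion; no direct ATP cost per transport event;
* **secondary transporters** — carriers moving substrates by facilitated
  diffusion or by coupling to ion electrochemical gradients;
* **ATP-dependent transporters** — primary active transporters that bind
  and hydrolyse ATP (ABC superfamily, P-type ATPases, protein
  translocases, ...).

Families that *generate* the cellular energy pools — the F/V/A-type
ATPases and ATP synthases — are carried in the registry with an
``is_energizer`` flag: they power the rest of the transportome and are
excluded from the ATP-dependent tally in all composition statistics.

The registry is the single source of truth for family → class lookups;
annotation tables mentioning a family absent from the active registry are
rejected at ingest.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from os import PathLike
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "TransporterClass",
    "FamilyDefinition",
    "FamilyRegistry",
    "RegistryError",
    "UnknownFamilyError",
    "load_family_registry",
    "write_registry",
    "bundled_registry",
]


class RegistryError(ValueError):
    """A family registry file or definition violates the registry contract."""


class UnknownFamilyError(KeyError):
    """A family id was looked up that the active registry does not define."""

    def __init__(self, family_ids: Iterable[str]):
        ids = sorted(set(family_ids))
        self.family_ids = ids
        super().__init__(f"unknown transporter families: {', '.join(ids)}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class TransporterClass(enum.Enum):
    """The closed three-class vocabulary of the analysis."""

    ION_CHANNEL = "ION_CHANNEL"
    SECONDARY = "SECONDARY"
    ATP_DEPENDENT = "ATP_DEPENDENT"

    @classmethod
    def parse(cls, label: str) -> "TransporterClass":
        try:
            return cls(label.strip().upper())
        except ValueError:
            valid = ", ".join(m.value for m in cls)
            raise RegistryError(
                f"unknown transporter class label {label!r}; expected one of {valid}"
            ) from None


@dataclass(frozen=True)
class FamilyDefinition:
    """One transporter family: a TC-style id, a human name, a class.

    ``is_energizer`` may only be set on ATP-dependent families (the
    F/V/A-ATPases and ATP synthases sit inside the primary active
    transporter class but are excluded from its statistics).
    """

    family_id: str
    name: str
    transporter_class: TransporterClass
    is_energizer: bool = False

    def __post_init__(self) -> None:
        if not self.family_id:
            raise RegistryError("family_id must be a non-empty string")
        if self.is_energizer and self.transporter_class is not TransporterClass.ATP_DEPENDENT:
            raise RegistryError(
                f"family {self.family_id!r}: is_energizer is only valid for "
                f"ATP_DEPENDENT families, not {self.transporter_class.value}"
            )


@dataclass
class FamilyRegistry:
    """Validated collection of family definitions, indexed by family id."""

    _families: dict[str, FamilyDefinition] = field(default_factory=dict)

    @classmethod
    def from_definitions(cls, definitions: Iterable[FamilyDefinition]) -> "FamilyRegistry":
        reg = cls()
        for d in definitions:
            if d.family_id in reg._families:
                raise RegistryError(f"duplicate family_id {d.family_id!r} in registry")
            reg._families[d.family_id] = d
        return reg

    def __contains__(self, family_id: str) -> bool:
        return family_id in self._families

    def __getitem__(self, family_id: str) -> FamilyDefinition:
        try:
            return self._families[family_id]
        except KeyError:
            raise UnknownFamilyError([family_id]) from None

    def __iter__(self) -> Iterator[FamilyDefinition]:
        return iter(self._families.values())

    def __len__(self) -> int:
        return len(self._families)

    @property
    def family_ids(self) -> list[str]:
        return list(self._families)

    def transporter_class(self, family_id: str) -> TransporterClass:
        return self[family_id].transporter_class

    def is_energizer(self, family_id: str) -> bool:
        return self[family_id].is_energizer

    def class_counts(self) -> dict[TransporterClass, int]:
        """Family count per class; the three counts sum to ``len(self)``."""
        counts = {c: 0 for c in TransporterClass}
        for fam in self:
            counts[fam.transporter_class] += 1
        return counts

    def check_known(self, family_ids: Iterable[str]) -> None:
        """Raise :class:`UnknownFamilyError` listing every unresolvable id."""
        unknown = {f for f in family_ids if f not in self._families}
        if unknown:
            raise UnknownFamilyError(unknown)


_REQUIRED_COLUMNS = ("family_id", "name", "class", "is_energizer")
_BOOL_LABELS = {"true": True, "false": False, "1": True, "0": False}


def load_family_registry(path: str | PathLike) -> FamilyRegistry:
    """Read a tab-separated family registry file.

    Expected columns: ``family_id``, ``name``, ``class`` (one of
    ION_CHANNEL / SECONDARY / ATP_DEPENDENT) and ``is_energizer``
    (true/false). Duplicate ids, unknown class labels and energizer flags
    on non-ATP-dependent families are hard errors.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise RegistryError(f"registry file {path} lacks required columns: {missing}")

    definitions = []
    for idx, row in enumerate(table.to_dict("records")):
        flag = str(row["is_energizer"]).strip().lower()
        if flag not in _BOOL_LABELS:
            raise RegistryError(
                f"row {idx + 2} of {path}: is_energizer must be true/false, "
                f"got {row['is_energizer']!r}"
            )
        try:
            tclass = TransporterClass.parse(row["class"])
        except RegistryError as exc:
            raise RegistryError(f"row {idx + 2} of {path}: {exc}") from None
        definitions.append(
            FamilyDefinition(
                family_id=str(row["family_id"]).strip(),
                name=str(row["name"]).strip(),
                transporter_class=tclass,
                is_energizer=_BOOL_LABELS[flag],
            )
        )
    return FamilyRegistry.from_definitions(definitions)


def write_registry(registry: FamilyRegistry, path: str | PathLike) -> None:
    """Write a registry in the same tab-separated dialect the loader reads."""
    frame = pd.DataFrame(
        {
            "family_id": [f.family_id for f in registry],
            "name": [f.name for f in registry],
            "class": [f.transporter_class.value for f in registry],
            "is_energizer": ["true" if f.is_energizer else "false" for f in registry],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def bundled_registry() -> FamilyRegistry:
    """The example registry shipped with the package.

    Covers the well-known families referenced throughout the analysis (ABC
    superfamily, MFS, mitochondrial carrier / SLC25, F/V/A-ATPases,
    lineage-restricted channel and carrier families). It is an illustrative
    working set for demos, tests and the synthetic-data generator — not a
    reconstruction of any external database.
    """
    ref = resources.files("transportome").joinpath("data/example_registry.tsv")
    with resources.as_file(ref) as path:
        return load_family_registry(path)
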