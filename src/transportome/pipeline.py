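"""End-to-end analysis pipeline: ingest → composition → EUE → family sets.

:func:`run_pipeline` ties the stages together the way the full analysis
is meant to be run: read (or receive) a family registry, annotation table
and species metadata; apply the filter chain; compute per-species
compositions and intra-genomic frequencies; summarise per group with
t-based confidence intervals and pairwise Student's t-tests (raw and
arcsin-√ transformed); build the ΔEUE matrix; and derive the family
presence matrix, prokaryote/eukaryote specificity partitions per class
and an optional single-family marker screen. Every table is written
tab-separated, a JSON summary collects the headline numbers, and an
audit log records every dropped or merged record and every parameter.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import composition as comp
from . import family_sets as fams
from . import ingest
from .eue import EUEResult, EUEWeights, eue_matrix, format_delta_matrix, species_eue
from .ontology import FamilyRegistry, TransporterClass, bundled_registry, load_family_registry

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("transportome")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (CLI flags override file values)."""

    annotations: str | PathLike
    metadata: str | PathLike
    out_dir: str | PathLike
    registry: str | PathLike | None = None  # None -> bundled example registry
    exclude_energizers: bool = True
    min_len: int = ingest.DEFAULT_MIN_LENGTH
    confidence: float = 0.99
    weights: EUEWeights = field(default_factory=EUEWeights)
    superset_a: tuple[str, ...] = tuple(sorted(fams.PROKARYOTE_GROUPS))
    superset_b: tuple[str, ...] = tuple(sorted(fams.EUKARYOTE_GROUPS))
    marker_family: str | None = "2.A.29"
    min_species_presence: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError(f"confidence must be in (0, 1), got {self.confidence}")

    @classmethod
    def from_yaml(cls, path: str | PathLike, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "weights" in raw and isinstance(raw["weights"], dict):
            raw["weights"] = EUEWeights(**raw["weights"])
        for key in ("superset_a", "superset_b"):
            if key in raw:
                raw[key] = tuple(raw[key])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one run."""

    transportomes: list[ingest.Transportome]
    compositions: list[comp.CompositionRecord]
    summaries: list[comp.GroupSummary]
    ttests: pd.DataFrame
    eue_result: EUEResult
    presence: fams.FamilyPresence
    partitions: dict[str, fams.SpecificityPartition]  # "all" + one per class
    marker_hits: list[str] | None
    filter_report: list[dict]
    paths: dict[str, Path]
    summary: dict


def _composition_frame(records: Sequence[comp.CompositionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "pct_adt": round(r.pct_adt, 4),
                "pct_st": round(r.pct_st, 4),
                "pct_ic": round(r.pct_ic, 4),
                "freq_adt": r.freq_adt,
                "freq_st": r.freq_st,
                "freq_ic": r.freq_ic,
                "n_excluded_energizers": r.n_excluded_energizers,
            }
            for r in records
        ]
    )


def _summary_frame(summaries: Sequence[comp.GroupSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"group_label": s.group_label, "n_species": s.n_species}
        for key in comp.CLASS_KEYS:
            row.update(
                {
                    f"mean_pct_{key}": round(s.mean[key], 4),
                    f"sd_pct_{key}": round(s.sd[key], 4),
                    f"ci_low_pct_{key}": round(s.ci_low[key], 4),
                    f"ci_high_pct_{key}": round(s.ci_high[key], 4),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _pairwise_ttests(
    records: Sequence[comp.CompositionRecord],
    meta: Sequence[ingest.SpeciesMeta],
) -> pd.DataFrame:
    """Student's t-tests for every group pair and class, raw and arcsin-√."""
    group_of = {m.species_id: m.group_label for m in meta}
    by_group: dict[str, list[comp.CompositionRecord]] = {}
    for m in meta:
        by_group.setdefault(m.group_label, [])
    for r in records:
        by_group[group_of[r.species_id]].append(r)
    groups = [g for g, members in by_group.items() if len(members) >= 2]

    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        for key in comp.CLASS_KEYS:
            a = [getattr(r, f"pct_{key}") for r in by_group[ga]]
            b = [getattr(r, f"pct_{key}") for r in by_group[gb]]
            t_raw, df, p_raw = comp.ttest_groups(a, b)
            ta = comp.arcsin_sqrt([x / 100.0 for x in a])
            tb = comp.arcsin_sqrt([x / 100.0 for x in b])
            t_tr, _, p_tr = comp.ttest_groups(ta, tb)
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "class": key,
                    "t": t_raw,
                    "df": df,
                    "p": p_raw,
                    "t_arcsin_sqrt": t_tr,
                    "p_arcsin_sqrt": p_tr,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    annotations: Sequence[ingest.ProteinAnnotation] | None = None,
    metadata: Sequence[ingest.SpeciesMeta] | None = None,
    registry: FamilyRegistry | None = None,
) -> PipelineResult:
    """Run the complete analysis and write its report bundle.

    Inputs may be passed in-memory (``annotations`` / ``metadata`` /
    ``registry``); otherwise they are read from the paths in ``config``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if registry is None:
        registry = (
            load_family_registry(config.registry)
            if config.registry is not None
            else bundled_registry()
        )
    if annotations is None:
        annotations = ingest.read_annotations(config.annotations, registry)
    if metadata is None:
        metadata = ingest.read_species_meta(config.metadata)
    meta_by_id = {m.species_id: m for m in metadata}

    # --- ingest filters ---
    report: list[dict] = []
    filtered = ingest.apply_filters(
        annotations, registry, min_len=config.min_len, report=report
    )
    transportomes = ingest.build_transportomes(filtered, registry)
    logger.info(
        "ingest: %d raw records -> %d transporters in %d species (%d filter actions)",
        len(annotations), len(filtered), len(transportomes), len(report),
    )

    # --- composition ---
    compositions = []
    for t in transportomes:
        if t.species_id not in meta_by_id:
            raise ingest.AnnotationError(f"no metadata for species {t.species_id!r}")
        compositions.append(
            comp.intragenomic_frequencies(
                t, meta_by_id[t.species_id], registry,
                exclude_energizers=config.exclude_energizers,
            )
        )
    summaries = comp.group_summary(compositions, metadata, confidence=config.confidence)
    ttests = _pairwise_ttests(compositions, metadata)

    # --- EUE ---
    eue_result = eue_matrix(
        summaries,
        w=config.weights,
        per_species=species_eue(compositions, config.weights),
    )

    # --- family sets ---
    presence = fams.presence_matrix(
        transportomes, metadata, registry, min_species=config.min_species_presence
    )
    observed_groups = set(presence.groups)
    set_a = tuple(g for g in config.superset_a if g in observed_groups)
    set_b = tuple(g for g in config.superset_b if g in observed_groups)
    partitions: dict[str, fams.SpecificityPartition] = {}
    if set_a and set_b:
        labels = ("|".join(set_a), "|".join(set_b))
        partitions["all"] = fams.specificity_partition(
            presence, set_a, set_b, labels=labels
        )
        for cls in TransporterClass:
            partitions[cls.value] = fams.specificity_partition(
                presence, set_a, set_b, registry=registry, class_filter=cls, labels=labels
            )
    marker_hits = (
        fams.marker_screen(transportomes, config.marker_family, registry)
        if config.marker_family
        else None
    )

    # --- write report bundle ---
    paths: dict[str, Path] = {}

    def write_frame(name: str, frame: pd.DataFrame) -> None:
        paths[name] = out_dir / f"{name}.tsv"
        frame.to_csv(paths[name], sep="\t", index=False)

    write_frame("compositions", _composition_frame(compositions))
    write_frame("group_summary", _summary_frame(summaries))
    write_frame("ttests", ttests)
    write_frame(
        "eue_long",
        pd.DataFrame(
            [
                {"group_row": gr, "group_col": gc,
                 "delta_eue": eue_result.delta_entry(gr, gc)}
                for gr in eue_result.group_order
                for gc in eue_result.group_order
                if gr != gc
            ]
        ),
    )
    paths["eue_matrix"] = out_dir / "eue_matrix.tsv"
    paths["eue_matrix"].write_text(format_delta_matrix(eue_result))
    paths["presence_matrix"] = out_dir / "presence_matrix.tsv"
    presence.frame().astype(int).to_csv(
        paths["presence_matrix"], sep="\t", index_label="family_id"
    )
    if partitions:
        rows = []
        for scope, part in partitions.items():
            for label, families in (
                ("a_only", part.a_only), ("b_only", part.b_only), ("shared", part.shared)
            ):
                for family_id in sorted(families):
                    rows.append(
                        {
                            "scope": scope,
                            "family_id": family_id,
                            "class": registry.transporter_class(family_id).value,
                            "set_label": label,
                        }
                    )
        write_frame("specificity_partition", pd.DataFrame(rows))
    if marker_hits is not None:
        paths["marker_screen"] = out_dir / "marker_screen.tsv"
        pd.DataFrame({"species_id": marker_hits}).to_csv(
            paths["marker_screen"], sep="\t", index=False
        )
    paths["audit_log"] = out_dir / "audit_log.tsv"
    pd.DataFrame(
        report, columns=["action", "species_id", "protein_id", "detail"]
    ).to_csv(paths["audit_log"], sep="\t", index=False)

    summary = {
        "parameters": {
            "exclude_energizers": config.exclude_energizers,
            "min_len": config.min_len,
            "confidence": config.confidence,
            "weights": list(config.weights.as_tuple()),
            "superset_a": list(set_a),
            "superset_b": list(set_b),
            "marker_family": config.marker_family,
        },
        "n_species": len(transportomes),
        "n_raw_records": len(annotations),
        "n_counted_transporters": sum(t.total_transporters for t in transportomes),
        "group_mean_pct": {
            s.group_label: {k: round(s.mean[k], 4) for k in comp.CLASS_KEYS}
            for s in summaries
        },
        "group_mean_eue": {
            g: round(v, 6) for g, v in eue_result.group_mean_eue.items()
        },
        "delta_eue": {
            f"{gr}|{gc}": round(eue_result.delta_entry(gr, gc), 6)
            for i, gr in enumerate(eue_result.group_order)
            for gc in eue_result.group_order[:i]
        },
        "partition_sizes": {
            scope: {
                "a_only": len(p.a_only),
                "b_only": len(p.b_only),
                "shared": len(p.shared),
            }
            for scope, p in partitions.items()
        },
        "marker_hits": marker_hits,
    }
    paths["summary"] = out_dir / "summary.json"
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        transportomes=transportomes,
        compositions=compositions,
        summaries=summaries,
        ttests=ttests,
        eue_result=eue_result,
        presence=presence,
        partitions=partitions,
        marker_hits=marker_hits,
        filter_report=report,
        paths=paths,
        summary=summary,
    )
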