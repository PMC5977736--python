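import pytest
from hypothesis import given
from hypothesis import strategies as st

from transportome import (
    AnnotationError,
    ProteinAnnotation,
    apply_filters,
    build_transportomes,
    collapse_complexes,
    deduplicate_hits,
    filter_short_proteins,
    read_annotations,
    write_annotations,
)


def ann(protein, family="2.A.1", species="sp1", gene=None, length=None, complex_id=None):
    return ProteinAnnotation(
        species_id=species,
        protein_id=protein,
        family_id=family,
        gene_id=gene,
        length_aa=length,
        complex_id=complex_id,
    )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def test_read_back_well_formed_file(tmp_path, registry):
    records = [
        ann("p1", length=200, gene="g1"),
        ann("p2", family="1.A.1"),
        ann("p3", family="3.A.1", complex_id="op1"),
        ann("p4", species="sp2"),
        ann("p5", species="sp2", length=99),
    ]
    path = tmp_path / "annot.tsv"
    write_annotations(records, path)
    back = read_annotations(path, registry)
    assert back == records


def test_unknown_family_errors_with_id(tmp_path, registry):
    path = tmp_path / "annot.tsv"
    path.write_text(
        "species_id\tprotein_id\tfamily_id\nsp1\tp1\t2.A.1\nsp1\tp2\tXYZ\n"
    )
    with pytest.raises(Exception, match="XYZ"):
        read_annotations(path, registry)


def test_malformed_row_errors_with_line_number(tmp_path, registry):
    path = tmp_path / "annot.tsv"
    path.write_text(
        "species_id\tprotein_id\tfamily_id\tlength_aa\nsp1\tp1\t2.A.1\tlong\n"
    )
    with pytest.raises(AnnotationError, match="line 2"):
        read_annotations(path, registry)


def test_generator_output_reread_matches_record_count(tmp_path, registry, clean_small):
    path = tmp_path / "annot.tsv"
    write_annotations(clean_small.annotations, path)
    assert len(read_annotations(path, registry)) == len(clean_small.annotations)


# ---------------------------------------------------------------------------
# length filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "length,kept",
    [(99, False), (100, True), (1, False), (150, True), (None, True)],
)
def test_short_protein_cutoff_is_strict(length, kept):
    out = filter_short_proteins([ann("p1", length=length)])
    assert (len(out) == 1) is kept


def test_length_filter_keeps_order_and_unknown_lengths():
    records = [ann("p1"), ann("p2", length=99), ann("p3"), ann("p4", length=100)]
    assert filter_short_proteins(records) == [records[0], records[2], records[3]]


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def test_multi_hit_resolution_is_order_insensitive():
    a = ann("p1", family="2.A.6")
    b = ann("p1", family="2.A.1")
    for order in ([a, b], [b, a]):
        out = deduplicate_hits(order)
        assert len(out) == 1
        assert out[0].family_id == "2.A.1"  # lexicographically smallest


def test_isoforms_of_one_gene_collapse_to_one_record():
    report = []
    out = deduplicate_hits(
        [ann("p1", gene="g1"), ann("p2", gene="g1"), ann("p3", gene="g2")],
        report=report,
    )
    assert [r.protein_id for r in out] == ["p1", "p3"]
    assert report[0]["action"] == "drop_isoform"


def test_dedup_is_identity_on_unique_records():
    records = [ann(f"p{i}", gene=f"g{i}") for i in range(5)]
    assert deduplicate_hits(records) == records


def test_same_gene_in_different_species_not_collapsed():
    records = [ann("p1", gene="g1", species="sp1"), ann("p1", gene="g1", species="sp2")]
    assert len(deduplicate_hits(records)) == 2


# ---------------------------------------------------------------------------
# complex collapsing
# ---------------------------------------------------------------------------

def test_abc_operon_subunits_collapse_to_single_transporter(registry):
    subunits = [
        ann(f"p{i}", family="3.A.1", complex_id="op1", gene=f"g{i}") for i in range(3)
    ]
    out = collapse_complexes(subunits, registry)
    assert len(out) == 1
    assert out[0].protein_id == "p0"


def test_records_without_complex_id_are_untouched(registry):
    records = [ann(f"p{i}", family="3.A.1") for i in range(3)]
    assert collapse_complexes(records, registry) == records


def test_two_complexes_each_collapse_separately(registry):
    records = [
        ann("p1", family="3.A.1", complex_id="op1"),
        ann("p2", family="3.A.1", complex_id="op1"),
        ann("p3", family="3.A.1", complex_id="op2"),
        ann("p4", family="3.A.1", complex_id="op2"),
    ]
    out = collapse_complexes(records, registry)
    assert [r.protein_id for r in out] == ["p1", "p3"]


def test_non_atp_dependent_complexes_not_collapsed(registry):
    records = [
        ann("p1", family="2.A.1", complex_id="het1"),
        ann("p2", family="2.A.1", complex_id="het1"),
    ]
    assert len(collapse_complexes(records, registry)) == 2


def test_complex_spanning_families_is_ambiguous(registry):
    records = [
        ann("p1", family="3.A.1", complex_id="op1"),
        ann("p2", family="3.A.3", complex_id="op1"),
    ]
    with pytest.raises(AnnotationError, match="op1"):
        collapse_complexes(records, registry)


# ---------------------------------------------------------------------------
# transportome assembly and pipeline properties
# ---------------------------------------------------------------------------

def test_counts_reflect_record_multiplicities(registry):
    records = [ann("p1"), ann("p2"), ann("p3", family="1.A.1"), ann("p4", family="1.A.1")]
    (t,) = build_transportomes(records, registry)
    assert t.family_counts == {"1.A.1": 2, "2.A.1": 2}
    assert t.total_transporters == 4


def test_empty_input_gives_empty_list(registry):
    assert build_transportomes([], registry) == []


def test_totals_match_generator_manifest(registry, clean_small):
    filtered = apply_filters(clean_small.annotations, registry)
    for t in build_transportomes(filtered, registry):
        assert t.total_transporters == clean_small.manifest.expected_total(t.species_id)


@st.composite
def annotation_lists(draw):
    n = draw(st.integers(0, 12))
    records = []
    for i in range(n):
        records.append(
            ProteinAnnotation(
                species_id=draw(st.sampled_from(["spA", "spB"])),
                protein_id=f"p{draw(st.integers(0, 5))}",
                family_id=draw(st.sampled_from(["2.A.1", "3.A.1", "1.A.1", "3.A.3"])),
                gene_id=draw(st.sampled_from([None, "g1", "g2", "g3"])),
                length_aa=draw(st.sampled_from([None, 50, 99, 100, 400])),
                complex_id=draw(st.sampled_from([None, "cx1", "cx2"])),
            )
        )
    return records


@given(records=annotation_lists())
def test_each_filter_is_idempotent(registry, records):
    short_once = filter_short_proteins(records)
    assert filter_short_proteins(short_once) == short_once
    dedup_once = deduplicate_hits(short_once)
    assert deduplicate_hits(dedup_once) == dedup_once
    try:
        collapsed = collapse_complexes(dedup_once, registry)
    except AnnotationError:
        return  # ambiguous complex in the random draw
    assert collapse_complexes(collapsed, registry) == collapsed


@given(records=annotation_lists())
def test_filters_never_increase_counts(registry, records):
    try:
        filtered = apply_filters(records, registry)
    except AnnotationError:
        return
    per_species_in = {}
    for r in records:
        per_species_in[r.species_id] = per_species_in.get(r.species_id, 0) + 1
    for t in build_transportomes(filtered, registry):
        assert t.total_transporters <= per_species_in[t.species_id]


def test_collapse_without_complex_ids_is_identity(registry):
    records = [ann(f"p{i}", family="3.A.1") for i in range(4)]
    assert collapse_complexes(records, registry) == records
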