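import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from transportome import (
    CompositionError,
    SpeciesMeta,
    Transportome,
    arcsin_sqrt,
    class_fractions,
    group_summary,
    intragenomic_frequencies,
    pearson,
    ttest_groups,
)
from transportome.composition import CompositionRecord


def transportome(counts, species="sp1"):
    return Transportome(species_id=species, family_counts=counts)


def record(species, adt, st_, ic):
    return CompositionRecord(species_id=species, pct_adt=adt, pct_st=st_, pct_ic=ic)


# ---------------------------------------------------------------------------
# class fractions
# ---------------------------------------------------------------------------

def test_fractions_are_percentages_of_post_filter_counts(registry):
    t = transportome({"3.A.1": 5, "2.A.1": 3, "1.A.1": 2})
    rec = class_fractions(t, registry)
    assert (rec.pct_adt, rec.pct_st, rec.pct_ic) == (50.0, 30.0, 20.0)


def test_energizers_removed_from_numerator_and_denominator(registry):
    t = transportome({"3.A.2.F": 4, "1.A.1": 6})
    rec = class_fractions(t, registry, exclude_energizers=True)
    assert (rec.pct_adt, rec.pct_st, rec.pct_ic) == (0.0, 0.0, 100.0)
    assert rec.n_excluded_energizers == 4
    kept = class_fractions(t, registry, exclude_energizers=False)
    assert kept.pct_adt == 40.0 and kept.pct_ic == 60.0


def test_single_class_transportome(registry):
    rec = class_fractions(transportome({"1.A.1": 7, "1.A.8": 3}), registry)
    assert (rec.pct_adt, rec.pct_st, rec.pct_ic) == (0.0, 0.0, 100.0)


def test_empty_after_energizer_exclusion_names_species(registry):
    with pytest.raises(CompositionError, match="sp1"):
        class_fractions(transportome({"3.A.2.F": 3}), registry)


@given(
    counts=st.tuples(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)).filter(
        lambda c: sum(c) > 0
    ),
    k=st.integers(1, 9),
)
def test_fractions_invariant_to_count_scaling(registry, counts, k):
    adt, sec, ic = counts
    base = {"3.A.1": adt, "2.A.1": sec, "1.A.1": ic}
    scaled = {f: n * k for f, n in base.items()}
    a = class_fractions(transportome(base), registry)
    b = class_fractions(transportome(scaled), registry)
    assert a.percentages() == pytest.approx(b.percentages(), abs=1e-12)


# ---------------------------------------------------------------------------
# intra-genomic frequencies
# ---------------------------------------------------------------------------

def test_frequency_is_count_over_total_genes(registry):
    t = transportome({"3.A.1": 100})
    meta = SpeciesMeta(species_id="sp1", group_label="bacteria", total_genes=10_000)
    rec = intragenomic_frequencies(t, meta, registry)
    assert rec.freq_adt == pytest.approx(0.01)
    assert rec.freq_st == 0.0 and rec.freq_ic == 0.0


def test_frequencies_require_matching_metadata(registry):
    t = transportome({"3.A.1": 5})
    other = SpeciesMeta(species_id="sp2", group_label="bacteria", total_genes=100)
    with pytest.raises(CompositionError):
        intragenomic_frequencies(t, other, registry)


def test_frequencies_track_generator_truth(registry, clean_small):
    from transportome import apply_filters, build_transportomes

    manifest = clean_small.manifest
    meta = {m.species_id: m for m in clean_small.metadata}
    transportomes = build_transportomes(
        apply_filters(clean_small.annotations, registry), registry
    )
    for t in transportomes:
        rec = intragenomic_frequencies(t, meta[t.species_id], registry)
        truth = manifest.species[t.species_id]
        assert rec.freq_adt == pytest.approx(truth["n_adt"] / truth["total_genes"])
        assert rec.freq_ic == pytest.approx(truth["n_ic"] / truth["total_genes"])


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def meta_for(groups):
    return [
        SpeciesMeta(species_id=s, group_label=g, total_genes=1000)
        for s, g in groups.items()
    ]


def test_identical_records_collapse_ci_to_mean():
    records = [record(f"s{i}", 20.0, 50.0, 30.0) for i in range(4)]
    meta = meta_for({f"s{i}": "g" for i in range(4)})
    (summary,) = group_summary(records, meta)
    assert summary.sd["adt"] == 0.0
    assert summary.ci_low["adt"] == summary.ci_high["adt"] == 20.0


def test_two_species_ci_matches_closed_form():
    """Half-width must be t_{0.995, 1} x s / sqrt(2) for n = 2 at 99%."""
    records = [record("a", 30.0, 30.0, 40.0), record("b", 30.0, 10.0, 60.0)]
    meta = meta_for({"a": "g", "b": "g"})
    (summary,) = group_summary(records, meta, confidence=0.99)
    assert summary.mean["ic"] == pytest.approx(50.0)
    sd = math.sqrt(((40 - 50) ** 2 + (60 - 50) ** 2) / 1)  # sample sd
    t995_df1 = 63.65674116287158  # textbook t quantile, df = 1
    assert summary.sd["ic"] == pytest.approx(sd, abs=1e-10)
    assert summary.ci_high["ic"] - summary.mean["ic"] == pytest.approx(
        t995_df1 * sd / math.sqrt(2), rel=1e-10
    )


def test_singleton_group_is_an_error():
    records = [record("a", 10, 60, 30), record("b", 10, 60, 30), record("c", 10, 60, 30)]
    meta = meta_for({"a": "g1", "b": "g1", "c": "g2"})
    with pytest.raises(CompositionError, match="g2"):
        group_summary(records, meta)


def test_group_summary_worked_three_species_example_to_1e10():
    """CI limbs agree with the closed-form t-interval for n = 3."""
    values = [10.0, 16.0, 25.0]
    records = [record(f"s{i}", v, 70.0 - v + 20.0, 10.0) for i, v in enumerate(values)]
    # pct_adt = v, pct_st = 90 - v, pct_ic = 10
    meta = meta_for({f"s{i}": "g" for i in range(3)})
    (summary,) = group_summary(records, meta, confidence=0.99)
    mean = sum(values) / 3
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / 2)
    half = stats.t.ppf(0.995, df=2) * sd / math.sqrt(3)
    assert summary.mean["adt"] == pytest.approx(mean, abs=1e-10)
    assert summary.ci_low["adt"] == pytest.approx(mean - half, abs=1e-10)
    assert summary.ci_high["adt"] == pytest.approx(mean + half, abs=1e-10)


# ---------------------------------------------------------------------------
# arcsin sqrt
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p,expected", [(0.0, 0.0), (1.0, math.pi / 2), (0.5, math.pi / 4)]
)
def test_arcsin_sqrt_fixed_points(p, expected):
    assert arcsin_sqrt(p) == pytest.approx(expected, abs=1e-12)


def test_arcsin_sqrt_rejects_out_of_range():
    with pytest.raises(CompositionError):
        arcsin_sqrt(1.2)
    with pytest.raises(CompositionError):
        arcsin_sqrt(-0.1)


@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_arcsin_sqrt_is_monotone(p, q):
    if p == q:
        assert arcsin_sqrt(p) == arcsin_sqrt(q)
    else:
        lo, hi = min(p, q), max(p, q)
        assert arcsin_sqrt(lo) <= arcsin_sqrt(hi)
        if hi - lo > 1e-9:  # strict away from float-adjacent inputs
            assert arcsin_sqrt(lo) < arcsin_sqrt(hi)


# ---------------------------------------------------------------------------
# t-test and Pearson
# ---------------------------------------------------------------------------

def test_identical_samples_give_t0_p1():
    t, df, p = ttest_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert df == 4
    assert p == pytest.approx(1.0)


def test_large_shift_is_highly_significant():
    t, _, p = ttest_groups([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
    assert p < 1e-3


def test_pooled_t_matches_hand_computation_to_1e10():
    a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 9.0]
    t, df, p = ttest_groups(a, b)
    sa2 = np.var(a, ddof=1)
    sb2 = np.var(b, ddof=1)
    pooled = ((len(a) - 1) * sa2 + (len(b) - 1) * sb2) / (len(a) + len(b) - 2)
    t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(pooled * (1 / len(a) + 1 / len(b)))
    p_hand = 2 * stats.t.sf(abs(t_hand), df=len(a) + len(b) - 2)
    assert t == pytest.approx(t_hand, abs=1e-10)
    assert df == len(a) + len(b) - 2
    assert p == pytest.approx(p_hand, abs=1e-10)


def test_ttest_rejects_tiny_samples():
    with pytest.raises(CompositionError):
        ttest_groups([1.0], [1.0, 2.0])


def test_pearson_exact_on_affine_relations():
    x = [1.0, 2.0, 3.0, 4.0]
    assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
    assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)


def test_pearson_matches_covariance_definition():
    x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
    y = np.array([2.0, 3.0, 1.0, 9.0, 4.0])
    expected = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert pearson(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_rejects_constant_vectors():
    with pytest.raises(CompositionError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# transform preserves group ordering of mean fractions
# ---------------------------------------------------------------------------

def test_mean_difference_sign_stable_under_arcsin_sqrt(study_result):
    """Group-pair conclusions must not depend on the proportion scale."""
    for row in study_result.ttests.itertuples():
        if min(row.p, row.p_arcsin_sqrt) < 0.01:
            assert np.sign(row.t) == np.sign(row.t_arcsin_sqrt)
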