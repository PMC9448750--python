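"""Channel model, catalogue construction, masks, opportunities, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffpecorrect import (
    ALL_MASK,
    CHANNEL_LABELS,
    CONTEXTS_32,
    CT_MASK,
    NON_TC_MASK,
    TC_MASK,
    Catalogue,
    MutationRecord,
    OpportunityVector,
    build_catalogue,
    classify_variant,
    concordance_classify,
    concordant_wgs,
    cosine_similarity,
    expand_from_80c,
    ffpe_only_filter,
    normalize_to_genome,
    parse_channel,
    read_catalogue_tsv,
    reduce_to_80c,
    write_catalogue_tsv,
)
from ffpecorrect.catalogue import (
    ChannelError,
    ReferenceMismatchError,
    UndefinedSimilarityError,
    UnsupportedVariantError,
)

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# --------------------------------------------------------------------- channels


@pytest.mark.parametrize(
    "label,index",
    [("A[C>A]A", 0), ("T[C>A]T", 15), ("A[C>T]A", 32), ("A[T>C]A", 64), ("T[T>G]T", 95)],
)
def test_parse_channel_canonical_indices(label, index):
    ch = parse_channel(label)
    assert ch.index == index
    assert ch.label == label  # round-trip


@pytest.mark.parametrize("bad", ["A[G>T]A", "A[C>C]A", "AC>TA", "A[C>T]", "N[C>T]A"])
def test_parse_channel_rejects_invalid(bad):
    with pytest.raises(ChannelError):
        parse_channel(bad)


def test_channel_context_mapping():
    ch = parse_channel("G[T>A]C")
    assert ch.context == "GTC"
    assert CONTEXTS_32[ch.context_index] == "GTC"


def test_classify_variant_forward_and_folded():
    lookup = {("1", 100): "ACG", ("1", 200): "TGT"}
    ch = classify_variant("1", 100, "C", "T", lambda c, p: lookup[(c, p)])
    assert ch.label == "A[C>T]G"
    # G>A on forward strand folds to C>T with reverse-complemented context
    ch = classify_variant("1", 200, "G", "A", lambda c, p: lookup[(c, p)])
    assert ch.label == "A[C>T]A"


def test_classify_variant_errors():
    with pytest.raises(ReferenceMismatchError):
        classify_variant("1", 1, "C", "T", lambda c, p: "AAG")
    with pytest.raises(UnsupportedVariantError):
        classify_variant("1", 1, "CT", "T", lambda c, p: "ACG")
    with pytest.raises(UnsupportedVariantError):
        classify_variant("1", 1, "C", "C", lambda c, p: "ACG")


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    five=st.sampled_from(BASES),
    centre=st.sampled_from("CT"),
    three=st.sampled_from(BASES),
    alt_shift=st.integers(1, 3),
)
def test_classify_variant_strand_involutive(five, centre, three, alt_shift):
    """Classifying a variant from its reverse-complement representation
    yields the identical channel."""
    alt = BASES[(BASES.index(centre) + alt_shift) % 4]
    ctx = f"{five}{centre}{three}"
    fwd = classify_variant("1", 5, centre, alt, lambda c, p: ctx)
    rc_ctx = "".join(COMP[b] for b in reversed(ctx))
    rev = classify_variant("1", 5, COMP[centre], COMP[alt], lambda c, p: rc_ctx)
    assert fwd == rev


# ------------------------------------------------------------------- catalogue


def rec(sample, chrom, pos, label, reads=None):
    ch = parse_channel(label)
    ref, alt = ch.substitution[0], ch.substitution[2]
    return MutationRecord(sample, chrom, pos, ref, alt, ch, reads)


def test_build_catalogue_counts_and_conservation(rng):
    labels = rng.choice(CHANNEL_LABELS, size=50)
    records = [rec("s1", "1", i, lab) for i, lab in enumerate(labels)]
    cat = build_catalogue(records)
    assert cat.total() == 50  # record count conserved
    assert cat.counts[parse_channel(labels[0]).index] >= 1


def test_build_catalogue_empty_warns():
    with pytest.warns(UserWarning):
        cat = build_catalogue([], sample_id="s0")
    assert cat.total() == 0
    assert cat.metadata["empty_input"]


def test_catalogue_rejects_negative_and_wrong_length():
    with pytest.raises(ValueError):
        Catalogue("x", np.full(95, 1.0))
    bad = np.zeros(96)
    bad[0] = -1
    with pytest.raises(ValueError):
        Catalogue("x", bad)


# ---------------------------------------------------------------- opportunities


def test_normalize_to_genome_identity_projection():
    counts = np.zeros(96)
    counts[0] = 30
    counts[40] = 10
    cat = Catalogue("s", counts)
    opp = OpportunityVector(np.full(32, 1.0))
    prof = normalize_to_genome(cat, opp, opp)
    assert np.allclose(prof, counts / counts.sum())


def test_normalize_to_genome_reweights():
    # 10 counts in a context with panel 5 / genome 20 (weight 40) and 10 in
    # one with panel 10 / genome 10 (weight 10) -> probabilities 0.8 / 0.2
    ch_a, ch_b = parse_channel("A[C>A]A"), parse_channel("C[C>A]C")
    counts = np.zeros(96)
    counts[ch_a.index] = 10
    counts[ch_b.index] = 10
    panel = np.full(32, 1.0)
    genome = np.full(32, 1.0)
    panel[ch_a.context_index], genome[ch_a.context_index] = 5, 20
    panel[ch_b.context_index], genome[ch_b.context_index] = 10, 10
    prof = normalize_to_genome(
        Catalogue("s", counts), OpportunityVector(panel), OpportunityVector(genome)
    )
    assert prof[ch_a.index] == pytest.approx(0.8)
    assert prof[ch_b.index] == pytest.approx(0.2)


def test_normalize_to_genome_zero_panel_opportunity_errors():
    counts = np.zeros(96)
    counts[0] = 3
    panel = np.full(32, 1.0)
    panel[parse_channel("A[C>A]A").context_index] = 0.0
    with pytest.raises(ValueError, match="zero panel opportunity"):
        normalize_to_genome(
            Catalogue("s", counts), OpportunityVector(panel), OpportunityVector(np.ones(32))
        )


# ------------------------------------------------------------------ 80c & masks


def test_reduce_to_80c_uniform():
    prof = np.full(96, 1 / 96)
    out = reduce_to_80c(prof)
    assert out.shape == (80,)
    assert np.allclose(out, 1 / 80)


def test_reduce_expand_idempotent(rng):
    vec = rng.random(96)
    vec[list(TC_MASK.indices)] = 0.0
    vec /= vec.sum()
    once = reduce_to_80c(vec)
    again = reduce_to_80c(expand_from_80c(once))
    assert np.allclose(once, again)
    # signature with zero T>C mass is unchanged by the reduction
    assert np.allclose(once, vec[list(NON_TC_MASK.indices)])


def test_reduce_to_80c_all_tc_mass_errors():
    vec = np.zeros(96)
    vec[64] = 1.0
    with pytest.raises(ValueError, match="T>C"):
        reduce_to_80c(vec)
    assert reduce_to_80c(vec, renormalize=False).sum() == 0


def test_cosine_similarity_hand_value_and_errors():
    assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(0.7071, abs=1e-4)
    a = np.zeros(96)
    with pytest.raises(UndefinedSimilarityError):
        cosine_similarity(a, np.ones(96), CT_MASK)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    scale=st.floats(0.01, 100.0),
    mask=st.sampled_from([ALL_MASK, CT_MASK, NON_TC_MASK]),
)
def test_cosine_symmetric_and_scale_invariant(seed, scale, mask):
    r = np.random.default_rng(seed)
    a, b = r.random(96) + 1e-6, r.random(96) + 1e-6
    s1 = cosine_similarity(a, b, mask)
    assert s1 == pytest.approx(cosine_similarity(b, a, mask))
    assert s1 == pytest.approx(cosine_similarity(scale * a, b, mask))


# ------------------------------------------------------------------ concordance


def test_concordance_private_mutations_all_zero():
    tables = {
        "s1": [rec("s1", "1", 10, "A[C>T]A")],
        "s2": [rec("s2", "1", 20, "A[C>T]A")],
        "s3": [rec("s3", "1", 30, "A[C>T]A")],
    }
    _, per_sub, pairwise = concordance_classify(tables)
    assert per_sub["C>T"] == 0.0
    assert (pairwise["concordance"] == 0).all()


def test_concordance_shared_fraction_brute_force():
    # one mutation in 2 of 3 samples plus one private -> 2 of 3 instances
    # of that class are concordant
    shared = ("1", 100, "C", "T")
    tables = {
        "s1": [MutationRecord("s1", *shared)],
        "s2": [MutationRecord("s2", *shared)],
        "s3": [MutationRecord("s3", "1", 300, "C", "T")],
    }
    per_mut, per_sub, _ = concordance_classify(tables)
    assert per_sub["C>T"] == pytest.approx(2 / 3)
    assert per_mut["concordant"].sum() == 2


def test_concordance_deduplicates_with_warning():
    dup = MutationRecord("s1", "1", 5, "T", "C")
    with pytest.warns(UserWarning, match="duplicate"):
        per_mut, _, _ = concordance_classify({"s1": [dup, dup], "s2": []})
    assert len(per_mut) == 1


def test_ffpe_only_filter_rules():
    m_all_ff = MutationRecord("f", "1", 1, "C", "T")
    m_normal = MutationRecord("f", "1", 2, "C", "T")
    m_posterior_hi = MutationRecord("f", "1", 3, "C", "T")
    m_posterior_lo = MutationRecord("f", "1", 4, "C", "T")
    m_germ = MutationRecord("f", "1", 5, "C", "T")
    m_keep = MutationRecord("f", "1", 6, "C", "T")
    ff = {
        "ff1": [MutationRecord("ff1", "1", 1, "C", "T")],
        "ff2": [MutationRecord("ff2", "1", 1, "C", "T")],
    }
    out = ffpe_only_filter(
        [m_all_ff, m_normal, m_posterior_hi, m_posterior_lo, m_germ, m_keep],
        ff,
        normal_muts=[MutationRecord("n", "1", 2, "C", "T")],
        germline_sites=[("1", 5, "C", "T")],
        somatic_posterior={("1", 3, "C", "T"): 0.95, ("1", 4, "C", "T"): 0.90},
    )
    # posterior filter is strict >0.90: 0.95 removed, 0.90 kept
    assert [m.pos for m in out] == [4, 6]


def test_ffpe_only_filter_warns_without_posterior():
    m = MutationRecord("f", "1", 1, "C", "T")
    with pytest.warns(UserWarning, match="posterior"):
        out = ffpe_only_filter([m], {}, [], [])
    assert out == [m]


def test_concordant_wgs_read_boundary():
    a = [rec("a", "1", 1, "A[C>T]A", 5), rec("a", "1", 2, "A[C>T]A", 5),
         rec("a", "1", 3, "A[C>T]A", 9)]
    b = [rec("b", "1", 1, "A[C>T]A", 5), rec("b", "1", 2, "A[C>T]A", 4),
         rec("b", "1", 3, "A[C>T]A", 7), rec("b", "1", 9, "A[C>T]A", 9)]
    out = concordant_wgs(a, b, min_reads=5)
    assert [m.pos for m in out] == [1, 3]  # (5,4) dropped, disjoint dropped


# ------------------------------------------------------------------------- IO


def test_catalogue_tsv_roundtrip_and_row_order(tmp_path, rng):
    counts = rng.integers(0, 50, 96).astype(float)
    cat = Catalogue("sampleX", counts)
    path = tmp_path / "cat.tsv"
    write_catalogue_tsv(cat, path)
    # shuffle rows: the parser must re-sort by canonical channel
    df = pd.read_csv(path, sep="\t").sample(frac=1, random_state=0)
    df.to_csv(path, sep="\t", index=False)
    back = read_catalogue_tsv(path)
    assert back.sample_id == "sampleX"
    assert np.array_equal(back.counts, counts)


def test_opportunity_tsv_roundtrip(tmp_path, rng):
    from ffpecorrect import read_opportunity_tsv
    from ffpecorrect.catalogue import write_opportunity_tsv

    opp = OpportunityVector(rng.random(32) + 0.5, scope="panel")
    path = tmp_path / "opp.tsv"
    write_opportunity_tsv(opp, path)
    back = read_opportunity_tsv(path, scope="panel")
    assert np.allclose(back.freq, opp.freq)
    assert back.per_channel().shape == (96,)


def test_catalogue_from_vcf(tmp_path):
    pytest.importorskip("pysam")
    fasta = tmp_path / "ref.fa"
    #            123456789
    fasta.write_text(">chr1\nGACGTTGCA\n")
    vcf = tmp_path / "muts.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1,length=9>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t3\t.\tC\tT\t.\tPASS\t.\n"  # ACG -> A[C>T]G
        "chr1\t6\t.\tT\tA\t.\tPASS\t.\n"  # TTG -> T[T>A]G
        "chr1\t7\t.\tG\tA\t.\tPASS\t.\n"  # TGC -> folds to G[C>T]A
        "chr1\t4\t.\tG\tGA\t.\tPASS\t.\n"  # indel: skipped
    )
    with pytest.warns(UserWarning, match="non-SNV"):
        cat = catalogue_from_vcf_checked(vcf, fasta)
    from ffpecorrect import parse_channel as pc

    assert cat.total() == 3
    for lab in ("A[C>T]G", "T[T>A]G", "G[C>T]A"):
        assert cat.counts[pc(lab).index] == 1


def catalogue_from_vcf_checked(vcf, fasta):
    from ffpecorrect import catalogue_from_vcf

    return catalogue_from_vcf(vcf, fasta, sample_id="vcf_sample")
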