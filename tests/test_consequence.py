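"""Consequence classifier vs. an independent naive-translation oracle."""

import numpy as np
import pytest

from mutseg.consequence import (
    ConsequenceClass,
    TranscriptModel,
    apply_variant,
    classify_consequence,
    exon_of,
    extension_share_of_frameshifts,
    exon_share_of_extensions,
    net_frame,
    tally_classes,
    translate,
)
from mutseg.io import MutationRecord, VariantClass
from mutseg.simulate import make_toy_transcript
from mutseg.transcripts import extension_panel, synthetic_gata3_transcript

# Independent hard-coded standard genetic code (oracle; not the package's table)
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
ORACLE_TABLE = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(seq):
    """Naive table-driven translation to the first stop."""
    out = []
    for i in range(0, len(seq) - 2, 3):
        aa = ORACLE_TABLE[seq[i : i + 3]]
        if aa == "*":
            return "".join(out), True
        out.append(aa)
    return "".join(out), False


def oracle_classify(t, cds_pos, ref, alt):
    """Mutate the whole mRNA, translate from the start, diff the proteins."""
    ins_len = 0 if alt == "-" else len(alt)
    del_len = 0 if ref == "-" else len(ref)
    frame = {0: 0, 1: 1, 2: -1}[(ins_len - del_len) % 3]
    tpos = t.cds_start + cds_pos - 1
    if ref == "-":
        mutant = t.cdna[:tpos] + alt + t.cdna[tpos:]
    else:
        assert t.cdna[tpos - 1 : tpos - 1 + len(ref)] == ref
        mutant = t.cdna[: tpos - 1] + ("" if alt == "-" else alt) + t.cdna[tpos - 1 + len(ref):]
    wild, _ = oracle_translate(t.cdna[t.cds_start - 1 :])
    mut, stopped = oracle_translate(mutant[t.cds_start - 1 :])
    first = None
    for i, (a, b) in enumerate(zip(wild, mut)):
        if a != b:
            first = i + 1
            break
    if first is None and len(wild) != len(mut):
        first = min(len(wild), len(mut)) + 1
    if frame == 0:
        return None  # oracle only adjudicates frameshifts here
    if not stopped:
        cls = ConsequenceClass.no_stop
    elif len(mut) < len(wild):
        cls = ConsequenceClass.frameshift_truncation
    elif len(mut) > len(wild):
        cls = ConsequenceClass.frameshift_extension
    else:
        cls = ConsequenceClass.frameshift_same_length
    return cls, first, len(mut)


@pytest.mark.parametrize(
    "ins,dele,expected",
    [(1, 0, 1), (0, 1, -1), (3, 0, 0), (2, 0, -1), (0, 2, 1), (4, 1, 0), (0, 0, 0)],
)
def test_net_frame(ins, dele, expected):
    assert net_frame(ins, dele) == expected


def test_net_frame_rejects_negative():
    with pytest.raises(ValueError):
        net_frame(-1, 0)


@pytest.fixture(scope="module")
def toy():
    # hand-built 2-exon transcript: 5'UTR "GG", CDS ATG GAA TGC TAA, 3'UTR "AA"
    return TranscriptModel(
        gene="T", transcript_id="T1", cdna="GGATGGAATGCTAAAA",
        cds_start=3, cds_end=14, exon_ends=(8, 16),
    )


def test_apply_variant_insertion_deletion_substitution(toy):
    assert apply_variant(toy, 4, "-", "G") == "GGATGGGAATGCTAAAA"
    assert apply_variant(toy, 4, "T", "-") == "GGAGGAATGCTAAAA"
    assert apply_variant(toy, 1, "G", "T") == "TGATGGAATGCTAAAA"


def test_apply_variant_reference_mismatch_quotes_bases(toy):
    with pytest.raises(ValueError, match="expected 'C', found 'T'"):
        apply_variant(toy, 4, "C", "A")


def test_translate_basic():
    assert translate("ATGTAA") == ("M", True)
    assert translate("ATGGAATGA") == ("ME", True)
    assert translate("ATGGAA") == ("ME", False)  # runs off the end


def test_translate_rejects_non_acgt():
    with pytest.raises(ValueError, match="offset 3"):
        translate("ATGNCC")


def test_translate_matches_table_oracle(rng):
    sense = [c for c in ORACLE_TABLE if ORACLE_TABLE[c] != "*"]
    for _ in range(25):
        n = int(rng.integers(10, 100))
        seq = "".join(rng.choice(list("ACGT"), size=3 * n))
        mine = translate(seq)
        theirs = oracle_translate(seq)
        assert (mine.protein, mine.hit_stop) == theirs


def test_gata3_worked_frameshifts(gata3):
    """The two characterised GATA3 frameshifts: early stop vs. C-terminal
    extension reading 63 novel residues into the 3'UTR."""
    trunc = classify_consequence(
        gata3,
        MutationRecord("S", "GATA3", 1, VariantClass.frameshift_ins, "-", "G",
                       cdna_position=1006),
    )
    assert trunc.consequence_class == ConsequenceClass.frameshift_truncation
    assert trunc.protein_change == "p.G336fs"
    assert trunc.frame_shift == 1
    assert trunc.mutant_length < gata3.protein_length

    ext = classify_consequence(
        gata3,
        MutationRecord("S", "GATA3", 1, VariantClass.frameshift_ins, "-", "G",
                       cdna_position=1224),
    )
    assert ext.consequence_class == ConsequenceClass.frameshift_extension
    assert ext.protein_change == "p.P409fs"
    assert ext.frame_shift == 1
    assert ext.novel_cterm_length == 63
    assert ext.mutant_length == gata3.protein_length + 63


def test_gata3_extension_panel_max_altered(gata3):
    """Across extensions anchored at residues 395..444, at most 49 original
    C-terminal residues are altered and all append the same 63-residue tail."""
    results = [classify_consequence(gata3, m) for m in extension_panel()]
    assert all(
        r.consequence_class == ConsequenceClass.frameshift_extension for r in results
    )
    assert max(r.altered_original_residues for r in results) == 49
    assert {r.novel_cterm_length for r in results} == {63}


def test_classifier_matches_oracle_on_random_indels(rng):
    """Class, first altered residue and mutant length agree with the naive
    mutate-whole-mRNA / translate / diff oracle on random toy transcripts."""
    n_checked = 0
    for _ in range(25):
        t, variants = make_toy_transcript(rng, n_codons=int(rng.integers(10, 60)))
        for cds_pos, ref, alt, _cls in variants:
            expected = oracle_classify(t, cds_pos, ref, alt)
            m = MutationRecord("S", t.gene, 1, VariantClass.other, ref, alt,
                               cdna_position=cds_pos)
            got = classify_consequence(t, m)
            if expected is None:
                assert got.frame_shift == 0
                continue
            cls, first, length = expected
            assert got.consequence_class == cls
            assert got.first_altered_residue == first
            assert got.mutant_length == length
            n_checked += 1
    assert n_checked >= 200


def test_single_base_insertion_invariants(rng):
    """Any in-CDS 1-bp insertion is a +1 shift and never in-frame; extension
    lengths are internally consistent."""
    t, _ = make_toy_transcript(rng, n_codons=30, utr3_len=90)
    W = t.protein_length
    for cds_pos in range(4, t.cds_len - 6, 7):
        m = MutationRecord("S", t.gene, 1, VariantClass.frameshift_ins, "-", "A",
                           cdna_position=cds_pos)
        pc = classify_consequence(t, m)
        assert pc.frame_shift == 1
        assert pc.consequence_class != ConsequenceClass.in_frame
        if pc.consequence_class == ConsequenceClass.frameshift_extension:
            assert pc.mutant_length - W == pc.novel_cterm_length > 0
        elif pc.consequence_class == ConsequenceClass.frameshift_truncation:
            assert pc.mutant_length < W


def test_codon_boundary_insertion_first_altered(gata3):
    """An insertion right after a codon boundary first alters the next codon
    (unless the shifted codon is synonymous, in which case later)."""
    for anchor in (350, 400, 420):
        pos = 3 * (anchor - 1)
        m = MutationRecord("S", "GATA3", 1, VariantClass.frameshift_ins, "-", "G",
                           cdna_position=pos)
        pc = classify_consequence(gata3, m)
        assert pc.first_altered_residue is not None
        assert pc.first_altered_residue >= anchor


def test_noncoding_positions(gata3):
    m = MutationRecord("S", "GATA3", 1, VariantClass.other, "C", "A",
                       cdna_position=gata3.cds_len + 50)
    assert classify_consequence(gata3, m).consequence_class == ConsequenceClass.noncoding
    m2 = MutationRecord("S", "GATA3", 1, VariantClass.other, "C", "A")
    assert classify_consequence(gata3, m2).consequence_class == ConsequenceClass.noncoding


def test_exon_of_boundaries():
    t = TranscriptModel(
        gene="T", transcript_id="T2",
        cdna="GG" + "ATG" + "GAA" * 130 + "TAA" + "AA",
        cds_start=3, cds_end=2 + 3 + 390 + 3,
        exon_ends=(100, 250, 400),
    )
    assert exon_of(t, 100) == 1  # boundary inclusive
    assert exon_of(t, 101) == 2
    assert exon_of(t, 400) == 3
    with pytest.raises(ValueError):
        exon_of(t, 401)
    # linear-scan oracle
    rng = np.random.default_rng(0)
    for pos in rng.integers(1, 401, size=50):
        expected = next(
            i + 1 for i, end in enumerate(t.exon_ends) if pos <= end
        )
        assert exon_of(t, int(pos)) == expected


def test_tally_classes_empty_and_truth(gata3, sim_default):
    assert tally_classes([], gata3).empty
    _, cohort, truth = sim_default
    singles = {m.sample_id: m for m in cohort.mutations}
    tally = tally_classes(cohort.mutations, gata3)
    assert tally["count"].sum() == len(cohort.mutations)  # partition
    # tally per class equals simulator ground truth
    for cls in set(truth.consequence_classes.values()):
        expected = sum(1 for c in truth.consequence_classes.values() if c == cls)
        got = tally.loc[tally["consequence_class"] == cls, "count"].sum()
        assert got == expected
    share = extension_share_of_frameshifts(tally)
    assert 0.0 <= share <= 1.0
    ex6 = exon_share_of_extensions(tally, 6)
    assert ex6 > 0.5  # extensions concentrate in the last exon
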