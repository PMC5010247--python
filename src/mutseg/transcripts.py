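"""Deterministic transcript fixtures, including a synthetic GATA3-like model.

The real GATA3 reference cDNA is not bundled; :func:`synthetic_gata3_transcript`
constructs a SYNTHETIC stand-in whose coding arithmetic reproduces the
documented behaviour of the 444-residue GATA3 isoform exactly:

* the wild-type protein is 444 residues, ending in glycine (G444);
* an insertion of G after coding position 1006 (within the glycine-336
  codon) shifts into the +1 frame and meets an immediate stop — a
  frameshift truncation annotated ``p.G336fs``;
* an insertion of G after coding position 1224 (the proline-409 codon
  boundary) shifts into the +1 frame, reads through the wild-type stop
  into the 3'UTR and terminates 63 codons later — a C-terminal extension
  annotated ``p.P409fs`` appending 63 novel residues;
* +1-frame insertions across codons 395..444 all yield the same 507-residue
  extended protein; the earliest (alanine 395, whose codon tolerates the
  inserted base synonymously) alters 49 of the original C-terminal
  residues, the documented maximum;
* -1-frame deletions in the extension hotspot region instead truncate.

The sequence outside these engineered sites is synthetic filler and does
not resemble the real GATA3 nucleotide sequence.
"""

from __future__ import annotations

from .consequence import TranscriptModel
from .io import MutationRecord, VariantClass

__all__ = [
    "synthetic_gata3_transcript",
    "extension_panel",
    "GATA3_GENOMIC_START",
]

#: Arbitrary genomic anchor used to map coding positions onto "genomic"
#: coordinates in simulations (GATA3 lies near 8.1 Mb on chromosome 10).
GATA3_GENOMIC_START = 8_096_667

_FILLER = ["GCC", "AAC", "GAC", "TCC", "ATC", "CTC", "GTC", "CAC"]

_SPECIAL = {
    1: "ATG",   # start
    336: "GGT", # Gly336; with codon 337 forms a +1-frame TAA at coding pos 1008
    337: "AAA",
    354: "CTA", # with codon 355 forms a -1-frame TAA (early -1 stop)
    355: "AAC",
    395: "GCC", # Ala395: a base inserted after its 2nd position is synonymous
    396: "AAC",
    409: "CCC", # Pro409 extension hotspot
    418: "CTA", # with codon 419 forms a -1-frame TAA in the hotspot region
    419: "AAC",
    444: "GGC", # Gly444, last wild-type residue
}

_UTR5 = "GCCGCCACC"  # 9 nt, no upstream ATG
_UTR3_LEN = 200
# coding-relative positions of the stop codons planted in the 3'UTR:
# +1-frame lattice stop at 1521 (=> 507-residue extended ORF, 444 + 63),
# -1-frame lattice stop at 1526.
_UTR3_PLUS1_STOP = 1521
_UTR3_MINUS1_STOP = 1526


def synthetic_gata3_transcript() -> TranscriptModel:
    """Build the synthetic GATA3-like transcript model (see module docstring)."""
    codons = []
    for i in range(1, 445):
        codons.append(_SPECIAL.get(i, _FILLER[i % len(_FILLER)]))
    cds = "".join(codons) + "TAA"
    assert len(cds) == 444 * 3 + 3

    utr3 = ["C"] * _UTR3_LEN
    cds_len = len(cds)
    for stop_pos in (_UTR3_PLUS1_STOP, _UTR3_MINUS1_STOP):
        off = stop_pos - cds_len - 1  # 0-based index into the UTR
        utr3[off : off + 3] = list("TAA")
    cdna = _UTR5 + cds + "".join(utr3)

    return TranscriptModel(
        gene="GATA3",
        transcript_id="GATA3-synthetic-444aa",
        cdna=cdna,
        cds_start=len(_UTR5) + 1,
        cds_end=len(_UTR5) + len(cds),
        exon_ends=(140, 410, 745, 985, 1110, len(cdna)),
    )


def extension_panel() -> list[MutationRecord]:
    """+1-frame insG variants anchoring extensions at residues 395..444.

    One insertion per anchor codon, placed at the codon boundary before
    it; the earliest (alanine-395) anchor instead uses the in-codon
    wobble site after coding position 1184, which preserves Ala395 — the
    configuration under which the extension spectrum alters at most 49
    of the original C-terminal residues while appending 63 novel ones.
    """
    records = [
        MutationRecord(
            sample_id="panel-395",
            gene="GATA3",
            genomic_position=GATA3_GENOMIC_START + 1184,
            variant_class=VariantClass.frameshift_ins,
            ref_allele="-",
            alt_allele="G",
            cdna_position=1184,
        )
    ]
    for anchor in range(396, 445):
        pos = 3 * (anchor - 1)  # boundary after the previous codon
        records.append(
            MutationRecord(
                sample_id=f"panel-{anchor}",
                gene="GATA3",
                genomic_position=GATA3_GENOMIC_START + pos,
                variant_class=VariantClass.frameshift_ins,
                ref_allele="-",
                alt_allele="G",
                cdna_position=pos,
            )
        )
    return records
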