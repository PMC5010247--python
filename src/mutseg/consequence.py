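"""Protein-level consequence prediction for coding variants.

A variant is applied to the spliced transcript, the mutant message is
re-translated from the start codon through the 3'UTR, and the mutant
open reading frame is compared with the wild type.  Frameshifts are
labelled by net frame (+1 for a net insertion of 1 mod 3, -1 for 2 mod 3)
and classified by mutant ORF length L against wild-type protein length W:
L < W is a truncation, L > W a C-terminal extension (the novel tail has
L - W residues), L = W a same-length frameshift.  If translation runs off
the end of the provided cDNA without a stop codon the call is ``no_stop``
rather than a guess — extensions are only computable when the 3'UTR is
part of the transcript model.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .io import MutationRecord, VariantClass

__all__ = [
    "TranscriptModel",
    "ProteinConsequence",
    "ConsequenceClass",
    "Translation",
    "net_frame",
    "apply_variant",
    "translate",
    "classify_consequence",
    "classify_from_annotation",
    "exon_of",
    "tally_classes",
    "consequence_table",
    "read_transcripts",
    "write_transcripts",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_TABLE.forward_table)
_STOP_CODONS = set(_TABLE.stop_codons)
_START_CODONS = {"ATG"}
_VALID_BASES = set("ACGT")


class ConsequenceClass(str, Enum):
    in_frame = "in_frame"
    frameshift_truncation = "frameshift_truncation"
    frameshift_extension = "frameshift_extension"
    frameshift_same_length = "frameshift_same_length"
    nonsense = "nonsense"
    missense = "missense"
    silent = "silent"
    no_stop = "no_stop"
    noncoding = "noncoding"


@dataclass(frozen=True)
class TranscriptModel:
    """Spliced transcript: 5'UTR + CDS + 3'UTR with exon boundaries.

    ``cds_start``/``cds_end`` are 1-based inclusive on the cDNA;
    ``cds_end`` is the last base of the stop codon.  ``exon_ends`` holds
    the cDNA position of each exon's last base (strictly increasing, the
    last equal to the transcript length).
    """

    gene: str
    transcript_id: str
    cdna: str
    cds_start: int
    cds_end: int
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        cdna = self.cdna.upper()
        object.__setattr__(self, "cdna", cdna)
        object.__setattr__(self, "exon_ends", tuple(self.exon_ends))
        bad = set(cdna) - _VALID_BASES
        if bad:
            raise ValueError(f"cdna contains non-ACGT characters: {sorted(bad)}")
        if not (1 <= self.cds_start < self.cds_end <= len(cdna)):
            raise ValueError("CDS bounds out of range")
        if (self.cds_end - self.cds_start + 1) % 3 != 0:
            raise ValueError("CDS length not a multiple of 3")
        if cdna[self.cds_start - 1 : self.cds_start + 2] not in _START_CODONS:
            raise ValueError("CDS does not begin with a start codon")
        if cdna[self.cds_end - 3 : self.cds_end] not in _STOP_CODONS:
            raise ValueError("CDS does not end with a stop codon")
        if list(self.exon_ends) != sorted(set(self.exon_ends)):
            raise ValueError("exon_ends must be strictly increasing")
        if self.exon_ends[-1] != len(cdna):
            raise ValueError("last exon end must equal transcript length")

    @property
    def cds(self) -> str:
        return self.cdna[self.cds_start - 1 : self.cds_end]

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def protein(self) -> str:
        return translate(self.cds).protein

    @property
    def protein_length(self) -> int:
        return self.cds_len // 3 - 1  # minus stop codon


@dataclass(frozen=True)
class ProteinConsequence:
    """Outcome of re-translating a mutant transcript."""

    consequence_class: ConsequenceClass
    frame_shift: int  # 0, +1 or -1
    protein_change: str
    first_altered_residue: int | None = None
    mutant_length: int | None = None
    novel_cterm_length: int | None = None
    altered_original_residues: int | None = None

    def __post_init__(self) -> None:
        if self.frame_shift not in (0, 1, -1):
            raise ValueError("frame_shift must be 0, +1 or -1")


class Translation(NamedTuple):
    protein: str
    hit_stop: bool


def net_frame(inserted_len: int, deleted_len: int) -> int:
    """Net reading-frame shift of an indel: 0, +1 (net 1 mod 3) or -1 (net 2)."""
    if inserted_len < 0 or deleted_len < 0:
        raise ValueError("lengths must be non-negative")
    net = (inserted_len - deleted_len) % 3
    return {0: 0, 1: 1, 2: -1}[net]


def _allele_len(allele: str) -> int:
    return 0 if allele == "-" else len(allele)


def apply_variant(t: TranscriptModel, cdna_pos: int, ref: str, alt: str) -> str:
    """Apply a substitution/insertion/deletion to the cDNA.

    ``cdna_pos`` is 1-based on the cDNA string.  Pure insertions
    (``ref == "-"``) insert ``alt`` *after* ``cdna_pos``; deletions remove
    ``len(ref)`` bases starting at ``cdna_pos``.  The reference allele is
    checked against the transcript.
    """
    seq = t.cdna
    if not (1 <= cdna_pos <= len(seq)):
        raise ValueError(f"cdna_pos {cdna_pos} outside transcript (length {len(seq)})")
    if ref == "-":  # pure insertion after cdna_pos
        return seq[:cdna_pos] + alt.upper() + seq[cdna_pos:]
    ref = ref.upper()
    found = seq[cdna_pos - 1 : cdna_pos - 1 + len(ref)]
    if found != ref:
        raise ValueError(
            f"reference mismatch at cDNA position {cdna_pos}: expected {ref!r}, "
            f"found {found!r}"
        )
    alt_seq = "" if alt == "-" else alt.upper()
    return seq[: cdna_pos - 1] + alt_seq + seq[cdna_pos - 1 + len(ref):]


def translate(seq: str) -> Translation:
    """Translate from position 1 to the first stop codon (stop excluded).

    Returns the amino-acid string and whether a stop codon was reached;
    without a stop the full translation of complete codons is returned
    with ``hit_stop=False``.  Non-ACGT characters raise with their offset.
    """
    seq = seq.upper()
    for off, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise ValueError(f"non-ACGT character {base!r} at offset {off}")
    aas: list[str] = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in _STOP_CODONS:
            return Translation("".join(aas), True)
        aas.append(_CODON_MAP[codon])
    return Translation("".join(aas), False)


def _first_difference(a: str, b: str) -> int | None:
    """1-based index of first differing residue; None if identical."""
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i + 1
    if len(a) != len(b):
        return min(len(a), len(b)) + 1
    return None


def _fs_anchor_residue(cdna_pos: int, ins_len: int, del_len: int) -> int:
    """First CDS codon touched by a shifted reading frame (HGVS-like).

    For a pure insertion after coding position p the first shifted base is
    p+1, so the anchor codon is p//3 + 1; for deletions/delins starting at
    p it is the codon containing p.  ``cdna_pos`` is CDS-relative here.
    """
    if del_len == 0:  # pure insertion after cdna_pos
        return cdna_pos // 3 + 1
    return (cdna_pos - 1) // 3 + 1


def classify_consequence(t: TranscriptModel, m: MutationRecord) -> ProteinConsequence:
    """Re-translate a mutant transcript and classify the protein outcome.

    ``m.cdna_position`` follows the coding convention (+1 = A of the start
    codon).  Positions outside the CDS (or absent) yield ``noncoding``.
    """
    if m.cdna_position is None:
        return ProteinConsequence(ConsequenceClass.noncoding, 0, "p.?")
    cds_pos = m.cdna_position
    n_coding = t.cds_len - 3  # coding positions excluding the stop codon
    if not (1 <= cds_pos <= n_coding):
        return ProteinConsequence(ConsequenceClass.noncoding, 0, "p.?")

    ins_len = _allele_len(m.alt_allele)
    del_len = _allele_len(m.ref_allele)
    frame = net_frame(ins_len, del_len)
    tpos = t.cds_start + cds_pos - 1  # transcript coordinate
    mutant_cdna = apply_variant(t, tpos, m.ref_allele, m.alt_allele)

    wild = t.protein
    W = len(wild)
    # translate mutant from the start codon through the 3'UTR
    mutant_tx = translate(mutant_cdna[t.cds_start - 1 :])
    mut = mutant_tx.protein
    L = len(mut)
    first_altered = _first_difference(wild, mut)

    if frame == 0 and ins_len == del_len and del_len >= 1:
        # substitution (possibly multi-base, in place)
        aa_pos = (cds_pos - 1) // 3 + 1
        if mut == wild:
            return ProteinConsequence(
                ConsequenceClass.silent, 0, f"p.{wild[aa_pos - 1]}{aa_pos}=",
                mutant_length=L,
            )
        if mutant_tx.hit_stop and L < W:
            return ProteinConsequence(
                ConsequenceClass.nonsense, 0,
                f"p.{wild[first_altered - 1]}{first_altered}*",
                first_altered_residue=first_altered, mutant_length=L,
            )
        if not mutant_tx.hit_stop:
            return ProteinConsequence(
                ConsequenceClass.no_stop, 0, f"p.{wild[aa_pos - 1]}{aa_pos}ext?",
                first_altered_residue=first_altered, mutant_length=L,
            )
        return ProteinConsequence(
            ConsequenceClass.missense, 0,
            f"p.{wild[first_altered - 1]}{first_altered}{mut[first_altered - 1]}",
            first_altered_residue=first_altered, mutant_length=L,
        )

    if frame == 0:
        # in-frame indel
        anchor = _fs_anchor_residue(cds_pos, ins_len, del_len)
        anchor = min(anchor, W)
        return ProteinConsequence(
            ConsequenceClass.in_frame, 0,
            f"p.{wild[anchor - 1]}{anchor}delins",
            first_altered_residue=first_altered, mutant_length=L,
        )

    # frameshift
    anchor = min(_fs_anchor_residue(cds_pos, ins_len, del_len), W)
    change = f"p.{wild[anchor - 1]}{anchor}fs"
    if not mutant_tx.hit_stop:
        return ProteinConsequence(
            ConsequenceClass.no_stop, frame, change,
            first_altered_residue=first_altered, mutant_length=L,
        )
    if L < W:
        cls = ConsequenceClass.frameshift_truncation
        novel = None
        altered = None
    elif L > W:
        cls = ConsequenceClass.frameshift_extension
        novel = L - W
        altered = W - first_altered + 1 if first_altered is not None else 0
    else:
        cls = ConsequenceClass.frameshift_same_length
        novel = None
        altered = None
    return ProteinConsequence(
        cls, frame, change,
        first_altered_residue=first_altered,
        mutant_length=L,
        novel_cterm_length=novel,
        altered_original_residues=altered,
    )


_FS_RE = re.compile(r"p\.[A-Z*]([0-9]+)")


def classify_from_annotation(
    m: MutationRecord,
    protein_length: int,
    extension_start_residue: int = 395,
) -> ProteinConsequence:
    """Annotation-trusting alternative to re-translation.

    Uses the allele lengths for the net frame and the ``p.X###fs``
    annotation for the start residue; +1-frame shifts starting at or
    after ``extension_start_residue`` are labelled extensions, other
    frameshifts truncations.  Lengths are not computable in this mode.
    """
    ins_len = _allele_len(m.alt_allele)
    del_len = _allele_len(m.ref_allele)
    if m.variant_class in (VariantClass.frameshift_ins, VariantClass.frameshift_del):
        frame = net_frame(ins_len, del_len)
        match = _FS_RE.match(m.protein_change or "")
        if not match:
            return ProteinConsequence(ConsequenceClass.no_stop, frame, "p.?")
        residue = int(match.group(1))
        if frame == 1 and residue >= extension_start_residue:
            cls = ConsequenceClass.frameshift_extension
        else:
            cls = ConsequenceClass.frameshift_truncation
        return ProteinConsequence(
            cls, frame, m.protein_change or "p.?", first_altered_residue=residue
        )
    mapping = {
        VariantClass.missense: ConsequenceClass.missense,
        VariantClass.nonsense: ConsequenceClass.nonsense,
        VariantClass.silent: ConsequenceClass.silent,
        VariantClass.inframe_indel: ConsequenceClass.in_frame,
    }
    cls = mapping.get(m.variant_class, ConsequenceClass.noncoding)
    return ProteinConsequence(cls, 0, m.protein_change or "p.?")


def exon_of(t: TranscriptModel, cdna_pos: int) -> int:
    """1-based exon index containing a transcript coordinate (ends inclusive)."""
    if not (1 <= cdna_pos <= len(t.cdna)):
        raise ValueError(f"cdna_pos {cdna_pos} outside transcript")
    return bisect.bisect_left(t.exon_ends, cdna_pos) + 1


def tally_classes(
    records: Sequence[MutationRecord], t: TranscriptModel
) -> pd.DataFrame:
    """Count mutations by (consequence class, frame, exon).

    Records must belong to one gene; each contributes exactly one row of
    the tally.  The exon is that of the cDNA position (0 if unknown).
    """
    rows = []
    for m in records:
        pc = classify_consequence(t, m)
        if m.cdna_position is not None and 1 <= t.cds_start + m.cdna_position - 1 <= len(t.cdna):
            exon = exon_of(t, t.cds_start + m.cdna_position - 1)
        else:
            exon = 0
        rows.append(
            {
                "consequence_class": pc.consequence_class.value,
                "frame_shift": pc.frame_shift,
                "exon": exon,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["consequence_class", "frame_shift", "exon", "count"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["consequence_class", "frame_shift", "exon"])
        .size()
        .reset_index(name="count")
    )
    return out


def extension_share_of_frameshifts(tally: pd.DataFrame) -> float:
    """Fraction of frameshift consequences that are extensions."""
    fs = tally[
        tally["consequence_class"].isin(
            [
                ConsequenceClass.frameshift_truncation.value,
                ConsequenceClass.frameshift_extension.value,
                ConsequenceClass.frameshift_same_length.value,
            ]
        )
    ]
    total = fs["count"].sum()
    if total == 0:
        return float("nan")
    ext = fs.loc[
        fs["consequence_class"] == ConsequenceClass.frameshift_extension.value,
        "count",
    ].sum()
    return float(ext) / float(total)


def exon_share_of_extensions(tally: pd.DataFrame, exon: int) -> float:
    """Fraction of extension consequences falling in the given exon."""
    ext = tally[
        tally["consequence_class"] == ConsequenceClass.frameshift_extension.value
    ]
    total = ext["count"].sum()
    if total == 0:
        return float("nan")
    return float(ext.loc[ext["exon"] == exon, "count"].sum()) / float(total)


def consequence_table(
    records: Sequence[MutationRecord], t: TranscriptModel
) -> pd.DataFrame:
    """One row per mutation with its predicted consequence (TSV-ready)."""
    rows = []
    for m in records:
        pc = classify_consequence(t, m)
        rows.append(
            {
                "sample_id": m.sample_id,
                "gene": m.gene,
                "cdna_position": m.cdna_position,
                "ref_allele": m.ref_allele,
                "alt_allele": m.alt_allele,
                "consequence_class": pc.consequence_class.value,
                "frame_shift": pc.frame_shift,
                "protein_change": pc.protein_change,
                "first_altered_residue": pc.first_altered_residue,
                "mutant_length": pc.mutant_length,
                "novel_cterm_length": pc.novel_cterm_length,
                "altered_original_residues": pc.altered_original_residues,
            }
        )
    return pd.DataFrame(rows)


def read_transcripts(
    fasta_path: str | Path, sidecar_path: str | Path
) -> dict[str, TranscriptModel]:
    """Load transcripts from FASTA plus a TSV sidecar.

    Sidecar columns: transcript_id, gene, cds_start, cds_end and
    comma-separated exon_ends.
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    side = pd.read_csv(sidecar_path, sep="\t", dtype=str)
    out: dict[str, TranscriptModel] = {}
    for row in side.itertuples(index=False):
        tid = str(row.transcript_id)
        if tid not in seqs:
            raise ValueError(f"transcript {tid} in sidecar but not in FASTA")
        out[tid] = TranscriptModel(
            gene=str(row.gene),
            transcript_id=tid,
            cdna=seqs[tid],
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            exon_ends=tuple(int(x) for x in str(row.exon_ends).split(",")),
        )
    return out


def write_transcripts(
    transcripts: Sequence[TranscriptModel],
    fasta_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    records = [
        SeqRecord(Seq(t.cdna), id=t.transcript_id, description=t.gene)
        for t in transcripts
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "gene": [t.gene for t in transcripts],
            "cds_start": [t.cds_start for t in transcripts],
            "cds_end": [t.cds_end for t in transcripts],
            "exon_ends": [",".join(map(str, t.exon_ends)) for t in transcripts],
        }
    ).to_csv(sidecar_path, sep="\t", index=False)
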