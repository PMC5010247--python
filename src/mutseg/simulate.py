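"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:
one driver-gene mutation per patient drawn from a hotspot mixture (with
frame labels realised as actual 1-bp insertions, 1-bp deletions or
substitutions on the bundled synthetic driver transcript), expression in
which *response genes* carry a step shift at a planted ordinal breakpoint
along the mutation-position ranking while *null genes* are pure noise,
and exponential disease-free-survival times with an elevated hazard for
the +1-frame extension group.  All ground truth (per-sample positions,
frames, consequence classes; per-gene response flags, boundaries and
directions; survival group labels) is retained and serialised.

Expression is Gaussian around a positive baseline on the raw scale —
deliberately not a realistic RNA-seq count model, because the pipeline
consumes ranks only; effects are injected before the rank transform so
the midrank machinery is genuinely exercised.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .consequence import (
    ConsequenceClass,
    TranscriptModel,
    apply_variant,
    translate,
)
from .io import (
    ClinicalRecord,
    Cohort,
    ExpressionMatrix,
    MutationRecord,
    VariantClass,
    write_clinical,
    write_mutations,
)
from .transcripts import GATA3_GENOMIC_START, synthetic_gata3_transcript

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "make_toy_transcript",
    "naive_consequence",
    "write_cohort",
]


@dataclass
class SimulationConfig:
    """Study conditions for a simulated cohort.

    Positions are coding (cDNA) positions on the driver transcript;
    genomic coordinates are a fixed linear offset of these.  The true
    breakpoint is ordinal: the expression shift applies to samples whose
    mutation-position rank exceeds the boundary.  ``effect_size`` is the
    mean shift in units of ``noise_sd``.
    """

    n_patients: int = 60
    hotspots: tuple[tuple[int, float], ...] = ((1224, 0.45), (1006, 0.2))
    hotspot_sd: float = 15.0
    uniform_weight: float = 0.35
    frame_probs: tuple[float, float, float] = (0.6, 0.15, 0.25)  # +1, -1, 0
    true_breakpoint: tuple[int, ...] = (30,)
    n_response_genes: int = 5
    n_null_genes: int = 95
    n_group_genes: int = 0  # genes shifted in the ext_plus1 group specifically
    group_effect_size: float = 2.0
    effect_size: float = 2.0
    noise_sd: float = 1.0
    base_expression: float = 8.0
    baseline_hazard: float = 0.02  # events per month
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.4
    seed: int = 0
    driver: str = "GATA3"
    n_multi_mutant: int = 0  # contaminant samples with 2 driver mutations

    def __post_init__(self) -> None:
        total = self.uniform_weight + sum(w for _, w in self.hotspots)
        if not np.isclose(total, 1.0):
            raise ValueError("hotspot weights plus uniform_weight must sum to 1")
        if not np.isclose(sum(self.frame_probs), 1.0):
            raise ValueError("frame_probs must sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for b in self.true_breakpoint:
            if not (1 <= b < self.n_patients):
                raise ValueError(
                    f"true breakpoint {b} outside 1..{self.n_patients - 1}"
                )


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    sample_ids: list[str]
    cdna_positions: dict[str, int]
    genomic_positions: dict[str, int]
    frames: dict[str, int]
    consequence_classes: dict[str, str]
    group_labels: dict[str, str]  # ext_plus1 / ... / other_mutant
    response_genes: list[str]
    null_genes: list[str]
    group_genes: list[str]  # genes shifted in ext_plus1 samples
    gene_directions: dict[str, int]  # +1 up after boundary / in cases, -1 down
    boundary_ordinals: list[int]
    boundary_coords: list[float]  # genomic image of each ordinal boundary
    ordered_samples: list[str]  # mutation-position order (ties by id)
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def naive_consequence(t: TranscriptModel, cds_pos: int, ref: str, alt: str) -> tuple[str, int]:
    """Brute-force consequence: mutate the whole mRNA, translate, diff.

    Independent reference path used for ground-truth labels: returns
    (consequence class name, net frame).  Codon table is looked up base
    by base via :func:`translate`, but classification here is a direct
    re-derivation from the two protein strings.
    """
    ins_len = 0 if alt == "-" else len(alt)
    del_len = 0 if ref == "-" else len(ref)
    net = (ins_len - del_len) % 3
    frame = {0: 0, 1: 1, 2: -1}[net]
    tpos = t.cds_start + cds_pos - 1
    mutant = apply_variant(t, tpos, ref, alt)
    wild_p = translate(t.cdna[t.cds_start - 1 :]).protein
    mut_tx = translate(mutant[t.cds_start - 1 :])
    mut_p = mut_tx.protein
    if frame == 0:
        if del_len == ins_len and del_len >= 1:
            if mut_p == wild_p:
                return ConsequenceClass.silent.value, 0
            if mut_tx.hit_stop and len(mut_p) < len(wild_p):
                return ConsequenceClass.nonsense.value, 0
            if not mut_tx.hit_stop:
                return ConsequenceClass.no_stop.value, 0
            return ConsequenceClass.missense.value, 0
        return ConsequenceClass.in_frame.value, 0
    if not mut_tx.hit_stop:
        return ConsequenceClass.no_stop.value, frame
    if len(mut_p) < len(wild_p):
        return ConsequenceClass.frameshift_truncation.value, frame
    if len(mut_p) > len(wild_p):
        return ConsequenceClass.frameshift_extension.value, frame
    return ConsequenceClass.frameshift_same_length.value, frame


def _draw_position(rng: np.random.Generator, config: SimulationConfig, lo: int, hi: int) -> int:
    weights = [w for _, w in config.hotspots] + [config.uniform_weight]
    choice = rng.choice(len(weights), p=np.array(weights) / sum(weights))
    if choice < len(config.hotspots):
        center = config.hotspots[choice][0]
        pos = int(round(rng.normal(center, config.hotspot_sd)))
    else:
        pos = int(rng.integers(lo, hi + 1))
    return int(np.clip(pos, lo, hi))


def _make_variant(
    rng: np.random.Generator, t: TranscriptModel, cds_pos: int, frame: int
) -> tuple[str, str, VariantClass]:
    """Realise a frame label as concrete alleles at a coding position."""
    tpos = t.cds_start + cds_pos - 1
    ref_base = t.cdna[tpos - 1]
    if frame == 1:
        return "-", "G", VariantClass.frameshift_ins
    if frame == -1:
        return ref_base, "-", VariantClass.frameshift_del
    alt = rng.choice([b for b in "ACGT" if b != ref_base])
    return ref_base, str(alt), VariantClass.missense


def simulate_cohort(
    config: SimulationConfig,
    transcript: TranscriptModel | None = None,
) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and its ground truth; reproducible from the seed."""
    t = transcript if transcript is not None else synthetic_gata3_transcript()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    coding_lo, coding_hi = 4, t.cds_len - 6  # keep start/stop codons intact

    sample_ids = [f"SIM-{i:04d}" for i in range(1, n + 1)]
    frames_draw = rng.choice([1, -1, 0], size=n, p=config.frame_probs)
    mutations: list[MutationRecord] = []
    cdna_positions: dict[str, int] = {}
    genomic_positions: dict[str, int] = {}
    frames: dict[str, int] = {}
    classes: dict[str, str] = {}
    group_labels: dict[str, str] = {}

    for sid, frame in zip(sample_ids, frames_draw):
        cds_pos = _draw_position(rng, config, coding_lo, coding_hi)
        ref, alt, vclass = _make_variant(rng, t, cds_pos, int(frame))
        cls, net = naive_consequence(t, cds_pos, ref, alt)
        gpos = GATA3_GENOMIC_START + cds_pos
        mutations.append(
            MutationRecord(
                sample_id=sid,
                gene=config.driver,
                genomic_position=gpos,
                variant_class=vclass,
                ref_allele=ref,
                alt_allele=alt,
                cdna_position=cds_pos,
            )
        )
        cdna_positions[sid] = cds_pos
        genomic_positions[sid] = gpos
        frames[sid] = net
        classes[sid] = cls
        if cls == ConsequenceClass.frameshift_extension.value and net == 1:
            group_labels[sid] = "ext_plus1"
        elif cls == ConsequenceClass.frameshift_extension.value:
            group_labels[sid] = "ext_minus1"
        elif cls == ConsequenceClass.frameshift_truncation.value and net == 1:
            group_labels[sid] = "trunc_plus1"
        elif cls == ConsequenceClass.frameshift_truncation.value:
            group_labels[sid] = "trunc_minus1"
        else:
            group_labels[sid] = "other_mutant"

    # contaminant multi-mutant samples (excluded by the pipeline's filter)
    for i in range(config.n_multi_mutant):
        sid = f"SIM-M{i:03d}"
        for _ in range(2):
            cds_pos = _draw_position(rng, config, coding_lo, coding_hi)
            ref, alt, vclass = _make_variant(rng, t, cds_pos, 0)
            mutations.append(
                MutationRecord(
                    sample_id=sid,
                    gene=config.driver,
                    genomic_position=GATA3_GENOMIC_START + cds_pos,
                    variant_class=vclass,
                    ref_allele=ref,
                    alt_allele=alt,
                    cdna_position=cds_pos,
                )
            )

    # ordinal ordering: mutation position, ties by sample id (as the pipeline)
    ordered = sorted(sample_ids, key=lambda s: (genomic_positions[s], s))
    rank_of = {s: i + 1 for i, s in enumerate(ordered)}

    response_genes = [f"RESP{i:03d}" for i in range(1, config.n_response_genes + 1)]
    null_genes = [f"NULL{i:03d}" for i in range(1, config.n_null_genes + 1)]
    directions: dict[str, int] = {}
    all_samples = sample_ids + [f"SIM-M{i:03d}" for i in range(config.n_multi_mutant)]
    expr = {}
    shift = config.effect_size * config.noise_sd
    for g in response_genes:
        direction = int(rng.choice([1, -1]))
        directions[g] = direction
        vals = config.base_expression + rng.normal(0, config.noise_sd, len(all_samples))
        for idx, sid in enumerate(all_samples):
            r = rank_of.get(sid)
            if r is None:
                continue
            n_above = sum(1 for b in config.true_breakpoint if r > b)
            vals[idx] += direction * shift * n_above
        expr[g] = np.clip(vals, 0.0, None)
    for g in null_genes:
        expr[g] = np.clip(
            config.base_expression + rng.normal(0, config.noise_sd, len(all_samples)),
            0.0,
            None,
        )
    group_genes = [f"GRP{i:03d}" for i in range(1, config.n_group_genes + 1)]
    g_shift = config.group_effect_size * config.noise_sd
    for g in group_genes:
        direction = int(rng.choice([1, -1]))
        directions[g] = direction
        vals = config.base_expression + rng.normal(0, config.noise_sd, len(all_samples))
        for idx, sid in enumerate(all_samples):
            if group_labels.get(sid) == "ext_plus1":
                vals[idx] += direction * g_shift
        expr[g] = np.clip(vals, 0.0, None)
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=all_samples).T[all_samples]
    )

    # survival: exponential with group hazard ratio, independent censoring
    clinical: list[ClinicalRecord] = []
    cens_hazard = (
        config.baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
        if 0 < config.censoring_rate < 1
        else 0.0
    )
    for sid in sample_ids:
        hr = config.hazard_ratio if group_labels[sid] == "ext_plus1" else 1.0
        event_time = rng.exponential(1.0 / (config.baseline_hazard * hr))
        if cens_hazard > 0:
            censor_time = rng.exponential(1.0 / cens_hazard)
        else:
            censor_time = np.inf
        time = min(event_time, censor_time)
        clinical.append(ClinicalRecord(sid, float(time), bool(event_time <= censor_time)))

    boundary_coords = []
    for b in config.true_breakpoint:
        a = genomic_positions[ordered[b - 1]]
        c = genomic_positions[ordered[b]] if b < n else a
        boundary_coords.append((a + c) / 2.0)

    truth = GroundTruth(
        sample_ids=sample_ids,
        cdna_positions=cdna_positions,
        genomic_positions=genomic_positions,
        frames=frames,
        consequence_classes=classes,
        group_labels=group_labels,
        response_genes=response_genes,
        null_genes=null_genes,
        group_genes=group_genes,
        gene_directions=directions,
        boundary_ordinals=list(config.true_breakpoint),
        boundary_coords=boundary_coords,
        ordered_samples=ordered,
        seed=config.seed,
    )
    cohort = Cohort(mutations=mutations, expression=expression, clinical=clinical)
    return cohort, truth


def write_cohort(cohort: Cohort, truth: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Serialise a simulated cohort: MAF-dialect mutations, expression,
    clinical TSVs and the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": out / "mutations.maf.tsv",
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
    }
    write_mutations(cohort.mutations, paths["mutations"], dialect="maf")
    cohort.expression.to_tsv(paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    truth.to_json(paths["truth"])
    return paths


def make_toy_transcript(
    rng: np.random.Generator, n_codons: int = 40, utr3_len: int = 60
) -> tuple[TranscriptModel, list[tuple[int, str, str, str]]]:
    """Random toy transcript plus planted indels with oracle consequences.

    Returns the transcript and a list of (cds_pos, ref, alt,
    oracle_class) tuples: one in-frame 3-bp insertion, several 1-bp
    insertions and deletions.  The 3'UTR is random, so shifted frames may
    or may not find a stop — the oracle label records whichever outcome.
    """
    if n_codons < 5 or utr3_len < 3:
        raise ValueError("toy transcript too small")
    sense = [c for c in _all_codons() if c not in ("TAA", "TAG", "TGA", "ATG")]
    body = [sense[rng.integers(len(sense))] for _ in range(n_codons - 1)]
    cds = "ATG" + "".join(body) + "TAA"
    utr5 = "".join(rng.choice(list("ACGT"), size=6))
    utr3 = "".join(rng.choice(list("ACGT"), size=utr3_len))
    cdna = utr5 + cds + utr3
    t = TranscriptModel(
        gene="TOY",
        transcript_id=f"TOY-{n_codons}",
        cdna=cdna,
        cds_start=len(utr5) + 1,
        cds_end=len(utr5) + len(cds),
        exon_ends=(len(utr5) + len(cds) // 2, len(cdna)),
    )
    variants = []
    coding_hi = t.cds_len - 6
    for _ in range(6):
        pos = int(rng.integers(4, coding_hi + 1))
        base = str(rng.choice(list("ACGT")))
        cls, _ = naive_consequence(t, pos, "-", base)
        variants.append((pos, "-", base, cls))
    for _ in range(4):
        pos = int(rng.integers(4, coding_hi + 1))
        ref = t.cdna[t.cds_start + pos - 2]
        cls, _ = naive_consequence(t, pos, ref, "-")
        variants.append((pos, ref, "-", cls))
    pos = int(rng.integers(4, coding_hi + 1))
    cls, _ = naive_consequence(t, pos, "-", "GAT")
    variants.append((pos, "-", "GAT", cls))
    return t, variants


def _all_codons() -> list[str]:
    return [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
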