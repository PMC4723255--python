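"""Gene-model-based variant annotation and marker summaries.

Variants are located relative to transcript models parsed from GFF3 with a
fixed category precedence (CDS > UTR exon > intron > TSS window > TTS
window > intergenic) so that every variant gets exactly one region label.
SNPs inside CDS additionally get a coding effect from codon translation.
The module also summarizes region/effect distributions, InDel length
classes, and selects markers flanking a target locus for marker-assisted
selection using a physical-to-genetic distance approximation.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import gffutils
from Bio.Seq import Seq

from radmarker.somatic import MarkerRecord
from radmarker.variant_call import VariantCall, VariantType

logger = logging.getLogger(__name__)


class Region(enum.Enum):
    CDS = "CDS"
    EXON_UTR5 = "EXON_UTR5"
    EXON_UTR3 = "EXON_UTR3"
    INTRON = "INTRON"
    TSS_REGION = "TSS_REGION"
    TTS_REGION = "TTS_REGION"
    INTERGENIC = "INTERGENIC"


#: lower value = higher precedence when a variant overlaps several categories
_REGION_PRECEDENCE = {
    Region.CDS: 0,
    Region.EXON_UTR5: 1,
    Region.EXON_UTR3: 1,
    Region.INTRON: 2,
    Region.TSS_REGION: 3,
    Region.TTS_REGION: 4,
    Region.INTERGENIC: 5,
}


class Effect(enum.Enum):
    SYNONYMOUS = "SYNONYMOUS"
    NONSYNONYMOUS = "NONSYNONYMOUS"
    STOP_GAIN = "STOP_GAIN"
    STOP_LOSS = "STOP_LOSS"
    NONCODING = "NONCODING"
    NA = "NA"


#: lower value = more severe; used to pick the reported effect across transcripts
_EFFECT_SEVERITY = {
    Effect.STOP_GAIN: 0,
    Effect.STOP_LOSS: 1,
    Effect.NONSYNONYMOUS: 2,
    Effect.SYNONYMOUS: 3,
    Effect.NONCODING: 4,
    Effect.NA: 5,
}


@dataclass(frozen=True)
class AnnotationParams:
    tss_upstream: int = 1000
    tss_downstream: int = 1000
    tts_upstream: int = 500
    tts_downstream: int = 500

    def __post_init__(self) -> None:
        if min(self.tss_upstream, self.tss_downstream, self.tts_upstream, self.tts_downstream) < 0:
            raise ValueError("window extents must be >= 0")


@dataclass
class GeneModel:
    """One transcript: strand-aware structure in 1-based inclusive coords."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivals = sorted(getattr(self, name))
            for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(f"{self.transcript_id}: overlapping {name} intervals")
            setattr(self, name, ivals)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
        return any(s <= pos <= e for s, e in intervals)

    def cds_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position within the spliced CDS."""
        if not self.contains(pos, self.cds):
            return None
        offset = 0
        if self.strand == "+":
            for s, e in self.cds:
                if pos > e:
                    offset += e - s + 1
                else:
                    return offset + pos - s
        else:
            for s, e in reversed(self.cds):
                if pos < s:
                    offset += e - s + 1
                else:
                    return offset + e - pos
        return None  # unreachable

    def spliced_cds_sequence(self, chrom_seq: str) -> str:
        """CDS sequence in translation order (reverse-complemented for '-')."""
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts).upper()
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


class GFF3ParseError(ValueError):
    pass


_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr", "3UTR"}
_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def parse_gff3(path: Union[str, Path]) -> list[GeneModel]:
    """One :class:`GeneModel` per mRNA/transcript feature, deterministic order."""
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GFF3ParseError(f"{path}: {exc}") from exc
    models = []
    for ftype in sorted(_TRANSCRIPT_TYPES):
        for mrna in db.features_of_type(ftype):
            if mrna.end < mrna.start:
                raise GFF3ParseError(f"{mrna.id}: end < start")
            parents = mrna.attributes.get("Parent", [mrna.id])
            model = GeneModel(
                transcript_id=mrna.id,
                gene_id=parents[0],
                chrom=mrna.seqid,
                strand=mrna.strand,
                start=mrna.start,
                end=mrna.end,
            )
            for child in db.children(mrna):
                ival = (child.start, child.end)
                if child.end < child.start:
                    raise GFF3ParseError(f"{mrna.id} child {child.id}: end < start")
                if child.featuretype == "exon":
                    model.exons.append(ival)
                elif child.featuretype == "CDS":
                    model.cds.append(ival)
                elif child.featuretype in _UTR5_TYPES:
                    model.utr5.append(ival)
                elif child.featuretype in _UTR3_TYPES:
                    model.utr3.append(ival)
            models.append(GeneModel(**vars(model)))  # re-validate sorted intervals
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: Union[VariantCall, MarkerRecord]
    region: Region
    gene_id: str | None
    effect: Effect

    @property
    def call(self) -> VariantCall:
        if isinstance(self.variant, MarkerRecord):
            return self.variant.call
        return self.variant


def _region_for_model(
    pos: int, model: GeneModel, params: AnnotationParams
) -> Region | None:
    """Highest-precedence category this single model assigns, or None."""
    if model.start <= pos <= model.end:
        if model.contains(pos, model.cds):
            return Region.CDS
        if model.contains(pos, model.utr5):
            return Region.EXON_UTR5
        if model.contains(pos, model.utr3):
            return Region.EXON_UTR3
        if model.contains(pos, model.exons):
            # exon base not covered by CDS/UTR records: side with the UTRs
            return Region.EXON_UTR5 if _is_five_prime_side(pos, model) else Region.EXON_UTR3
        return Region.INTRON
    sign = 1 if model.strand == "+" else -1
    tss_lo = model.tss - sign * params.tss_upstream
    tss_hi = model.tss + sign * params.tss_downstream
    if min(tss_lo, tss_hi) <= pos <= max(tss_lo, tss_hi):
        return Region.TSS_REGION
    tts_lo = model.tts - sign * params.tts_upstream
    tts_hi = model.tts + sign * params.tts_downstream
    if min(tts_lo, tts_hi) <= pos <= max(tts_lo, tts_hi):
        return Region.TTS_REGION
    return None


def _is_five_prime_side(pos: int, model: GeneModel) -> bool:
    if not model.cds:
        return True
    cds_start = model.cds[0][0] if model.strand == "+" else model.cds[-1][1]
    return pos < cds_start if model.strand == "+" else pos > cds_start


def locate_variant(
    variant: Union[VariantCall, MarkerRecord],
    models: Sequence[GeneModel],
    params: AnnotationParams = AnnotationParams(),
    genome: Mapping[str, str] | None = None,
) -> AnnotatedVariant:
    """Assign the single highest-precedence region category and effect.

    A variant inside one gene's body and another gene's TSS/TTS window takes
    the gene-body category. With a ``genome`` mapping, SNPs landing in CDS
    get a translated coding effect (most severe across transcripts).
    """
    call = variant.call if isinstance(variant, MarkerRecord) else variant
    chrom_models = [m for m in models if m.chrom == call.chrom]
    if not chrom_models and models:
        logger.warning("chromosome %s absent from annotation", call.chrom)
    best: tuple[int, int, Region, GeneModel] | None = None
    for i, model in enumerate(chrom_models):
        region = _region_for_model(call.pos, model, params)
        if region is None:
            continue
        key = (_REGION_PRECEDENCE[region], i)
        if best is None or key < best[:2]:
            best = (*key, region, model)
    if best is None:
        return AnnotatedVariant(variant, Region.INTERGENIC, None, Effect.NONCODING)
    region = best[2]
    if region is not Region.CDS:
        return AnnotatedVariant(variant, region, best[3].gene_id, Effect.NONCODING)
    if call.vtype is not VariantType.SNP or genome is None:
        # translated effects are defined for SNPs only; indels in CDS get NA
        return AnnotatedVariant(variant, region, best[3].gene_id, Effect.NA)
    candidates = [
        (m, coding_effect(call, m, genome))
        for m in chrom_models
        if m.contains(call.pos, m.cds)
    ]
    candidates.sort(key=lambda me: (_EFFECT_SEVERITY[me[1]], me[0].transcript_id))
    model, effect = candidates[0]
    return AnnotatedVariant(variant, region, model.gene_id, effect)


def coding_effect(
    snp: VariantCall, model: GeneModel, genome: Mapping[str, str]
) -> Effect:
    """Translate the reference and alternate codons of a CDS SNP."""
    chrom_seq = genome[snp.chrom]
    ref_genomic = chrom_seq[snp.pos - 1].upper()
    if ref_genomic != snp.ref.upper():
        raise ValueError(
            f"{snp.chrom}:{snp.pos}: reference base {snp.ref} disagrees with "
            f"genome FASTA ({ref_genomic})"
        )
    offset = model.cds_offset(snp.pos)
    if offset is None:
        raise ValueError(f"{snp.chrom}:{snp.pos} not inside CDS of {model.transcript_id}")
    cds_seq = model.spliced_cds_sequence(chrom_seq)
    alt = snp.alt.upper()
    if model.strand == "-":
        alt = str(Seq(alt).complement())
    codon_idx = offset // 3
    within = offset % 3
    codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:
        return Effect.NA  # partial terminal codon
    alt_codon = codon[:within] + alt + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return Effect.SYNONYMOUS
    if aa_alt == "*":
        return Effect.STOP_GAIN
    if aa_ref == "*":
        return Effect.STOP_LOSS
    return Effect.NONSYNONYMOUS


def annotate_variants(
    variants: Iterable[Union[VariantCall, MarkerRecord]],
    models: Sequence[GeneModel],
    params: AnnotationParams = AnnotationParams(),
    genome: Mapping[str, str] | None = None,
) -> list[AnnotatedVariant]:
    return [locate_variant(v, models, params, genome) for v in variants]


def summarize_annotation(annotated: Sequence[AnnotatedVariant]):
    """Counts and fractions per region and per effect as a DataFrame."""
    import pandas as pd

    rows = []
    n = len(annotated)
    if n:
        region_counts: dict[str, int] = {}
        effect_counts: dict[str, int] = {}
        for a in annotated:
            region_counts[a.region.value] = region_counts.get(a.region.value, 0) + 1
            if a.effect is not Effect.NA:
                effect_counts[a.effect.value] = effect_counts.get(a.effect.value, 0) + 1
        for cat, count in sorted(region_counts.items()):
            rows.append(("region", cat, count, count / n))
        n_eff = sum(effect_counts.values())
        for cat, count in sorted(effect_counts.items()):
            rows.append(("effect", cat, count, count / n_eff))
    return pd.DataFrame(rows, columns=["partition", "category", "count", "fraction"])


def indel_length_summary(
    variants: Iterable[Union[VariantCall, MarkerRecord, AnnotatedVariant]],
) -> dict:
    """Insertion/deletion length histograms plus coarse length-class fractions."""
    ins_hist: dict[int, int] = {}
    del_hist: dict[int, int] = {}
    for v in variants:
        call = v.call if isinstance(v, (MarkerRecord, AnnotatedVariant)) else v
        if call.vtype is VariantType.INS:
            length = len(call.alt) - len(call.ref)
            ins_hist[length] = ins_hist.get(length, 0) + 1
        elif call.vtype is VariantType.DEL:
            length = len(call.ref) - len(call.alt)
            del_hist[length] = del_hist.get(length, 0) + 1
    total = sum(ins_hist.values()) + sum(del_hist.values())

    def frac(pred) -> float | None:
        if total == 0:
            return None
        hits = sum(c for l, c in ins_hist.items() if pred(l)) + sum(
            c for l, c in del_hist.items() if pred(l)
        )
        return hits / total

    return {
        "insertions": dict(sorted(ins_hist.items())),
        "deletions": dict(sorted(del_hist.items())),
        "n_indels": total,
        "frac_1bp": frac(lambda l: l == 1),
        "frac_2_5bp": frac(lambda l: 2 <= l <= 5),
        "frac_gt22bp": frac(lambda l: l > 22),
    }


@dataclass(frozen=True)
class LinkedMarker:
    marker: Union[VariantCall, MarkerRecord]
    distance_bp: int
    distance_cm: float  # physical approximation: cm_per_mb * Mb


def select_linked_markers(
    markers: Iterable[Union[VariantCall, MarkerRecord]],
    target_chrom: str,
    target_start: int,
    target_end: int,
    window_bp: int | None = None,
    max_cm: float | None = None,
    cm_per_mb: float = 4.0,
) -> list[LinkedMarker]:
    """Markers flanking a target locus, ranked by distance.

    Distance is measured from the marker position to the nearest edge of the
    target interval (0 inside it). Genetic distance is a physical-window
    proxy (``cm_per_mb`` centimorgan per megabase); select markers within
    ``window_bp`` and/or ``max_cm`` of the target.
    """
    out = []
    for m in markers:
        chrom = m.chrom if isinstance(m, MarkerRecord) else m.chrom
        pos = m.pos
        if chrom != target_chrom:
            continue
        if pos < target_start:
            dist = target_start - pos
        elif pos > target_end:
            dist = pos - target_end
        else:
            dist = 0
        cm = dist / 1e6 * cm_per_mb
        if window_bp is not None and dist > window_bp:
            continue
        if max_cm is not None and cm > max_cm:
            continue
        out.append(LinkedMarker(m, dist, cm))
    out.sort(key=lambda lm: (lm.distance_bp, lm.marker.pos))
    return out


ANNOTATED_COLUMNS = ("chrom", "pos", "ref", "alt", "type", "region", "gene_id", "effect")


def write_annotated(annotated: Iterable[AnnotatedVariant], path: Union[str, Path]) -> int:
    n = 0
    with open(path, "w") as handle:
        handle.write("\t".join(ANNOTATED_COLUMNS) + "\n")
        for a in annotated:
            c = a.call
            handle.write(
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.vtype.value}\t"
                f"{a.region.value}\t{a.gene_id or '.'}\t{a.effect.value}\n"
            )
            n += 1
    return n
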