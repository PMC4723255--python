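"""Single-sample SNP/InDel calling from pileup sites.

A site is called when all four count conditions hold: depth at least
``min_depth``, at least ``min_mut_reads`` reads supporting the dominant
non-reference allele, mutant ratio strictly above ``min_mut_ratio``, and
mutant ratio at least ``hetero_prop_level`` (the candidate-site proportion
floor). Sites at or above ``homo_prop_level`` are genotyped homozygous,
otherwise heterozygous.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from radmarker.pileup import PileupSite, read_pileup


class VariantType(enum.Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


class Genotype(enum.Enum):
    HET = "HET"
    HOM = "HOM"


@dataclass(frozen=True)
class CallParams:
    min_depth: int = 3
    min_mut_reads: int = 3  # "more than 2 mutant reads"
    min_mut_ratio: float = 0.20  # exclusive floor
    hetero_prop_level: float = 0.3  # inclusive candidate-site floor
    homo_prop_level: float = 0.8  # HOM/HET boundary, inclusive for HOM

    def __post_init__(self) -> None:
        if not 0 <= self.min_mut_ratio < self.hetero_prop_level <= self.homo_prop_level <= 1:
            raise ValueError(
                "require 0 <= min_mut_ratio < hetero_prop_level <= homo_prop_level <= 1"
            )
        if self.min_mut_reads < 1:
            raise ValueError("min_mut_reads must be >= 1")


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int  # 1-based; anchor base for indels
    ref: str
    alt: str
    vtype: VariantType
    depth: int
    mut_reads: int
    mut_ratio: float
    genotype: Genotype

    def __post_init__(self) -> None:
        if self.mut_reads > self.depth:
            raise ValueError("mut_reads exceeds depth")
        if self.vtype is VariantType.SNP and self.ref == self.alt:
            raise ValueError("SNP with identical ref and alt")
        if not self.ref or not self.alt:
            raise ValueError("empty allele")


def _allele_to_variant(allele: str, ref_base: str) -> tuple[str, str, VariantType]:
    """VCF-style (ref, alt, type) for a pileup allele key."""
    if allele.startswith("ins:"):
        seq = allele[4:]
        return ref_base, ref_base + seq, VariantType.INS
    if allele.startswith("del:"):
        seq = allele[4:]
        return ref_base + seq, ref_base, VariantType.DEL
    return ref_base, allele, VariantType.SNP


def call_site(site: PileupSite, params: CallParams = CallParams()) -> VariantCall | None:
    """Apply the four calling conditions; None is the normal no-call outcome."""
    dom = site.dominant_mutant()
    if dom is None:
        return None
    allele, mut_reads = dom
    if site.depth < params.min_depth:
        return None
    if mut_reads < params.min_mut_reads:
        return None
    ratio = mut_reads / site.depth
    if ratio <= params.min_mut_ratio:
        return None
    if ratio < params.hetero_prop_level:
        return None
    ref, alt, vtype = _allele_to_variant(allele, site.ref_base)
    genotype = Genotype.HOM if ratio >= params.homo_prop_level else Genotype.HET
    return VariantCall(
        site.chrom, site.pos, ref, alt, vtype, site.depth, mut_reads, ratio, genotype
    )


def call_variants(
    sites: Union[str, Path, Iterable[PileupSite]],
    params: CallParams = CallParams(),
) -> Iterator[VariantCall]:
    """One ordered pass over a sorted pileup, yielding calls.

    Raises on unsorted input, naming the first offending position.
    """
    if isinstance(sites, (str, Path)):
        sites = read_pileup(sites)
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()
    for site in sites:
        if last is not None:
            if site.chrom == last[0] and site.pos < last[1]:
                raise ValueError(
                    f"unsorted pileup: {site.chrom}:{site.pos} after {last[0]}:{last[1]}"
                )
            if site.chrom != last[0] and site.chrom in seen_chroms:
                raise ValueError(
                    f"unsorted pileup: chromosome {site.chrom} re-appears at position {site.pos}"
                )
        seen_chroms.add(site.chrom)
        last = (site.chrom, site.pos)
        call = call_site(site, params)
        if call is not None:
            yield call


SNPINFO_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "type",
    "depth",
    "mut_reads",
    "mut_ratio",
    "genotype",
)


def write_snpinfo(calls: Iterable[VariantCall], path: Union[str, Path, IO[str]]) -> int:
    """Write calls as a SnpInfo TSV; returns the number of rows written."""
    own = isinstance(path, (str, Path))
    handle: IO[str] = open(path, "w") if own else path  # type: ignore[arg-type]
    n = 0
    try:
        handle.write("\t".join(SNPINFO_COLUMNS) + "\n")
        for c in calls:
            handle.write(
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.vtype.value}\t"
                f"{c.depth}\t{c.mut_reads}\t{c.mut_ratio:.6g}\t{c.genotype.value}\n"
            )
            n += 1
    finally:
        if own:
            handle.close()
    return n


def read_snpinfo(path: Union[str, Path, Iterable[str]]) -> list[VariantCall]:
    """Parse a SnpInfo TSV back into :class:`VariantCall` records."""
    if isinstance(path, (str, Path)):
        with open(path) as handle:
            return read_snpinfo(handle)
    lines = iter(path)
    header = next(lines, None)
    if header is None or tuple(header.rstrip("\n").split("\t")) != SNPINFO_COLUMNS:
        raise ValueError("not a SnpInfo file: bad or missing header")
    calls = []
    for line in lines:
        if not line.strip():
            continue
        chrom, pos, ref, alt, vtype, depth, mut_reads, mut_ratio, genotype = (
            line.rstrip("\n").split("\t")
        )
        calls.append(
            VariantCall(
                chrom,
                int(pos),
                ref,
                alt,
                VariantType(vtype),
                int(depth),
                int(mut_reads),
                float(mut_ratio),
                Genotype(genotype),
            )
        )
    return calls


def write_vcf(
    calls: Iterable[VariantCall], path: Union[str, Path], sample: str = "SAMPLE"
) -> None:
    """Minimal VCF 4.2 export of single-sample calls."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        handle.write(
            f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n"
        )
        for c in calls:
            gt = "1/1" if c.genotype is Genotype.HOM else "0/1"
            handle.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                f"DP={c.depth}\tGT\t{gt}\n"
            )
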