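"""Deterministic synthetic data: genomes, gene models, planted divergent
variants between two varieties, and samtools-pileup files with configurable
depth and per-base error, plus truth-table evaluation of recovered markers.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from ``SimSpec.seed``; identical specs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import numpy as np

from radmarker.digest import reverse_complement
from radmarker.pileup import PileupSite
from radmarker.somatic import MarkerRecord, SomaticParams

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic two-variety dataset."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 200_000
    gc_fraction: float = 0.43
    n_genes: int = 20
    n_divergent_snps: int = 100
    n_divergent_indels: int = 20
    max_indel_len: int = 30
    het_fraction: float = 0.0
    mean_depth: float = 20.0
    error_rate: float = 0.01
    min_variant_spacing: int = 40
    site_sequence: str | None = None
    site_spacing: int = 500
    sites_per_chrom: int = 0
    decorate_rate: float = 0.02  # fraction of pileup lines carrying ^/$ marks

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.chrom_length, self.n_genes, self.n_divergent_snps,
               self.n_divergent_indels, self.sites_per_chrom) < 0:
            raise ValueError("counts must be >= 0")
        if not (0 <= self.gc_fraction <= 1 and 0 <= self.error_rate <= 1):
            raise ValueError("gc_fraction and error_rate must be in [0, 1]")
        if self.min_variant_spacing <= self.max_indel_len + 1:
            raise ValueError("min_variant_spacing must exceed max_indel_len + 1")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int  # 1-based; anchor base for indels (VCF-style)
    ref: str
    alt: str
    vtype: str  # SNP | INS | DEL
    carrier: str  # 'A' or 'B'
    zygosity: str  # HOM | HET


# ---------------------------------------------------------------------------
# genome


def make_genome(
    spec: SimSpec, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], dict[str, list[int]]]:
    """Random genome with optionally planted restriction sites.

    Returns (chrom -> sequence, chrom -> ground-truth cut positions). When
    ``site_sequence`` is set, accidental occurrences of the recognition
    sequence are scrubbed before planting so the returned list is complete.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    genome: dict[str, str] = {}
    cuts: dict[str, list[int]] = {}
    for chrom in spec.chrom_names():
        arr = rng.choice(_BASES, size=spec.chrom_length, p=probs)
        seq = "".join(arr)
        chrom_cuts: list[int] = []
        if spec.site_sequence and spec.sites_per_chrom > 0:
            site = spec.site_sequence.upper()
            needed = (spec.sites_per_chrom + 1) * spec.site_spacing
            if needed > spec.chrom_length:
                raise ValueError(
                    f"chrom_length {spec.chrom_length} too small for "
                    f"{spec.sites_per_chrom} sites spaced {spec.site_spacing} bp"
                )
            seq = _scrub_site(seq, site, rng)
            chars = list(seq)
            # plant occurrence k starting at 0-based site_spacing * (k + 1)
            cut_offset = 1 if site == "TCGA" else 0
            for k in range(spec.sites_per_chrom):
                start = spec.site_spacing * (k + 1)
                chars[start : start + len(site)] = site
                chrom_cuts.append(start + cut_offset)
            seq = _scrub_site("".join(chars), site, rng, keep_starts={
                spec.site_spacing * (k + 1) for k in range(spec.sites_per_chrom)
            })
        genome[chrom] = seq
        cuts[chrom] = chrom_cuts
    return genome, cuts


def _scrub_site(
    seq: str, site: str, rng: np.random.Generator, keep_starts: set[int] = frozenset()
) -> str:
    """Destroy all occurrences of ``site`` except those starting in keep_starts."""
    chars = list(seq)
    guard = {p for s in keep_starts for p in range(s, s + len(site))}
    while True:
        s = "".join(chars)
        hits = [
            i for i in _find_all(s, site) if i not in keep_starts
        ]
        if not hits:
            return s
        for i in hits:
            # flip one base outside any planted window
            for j in range(i, i + len(site)):
                if j not in guard:
                    old = chars[j]
                    choices = [b for b in "ACGT" if b != old]
                    chars[j] = choices[int(rng.integers(len(choices)))]
                    break


def _find_all(seq: str, pattern: str) -> Iterator[int]:
    i = seq.find(pattern)
    while i != -1:
        yield i
        i = seq.find(pattern, i + 1)


def write_fasta(genome: Mapping[str, str], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneTruth:
    """Planted transcript structure, mirrored by the emitted GFF3."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...]
    utr3: tuple[tuple[int, int], ...]
    cds_seq: str  # transcript-order coding sequence (ATG .. stop)


def make_annotation(
    spec: SimSpec,
    genome: dict[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneTruth], str]:
    """Plant non-overlapping two-exon genes; returns (truth, GFF3 text).

    The coding sequence of every gene (valid start, internal stop-free
    codons, terminal stop) is written into the genome dict in place, so
    call after :func:`make_genome` and before :func:`plant_variants`.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    chroms = spec.chrom_names()
    per_chrom = _split_evenly(spec.n_genes, len(chroms))
    gff = ["##gff-version 3\n"]
    truths: list[GeneTruth] = []
    gene_no = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        slot = len(genome[chrom]) // n_here
        for k in range(n_here):
            gene_no += 1
            u5 = int(rng.integers(40, 80))
            u3 = int(rng.integers(40, 80))
            n_codons = int(rng.integers(30, 80))  # incl. start and stop
            intron = int(rng.integers(60, 140))
            cds_len = 3 * n_codons
            body = u5 + cds_len + intron + u3
            slot_start = k * slot
            flank = min(2000, max(200, slot // 4))  # TSS/TTS windows + intergenic
            margin = slot - body - 2 * flank
            if margin <= 0:
                raise ValueError(
                    f"chrom_length too small: gene {gene_no} needs {body + 2 * flank} bp "
                    f"but slot is {slot} bp"
                )
            g = slot_start + flank + int(rng.integers(margin)) + 1  # 1-based start
            strand = "+" if rng.random() < 0.5 else "-"
            split = 3 * int(rng.integers(5, n_codons - 5))  # CDS split point
            truth = _build_gene(
                gene_no, chrom, strand, g, u5, u3, cds_len, split, intron, rng
            )
            _write_cds_into_genome(genome, truth)
            truths.append(truth)
            gff.append(_gene_to_gff3(truth))
    return truths, "".join(gff)


def _split_evenly(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _build_gene(
    gene_no: int,
    chrom: str,
    strand: str,
    g: int,
    u5: int,
    u3: int,
    cds_len: int,
    split: int,
    intron: int,
    rng: np.random.Generator,
) -> GeneTruth:
    n_mid = cds_len // 3 - 2
    cds_seq = "ATG" + "".join(
        _NONSTOP_CODONS[int(i)] for i in rng.integers(len(_NONSTOP_CODONS), size=n_mid)
    ) + ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    # genomic skeleton, left to right: uL | cdsL | intron | cdsR | uR
    if strand == "+":
        uL, uR = u5, u3
        cL, cR = split, cds_len - split
    else:
        uL, uR = u3, u5
        cL, cR = cds_len - split, split
    utrL = (g, g + uL - 1)
    cdsL = (g + uL, g + uL + cL - 1)
    cdsR_start = cdsL[1] + intron + 1
    cdsR = (cdsR_start, cdsR_start + cR - 1)
    utrR = (cdsR[1] + 1, cdsR[1] + uR)
    exons = ((utrL[0], cdsL[1]), (cdsR[0], utrR[1]))
    end = utrR[1]
    gid = f"gene{gene_no:03d}"
    if strand == "+":
        utr5_ivals, utr3_ivals = (utrL,), (utrR,)
    else:
        utr5_ivals, utr3_ivals = (utrR,), (utrL,)
    return GeneTruth(
        gene_id=gid,
        transcript_id=f"{gid}.1",
        chrom=chrom,
        strand=strand,
        start=g,
        end=end,
        exons=exons,
        cds=(cdsL, cdsR),
        utr5=utr5_ivals,
        utr3=utr3_ivals,
        cds_seq=cds_seq,
    )


def _write_cds_into_genome(genome: dict[str, str], truth: GeneTruth) -> None:
    genomic_cds = (
        truth.cds_seq if truth.strand == "+" else reverse_complement(truth.cds_seq)
    )
    chars = list(genome[truth.chrom])
    offset = 0
    for s, e in truth.cds:
        n = e - s + 1
        chars[s - 1 : e] = genomic_cds[offset : offset + n]
        offset += n
    genome[truth.chrom] = "".join(chars)


def _gene_to_gff3(t: GeneTruth) -> str:
    lines = []

    def row(ftype: str, s: int, e: int, attrs: str, phase: str = ".") -> None:
        lines.append(
            f"{t.chrom}\tradmarker_sim\t{ftype}\t{s}\t{e}\t.\t{t.strand}\t{phase}\t{attrs}\n"
        )

    row("gene", t.start, t.end, f"ID={t.gene_id};Name={t.gene_id}")
    row("mRNA", t.start, t.end, f"ID={t.transcript_id};Parent={t.gene_id}")
    for i, (s, e) in enumerate(t.exons, 1):
        row("exon", s, e, f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}")
    # phase: transcript-order first CDS chunk starts in frame 0
    order = t.cds if t.strand == "+" else tuple(reversed(t.cds))
    done = 0
    phased = []
    for s, e in order:
        phased.append((s, e, (3 - done % 3) % 3))
        done += e - s + 1
    for i, (s, e, phase) in enumerate(sorted(phased), 1):
        row("CDS", s, e, f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}", str(phase))
    for i, (s, e) in enumerate(t.utr5, 1):
        row("five_prime_UTR", s, e, f"ID={t.transcript_id}.utr5p{i};Parent={t.transcript_id}")
    for i, (s, e) in enumerate(t.utr3, 1):
        row("three_prime_UTR", s, e, f"ID={t.transcript_id}.utr3p{i};Parent={t.transcript_id}")
    return "".join(lines)


# ---------------------------------------------------------------------------
# divergent variants


def plant_variants(
    spec: SimSpec,
    genome: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], dict[str, str], list[TruthVariant]]:
    """Plant divergent SNPs/InDels, each carried by one variety.

    Returns (variety A genome, variety B genome, truth). Positions respect
    ``min_variant_spacing`` within and across chromosomes' coordinate
    space, and deletions never run off the chromosome end.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    chroms = list(genome)
    truth: list[TruthVariant] = []
    taken: dict[str, list[int]] = {c: [] for c in chroms}
    n_total = spec.n_divergent_snps + spec.n_divergent_indels
    kinds = ["SNP"] * spec.n_divergent_snps + ["INDEL"] * spec.n_divergent_indels
    rng.shuffle(kinds)
    attempts = 0
    planted = 0
    while planted < n_total:
        attempts += 1
        if attempts > 200 * n_total + 100:
            raise ValueError("cannot satisfy variant spacing; reduce counts or spacing")
        chrom = chroms[int(rng.integers(len(chroms)))]
        seq = genome[chrom]
        pos = int(rng.integers(spec.min_variant_spacing, len(seq) - spec.min_variant_spacing)) + 1
        if any(abs(pos - p) < spec.min_variant_spacing for p in taken[chrom]):
            continue
        ref_base = seq[pos - 1]
        if ref_base == "N":
            continue
        kind = kinds[planted]
        carrier = "A" if planted % 2 == 0 else "B"
        zygosity = "HET" if rng.random() < spec.het_fraction else "HOM"
        if kind == "SNP":
            alt = "ACGT"[int(rng.integers(4))]
            while alt == ref_base:
                alt = "ACGT"[int(rng.integers(4))]
            truth.append(TruthVariant(chrom, pos, ref_base, alt, "SNP", carrier, zygosity))
        else:
            length = int(rng.integers(1, spec.max_indel_len + 1))
            if rng.random() < 0.5:
                ins = "".join("ACGT"[int(i)] for i in rng.integers(4, size=length))
                truth.append(
                    TruthVariant(chrom, pos, ref_base, ref_base + ins, "INS", carrier, zygosity)
                )
            else:
                deleted = seq[pos : pos + length]
                truth.append(
                    TruthVariant(chrom, pos, ref_base + deleted, ref_base, "DEL", carrier, zygosity)
                )
        taken[chrom].append(pos)
        planted += 1
    truth.sort(key=lambda t: (t.chrom, t.pos))
    variety_a = _apply_variants(genome, [t for t in truth if t.carrier == "A"])
    variety_b = _apply_variants(genome, [t for t in truth if t.carrier == "B"])
    return variety_a, variety_b, truth


def _apply_variants(
    genome: Mapping[str, str], variants: Sequence[TruthVariant]
) -> dict[str, str]:
    out = dict(genome)
    for chrom in out:
        edits = sorted(
            (v for v in variants if v.chrom == chrom), key=lambda v: -v.pos
        )
        seq = out[chrom]
        for v in edits:
            i = v.pos - 1
            seq = seq[:i] + v.alt + seq[i + len(v.ref) :]
        out[chrom] = seq
    return out


# ---------------------------------------------------------------------------
# pileup simulation


def simulate_pileup(
    reference: Mapping[str, str],
    truth: Sequence[TruthVariant],
    carrier: str,
    spec: SimSpec,
    rng: np.random.Generator,
) -> Iterator[str]:
    """Yield samtools pileup lines for one variety against the reference.

    Depth per position is Poisson(``mean_depth``); each observation shows
    the variety allele with probability ``1 - error_rate``, otherwise a
    uniform random different base (indel-carrying observations lose the
    indel instead). Deletion-spanned positions show ``*``. A fraction of
    lines carry ``^``/``$`` read-boundary decorations. Positions with zero
    depth are absent, as in real pileup.
    """
    events: dict[tuple[str, int], TruthVariant] = {
        (v.chrom, v.pos): v for v in truth if v.carrier == carrier
    }
    del_spans: dict[tuple[str, int], None] = {}
    for v in truth:
        if v.carrier == carrier and v.vtype == "DEL":
            for p in range(v.pos + 1, v.pos + len(v.ref)):
                del_spans[(v.chrom, p)] = None
    err = spec.error_rate
    for chrom, seq in reference.items():
        n = len(seq)
        depths = rng.poisson(spec.mean_depth, size=n)
        err_counts = rng.binomial(depths, err) if err > 0 else np.zeros(n, dtype=int)
        decorated = rng.random(n) < spec.decorate_rate
        for i in range(n):
            d = int(depths[i])
            if d == 0:
                continue
            pos = i + 1
            key = (chrom, pos)
            ref_base = seq[i]
            e = int(err_counts[i])
            if key in events:
                bases = _variant_bases(events[key], ref_base, d, err, rng)
            elif key in del_spans:
                n_star = d if err == 0 else int(rng.binomial(d, 1 - err))
                bases = "*" * n_star + "." * (d - n_star)
            elif e == 0:
                bases = "." * d
            else:
                wrong = "".join(
                    _random_other(ref_base, rng) for _ in range(e)
                )
                bases = "." * (d - e) + wrong
            if decorated[i]:
                bases = "^I" + bases + "$"
            yield f"{chrom}\t{pos}\t{ref_base}\t{d}\t{bases}\t{'I' * d}"


def _random_other(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def _variant_bases(
    v: TruthVariant, ref_base: str, depth: int, err: float, rng: np.random.Generator
) -> str:
    obs: list[str] = []
    for _ in range(depth):
        on_alt = v.zygosity == "HOM" or rng.random() < 0.5
        errored = err > 0 and rng.random() < err
        if v.vtype == "SNP":
            allele = v.alt if on_alt else v.ref
            if errored:
                allele = _random_other(allele, rng)
            obs.append("." if allele == ref_base else allele)
        elif v.vtype == "INS":
            if on_alt and not errored:
                obs.append(f".+{len(v.alt) - 1}{v.alt[1:]}")
            else:
                obs.append("." if not errored else _random_other(ref_base, rng))
        else:  # DEL anchored here
            if on_alt and not errored:
                obs.append(f".-{len(v.ref) - 1}{v.ref[1:]}")
            else:
                obs.append("." if not errored else _random_other(ref_base, rng))
    return "".join(obs)


def write_pileup(lines: Iterable[str], path: Union[str, Path]) -> int:
    n = 0
    with open(path, "w") as handle:
        for line in lines:
            handle.write(line + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# truth I/O and evaluation

TRUTH_COLUMNS = ("chrom", "pos", "ref", "alt", "vtype", "carrier", "zygosity")


def write_truth(truth: Iterable[TruthVariant], path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(TRUTH_COLUMNS) + "\n")
        for v in truth:
            handle.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.vtype}\t{v.carrier}\t{v.zygosity}\n"
            )


def read_truth(path: Union[str, Path]) -> list[TruthVariant]:
    with open(path) as handle:
        header = next(handle)
        if tuple(header.rstrip("\n").split("\t")) != TRUTH_COLUMNS:
            raise ValueError("not a truth file")
        return [
            TruthVariant(c, int(p), r, a, t, ca, z)
            for c, p, r, a, t, ca, z in (
                line.rstrip("\n").split("\t") for line in handle if line.strip()
            )
        ]


def evaluate_calls(
    markers: Sequence[MarkerRecord],
    truth: Sequence[TruthVariant],
) -> dict:
    """Precision/recall of recovered markers against the planted truth.

    A marker matches a truth row when chromosome, anchored position and alt
    allele agree. Precision is None (NA) when nothing was called.
    """
    truth_keys = {(t.chrom, t.pos, t.alt) for t in truth}
    matched = [
        m for m in markers if (m.chrom, m.pos, m.call.alt) in truth_keys
    ]
    by_type: dict[str, dict[str, int]] = {}
    matched_keys = {(m.chrom, m.pos, m.call.alt) for m in matched}
    for t in truth:
        d = by_type.setdefault(t.vtype, {"planted": 0, "recovered": 0})
        d["planted"] += 1
        if (t.chrom, t.pos, t.alt) in matched_keys:
            d["recovered"] += 1
    return {
        "n_called": len(markers),
        "n_planted": len(truth),
        "n_matched": len(matched),
        "precision": len(matched) / len(markers) if markers else None,
        "recall": len(matched) / len(truth) if truth else None,
        "by_type": by_type,
    }


def recoverable_truth(
    truth: Sequence[TruthVariant],
    sites_a: Mapping[tuple[str, int], PileupSite],
    sites_b: Mapping[tuple[str, int], PileupSite],
    params: SomaticParams = SomaticParams(),
) -> list[TruthVariant]:
    """Planted variants whose realized pileups satisfy the marker rules.

    The check is written as direct arithmetic on the simulated counts —
    independent of the calling/somatic code paths — so evaluation against
    this subset exercises the pipeline rather than restating it.
    """
    out = []
    for t in truth:
        treat = sites_a if t.carrier == "A" else sites_b
        control = sites_b if t.carrier == "A" else sites_a
        ts = treat.get((t.chrom, t.pos))
        cs = control.get((t.chrom, t.pos))
        if ts is None or cs is None:
            continue
        if t.vtype == "SNP":
            key = t.alt
        elif t.vtype == "INS":
            key = "ins:" + t.alt[1:]
        else:
            key = "del:" + t.ref[1:]
        alt_count = ts.base_counts.get(key, 0)
        # the planted allele must itself be the dominant one
        if any(c > alt_count for a, c in ts.base_counts.items() if a != key):
            continue
        ratio = alt_count / ts.depth if ts.depth else 0.0
        treat_ok = (
            ts.depth >= params.call.min_depth
            and alt_count >= params.call.min_mut_reads
            and ratio > params.call.min_mut_ratio
            and ratio >= params.call.hetero_prop_level
        )
        c_mut = (cs.depth - cs.n_ref - cs.n_skipped) + sum(
            c for a, c in cs.base_counts.items() if a.startswith(("ins:", "del:"))
        )
        control_ok = (
            cs.depth >= params.control_min_depth
            and c_mut < params.control_max_mut_reads
            and c_mut / cs.depth < params.control_max_mut_ratio
        )
        if treat_ok and control_ok:
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# orchestration


def simulate(spec: SimSpec, outdir: Union[str, Path]) -> dict[str, Path]:
    """Generate a full dataset on disk; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    genome, _ = make_genome(spec, rng)
    gene_truth, gff_text = (
        make_annotation(spec, genome, rng) if spec.n_genes else ([], "##gff-version 3\n")
    )
    variety_a, variety_b, truth = plant_variants(spec, genome, rng)
    paths = {
        "genome": outdir / "genome.fa",
        "gff3": outdir / "genes.gff3",
        "pileup_a": outdir / "A.pileup",
        "pileup_b": outdir / "B.pileup",
        "truth": outdir / "truth.tsv",
        "variety_a": outdir / "A.fa",
        "variety_b": outdir / "B.fa",
    }
    write_fasta(genome, paths["genome"])
    write_fasta(variety_a, paths["variety_a"])
    write_fasta(variety_b, paths["variety_b"])
    paths["gff3"].write_text(gff_text)
    write_pileup(simulate_pileup(genome, truth, "A", spec, rng), paths["pileup_a"])
    write_pileup(simulate_pileup(genome, truth, "B", spec, rng), paths["pileup_b"])
    write_truth(truth, paths["truth"])
    return paths
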