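"""Two-sample (inter-variety) marker discovery with post-filters.

A marker is a position called variant in the "treat" sample whose
counterpart in the "control" sample is clean reference: covered by at least
``control_min_depth`` reads, fewer than ``control_max_mut_reads`` mutant
reads and a mutant ratio strictly below ``control_max_mut_ratio``. Both
directions are run and merged, then two post-filters apply: the treat side
must reach ``post_min_treat_depth`` reads while the control side shows no
mutant read at all, and any surviving markers on the same chromosome closer
than ``min_spacing_bp`` are all eliminated (whole chains, both members).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from radmarker.pileup import PileupSite, read_pileup
from radmarker.variant_call import (
    CallParams,
    Genotype,
    VariantCall,
    VariantType,
    call_site,
)


class Direction(enum.Enum):
    A_VS_B = "A_vs_B"  # variant in A, clean in B
    B_VS_A = "B_vs_A"


@dataclass(frozen=True)
class SomaticParams:
    control_min_depth: int = 10
    control_max_mut_reads: int = 2  # exclusive: "less than 2 mutant reads"
    control_max_mut_ratio: float = 0.04  # exclusive: "less than 4%"
    call: CallParams = field(default_factory=CallParams)
    post_min_treat_depth: int = 8
    post_max_control_mut: int = 0  # "none in the other"
    min_spacing_bp: int = 10

    def __post_init__(self) -> None:
        if min(
            self.control_min_depth,
            self.control_max_mut_reads,
            self.control_max_mut_ratio,
            self.post_min_treat_depth,
            self.post_max_control_mut,
        ) < 0:
            raise ValueError("all bounds must be >= 0")
        if self.min_spacing_bp < 1:
            raise ValueError("min_spacing_bp must be >= 1")


@dataclass(frozen=True)
class MarkerRecord:
    """A treat-side call paired with its clean-control evidence."""

    call: VariantCall
    direction: Direction
    control_depth: int
    control_mut_reads: int

    @property
    def chrom(self) -> str:
        return self.call.chrom

    @property
    def pos(self) -> int:
        return self.call.pos


def is_clean_control(site: PileupSite, params: SomaticParams = SomaticParams()) -> bool:
    """All three control conditions: depth, mutant-read count, mutant ratio."""
    if site.depth < params.control_min_depth:
        return False
    mut = site.total_mut_reads
    if mut >= params.control_max_mut_reads:
        return False
    return mut / site.depth < params.control_max_mut_ratio


def _index_sites(
    sites: Union[str, Path, Iterable[PileupSite]],
) -> dict[tuple[str, int], PileupSite]:
    if isinstance(sites, (str, Path)):
        sites = read_pileup(sites)
    return {(s.chrom, s.pos): s for s in sites}


def somatic_one_direction(
    treat: Union[str, Path, Iterable[PileupSite], dict[tuple[str, int], PileupSite]],
    control: Union[str, Path, Iterable[PileupSite], dict[tuple[str, int], PileupSite]],
    params: SomaticParams = SomaticParams(),
    direction: Direction = Direction.A_VS_B,
) -> list[MarkerRecord]:
    """Markers variant in ``treat`` with clean-reference ``control``.

    Positions absent from the control pileup are not emitted: with no
    control line there is no evidence of clean coverage.
    """
    treat_idx = treat if isinstance(treat, dict) else _index_sites(treat)
    control_idx = control if isinstance(control, dict) else _index_sites(control)
    _check_same_reference(treat_idx, control_idx)
    records = []
    for key, site in treat_idx.items():
        call = call_site(site, params.call)
        if call is None:
            continue
        csite = control_idx.get(key)
        if csite is None or not is_clean_control(csite, params):
            continue
        records.append(
            MarkerRecord(call, direction, csite.depth, csite.total_mut_reads)
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def _check_same_reference(
    a: dict[tuple[str, int], PileupSite], b: dict[tuple[str, int], PileupSite]
) -> None:
    chroms_a = {c for c, _ in a}
    chroms_b = {c for c, _ in b}
    if a and b and not (chroms_a & chroms_b):
        raise ValueError(
            f"no shared chromosomes between pileups: {sorted(chroms_a)} vs {sorted(chroms_b)}"
        )


def somatic_bidirectional(
    pileup_a: Union[str, Path, Iterable[PileupSite]],
    pileup_b: Union[str, Path, Iterable[PileupSite]],
    params: SomaticParams = SomaticParams(),
) -> list[MarkerRecord]:
    """Union of both comparison directions, sorted by (chrom, pos)."""
    idx_a = _index_sites(pileup_a)
    idx_b = _index_sites(pileup_b)
    records = somatic_one_direction(idx_a, idx_b, params, Direction.A_VS_B)
    records += somatic_one_direction(idx_b, idx_a, params, Direction.B_VS_A)
    records.sort(key=lambda r: (r.chrom, r.pos, r.direction.value))
    return records


def apply_post_filters(
    records: list[MarkerRecord], params: SomaticParams = SomaticParams()
) -> list[MarkerRecord]:
    """Coverage filter then spacing filter; output is a subset of input.

    Coverage: treat depth >= ``post_min_treat_depth`` and control mutant
    reads <= ``post_max_control_mut``. Spacing: per chromosome, chains of
    surviving markers with consecutive gaps < ``min_spacing_bp`` are removed
    entirely (both/all members).
    """
    covered = [
        r
        for r in records
        if r.call.depth >= params.post_min_treat_depth
        and r.control_mut_reads <= params.post_max_control_mut
    ]
    covered.sort(key=lambda r: (r.chrom, r.pos))
    kept: list[MarkerRecord] = []
    chain: list[MarkerRecord] = []
    positions: set[int] = set()

    def flush() -> None:
        if len(positions) == 1:
            kept.extend(chain)
        chain.clear()
        positions.clear()

    for r in covered:
        if chain and (
            r.chrom != chain[-1].chrom
            or r.pos - max(positions) >= params.min_spacing_bp
        ):
            flush()
        chain.append(r)
        positions.add(r.pos)
    flush()
    return kept


MARKER_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "type",
    "depth",
    "mut_reads",
    "mut_ratio",
    "genotype",
    "direction",
    "control_depth",
    "control_mut_reads",
)


def write_markers(
    records: Iterable[MarkerRecord], path: Union[str, Path, IO[str]]
) -> int:
    """Marker TSV: SnpInfo columns plus direction and control statistics."""
    own = isinstance(path, (str, Path))
    handle: IO[str] = open(path, "w") if own else path  # type: ignore[arg-type]
    n = 0
    try:
        handle.write("\t".join(MARKER_COLUMNS) + "\n")
        for r in records:
            c = r.call
            handle.write(
                f"{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.vtype.value}\t"
                f"{c.depth}\t{c.mut_reads}\t{c.mut_ratio:.6g}\t{c.genotype.value}\t"
                f"{r.direction.value}\t{r.control_depth}\t{r.control_mut_reads}\n"
            )
            n += 1
    finally:
        if own:
            handle.close()
    return n


def read_markers(path: Union[str, Path, Iterable[str]]) -> list[MarkerRecord]:
    if isinstance(path, (str, Path)):
        with open(path) as handle:
            return read_markers(handle)
    lines = iter(path)
    header = next(lines, None)
    if header is None or tuple(header.rstrip("\n").split("\t")) != MARKER_COLUMNS:
        raise ValueError("not a marker file: bad or missing header")
    records = []
    for line in lines:
        if not line.strip():
            continue
        (
            chrom, pos, ref, alt, vtype, depth, mut_reads, mut_ratio,
            genotype, direction, control_depth, control_mut,
        ) = line.rstrip("\n").split("\t")
        call = VariantCall(
            chrom, int(pos), ref, alt, VariantType(vtype), int(depth),
            int(mut_reads), float(mut_ratio), Genotype(genotype),
        )
        records.append(
            MarkerRecord(call, Direction(direction), int(control_depth), int(control_mut))
        )
    return records
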