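"""In-silico restriction digestion and fragment-size selection.

Locates recognition sites on the forward strand (complete for palindromic
sites such as TaqαI's T/CGA), derives fragment lengths between consecutive
cuts, and counts fragments inside an inclusive size window to judge whether
a genome/enzyme combination yields a workable number of RAD tags.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A recognition sequence and the cut position inside it.

    ``cut_offset`` is the 0-based offset of the cut within the recognition
    sequence; the reported cut coordinate is the position of the first base
    *after* the cut.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("recognition sequence must be non-empty")
        if not set(self.recognition) <= set("ACGT"):
            raise ValueError("recognition sequence must be over {A,C,G,T}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition sequence")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition


#: TaqαI cuts T/CGA: between the T and the C.
TAQ_ALPHA_I = RestrictionEnzyme("TaqaI", "TCGA", 1)


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All forward-strand cut positions, ascending, overlapping included.

    Matching is case-insensitive; windows containing N never match. For
    non-palindromic enzymes the reverse strand is scanned too and cut
    positions are deduplicated.
    """
    seq = seq.upper()
    cuts = _scan_forward(seq, enzyme.recognition, enzyme.cut_offset)
    if not enzyme.is_palindromic:
        # a reverse-strand match at forward index i spans i..i+m-1; its cut
        # sits cut_offset bases from the 3' end of the forward-strand window
        rc = reverse_complement(enzyme.recognition)
        m = len(rc)
        rev = [
            i + (m - enzyme.cut_offset)
            for i in _scan_forward_starts(seq, rc)
        ]
        cuts = sorted(set(cuts) | set(rev))
    return cuts


def _scan_forward_starts(seq: str, pattern: str) -> Iterator[int]:
    start = seq.find(pattern)
    while start != -1:
        yield start
        start = seq.find(pattern, start + 1)


def _scan_forward(seq: str, pattern: str, cut_offset: int) -> list[int]:
    return [i + cut_offset for i in _scan_forward_starts(seq, pattern)]


def digest_fragments(
    seq: str, enzyme: RestrictionEnzyme, include_terminal: bool = False
) -> list[int]:
    """Fragment lengths between consecutive cuts on one sequence.

    By default the two terminal pieces (sequence start to first cut and
    last cut to sequence end) are excluded: they carry only one ligatable
    cut end and do not become RAD tags. With ``include_terminal`` they are
    prepended/appended, so the lengths then sum to ``len(seq)``.
    """
    cuts = find_sites(seq, enzyme)
    return fragments_from_cuts(cuts, len(seq), include_terminal)


def fragments_from_cuts(
    cuts: list[int], seq_len: int, include_terminal: bool = False
) -> list[int]:
    """Fragment lengths given precomputed cut coordinates on one sequence."""
    internal = [b - a for a, b in zip(cuts, cuts[1:])]
    if not include_terminal:
        return internal
    if not cuts:
        return [seq_len]
    return [cuts[0]] + internal + [seq_len - cuts[-1]]


@dataclass
class DigestSummary:
    """Per-chromosome digestion results plus a windowed fragment count."""

    enzyme: RestrictionEnzyme
    window_lo: int
    window_hi: int
    include_terminal: bool = False
    site_counts: dict[str, int] = field(default_factory=dict)
    fragment_lengths: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return sum(self.site_counts.values())

    @property
    def n_fragments(self) -> int:
        return sum(len(v) for v in self.fragment_lengths.values())

    @property
    def n_in_window(self) -> int:
        lo, hi = self.window_lo, self.window_hi
        return sum(
            1
            for lengths in self.fragment_lengths.values()
            for length in lengths
            if lo <= length <= hi
        )

    def n_in_window_per_chrom(self) -> dict[str, int]:
        lo, hi = self.window_lo, self.window_hi
        return {
            chrom: sum(1 for length in lengths if lo <= length <= hi)
            for chrom, lengths in self.fragment_lengths.items()
        }

    def histogram(self, bin_width: int = 1) -> Counter[int]:
        """Counts of fragment lengths binned to ``bin_width`` (floor)."""
        hist: Counter[int] = Counter()
        for lengths in self.fragment_lengths.values():
            for length in lengths:
                hist[(length // bin_width) * bin_width] += 1
        return hist

    def as_tsv(self) -> str:
        per_chrom = self.n_in_window_per_chrom()
        out = ["chrom\tn_sites\tn_fragments\tn_in_window\n"]
        for chrom in self.site_counts:
            out.append(
                f"{chrom}\t{self.site_counts[chrom]}\t"
                f"{len(self.fragment_lengths[chrom])}\t{per_chrom[chrom]}\n"
            )
        out.append(f"TOTAL\t{self.n_sites}\t{self.n_fragments}\t{self.n_in_window}\n")
        return "".join(out)


def iter_fasta(path: Union[str, Path]) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a (optionally gzipped) multi-FASTA."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    name: str | None = None
    chunks: list[str] = []
    with opener(path, "rt") as handle:
        for line in handle:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first FASTA header")
                chunks.append(line)
    if name is None:
        raise ValueError(f"{path}: empty or unreadable FASTA")
    yield name, "".join(chunks)


def summarize_digest(
    genome: Union[str, Path, Iterable[tuple[str, str]]],
    enzyme: RestrictionEnzyme,
    window_lo: int,
    window_hi: int,
    include_terminal: bool = False,
) -> DigestSummary:
    """Digest every sequence of a multi-FASTA (path or (name, seq) pairs)."""
    if isinstance(genome, (str, Path)):
        genome = iter_fasta(genome)
    summary = DigestSummary(enzyme, window_lo, window_hi, include_terminal)
    for name, seq in genome:
        cuts = find_sites(seq, enzyme)
        summary.site_counts[name] = len(cuts)
        summary.fragment_lengths[name] = fragments_from_cuts(
            cuts, len(seq), include_terminal
        )
    return summary


def summarize_from_cut_positions(
    cuts_by_chrom: dict[str, list[int]],
    chrom_lengths: dict[str, int],
    enzyme: RestrictionEnzyme,
    window_lo: int,
    window_hi: int,
    include_terminal: bool = False,
) -> DigestSummary:
    """Build a :class:`DigestSummary` from precomputed cut coordinates.

    Used when the sequence itself is unavailable but its site map is, e.g.
    a site catalogue extracted once from a reference genome.
    """
    summary = DigestSummary(enzyme, window_lo, window_hi, include_terminal)
    for chrom, cuts in cuts_by_chrom.items():
        summary.site_counts[chrom] = len(cuts)
        summary.fragment_lengths[chrom] = fragments_from_cuts(
            sorted(cuts), chrom_lengths[chrom], include_terminal
        )
    return summary


def tag_yield_check(summary: DigestSummary, lo: int = 100_000, hi: int = 150_000) -> bool:
    """PASS (True) iff the windowed fragment count is inside [lo, hi]."""
    return lo <= summary.n_in_window <= hi
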