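"""Quality trimming and percentage-based read filtering.

Reads are processed in three steps: terminal low-quality bases are trimmed
from both ends, reads shorter than a minimum post-trim length are dropped,
and the survivors are classified against one of four named filtering
standards. Each standard is a disjunction of "more than X percent of bases
below quality Q" conditions; a read is discarded as soon as any condition
holds. Fractions are compared with strict inequality and base qualities
with strict ``Q < cutoff`` (boundary reads are kept).
"""

from __future__ import annotations

import enum
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union


class FilterStandard(enum.Enum):
    """Named read-filtering standards, strictest to most permissive."""

    STRICT = "strict"
    MODERATE = "moderate"
    RELAX = "relax"
    NOTFILTER = "none"


#: (quality cutoff, maximum tolerated fraction of bases with Q < cutoff).
#: A read is discarded when, for any pair, frac(Q < cutoff) > max_fraction.
STANDARD_CONDITIONS: dict[FilterStandard, tuple[tuple[int, float], ...]] = {
    FilterStandard.STRICT: ((10, 0.07), (13, 0.07), (20, 0.15)),
    FilterStandard.MODERATE: ((10, 0.10), (13, 0.14), (20, 0.20)),
    FilterStandard.RELAX: ((10, 0.15), (13, 0.20)),
    FilterStandard.NOTFILTER: (),
}


class InvalidRecordError(ValueError):
    """A FASTQ record violates its structural invariants."""


@dataclass(frozen=True)
class SequenceRead:
    """One FASTQ record: identifier, bases and per-base Phred qualities."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise InvalidRecordError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 for q in self.quals):
            raise InvalidRecordError(f"read {self.read_id!r}: negative quality")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class FilterPolicy:
    """How to trim and which standard to filter with."""

    standard: FilterStandard = FilterStandard.RELAX
    trim_end_quality: int = 20
    min_length_after_trim: int = 50

    def __post_init__(self) -> None:
        if self.min_length_after_trim < 1:
            raise ValueError("min_length_after_trim must be >= 1")
        if self.trim_end_quality < 0:
            raise ValueError("trim_end_quality must be >= 0")


@dataclass
class FilterStats:
    """Conservation-checked tallies for one filtering run."""

    n_input: int = 0
    n_discarded_length: int = 0
    n_discarded_quality: int = 0
    n_retained: int = 0
    bases_trimmed: int = 0

    def check(self) -> None:
        assert (
            self.n_input
            == self.n_retained + self.n_discarded_quality + self.n_discarded_length
        )

    def as_tsv(self) -> str:
        rows = [
            ("n_input", self.n_input),
            ("n_discarded_length", self.n_discarded_length),
            ("n_discarded_quality", self.n_discarded_quality),
            ("n_retained", self.n_retained),
            ("bases_trimmed", self.bases_trimmed),
        ]
        return "".join(f"{k}\t{v}\n" for k, v in rows)


def trim_read(read: SequenceRead, q: int) -> SequenceRead:
    """Trim terminal runs of bases with quality < ``q`` from both ends.

    Interior low-quality bases are kept; only the maximal low-quality runs
    at the 5' and 3' ends are removed. May return an empty read.
    """
    lo = 0
    hi = len(read.quals)
    while lo < hi and read.quals[lo] < q:
        lo += 1
    while hi > lo and read.quals[hi - 1] < q:
        hi -= 1
    if lo == 0 and hi == len(read.quals):
        return read
    return SequenceRead(read.read_id, read.bases[lo:hi], read.quals[lo:hi])


def passes_length(read: SequenceRead, min_len: int) -> bool:
    """True iff the (already trimmed) read retains at least ``min_len`` bases."""
    return len(read) >= min_len


def classify_read(read: SequenceRead, standard: FilterStandard) -> bool:
    """Return True to KEEP the read, False to DISCARD it.

    Raises on empty reads: the per-base fractions are undefined.
    """
    if len(read) == 0:
        raise InvalidRecordError(f"read {read.read_id!r}: empty read has no quality fractions")
    n = len(read)
    for cutoff, max_frac in STANDARD_CONDITIONS[standard]:
        n_below = sum(1 for q in read.quals if q < cutoff)
        if n_below / n > max_frac:
            return False
    return True


# ---------------------------------------------------------------------------
# FASTQ I/O


def _open_text(path: Union[str, Path], mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(handle: Iterable[str], phred_offset: int = 33) -> Iterator[SequenceRead]:
    """Parse 4-line FASTQ records, raising on structural problems."""
    lines = iter(handle)
    idx = 0
    while True:
        try:
            header = next(lines)
        except StopIteration:
            return
        header = header.rstrip("\n")
        try:
            bases = next(lines).rstrip("\n")
            plus = next(lines).rstrip("\n")
            quals = next(lines).rstrip("\n")
        except StopIteration:
            raise InvalidRecordError(f"truncated FASTQ record at index {idx}") from None
        if not header.startswith("@") or not plus.startswith("+"):
            raise InvalidRecordError(f"malformed FASTQ record at index {idx}")
        try:
            yield SequenceRead(
                header[1:].split()[0] if len(header) > 1 else "",
                bases,
                tuple(ord(c) - phred_offset for c in quals),
            )
        except InvalidRecordError as exc:
            raise InvalidRecordError(f"record index {idx}: {exc}") from None
        idx += 1


def write_fastq(reads: Iterable[SequenceRead], handle: IO[str], phred_offset: int = 33) -> None:
    for r in reads:
        qual_str = "".join(chr(q + phred_offset) for q in r.quals)
        handle.write(f"@{r.read_id}\n{r.bases}\n+\n{qual_str}\n")


def filter_reads(
    reads: Iterable[SequenceRead],
    policy: FilterPolicy,
    stats: FilterStats | None = None,
) -> Iterator[SequenceRead]:
    """Trim, length-check and classify each read; yields retained reads.

    Pass a :class:`FilterStats` to collect tallies; it is updated in place
    as the stream is consumed.
    """
    if stats is None:
        stats = FilterStats()
    for read in reads:
        stats.n_input += 1
        trimmed = trim_read(read, policy.trim_end_quality)
        stats.bases_trimmed += len(read) - len(trimmed)
        if not passes_length(trimmed, policy.min_length_after_trim):
            stats.n_discarded_length += 1
            continue
        if not classify_read(trimmed, policy.standard):
            stats.n_discarded_quality += 1
            continue
        stats.n_retained += 1
        yield trimmed


def filter_fastq(
    in_path: Union[str, Path],
    out_path: Union[str, Path],
    policy: FilterPolicy,
    phred_offset: int = 33,
) -> FilterStats:
    """File-to-file filtering; returns the conservation-checked stats."""
    stats = FilterStats()
    with _open_text(in_path) as fin, _open_text(out_path, "wt") as fout:
        write_fastq(
            filter_reads(read_fastq(fin, phred_offset), policy, stats),
            fout,
            phred_offset,
        )
    stats.check()
    return stats
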