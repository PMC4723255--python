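"""samtools pileup/mpileup text parsing into per-position allele summaries.

This is the hand-off point from external alignment into the calling logic:
all downstream thresholds operate on the counts decoded here. The bases
column is decoded per the samtools conventions: ``.``/``,`` reference
match, ``ACGTacgt`` mismatch, ``+<n><seq>``/``-<n><seq>`` insertion or
deletion attached to the preceding read observation, ``^`` consumes the
following mapping-quality character, ``$`` marks a read end, and ``*``,
``>``, ``<`` and ``N`` are counted as skipped observations.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union


class PileupParseError(ValueError):
    """A pileup line could not be decoded."""


_SNP_BASES = frozenset("ACGTacgt")
_SKIP = frozenset("*><Nn")


@dataclass
class PileupSite:
    """One genomic position's base-call summary.

    ``base_counts`` maps alleles to observation counts. SNP alleles are the
    uppercase base; insertion/deletion alleles are keyed ``ins:<SEQ>`` /
    ``del:<SEQ>``. SNP mismatch counts partition the depth together with
    ``n_ref`` and ``n_skipped``; indel observations ride along with the
    (usually reference-matching) read they follow and are counted in
    addition, so they do not enter the depth partition.
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    depth: int
    base_counts: dict[str, int] = field(default_factory=dict)
    n_ref: int = 0
    n_skipped: int = 0

    @property
    def n_snp_mut(self) -> int:
        """Mismatching base observations (depth minus ref minus skipped)."""
        return self.depth - self.n_ref - self.n_skipped

    @property
    def n_indel_obs(self) -> int:
        return sum(
            c for a, c in self.base_counts.items() if a.startswith(("ins:", "del:"))
        )

    @property
    def total_mut_reads(self) -> int:
        """Reads carrying any non-reference signal (mismatch or indel).

        Indel events are attached to reference-matching observations, so
        mismatch and indel tallies count disjoint reads except for the rare
        read carrying both; that corner is accepted and documented.
        """
        return self.n_snp_mut + self.n_indel_obs

    def dominant_mutant(self) -> tuple[str, int] | None:
        """The single most frequent non-reference allele and its count.

        Ties break deterministically: SNP bases before indel alleles, then
        lexicographically.
        """
        if not self.base_counts:
            return None
        allele = min(
            self.base_counts,
            key=lambda a: (-self.base_counts[a], a.startswith(("ins:", "del:")), a),
        )
        return allele, self.base_counts[allele]


def site_mutant_ratio(site: PileupSite) -> float:
    """Fraction of reads supporting the dominant non-reference allele."""
    if site.depth == 0:
        raise ValueError(
            f"{site.chrom}:{site.pos}: mutant ratio undefined at zero depth"
        )
    dom = site.dominant_mutant()
    if dom is None:
        return 0.0
    return dom[1] / site.depth


def decode_bases_column(bases: str, ref_base: str) -> tuple[dict[str, int], int, int]:
    """Decode a pileup bases column into (base_counts, n_ref, n_skipped)."""
    # fast path: the overwhelmingly common all-reference line
    if not bases.strip(".,"):
        return {}, len(bases), 0
    counts: dict[str, int] = {}
    n_ref = 0
    n_skipped = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c in ".,":
            n_ref += 1
            i += 1
        elif c in _SNP_BASES:
            b = c.upper()
            counts[b] = counts.get(b, 0) + 1
            i += 1
        elif c in _SKIP:
            n_skipped += 1
            i += 1
        elif c == "^":
            if i + 1 >= n:
                raise PileupParseError("dangling '^' at end of bases column")
            i += 2  # '^' + mapping quality char
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"'{c}' not followed by a length")
            length = int(bases[i + 1 : j])
            seq = bases[j : j + length]
            if len(seq) < length:
                raise PileupParseError("indel sequence shorter than declared length")
            key = ("ins:" if c == "+" else "del:") + seq.upper()
            counts[key] = counts.get(key, 0) + 1
            i = j + length
        else:
            raise PileupParseError(f"unexpected character {c!r} in bases column")
    return counts, n_ref, n_skipped


def parse_pileup_line(
    line: str, line_number: int | None = None, min_base_quality: int = 0
) -> PileupSite:
    """Parse one 5- or 6-column samtools pileup line.

    With ``min_base_quality`` > 0, observations whose base quality
    (Phred+33, column 6) falls below the threshold are reclassified as
    skipped. Indel observations carry no per-event quality and are kept.
    """
    where = f"line {line_number}: " if line_number is not None else ""
    fields = line.rstrip("\n").split("\t")
    if len(fields) not in (5, 6):
        raise PileupParseError(
            f"{where}expected 5 or 6 tab-separated columns, got {len(fields)}"
        )
    chrom, pos_s, ref, depth_s, bases = fields[:5]
    quals = fields[5] if len(fields) == 6 else None
    try:
        pos = int(pos_s)
        depth = int(depth_s)
    except ValueError:
        raise PileupParseError(f"{where}non-integer position or depth") from None
    try:
        counts, n_ref, n_skipped = decode_bases_column(bases, ref)
    except PileupParseError as exc:
        raise PileupParseError(f"{where}{exc}") from None
    n_obs = n_ref + n_skipped + sum(
        c for a, c in counts.items() if not a.startswith(("ins:", "del:"))
    )
    if n_obs != depth:
        raise PileupParseError(
            f"{where}declared depth {depth} but decoded {n_obs} observations"
        )
    site = PileupSite(chrom, pos, ref.upper(), depth, counts, n_ref, n_skipped)
    if min_base_quality > 0 and quals is not None:
        _mask_low_quality(site, bases, quals, min_base_quality)
    return site


def _mask_low_quality(site: PileupSite, bases: str, quals: str, min_q: int) -> None:
    """Reclassify low-quality ref/SNP observations as skipped, in place."""
    obs_kinds: list[str] = []  # per depth-consuming observation: 'ref'/'skip'/base
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c in ".,":
            obs_kinds.append("ref")
            i += 1
        elif c in _SNP_BASES:
            obs_kinds.append(c.upper())
            i += 1
        elif c in _SKIP:
            obs_kinds.append("skip")
            i += 1
        elif c == "^":
            i += 2
        elif c == "$":
            i += 1
        else:  # indel
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            i = j + int(bases[i + 1 : j])
    for kind, qc in zip(obs_kinds, quals):
        if kind == "skip" or ord(qc) - 33 >= min_q:
            continue
        if kind == "ref":
            site.n_ref -= 1
        else:
            site.base_counts[kind] -= 1
            if site.base_counts[kind] == 0:
                del site.base_counts[kind]
        site.n_skipped += 1


def read_pileup(
    source: Union[str, Path, Iterable[str]], min_base_quality: int = 0
) -> Iterator[PileupSite]:
    """Iterate :class:`PileupSite` over a pileup file or line iterable."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            yield from read_pileup(handle, min_base_quality)
        return
    for i, line in enumerate(source, start=1):
        if line.strip():
            yield parse_pileup_line(line, i, min_base_quality)
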