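"""Genomic intervals and overlap arithmetic.

All coordinates inside the package are 0-based half-open, the convention of
BED and of ``range()``. Tabular inputs in the 1-based inclusive convention of
genome-browser displays and copy-number call tables are converted at the I/O
boundary (:func:`GenomicInterval.from_one_based` / :meth:`GenomicInterval.to_one_based`).

Chromosome labels are compared as normalized strings: a leading ``chr`` prefix
is stripped and the remainder upper-cased, so ``chr2``, ``Chr2`` and ``2``
denote the same chromosome. Genome-build labels (``hg18``, ``NCBI36``...) are
carried as informational strings; no liftover is performed. CNVs are
unstranded, so intervals carry no strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "AUTOSOMES",
    "GenomicInterval",
    "normalize_chrom",
    "chrom_sort_key",
    "length",
    "overlap_bp",
    "merge_union",
    "coverage_fraction",
    "best_single_fraction",
    "reciprocal_overlap",
]

#: Normalized labels of the human autosomes.
AUTOSOMES: frozenset[str] = frozenset(str(i) for i in range(1, 23))


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label: strip a leading ``chr`` (any case), upper-case the rest.

    >>> normalize_chrom("chr2"), normalize_chrom("Chr17"), normalize_chrom("x")
    ('2', '17', 'X')
    """
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.upper()


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Sort key placing numeric chromosomes first in numeric order, then others lexically."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A contiguous span on a named chromosome; the unit of all overlap arithmetic.

    Parameters
    ----------
    chrom : str
        Chromosome label; normalized on construction (``chr`` stripped).
    start, end : int
        0-based half-open coordinates; ``end`` must exceed ``start``
        (zero-length intervals are rejected).
    build : str
        Genome-build label, informational only (default ``"hg18"``).
    """

    chrom: str
    start: int
    end: int
    build: str = field(default="hg18", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval: start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        """Span in base pairs (``end - start``), strictly positive."""
        return self.end - self.start

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in AUTOSOMES

    @classmethod
    def from_one_based(cls, chrom: str, start: int, end: int, build: str = "hg18") -> "GenomicInterval":
        """Build from 1-based inclusive coordinates, the convention of call tables."""
        return cls(chrom, int(start) - 1, int(end), build)

    def to_one_based(self) -> tuple[int, int]:
        """Return (start, end) in 1-based inclusive coordinates."""
        return self.start + 1, self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def length(iv: GenomicInterval) -> int:
    """Base-pair length of *iv*."""
    return iv.length


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by *a* and *b*; 0 for different chromosomes. Symmetric."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_union(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse intervals into their union: per chromosome, sorted, pairwise disjoint.

    Abutting intervals (one ending exactly where the next starts) are merged:
    union coverage is a measure over base pairs and a 0-bp gap is no gap.
    Idempotent. Output order is (chromosome, start).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    builds: dict[str, str] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
        builds.setdefault(iv.chrom, iv.build)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        spans = sorted((iv.start, iv.end) for iv in by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:  # overlap or abutting
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e, builds[chrom]))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e, builds[chrom]))
    return merged


def coverage_fraction(target: GenomicInterval, others: Sequence[GenomicInterval]) -> float:
    """Fraction of *target* covered by the union of *others*, in [0, 1].

    Monotone nondecreasing as *others* grows; equals 1.0 when *others*
    contains *target* itself.
    """
    covered = 0
    for iv in merge_union(o for o in others if o.chrom == target.chrom):
        covered += overlap_bp(target, iv)
    return covered / target.length


def best_single_fraction(target: GenomicInterval, others: Sequence[GenomicInterval]) -> float:
    """Largest single-interval overlap with *target*, as a fraction of its length.

    Never exceeds :func:`coverage_fraction` on the same inputs; 0.0 when
    *others* is empty.
    """
    best = 0
    for o in others:
        best = max(best, overlap_bp(target, o))
    return best / target.length


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap of *a* and *b* expressed as a fraction of each interval's length."""
    ob = overlap_bp(a, b)
    return ob / a.length, ob / b.length
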