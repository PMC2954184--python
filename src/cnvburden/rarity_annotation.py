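"""Rarity classification against a population catalogue and locus annotation.

A call is *rare* when at most ``max_known_overlap`` (default 80%) of its
length is overlapped by previously catalogued variants — the threshold is
inclusive, so a call exactly 80% covered is still rare. Two readings of
"overlapped" are supported:

``union`` (default)
    fraction of the call covered by the union of all overlapping catalogue
    variants; a call 90% tiled by two known variants counts as known —
    conservative toward calling things rare.
``best_single``
    largest overlap with any single catalogue variant, for sensitivity
    analysis against the alternative reading.

Candidate-locus annotation records every prior-evidence region covering at
least ``locus_min_overlap`` (default 50%, non-strict) of the call's length.

Recurrent rare calls are grouped by single-linkage clustering: two rare calls
of the same state are linked when their reciprocal overlap is at least
``recurrence_reciprocal_overlap`` in *both* directions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .cnv_io import (
    CandidateLocus,
    CatalogueVariant,
    CnvCall,
    CnvDataset,
    CnvState,
    Group,
    VariantType,
)
from .genomic_intervals import (
    GenomicInterval,
    best_single_fraction,
    chrom_sort_key,
    coverage_fraction,
    reciprocal_overlap,
)

import logging

logger = logging.getLogger(__name__)

__all__ = ["RarityConfig", "RecurrentGroup", "annotate_rarity",
           "annotate_candidate_loci", "recurrent_rare_groups"]


@dataclass(frozen=True, slots=True)
class RarityConfig:
    max_known_overlap: float = 0.80
    overlap_mode: str = "union"  # or "best_single"
    type_matched: bool = False
    locus_min_overlap: float = 0.50
    recurrence_reciprocal_overlap: float = 0.50

    def __post_init__(self) -> None:
        for name in ("max_known_overlap", "locus_min_overlap", "recurrence_reciprocal_overlap"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.overlap_mode not in ("union", "best_single"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")


def _build_trees(intervals: Iterable[tuple[GenomicInterval, object]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
    return trees


def _type_compatible(call_state: CnvState, vtype: VariantType) -> bool:
    # MIXED catalogue records match either state; UNKNOWN matches neither
    # when type matching is requested (an untyped record carries no evidence
    # the same event type was seen before).
    if vtype is VariantType.MIXED:
        return True
    return vtype.name == call_state.name


def annotate_rarity(ds: CnvDataset, catalogue: Sequence[CatalogueVariant],
                    cfg: RarityConfig | None = None) -> CnvDataset:
    """Set ``known_overlap_fraction`` and ``is_rare`` on every call.

    Deterministic given inputs. Warns (does not fail) when the catalogue's
    build label differs from the dataset's.
    """
    cfg = cfg or RarityConfig()
    builds = {v.interval.build for v in catalogue}
    if builds and builds != {ds.build}:
        logger.warning("catalogue build %s differs from dataset build %s",
                       "/".join(sorted(builds)), ds.build)
    trees = _build_trees((v.interval, v) for v in catalogue)
    frac_of = coverage_fraction if cfg.overlap_mode == "union" else best_single_fraction
    annotated: list[CnvCall] = []
    for call in ds.calls:
        tree = trees.get(call.interval.chrom)
        if tree is None:
            frac = 0.0
        else:
            hits = [h.data for h in tree.overlap(call.interval.start, call.interval.end)]
            if cfg.type_matched:
                hits = [v for v in hits if _type_compatible(call.state, v.variant_type)]
            frac = frac_of(call.interval, [v.interval for v in hits])
        annotated.append(replace(call, known_overlap_fraction=frac,
                                 is_rare=frac <= cfg.max_known_overlap))
    return ds.with_calls(annotated)


def annotate_candidate_loci(ds: CnvDataset, loci: Sequence[CandidateLocus],
                            cfg: RarityConfig | None = None) -> CnvDataset:
    """Record, per call, every locus overlapping >= ``locus_min_overlap`` of the call."""
    cfg = cfg or RarityConfig()
    trees = _build_trees((l.interval, l) for l in loci)
    annotated: list[CnvCall] = []
    for call in ds.calls:
        tree = trees.get(call.interval.chrom)
        hits: list[str] = []
        if tree is not None:
            for h in tree.overlap(call.interval.start, call.interval.end):
                locus: CandidateLocus = h.data
                frac_of_call, _ = reciprocal_overlap(call.interval, locus.interval)
                if frac_of_call >= cfg.locus_min_overlap:
                    hits.append(locus.name)
        annotated.append(replace(call, locus_hits=tuple(sorted(hits))))
    return ds.with_calls(annotated)


@dataclass(frozen=True)
class RecurrentGroup:
    """A single-linkage cluster of mutually similar rare calls of one state."""

    calls: tuple[CnvCall, ...]
    case_subjects: tuple[str, ...]
    control_subjects: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return len(self.case_subjects) + len(self.control_subjects)

    @property
    def is_recurrent(self) -> bool:
        return self.n_subjects > 1


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def recurrent_rare_groups(ds: CnvDataset, cfg: RarityConfig | None = None) -> list[RecurrentGroup]:
    """Cluster rare calls by reciprocal overlap; report carriers per group.

    Single linkage: calls A and C sharing no direct overlap still cluster
    together when both match an intermediate call B at the threshold.
    Singleton clusters are included. Output order is deterministic
    (chromosome, start of the leftmost member).
    """
    cfg = cfg or RarityConfig()
    rare = [c for c in ds.calls if c.is_rare]
    if any(c.is_rare is None for c in ds.calls):
        raise ValueError("rarity annotation required before recurrence grouping")
    gm = {s.sample_id: s.group for s in ds.subjects}

    groups: list[RecurrentGroup] = []
    by_key: dict[tuple[str, CnvState], list[CnvCall]] = {}
    for c in rare:
        by_key.setdefault((c.interval.chrom, c.state), []).append(c)
    for key in sorted(by_key, key=lambda k: (chrom_sort_key(k[0]), k[1].value)):
        members = sorted(by_key[key], key=lambda c: (c.interval.start, c.interval.end, c.call_id))
        uf = _UnionFind(len(members))
        for i, a in enumerate(members):
            for j in range(i + 1, len(members)):
                b = members[j]
                if b.interval.start >= a.interval.end:
                    break  # sorted by start: no later call can overlap a
                fa, fb = reciprocal_overlap(a.interval, b.interval)
                if fa >= cfg.recurrence_reciprocal_overlap and fb >= cfg.recurrence_reciprocal_overlap:
                    uf.union(i, j)
        clusters: dict[int, list[CnvCall]] = {}
        for i, c in enumerate(members):
            clusters.setdefault(uf.find(i), []).append(c)
        for root in sorted(clusters, key=lambda r: members[r].interval.start):
            cs = clusters[root]
            cases = sorted({c.sample_id for c in cs if gm[c.sample_id] is Group.CASE})
            controls = sorted({c.sample_id for c in cs if gm[c.sample_id] is Group.CONTROL})
            groups.append(RecurrentGroup(tuple(cs), tuple(cases), tuple(controls)))
    return groups
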