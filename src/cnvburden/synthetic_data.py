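"""Synthetic case-control CNV cohorts with known ground truth.

The generator emulates the structure of an SNP-array CNV callset from a
case-control schizophrenia cohort: Poisson per-person call counts with
group-specific rates, a group-specific deletion/duplication mix, heavy-tailed
(log-normal) call sizes, marker counts consistent with a dense genotyping
array, and a controllable fraction of calls copied verbatim from a
population-variant catalogue (hence classified "known") versus placed in
regions with zero catalogue coverage (hence "rare").

Defaults are shaped after a published cohort of 172 cases and 160 controls
with ~12.6 calls/person, a rare fraction near 4.3%, median call size ~205 kb
and a maximum around 2.5 Mb. "Known" calls are *exact* catalogue copies, so
rarity ground truth is unambiguous at any overlap threshold; an optional
jitter shifts the copies for threshold-sensitivity experiments.

Every generated call passes the default retention filter by construction
(lengths are truncated above 100 kb and marker counts follow the array
density), so a filter pass over synthetic data must drop nothing.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .cnv_io import (
    CatalogueVariant,
    CnvCall,
    CnvDataset,
    CnvState,
    Group,
    SubjectRecord,
    VariantType,
)
from .genomic_intervals import GenomicInterval, merge_union

__all__ = ["HG18_AUTOSOME_SIZES", "SyntheticConfig", "TruthRecord",
           "generate_catalogue", "generate_dataset", "recover_parameters"]

#: Approximate autosome lengths (bp) of the NCBI36/hg18 assembly; informational
#: placement bounds for the simulator, not a liftover resource.
HG18_AUTOSOME_SIZES: dict[str, int] = {
    "1": 247_249_719, "2": 242_951_149, "3": 199_501_827, "4": 191_273_063,
    "5": 180_857_866, "6": 170_899_992, "7": 158_821_424, "8": 146_274_826,
    "9": 140_273_252, "10": 135_374_737, "11": 134_452_384, "12": 132_349_534,
    "13": 114_142_980, "14": 106_368_585, "15": 100_338_915, "16": 88_827_254,
    "17": 78_774_742, "18": 76_117_153, "19": 63_811_651, "20": 62_435_964,
    "21": 46_944_323, "22": 49_691_432,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for a synthetic cohort.

    rate_lambda_case / rate_lambda_control
        Poisson mean calls per person per group (defaults 12.7 / 12.5).
    loss_prob_case / loss_prob_control
        Probability a call is a deletion (defaults 0.35 / 0.33).
    length_log_mean / length_log_sd
        Natural-log parameters of the log-normal call length in bp
        (median ~205 kb, log-sd 0.7), truncated below at
        ``min_length_bp`` + 1 so every call passes the default filter.
    marker_density_bp
        Mean inter-marker distance used to assign marker counts (1500 bp,
        a dense-genotyping-array figure; implies spacing far below the
        10 kb retention limit).
    frac_known
        Probability a call is copied from a catalogue region (default
        0.957, i.e. a rare fraction near 4.3%).
    jitter_bp
        When positive, catalogue copies are shifted by a uniform offset in
        [-jitter_bp, +jitter_bp] (for overlap-threshold sensitivity tests).
    catalogue_size
        Number of catalogue variants to simulate.
    chrom_sizes
        Map chromosome label -> length in bp.
    """

    n_cases: int = 172
    n_controls: int = 160
    rate_lambda_case: float = 12.7
    rate_lambda_control: float = 12.5
    loss_prob_case: float = 0.35
    loss_prob_control: float = 0.33
    length_log_mean: float = float(np.log(205_000.0))
    length_log_sd: float = 0.7
    min_length_bp: int = 100_000
    marker_density_bp: float = 1_500.0
    min_markers: int = 25
    frac_known: float = 0.957
    jitter_bp: int = 0
    catalogue_size: int = 4_000
    chrom_sizes: dict[str, int] = field(default_factory=lambda: dict(HG18_AUTOSOME_SIZES))
    build: str = "hg18"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_prob_case", "loss_prob_control", "frac_known"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {v}")
        if self.rate_lambda_case <= 0 or self.rate_lambda_control <= 0:
            raise ValueError("Poisson rates must be positive")
        if any(size <= 0 for size in self.chrom_sizes.values()):
            raise ValueError("chromosome sizes must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True, slots=True)
class TruthRecord:
    """Ground truth for one generated call."""

    call_id: str
    from_catalogue: bool
    generating_region: str | None = None


def _draw_length(cfg: SyntheticConfig, rng: np.random.Generator, lo: int, hi: int) -> int:
    """Log-normal length truncated to (lo, hi] by resampling."""
    for _ in range(10_000):
        n = int(round(rng.lognormal(cfg.length_log_mean, cfg.length_log_sd)))
        if lo < n <= hi:
            return n
    raise RuntimeError("length truncation failed; check length/chromosome parameters")


def _pick_chrom(rng: np.random.Generator, chroms: list[str], weights: np.ndarray) -> str:
    return chroms[int(rng.choice(len(chroms), p=weights))]


def generate_catalogue(cfg: SyntheticConfig, rng: np.random.Generator) -> list[CatalogueVariant]:
    """Simulate a population-variant catalogue: uniform placement, log-normal sizes.

    Variant types are a mix of Loss/Gain/Unknown to exercise type-matched
    classification. Deterministic given the generator state.
    """
    chroms = sorted(cfg.chrom_sizes, key=lambda c: -cfg.chrom_sizes[c])
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    types = [VariantType.LOSS, VariantType.GAIN, VariantType.UNKNOWN]
    out: list[CatalogueVariant] = []
    for i in range(cfg.catalogue_size):
        chrom = _pick_chrom(rng, chroms, weights)
        clen = cfg.chrom_sizes[chrom]
        n = _draw_length(cfg, rng, cfg.min_length_bp, clen)
        start = int(rng.integers(0, clen - n + 1))
        vtype = types[int(rng.choice(3, p=[0.4, 0.4, 0.2]))]
        out.append(CatalogueVariant(f"CAT{i:06d}",
                                    GenomicInterval(chrom, start, start + n, cfg.build),
                                    vtype))
    return out


class _CataloguePlacer:
    """Placement helper: O(log n) zero-overlap checks against the merged catalogue."""

    def __init__(self, catalogue, chrom_sizes):
        merged = merge_union(v.interval for v in catalogue)
        self.starts: dict[str, list[int]] = {}
        self.ends: dict[str, list[int]] = {}
        for iv in merged:
            self.starts.setdefault(iv.chrom, []).append(iv.start)
            self.ends.setdefault(iv.chrom, []).append(iv.end)

    def clear_of_catalogue(self, chrom: str, start: int, end: int) -> bool:
        starts = self.starts.get(chrom)
        if not starts:
            return True
        i = bisect.bisect_left(starts, end)  # first catalogue iv starting at/after end
        if i == 0:
            return True
        return self.ends[chrom][i - 1] <= start  # previous iv must end before start


def _n_markers(cfg: SyntheticConfig, length: int, rng: np.random.Generator) -> int:
    return max(cfg.min_markers, int(round(length / cfg.marker_density_bp)) + 1)


def generate_dataset(cfg: SyntheticConfig, catalogue: list[CatalogueVariant],
                     rng: np.random.Generator,
                     max_placement_retries: int = 1_000) -> tuple[CnvDataset, list[TruthRecord]]:
    """Simulate the cohort callset.

    Per subject the call count is Poisson with the group's rate. Each call is,
    with probability ``frac_known``, an exact copy of a random catalogue
    interval (optionally jittered); otherwise it is placed so that it has
    zero catalogue overlap. Raises when a novel call cannot avoid a dense
    catalogue after ``max_placement_retries`` attempts (use larger
    chromosomes or a smaller catalogue).
    """
    chroms = sorted(cfg.chrom_sizes, key=lambda c: -cfg.chrom_sizes[c])
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    placer = _CataloguePlacer(catalogue, cfg.chrom_sizes)

    subjects = [SubjectRecord(f"case{i:04d}", Group.CASE) for i in range(1, cfg.n_cases + 1)]
    subjects += [SubjectRecord(f"ctrl{i:04d}", Group.CONTROL) for i in range(1, cfg.n_controls + 1)]

    calls: list[CnvCall] = []
    truth: list[TruthRecord] = []
    counter = 0
    for subj in subjects:
        lam = cfg.rate_lambda_case if subj.group is Group.CASE else cfg.rate_lambda_control
        loss_p = cfg.loss_prob_case if subj.group is Group.CASE else cfg.loss_prob_control
        k = int(rng.poisson(lam))
        for _ in range(k):
            counter += 1
            call_id = f"cnv{counter:06d}"
            state = CnvState.LOSS if rng.random() < loss_p else CnvState.GAIN
            if catalogue and rng.random() < cfg.frac_known:
                src = catalogue[int(rng.integers(len(catalogue)))]
                iv = src.interval
                if cfg.jitter_bp > 0:
                    clen = cfg.chrom_sizes[iv.chrom]
                    shift = int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1))
                    s = min(max(0, iv.start + shift), clen - iv.length)
                    iv = GenomicInterval(iv.chrom, s, s + iv.length, cfg.build)
                calls.append(CnvCall(call_id, subj.sample_id, iv, state,
                                     _n_markers(cfg, iv.length, rng)))
                truth.append(TruthRecord(call_id, True, src.accession))
            else:
                placed = False
                for _ in range(max_placement_retries):
                    chrom = _pick_chrom(rng, chroms, weights)
                    clen = cfg.chrom_sizes[chrom]
                    n = _draw_length(cfg, rng, cfg.min_length_bp, clen)
                    start = int(rng.integers(0, clen - n + 1))
                    if placer.clear_of_catalogue(chrom, start, start + n):
                        iv = GenomicInterval(chrom, start, start + n, cfg.build)
                        calls.append(CnvCall(call_id, subj.sample_id, iv, state,
                                             _n_markers(cfg, n, rng)))
                        truth.append(TruthRecord(call_id, False, None))
                        placed = True
                        break
                if not placed:
                    raise RuntimeError(
                        "could not place a novel call clear of the catalogue after "
                        f"{max_placement_retries} attempts; increase chrom_sizes or "
                        "reduce catalogue_size")
    return CnvDataset(tuple(subjects), tuple(calls), cfg.build), truth


@dataclass(frozen=True, slots=True)
class RecoveredParameters:
    """Point estimates of the generative parameters from an annotated dataset."""

    rate_case: float | None
    rate_control: float | None
    loss_fraction: float | None
    rare_fraction: float | None
    frac_known: float | None
    n_calls: int

    @property
    def defined(self) -> bool:
        return self.n_calls > 0


def recover_parameters(ds: CnvDataset, truth: list[TruthRecord] | None = None) -> RecoveredParameters:
    """Estimate per-group rates, the loss fraction, and the known fraction.

    ``frac_known`` comes from rarity annotation (1 - rare fraction) when the
    dataset is annotated, else from *truth* when supplied. With zero calls
    all estimates are None (flagged undefined) rather than raising.
    """
    n_cases = len(ds.subjects_in(Group.CASE))
    n_controls = len(ds.subjects_in(Group.CONTROL))
    n_calls = len(ds.calls)
    rate_case = len(ds.calls_in(Group.CASE)) / n_cases if n_cases else None
    rate_control = len(ds.calls_in(Group.CONTROL)) / n_controls if n_controls else None
    if n_calls == 0:
        return RecoveredParameters(rate_case, rate_control, None, None, None, 0)
    loss_fraction = sum(1 for c in ds.calls if c.state is CnvState.LOSS) / n_calls
    rare_fraction = None
    if all(c.is_rare is not None for c in ds.calls):
        rare_fraction = sum(1 for c in ds.calls if c.is_rare) / n_calls
    elif truth is not None:
        rare_fraction = sum(1 for t in truth if not t.from_catalogue) / len(truth)
    frac_known = None if rare_fraction is None else 1.0 - rare_fraction
    return RecoveredParameters(rate_case, rate_control, loss_fraction,
                               rare_fraction, frac_known, n_calls)
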