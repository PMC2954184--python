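"""Call-retention filters and subject-QC exclusion, with per-rule accounting.

The retention rules mirror a conservative SNP-array CNV post-processing
scheme: keep autosomal calls strictly larger than 100 kb, supported by at
least 25 markers, with mean inter-marker spacing strictly below 10 kb.
"Larger than" and "lower than" are strict inequalities; "at least" is not.
Rules are evaluated in a fixed order (autosome, length, markers, density) and
each dropped call is attributed to the first rule it fails; the retained set
itself does not depend on that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .cnv_io import CnvCall, CnvDataset

__all__ = [
    "FilterConfig",
    "FilterAudit",
    "RULE_ORDER",
    "mean_marker_spacing",
    "apply_call_filters",
    "apply_subject_qc",
]

RULE_ORDER = ("autosome", "length", "markers", "density")


@dataclass(frozen=True, slots=True)
class FilterConfig:
    """Thresholds for call retention.

    min_length_bp
        Calls must be strictly longer than this (default 100 kb).
    min_markers
        At least this many supporting probes (default 25, non-strict).
    max_mean_spacing_bp
        Mean inter-marker spacing strictly below this (default 10 kb).
    autosomes_only
        Drop sex-chromosome calls (default True).
    apply_subject_qc
        Whether the pipeline also removes QC-failing subjects (default True).
    """

    min_length_bp: int = 100_000
    min_markers: int = 25
    max_mean_spacing_bp: int = 10_000
    autosomes_only: bool = True
    apply_subject_qc: bool = True

    def __post_init__(self) -> None:
        if min(self.min_length_bp, self.min_markers, self.max_mean_spacing_bp) <= 0:
            raise ValueError("filter thresholds must be positive")


@dataclass(frozen=True)
class FilterAudit:
    """Accounting for one filter pass: input = retained + sum(dropped_by_rule)."""

    input_calls: int
    retained: int
    dropped_by_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.input_calls != self.retained + sum(self.dropped_by_rule.values()):
            raise ValueError("audit counts do not balance")


def mean_marker_spacing(call: CnvCall) -> float:
    """Average distance between adjacent markers: length / (n_markers - 1) gaps.

    A single-marker call has no gaps; its spacing is +inf, so it always fails
    the density rule.
    """
    if call.n_markers < 2:
        return math.inf
    return call.length / (call.n_markers - 1)


def _first_failing_rule(call: CnvCall, cfg: FilterConfig) -> str | None:
    if cfg.autosomes_only and not call.interval.is_autosomal:
        return "autosome"
    if not call.length > cfg.min_length_bp:
        return "length"
    if not call.n_markers >= cfg.min_markers:
        return "markers"
    if not mean_marker_spacing(call) < cfg.max_mean_spacing_bp:
        return "density"
    return None


def apply_call_filters(ds: CnvDataset, cfg: FilterConfig | None = None) -> tuple[CnvDataset, FilterAudit]:
    """Retain calls passing every rule in *cfg*; idempotent and threshold-monotone."""
    cfg = cfg or FilterConfig()
    kept: list[CnvCall] = []
    dropped = {rule: 0 for rule in RULE_ORDER}
    for call in ds.calls:
        rule = _first_failing_rule(call, cfg)
        if rule is None:
            kept.append(call)
        else:
            dropped[rule] += 1
    audit = FilterAudit(
        input_calls=len(ds.calls),
        retained=len(kept),
        dropped_by_rule={r: n for r, n in dropped.items() if n},
    )
    return ds.with_calls(kept), audit


def apply_subject_qc(ds: CnvDataset) -> tuple[CnvDataset, list[str]]:
    """Remove subjects whose array QC failed, together with all their calls.

    Returns the reduced dataset and the excluded sample ids (manifest order).
    """
    excluded = [s.sample_id for s in ds.subjects if not s.qc_pass]
    if not excluded:
        return ds, []
    bad = set(excluded)
    subjects = tuple(s for s in ds.subjects if s.sample_id not in bad)
    calls = tuple(c for c in ds.calls if c.sample_id not in bad)
    return CnvDataset(subjects, calls, ds.build), excluded
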