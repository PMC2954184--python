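"""Readers, writers and domain records for the CNV burden pipeline.

External file formats
---------------------
Call table (TSV, ``tsv`` dialect)
    Columns ``sample_id  chrom  start  end  state  n_markers`` with 1-based
    inclusive coordinates and state tokens ``Loss``/``Gain`` (case-insensitive;
    ``del``/``dup`` synonyms accepted). Optional annotation columns
    ``known_overlap_fraction``, ``is_rare``, ``locus_hits`` survive a
    write/read round trip. Copy-neutral rows are dropped with a logged count.
Call table (``bed`` dialect)
    BED5: 0-based half-open, ``name`` = ``sample_id|state``, ``score`` =
    marker count; an optional leading ``track`` line is ignored on read.
Subject manifest (TSV)
    ``sample_id  group`` plus optional array-QC metrics ``contrast_qc`` and
    ``mapd``. A subject fails QC when contrast QC <= 0.4 or MAPD >= 0.4
    (boundary values fail); subjects without metrics pass.
Known-variant catalogue (TSV)
    ``accession  chrom  start  end [type]``, 1-based inclusive, in the style
    of a Database of Genomic Variants (DGV) release export. Unrecognized type
    tokens become UNKNOWN; duplicate rows are kept (deduplication is the
    caller's choice).
Candidate loci (BED)
    ``chrom  start  end  name [evidence]``, 0-based half-open.
"""

from __future__ import annotations

import enum
import io
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import pandas as pd

from .genomic_intervals import GenomicInterval, chrom_sort_key

logger = logging.getLogger(__name__)

Source = Union[str, Path, IO[str]]

__all__ = [
    "CnvState",
    "Group",
    "VariantType",
    "CnvCall",
    "SubjectRecord",
    "CnvDataset",
    "CatalogueVariant",
    "CandidateLocus",
    "read_cnv_table",
    "read_subject_manifest",
    "read_catalogue",
    "read_candidate_loci",
    "write_cnv_table",
    "write_subject_manifest",
    "write_ucsc_bed",
    "write_report",
    "CONTRAST_QC_MAX_FAIL",
    "MAPD_MIN_FAIL",
]

# Array-QC exclusion thresholds: contrast QC at or below 0.4 fails,
# MAPD at or above 0.4 fails (boundaries are failures on both).
CONTRAST_QC_MAX_FAIL = 0.4
MAPD_MIN_FAIL = 0.4


class CnvState(enum.Enum):
    """Copy-number state of a call: deletion (LOSS) or duplication (GAIN)."""

    LOSS = "Loss"
    GAIN = "Gain"


class Group(enum.Enum):
    CASE = "case"
    CONTROL = "control"


class VariantType(enum.Enum):
    """Type of a catalogue variant; records without a usable type are UNKNOWN."""

    LOSS = "Loss"
    GAIN = "Gain"
    MIXED = "Mixed"
    UNKNOWN = "Unknown"


_STATE_TOKENS = {
    "loss": CnvState.LOSS, "del": CnvState.LOSS, "deletion": CnvState.LOSS,
    "gain": CnvState.GAIN, "dup": CnvState.GAIN, "duplication": CnvState.GAIN,
}
_NEUTRAL_TOKENS = {"neutral", "normal", "diploid", "cn=2", "2"}
_VTYPE_TOKENS = {
    "loss": VariantType.LOSS, "del": VariantType.LOSS, "deletion": VariantType.LOSS,
    "gain": VariantType.GAIN, "dup": VariantType.GAIN, "duplication": VariantType.GAIN,
    "insertion": VariantType.GAIN,
    "mixed": VariantType.MIXED, "both": VariantType.MIXED, "gain+loss": VariantType.MIXED,
}
_GROUP_TOKENS = {
    "case": Group.CASE, "patient": Group.CASE, "cases": Group.CASE,
    "control": Group.CONTROL, "ctrl": Group.CONTROL, "controls": Group.CONTROL,
}


@dataclass(frozen=True, slots=True)
class CnvCall:
    """One deletion/duplication event in one subject, with marker support.

    ``known_overlap_fraction``, ``is_rare`` and ``locus_hits`` are annotation
    slots filled by the rarity/locus annotation stage; they default to unset.
    """

    call_id: str
    sample_id: str
    interval: GenomicInterval
    state: CnvState
    n_markers: int
    known_overlap_fraction: float | None = None
    is_rare: bool | None = None
    locus_hits: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError(f"call {self.call_id}: n_markers must be >= 1")
        f = self.known_overlap_fraction
        if f is not None and not (0.0 <= f <= 1.0):
            raise ValueError(f"call {self.call_id}: overlap fraction {f} outside [0,1]")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True, slots=True)
class SubjectRecord:
    """A study subject with group membership and array-QC status."""

    sample_id: str
    group: Group
    qc_pass: bool = True
    contrast_qc: float | None = None
    mapd: float | None = None


@dataclass(frozen=True)
class CnvDataset:
    """Subject manifest plus calls; the object every pipeline stage transforms."""

    subjects: tuple[SubjectRecord, ...]
    calls: tuple[CnvCall, ...]
    build: str = "hg18"

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "calls", tuple(self.calls))
        ids = [s.sample_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample_id in subject manifest")
        known = set(ids)
        for c in self.calls:
            if c.sample_id not in known:
                raise ValueError(f"call {c.call_id}: unknown sample_id {c.sample_id!r}")
        cids = [c.call_id for c in self.calls]
        if len(cids) != len(set(cids)):
            raise ValueError("duplicate call_id in call set")

    def group_of(self, sample_id: str) -> Group:
        return self._group_map()[sample_id]

    def _group_map(self) -> dict[str, Group]:
        return {s.sample_id: s.group for s in self.subjects}

    def subjects_in(self, group: Group) -> tuple[SubjectRecord, ...]:
        return tuple(s for s in self.subjects if s.group is group)

    def calls_in(self, group: Group) -> tuple[CnvCall, ...]:
        gm = self._group_map()
        return tuple(c for c in self.calls if gm[c.sample_id] is group)

    def rare_subset(self) -> "CnvDataset":
        """Dataset restricted to calls flagged rare (annotation required)."""
        for c in self.calls:
            if c.is_rare is None:
                raise ValueError(f"call {c.call_id} has no rarity annotation")
        return replace(self, calls=tuple(c for c in self.calls if c.is_rare))

    def with_calls(self, calls: Iterable[CnvCall]) -> "CnvDataset":
        return replace(self, calls=tuple(calls))


@dataclass(frozen=True, slots=True)
class CatalogueVariant:
    """A known structural variant from a population catalogue (DGV-style)."""

    accession: str
    interval: GenomicInterval
    variant_type: VariantType = VariantType.UNKNOWN


@dataclass(frozen=True, slots=True)
class CandidateLocus:
    """A region previously implicated in the phenotype (e.g. NRXN1, 15q11.2)."""

    name: str
    interval: GenomicInterval
    evidence: str = ""


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _open_text(source: Source):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def _parse_state(token: str, line_no: int) -> CnvState | None:
    """Return the call state, None for copy-neutral tokens, raise otherwise."""
    t = str(token).strip().lower()
    if t in _STATE_TOKENS:
        return _STATE_TOKENS[t]
    if t in _NEUTRAL_TOKENS:
        return None
    raise ValueError(f"line {line_no}: unknown copy-number state token {token!r}")


def read_cnv_table(source: Source, dialect: str = "tsv", build: str = "hg18") -> list[CnvCall]:
    """Read a CNV call table; returns calls only (pair with a manifest for a dataset).

    ``tsv``: headered TSV, 1-based inclusive coordinates. ``bed``:
    BED5 as written by :func:`write_ucsc_bed`. Any size column is ignored
    (lengths are recomputed from coordinates). Copy-neutral rows are dropped;
    their count is logged.
    """
    if dialect == "bed":
        return _read_bed_calls(source, build)
    if dialect != "tsv":
        raise ValueError(f"unknown call-table dialect {dialect!r}")

    fh, close = _open_text(source)
    try:
        df = pd.read_csv(fh, sep="\t", dtype=str, comment="#")
    finally:
        if close:
            fh.close()
    required = ["sample_id", "chrom", "start", "end", "state", "n_markers"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"call table missing column(s): {', '.join(missing)}")

    has_ann = "known_overlap_fraction" in df.columns
    calls: list[CnvCall] = []
    n_neutral = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        d = row._asdict()
        state = _parse_state(d["state"], i)
        if state is None:
            n_neutral += 1
            continue
        try:
            start, end = int(d["start"]), int(d["end"])
            n_markers = int(d["n_markers"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"line {i}: malformed numeric field ({exc})") from None
        if end < start:
            raise ValueError(f"line {i}: end {end} precedes start {start}")
        iv = GenomicInterval.from_one_based(d["chrom"], start, end, build)
        call_id = str(d["call_id"]) if "call_id" in d and pd.notna(d["call_id"]) else f"cnv{i - 1:06d}"
        frac = None
        rare = None
        hits: tuple[str, ...] = ()
        if has_ann:
            fv = d.get("known_overlap_fraction")
            if fv is not None and pd.notna(fv) and str(fv) != "":
                frac = float(fv)
            rv = d.get("is_rare")
            if rv is not None and pd.notna(rv) and str(rv) != "":
                rare = str(rv).strip().lower() in ("true", "1", "yes")
            hv = d.get("locus_hits")
            if hv is not None and pd.notna(hv) and str(hv) != "":
                hits = tuple(str(hv).split(","))
        calls.append(CnvCall(call_id, str(d["sample_id"]), iv, state, n_markers,
                             known_overlap_fraction=frac, is_rare=rare, locus_hits=hits))
    if n_neutral:
        logger.warning("dropped %d copy-neutral row(s) from call table", n_neutral)
    return calls


def _read_bed_calls(source: Source, build: str) -> list[CnvCall]:
    fh, close = _open_text(source)
    calls: list[CnvCall] = []
    try:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"line {i}: expected >=5 BED fields, got {len(parts)}")
            chrom, start, end, name, score = parts[:5]
            try:
                iv = GenomicInterval(chrom, int(start), int(end), build)
                n_markers = int(score)
            except ValueError as exc:
                raise ValueError(f"line {i}: {exc}") from None
            if "|" not in name:
                raise ValueError(f"line {i}: BED name field must be sample_id|state")
            sample_id, state_tok = name.rsplit("|", 1)
            state = _parse_state(state_tok, i)
            if state is None:
                continue
            calls.append(CnvCall(f"cnv{len(calls) + 1:06d}", sample_id, iv, state, n_markers))
    finally:
        if close:
            fh.close()
    return calls


def _qc_pass(contrast_qc: float | None, mapd: float | None) -> bool:
    if contrast_qc is not None and contrast_qc <= CONTRAST_QC_MAX_FAIL:
        return False
    if mapd is not None and mapd >= MAPD_MIN_FAIL:
        return False
    return True


def read_subject_manifest(source: Source) -> list[SubjectRecord]:
    """Read a subject manifest TSV into :class:`SubjectRecord` rows.

    Group tokens parse case-insensitively (``case``/``patient``,
    ``control``/``ctrl``). ``qc_pass`` is computed from the QC metrics when
    present and defaults to True when absent.
    """
    fh, close = _open_text(source)
    try:
        df = pd.read_csv(fh, sep="\t", dtype=str, comment="#")
    finally:
        if close:
            fh.close()
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"subject manifest missing column {col!r}")
    subjects: list[SubjectRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        sid = str(d["sample_id"])
        if sid in seen:
            raise ValueError(f"line {i}: duplicate sample_id {sid!r}")
        seen.add(sid)
        gtok = str(d["group"]).strip().lower()
        if gtok not in _GROUP_TOKENS:
            raise ValueError(f"line {i}: unknown group token {d['group']!r}")
        cq = d.get("contrast_qc")
        cq = float(cq) if cq is not None and pd.notna(cq) and str(cq) != "" else None
        md = d.get("mapd")
        md = float(md) if md is not None and pd.notna(md) and str(md) != "" else None
        subjects.append(SubjectRecord(sid, _GROUP_TOKENS[gtok], _qc_pass(cq, md), cq, md))
    return subjects


def read_catalogue(source: Source, build: str = "hg18") -> list[CatalogueVariant]:
    """Read a DGV-style known-variant catalogue TSV (1-based inclusive coordinates).

    Unparseable type tokens are retained as UNKNOWN; verbatim duplicate rows
    are both kept.
    """
    fh, close = _open_text(source)
    try:
        df = pd.read_csv(fh, sep="\t", dtype=str, comment="#")
    finally:
        if close:
            fh.close()
    for col in ("accession", "chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"catalogue missing column {col!r}")
    out: list[CatalogueVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            start, end = int(d["start"]), int(d["end"])
        except (TypeError, ValueError):
            raise ValueError(f"line {i}: malformed coordinates "
                             f"({d['start']!r}, {d['end']!r})") from None
        if end < start:
            raise ValueError(f"line {i}: end {end} precedes start {start}")
        vtype = VariantType.UNKNOWN
        tok = d.get("type")
        if tok is not None and pd.notna(tok):
            vtype = _VTYPE_TOKENS.get(str(tok).strip().lower(), VariantType.UNKNOWN)
        out.append(CatalogueVariant(str(d["accession"]),
                                    GenomicInterval.from_one_based(d["chrom"], start, end, build),
                                    vtype))
    return out


def read_candidate_loci(source: Source, build: str = "hg18") -> list[CandidateLocus]:
    """Read candidate loci from BED (0-based half-open) with a mandatory name field."""
    fh, close = _open_text(source)
    loci: list[CandidateLocus] = []
    names: set[str] = set()
    try:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"line {i}: candidate-locus BED needs chrom/start/end/name")
            chrom, start, end, name = parts[:4]
            if name in names:
                raise ValueError(f"line {i}: duplicate locus name {name!r}")
            names.add(name)
            evidence = parts[4] if len(parts) > 4 else ""
            loci.append(CandidateLocus(name, GenomicInterval(chrom, int(start), int(end), build), evidence))
    finally:
        if close:
            fh.close()
    return loci


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _open_sink(sink: Source):
    if isinstance(sink, (str, Path)):
        return open(sink, "w", encoding="utf-8"), True
    return sink, False


def _call_sort_key(c: CnvCall):
    return (chrom_sort_key(c.interval.chrom), c.interval.start, c.interval.end, c.sample_id)


def write_cnv_table(calls: Sequence[CnvCall], sink: Source) -> None:
    """Write calls as a ``tsv`` TSV (1-based inclusive), annotations included.

    Row order is deterministic (chromosome, start, end, sample). Unset
    annotation fields are written as empty strings.
    """
    fh, close = _open_sink(sink)
    try:
        fh.write("call_id\tsample_id\tchrom\tstart\tend\tstate\tn_markers\t"
                 "known_overlap_fraction\tis_rare\tlocus_hits\n")
        for c in sorted(calls, key=_call_sort_key):
            s1, e1 = c.interval.to_one_based()
            frac = "" if c.known_overlap_fraction is None else repr(c.known_overlap_fraction)
            rare = "" if c.is_rare is None else str(c.is_rare)
            fh.write(f"{c.call_id}\t{c.sample_id}\t{c.interval.chrom}\t{s1}\t{e1}\t"
                     f"{c.state.value}\t{c.n_markers}\t{frac}\t{rare}\t{','.join(c.locus_hits)}\n")
    finally:
        if close:
            fh.close()


def write_subject_manifest(subjects: Sequence[SubjectRecord], sink: Source) -> None:
    fh, close = _open_sink(sink)
    try:
        fh.write("sample_id\tgroup\tcontrast_qc\tmapd\n")
        for s in subjects:
            cq = "" if s.contrast_qc is None else repr(s.contrast_qc)
            md = "" if s.mapd is None else repr(s.mapd)
            fh.write(f"{s.sample_id}\t{s.group.value}\t{cq}\t{md}\n")
    finally:
        if close:
            fh.close()


def write_ucsc_bed(ds: CnvDataset, sink: Source, track_name: str = "cnv_calls") -> None:
    """Export calls as a genome-browser-loadable BED5 track.

    0-based half-open coordinates, ``name`` = ``sample_id|state``, ``score`` =
    marker count; deterministic row order (chrom, start, end, sample_id).
    """
    fh, close = _open_sink(sink)
    try:
        fh.write(f'track name={track_name} description="CNV calls ({ds.build})"\n')
        for c in sorted(ds.calls, key=_call_sort_key):
            fh.write(f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                     f"{c.sample_id}|{c.state.value}\t{c.n_markers}\n")
    finally:
        if close:
            fh.close()


def _fmt(value, kind: str) -> str:
    """Format a report number the way the study prints it; raw values live in JSON."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if kind == "count":
        return str(int(value))
    if kind == "ratio":
        return f"{value:.2f}"
    if kind == "rate":
        return f"{value:.1f}"
    if kind == "p":
        return f"{value:.3f}"
    return str(value)


def write_report(report, sink: Source, format: str = "tsv") -> None:
    """Serialize a burden report.

    ``tsv`` prints counts as integers, ratios to 2 decimals, rates to 1 and
    p-values to 3 (the study's printing conventions); ``json`` carries the
    full-precision values alongside the formatted strings.
    """
    rows = report.as_rows()  # list of (section, name, value, kind)
    if format == "json":
        payload = {
            "schema": "cnvburden-report-v1",
            "values": {f"{sec}.{name}": val for sec, name, val, _ in rows},
            "printed": {f"{sec}.{name}": _fmt(val, kind) for sec, name, val, kind in rows},
            "metadata": report.metadata,
        }
        fh, close = _open_sink(sink)
        try:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        finally:
            if close:
                fh.close()
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    fh, close = _open_sink(sink)
    try:
        fh.write("section\tstatistic\tvalue\n")
        for sec, name, val, kind in rows:
            fh.write(f"{sec}\t{name}\t{_fmt(val, kind)}\n")
    finally:
        if close:
            fh.close()
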