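import pytest

from cnvburden import (
    CnvCall,
    CnvDataset,
    CnvState,
    GenomicInterval,
    Group,
    SubjectRecord,
)

_COUNTER = {"n": 0}


def make_call(sample_id, chrom, start, end, state=CnvState.LOSS, n_markers=100,
              call_id=None, **kw):
    """Build a CnvCall with 0-based half-open coordinates and an auto id."""
    if call_id is None:
        _COUNTER["n"] += 1
        call_id = f"t{_COUNTER['n']:05d}"
    return CnvCall(call_id, sample_id, GenomicInterval(chrom, start, end),
                   state, n_markers, **kw)


def make_dataset(calls, case_ids=(), control_ids=()):
    """Dataset from explicit calls; subjects inferred plus any extra ids given."""
    case_ids = set(case_ids)
    control_ids = set(control_ids)
    for c in calls:
        if c.sample_id not in case_ids | control_ids:
            case_ids.add(c.sample_id)
    subjects = [SubjectRecord(s, Group.CASE) for s in sorted(case_ids)]
    subjects += [SubjectRecord(s, Group.CONTROL) for s in sorted(control_ids)]
    return CnvDataset(tuple(subjects), tuple(calls))


@pytest.fixture
def small_dataset():
    """Two cases, two controls, six well-formed autosomal calls >100 kb."""
    calls = [
        make_call("caseA", "1", 1_000_000, 1_200_000, CnvState.LOSS, 150),
        make_call("caseA", "2", 5_000_000, 5_300_000, CnvState.GAIN, 220),
        make_call("caseB", "2", 5_000_000, 5_300_000, CnvState.GAIN, 220),
        make_call("ctrlA", "3", 9_000_000, 9_150_000, CnvState.LOSS, 110),
        make_call("ctrlA", "4", 2_000_000, 2_400_000, CnvState.GAIN, 280),
        make_call("ctrlB", "5", 7_000_000, 7_250_000, CnvState.GAIN, 190),
    ]
    return make_dataset(calls, case_ids={"caseA", "caseB"},
                        control_ids={"ctrlA", "ctrlB"})
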