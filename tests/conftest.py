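import pytest

from morphokin.events import Cohort, EmbryoRecord, Stage, Symmetry, TransitionEvent


def cleave(t, count, sym=Symmetry.NOT_APPLICABLE, grade=None):
    if count == 2 and sym is Symmetry.NOT_APPLICABLE:
        sym = Symmetry.EQUAL
    return TransitionEvent(time_h=t, stage=Stage.CLEAVAGE, cell_count=count,
                           symmetry=sym, grade=grade)


def stage(t, s):
    return TransitionEvent(time_h=t, stage=s)


@pytest.fixture
def synchronous_record():
    """One full synchronous embryo with the canonical median timings."""
    return EmbryoRecord(
        embryo_id="e1",
        run_id="r1",
        events=[
            cleave(29.0, 2),
            cleave(38.7, 4),
            cleave(51.0, 8),
            stage(113.0, Stage.MORULA),
            stage(130.5, Stage.EARLY_BLASTOCYST),
            stage(159.5, Stage.BLASTOCYST),
        ],
    )


@pytest.fixture
def small_cohort(synchronous_record):
    direct = EmbryoRecord(
        embryo_id="e2", run_id="r1",
        events=[cleave(31.0, 3), stage(120.0, Stage.MORULA)],
    )
    reverse = EmbryoRecord(
        embryo_id="e3", run_id="r2",
        events=[cleave(28.0, 2), cleave(33.0, 1)],
        end_of_record_h=190.0,
    )
    return Cohort(records=[synchronous_record, direct, reverse])
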