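import numpy as np
import pytest

from g4ltr import (
    DEFAULT_PARAMS,
    GRun,
    PQSHit,
    Superfamily,
    TERecord,
    WILD_TYPE_MOTIFS,
)


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def motifs():
    return WILD_TYPE_MOTIFS


def make_hit(
    seq_id: str,
    start: int,
    strand: str = "+",
    score: float = 70.0,
    span: int = 30,
) -> PQSHit:
    """Minimal well-formed PQSHit for bookkeeping-level tests."""
    runs = tuple(
        GRun(start + i * 8, start + i * 8 + 3, 3) for i in range(4)
    )
    return PQSHit(
        seq_id=seq_id,
        start=start,
        end=start + span,
        strand=strand,
        runs=runs,
        loops=(5, 5, 5),
        tetrads=3,
        n_bulged=0,
        score=score,
    )


@pytest.fixture
def simple_te():
    """1 kb element, 100 nt LTRs at both ends."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("AT"), size=1000))
    return TERecord(
        te_id="TE0001",
        superfamily=Superfamily.GYPSY,
        sequence=seq,
        ltr5=(0, 100),
        ltr3=(900, 1000),
    )
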