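import numpy as np
import pytest

from stereorep.io import RearrangementRecord
from stereorep.stereotypes import ClanTable, SimilarityGroups, SubsetDefinition


def make_record(
    sequence_id: str,
    junction: str = "TGTGCAAGAGATTGG",
    v_call: str = "IGHV1-69*01",
    j_call: str = "IGHJ4*02",
    duplicate_count: int = 1,
    productive: bool = True,
    **kwargs,
) -> RearrangementRecord:
    """Record factory for unit tests; skips invariant validation so
    clustering tests can use arbitrary junction strings."""
    from stereorep.io import translate_junction

    try:
        cdr3 = translate_junction(junction)[1:-1]
    except ValueError:
        cdr3 = ""
    defaults = dict(
        sequence_id=sequence_id,
        v_call=v_call,
        j_call=j_call,
        junction_nt=junction,
        cdr3_aa=cdr3,
        duplicate_count=duplicate_count,
        productive=productive,
        isotype="IGHM",
        population_label="FM",
    )
    defaults.update(kwargs)
    return RearrangementRecord(**defaults)


@pytest.fixture
def groups() -> SimilarityGroups:
    return SimilarityGroups()


@pytest.fixture
def clans() -> ClanTable:
    return ClanTable()


@pytest.fixture
def demo_subsets() -> list[SubsetDefinition]:
    return [
        SubsetDefinition(
            subset_id="#A",
            cdr3_length_aa=13,
            pattern="ARDLGW",
            pattern_offset=2,
            clan="I",
            typical_v_genes=frozenset({"IGHV1-69"}),
        ),
        SubsetDefinition(
            subset_id="#B",
            cdr3_length_aa=17,
            pattern="GYYDSSG",
            pattern_offset=4,
            clan="I",
            typical_v_genes=frozenset({"IGHV1-2", "IGHV1-18"}),
        ),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
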