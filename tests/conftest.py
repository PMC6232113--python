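import numpy as np
import pandas as pd
import pytest

from simms.pathway_db import Subnetwork
from simms.preprocess import ExpressionMatrix, SurvivalTable


def make_survival(times, events, sample_ids=None) -> SurvivalTable:
    ids = sample_ids or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(pd.DataFrame(
        {"time": np.asarray(times, float), "event": np.asarray(events, int)},
        index=pd.Index(ids)))


def make_subnetwork(sid, nodes, edges, pathway=None) -> Subnetwork:
    canon = frozenset(tuple(sorted(e)) for e in edges)
    return Subnetwork(sid, pathway or sid.split(".")[0], frozenset(nodes),
                      canon)


@pytest.fixture
def toy_survival() -> SurvivalTable:
    """Six samples, all events, distinct times."""
    return make_survival([1, 2, 3, 4, 5, 6], [1] * 6)


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    genes = [f"g{i:02d}" for i in range(6)]
    samples = [f"s{i}" for i in range(6)]
    return ExpressionMatrix("toy", pd.DataFrame(
        rng.normal(size=(6, 6)), index=genes, columns=samples))


@pytest.fixture
def edge_list_file(tmp_path):
    """Small pathway interaction edge list with a comment, a duplicate pair
    (reversed), and a self-loop."""
    p = tmp_path / "interactions.tsv"
    p.write_text(
        "# pathway\tgene_a\tgene_b\n"
        "P1\tA\tB\n"
        "P1\tB\tC\n"
        "P1\tB\tA\n"   # duplicate of A-B, reversed
        "P1\tD\tD\n"   # self-loop
        "P2\tA\tX\n"
        "P2\tX\tY\n"
    )
    return p
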