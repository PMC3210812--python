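import io

import numpy as np
import pandas as pd
import pytest

from pdzscreen import gocluster

TOY_OBO = """\
format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: A
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: B
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000004
name: C
namespace: biological_process
is_a: GO:0000002 ! A
"""


@pytest.fixture(scope="session")
def toy_dag() -> gocluster.GoDag:
    """Chain R <- A <- C plus sibling R <- B."""
    return gocluster.parse_obo(io.StringIO(TOY_OBO))


@pytest.fixture(scope="session")
def toy_annotations() -> gocluster.AnnotationSet:
    ann = gocluster.AnnotationSet()
    ann.add("P1", "BP", "GO:0000004")   # induced {C, A, root}
    ann.add("P2", "BP", "GO:0000003")   # induced {B, root}
    ann.add("Proot", "BP", "GO:0000001")
    return ann


def spot_frame(net: np.ndarray, conc=None, slide_id: str = "s1",
               pair_cols: int = 10) -> pd.DataFrame:
    """Canonical spot frame from per-spot net signals (two spots per
    protein, laid out row-major with duplicates in adjacent columns)."""
    net = np.asarray(net, dtype=float)
    assert net.size % 2 == 0
    n = net.size // 2
    prot = np.repeat(np.arange(n), 2)
    bg = np.full(net.size, 200.0)
    if conc is None:
        conc = np.ones(net.size)
    return pd.DataFrame({
        "slide_id": slide_id,
        "block": 1,
        "row": prot // pair_cols + 1,
        "col": 2 * (prot % pair_cols) + 1 + np.tile([0, 1], n),
        "protein_id": [f"P{i + 1:04d}" for i in prot],
        "replicate_index": np.tile([1, 2], n),
        "fg": bg + net,
        "bg": bg,
        "conc": np.asarray(conc, dtype=float),
    })
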