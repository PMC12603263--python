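import numpy as np
import pandas as pd
import pytest

from plasmaqc.quant import QuantMatrix


def make_matrix(data: dict, protein_ids=None, scale="linear", precursors=None):
    """Build a QuantMatrix from {sample_id: [values]} (None = missing)."""
    frame = pd.DataFrame(
        {k: [np.nan if v is None else float(v) for v in vals]
         for k, vals in data.items()}
    )
    if protein_ids is None:
        protein_ids = [f"PROT{i}" for i in range(len(frame))]
    frame.index = pd.Index(protein_ids, name="protein_id")
    pc = pd.Series(precursors, index=frame.index) if precursors is not None else None
    return QuantMatrix(frame, scale=scale, precursor_counts=pc)


@pytest.fixture
def toy_matrix():
    return make_matrix(
        {"s1": [100.0, 10.0, None], "s2": [50.0, None, 5.0]},
        protein_ids=["A", "B", "C"],
    )
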