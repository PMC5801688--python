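import numpy as np
import pandas as pd
import pytest

from phimarker.io import MutationPanel, ResponsePanel


def make_panels(resp: dict, muts: dict, cells: list[str]):
    """Build (ResponsePanel, MutationPanel) from column dicts keyed by
    drug/feature name; values are per-cell lists (NaN allowed)."""
    rp = ResponsePanel(pd.DataFrame(resp, index=cells, dtype=float))
    mp = MutationPanel(pd.DataFrame(muts, index=cells, dtype=float))
    return rp, mp


@pytest.fixture
def tiny_panels():
    """2 drugs x 4 cells, one clear sensitising mutation on drugA/geneX."""
    cells = ["c1", "c2", "c3", "c4"]
    rp, mp = make_panels(
        {"drugA": [-2.0, -2.0, 0.0, 0.0], "drugB": [1.0, np.nan, 0.5, 0.7]},
        {"geneX": [1, 1, 0, 0], "geneY": [0, 1, 0, 1]},
        cells,
    )
    return rp, mp


def rename_cells(panel, prefix: str):
    """Return a copy of a panel with cell identifiers prefixed (to build
    disjoint test releases from independently generated panels)."""
    frame = panel.frame.rename(index=lambda c: prefix + c)
    return type(panel)(frame)
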