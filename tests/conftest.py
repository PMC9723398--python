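import numpy as np
import pandas as pd
import pytest

from phosphonet import ComparisonDesign, Thresholds


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture
def comparison():
    return ComparisonDesign("stim_vs_ctrl", "stim", "ctrl")


def make_table(stim_ratios, ctrl_ratios=None, proteins=None):
    """Small phosphosite table from per-site replicate ratio lists.

    ``stim_ratios`` is a list of length-3 lists (None for an absent
    replicate); the reference condition defaults to all-ones.
    """
    n = len(stim_ratios)
    if ctrl_ratios is None:
        ctrl_ratios = [[1.0, 1.0, 1.0]] * n
    if proteins is None:
        proteins = [f"P{i:03d}" for i in range(n)]
    data = {
        "site_id": [f"S{i:03d}" for i in range(n)],
        "protein_id": proteins,
        "amino_acid": ["S"] * n,
        "position": list(range(10, 10 + n)),
        "sequence_window": ["GGGGGGSGGGGGG"] * n,
    }
    for cond, ratios in (("ctrl", ctrl_ratios), ("stim", stim_ratios)):
        for k in range(3):
            data[f"ratio_{cond}_rep{k + 1}"] = [
                np.nan if r[k] is None else float(r[k]) for r in ratios
            ]
    return pd.DataFrame(data)
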