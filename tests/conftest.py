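import numpy as np
import pandas as pd
import pytest

from ubscan.fitness import FitnessLandscape
from ubscan.synthetic_data import (
    CompetitionConfig,
    TrueLandscapeConfig,
    generate_library,
    generate_true_landscape,
    simulate_competition,
)
from ubscan.variants import RESIDUES

#: Small reference sequence (6 residues) for fast unit tests.
MINI_WT = "MACDEF"


@pytest.fixture(scope="session")
def mini_library():
    return generate_library(MINI_WT, barcodes_per_variant=2, barcode_length=8, seed=7)


@pytest.fixture(scope="session")
def mini_landscapes():
    from ubscan.synthetic_data import ConditionEffect

    cfg = TrueLandscapeConfig(
        wt_sequence=MINI_WT,
        condition_effects={
            "treatA": (ConditionEffect((2, 3), -0.3),),
            "treatB": (ConditionEffect((4, 5), 0.1),),
        },
        seed=7,
    )
    return generate_true_landscape(cfg)


@pytest.fixture(scope="session")
def mini_counts(mini_landscapes, mini_library):
    """One small simulated competition (control condition)."""
    comp = CompetitionConfig(depth=50_000, n_replicates=2, seed=7)
    return simulate_competition(mini_landscapes["DMSO"], mini_library, comp)


def make_landscape(values_by_position, wt_sequence=MINI_WT, condition="X", normalized=True):
    """Build a landscape from {position: {residue: value}} with WT
    cells at 0 and unlisted cells missing."""
    positions = pd.RangeIndex(2, len(wt_sequence) + 1, name="position")
    values = pd.DataFrame(np.nan, index=positions, columns=list(RESIDUES))
    for pos in positions:
        values.at[pos, wt_sequence[pos - 1]] = 0.0
    for pos, cells in values_by_position.items():
        for res, val in cells.items():
            values.at[pos, res] = val
    return FitnessLandscape(
        condition=condition,
        values=values,
        wt_sequence=wt_sequence,
        normalized=normalized,
    )
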