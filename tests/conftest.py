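import numpy as np
import pandas as pd
import pytest

from subcellflow.core import QuantTable, SampleDesign
from subcellflow.io import PipelineConfig
from subcellflow.pipeline import simulate_dataset


@pytest.fixture(scope="session")
def design_two_conditions() -> SampleDesign:
    """Six fractions, control + stimulated, four replicates."""
    return SampleDesign.from_layout(
        n_fractions=6, conditions=("control", "stimulated"), n_replicates=4
    )


@pytest.fixture(scope="session")
def default_simulation():
    """The default study conditions: 1000 features, 6 fractions, 4
    replicates, 5% translocators with delta in [0.2, 0.4], noise sd 0.3,
    2% MCAR plus logistic MNAR dropout."""
    cfg = PipelineConfig(seed=7)
    table, truth = simulate_dataset(cfg)
    return table, truth, cfg


def make_table(values: dict, design: SampleDesign) -> QuantTable:
    """Build a QuantTable from {feature: {sample: value}} nested dicts."""
    frame = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    frame = frame.reindex(columns=design.samples)
    return QuantTable(frame, design)


@pytest.fixture
def single_condition_design() -> SampleDesign:
    return SampleDesign.from_layout(
        n_fractions=6, conditions=("control",), n_replicates=1
    )


def profile_table(profiles: dict, design: SampleDesign, abundance: float = 20.0):
    """QuantTable whose single-replicate log2 values realize the given
    fraction-proportion profiles exactly (zeros become missing)."""
    rows = {}
    for feature, profile in profiles.items():
        row = {}
        for f, p in enumerate(profile, start=1):
            (sample,) = design.samples_for(fraction=f)
            row[sample] = abundance + np.log2(p) if p > 0 else np.nan
        rows[feature] = row
    return make_table(rows, design)
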