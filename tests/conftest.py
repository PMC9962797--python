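import numpy as np
import pandas as pd
import pytest

from mmnet import FeatureTable, GroupDesign, SyntheticConfig


@pytest.fixture
def small_design() -> GroupDesign:
    samples = [f"{g}-{i}" for g in ("Chow", "Chow+GWI", "WD", "WD+GWI") for i in (1, 2, 3)]
    groups = [s.rsplit("-", 1)[0] for s in samples]
    return GroupDesign(pd.Series(groups, index=samples))


@pytest.fixture
def small_metabolite_table(small_design) -> FeatureTable:
    rng = np.random.default_rng(11)
    vals = pd.DataFrame(
        np.exp(rng.normal(10, 1, size=(5, 12))),
        index=[f"met{i}" for i in range(5)],
        columns=small_design.assignments.index,
    )
    return FeatureTable(vals, "metabolite")


@pytest.fixture
def small_microbe_table(small_design) -> FeatureTable:
    rng = np.random.default_rng(12)
    raw = np.exp(rng.normal(0, 1, size=(6, 12)))
    vals = pd.DataFrame(
        raw / raw.sum(axis=0),
        index=[f"sp{i}" for i in range(6)],
        columns=small_design.assignments.index,
    )
    ann = pd.Series(["Firmicutes"] * 3 + ["Bacteroidetes"] * 3, index=vals.index)
    return FeatureTable(vals, "microbe", ann, compositional=True)


@pytest.fixture
def tiny_config() -> SyntheticConfig:
    return SyntheticConfig(n_species=12, n_metabolites=20, seed=5)
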