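import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from microshift import (GenusCountTable, PhenotypeTable, SampleMetadata,
                        SimDesign, simulate_counts, to_relative)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_counts() -> GenusCountTable:
    """2 samples × 3 genera, the worked micro-example used across modules."""
    return GenusCountTable(
        sample_ids=["s1", "s2"],
        genus_ids=["gA", "gB", "gC"],
        counts=np.array([[2, 0, 6], [1, 3, 0]]),
        taxonomy={"gA": "Firmicutes", "gB": "Bacteroidota", "gC": "Firmicutes"},
    )


@pytest.fixture
def two_group_meta() -> SampleMetadata:
    rows = [{"sample_id": f"{g}_m{i}", "mouse_id": f"{g}_m{i}", "group": g, "week": 10}
            for g in ("A", "B") for i in range(1, 6)]
    return SampleMetadata(pd.DataFrame(rows))


def null_two_group_design(seed: int, n_mice: int = 5, n_genera: int = 66,
                          theta: float = 50.0, span: float = 4.0) -> SimDesign:
    """Two exchangeable groups, one week, no planted effect."""
    return SimDesign(groups=("A", "B"), weeks=(4,), n_mice_per_group=n_mice,
                     theta=theta,
                     base_log_abundance=-np.linspace(0, span, n_genera),
                     n_genera=n_genera,
                     effect_table={("A", 4): np.zeros(n_genera)}, seed=seed)


@pytest.fixture
def default_study():
    """One simulated default study (4 groups × 5 mice × weeks 4/10)."""
    design = SimDesign(seed=11)
    counts, meta, truth = simulate_counts(design)
    return design, counts, meta, truth


def constant_phenotype(groups_means: dict[str, tuple[float, float, float, float]],
                       n_mice: int = 5) -> tuple[PhenotypeTable, SampleMetadata]:
    """Phenotype table where every mouse sits at its group mean:
    groups_means[g] = (bw_w4, bw_w10, fbg_w4, fbg_w10)."""
    prows, mrows = [], []
    for g, (bw4, bw10, f4, f10) in groups_means.items():
        for i in range(1, n_mice + 1):
            mid = f"{g}_m{i}"
            prows += [{"mouse_id": mid, "week": 4, "bw": bw4, "fbg": f4},
                      {"mouse_id": mid, "week": 10, "bw": bw10, "fbg": f10}]
            mrows += [{"sample_id": f"{mid}_w{w}", "mouse_id": mid,
                       "group": g, "week": w} for w in (4, 10)]
    return PhenotypeTable(pd.DataFrame(prows)), SampleMetadata(pd.DataFrame(mrows))
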