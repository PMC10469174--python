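import numpy as np
import pandas as pd
import pytest

import stilkit as sk


@pytest.fixture(scope="session")
def small_map() -> sk.TissueMap:
    """A 800×800 μm slide at 2 μm/px with 40% stroma, 35% cancer area."""
    return sk.generate_tissue_map(
        800, 800, mpp=2.0, stroma_fraction=0.4, cancer_fraction=0.35, seed=11, slide_id="fix"
    )


@pytest.fixture(scope="session")
def small_cells(small_map) -> pd.DataFrame:
    return sk.generate_cells(small_map, sk.IntensityConfig(base_density=5000.0), seed=12)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_panel(scores: dict[str, list[float]], slides: list[str] | None = None) -> pd.DataFrame:
    """Wide score panel from reader -> per-slide score lists (None = missing)."""
    df = pd.DataFrame(scores, dtype=float)
    df.index = slides if slides is not None else [f"s{i}" for i in range(len(df))]
    df.index.name = "slide_id"
    return df
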