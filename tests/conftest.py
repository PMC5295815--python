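import numpy as np
import pandas as pd
import pytest

from goldmim.colour import ColourMatrix
from goldmim.simulate import BODY_PARTS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_colour_matrix():
    """Three species, eight parts, hand-sized values."""
    rng = np.random.default_rng(7)
    species = pd.Index(["a", "b", "c"], name="species_id")
    cols = pd.MultiIndex.from_product([BODY_PARTS, ("R", "G", "B")])
    part_rgb = pd.DataFrame(rng.uniform(0, 255, (3, 24)), index=species,
                            columns=cols)
    lengths = pd.DataFrame(rng.uniform(0.5, 2.0, (3, 8)), index=species,
                           columns=list(BODY_PARTS))
    return ColourMatrix(part_rgb=part_rgb, part_length=lengths,
                        body_size=pd.Series([8.0, 9.0, 10.0], index=species),
                        golden_area=pd.Series([2.0, 3.0, 4.0], index=species))
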