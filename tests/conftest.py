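import numpy as np
import pytest

from spatialih import hotspots as hs
from spatialih.celltable import IMMUNE_SUBSETS
from spatialih import synthetic as syn


def label_map_from_names(names, alpha=0.05):
    """Build a HotspotLabelMap directly from a 2-D array of label names.

    p values are synthesised to be consistent with the requested labels;
    every grid is tissue.
    """
    names = np.asarray(names, dtype=object)
    codes = np.vectorize(hs.LABEL_CODES.get)(names).astype(np.int8)
    lo, hi = alpha / 2, 0.5
    p_c = np.where(np.isin(codes, (hs.CH, hs.IH_INTRA)), lo, hi)
    p_l = np.where(np.isin(codes, (hs.IH_PERI, hs.IH_INTRA)), lo, hi)
    tissue = np.ones(names.shape, dtype=bool)
    spec = hs.GridSpec(0.0, 0.0, 50.0, names.shape[1], names.shape[0])
    z = np.zeros(names.shape)
    return hs.HotspotLabelMap(spec, z, z, p_c, p_l, codes, tissue, alpha)


@pytest.fixture
def uniform_mix():
    return {s: 1.0 / len(IMMUNE_SUBSETS) for s in IMMUNE_SUBSETS}


@pytest.fixture
def nest_slide_config(uniform_mix):
    """One cancer nest plus a distant immune infiltrate."""
    return syn.SlideConfig(
        width_um=3000.0,
        height_um=3000.0,
        tumor_nests=(syn.TumorNest((800.0, 800.0), 450.0, 0.005),),
        immune_fields=(
            syn.ImmuneField("distant", uniform_mix, 5e-5, 15.0, 30.0),
        ),
        stromal_intensity=3e-4,
        seed=7,
    )
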