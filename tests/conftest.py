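import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def make_normalized_slide():
    """Build a NormalizedSlide directly from per-gene M values."""
    from rhizoclass.arrays import NormalizedSlide

    def _make(
        m_values,
        slide_id="s1",
        condition_ch1="pea",
        condition_ch2="glucose",
        dye_swap=False,
        a_values=None,
        flagged=None,
        gene_ids=None,
    ):
        m = np.asarray(m_values, float)
        n = len(m)
        data = pd.DataFrame(
            {
                "gene_id": gene_ids if gene_ids is not None else [f"g{i}" for i in range(n)],
                "M": m,
                "A": a_values if a_values is not None else np.full(n, 10.0),
                "flagged": flagged if flagged is not None else np.zeros(n, bool),
            }
        )
        return NormalizedSlide(
            slide_id=slide_id,
            condition_ch1=condition_ch1,
            condition_ch2=condition_ch2,
            dye_swap=dye_swap,
            data=data,
        )

    return _make


@pytest.fixture
def raw_slide():
    """A small raw SlideTable with controllable intensities."""
    from rhizoclass.arrays import SlideTable

    def _make(rows, **meta):
        spots = pd.DataFrame(
            rows, columns=["gene_id", "ch1_fg", "ch1_bg", "ch2_fg", "ch2_bg"]
        )
        defaults = dict(
            slide_id="raw1",
            condition_ch1="pea",
            condition_ch2="glucose",
            dye_swap=False,
        )
        defaults.update(meta)
        return SlideTable(spots=spots, **defaults)

    return _make
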