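import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from cghindel.probes import ProbeMap, RatioProfile
from cghindel.synthetic import LayoutConfig, generate_probe_map


def make_probe_map(n_probes: int, chromosome: str = "c1", spacing: int = 100,
                   length: int = 50, region: str = "center") -> ProbeMap:
    """Regularly spaced probes for hand-built fixtures."""
    starts = 1 + spacing * np.arange(n_probes)
    return ProbeMap(
        pd.DataFrame(
            {
                "probe_id": [f"{chromosome}_p{i:05d}" for i in range(n_probes)],
                "chromosome": chromosome,
                "start": starts,
                "end": starts + length - 1,
                "region": region,
            }
        )
    )


def make_profile(ratios, strain="test", probe_map=None, normalized=True, **pm_kwargs):
    ratios = np.asarray(ratios, dtype=float)
    pm = probe_map if probe_map is not None else make_probe_map(len(ratios), **pm_kwargs)
    return RatioProfile(strain=strain, probe_map=pm, log2_ratio=ratios, normalized=normalized)


@pytest.fixture
def small_layout():
    return LayoutConfig(chromosome_names=("c1",), chromosome_lengths=(200_000,))


@pytest.fixture
def small_map(small_layout):
    return generate_probe_map(small_layout, seed=1)
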