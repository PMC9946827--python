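import numpy as np
import pandas as pd
import pytest

from peatmap import linkage_map as lm
from peatmap import simdata as sim


def make_genotypes(markers: pd.DataFrame, calls: np.ndarray) -> lm.HaploidGenotypes:
    return lm.HaploidGenotypes(
        markers=markers,
        samples=[f"ind{i:03d}" for i in range(calls.shape[1])],
        calls=np.asarray(calls, dtype=np.int8),
    )


def toy_genotypes(calls, positions=None, chrom="chr1") -> lm.HaploidGenotypes:
    """Genotypes from a raw matrix; positions default to 1, 2, 3, ..."""
    calls = np.asarray(calls, dtype=np.int8)
    n = calls.shape[0]
    pos = np.arange(1, n + 1) if positions is None else np.asarray(positions)
    markers = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "id": [f"m{i}" for i in range(n)]}
    )
    return make_genotypes(markers, calls)


@pytest.fixture(scope="session")
def pedigree_uv():
    """174-gametophyte pedigree with a non-recombining U/V chromosome."""
    cfg = sim.SimConfig(
        seed=11,
        n_individuals=174,
        chrom_lengths_bp=(10_000_000,) * 5,
        marker_spacing_bp=500_000,
        uv_chrom_index=4,
    )
    markers, calls, truth = sim.sim_pedigree(cfg)
    return cfg, markers, calls, truth
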