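import numpy as np
import pandas as pd
import pytest

import hybridtrace as ht


@pytest.fixture(scope="session")
def small_swarm() -> ht.SwarmDataset:
    """A small hybrid-swarm dataset reused by read-only tests."""
    cfg = ht.SimulationConfig(
        seed=42, n_sites=4000, chrom_length=1_000_000, n_species=2,
        n_diploids=5, n_control_pairs=1,
    )
    return ht.simulate_hybrid_swarm(cfg)


@pytest.fixture(scope="session")
def small_freqs(small_swarm) -> ht.FrequencyTable:
    return ht.allele_freqs(small_swarm.gm, small_swarm.popmap)


def make_freq_table(freq_by_group: dict[str, np.ndarray],
                    scaffold: str = "s1") -> ht.FrequencyTable:
    """Hand-build a FrequencyTable from per-group frequency vectors."""
    groups = list(freq_by_group)
    freq = np.column_stack([np.asarray(freq_by_group[g], dtype=float) for g in groups])
    n = len(freq)
    sites = pd.DataFrame(
        {"scaffold": scaffold, "pos": np.arange(1, n + 1), "ref": "A", "alt": "T"}
    )
    n_called = np.where(np.isnan(freq), 0, 10).astype(int)
    return ht.FrequencyTable(sites=sites, groups=groups, freq=freq, n_called=n_called)
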