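import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """Compact simulated family study with one causal gene (40 samples)."""
    from methvc.simulate import desk_preset, simulate_dataset

    cfg = desk_preset(
        seed=42, n_families=8, n_sites=80, n_genes=6, sites_per_gene=(5, 10),
        causal_genes=("GENE0001",), trait_h_meth2=0.2,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def trio_ped(tmp_path):
    """Minimal PED file: child listed first, founder parents after."""
    p = tmp_path / "trio.ped"
    p.write_text(
        "FAM1\tkid\tdad\tmom\t1\n"
        "FAM1\tdad\t0\t0\t1\n"
        "FAM1\tmom\t0\t0\t2\n"
    )
    return p
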