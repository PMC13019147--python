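import pytest

from bnctmicro.geometry import MorphologyGrid
from bnctmicro.mc import SimConfig
from bnctmicro.tables import build_table


@pytest.fixture(scope="session")
def small_table():
    """Reduced-grid parameter table with all components and a few domain
    sizes; shared across tests that exercise interpolation and the pipeline."""
    grid = MorphologyGrid(
        s_nucl_values=(9.0, 81.0),
        s_ratio_values=(0.2, 0.4, 0.6),
        gap_values=(0.5, 2.0, 6.0, 12.0),
    )
    cfg = SimConfig(ds_um=0.1, domain_diameters=(0.3, 0.5, 1.0),
                    n_domain_samples=8000)
    return build_table(grid, cfg, n_histories=2000, seed=1234,
                       n_background=600, n_cap=16000)


@pytest.fixture(scope="session")
def surrogate_table():
    """Full 512-node morphology grid, boron component only, at a reduced
    history budget; used for the interpolation-accuracy and sensitivity
    checks."""
    return build_table(cfg=SimConfig(ds_um=0.1, domain_diameters=()),
                       n_histories=4000, seed=20260924 % (2**31 - 1),
                       components=("B",))
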