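import numpy as np
import pandas as pd
import pytest

from pqtlkit.simulate import SimConfig, simulate_ld_panel
from pqtlkit.sumstats import LDReference, VariantKey


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    return SimConfig(n_cohorts=5, cohort_ns=(3000, 2500, 2000, 1500, 1000),
                     n_blocks=2, block_size=30, rho=0.8, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_sim_config):
    return simulate_ld_panel(small_sim_config)


def make_region_panel(n_variants: int, rho: float, seed: int = 0,
                      maf_range=(0.1, 0.5)):
    """One-block panel + AR(1) LD reference for region-level simulations."""
    cfg = SimConfig(n_cohorts=1, cohort_ns=(10_000,), n_blocks=1,
                    block_size=n_variants, rho=rho, seed=seed,
                    maf_range=maf_range)
    panel, ld = simulate_ld_panel(cfg)
    return panel, ld


def custom_ld(panel: pd.DataFrame, r: np.ndarray) -> LDReference:
    """Wrap an explicit correlation matrix over a panel's variants."""
    variants = [VariantKey(str(c), int(p), str(a), str(o))
                for c, p, a, o in zip(panel["CHR"], panel["POS"],
                                      panel["EA"], panel["OA"])]
    return LDReference(variants=variants, r=r, n_ref=0)
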