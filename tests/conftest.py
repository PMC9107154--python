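import numpy as np
import pandas as pd
import pytest

from triomr.datatypes import SampleSheet
from triomr.mr import IVSet
from triomr.simulate import ScenarioConfig, simulate_study


@pytest.fixture(scope="session")
def small_bundle():
    """One simulated study at reduced scale, shared across read-only tests."""
    cfg = ScenarioConfig(n_genes=30, n_sites=20, n_metabolites=15,
                         variants_per_chrom=40, n_deg=6, n_dmr=4, n_dam=5)
    return simulate_study(cfg, seed=11)


@pytest.fixture
def sheet40():
    """Plain 40-sample design: balanced groups, one binary covariate."""
    rng = np.random.default_rng(5)
    n = 40
    table = pd.DataFrame({
        "group": np.repeat([0, 1], n // 2),
        "exercise": rng.integers(0, 2, n),
    }, index=pd.Index([f"S{i:03d}" for i in range(n)], name="sample"))
    return SampleSheet(table=table)


def random_ivset(rng: np.random.Generator, k: int = 8, causal: float = 0.0) -> IVSet:
    """Instrument summary statistics with a known causal slope."""
    beta_exp = rng.uniform(0.2, 1.0, k) * rng.choice((-1.0, 1.0), k)
    se_exp = rng.uniform(0.02, 0.1, k)
    se_out = rng.uniform(0.05, 0.2, k)
    beta_out = causal * beta_exp + rng.normal(0.0, se_out)
    table = pd.DataFrame({
        "variant": [f"v{j:03d}" for j in range(k)],
        "beta_exp": beta_exp, "se_exp": se_exp,
        "beta_out": beta_out, "se_out": se_out,
        "proxy": False, "proxy_r2": np.nan,
        "theta": beta_out / beta_exp,
        "se_theta": se_out / np.abs(beta_exp),
        "weight": (np.abs(beta_exp) / se_out) ** 2,
    })
    return IVSet(exposure="x", outcome="y", table=table)
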