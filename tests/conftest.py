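import numpy as np
import pandas as pd
import pytest

import gelflux as gf


@pytest.fixture(scope="session")
def default_dataset():
    """One deterministic default-scenario dataset shared across tests."""
    return gf.generate_scenario(gf.ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def np_like_dataset():
    """North-Pacific-like scenario: translating deep layer, negative coupling."""
    return gf.generate_scenario(gf.ScenarioConfig.north_pacific_like(seed=11))


@pytest.fixture(scope="session")
def na_like_dataset():
    """North-Atlantic-like scenario: decaying profiles, positive coupling."""
    return gf.generate_scenario(gf.ScenarioConfig.north_atlantic_like(seed=13))


@pytest.fixture()
def sample_meta():
    def _make(ds):
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "site": s.site,
                    "deployment": s.deployment,
                    "depth_m": s.depth_m,
                    "platform": s.platform,
                }
                for s in ds.trap_samples
            ]
        ).set_index("sample_id")

    return _make


def layer_truth_profiles(cfg: gf.ScenarioConfig, taxon: str, deployments, depths=None):
    """Noise-free flux profiles of the layer taxon straight from the truth model."""
    z = np.asarray(depths if depths is not None else cfg.depths_m, dtype=float)
    out = []
    for dep in deployments:
        f = np.array([cfg.true_flux(taxon, zz, dep) for zz in z])
        out.append(
            gf.FluxProfile(depths_m=z, values=f, taxon=taxon, deployment=dep)
        )
    return out
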