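import numpy as np
import pytest

import spotcycle as sp


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic study: 4 types in spatial blocks, 8×8 grid, 200 genes."""
    cfg = sp.SimulationConfig()
    ref, st, gt = sp.simulate_pair(cfg)
    return cfg, ref, st, gt


@pytest.fixture(scope="session")
def bench_config():
    """Desk-scale benchmark configuration (reduced epochs and layer widths)."""
    return sp.RunConfig(epochs_vgae=200, epochs_cgan=100, epochs_mapping=150,
                        d_hidden=64, d_latent=16, d_disc=32)


@pytest.fixture(scope="session")
def tiny_config():
    """A few epochs of everything — exercises code paths, not convergence."""
    return sp.RunConfig(epochs_vgae=5, epochs_cgan=3, epochs_mapping=3,
                        d_hidden=16, d_latent=4, d_disc=8, reg_negatives=3)


@pytest.fixture(scope="session")
def ablation_study(small_sim, bench_config):
    """Full-scale runs of the complete model and its three ablations over
    five seeds on the blocks benchmark; shared across the acceptance tests."""
    _, ref, st, gt = small_sim
    variants = {"full": {}, "no_cyc": {"no_cyc": True},
                "no_disc": {"no_disc": True}, "no_reg": {"no_reg": True}}
    out = {"truth": gt.proportions, "rmse": {}, "results": {}}
    for name, kw in variants.items():
        model = sp.SpatialDeconvolutionModel(st, ref, bench_config.replace(**kw))
        vals = []
        for seed in range(5):
            res = model.fit(seed=seed)
            vals.append(res.score(gt.proportions)["rmse"])
            if seed == 0:
                out["results"][name] = res
        out["rmse"][name] = vals
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
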