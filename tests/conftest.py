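import numpy as np
import pytest

from waverep import synthetic


@pytest.fixture(scope="session")
def small_genotypes():
    return synthetic.simulate_genotypes(800, 60, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared small cohort for cross-module tests (no LD, 3 factors)."""
    return synthetic.simulate_cohort(n=800, m=60, n_factors=3,
                                     causal_per_factor=4, h2=0.5, seed=5)


@pytest.fixture(scope="session")
def spiro_waves_small():
    """Decimated (length-100) 2-channel spirograms from 3 nonlinear
    factors, with per-record EDFs; shared by the model tests."""
    from waverep.spiro import compute_spirogram_edfs

    rng = np.random.default_rng(17)
    n = 700
    F = rng.standard_normal((n, 3))
    cfg = synthetic.SpiroShapeConfig(tp_base=0.3, tp_log_per_sd=0.6,
                                     tp_bounds=(0.08, 1.2),
                                     lambda_log_per_sd=0.5)
    recs = [synthetic.render_spirogram(F[i], cfg) for i in range(n)]
    X = np.stack([np.stack([r.volume_time[::10], r.flow_time[::10]])
                  for r in recs])
    FV = np.stack([r.flow_volume[::10] for r in recs])
    edfs = np.stack([compute_spirogram_edfs(r).as_array() for r in recs])
    return {"curves": X, "flow_volume": FV, "edfs": edfs, "factors": F}


@pytest.fixture(scope="session")
def trained_spinc_small(spiro_waves_small):
    from waverep import vae

    cfg = vae.default_config("spinc", input_length=100,
                             conv_channels=(6, 12, 24), epochs=25,
                             batch_size=128, seed=3, kl_weight=1e-4)
    return vae.train(spiro_waves_small["curves"], cfg)


@pytest.fixture(scope="session")
def trained_rspinc_small(spiro_waves_small):
    from waverep import vae

    cfg = vae.default_config("rspinc", input_length=100,
                             conv_channels=(6, 12, 24), epochs=30,
                             batch_size=128, seed=4, kl_weight=1e-3)
    return vae.train(spiro_waves_small["flow_volume"][:, None, :], cfg,
                     edfs=spiro_waves_small["edfs"])


@pytest.fixture(scope="session")
def ppg_cohort():
    rng = np.random.default_rng(3)
    F = rng.standard_normal((1200, 3))
    return np.stack([synthetic.render_ppg(F[i]).samples
                     for i in range(1200)]), F
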