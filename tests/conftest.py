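import numpy as np
import pytest

from turbflux.synthetic import SyntheticConfig


def constant_eps_config(seed: int, eps: float = 1e-8, *, nu: float = 1.2e-6,
                        record_seconds: float = 20.0, **kw) -> SyntheticConfig:
    """One-station config with depth-constant dissipation and viscosity."""
    def eps_fn(z, station=0, _e=eps):
        return np.full_like(np.asarray(z, dtype=float), _e)
    kw.setdefault("depth_max", 300.0)
    kw.setdefault("bottle_depths", (0.0, 50.0, 100.0, 200.0, 300.0))
    kw.setdefault("n_stations", 1)
    return SyntheticConfig(seed=seed, epsilon_truth=eps_fn,
                           nu_constant=nu, record_seconds=record_seconds, **kw)


@pytest.fixture(scope="session")
def pipeline_run():
    """One full small-section pipeline run shared across tests."""
    from turbflux.pipeline import PipelineConfig, run_pipeline
    from turbflux.synthetic import ridge_section_epsilon

    syn = SyntheticConfig(seed=42, n_stations=3, depth_max=300.0,
                          epsilon_truth=ridge_section_epsilon(peak_station=1),
                          bottle_depths=(0.0, 50.0, 100.0, 200.0, 300.0))
    cfg = PipelineConfig(synthetic=syn, n_casts=1, n_probes=2)
    return run_pipeline(cfg)
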