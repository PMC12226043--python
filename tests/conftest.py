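import numpy as np
import pytest

from vaguscap.types import SessionPlan, SimConfig, UnitProfile


def small_config(
    rates=(10.0,),
    burst_gain=1.0,
    responses=((0.0, 0.0),),
    duration_sd_ms=10.0,
    period_sd_ms=60.0,
    cardiac_rate_hz=0.0,
    noise_sd=0.0,
    noise_burst_multiplier=1.0,
    jitter_shape=1e9,
    template_ids=None,
    seed=0,
    **kw,
):
    """One-mouse config with near-deterministic rates by default."""
    n = len(rates)
    if template_ids is None:
        template_ids = [4 * (j % 3) for j in range(n)]
    profiles = tuple(
        UnitProfile(
            baseline_rate=r,
            burst_gain=burst_gain,
            response_c1=c[0],
            response_c2=c[1],
            template_id=t,
        )
        for r, c, t in zip(rates, list(responses) * n, template_ids)
    )
    return SimConfig(
        group_label="CON",
        n_mice=1,
        units_per_mouse=(n,),
        unit_profiles=profiles,
        resp_burst_duration_ms=(133.73, duration_sd_ms),
        resp_burst_period_ms=(649.75, period_sd_ms),
        cardiac_rate_hz=cardiac_rate_hz,
        noise_sd_base_uv=noise_sd,
        noise_burst_multiplier=noise_burst_multiplier,
        rate_jitter_shape=jitter_shape,
        seed=seed,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plan():
    return SessionPlan()
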