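import numpy as np
import pytest

from firefit import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic cohort: n=20, two latent factors, noise 0.3."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Noise-free rank-2 cohort (responses exactly linear in predictors)."""
    return generate_dataset(SyntheticConfig(noise_sd_x=0.0, noise_sd_y=0.0, seed=11))


def make_rank_l_config(l, loading_seed, data_seed, noise=0.0):
    """Rank-l generator config with decreasing per-factor response strength.

    Successive latent factors carry response variance in ratio 1 : 0.09 :
    0.0225 so that each extracted component has genuine incremental
    predictive value (with equal-strength factors the Q² rule can
    legitimately stop early, because an h-component model's leave-one-out
    error still contains every unexplained factor).
    """
    rng = np.random.default_rng(loading_seed)
    P = np.linalg.qr(rng.standard_normal((5, l)))[0]
    Q = np.zeros((7, l))
    for j in range(7):
        Q[j, j % l] = 1.0
    Q += 0.2 * rng.standard_normal((7, l))
    Q *= np.array([1.0, 0.3, 0.15, 0.1, 0.08])[:l]
    return SyntheticConfig(
        latent_rank=l, P=P, Q=Q, noise_sd_x=noise, noise_sd_y=noise, seed=data_seed
    )
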