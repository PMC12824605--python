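import numpy as np
import pytest

from ploidymix.depth_io import AllelicSample, filter_sites
from ploidymix.simulate import DepthSimConfig, simulate_depths


def make_sample(
    ploidy: str,
    seed: int,
    n_sites: int = 1000,
    depth_mean: float = 50.0,
    inheritance: str | None = None,
    **kwargs,
) -> AllelicSample:
    """Simulated, filtered allelic-ratio sample with known generative truth."""
    cfg = DepthSimConfig(
        ploidy=ploidy,
        inheritance=inheritance,
        n_sites=n_sites,
        depth_mean=depth_mean,
        seed=seed,
        sample_id=f"{ploidy}_{seed}",
        **kwargs,
    )
    sample, _ = filter_sites(simulate_depths(cfg))
    return sample


def ratio_sample(
    weights: tuple[float, ...],
    means: tuple[float, ...],
    sd: float,
    n_sites: int,
    seed: int,
    support: tuple[float, float] = (0.15, 0.85),
    sample_id: str = "ratio-sim",
) -> AllelicSample:
    """Sample drawn directly from a normal(-uniform) mixture on the ratio
    scale: the generative family of the ratio-based models, used as a
    parameter-recovery oracle.  The last weight (if len(weights) ==
    len(means) + 1) is a uniform component over the support."""
    rng = np.random.default_rng(seed)
    k = len(means)
    comp = rng.choice(len(weights), size=n_sites, p=np.asarray(weights))
    lo, hi = support
    x = np.where(
        comp < k,
        rng.normal(np.asarray(means + (0.5,))[np.minimum(comp, k - 1)], sd),
        rng.uniform(lo, hi, size=n_sites),
    )
    x = np.clip(x, lo + 1e-9, hi - 1e-9)
    totals = np.full(n_sites, 100)
    return AllelicSample(
        sample_id=sample_id,
        ratios=x,
        totals=totals,
        b_counts=np.round(x * totals).astype(int),
    )


@pytest.fixture(scope="session")
def diploid_sample() -> AllelicSample:
    return make_sample("diploid", seed=101)


@pytest.fixture(scope="session")
def tetraploid_sample() -> AllelicSample:
    return make_sample("tetraploid", seed=202, inheritance="tetrasomic")
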