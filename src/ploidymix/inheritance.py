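"""Allo- vs autopolyploid classification from heterozygote-class proportions.

A tetraploid with tetrasomic inheritance (autopolyploid) spreads heterozygous
sites roughly equally over the aaab / aabb / abbb classes, giving a trimodal
allelic-ratio spectrum at 0.25 / 0.5 / 0.75.  Disomic inheritance of two
diverged subgenomes (allopolyploid) concentrates heterozygosity in the aabb
class at ratio 0.5.  The mixing proportions (alpha values) of the tetraploid
normal-uniform mixture therefore diagnose the mode of polyploidy: a sample is
called allopolyploid when its alpha at 0.5 strictly exceeds the alphas at
both 0.25 and 0.75.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ploidymix.depth_io import AllelicSample
from ploidymix.mixtures import MixtureSpec, em_fit

__all__ = [
    "AlphaEstimate",
    "InheritanceCall",
    "tetraploid_nu_spec",
    "estimate_alphas",
    "classify_inheritance",
    "plot_allele_ratio_histogram",
]

#: EM starting parameters for alpha estimation (tetraploid normal-uniform):
#: avec = (0.3, 0.3, 0.3, 0.1), mvec = (0.25, 0.50, 0.75), svec = (0.01,)*3.
DEFAULT_START = {
    "avec": (0.3, 0.3, 0.3, 0.1),
    "mvec": (0.25, 0.50, 0.75),
    "svec": (0.01, 0.01, 0.01),
}


@dataclass(frozen=True)
class AlphaEstimate:
    """Converged mixing proportions of the tetraploid normal-uniform model."""

    sample_id: str
    alpha_25: float
    alpha_50: float
    alpha_75: float
    alpha_uniform: float
    loglik: float

    def __post_init__(self) -> None:
        total = self.alpha_25 + self.alpha_50 + self.alpha_75 + self.alpha_uniform
        if abs(total - 1.0) > 1e-6 or min(
            self.alpha_25, self.alpha_50, self.alpha_75, self.alpha_uniform
        ) < -1e-12:
            raise ValueError("alpha values must be >= 0 and sum to 1")


@dataclass(frozen=True)
class InheritanceCall:
    """Allo/auto verdict for one sample, with the alphas that produced it."""

    sample_id: str
    mode: str  # "allopolyploid" | "autopolyploid"
    alpha: AlphaEstimate
    caveat: str = ""  # e.g. "not-tetraploid" when the ploidy call disagrees


def tetraploid_nu_spec(scheme: str = "fixed_2") -> MixtureSpec:
    """The tetraploid normal-uniform spec with the default starting values."""
    return MixtureSpec(
        family="normal",
        with_uniform=True,
        scheme=scheme,
        ploidy="tetraploid",
        mvec=DEFAULT_START["mvec"],
        svec=DEFAULT_START["svec"],
        avec=DEFAULT_START["avec"],
    )


def estimate_alphas(
    sample: AllelicSample,
    seed: int | None = None,
    scheme: str = "fixed_2",
    max_iter: int = 1000,
) -> AlphaEstimate:
    """EM alpha estimation under the tetraploid normal-uniform model.

    Uses the documented default starting parameters; ``scheme`` defaults to
    alpha-and-variance free (the calibrated shape).  Raises on an empty
    sample.
    """
    if sample.n_sites == 0:
        raise ValueError("cannot estimate alphas for an empty sample")
    fit = em_fit(sample, tetraploid_nu_spec(scheme), seed=seed, max_iter=max_iter)
    a25, a50, a75, a_unif = fit.fitted_avec
    return AlphaEstimate(
        sample_id=sample.sample_id,
        alpha_25=a25,
        alpha_50=a50,
        alpha_75=a75,
        alpha_uniform=a_unif,
        loglik=fit.loglik,
    )


#: Default dominance margin for the allopolyploid call: roughly three
#: standard errors of a mixing-proportion estimate at ~1000 retained sites
#: (se ~ sqrt(1/3*2/3/1000) ~ 0.015).  With margin 0 the strict argmax rule
#: calls one of three symmetric alphas "largest" by chance alone, so a
#: tetrasomic sample would be misclassified about a third of the time however
#: much data is available; the margin asks for dominance beyond estimation
#: noise.  Pass ``margin=0`` for the verbatim strict-inequality rule.
DEFAULT_MARGIN = 0.05


def classify_inheritance(
    alpha: AlphaEstimate, margin: float = DEFAULT_MARGIN, caveat: str = ""
) -> InheritanceCall:
    """Classify allo- vs autopolyploid from the alpha estimate.

    Allopolyploid requires alpha_50 to exceed both alpha_25 and alpha_75 by
    more than ``margin``; equality (within the margin) and everything else is
    autopolyploid.  Pure function of its inputs.
    """
    is_allo = (
        alpha.alpha_50 > alpha.alpha_25 + margin
        and alpha.alpha_50 > alpha.alpha_75 + margin
    )
    return InheritanceCall(
        sample_id=alpha.sample_id,
        mode="allopolyploid" if is_allo else "autopolyploid",
        alpha=alpha,
        caveat=caveat,
    )


def plot_allele_ratio_histogram(
    sample: AllelicSample,
    out: str,
    alpha: AlphaEstimate | None = None,
    bins: int = 30,
) -> str:
    """Histogram of a sample's allelic ratios with the fitted normal-uniform
    mixture density overlaid; writes ``out`` and returns the path."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats

    if sample.n_sites == 0:
        raise ValueError("cannot plot an empty sample")
    spec = tetraploid_nu_spec()
    lo, hi = spec.support
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(
        sample.ratios, bins=bins, range=(lo, hi), density=True,
        color="#74a9cf", edgecolor="white",
    )
    if alpha is None:
        try:
            alpha = estimate_alphas(sample)
        except ValueError:
            alpha = None
    if alpha is not None:
        fit = em_fit(sample, spec)
        xs = np.linspace(lo, hi, 400)
        dens = np.zeros_like(xs)
        weights = fit.fitted_avec
        for w, m, s in zip(weights[:3], spec.mvec, fit.fitted_svec):
            dens += w * stats.norm.pdf(xs, m, s)
        dens += weights[3] / (hi - lo)
        ax.plot(xs, dens, color="#d7301f", lw=1.5, label="fitted mixture")
        ax.legend(frameon=False)
    ax.set_xlabel("allelic ratio (allele b / total depth)")
    ax.set_ylabel("density")
    ax.set_title(sample.sample_id or "allelic ratios")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
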