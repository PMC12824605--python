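"""Allelic-ratio mixture models: EM fitting, BIC ploidy selection, bootstrap.

The model family crosses three axes into 18 *shapes*:

* component **family**: ``normal``, ``beta`` (both on the ratio scale) or
  ``beta-binomial`` (on read counts, respecting per-site depth);
* an optional truncated-**uniform** noise component over the ratio
  truncation interval;
* a parameter-freedom **scheme**: ``fixed`` (mixing proportions free, scales
  fixed), ``fixed_2`` (mixing proportions and scales free), ``fixed_3``
  (scales free, mixing proportions fixed).  Component means are never free.

Each shape is fitted to one sample under three ploidy layouts whose component
means are the heterozygote-class expected ratios — diploid (0.5), triploid
(1/3, 2/3), tetraploid (0.25, 0.5, 0.75) — and the ploidy with the lowest BIC
wins (ties favour the lower ploidy).  Call stability is assessed by
resampling sites with replacement and re-running the selection.

Beta components are parameterised by mean ``m`` and scale ``s`` through
moment matching on the latent beta: ``nu = m(1-m)/s^2 - 1``, ``alpha = m*nu``,
``beta = (1-m)*nu``; beta-binomial components use the same mapping for their
latent beta.  Degenerate requests (``s^2 >= m(1-m)``) clamp ``s`` with a
logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize, special, stats

from ploidymix.depth_io import AllelicSample

__all__ = [
    "PLOIDIES",
    "MODEL_SHAPES",
    "ModelShape",
    "MixtureSpec",
    "MixtureFit",
    "PloidyCall",
    "component_layout",
    "default_spec",
    "em_fit",
    "bic",
    "fit_model_grid",
    "calibrate_model",
    "select_ploidy",
    "bootstrap_ploidy",
]

logger = logging.getLogger(__name__)

PLOIDIES = ("diploid", "triploid", "tetraploid")
FAMILIES = ("normal", "beta", "beta-binomial")
SCHEMES = ("fixed", "fixed_2", "fixed_3")

_LAYOUTS: dict[str, tuple[float, ...]] = {
    "diploid": (0.5,),
    "triploid": (1.0 / 3.0, 2.0 / 3.0),
    "tetraploid": (0.25, 0.50, 0.75),
}

#: Floor on component scales: with fixed means a component can otherwise
#: collapse onto repeated ratio values and send the likelihood to infinity.
MIN_SCALE = 1e-3


def component_layout(ploidy: str) -> tuple[float, ...]:
    """Heterozygote-class expected allelic ratios for a ploidy level."""
    try:
        return _LAYOUTS[ploidy]
    except KeyError:
        raise ValueError(f"unknown ploidy {ploidy!r}; expected one of {PLOIDIES}")


@dataclass(frozen=True)
class ModelShape:
    """One of the 18 members of the model family (ploidy-agnostic)."""

    family: str
    with_uniform: bool
    scheme: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def label(self) -> str:
        u = "uniform" if self.with_uniform else "plain"
        return f"{self.family}/{u}/{self.scheme}"

    @classmethod
    def from_label(cls, label: str) -> "ModelShape":
        family, u, scheme = label.split("/")
        return cls(family, u == "uniform", scheme)


MODEL_SHAPES: tuple[ModelShape, ...] = tuple(
    ModelShape(family, with_uniform, scheme)
    for family in FAMILIES
    for with_uniform in (False, True)
    for scheme in SCHEMES
)


@dataclass(frozen=True)
class MixtureSpec:
    """A fully specified mixture: shape + ploidy layout + starting parameters.

    ``avec`` holds mixing proportions over the heterozygote components plus,
    when ``with_uniform``, a trailing uniform-noise proportion.  ``support``
    is the ratio truncation interval on which the uniform component lives.
    When ``renormalize`` is true, component densities are renormalized over
    the support (off by default; see package docs).
    """

    family: str
    with_uniform: bool
    scheme: str
    ploidy: str
    mvec: tuple[float, ...]
    svec: tuple[float, ...]
    avec: tuple[float, ...]
    support: tuple[float, float] = (0.15, 0.85)
    renormalize: bool = False

    def __post_init__(self) -> None:
        ModelShape(self.family, self.with_uniform, self.scheme)  # validates
        if self.ploidy not in PLOIDIES:
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        k = len(self.mvec)
        if len(self.svec) != k:
            raise ValueError("svec length must match mvec")
        if len(self.avec) != k + (1 if self.with_uniform else 0):
            raise ValueError("avec length must be n_components (+1 with uniform)")
        if any(s <= 0 for s in self.svec):
            raise ValueError("svec entries must be > 0")
        if any(a < 0 for a in self.avec) or abs(sum(self.avec) - 1.0) > 1e-8:
            raise ValueError("avec entries must be >= 0 and sum to 1")
        if not all(0.0 < m < 1.0 for m in self.mvec) or list(self.mvec) != sorted(
            set(self.mvec)
        ):
            raise ValueError("mvec must be strictly increasing within (0,1)")

    @property
    def shape(self) -> ModelShape:
        return ModelShape(self.family, self.with_uniform, self.scheme)

    @property
    def n_components(self) -> int:
        return len(self.mvec)

    @property
    def n_free(self) -> int:
        """Free-parameter count under the scheme.

        ``fixed``: the K (+uniform) mixing proportions contribute K+u-1;
        ``fixed_2``: additionally the K component scales; ``fixed_3``: only
        the K scales.
        """
        k = self.n_components
        u = 1 if self.with_uniform else 0
        if self.scheme == "fixed":
            return k + u - 1
        if self.scheme == "fixed_2":
            return k + u - 1 + k
        return k  # fixed_3


def default_spec(
    shape: ModelShape,
    ploidy: str,
    scale: float = 0.01,
    uniform_weight: float = 0.1,
    support: tuple[float, float] = (0.15, 0.85),
    renormalize: bool = False,
) -> MixtureSpec:
    """Default starting parameters for a shape x ploidy layout.

    Heterozygote components share the non-uniform mass equally; with a
    uniform component the noise proportion starts at ``uniform_weight``
    (tetraploid default avec (0.3, 0.3, 0.3, 0.1)).
    """
    mvec = component_layout(ploidy)
    k = len(mvec)
    if shape.with_uniform:
        avec = tuple([(1.0 - uniform_weight) / k] * k + [uniform_weight])
    else:
        avec = tuple([1.0 / k] * k)
    return MixtureSpec(
        family=shape.family,
        with_uniform=shape.with_uniform,
        scheme=shape.scheme,
        ploidy=ploidy,
        mvec=mvec,
        svec=(scale,) * k,
        avec=avec,
        support=support,
        renormalize=renormalize,
    )


@dataclass
class MixtureFit:
    """Converged (or max-iteration) EM fit of one spec to one sample."""

    spec: MixtureSpec
    fitted_avec: tuple[float, ...]
    fitted_svec: tuple[float, ...]
    loglik: float
    n_free: int
    n_sites: int
    bic: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list, repr=False)


def bic(loglik: float, n_free: int, n_sites: int) -> float:
    """Bayesian Information Criterion ``k*ln(n) - 2*loglik`` (lower is better)."""
    if n_sites < 1:
        raise ValueError("BIC undefined for n_sites = 0")
    if n_free == 0:
        return -2.0 * loglik
    return n_free * math.log(n_sites) - 2.0 * loglik


# ---------------------------------------------------------------------------
# component densities


def _beta_params(m: float, s: float) -> tuple[float, float]:
    """Moment-matched beta (alpha, beta) for mean m and sd s, clamping
    degenerate requests s^2 >= m(1-m)."""
    vmax = m * (1.0 - m)
    if s * s >= vmax:
        s_clamped = math.sqrt(0.95 * vmax)
        logger.warning(
            "beta scale %.4g >= sqrt(m(1-m)) for mean %.3g; clamped to %.4g",
            s,
            m,
            s_clamped,
        )
        s = s_clamped
    nu = vmax / (s * s) - 1.0
    return m * nu, (1.0 - m) * nu


def _component_logdens(
    family: str,
    m: float,
    s: float,
    ratios: np.ndarray,
    b_counts: np.ndarray,
    totals: np.ndarray,
    support: tuple[float, float],
    renormalize: bool,
) -> np.ndarray:
    """Log density of one heterozygote-class component at every site."""
    lo, hi = support
    if family == "normal":
        ld = stats.norm.logpdf(ratios, loc=m, scale=s)
        if renormalize:
            mass = stats.norm.cdf(hi, m, s) - stats.norm.cdf(lo, m, s)
            ld -= math.log(max(mass, 1e-300))
        return ld
    if family == "beta":
        a, b = _beta_params(m, s)
        ld = stats.beta.logpdf(ratios, a, b)
        if renormalize:
            mass = stats.beta.cdf(hi, a, b) - stats.beta.cdf(lo, a, b)
            ld -= math.log(max(mass, 1e-300))
        return ld
    # beta-binomial on counts
    a, b = _beta_params(m, s)
    ld = stats.betabinom.logpmf(b_counts, totals, a, b)
    if renormalize:
        hi_k = np.floor(hi * totals)
        lo_k = np.ceil(lo * totals)
        mass = stats.betabinom.cdf(hi_k, totals, a, b) - stats.betabinom.cdf(
            lo_k - 1, totals, a, b
        )
        ld -= np.log(np.maximum(mass, 1e-300))
    return ld


def _uniform_logdens(
    family: str,
    ratios: np.ndarray,
    totals: np.ndarray,
    support: tuple[float, float],
) -> np.ndarray:
    """Log density of the noise component: constant 1/width on the ratio
    scale; for count models, discrete-uniform over the counts whose ratio
    falls inside the support."""
    lo, hi = support
    n = len(ratios)
    if family in ("normal", "beta"):
        return np.full(n, -math.log(hi - lo))
    n_valid = np.floor(hi * totals) - np.ceil(lo * totals) + 1.0
    return -np.log(np.maximum(n_valid, 1.0))


def _logdens_matrix(
    spec: MixtureSpec,
    svec: Iterable[float],
    sample: AllelicSample,
) -> np.ndarray:
    """(n_sites, n_components [+1]) matrix of component log densities."""
    cols = [
        _component_logdens(
            spec.family,
            m,
            s,
            sample.ratios,
            sample.b_counts,
            sample.totals,
            spec.support,
            spec.renormalize,
        )
        for m, s in zip(spec.mvec, svec)
    ]
    if spec.with_uniform:
        cols.append(
            _uniform_logdens(spec.family, sample.ratios, sample.totals, spec.support)
        )
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# EM


def _scale_bounds(family: str, m: float) -> tuple[float, float]:
    if family == "normal":
        return MIN_SCALE, 0.5
    return MIN_SCALE, 0.999 * math.sqrt(m * (1.0 - m))


def _update_scale(
    family: str,
    m: float,
    s_old: float,
    resp: np.ndarray,
    sample: AllelicSample,
    spec: MixtureSpec,
) -> float:
    """Maximise the responsibility-weighted component log likelihood in s.

    Normal components have the closed-form weighted-variance update; beta and
    beta-binomial scales are optimised numerically.  The update never
    decreases the weighted objective (falls back to ``s_old``), which keeps
    the generalised EM monotone.
    """
    lo, hi = _scale_bounds(family, m)
    w = resp
    wsum = w.sum()
    if wsum <= 1e-12:
        return s_old

    def neg_obj(s: float) -> float:
        ld = _component_logdens(
            family,
            m,
            s,
            sample.ratios,
            sample.b_counts,
            sample.totals,
            spec.support,
            spec.renormalize,
        )
        return -float(w @ ld)

    if family == "normal" and not spec.renormalize:
        var = float(w @ (sample.ratios - m) ** 2) / wsum
        s_new = min(max(math.sqrt(max(var, 0.0)), lo), hi)
    else:
        res = optimize.minimize_scalar(
            neg_obj, bounds=(lo, hi), method="bounded", options={"maxiter": 40}
        )
        s_new = float(res.x)
    s_old_clamped = min(max(s_old, lo), hi)
    if neg_obj(s_new) > neg_obj(s_old_clamped):
        return s_old_clamped
    return s_new


def em_fit(
    sample: AllelicSample,
    spec: MixtureSpec,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int | None = None,
) -> MixtureFit:
    """Fit ``spec`` to ``sample`` by (generalised) EM.

    Only the parameters free under ``spec.scheme`` move; the per-iteration
    log likelihood is non-decreasing.  Convergence is declared when the log
    likelihood changes by less than ``tol``; otherwise the fit is returned
    after ``max_iter`` iterations with ``converged=False``.  ``seed`` is
    accepted for interface uniformity — the algorithm is deterministic.
    """
    del seed
    n = sample.n_sites
    if n == 0:
        raise ValueError("cannot fit a mixture to an empty sample")
    if n < spec.n_free:
        raise ValueError(
            f"n_sites={n} < {spec.n_free} free parameters for {spec.shape.label}"
        )

    avec = np.asarray(spec.avec, dtype=float)
    svec = [max(s, MIN_SCALE) for s in spec.svec]
    free_alpha = spec.scheme in ("fixed", "fixed_2")
    free_scale = spec.scheme in ("fixed_2", "fixed_3")

    logdens = _logdens_matrix(spec, svec, sample)
    trace: list[float] = []
    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore"):
            log_weighted = logdens + np.log(avec)
        log_norm = special.logsumexp(log_weighted, axis=1)
        new_loglik = float(log_norm.sum())
        trace.append(new_loglik)
        if new_loglik - loglik < tol and it > 1:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

        resp = np.exp(log_weighted - log_norm[:, None])
        if free_alpha:
            avec = resp.mean(axis=0)
            avec = np.maximum(avec, 0.0)
            avec /= avec.sum()
        if free_scale:
            for c, m in enumerate(spec.mvec):
                svec[c] = _update_scale(
                    spec.family, m, svec[c], resp[:, c], sample, spec
                )
            logdens = _logdens_matrix(spec, svec, sample)
        elif free_alpha:
            pass  # densities unchanged; only weights moved
        else:  # nothing free: single evaluation suffices
            converged = True
            break

    return MixtureFit(
        spec=spec,
        fitted_avec=tuple(float(a) for a in avec),
        fitted_svec=tuple(float(s) for s in svec),
        loglik=loglik,
        n_free=spec.n_free,
        n_sites=n,
        bic=bic(loglik, spec.n_free, n),
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# model grid, calibration, ploidy selection


def fit_model_grid(
    sample: AllelicSample,
    ploidies: Iterable[str] = PLOIDIES,
    scale: float = 0.01,
    renormalize: bool = False,
    max_iter: int = 1000,
) -> tuple[dict[ModelShape, dict[str, MixtureFit]], dict[tuple[ModelShape, str], str]]:
    """Fit all 18 shapes under each ploidy layout.

    Returns ``(fits, errors)``: fits[shape][ploidy] for every cell that
    fitted, and a map of failed cells to their error message (failures do not
    abort the grid).
    """
    fits: dict[ModelShape, dict[str, MixtureFit]] = {}
    errors: dict[tuple[ModelShape, str], str] = {}
    for shape in MODEL_SHAPES:
        fits[shape] = {}
        for ploidy in ploidies:
            spec = default_spec(shape, ploidy, scale=scale, renormalize=renormalize)
            try:
                fits[shape][ploidy] = em_fit(sample, spec, max_iter=max_iter)
            except Exception as exc:  # noqa: BLE001 — recorded per cell
                errors[(shape, ploidy)] = str(exc)
    return fits, errors


def _shape_complexity(shape: ModelShape) -> int:
    """Free-parameter count of a shape under its richest (tetraploid) layout."""
    return default_spec(shape, "tetraploid").n_free


def calibrate_model(
    fits_by_sample: Mapping[str, Mapping[ModelShape, Mapping[str, MixtureFit]]],
    truth: Mapping[str, str],
) -> ModelShape:
    """Pick the shape whose within-shape BIC ploidy calls best match known
    ploidies.

    Ties break toward fewer free parameters, then family order
    normal < beta < beta-binomial.
    """
    if not truth:
        raise ValueError("calibration requires at least one known-ploidy sample")
    accuracy: dict[ModelShape, float] = {}
    for shape in MODEL_SHAPES:
        correct = 0
        total = 0
        for sample_id, true_ploidy in truth.items():
            per_ploidy = fits_by_sample.get(sample_id, {}).get(shape)
            if not per_ploidy:
                continue
            total += 1
            called = _argmin_bic({p: f.bic for p, f in per_ploidy.items()})
            if called == true_ploidy:
                correct += 1
        accuracy[shape] = correct / total if total else -1.0
    return min(
        MODEL_SHAPES,
        key=lambda sh: (
            -accuracy[sh],
            _shape_complexity(sh),
            FAMILIES.index(sh.family),
        ),
    )


def _argmin_bic(per_ploidy_bic: Mapping[str, float]) -> str:
    """Lowest-BIC ploidy; exact ties resolve to the lower ploidy level."""
    best = None
    best_bic = math.inf
    for ploidy in PLOIDIES:  # ordered low -> high so ties keep the lower
        if ploidy not in per_ploidy_bic:
            continue
        b = per_ploidy_bic[ploidy]
        if b < best_bic:
            best, best_bic = ploidy, b
    if best is None:
        raise ValueError("no ploidy fits available")
    return best


@dataclass
class PloidyCall:
    """Best-BIC ploidy for one sample, optionally with bootstrap tallies."""

    sample_id: str
    shape: ModelShape
    per_ploidy_bic: dict[str, float]
    best_ploidy: str
    bootstrap_tally: dict[str, int] = field(default_factory=dict)
    n_boot: int = 0

    @property
    def confident(self) -> bool:
        """True when the winning ploidy took more than 60% of bootstrap
        replicates (the > 600/1000 stability rule)."""
        if not self.n_boot:
            return False
        return self.bootstrap_tally.get(self.best_ploidy, 0) > 0.6 * self.n_boot


def select_ploidy(
    sample: AllelicSample,
    shape: ModelShape,
    scale: float = 0.01,
    renormalize: bool = False,
    max_iter: int = 1000,
) -> PloidyCall:
    """Call ploidy for one sample under one model shape by BIC comparison of
    the diploid / triploid / tetraploid layouts."""
    per_ploidy_bic: dict[str, float] = {}
    for ploidy in PLOIDIES:
        spec = default_spec(shape, ploidy, scale=scale, renormalize=renormalize)
        fit = em_fit(sample, spec, max_iter=max_iter)
        per_ploidy_bic[ploidy] = fit.bic
    return PloidyCall(
        sample_id=sample.sample_id,
        shape=shape,
        per_ploidy_bic=per_ploidy_bic,
        best_ploidy=_argmin_bic(per_ploidy_bic),
    )


def bootstrap_ploidy(
    sample: AllelicSample,
    shape: ModelShape,
    n_boot: int = 1000,
    seed: int = 0,
    scale: float = 0.01,
    max_iter: int = 200,
) -> dict[str, int]:
    """Bootstrap model competition: resample sites with replacement, re-run
    :func:`select_ploidy`, and tally the winning ploidy per replicate.

    Replicate ``r`` uses seed ``seed + r``, so tallies are reproducible and
    individual replicates can be replayed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if sample.n_sites == 0:
        raise ValueError("cannot bootstrap an empty sample")
    tally = {p: 0 for p in PLOIDIES}
    n = sample.n_sites
    for r in range(n_boot):
        rng = np.random.default_rng(seed + r)
        idx = rng.integers(0, n, size=n)
        boot = AllelicSample(
            sample_id=sample.sample_id,
            ratios=sample.ratios[idx],
            totals=sample.totals[idx],
            b_counts=sample.b_counts[idx],
        )
        call = select_ploidy(boot, shape, scale=scale, max_iter=max_iter)
        tally[call.best_ploidy] += 1
    return tally


def attach_bootstrap(call: PloidyCall, tally: dict[str, int]) -> PloidyCall:
    """Return a copy of ``call`` carrying a bootstrap tally."""
    n_boot = sum(tally.values())
    return PloidyCall(
        sample_id=call.sample_id,
        shape=call.shape,
        per_ploidy_bic=dict(call.per_ploidy_bic),
        best_ploidy=call.best_ploidy,
        bootstrap_tally=dict(tally),
        n_boot=n_boot,
    )
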