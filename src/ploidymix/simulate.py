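"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's three input kinds:

* **allelic depths** — per-site read counts whose ratio spectrum carries the
  ploidy signal: heterozygote classes at 0.5 (diploid), 1/3 and 2/3
  (triploid), 0.25/0.5/0.75 (tetraploid), with tetrasomic (equal classes) or
  disomic (0.5-dominated) mixing for tetraploids, a uniform-noise site
  fraction, finite sequencing depth, per-read error and optional
  beta-binomial overdispersion;
* **trees and binary traits** — ultrametric Yule trees of unit depth with
  tip states assigned either uniformly at random at a fixed prevalence or by
  thresholding a Brownian liability (the two nulls of Fritz's D);
* **per-locus p-value tables** — four annotation classes at the study's
  locus counts (defence chemistry 113, single copy 1044, differentially
  expressed 109, miscellaneous 54) with a configurable fraction of
  true-signal loci per run x annotation, signal p-values ~ Beta(a, 1) and
  null p-values ~ Uniform(0, 1).

Every generator is deterministic given its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ploidymix.depth_io import SiteDepthRecord
from ploidymix.phylo_signal import (
    PhyloTree,
    brownian_liabilities,
    threshold_by_rank,
    tree_from_dendropy,
)
from ploidymix.selection import ANNOTATIONS, LocusSelectionRecord

__all__ = [
    "DepthSimConfig",
    "TraitSimConfig",
    "PvalSimConfig",
    "simulate_depths",
    "simulate_tree",
    "simulate_binary_trait",
    "simulate_pvalue_table",
]

DEFAULT_CLASS_PROBS = {
    ("diploid", None): (1.0,),
    ("triploid", None): (0.5, 0.5),
    ("tetraploid", "tetrasomic"): (1 / 3, 1 / 3, 1 / 3),
    ("tetraploid", "disomic"): (0.15, 0.70, 0.15),
}

CLASS_MEANS = {
    "diploid": (0.5,),
    "triploid": (1 / 3, 2 / 3),
    "tetraploid": (0.25, 0.5, 0.75),
}

#: Default per-annotation locus counts (defence chemistry, single copy,
#: differentially expressed, miscellaneous) — 1320 loci in total.
DEFAULT_ANNOTATION_COUNTS = {
    "defence_chemistry": 113,
    "single_copy": 1044,
    "differentially_expressed": 109,
    "miscellaneous": 54,
}


@dataclass
class DepthSimConfig:
    """Configuration of the allelic-depth generator for one sample.

    ``class_probs`` defaults to the inheritance-appropriate mixing:
    tetrasomic tetraploids (1/3, 1/3, 1/3), disomic tetraploids
    (0.15, 0.70, 0.15); heterozygote-class means are used as the true
    allelic ratios, with optional within-class Gaussian jitter.
    """

    ploidy: str = "diploid"
    inheritance: str | None = None  # tetraploid only: disomic | tetrasomic
    class_probs: tuple[float, ...] | None = None
    noise_prob: float = 0.05
    n_sites: int = 1000
    depth_mean: float = 50.0
    depth_model: str = "poisson"  # fixed | poisson | negative-binomial
    depth_shape: float = 5.0  # negative-binomial size parameter
    error_rate: float = 0.01
    overdispersion_rho: float = 0.0
    class_jitter_sd: float = 0.0
    sample_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy not in CLASS_MEANS:
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        if self.ploidy == "tetraploid" and self.inheritance is None:
            self.inheritance = "tetrasomic"
        if self.ploidy != "tetraploid":
            self.inheritance = None
        if self.class_probs is None:
            self.class_probs = DEFAULT_CLASS_PROBS[(self.ploidy, self.inheritance)]
        k = len(CLASS_MEANS[self.ploidy])
        if len(self.class_probs) != k or abs(sum(self.class_probs) - 1.0) > 1e-8:
            raise ValueError(
                f"class_probs must have {k} entries summing to 1 for {self.ploidy}"
            )
        if self.n_sites < 0 or self.depth_mean < 1:
            raise ValueError("need n_sites >= 0 and depth_mean >= 1")
        if not (0.0 <= self.noise_prob <= 1.0):
            raise ValueError("noise_prob must be in [0,1]")
        if not (0.0 <= self.overdispersion_rho < 1.0):
            raise ValueError("overdispersion_rho must be in [0,1)")
        if self.depth_model not in ("fixed", "poisson", "negative-binomial"):
            raise ValueError(f"unknown depth_model {self.depth_model!r}")


def simulate_depths(cfg: DepthSimConfig) -> list[SiteDepthRecord]:
    """Generate per-site allelic-depth records under ``cfg``.

    Per site: total depth N from the depth model; with probability
    ``noise_prob`` a uniform true ratio, otherwise a heterozygote class mean;
    allele-b reads ~ Binomial(N, r') with r' = r(1-e) + (1-r)e folding in the
    per-read error rate e, or beta-binomial when ``overdispersion_rho > 0``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_sites
    if n == 0:
        return []

    if cfg.depth_model == "fixed":
        totals = np.full(n, int(round(cfg.depth_mean)), dtype=np.int64)
    elif cfg.depth_model == "poisson":
        totals = rng.poisson(cfg.depth_mean, size=n)
    else:
        k = cfg.depth_shape
        p = k / (k + cfg.depth_mean)
        totals = rng.negative_binomial(k, p, size=n)
    totals = np.maximum(totals, 1)

    means = np.array(CLASS_MEANS[cfg.ploidy])
    classes = rng.choice(len(means), size=n, p=np.asarray(cfg.class_probs))
    ratios = means[classes]
    if cfg.class_jitter_sd > 0:
        ratios = np.clip(
            ratios + rng.normal(0.0, cfg.class_jitter_sd, size=n), 1e-6, 1 - 1e-6
        )
    is_noise = rng.random(n) < cfg.noise_prob
    ratios = np.where(is_noise, rng.random(n), ratios)

    eps = cfg.error_rate
    p_read = ratios * (1.0 - eps) + (1.0 - ratios) * eps
    if cfg.overdispersion_rho > 0:
        rho = cfg.overdispersion_rho
        nu = (1.0 - rho) / rho
        a = p_read * nu
        b = (1.0 - p_read) * nu
        p_read = rng.beta(a, b)
    b_counts = rng.binomial(totals, p_read)

    return [
        SiteDepthRecord(
            sample_id=cfg.sample_id,
            locus_id=f"L{i:06d}",
            depth_a=int(totals[i] - b_counts[i]),
            depth_b=int(b_counts[i]),
        )
        for i in range(n)
    ]


def simulate_tree(n_tips: int, seed: int = 0) -> PhyloTree:
    """Ultrametric Yule (pure-birth) tree with unit root-to-tip depth and
    tip labels ``t1..tn``."""
    import dendropy

    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = np.random.default_rng(seed)

    # grow lineages: with k extant lineages the next split waits Exp(k)
    next_id = [0]

    def new_node(birth: float) -> dict:
        next_id[0] += 1
        return {"id": next_id[0], "birth": birth, "children": None}

    root = new_node(0.0)
    root["split"] = 0.0  # the root divergence defines time zero
    kids = [new_node(0.0), new_node(0.0)]
    root["children"] = kids
    active = list(kids)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        node = active.pop(idx)
        node["split"] = t
        node["children"] = [new_node(t), new_node(t)]
        active.extend(node["children"])
    present = t + rng.exponential(1.0 / n_tips)

    labels = iter(f"t{i}" for i in range(1, n_tips + 1))

    def to_newick(node: dict) -> str:
        if node["children"] is None:
            return f"{next(labels)}:{present - node['birth']:.10f}"
        left, right = node["children"]
        inner = f"({to_newick(left)},{to_newick(right)})"
        if node is root:
            return inner
        return f"{inner}:{node['split'] - node['birth']:.10f}"

    newick = to_newick(root) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    flat = tree_from_dendropy(tree, seed=seed)
    flat.edge_len = flat.edge_len / max(present, 1e-12)  # unit depth
    return flat


@dataclass
class TraitSimConfig:
    """Binary-trait simulation: random tip assignment or Brownian threshold."""

    n_tips: int = 50
    prevalence: float = 0.15
    model: str = "random"  # random | brownian_threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0,1)")
        if self.model not in ("random", "brownian_threshold"):
            raise ValueError(f"unknown trait model {self.model!r}")


def simulate_binary_trait(tree: PhyloTree, cfg: TraitSimConfig) -> dict[str, int]:
    """Assign 0/1 states to the tips of ``tree``.

    The state-1 count is ``round(prevalence * n_tips)`` under banker's
    rounding (round-half-even).  ``random`` picks that many tips uniformly;
    ``brownian_threshold`` simulates a unit-rate Brownian liability and marks
    the top-k tips.
    """
    n = tree.n_tips
    k = round(cfg.prevalence * n)  # Python round = round-half-even
    if k < 1 or k > n - 1:
        raise ValueError(
            f"prevalence {cfg.prevalence} with {n} tips gives degenerate k={k}"
        )
    rng = np.random.default_rng(cfg.seed)
    if cfg.model == "random":
        ones = rng.choice(n, size=k, replace=False)
        states = np.zeros(n, dtype=int)
        states[ones] = 1
    else:
        lia = brownian_liabilities(tree, 1, rng)
        states = threshold_by_rank(lia, k, rng)[:, 0].astype(int)
    return {label: int(s) for label, s in zip(tree.tip_labels, states)}


@dataclass
class PvalSimConfig:
    """Per-locus selection p-value tables with annotation-class structure."""

    annotation_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ANNOTATION_COUNTS)
    )
    runs: tuple[str, ...] = ("polyploid", *(f"diploid_{i}" for i in range(1, 7)))
    signal_fraction: dict = field(default_factory=dict)  # (run, annotation) or run
    signal_beta_a: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for ann, n in self.annotation_counts.items():
            if ann not in ANNOTATIONS:
                raise ValueError(f"unknown annotation {ann!r}")
            if n < 0:
                raise ValueError("annotation counts must be >= 0")
        for frac in self.signal_fraction.values():
            if not (0.0 <= frac <= 1.0):
                raise ValueError("signal fractions must be in [0,1]")

    def fraction_for(self, run: str, annotation: str) -> float:
        if (run, annotation) in self.signal_fraction:
            return self.signal_fraction[(run, annotation)]
        return self.signal_fraction.get(run, 0.0)


def simulate_pvalue_table(cfg: PvalSimConfig) -> list[LocusSelectionRecord]:
    """Generate per-run p-value tables with planted signal.

    Locus ids are shared across runs; within each run x annotation the first
    ``round(fraction * n)`` loci carry signal p-values ~ Beta(signal_beta_a, 1)
    and the remainder are null ~ Uniform(0, 1).
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[LocusSelectionRecord] = []
    for run in cfg.runs:
        for ann, n in cfg.annotation_counts.items():
            if n == 0:
                continue
            frac = cfg.fraction_for(run, ann)
            n_signal = int(round(frac * n))
            p = rng.random(n)
            if n_signal:
                p[:n_signal] = rng.beta(cfg.signal_beta_a, 1.0, size=n_signal)
            for i in range(n):
                records.append(
                    LocusSelectionRecord(
                        locus_id=f"{ann}_{i:05d}",
                        annotation=ann,
                        run_id=run,
                        p_raw=float(p[i]),
                    )
                )
    return records
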