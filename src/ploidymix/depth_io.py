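"""Read, validate and filter per-site allelic-depth data.

The unit of ploidy inference is one sample's vector of allelic ratios
``x_i = depth_b / (depth_a + depth_b)`` over biallelic sites.  Before model
fitting, sites are filtered in a fixed order:

1. **depth** — total depth must reach ``min_depth`` (default 10);
2. **error** — the minor-allele count must not be attributable to sequencing
   error alone: a site is dropped when ``P(X >= m | X ~ Binomial(N, error_rate))``
   exceeds ``error_alpha``, i.e. the minor allele is plausibly pure noise;
3. **truncation** — the ratio must lie inside ``[trunc_low, trunc_high]``
   (default [0.15, 0.85]), removing homozygous-looking tails.

Each removed site is attributed to the first filter that rejects it, so the
per-filter removal counts always sum with the retained count to the input
count.  Ratios are kept unfolded (never reflected to <= 0.5) because the
tetraploid heterozygote classes at 0.25 and 0.75 must stay distinguishable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "SiteDepthRecord",
    "FilterConfig",
    "FilterReport",
    "AllelicSample",
    "read_site_depths",
    "write_site_depths",
    "filter_sites",
]

TSV_COLUMNS = ("sample_id", "locus_id", "depth_a", "depth_b")


class DepthValidationError(ValueError):
    """Malformed or invariant-violating depth input."""


@dataclass(frozen=True)
class SiteDepthRecord:
    """One biallelic site in one sample: read depths of the two alleles."""

    sample_id: str
    locus_id: str
    depth_a: int
    depth_b: int

    def __post_init__(self) -> None:
        if not self.sample_id or not self.locus_id:
            raise DepthValidationError("sample_id and locus_id must be non-empty")
        if self.depth_a < 0 or self.depth_b < 0:
            raise DepthValidationError(
                f"negative depth at {self.sample_id}/{self.locus_id}: "
                f"({self.depth_a}, {self.depth_b})"
            )
        if self.depth_a + self.depth_b < 1:
            raise DepthValidationError(
                f"zero total depth at {self.sample_id}/{self.locus_id}"
            )

    @property
    def total(self) -> int:
        return self.depth_a + self.depth_b

    @property
    def ratio(self) -> float:
        return self.depth_b / self.total


@dataclass(frozen=True)
class FilterConfig:
    """Site-filtering thresholds.

    Parameters
    ----------
    min_depth
        Minimum total read depth per site (reads).
    error_rate
        Assumed per-read sequencing error probability.
    error_alpha
        Tail-probability threshold of the binomial error filter: a site is
        removed when its minor-allele count is exceeded with probability
        greater than ``error_alpha`` under pure error.
    trunc_low, trunc_high
        Allelic-ratio truncation interval retained for analysis.
    """

    min_depth: int = 10
    error_rate: float = 0.01
    error_alpha: float = 0.05
    trunc_low: float = 0.15
    trunc_high: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 < self.trunc_low < self.trunc_high < 1.0):
            raise DepthValidationError("need 0 < trunc_low < trunc_high < 1")
        if not (0.0 < self.error_rate < 0.5):
            raise DepthValidationError("need 0 < error_rate < 0.5")
        if self.min_depth < 1:
            raise DepthValidationError("min_depth must be >= 1")
        if not (0.0 < self.error_alpha < 1.0):
            raise DepthValidationError("error_alpha must be in (0, 1)")


@dataclass
class FilterReport:
    """Per-sample accounting of sites removed by each filter, in order."""

    sample_id: str
    retained: int = 0
    removed_by_depth: int = 0
    removed_by_error: int = 0
    removed_by_truncation: int = 0

    @property
    def n_input(self) -> int:
        return (
            self.retained
            + self.removed_by_depth
            + self.removed_by_error
            + self.removed_by_truncation
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "sample_id": self.sample_id,
                "retained": self.retained,
                "removed_by_depth": self.removed_by_depth,
                "removed_by_error": self.removed_by_error,
                "removed_by_truncation": self.removed_by_truncation,
            }
        )


@dataclass
class AllelicSample:
    """Filtered allelic-ratio data for one accession.

    ``ratios``, ``totals`` and ``b_counts`` are parallel vectors over the
    retained sites; ratio-based mixture models consume ``ratios`` while
    count-based (beta-binomial) models consume ``b_counts`` / ``totals``.
    """

    sample_id: str
    ratios: np.ndarray = field(default_factory=lambda: np.empty(0))
    totals: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    b_counts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        self.b_counts = np.asarray(self.b_counts, dtype=np.int64)
        if not (len(self.ratios) == len(self.totals) == len(self.b_counts)):
            raise DepthValidationError("ratio/total/count vectors differ in length")

    @property
    def n_sites(self) -> int:
        return len(self.ratios)


def read_site_depths(path: str | Path) -> list[SiteDepthRecord]:
    """Parse a site-depth TSV into validated records.

    The format is one header row ``sample_id<TAB>locus_id<TAB>depth_a<TAB>depth_b``
    followed by one row per site per sample; lines starting with ``#`` are
    comments.  Malformed rows raise :class:`DepthValidationError` naming the
    offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SiteDepthRecord] = []
    header: list[str] | None = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if tuple(header) != TSV_COLUMNS:
                    raise DepthValidationError(
                        f"line {lineno}: expected header {list(TSV_COLUMNS)}, "
                        f"got {header}"
                    )
                continue
            if len(fields) != 4:
                raise DepthValidationError(
                    f"line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
                )
            try:
                da, db = int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise DepthValidationError(
                    f"line {lineno}: non-integer depth: {exc}"
                ) from exc
            try:
                records.append(SiteDepthRecord(fields[0], fields[1], da, db))
            except DepthValidationError as exc:
                raise DepthValidationError(f"line {lineno}: {exc}") from exc
    if header is None:
        raise DepthValidationError(f"{path}: no header row found")
    return records


def write_site_depths(
    records: list[SiteDepthRecord], path: str | Path, comment: str | None = None
) -> None:
    """Write records in the TSV format read by :func:`read_site_depths`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.locus_id}\t{r.depth_a}\t{r.depth_b}\n")


def filter_sites(
    records: list[SiteDepthRecord], cfg: FilterConfig | None = None
) -> tuple[AllelicSample, FilterReport]:
    """Filter one sample's sites and assemble its :class:`AllelicSample`.

    Filters apply in the fixed order depth -> error -> truncation, each site
    attributed to the first filter that removes it.  An empty input yields an
    empty sample (``n_sites = 0``), not an error; mixed sample ids raise.
    """
    cfg = cfg or FilterConfig()
    if not records:
        return AllelicSample(sample_id=""), FilterReport(sample_id="")

    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) != 1:
        raise DepthValidationError(
            f"filter_sites expects one sample, got {sorted(sample_ids)}"
        )
    sample_id = records[0].sample_id

    da = np.array([r.depth_a for r in records], dtype=np.int64)
    db = np.array([r.depth_b for r in records], dtype=np.int64)
    totals = da + db
    ratios = db / totals
    minor = np.minimum(da, db)

    report = FilterReport(sample_id=sample_id)
    alive = np.ones(len(records), dtype=bool)

    fail_depth = totals < cfg.min_depth
    report.removed_by_depth = int(np.count_nonzero(alive & fail_depth))
    alive &= ~fail_depth

    # P(X >= m | Binomial(N, error_rate)) > error_alpha  =>  minor allele is
    # plausibly pure sequencing error => drop the site.
    tail = stats.binom.sf(minor - 1, totals, cfg.error_rate)
    fail_error = tail > cfg.error_alpha
    report.removed_by_error = int(np.count_nonzero(alive & fail_error))
    alive &= ~fail_error

    fail_trunc = (ratios < cfg.trunc_low) | (ratios > cfg.trunc_high)
    report.removed_by_truncation = int(np.count_nonzero(alive & fail_trunc))
    alive &= ~fail_trunc

    report.retained = int(np.count_nonzero(alive))
    sample = AllelicSample(
        sample_id=sample_id,
        ratios=ratios[alive],
        totals=totals[alive],
        b_counts=db[alive],
    )
    return sample, report
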