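"""Balanced foreground design, FDR correction and enrichment tests.

Branch-site selection tests gain power with the number of foreground taxa,
so a polyploid foreground (n = 29) is compared against several diploid
foregrounds of matched size (27-28 taxa drawn from the diploid pool without
replacement).  Per-locus raw p-values from the selection software are
consumed as input; this module adjusts them with Benjamini-Hochberg FDR at
5% and asks two questions with Pearson chi-squared tests: within each
diploid run, is selection associated with locus annotation class, and within
each annotation class, is selection associated with ploidy (polyploid run vs
each diploid run)?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ANNOTATIONS",
    "LocusSelectionRecord",
    "FdrResult",
    "ContingencyResult",
    "ForegroundDesign",
    "build_foreground_sets",
    "bh_fdr",
    "chi_square_test",
    "compare_selection",
    "read_selection_table",
    "write_selection_table",
]

logger = logging.getLogger(__name__)

ANNOTATIONS = (
    "defence_chemistry",
    "single_copy",
    "differentially_expressed",
    "miscellaneous",
)

TSV_COLUMNS = ("locus_id", "annotation", "run_id", "p_raw")


@dataclass(frozen=True)
class LocusSelectionRecord:
    """Raw selection-test p-value for one locus in one foreground run."""

    locus_id: str
    annotation: str
    run_id: str
    p_raw: float

    def __post_init__(self) -> None:
        if self.annotation not in ANNOTATIONS:
            raise ValueError(
                f"unknown annotation {self.annotation!r}; expected {ANNOTATIONS}"
            )
        if not (0.0 <= self.p_raw <= 1.0):
            raise ValueError(f"p_raw must be in [0,1], got {self.p_raw}")


@dataclass(frozen=True)
class FdrResult:
    locus_id: str
    p_raw: float
    p_adj: float
    selected: bool


@dataclass(frozen=True)
class ContingencyResult:
    """Pearson chi-squared test of independence on a counts table."""

    table: tuple[tuple[int, ...], ...]
    chi2: float
    df: int
    p: float


@dataclass
class ForegroundDesign:
    """One polyploid foreground plus balanced diploid foreground sets."""

    polyploid_set: list[str]
    diploid_sets: list[list[str]]
    seed: int
    reused_taxa: list[str] = field(default_factory=list)

    @property
    def n_reused(self) -> int:
        return len(self.reused_taxa)


def build_foreground_sets(
    diploid_pool: Sequence[str],
    polyploid_set: Sequence[str] = (),
    n_sets: int = 6,
    size_range: tuple[int, int] = (27, 28),
    seed: int = 0,
) -> ForegroundDesign:
    """Draw ``n_sets`` diploid foreground sets without replacement.

    Set sizes are made as equal as possible within ``size_range`` given the
    pool: every set starts at the lower bound and is grown toward the upper
    bound while the pool allows.  Taxa are drawn sequentially from a seeded
    shuffle of the pool; if the pool is too small to supply all sets
    disjointly, the least-used taxa are reused and the reuse is logged (with
    160 diploids and six sets of 27, exactly two taxa are reused).
    """
    lo, hi = size_range
    pool = list(dict.fromkeys(diploid_pool))
    if len(pool) < lo:
        raise ValueError(
            f"diploid pool of {len(pool)} cannot supply one set of {lo}"
        )
    sizes = [lo] * n_sets
    spare = len(pool) - lo * n_sets
    i = 0
    while spare > 0 and any(s < hi for s in sizes):
        if sizes[i % n_sets] < hi:
            sizes[i % n_sets] += 1
            spare -= 1
        i += 1

    rng = np.random.default_rng(seed)
    order = [pool[i] for i in rng.permutation(len(pool))]
    use_count = {t: 0 for t in pool}
    sets: list[list[str]] = []
    reused: list[str] = []
    cursor = 0
    for size in sizes:
        chosen: list[str] = []
        while len(chosen) < size and cursor < len(order):
            chosen.append(order[cursor])
            cursor += 1
        if len(chosen) < size:
            # pool exhausted: reuse the least-used taxa not already in this set
            candidates = sorted(
                (t for t in pool if t not in chosen),
                key=lambda t: (use_count[t], order.index(t)),
            )
            for t in candidates[: size - len(chosen)]:
                chosen.append(t)
                reused.append(t)
        for t in chosen:
            use_count[t] += 1
        sets.append(chosen)
    if reused:
        logger.warning(
            "diploid pool exhausted: reused %d taxa across sets: %s",
            len(reused),
            reused,
        )
    return ForegroundDesign(
        polyploid_set=list(polyploid_set),
        diploid_sets=sets,
        seed=seed,
        reused_taxa=reused,
    )


def bh_fdr(
    records: Sequence[LocusSelectionRecord] | Sequence[float], q: float = 0.05
) -> list[FdrResult]:
    """Benjamini-Hochberg step-up adjusted p-values; selected = p_adj < q."""
    if not len(records):
        return []
    if isinstance(records[0], LocusSelectionRecord):
        ids = [r.locus_id for r in records]
        p_raw = np.array([r.p_raw for r in records])
    else:
        ids = [f"p{i}" for i in range(len(records))]
        p_raw = np.asarray(records, dtype=float)
    if np.any((p_raw < 0) | (p_raw > 1)):
        raise ValueError("p-values must lie in [0,1]")
    _, p_adj, _, _ = multipletests(p_raw, alpha=q, method="fdr_bh")
    return [
        FdrResult(locus_id=i, p_raw=float(p), p_adj=float(pa), selected=bool(pa < q))
        for i, p, pa in zip(ids, p_raw, p_adj)
    ]


def chi_square_test(
    table: Sequence[Sequence[int]], yates: bool = False
) -> ContingencyResult:
    """Pearson chi-squared test of independence (no continuity correction by
    default) on a counts table of at least 2x2 with no all-zero row/column."""
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a counts matrix of at least 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.floor(arr)) or np.any(arr < 0):
            raise ValueError("counts must be non-negative integers")
        arr = arr.astype(np.int64)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate table: all-zero row or column")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=yates)
    return ContingencyResult(
        table=tuple(tuple(int(v) for v in row) for row in arr),
        chi2=float(chi2),
        df=int(df),
        p=float(p),
    )


@dataclass
class SelectionSummary:
    """Counts, percentages and chi-squared tests across foreground runs."""

    counts: pd.DataFrame  # run_id, annotation, n_selected, n_total, pct_selected
    annotation_tests: dict[str, ContingencyResult]  # per diploid run
    annotation_tests_selected_only: dict[str, ContingencyResult]
    ploidy_tests: dict[tuple[str, str], ContingencyResult]  # (annotation, run)
    fdr: pd.DataFrame  # locus_id, annotation, run_id, p_raw, p_adj, selected


def compare_selection(
    records: Iterable[LocusSelectionRecord],
    polyploid_run: str,
    q: float = 0.05,
    yates: bool = False,
) -> SelectionSummary:
    """Full enrichment comparison over one polyploid and >= 1 diploid runs.

    FDR adjustment is applied within each run across all its loci.  Emits
    per run x annotation counts/percentages of selected loci; per diploid run
    a selected/not x annotation test (and the 2xK selected-counts-only
    variant); and per annotation a ploidy x selection test of the polyploid
    run against each diploid run.
    """
    df = pd.DataFrame(
        [
            (r.locus_id, r.annotation, r.run_id, r.p_raw)
            for r in records
        ],
        columns=list(TSV_COLUMNS),
    )
    if df.empty:
        raise ValueError("no selection records provided")
    runs = sorted(df["run_id"].unique())
    if polyploid_run not in runs:
        raise ValueError(f"polyploid run {polyploid_run!r} missing from input")
    diploid_runs = [r for r in runs if r != polyploid_run]
    if not diploid_runs:
        raise ValueError("need at least one diploid run")

    fdr_frames = []
    for run in runs:
        sub = df[df["run_id"] == run].reset_index(drop=True)
        res = bh_fdr(
            [
                LocusSelectionRecord(*row)
                for row in sub.itertuples(index=False, name=None)
            ],
            q=q,
        )
        sub = sub.assign(
            p_adj=[r.p_adj for r in res], selected=[r.selected for r in res]
        )
        fdr_frames.append(sub)
    fdr = pd.concat(fdr_frames, ignore_index=True)

    grouped = (
        fdr.groupby(["run_id", "annotation"], sort=True)
        .agg(n_selected=("selected", "sum"), n_total=("selected", "size"))
        .reset_index()
    )
    grouped["pct_selected"] = 100.0 * grouped["n_selected"] / grouped["n_total"]

    annotations = [a for a in ANNOTATIONS if a in set(df["annotation"])]

    annotation_tests: dict[str, ContingencyResult] = {}
    annotation_tests_sel: dict[str, ContingencyResult] = {}
    for run in diploid_runs:
        sub = grouped[grouped["run_id"] == run].set_index("annotation")
        sel = [int(sub.loc[a, "n_selected"]) for a in annotations]
        not_sel = [
            int(sub.loc[a, "n_total"] - sub.loc[a, "n_selected"])
            for a in annotations
        ]
        try:
            annotation_tests[run] = chi_square_test([sel, not_sel], yates=yates)
        except ValueError as exc:
            logger.warning("annotation test degenerate for %s: %s", run, exc)
        # variant: selected counts of this run vs the polyploid run, 2xK
        poly = grouped[grouped["run_id"] == polyploid_run].set_index("annotation")
        sel_poly = [int(poly.loc[a, "n_selected"]) for a in annotations]
        try:
            annotation_tests_sel[run] = chi_square_test(
                [sel, sel_poly], yates=yates
            )
        except ValueError as exc:
            logger.warning(
                "selected-only annotation test degenerate for %s: %s", run, exc
            )

    ploidy_tests: dict[tuple[str, str], ContingencyResult] = {}
    poly = grouped[grouped["run_id"] == polyploid_run].set_index("annotation")
    for annotation in annotations:
        for run in diploid_runs:
            sub = grouped[grouped["run_id"] == run].set_index("annotation")
            table = [
                [
                    int(poly.loc[annotation, "n_selected"]),
                    int(
                        poly.loc[annotation, "n_total"]
                        - poly.loc[annotation, "n_selected"]
                    ),
                ],
                [
                    int(sub.loc[annotation, "n_selected"]),
                    int(
                        sub.loc[annotation, "n_total"]
                        - sub.loc[annotation, "n_selected"]
                    ),
                ],
            ]
            try:
                ploidy_tests[(annotation, run)] = chi_square_test(
                    table, yates=yates
                )
            except ValueError as exc:
                logger.warning(
                    "ploidy test degenerate for %s/%s: %s", annotation, run, exc
                )
    return SelectionSummary(
        counts=grouped,
        annotation_tests=annotation_tests,
        annotation_tests_selected_only=annotation_tests_sel,
        ploidy_tests=ploidy_tests,
        fdr=fdr,
    )


def read_selection_table(path: str | Path) -> list[LocusSelectionRecord]:
    """Read the per-run TSV ``locus_id  annotation  run_id  p_raw``."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        LocusSelectionRecord(
            str(row.locus_id), str(row.annotation), str(row.run_id), float(row.p_raw)
        )
        for row in df.itertuples(index=False)
    ]


def write_selection_table(
    records: Sequence[LocusSelectionRecord], path: str | Path, comment: str = ""
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.locus_id}\t{r.annotation}\t{r.run_id}\t{r.p_raw:.17g}\n")
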