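"""Per-gene polymerase-count summaries and occupancy comparisons.

Miller-spread micrographs give a direct per-gene count of engaged Pol I
molecules; here those counts are summarised (mean, median, bootstrap CI,
negative-binomial dispersion) and compared between strains.  ChIP
percent-input tables are normalised to a reference strain's median per
amplicon and compared with Welch's t-test, mirroring how relative Pol I
occupancy on the rDNA unit is usually reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import SpreadCounts

__all__ = [
    "CountSummary",
    "OccupancyComparison",
    "summarize_counts",
    "compare_counts",
    "chip_relative_occupancy",
]


@dataclass(frozen=True)
class CountSummary:
    strain: str
    n_genes: int
    mean: float
    ci_low: float
    ci_high: float
    median: float
    dispersion: float  # NB size parameter k; inf in the Poisson limit


@dataclass(frozen=True)
class OccupancyComparison:
    strain_a: str
    strain_b: str
    mean_difference: float
    statistic: float
    p_value: float
    test: str


def summarize_counts(sc: SpreadCounts, n_boot: int = 2000, seed: int = 0) -> CountSummary:
    """Mean/median, percentile-bootstrap CI and method-of-moments dispersion.

    The dispersion is the negative-binomial size parameter
    k = mean^2 / (var - mean); when the sample variance does not exceed
    the mean (Poisson-like or under-dispersed) it is reported as inf.
    """
    counts = sc.counts
    if counts.size < 2:
        raise ValueError("need at least 2 genes to summarise")
    mean = float(counts.mean())
    var = float(counts.var(ddof=1))
    dispersion = mean**2 / (var - mean) if var > mean else np.inf

    rng = np.random.default_rng(seed)
    resamples = rng.integers(0, counts.size, size=(n_boot, counts.size))
    boot_means = counts[resamples].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return CountSummary(
        strain=sc.strain, n_genes=sc.n_genes, mean=mean,
        ci_low=float(lo), ci_high=float(hi),
        median=float(np.median(counts)), dispersion=float(dispersion),
    )


def compare_counts(
    a: SpreadCounts, b: SpreadCounts, method: str = "t", seed: int = 0
) -> OccupancyComparison:
    """Two-sided comparison of per-gene counts between two strains.

    ``method``: "t" (Welch, default), "mannwhitney", or "permutation"
    (difference of means, 10,000 resamples).  Identical zero-variance
    samples yield p = 1 with a warning for the t-test.
    """
    x, y = a.counts.astype(float), b.counts.astype(float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 genes")
    diff = float(x.mean() - y.mean())
    if method == "t":
        if x.var() == 0 and y.var() == 0 and diff == 0:
            warnings.warn("identical zero-variance samples; p set to 1", stacklevel=2)
            return OccupancyComparison(a.strain, b.strain, 0.0, 0.0, 1.0, "welch-t")
        res = stats.ttest_ind(x, y, equal_var=False)
        return OccupancyComparison(a.strain, b.strain, diff, float(res.statistic), float(res.pvalue), "welch-t")
    if method == "mannwhitney":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return OccupancyComparison(a.strain, b.strain, diff, float(res.statistic), float(res.pvalue), "mann-whitney")
    if method == "permutation":
        res = stats.permutation_test(
            (x, y), lambda u, v: np.mean(u) - np.mean(v),
            permutation_type="independent", n_resamples=10_000,
            alternative="two-sided", rng=np.random.default_rng(seed),
        )
        return OccupancyComparison(a.strain, b.strain, diff, float(res.statistic), float(res.pvalue), "permutation")
    raise ValueError(f"unknown method {method!r}")


CHIP_COLUMNS = ["amplicon", "strain", "replicate", "percent_input"]


def chip_relative_occupancy(
    tbl: pd.DataFrame, reference_strain: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalise ChIP percent-input to a reference strain, per amplicon.

    Every replicate's percent_input is divided by the reference
    strain's median for that amplicon; the reference strain therefore
    normalises to median 1 everywhere.  Returns ``(summary, tests)``:
    per-(strain, amplicon) median and SD of normalised values, and a
    Welch t-test of each non-reference strain against the reference per
    amplicon.  Output is invariant to a global rescaling of the input.
    """
    missing = [c for c in CHIP_COLUMNS if c not in tbl.columns]
    if missing:
        raise ValueError(f"ChIP table lacks columns {missing}")
    if np.any(tbl["percent_input"].to_numpy(dtype=float) < 0):
        raise ValueError("percent_input must be non-negative")
    if reference_strain not in set(tbl["strain"]):
        raise ValueError(f"reference strain {reference_strain!r} absent from table")

    ref = tbl[tbl["strain"] == reference_strain]
    ref_median = ref.groupby("amplicon")["percent_input"].median()
    amplicons = tbl["amplicon"].unique()
    absent = [a for a in amplicons if a not in ref_median.index]
    if absent:
        raise ValueError(f"reference strain missing amplicons {absent}")
    if (ref_median == 0).any():
        zero = list(ref_median.index[ref_median == 0])
        raise ValueError(f"reference median is zero for amplicons {zero}")

    norm = tbl.copy()
    norm["relative"] = norm["percent_input"] / norm["amplicon"].map(ref_median)

    summary = (
        norm.groupby(["strain", "amplicon"])["relative"]
        .agg(median="median", sd=lambda v: v.std(ddof=1), n="size")
        .reset_index()
    )

    rows = []
    for amplicon, grp in norm.groupby("amplicon"):
        ref_vals = grp.loc[grp["strain"] == reference_strain, "relative"].to_numpy()
        for strain, sub in grp.groupby("strain"):
            if strain == reference_strain:
                continue
            vals = sub["relative"].to_numpy()
            res = stats.ttest_ind(vals, ref_vals, equal_var=False)
            rows.append((amplicon, strain, reference_strain,
                         float(np.median(vals)), float(res.statistic), float(res.pvalue)))
    tests = pd.DataFrame(
        rows, columns=["amplicon", "strain", "reference", "median_relative", "t", "p_value"]
    )
    return summary, tests
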