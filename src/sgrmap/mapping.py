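"""Genome scan for suppressor loci from barcode enrichment ratios.

The mapping readout of a GIM suppressor screen is, per deletion-strain
barcode, the ratio of control-pool to query-pool intensity.  Barcodes
genetically linked to the suppressor are counter-selected in the query
pool, so their log2(control/query) score is high.  Ordering scores along
the genome, smoothing with a sliding mean over 20 barcodes, and calling
local maxima of the smoothed track localises the suppressor locus; a
genome-wide permutation null (scores shuffled across barcodes, positions
fixed) attaches a family-wise p-value to every peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GimSimConfig, simulate_gim_cross  # noqa: F401  (re-export convenience)

__all__ = [
    "normalize_arrays",
    "compute_scores",
    "sliding_window_profile",
    "call_loci",
    "map_suppressor",
    "LinkageProfile",
    "LocusCall",
]

logger = logging.getLogger(__name__)

BARCODE_COLUMNS = ["barcode_id", "gene", "chrom", "pos", "query", "control"]


@dataclass(frozen=True)
class LinkageProfile:
    """Smoothed genome-ordered linkage track.

    ``windows`` has columns ``chrom, start_idx, center, score`` where
    ``start_idx`` indexes the first barcode of the window within
    ``scored`` (the genome-sorted scored barcode table) and ``center``
    is the median bp position of the window's barcodes.
    """

    windows: pd.DataFrame
    scored: pd.DataFrame
    window_size: int


@dataclass(frozen=True)
class LocusCall:
    """One called suppressor locus."""

    chrom: str
    peak_pos: float
    score: float
    p_value: float
    candidate_genes: tuple[str, ...]
    rank: int = 0


def _check_barcode_table(table: pd.DataFrame) -> None:
    missing = [c for c in BARCODE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"barcode table lacks columns {missing}")


def normalize_arrays(table: pd.DataFrame) -> pd.DataFrame:
    """Median-scale both intensity channels to 1.

    Zero intensities are first replaced by half the smallest positive
    value in their channel (pseudocount), then each channel is divided
    by its median.  The result is invariant to a global rescaling of
    either channel.
    """
    _check_barcode_table(table)
    out = table.copy()
    for channel in ("query", "control"):
        values = out[channel].to_numpy(dtype=float)
        if np.any(values < 0):
            raise ValueError(f"negative intensities in channel {channel!r}")
        positive = values[values > 0]
        if positive.size == 0:
            raise ValueError(f"channel {channel!r} is all zero")
        values = np.where(values == 0, positive.min() / 2.0, values)
        out[channel] = values / np.median(values)
    return out


def compute_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Per-barcode linkage score log2(control / query).

    Counter-selected (query-depleted) barcodes score high, so a linked
    locus appears as a local maximum of the smoothed score track.
    """
    _check_barcode_table(table)
    query = table["query"].to_numpy(dtype=float)
    control = table["control"].to_numpy(dtype=float)
    if np.any(query <= 0) or np.any(control <= 0):
        raise ValueError("intensities must be positive; normalize_arrays first")
    out = table[["barcode_id", "gene", "chrom", "pos"]].copy()
    out["score"] = np.log2(control / query)
    return out


def _chrom_slices(scored: pd.DataFrame) -> list[tuple[str, int, int]]:
    """(chrom, start, stop) row ranges of a genome-sorted scored table."""
    chroms = scored["chrom"].to_numpy()
    boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [len(chroms)]))
    return [(chroms[a], int(a), int(b)) for a, b in zip(starts, stops)]


def _window_means(values: np.ndarray, w: int) -> np.ndarray:
    """Means of every full window of w consecutive values (step 1)."""
    if values.shape[-1] < w:
        return np.empty(values.shape[:-1] + (0,))
    cs = np.cumsum(values, axis=-1, dtype=float)
    head = cs[..., w - 1 : w]  # first window sum
    return np.concatenate([head, cs[..., w:] - cs[..., :-w]], axis=-1) / w


def sliding_window_profile(scored: pd.DataFrame, window_size: int = 20) -> LinkageProfile:
    """Sliding mean of barcode scores over windows of ``window_size`` barcodes.

    Barcodes are sorted by (chromosome, position); windows are every run
    of W consecutive barcodes on one chromosome (step 1, full windows
    only).  The window score is the arithmetic mean of the W scores and
    the window center the median of the W positions.  Chromosomes with
    fewer than W barcodes yield no windows.
    """
    if window_size < 2:
        raise ValueError("window_size must be at least 2")
    scored = scored.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    positions = scored["pos"].to_numpy(dtype=float)
    scores = scored["score"].to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")

    frames = []
    for chrom, a, b in _chrom_slices(scored):
        n = b - a
        if n < window_size:
            logger.warning(
                "chromosome %s has %d barcodes (< window %d); no windows",
                chrom, n, window_size,
            )
            continue
        means = _window_means(scores[a:b], window_size)
        # median position of each window: mean of the two middle order
        # statistics (positions are already sorted within the chromosome)
        idx = np.arange(n - window_size + 1)
        lo = positions[a:b][idx + (window_size - 1) // 2]
        hi = positions[a:b][idx + window_size // 2]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start_idx": idx + a,
                    "center": (lo + hi) / 2.0,
                    "score": means,
                }
            )
        )
    if frames:
        windows = pd.concat(frames, ignore_index=True)
    else:
        windows = pd.DataFrame(columns=["chrom", "start_idx", "center", "score"])
    return LinkageProfile(windows=windows, scored=scored, window_size=window_size)


def _local_maxima(w: np.ndarray) -> list[int]:
    """Indices of local maxima; plateaus collapse to their leftmost window."""
    n = w.size
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and w[j + 1] == w[i]:
            j += 1
        left_ok = i == 0 or w[i - 1] < w[i]
        right_ok = j == n - 1 or w[j + 1] < w[i]
        if left_ok and right_ok:
            maxima.append(i)
        i = j + 1
    return maxima


def call_loci(
    profile: LinkageProfile,
    n_perm: int = 1000,
    min_prominence: float | None = None,
    seed: int = 0,
) -> list[LocusCall]:
    """Call suppressor loci as significant local maxima of the profile.

    A window is a candidate peak when its smoothed score is >= both
    neighbours (ties collapse to the leftmost window of the run) and its
    prominence above the chromosome median of window scores exceeds
    ``min_prominence`` (default: one median absolute deviation of that
    chromosome's window scores).  Significance comes from a genome-wide
    permutation null: barcode scores are shuffled across all barcodes
    (positions fixed), profiles recomputed, and the genome-wide maximum
    window score recorded per permutation;

        p = (1 + #{perm max >= peak score}) / (n_perm + 1).

    Calls are returned sorted by (p, -score) and ranked from 1.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    windows = profile.windows
    if windows.empty:
        return []

    # candidate peaks per chromosome
    candidates: list[tuple[str, float, float, int]] = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        w = grp["score"].to_numpy()
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        threshold = mad if min_prominence is None else min_prominence
        for i in _local_maxima(w):
            if w[i] - med > threshold:
                row = grp.iloc[i]
                candidates.append((chrom, float(row["center"]), float(w[i]), int(row["start_idx"])))
    if not candidates:
        return []

    perm_max = _permutation_max_scores(profile, n_perm, seed)

    scored = profile.scored
    W = profile.window_size
    calls = []
    for chrom, center, score, start_idx in candidates:
        exceed = int(np.sum(perm_max >= score))
        p = (1 + exceed) / (n_perm + 1)
        genes = tuple(scored["gene"].iloc[start_idx : start_idx + W])
        calls.append(LocusCall(chrom=chrom, peak_pos=center, score=score, p_value=p, candidate_genes=genes))
    calls.sort(key=lambda c: (c.p_value, -c.score))
    return [
        LocusCall(
            chrom=c.chrom, peak_pos=c.peak_pos, score=c.score,
            p_value=c.p_value, candidate_genes=c.candidate_genes, rank=r,
        )
        for r, c in enumerate(calls, start=1)
    ]


def _permutation_max_scores(profile: LinkageProfile, n_perm: int, seed: int) -> np.ndarray:
    """Genome-wide max window score for each score permutation.

    Vectorised: all permutations are drawn as rows of one matrix and the
    windowed means computed chromosome-slice by chromosome-slice with a
    cumulative sum, so the null costs O(n_perm * n_barcodes).
    """
    rng = np.random.default_rng(seed)
    scores = profile.scored["score"].to_numpy(dtype=float)
    perm = rng.permuted(np.broadcast_to(scores, (n_perm, scores.size)).copy(), axis=1)
    maxima = np.full(n_perm, -np.inf)
    for _, a, b in _chrom_slices(profile.scored):
        if b - a < profile.window_size:
            continue
        means = _window_means(perm[:, a:b], profile.window_size)
        np.maximum(maxima, means.max(axis=1), out=maxima)
    return maxima


def map_suppressor(
    table: pd.DataFrame,
    window_size: int = 20,
    n_perm: int = 1000,
    min_prominence: float | None = None,
    seed: int = 0,
) -> tuple[list[LocusCall], LinkageProfile]:
    """Full scan: normalize, score, smooth and call loci on a barcode table."""
    scored = compute_scores(normalize_arrays(table))
    profile = sliding_window_profile(scored, window_size=window_size)
    calls = call_loci(profile, n_perm=n_perm, min_prominence=min_prominence, seed=seed)
    return calls, profile
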