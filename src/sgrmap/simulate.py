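"""Synthetic-data generators for the suppressor-mapping pipeline.

Every downstream stage (linkage mapping, growth fitting, occupancy and
transcription quantification, mutation-frequency estimation) consumes
tables produced here, so the whole pipeline is testable without any
external dataset.  The central generator, :func:`simulate_gim_cross`,
emulates a genetic-interaction-mapping (GIM) screen: a query strain is
crossed to a pooled, barcoded genome-wide deletion collection, spores
are selected for the query marker and grown competitively, and barcode
abundance in the query pool relative to a neutral control pool reports
genetic linkage — deletion strains linked to the suppressor locus are
counter-selected because marker-selected recombinants rarely carry the
suppressor allele.

All generators take an explicit seed and are bit-reproducible; there is
no module-level RNG state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeMap",
    "GimSimConfig",
    "GrowthCurve",
    "SpreadCounts",
    "FluctuationCounts",
    "yeast_genome",
    "haldane_recomb",
    "simulate_gim_cross",
    "simulate_growth_curve",
    "simulate_spread_counts",
    "simulate_signal_table",
    "simulate_fluctuation",
]

# sacCer3 chromosome sizes (bp), chromosomes I..XVI.
_SACCER3_LENGTHS = (
    230218, 813184, 316620, 1531933, 576874, 270161, 1090940, 562643,
    439888, 745751, 666816, 1078177, 924431, 784333, 1091291, 948066,
)


@dataclass(frozen=True)
class GenomeMap:
    """Ordered chromosome sizes plus a uniform genetic-map rate.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.  Positions are 1-based and
        inclusive.
    cm_per_kb:
        Uniform genetic-map rate in centiMorgans per kilobase.  The
        default 0.35 cM/kb is a typical *S. cerevisiae* genome average.
    """

    chromosomes: tuple[tuple[str, int], ...]
    cm_per_kb: float = 0.35

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.cm_per_kb <= 0:
            raise ValueError("cm_per_kb must be positive")
        object.__setattr__(
            self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes)
        )

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    def length_of(self, name: str) -> int:
        for n, l in self.chromosomes:
            if n == name:
                return l
        raise KeyError(f"unknown chromosome {name!r}")

    def genetic_distance_cM(self, pos_a_bp: float, pos_b_bp: float) -> float:
        """Genetic distance between two same-chromosome coordinates."""
        return abs(pos_a_bp - pos_b_bp) / 1000.0 * self.cm_per_kb


def yeast_genome(cm_per_kb: float = 0.35) -> GenomeMap:
    """The 16 budding-yeast chromosomes with their sacCer3 sizes."""
    chroms = tuple(
        (f"chr{i + 1:02d}", length) for i, length in enumerate(_SACCER3_LENGTHS)
    )
    return GenomeMap(chromosomes=chroms, cm_per_kb=cm_per_kb)


@dataclass(frozen=True)
class GimSimConfig:
    """Generative model for one synthetic GIM suppressor screen.

    ``tau_suppressed``/``tau_unsuppressed`` are the doubling times (min)
    of marker-selected spores that do or do not carry the suppressor
    allele; the defaults are the measured doubling times of the
    suppressed double mutant (135 min) and the unsuppressed deletion
    strain (180 min).  ``competition_time`` is the pooled competitive
    growth duration in minutes (default ~10 generations of the faster
    grower).
    """

    genome: GenomeMap
    n_barcodes: int
    suppressor_locus: tuple[str, int]
    query_locus: tuple[str, int] | None = None
    tau_suppressed: float = 135.0
    tau_unsuppressed: float = 180.0
    competition_time: float = 1350.0
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_barcodes < 2:
            raise ValueError("n_barcodes must be at least 2")
        if self.tau_suppressed <= 0 or self.tau_unsuppressed <= 0:
            raise ValueError("doubling times must be positive")
        if self.tau_suppressed > self.tau_unsuppressed:
            raise ValueError("tau_suppressed must not exceed tau_unsuppressed")
        if self.competition_time < 0:
            raise ValueError("competition_time must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for locus in (self.suppressor_locus, self.query_locus):
            if locus is None:
                continue
            chrom, pos = locus
            length = self.genome.length_of(chrom)  # raises on unknown chromosome
            if not (1 <= pos <= length):
                raise ValueError(f"locus {locus} outside chromosome bounds")


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series for one strain; times in minutes."""

    strain: str
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if times.size != od.size:
            raise ValueError("times and od must have equal length")
        if times.size < 4:
            raise ValueError("a growth curve needs at least 4 time points")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od <= 0):
            raise ValueError("od values must be strictly positive")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)


@dataclass(frozen=True)
class SpreadCounts:
    """Per-gene polymerase counts from Miller-spread micrographs."""

    strain: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.size == 0:
            raise ValueError("counts must be non-empty")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def n_genes(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class FluctuationCounts:
    """Colony counts for one plating condition of a frequency assay."""

    condition: str
    cells_plated: int
    suppressor_colonies: int
    survival_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.cells_plated <= 0:
            raise ValueError("cells_plated must be positive")
        if not (0.0 < self.survival_fraction <= 1.0):
            raise ValueError("survival_fraction must be in (0, 1]")
        if not (0 <= self.suppressor_colonies <= self.cells_plated):
            raise ValueError("colonies must lie in [0, cells_plated]")


def haldane_recomb(distance_cM):
    """Recombination fraction for a genetic distance under no interference.

    Implements the Haldane map function ``r = (1 - exp(-2 d)) / 2`` with
    ``d`` the distance in Morgans.  ``r`` is 0 at zero distance and
    approaches 1/2 for unlinked loci.  Accepts scalars or arrays.
    """
    d = np.asarray(distance_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    if np.isscalar(distance_cM) or np.ndim(distance_cM) == 0:
        return float(r)
    return r


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def _place_barcodes(genome: GenomeMap, n: int, rng: np.random.Generator):
    """Distribute n barcodes over chromosomes proportionally to length,
    at uniform random positions, sorted within each chromosome."""
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    # largest-remainder apportionment so counts are deterministic in shape
    quota = n * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        order = np.argsort(-(quota - counts))
        counts[order[:remainder]] += 1
    chroms: list[str] = []
    positions: list[int] = []
    for (name, length), k in zip(genome.chromosomes, counts):
        pos = np.sort(rng.integers(1, length + 1, size=k))
        chroms.extend([name] * k)
        positions.extend(int(p) for p in pos)
    return np.array(chroms), np.array(positions, dtype=int)


def simulate_gim_cross(config: GimSimConfig) -> pd.DataFrame:
    """Simulate one GIM screen and return its barcode table.

    Returns a DataFrame with columns ``barcode_id, gene, chrom, pos,
    query, control`` (one row per deletion strain).  For a barcode at
    position x, the fraction p of marker-selected spores that carry the
    suppressor allele is the Haldane recombination fraction between x
    and the suppressor locus when both are on the same chromosome, and
    1/2 otherwise.  After competitive growth for time T the query-pool
    abundance is the two-component exponential mixture

        a = p * 2**(T / tau_suppressed) + (1 - p) * 2**(T / tau_unsuppressed)

    while the control pool has no fitness differential (abundance 1).
    Both channels receive independent unit-mean lognormal noise with the
    configured CV.  Barcodes linked to the suppressor therefore come out
    DEPLETED in the query channel.

    If ``query_locus`` is set, barcodes linked to the query marker are
    additionally depleted in the query channel by the normalised
    double-recombinant fraction r(d)/0.5 (a positive control mimicking
    the query gene's own linkage peak).
    """
    cfg = config
    if cfg.n_barcodes < 40:
        warnings.warn(
            "fewer than 40 barcodes: downstream 20-barcode windows may be empty",
            stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    chroms, positions = _place_barcodes(cfg.genome, cfg.n_barcodes, rng)

    sup_chrom, sup_pos = cfg.suppressor_locus
    p = np.full(cfg.n_barcodes, 0.5)
    on_sup = chroms == sup_chrom
    d = np.abs(positions[on_sup] - sup_pos) / 1000.0 * cfg.genome.cm_per_kb
    p[on_sup] = haldane_recomb(d)

    growth_fast = 2.0 ** (cfg.competition_time / cfg.tau_suppressed)
    growth_slow = 2.0 ** (cfg.competition_time / cfg.tau_unsuppressed)
    query_abund = p * growth_fast + (1.0 - p) * growth_slow

    if cfg.query_locus is not None:
        q_chrom, q_pos = cfg.query_locus
        on_q = chroms == q_chrom
        dq = np.abs(positions[on_q] - q_pos) / 1000.0 * cfg.genome.cm_per_kb
        query_abund[on_q] *= haldane_recomb(dq) / 0.5

    query = query_abund * _lognormal_noise(rng, cfg.noise_cv, cfg.n_barcodes)
    control = 1.0 * _lognormal_noise(rng, cfg.noise_cv, cfg.n_barcodes)

    return pd.DataFrame(
        {
            "barcode_id": [f"bc{i:05d}" for i in range(cfg.n_barcodes)],
            "gene": [
                f"y{c.removeprefix('chr')}g{i:04d}"
                for i, c in enumerate(chroms)
            ],
            "chrom": chroms,
            "pos": positions,
            "query": query,
            "control": control,
        }
    )


def simulate_growth_curve(
    tau_min: float,
    t_grid: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    od0: float = 0.05,
    strain: str = "strain",
) -> GrowthCurve:
    """Exponential OD600 curve with multiplicative lognormal noise.

    ``od(t) = od0 * 2**(t / tau_min) * noise`` with unit-mean noise of
    the given CV; deterministic for a fixed seed.
    """
    if tau_min <= 0:
        raise ValueError("tau_min must be positive")
    t = np.asarray(t_grid, dtype=float)
    rng = np.random.default_rng(seed)
    od = od0 * np.exp2(t / tau_min) * _lognormal_noise(rng, noise_cv, t.size)
    return GrowthCurve(strain=strain, times=t, od=od)


def simulate_spread_counts(
    mean_count: float,
    dispersion: float = math.inf,
    n_genes: int = 100,
    seed: int = 0,
    strain: str = "strain",
) -> SpreadCounts:
    """Per-gene polymerase counts, negative-binomially distributed.

    ``dispersion`` is the NB size parameter k (variance = m + m^2/k);
    ``dispersion=inf`` gives the Poisson limit.
    """
    if mean_count <= 0:
        raise ValueError("mean_count must be positive")
    if n_genes < 1:
        raise ValueError("n_genes must be at least 1")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    if math.isinf(dispersion):
        counts = rng.poisson(mean_count, size=n_genes)
    else:
        p = dispersion / (dispersion + mean_count)
        counts = rng.negative_binomial(dispersion, p, size=n_genes)
    return SpreadCounts(strain=strain, counts=counts.astype(np.int64))


def simulate_signal_table(
    true_fold: Mapping[str, Mapping[str, float]],
    control_probe: str,
    n_replicates: int = 3,
    noise_cv: float = 0.2,
    seed: int = 0,
    baseline: Mapping[str, float] | None = None,
    loading_cv: float = 0.3,
    loading: Mapping[tuple[str, int], float] | None = None,
) -> pd.DataFrame:
    """Replicate probe-by-strain signal intensities with a loading control.

    ``true_fold`` maps strain -> probe -> fold relative to baseline; the
    control probe must be present with fold 1 in every strain.  Each
    (strain, replicate) pair gets a loading multiplier (lognormal with
    CV ``loading_cv``, or taken from ``loading`` if supplied) applied to
    all its probes, control included, so that normalising to the control
    probe removes loading exactly.  Measurement noise is unit-mean
    lognormal with CV ``noise_cv``, independent per row.

    Returns a long-format DataFrame ``probe, strain, replicate, signal``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    strains = list(true_fold)
    if not strains:
        raise ValueError("true_fold must name at least one strain")
    probes = list(true_fold[strains[0]])
    for s in strains:
        if control_probe not in true_fold[s]:
            raise ValueError(f"control probe {control_probe!r} missing for strain {s!r}")
        if true_fold[s][control_probe] != 1.0:
            raise ValueError("control probe fold must be 1 in every strain")
        if set(true_fold[s]) != set(probes):
            raise ValueError("all strains must specify the same probe set")
    base = dict.fromkeys(probes, 1.0)
    if baseline is not None:
        base.update(baseline)

    rng = np.random.default_rng(seed)
    rows = []
    for s in strains:
        for rep in range(1, n_replicates + 1):
            if loading is not None and (s, rep) in loading:
                load = float(loading[(s, rep)])
            else:
                load = float(_lognormal_noise(rng, loading_cv, 1)[0])
            noise = _lognormal_noise(rng, noise_cv, len(probes))
            for probe, eps in zip(probes, noise):
                rows.append(
                    (probe, s, rep, base[probe] * true_fold[s][probe] * load * eps)
                )
    return pd.DataFrame(rows, columns=["probe", "strain", "replicate", "signal"])


def simulate_fluctuation(
    freq: float,
    n_cells: float = 1e8,
    uv_fold: float = 10.0,
    survival_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[FluctuationCounts, FluctuationCounts]:
    """Colony counts for a spontaneous vs UV-induced frequency assay.

    Spontaneous colonies ~ Binomial(n_cells, freq); UV colonies ~
    Binomial(round(n_cells * survival_fraction), freq * uv_fold) — UV
    kills (1 - survival_fraction) of plated cells and multiplies the
    per-survivor suppressor frequency by ``uv_fold``.
    """
    if not (0 <= freq < 1):
        raise ValueError("freq must lie in [0, 1)")
    if uv_fold < 1:
        raise ValueError("uv_fold must be at least 1")
    if freq * uv_fold >= 1:
        raise ValueError("freq * uv_fold must stay below 1")
    if not (0 < survival_fraction <= 1):
        raise ValueError("survival_fraction must be in (0, 1]")
    n = int(round(n_cells))
    rng = np.random.default_rng(seed)
    spont = FluctuationCounts(
        condition="spontaneous",
        cells_plated=n,
        suppressor_colonies=int(rng.binomial(n, freq)),
        survival_fraction=1.0,
    )
    n_uv_survivors = int(round(n * survival_fraction))
    uv = FluctuationCounts(
        condition="UV",
        cells_plated=n,
        suppressor_colonies=int(rng.binomial(n_uv_survivors, freq * uv_fold)),
        survival_fraction=survival_fraction,
    )
    return spont, uv
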