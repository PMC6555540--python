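"""Internal-control normalisation and fold changes for signal tables.

Pulse-label gels, transcriptional run-on (TRO) slot blots and northern
blots all reduce to the same long-format table: one signal per (probe,
strain, replicate).  Each replicate carries an unknown loading factor,
removed by dividing every probe's signal by the same replicate's
internal-control probe (5S for TRO, PGK1 or SCR1 for blots).  Fold
changes between strains are ratios of per-strain medians of the
normalised values, with a percentile-bootstrap interval over replicates
— robust with the 2-3 replicates these assays typically have.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FoldChangeEstimate",
    "normalize_to_control",
    "probe_group_mean",
    "fold_change",
]

SIGNAL_COLUMNS = ["probe", "strain", "replicate", "signal"]

# canonical TRO probe group spanning the Pol I transcription unit
POL_I_GROUP = ("5ETS", "18S.2", "25S.1", "3ETS")


@dataclass(frozen=True)
class FoldChangeEstimate:
    probe: str
    strain: str
    reference: str
    fold: float
    ci_low: float
    ci_high: float


def _check_signal_table(tbl: pd.DataFrame, value_col: str) -> None:
    missing = [c for c in ("probe", "strain", "replicate", value_col) if c not in tbl.columns]
    if missing:
        raise ValueError(f"signal table lacks columns {missing}")


def normalize_to_control(tbl: pd.DataFrame, control_probe: str) -> pd.DataFrame:
    """Divide every signal by its replicate's control-probe signal.

    The control probe must be present (with positive signal) in every
    (strain, replicate); it normalises to exactly 1 there, and any
    replicate-wide loading multiplier cancels.  Returns a table with a
    ``normalized`` column in place of ``signal``.
    """
    _check_signal_table(tbl, "signal")
    if np.any(tbl["signal"].to_numpy(dtype=float) < 0):
        raise ValueError("signals must be non-negative")
    ctrl = tbl[tbl["probe"] == control_probe].set_index(["strain", "replicate"])["signal"]
    if ctrl.empty:
        raise ValueError(f"control probe {control_probe!r} absent from table")
    groups = tbl.set_index(["strain", "replicate"]).index.unique()
    missing = [g for g in groups if g not in ctrl.index]
    if missing:
        raise ValueError(f"control probe {control_probe!r} missing for {missing}")
    zero = ctrl[ctrl == 0]
    if not zero.empty:
        raise ValueError(f"zero control signal in replicate(s) {list(zero.index)}")

    out = tbl[["probe", "strain", "replicate"]].copy()
    denom = pd.MultiIndex.from_frame(tbl[["strain", "replicate"]]).map(ctrl)
    out["normalized"] = tbl["signal"].to_numpy(dtype=float) / denom.to_numpy(dtype=float)
    return out


def probe_group_mean(
    ns: pd.DataFrame, group: Sequence[str], name: str = "group"
) -> pd.DataFrame:
    """Average several probes into one pseudo-probe, per (strain, replicate).

    Mirrors how multi-probe assays report a single transcription-unit
    value (e.g. the Pol I value of a TRO blot is the mean of the 5'ETS,
    18S.2, 25S.1 and 3'ETS probes).  Returns the input with the
    pseudo-probe rows appended.
    """
    _check_signal_table(ns, "normalized")
    present = set(ns["probe"])
    missing = [p for p in group if p not in present]
    if missing:
        raise ValueError(f"group probes missing from table: {missing}")
    sub = ns[ns["probe"].isin(set(group))]
    agg = (
        sub.groupby(["strain", "replicate"], as_index=False)["normalized"]
        .mean()
        .assign(probe=name)
    )
    return pd.concat([ns, agg[["probe", "strain", "replicate", "normalized"]]], ignore_index=True)


def fold_change(
    ns: pd.DataFrame,
    reference_strain: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> list[FoldChangeEstimate]:
    """Ratio-of-medians fold change of every probe vs a reference strain.

    fold = median(normalized | strain, probe) / median(normalized |
    reference, probe).  The 95% interval is a percentile bootstrap that
    resamples replicates independently within the two strains.  The
    reference strain itself is not reported (its fold is 1 by
    definition).
    """
    _check_signal_table(ns, "normalized")
    strains = ns["strain"].unique()
    if reference_strain not in strains:
        raise ValueError(f"reference strain {reference_strain!r} absent")
    rng = np.random.default_rng(seed)
    out: list[FoldChangeEstimate] = []
    for probe, grp in ns.groupby("probe", sort=False):
        ref_vals = grp.loc[grp["strain"] == reference_strain, "normalized"].to_numpy()
        if ref_vals.size == 0:
            continue
        ref_med = np.median(ref_vals)
        if ref_med == 0:
            raise ValueError(f"reference median is zero for probe {probe!r}")
        for strain in strains:
            if strain == reference_strain:
                continue
            vals = grp.loc[grp["strain"] == strain, "normalized"].to_numpy()
            if vals.size == 0:
                continue
            fold = float(np.median(vals) / ref_med)
            boot_s = vals[rng.integers(0, vals.size, size=(n_boot, vals.size))]
            boot_r = ref_vals[rng.integers(0, ref_vals.size, size=(n_boot, ref_vals.size))]
            ratios = np.median(boot_s, axis=1) / np.median(boot_r, axis=1)
            lo, hi = np.percentile(ratios, [2.5, 97.5])
            out.append(
                FoldChangeEstimate(
                    probe=probe, strain=strain, reference=reference_strain,
                    fold=fold, ci_low=float(lo), ci_high=float(hi),
                )
            )
    return out
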