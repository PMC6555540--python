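"""Tab-separated readers/writers with a ``#`` metadata preamble.

All pipeline tables travel as TSV with a header line, optionally
preceded by ``# key: value`` comment lines recording provenance (seed,
generator parameters).  Growth curves, spread counts and fluctuation
counts get small typed wrappers; barcode, ChIP and signal tables are
plain DataFrames with documented column contracts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import FluctuationCounts, GrowthCurve, SpreadCounts

__all__ = [
    "write_table",
    "read_table",
    "read_metadata",
    "write_growth_curve",
    "read_growth_curve",
    "write_spread_counts",
    "read_spread_counts",
    "write_fluctuation",
    "read_fluctuation",
]


def write_table(df: pd.DataFrame, path, metadata: Mapping[str, object] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_metadata(path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    return meta


def write_growth_curve(curve: GrowthCurve, path, metadata=None) -> None:
    df = pd.DataFrame({"time_min": curve.times, "od600": curve.od})
    meta = {"strain": curve.strain, **(metadata or {})}
    write_table(df, path, meta)


def read_growth_curve(path) -> GrowthCurve:
    df = read_table(path)
    strain = read_metadata(path).get("strain", Path(path).stem)
    return GrowthCurve(strain=strain, times=df["time_min"].to_numpy(), od=df["od600"].to_numpy())


def write_spread_counts(sc: SpreadCounts, path, metadata=None) -> None:
    df = pd.DataFrame({"gene_index": np.arange(sc.n_genes), "count": sc.counts})
    meta = {"strain": sc.strain, **(metadata or {})}
    write_table(df, path, meta)


def read_spread_counts(path) -> SpreadCounts:
    df = read_table(path)
    strain = read_metadata(path).get("strain", Path(path).stem)
    return SpreadCounts(strain=strain, counts=df["count"].to_numpy(dtype=np.int64))


def write_fluctuation(fc: FluctuationCounts, path, metadata=None) -> None:
    df = pd.DataFrame(
        {
            "condition": [fc.condition],
            "cells_plated": [fc.cells_plated],
            "suppressor_colonies": [fc.suppressor_colonies],
            "survival_fraction": [fc.survival_fraction],
        }
    )
    write_table(df, path, metadata)


def read_fluctuation(path) -> FluctuationCounts:
    row = read_table(path).iloc[0]
    return FluctuationCounts(
        condition=str(row["condition"]),
        cells_plated=int(row["cells_plated"]),
        suppressor_colonies=int(row["suppressor_colonies"]),
        survival_fraction=float(row["survival_fraction"]),
    )
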