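"""Tab-separated readers/writers for the tables the pipeline exchanges.

Summary statistics travel as a TSV with one row per variant; LD matrices as a
square whitespace-delimited numeric file with a variant-id header row. All
other tables (AEI wells, per-cell areas, growth counts, cohorts) are tidy
TSVs handled directly by :mod:`pandas`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: Column contract for a summary-statistics table.
SUMMARY_COLUMNS = [
    "variant_id",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "n",
]

#: Columns that must be present for fine-mapping / colocalisation to run.
REQUIRED_SUMMARY_COLUMNS = ["variant_id", "pos", "beta", "se"]


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a summary-statistics TSV and validate its column contract.

    Raises
    ------
    ValueError
        If required columns are missing or variant ids are duplicated.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chr": str, "variant_id": str})
    missing = [c for c in REQUIRED_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file {path} lacks columns: {missing}")
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate variant ids in {path}: {sorted(set(dup))[:5]}")
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUMMARY_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, sep="\t", index=False)


def write_ld_matrix(r: np.ndarray, variant_ids, path: str | Path) -> None:
    """Write a square correlation matrix with a variant-id header row."""
    r = np.asarray(r, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("LD matrix must be square")
    if r.shape[0] != len(variant_ids):
        raise ValueError("LD matrix size does not match number of variant ids")
    with open(path, "w") as fh:
        fh.write(" ".join(map(str, variant_ids)) + "\n")
        np.savetxt(fh, r, fmt="%.6g")


def read_ld_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        ids = fh.readline().split()
        r = np.loadtxt(fh)
    r = np.atleast_2d(r)
    if r.shape != (len(ids), len(ids)):
        raise ValueError(f"LD matrix in {path} is not square over its header ids")
    return r, ids
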