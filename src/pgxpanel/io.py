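"""TSV codecs and run manifests.

All exchange formats are plain TSV: genotype calls (sample_id, assay_id,
call), endpoint fluorescence (sample_id, assay_id, x, y, is_ntc), Ct
replicates in long format (sample_id, region, well, target_ct,
reference_ct; the literal ``no-Cq`` marks absent amplification), star-call
results (sample_id, gene, diplotype, mode, flags, ...), and a sample sheet
(sample_id, ethnicity). Each pipeline run can record a JSON manifest of
its exact configuration for bit-for-bit reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from ._util import CALLS

__all__ = [
    "read_genotype_calls", "write_genotype_calls",
    "read_fluorescence", "read_ct_table", "write_ct_table",
    "read_cn_calls", "read_results", "write_results",
    "read_sample_sheet", "write_manifest", "IoError",
]


class IoError(ValueError):
    pass


def _require(df: pd.DataFrame, columns: tuple[str, ...], what: str) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise IoError(f"{what} lacks columns {sorted(missing)}")


def read_genotype_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require(df, ("sample_id", "assay_id", "call"), "genotype TSV")
    bad = set(df["call"]) - set(CALLS)
    if bad:
        raise IoError(f"unknown genotype calls: {sorted(bad)}")
    return df


def write_genotype_calls(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fluorescence(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require(df, ("sample_id", "assay_id", "x", "y"), "fluorescence TSV")
    if "is_ntc" not in df.columns:
        df["is_ntc"] = False
    df["is_ntc"] = df["is_ntc"].astype(bool)
    return df


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require(df, ("sample_id", "region", "target_ct", "reference_ct"), "Ct TSV")
    for col in ("target_ct", "reference_ct"):
        df[col] = pd.to_numeric(
            df[col].replace({"no-Cq": np.nan, "no-cq": np.nan}), errors="raise"
        )
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("target_ct", "reference_ct"):
        out[col] = out[col].map(lambda v: "no-Cq" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False)


def read_cn_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    _require(df, ("sample_id", "region", "cn_integer"), "copy-number TSV")
    return df


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    _require(df, ("sample_id", "gene", "diplotype"), "results TSV")
    return df


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _require(df, ("sample_id", "ethnicity"), "sample sheet")
    return df


def write_manifest(path: str | Path, command: str, config: Any, **extra) -> None:
    """Record the exact run configuration next to its outputs."""
    from . import __version__

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, (Path,)):
            return str(obj)
        if isinstance(obj, pd.DataFrame):
            return "<table>"
        if isinstance(obj, np.generic):
            return obj.item()
        return str(obj)

    payload = dict(
        tool="pgxpanel",
        version=__version__,
        command=command,
        python=platform.python_version(),
        config=config,
        **extra,
    )
    Path(path).write_text(json.dumps(payload, indent=2, default=encode) + "\n")
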