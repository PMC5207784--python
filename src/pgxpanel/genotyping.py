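"""Qualitative genotype calling from normalized two-channel endpoint
fluorescence.

Each TaqMan genotyping assay reads two dye channels (ref-allele probe on x,
alt-allele probe on y, both already normalized to the ROX passive
reference). On a scatter plot a plate forms up to three clusters: hom-ref
hugging the x axis, het on the diagonal, hom-var hugging the y axis. The
caller works in polar coordinates: points are binned by angle
theta = atan2(y, x) with a 1-D k-means seeded at 0/45/90 degrees, and
points whose radius falls below an NTC-derived floor are left
undetermined. This stands in for the instrument's proprietary auto-caller;
a manual-override table mirrors the bench practice of manually calling an
assay with a noisy probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypingConfig",
    "AssayCallResult",
    "autocall",
    "call_plate",
    "call_rate",
    "concordance",
    "apply_overrides",
    "GenotypingError",
]

CLUSTER_LABELS = ("hom_ref", "het", "hom_var")


class GenotypingError(ValueError):
    pass


@dataclass
class GenotypingConfig:
    seed_angles: tuple[float, float, float] = (0.0, 45.0, 90.0)
    #: radius floor = factor x median NTC radius (absolute fallback below)
    radius_floor_factor: float = 2.0
    default_radius_floor: float = 0.1
    max_iterations: int = 50


@dataclass
class AssayCallResult:
    assay_id: str
    calls: pd.Series  # sample_id -> call
    centroids: tuple[float, float, float]
    separation: float  # silhouette-like cluster separation in [−1, 1]
    radius_floor: float
    n_undetermined: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_undetermined = int((self.calls == "undetermined").sum())


def _angular_kmeans(theta: np.ndarray, seeds: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    centroids = seeds.astype(float).copy()
    assign = np.zeros(len(theta), dtype=int)
    for _ in range(max_iter):
        d = np.abs(theta[:, None] - centroids[None, :])
        new_assign = np.argmin(d, axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for k in range(len(centroids)):
            members = theta[assign == k]
            if members.size:  # empty clusters keep their seed
                centroids[k] = members.mean()
    return assign, centroids


def _separation(theta: np.ndarray, assign: np.ndarray, centroids: np.ndarray) -> float:
    if len(theta) == 0:
        return 0.0
    occupied = np.unique(assign)
    if occupied.size < 2:
        return 1.0
    own = np.abs(theta - centroids[assign])
    d = np.abs(theta[:, None] - centroids[None, :])
    d[np.arange(len(theta)), assign] = np.inf
    nearest_other = d[:, occupied].min(axis=1)
    denom = np.maximum(np.maximum(own, nearest_other), 1e-12)
    return float(np.mean((nearest_other - own) / denom))


def autocall(
    signals: pd.DataFrame,
    config: GenotypingConfig | None = None,
) -> AssayCallResult:
    """Call genotypes for one assay across a plate.

    ``signals`` holds columns sample_id, assay_id, x, y and optionally
    is_ntc; NTC rows set the radius floor and receive no call.
    """
    config = config or GenotypingConfig()
    assay_ids = signals["assay_id"].unique()
    if len(assay_ids) != 1:
        raise GenotypingError("autocall expects signals for exactly one assay")
    is_ntc = (
        signals["is_ntc"].astype(bool)
        if "is_ntc" in signals.columns
        else pd.Series(False, index=signals.index)
    )
    wells = signals[~is_ntc]
    if wells.empty:
        raise GenotypingError(f"{assay_ids[0]}: no non-NTC signals")
    x = wells["x"].to_numpy(float)
    y = wells["y"].to_numpy(float)
    if np.any(x < 0) or np.any(y < 0):
        raise GenotypingError("negative normalized intensities")
    radius = np.hypot(x, y)
    ntc_radius = np.hypot(
        signals.loc[is_ntc, "x"].to_numpy(float),
        signals.loc[is_ntc, "y"].to_numpy(float),
    )
    floor = (
        config.radius_floor_factor * float(np.median(ntc_radius))
        if ntc_radius.size
        else config.default_radius_floor
    )
    amplified = radius > floor
    if not amplified.any():
        raise GenotypingError(f"{assay_ids[0]}: assay failure, no signal above radius floor")
    theta = np.degrees(np.arctan2(y, x))
    assign, centroids = _angular_kmeans(
        theta[amplified], np.asarray(config.seed_angles), config.max_iterations
    )
    calls = np.full(len(wells), "undetermined", dtype=object)
    calls[amplified] = np.asarray(CLUSTER_LABELS, dtype=object)[assign]
    sep = _separation(theta[amplified], assign, centroids)
    return AssayCallResult(
        assay_id=str(assay_ids[0]),
        calls=pd.Series(calls, index=wells["sample_id"].to_numpy(), name="call"),
        centroids=tuple(centroids),
        separation=sep,
        radius_floor=floor,
    )


def call_plate(
    signals: pd.DataFrame, config: GenotypingConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run :func:`autocall` for every assay on a plate.

    Returns (calls, diagnostics): calls is a long frame with columns
    sample_id, assay_id, call; diagnostics one row per assay.
    """
    call_frames, diag_rows = [], []
    for assay_id, rows in signals.groupby("assay_id", sort=False):
        result = autocall(rows, config)
        call_frames.append(
            pd.DataFrame(
                {
                    "sample_id": result.calls.index,
                    "assay_id": assay_id,
                    "call": result.calls.to_numpy(),
                }
            )
        )
        diag_rows.append(
            dict(
                assay_id=assay_id,
                separation=result.separation,
                n_undetermined=result.n_undetermined,
                radius_floor=result.radius_floor,
            )
        )
    return (
        pd.concat(call_frames, ignore_index=True),
        pd.DataFrame(diag_rows),
    )


def apply_overrides(calls: pd.DataFrame, overrides: pd.DataFrame) -> pd.DataFrame:
    """Apply manual calls (sample_id, assay_id, call) over auto calls."""
    merged = calls.merge(
        overrides.rename(columns={"call": "_forced"}),
        on=["sample_id", "assay_id"],
        how="left",
    )
    merged["call"] = merged["_forced"].fillna(merged["call"])
    return merged.drop(columns="_forced")


def call_rate(calls: pd.DataFrame) -> tuple[float, pd.Series]:
    """Fraction of determined calls over samples x assays, plus the
    per-assay breakdown used to spot assays needing manual calling."""
    if calls.empty:
        raise GenotypingError("no calls")
    determined = calls["call"] != "undetermined"
    per_assay = determined.groupby(calls["assay_id"]).mean().sort_index()
    return float(determined.mean()), per_assay


def concordance(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Agreement between two call sets on their overlapping
    (sample, assay) pairs; also returns the discordant pairs."""
    merged = calls_a.merge(
        calls_b, on=["sample_id", "assay_id"], suffixes=("_a", "_b")
    )
    if merged.empty:
        raise GenotypingError("call sets share no (sample, assay) pairs")
    agree = merged["call_a"] == merged["call_b"]
    discordant = merged[~agree].reset_index(drop=True)
    return float(agree.mean()), discordant
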