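"""CYP2D6 copy-number estimation by the comparative-Ct (ddCt) method.

Two TaqMan copy-number assays target different regions of CYP2D6: the
exon-9 assay counts all copies except the CYP2D6-2D7 hybrid *36 (whose
exon 9 is converted to 2D7 sequence), while the intron-2 assay counts all
copies. Both run against an RNaseP reference in quadruplicate; copy number
is estimated relative to a calibrator sample of known copy number (CN 2):

    dCt   = mean(target Ct) - mean(reference Ct)
    ddCt  = dCt_sample - dCt_calibrator
    CN    = calibrator_cn * 2 ** (-ddCt)

Absent amplification ("no-Cq") encodes CN 0 — a replicate set where at
least half the target wells never cross threshold is called CN 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CtReplicateSet",
    "CopyNumberCall",
    "CnvConfig",
    "delta_delta_ct",
    "call_cohort_cn",
    "CnvError",
]

REGIONS = ("exon9", "intron2")


class CnvError(ValueError):
    pass


@dataclass
class CnvConfig:
    #: flag (not drop) calls whose estimate sits this far from an integer
    confidence_floor: float = 0.5
    #: drop the max-deviation replicate when the Ct range exceeds 0.5 cycles
    outlier_trim: bool = False
    outlier_range: float = 0.5


@dataclass
class CtReplicateSet:
    """Replicate Ct values for one sample and target region.

    NaN encodes "no-Cq" (the target never crossed threshold).
    """

    sample_id: str
    region: str
    target_ct: np.ndarray
    reference_ct: np.ndarray

    def __post_init__(self) -> None:
        self.target_ct = np.asarray(self.target_ct, dtype=float)
        self.reference_ct = np.asarray(self.reference_ct, dtype=float)
        if self.region not in REGIONS:
            raise CnvError(f"unknown region {self.region!r}")
        if self.target_ct.size == 0 or self.reference_ct.size == 0:
            raise CnvError(f"{self.sample_id}/{self.region}: empty replicate set")
        for name, arr in (("target", self.target_ct), ("reference", self.reference_ct)):
            finite = arr[np.isfinite(arr)]
            if np.any(finite <= 0):
                raise CnvError(
                    f"{self.sample_id}/{self.region}: non-positive {name} Ct"
                )

    @property
    def no_cq_fraction(self) -> float:
        return float(np.mean(~np.isfinite(self.target_ct)))


@dataclass
class CopyNumberCall:
    sample_id: str
    region: str
    delta_ct: float
    delta_delta_ct: float
    cn_estimate: float
    cn_integer: int
    confidence: float
    flags: list[str] = field(default_factory=list)


def _mean_ct(values: np.ndarray, config: CnvConfig) -> float:
    vals = values[np.isfinite(values)]
    if vals.size == 0:
        raise CnvError("no finite Ct replicates")
    if config.outlier_trim and vals.size > 2 and np.ptp(vals) > config.outlier_range:
        vals = np.delete(vals, int(np.argmax(np.abs(vals - np.median(vals)))))
    return float(vals.mean())


def _round_half_away_int(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def delta_delta_ct(
    sample: CtReplicateSet,
    calibrator: CtReplicateSet,
    calibrator_cn: int = 2,
    config: CnvConfig | None = None,
) -> CopyNumberCall:
    """Call copy number for one sample/region against the calibrator."""
    config = config or CnvConfig()
    if sample.region != calibrator.region:
        raise CnvError(
            f"region mismatch: sample {sample.region}, calibrator {calibrator.region}"
        )
    if calibrator_cn < 1:
        raise CnvError("calibrator copy number must be >= 1")
    flags: list[str] = []
    if sample.no_cq_fraction >= 0.5:
        # target never amplifies: ddCt -> +inf, CN 0
        return CopyNumberCall(
            sample.sample_id, sample.region,
            delta_ct=float("inf"), delta_delta_ct=float("inf"),
            cn_estimate=0.0, cn_integer=0, confidence=1.0,
            flags=["no-amplification"],
        )
    if sample.no_cq_fraction > 0:
        flags.append("partial-no-cq")
    cal_dct = _mean_ct(calibrator.target_ct, config) - _mean_ct(
        calibrator.reference_ct, config
    )
    dct = _mean_ct(sample.target_ct, config) - _mean_ct(sample.reference_ct, config)
    ddct = dct - cal_dct
    estimate = calibrator_cn * 2.0 ** (-ddct)
    integer = _round_half_away_int(estimate)
    confidence = max(0.0, 1.0 - 2.0 * abs(estimate - integer))
    if confidence < config.confidence_floor:
        flags.append("low-confidence")
    return CopyNumberCall(
        sample.sample_id, sample.region, delta_ct=dct, delta_delta_ct=ddct,
        cn_estimate=estimate, cn_integer=integer, confidence=confidence,
        flags=flags,
    )


def replicate_sets_from_frame(ct: pd.DataFrame) -> list[CtReplicateSet]:
    """Group a long-format Ct table (sample_id, region, well, target_ct,
    reference_ct) into replicate sets; the "no-Cq" literal maps to NaN."""
    frame = ct.copy()
    for col in ("target_ct", "reference_ct"):
        frame[col] = pd.to_numeric(
            frame[col].replace({"no-Cq": np.nan, "no-cq": np.nan}), errors="raise"
        )
    sets = []
    for (sample_id, region), rows in frame.groupby(["sample_id", "region"], sort=False):
        sets.append(
            CtReplicateSet(
                str(sample_id), str(region),
                rows["target_ct"].to_numpy(), rows["reference_ct"].to_numpy(),
            )
        )
    return sets


def call_cohort_cn(
    ct: pd.DataFrame | list[CtReplicateSet],
    calibrator_id: str,
    calibrator_cn: int = 2,
    config: CnvConfig | None = None,
) -> pd.DataFrame:
    """Call both regions for every sample in a cohort.

    Returns one row per (sample, region) with columns sample_id, region,
    cn_estimate, cn_integer, confidence, flags. Samples whose integer
    exon-9 CN exceeds the intron-2 CN are flagged ``cn-inconsistent``
    (exon-9 copies are a subset of intron-2 copies, so that configuration
    is impossible), but never dropped.
    """
    config = config or CnvConfig()
    sets = ct if isinstance(ct, list) else replicate_sets_from_frame(ct)
    by_key = {(s.sample_id, s.region): s for s in sets}
    calibrators = {
        region: by_key.get((calibrator_id, region)) for region in REGIONS
    }
    if any(c is None for c in calibrators.values()):
        raise CnvError(f"calibrator {calibrator_id!r} missing a region")
    rows = []
    for s in sets:
        call = delta_delta_ct(s, calibrators[s.region], calibrator_cn, config)
        rows.append(call)
    frame = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in rows],
            "region": [c.region for c in rows],
            "cn_estimate": [c.cn_estimate for c in rows],
            "cn_integer": [c.cn_integer for c in rows],
            "confidence": [c.confidence for c in rows],
            "flags": [";".join(c.flags) for c in rows],
        }
    )
    wide = frame.pivot(index="sample_id", columns="region", values="cn_integer")
    if {"exon9", "intron2"} <= set(wide.columns):
        bad = wide.index[wide["intron2"] < wide["exon9"]]
        if len(bad):
            mask = frame["sample_id"].isin(bad)
            frame.loc[mask, "flags"] = (
                frame.loc[mask, "flags"].str.rstrip(";")
                + ";cn-inconsistent"
            ).str.lstrip(";")
    return frame


def cn_frequency_summary(calls: pd.DataFrame, max_cn: int = 4) -> pd.DataFrame:
    """Frequency of integer copy numbers per region (rows 0..max_cn-1 plus
    a pooled ``>= max_cn`` row), in the shape of a cohort CN table."""
    out = {}
    for region, rows in calls.groupby("region"):
        cn = rows["cn_integer"].clip(upper=max_cn)
        freq = cn.value_counts(normalize=True).sort_index()
        out[region] = {
            (f"{i}" if i < max_cn else f"{max_cn} and above"): freq.get(i, 0.0)
            for i in range(max_cn + 1)
        }
    return pd.DataFrame(out)
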