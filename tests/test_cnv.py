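"""Comparative-Ct copy-number estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxpanel.cnv import (
    CnvConfig,
    CnvError,
    CtReplicateSet,
    call_cohort_cn,
    cn_frequency_summary,
    delta_delta_ct,
)


def reps(sample_id, region, target, reference=25.0, n=4):
    return CtReplicateSet(
        sample_id, region, np.full(n, float(target)), np.full(n, float(reference))
    )


CAL = reps("CAL", "exon9", 25.5)  # dCt = 0.5 at CN 2


def test_sample_identical_to_calibrator_calls_cn2():
    call = delta_delta_ct(reps("S1", "exon9", 25.5), CAL, calibrator_cn=2)
    assert call.cn_estimate == pytest.approx(2.0)
    assert call.cn_integer == 2
    assert call.confidence == pytest.approx(1.0)


def test_one_cycle_later_halves_the_copy_number():
    call = delta_delta_ct(reps("S1", "exon9", 26.5), CAL, calibrator_cn=2)
    assert call.cn_estimate == pytest.approx(1.0)
    assert call.cn_integer == 1


def test_0585_cycles_earlier_is_three_copies():
    call = delta_delta_ct(reps("S1", "exon9", 25.5 - 0.585), CAL, calibrator_cn=2)
    assert call.cn_estimate == pytest.approx(3.0, abs=5e-4)
    assert call.cn_integer == 3


def test_matches_closed_form_on_random_noise_free_inputs():
    rng = np.random.default_rng(7)
    for _ in range(300):
        cal_target = rng.uniform(20, 30)
        shift = rng.uniform(-3, 3)
        cal = reps("CAL", "intron2", cal_target, reference=rng.uniform(20, 30))
        sample = reps(
            "S", "intron2", cal_target + shift, reference=cal.reference_ct[0]
        )
        call = delta_delta_ct(sample, cal, calibrator_cn=2)
        assert call.cn_estimate == pytest.approx(2 * 2.0 ** (-shift), abs=1e-9)


@pytest.mark.parametrize("cn", range(7))
def test_exact_inversion_of_integer_copy_numbers(cn):
    cal = reps("CAL", "exon9", 25.5)
    if cn == 0:
        sample = CtReplicateSet("S", "exon9", np.full(4, np.nan), np.full(4, 25.0))
    else:
        sample = reps("S", "exon9", 25.5 - np.log2(cn / 2.0))
    call = delta_delta_ct(sample, cal, calibrator_cn=2)
    assert call.cn_integer == cn
    if cn > 0:
        assert call.cn_estimate == pytest.approx(cn, abs=1e-9)


def test_no_cq_majority_yields_cn_zero():
    sample = CtReplicateSet(
        "S", "exon9", np.array([np.nan, np.nan, 25.4, np.nan]), np.full(4, 25.0)
    )
    call = delta_delta_ct(sample, CAL)
    assert call.cn_integer == 0 and "no-amplification" in call.flags


def test_low_confidence_is_flagged_not_dropped():
    sample = reps("S", "exon9", 25.5 - np.log2(2.4 / 2.0))  # estimate 2.4
    call = delta_delta_ct(sample, CAL, config=CnvConfig(confidence_floor=0.5))
    assert call.cn_integer == 2
    assert "low-confidence" in call.flags


def test_region_mismatch_and_empty_replicates_rejected():
    with pytest.raises(CnvError, match="region"):
        delta_delta_ct(reps("S", "intron2", 25.5), CAL)
    with pytest.raises(CnvError, match="empty"):
        CtReplicateSet("S", "exon9", np.array([]), np.array([25.0]))


@settings(max_examples=100, derandomize=True)
@given(shift=st.floats(-2, 2), delta=st.floats(0.01, 1.0))
def test_lower_target_ct_means_more_copies(shift, delta):
    cal = reps("CAL", "exon9", 25.5)
    higher = delta_delta_ct(reps("S", "exon9", 25.5 + shift), cal)
    lower = delta_delta_ct(reps("S", "exon9", 25.5 + shift - delta), cal)
    assert lower.cn_estimate > higher.cn_estimate


def _cohort_frame(rng, truth, noise_sd=0.05, n_rep=4):
    rows = []
    for sample_id, cns in truth.items():
        for region, cn in cns.items():
            for well in range(n_rep):
                target = (
                    np.nan
                    if cn == 0
                    else 25.5 - np.log2(cn / 2.0) + rng.normal(0, noise_sd)
                )
                rows.append(
                    dict(sample_id=sample_id, region=region, well=well,
                         target_ct=target,
                         reference_ct=25.0 + rng.normal(0, noise_sd))
                )
    return pd.DataFrame(rows)


def test_cohort_recovery_at_default_noise():
    rng = np.random.default_rng(11)
    truth = {"CAL": {"exon9": 2, "intron2": 2}}
    truth.update(
        {f"S{i:03d}": {"exon9": 2, "intron2": 4} for i in range(200)}
    )
    calls = call_cohort_cn(_cohort_frame(rng, truth), "CAL")
    merged = calls.assign(
        truth=[truth[s][r] for s, r in zip(calls["sample_id"], calls["region"])]
    )
    assert (merged["cn_integer"] == merged["truth"]).mean() >= 0.99
    summary = cn_frequency_summary(calls)
    assert summary["intron2"]["4 and above"] > 0.9


def test_single_sample_cohort_is_the_calibrator():
    rng = np.random.default_rng(0)
    calls = call_cohort_cn(
        _cohort_frame(rng, {"CAL": {"exon9": 2, "intron2": 2}}, noise_sd=0.0), "CAL"
    )
    assert (calls["cn_integer"] == 2).all()


def test_exon9_above_intron2_flagged_inconsistent():
    rng = np.random.default_rng(1)
    truth = {
        "CAL": {"exon9": 2, "intron2": 2},
        "BAD": {"exon9": 3, "intron2": 2},  # impossible: exon-9 is a subset
    }
    calls = call_cohort_cn(_cohort_frame(rng, truth, noise_sd=0.0), "CAL")
    bad = calls[calls["sample_id"] == "BAD"]
    assert bad["flags"].str.contains("cn-inconsistent").all()


def test_missing_calibrator_rejected():
    rng = np.random.default_rng(2)
    frame = _cohort_frame(rng, {"S1": {"exon9": 2, "intron2": 2}})
    with pytest.raises(CnvError, match="calibrator"):
        call_cohort_cn(frame, "CAL")
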