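"""Level calling, dwell extraction and molecule classification."""

import numpy as np
import pandas as pd
import pytest

from flptpm.preprocess import BMTrace
from flptpm.scheme import default_protocol
from flptpm.segment import (
    DWELL_COLUMNS,
    DwellSet,
    Level,
    LevelModel,
    Run,
    SegmentedTrace,
    call_levels,
    classify_molecule,
    default_level_model,
    extract_dwells,
    post_sds_level,
)

DIRECT = default_level_model("Flpe", "direct")
DT = 40 / 29.85


def _bm(values, t0=0.0):
    values = np.asarray(values, float)
    n = len(values)
    return BMTrace(
        time_mid=t0 + (np.arange(n) + 0.5) * DT, bm=values, sd_x=values, sd_y=values,
        window_frames=40, dt=DT, smoothed=False,
    )


def _levels(values):
    return [r.label for r in call_levels(_bm(values), DIRECT).runs]


def test_constant_high_trace_gives_single_run():
    seg = call_levels(_bm(np.full(50, 82.3)), DIRECT)
    assert [r.label for r in seg.runs] == ["HIGH"]


def test_three_level_descent_gives_three_runs_in_order():
    values = np.r_[np.full(20, 82.3), np.full(20, 59.2), np.full(30, 42.0)]
    assert _levels(values) == ["HIGH", "BOUND", "SYNAPSED"]


def test_segmentation_idempotent_on_idealized_trace():
    values = np.r_[np.full(15, 82.3), np.full(10, 59.2), np.full(20, 42.0), np.full(8, 59.2)]
    seg1 = call_levels(_bm(values), DIRECT)
    means = {lv.label: lv.mean for lv in DIRECT.levels}
    idealized = np.concatenate(
        [np.full(r.i_stop - r.i_start, means[r.label]) for r in seg1.runs]
    )
    seg2 = call_levels(_bm(idealized), DIRECT)
    assert [(r.label, r.i_start, r.i_stop) for r in seg1.runs] == [
        (r.label, r.i_start, r.i_stop) for r in seg2.runs
    ]


def test_run_durations_sum_to_trace_span():
    rng = np.random.default_rng(0)
    values = rng.choice([82.3, 59.2, 42.0], size=200) + rng.normal(0, 1, 200)
    seg = call_levels(_bm(values), DIRECT)
    assert sum(r.duration for r in seg.runs) == pytest.approx(200 * DT)
    for a, b in zip(seg.runs, seg.runs[1:]):
        assert a.t_end == pytest.approx(b.t_start)


def test_runs_shorter_than_persistence_are_absorbed():
    values = np.r_[np.full(20, 82.3), np.full(2, 59.2), np.full(20, 82.3)]
    assert _levels(values) == ["HIGH"]


def test_persistent_excursion_is_kept():
    values = np.r_[np.full(20, 82.3), np.full(6, 59.2), np.full(20, 82.3)]
    assert _levels(values) == ["HIGH", "BOUND", "HIGH"]


def test_threshold_grazing_run_is_absorbed_as_noise():
    # four points just under the BOUND|SYNAPSED midpoint inside a synapsed
    # phase: statistically indistinguishable from noise, must not split it
    thr = (59.2 + 42.0) / 2
    values = np.r_[np.full(30, 42.0), np.full(4, thr + 1.0), np.full(30, 42.0)]
    assert _levels(values) == ["SYNAPSED"]


def test_tie_at_threshold_assigned_to_lower_level():
    thr = (82.3 + 59.2) / 2
    idx = DIRECT.assign(np.array([thr, thr + 1e-9]))
    assert DIRECT.levels[idx[0]].label == "BOUND"
    assert DIRECT.levels[idx[1]].label == "HIGH"


def test_empty_trace_rejected():
    with pytest.raises(ValueError, match="empty"):
        call_levels(_bm(np.array([])), DIRECT)


def test_level_model_requires_decreasing_means():
    with pytest.raises(ValueError, match="decreasing"):
        LevelModel((Level("A", 50.0, 5.0), Level("B", 60.0, 5.0)))


def test_baseline_calibration_shifts_ladder_and_keeps_order():
    cal = DIRECT.calibrated(baseline_mean=86.0)
    means = [lv.mean for lv in cal.levels]
    assert means[0] > 82.3  # shifted toward the molecule's own baseline
    assert means[0] > means[1] > means[2]
    assert DIRECT.calibrated(82.3).levels[0].mean == pytest.approx(82.3)


def test_post_sds_level_calls_high_and_low():
    proto = default_protocol()
    n_post = 60
    t0 = proto.t_sds
    low = _bm(np.full(n_post, 45.1), t0=t0 + 3 * DT)
    high = _bm(np.full(n_post, 82.3), t0=t0 + 3 * DT)
    assert post_sds_level(low, DIRECT, proto.t_sds) == "LOW"
    assert post_sds_level(high, DIRECT, proto.t_sds) == "HIGH"


# -- dwell extraction --------------------------------------------------------


def _segmented(runs_spec, t_end=2040.0):
    runs = []
    for label, t0, t1 in runs_spec:
        runs.append(Run(label, t0, t1, 0, 0))
    return SegmentedTrace(runs=runs, molecule_id="m", dt=DT, metadata={"orientation": "direct"})


def test_dwell_arithmetic_on_constructed_path():
    proto = default_protocol()  # addition at 120 s, SDS at 1920 s
    seg = _segmented(
        [
            ("HIGH", 0.0, 160.0),  # association dwell = 160 - 120 = 40 s
            ("BOUND", 160.0, 220.0),  # presynaptic dwell = 60 s
            ("SYNAPSED", 220.0, 2040.0),
        ]
    )
    dwells = extract_dwells(seg, proto)
    assoc = dwells.records[dwells.records.dwell_type == "association"].iloc[0]
    ps = dwells.records[dwells.records.dwell_type == "presynaptic"].iloc[0]
    syn = dwells.records[dwells.records.dwell_type == "synapsed"].iloc[0]
    assert assoc.duration == pytest.approx(40.0)
    assert assoc.outcome == "presynaptic"
    assert ps.duration == pytest.approx(60.0)
    assert ps.outcome == "type_b"
    assert syn.censored and syn.outcome == "persists_to_sds"
    assert syn.duration == pytest.approx(1920.0 - 220.0)


def test_wayward_cycle_produces_type_a_and_returns_high_dwells():
    proto = default_protocol()
    seg = _segmented(
        [
            ("HIGH", 0.0, 150.0),
            ("BOUND", 150.0, 200.0),
            ("SYNAPSED", 200.0, 260.0),  # returns upward: wayward
            ("BOUND", 260.0, 300.0),
            ("HIGH", 300.0, 2040.0),
        ]
    )
    d = extract_dwells(seg, proto)
    ps = d.records[d.records.dwell_type == "presynaptic"]
    assert list(ps.outcome) == ["type_a"]
    syn = d.records[d.records.dwell_type == "synapsed"].iloc[0]
    assert syn.outcome == "returns_high" and not syn.censored
    npd = d.records[d.records.dwell_type == "nonproductive"].iloc[0]
    assert npd.outcome == "decayed" and npd.duration == pytest.approx(40.0)


def test_molecule_never_leaving_high_has_empty_dwell_set():
    proto = default_protocol()
    seg = _segmented([("HIGH", 0.0, 2040.0)])
    assert len(extract_dwells(seg, proto).records) == 0


# -- classification ----------------------------------------------------------


@pytest.mark.parametrize(
    "runs, orientation, endpoint, expected",
    [
        ([("HIGH", 0, 2040)], "direct", "HIGH", "unbound"),
        (
            [("HIGH", 0, 300), ("BOUND", 300, 700), ("HIGH", 700, 2040)],
            "direct",
            "HIGH",
            "non_productive",
        ),
        (
            [("HIGH", 0, 300), ("BOUND", 300, 400), ("SYNAPSED", 400, 2040)],
            "direct",
            "LOW",
            "synaptic",
        ),
        (
            [("HIGH", 0, 300), ("BOUND", 300, 400), ("SYNAPSED", 400, 2040)],
            "direct",
            "HIGH",
            "wayward",
        ),
        (
            [("HIGH", 0, 300), ("BOUND", 300, 400), ("SYNAPSED", 400, 2040)],
            "inverted",
            "HIGH",
            "ambiguous",
        ),
        (
            [("HIGH", 0, 300), ("BOUND", 300, 400), ("SYNAPSED", 400, 2040)],
            "inverted",
            "LOW",
            "synaptic",
        ),
    ],
)
def test_complex_classification(runs, orientation, endpoint, expected):
    proto = default_protocol()
    seg = _segmented(runs)
    dwells = extract_dwells(seg, proto)
    assert classify_molecule(seg, dwells, orientation, endpoint).label == expected


def test_classification_requires_sds_endpoint():
    proto = default_protocol()
    seg = _segmented([("HIGH", 0.0, 2040.0)])
    with pytest.raises(ValueError, match="endpoint"):
        classify_molecule(seg, extract_dwells(seg, proto), "direct", None)


def test_dwell_set_rejects_nonpositive_durations():
    bad = pd.DataFrame([("m", "synapsed", -1.0, "returns_high", False, 0.0)],
                       columns=DWELL_COLUMNS)
    with pytest.raises(ValueError, match="> 0"):
        DwellSet(bad)
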