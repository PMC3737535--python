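"""State-path simulation, trace emission, artifacts and the trace format."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from flptpm.io import read_trace, write_trace
from flptpm.preprocess import compute_bm
from flptpm.scheme import ExperimentProtocol, KineticScheme, MoleculeState, default_scheme
from flptpm.simulate import (
    ArtifactSpec,
    EmissionTable,
    LevelEmission,
    Segment,
    StatePath,
    amplitude_for_length,
    default_emission_table,
    emit_trace,
    inject_artifacts,
    simulate_cohort,
    simulate_state_path,
)


def _collect_dwells(scheme, protocol, state, n_paths, seed):
    out = []
    for child in np.random.SeedSequence(seed).spawn(n_paths):
        path = simulate_state_path(scheme, protocol, np.random.default_rng(child))
        out += [
            s.t_end - s.t_start
            for s in path.segments
            if s.state is state and s.t_end < protocol.t_sds
        ]
    return np.asarray(out)


def test_zero_rate_scheme_stays_free(protocol, rng):
    scheme = KineticScheme(variant="Flpe", orientation="direct")
    path = simulate_state_path(scheme, protocol, rng)
    pre_sds = [s for s in path.segments if s.t_start < protocol.t_sds]
    assert len(pre_sds) == 1
    assert pre_sds[0].state is MoleculeState.FREE
    assert pre_sds[0].t_start == 0.0 and pre_sds[0].t_end == protocol.t_sds
    assert path.post_sds_state is MoleculeState.POST_SDS_HIGH


@settings(deadline=None, max_examples=25)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_path_segments_contiguous_and_cover_experiment(seed):
    protocol = ExperimentProtocol(t_baseline=40, t_flp_add=50, t_sds=700, t_post_sds=50)
    scheme = default_scheme("Flpe", "direct")
    path = simulate_state_path(scheme, protocol, np.random.default_rng(seed))
    segs = path.segments
    assert segs[0].t_start == 0.0
    assert segs[0].state is MoleculeState.FREE
    assert segs[-1].t_end == pytest.approx(protocol.total_duration)
    for a, b in zip(segs, segs[1:]):
        assert a.t_end == pytest.approx(b.t_start)
    # irreversibility: nothing leaves the covalent state before the quench
    for a, b in zip(segs, segs[1:]):
        if a.state is MoleculeState.HOLLIDAY_OR_PRODUCT and b.t_start < protocol.t_sds:
            assert b.state is MoleculeState.HOLLIDAY_OR_PRODUCT


def test_nonproductive_dwell_mean_matches_decay_rate(direct_scheme, protocol):
    dwells = _collect_dwells(
        direct_scheme, protocol, MoleculeState.NONPRODUCTIVE, 3600, seed=77
    )
    assert len(dwells) >= 10_000
    mean, se = dwells.mean(), dwells.std(ddof=1) / np.sqrt(len(dwells))
    assert abs(mean - 25.0) < 3 * se


def test_dwell_samples_pass_ks_against_generating_exponential(direct_scheme, protocol):
    dwells = _collect_dwells(
        direct_scheme, protocol, MoleculeState.NONPRODUCTIVE, 3600, seed=78
    )[:10_000]
    p = stats.kstest(dwells, stats.expon(scale=1 / direct_scheme.k_d_np).cdf).pvalue
    assert p > 0.01


def test_cleavage_dead_cohort_never_reaches_low_endpoint(protocol):
    scheme = default_scheme("Y343F", "direct")
    for child in np.random.SeedSequence(5).spawn(300):
        path = simulate_state_path(scheme, protocol, np.random.default_rng(child))
        assert path.post_sds_state is MoleculeState.POST_SDS_HIGH


def test_occupancy_matches_stationary_distribution_without_chemistry():
    """With k_r = 0 the chain settles into the pre-synaptic/wayward cycle
    whose stationary occupancies follow from the rate matrix null space."""
    scheme = default_scheme("Y343F", "direct")
    protocol = ExperimentProtocol(
        t_baseline=10, t_flp_add=20, t_sds=2e5, t_post_sds=0.0
    )
    occ = {}
    for child in np.random.SeedSequence(3).spawn(30):
        path = simulate_state_path(scheme, protocol, np.random.default_rng(child))
        for seg in path.segments:
            t0 = max(seg.t_start, 1e5)  # discard the transient half
            if seg.t_end > t0:
                occ[seg.state] = occ.get(seg.state, 0.0) + seg.t_end - t0
    total = sum(occ.values())
    # analytic stationary distribution of the absorbing PS <-> SW cycle
    pi_ps = (1 / scheme.k_f_wayward) / (1 / scheme.k_f_wayward + 1 / scheme.k_d_wayward)
    assert occ.get(MoleculeState.FREE, 0.0) / total < 0.01
    assert occ[MoleculeState.PRESYNAPTIC] / total == pytest.approx(pi_ps, abs=0.03)
    assert occ[MoleculeState.SYNAPSED_WAYWARD] / total == pytest.approx(1 - pi_ps, abs=0.03)


def test_zero_amplitude_state_emits_exact_zeros(protocol, rng):
    table = EmissionTable("none", {MoleculeState.FREE: LevelEmission(0.0, 0.0),
                                   MoleculeState.POST_SDS_HIGH: LevelEmission(0.0, 0.0)})
    scheme = KineticScheme(variant="Flpe", orientation="none")
    path = simulate_state_path(scheme, protocol, rng)
    trace = emit_trace(path, table, protocol, rng)
    assert np.all(trace.x == 0.0) and np.all(trace.y == 0.0)


def test_free_tether_windowed_bm_matches_emission_mean(rng):
    protocol = ExperimentProtocol(t_baseline=100, t_flp_add=3000, t_sds=3000, t_post_sds=0)
    scheme = KineticScheme(variant="Flpe", orientation="none")
    path = simulate_state_path(scheme, protocol, rng)
    trace = emit_trace(
        path, default_emission_table("Flpe", "none"), protocol, rng, between_molecule=False
    )
    bm = compute_bm(trace)
    assert len(bm) > 2000
    assert bm.bm.mean() == pytest.approx(83.4, rel=0.01)


def test_synapsed_state_windowed_bm_matches_low_level(rng):
    protocol = ExperimentProtocol(t_baseline=100, t_flp_add=2000, t_sds=2000, t_post_sds=0)
    scheme = default_scheme("Flpe", "direct")
    path = StatePath(
        "m0",
        [Segment(MoleculeState.SYNAPSED_ACTIVE, 0.0, protocol.total_duration)],
        scheme,
        protocol,
    )
    trace = emit_trace(
        path, default_emission_table("Flpe", "direct"), protocol, rng, between_molecule=False
    )
    assert compute_bm(trace).bm.mean() == pytest.approx(42.0, rel=0.015)


def test_length_calibration_anchors():
    assert amplitude_for_length(1168) == pytest.approx(83.4)
    assert amplitude_for_length(549) == pytest.approx(45.1)


def test_emission_level_ordering_enforced():
    with pytest.raises(ValueError, match="exceed"):
        EmissionTable(
            "direct",
            {
                MoleculeState.FREE: LevelEmission(50.0, 5.0),
                MoleculeState.NONPRODUCTIVE: LevelEmission(60.0, 5.0),
                MoleculeState.POST_SDS_HIGH: LevelEmission(50.0, 5.0),
            },
        )


# -- artifacts ---------------------------------------------------------------


def _one_trace(protocol, seed=9):
    scheme = default_scheme("Flpe", "direct")
    rng = np.random.default_rng(seed)
    path = simulate_state_path(scheme, protocol, rng)
    return emit_trace(path, default_emission_table("Flpe", "direct"), protocol, rng), rng


def test_empty_artifact_spec_leaves_trace_untouched(short_protocol):
    trace, rng = _one_trace(short_protocol)
    out = inject_artifacts(trace, ArtifactSpec(), rng)
    assert np.array_equal(out.x, trace.x) and np.array_equal(out.y, trace.y)
    assert out.metadata["artifacts"] == []


def test_overlapping_artifact_intervals_rejected(short_protocol):
    trace, rng = _one_trace(short_protocol)
    spec = ArtifactSpec(stuck=((100.0, 140.0),), distorted=((120.0, 180.0),))
    with pytest.raises(ValueError, match="overlap"):
        inject_artifacts(trace, spec, rng)


def test_artifacts_annotated_and_shape_preserving(short_protocol):
    trace, rng = _one_trace(short_protocol)
    spec = ArtifactSpec(stuck=((60.0, 80.0),), distorted=((120.0, 180.0),))
    out = inject_artifacts(trace, spec, rng)
    assert len(out.x) == len(trace.x)
    kinds = {a[0] for a in out.metadata["artifacts"]}
    assert kinds == {"stuck", "distorted"}
    sel = (out.times >= 60.0) & (out.times < 80.0)
    assert out.x[sel].std() < 15.0  # collapsed motion inside the stuck window


# -- determinism and the trace format ---------------------------------------


def test_identical_seed_gives_byte_identical_trace_files(tmp_path, short_protocol):
    scheme = default_scheme("Flpe", "direct")
    files = []
    for run in ("a", "b"):
        traces, _, _ = simulate_cohort(scheme, short_protocol, 3, seed=321)
        p = tmp_path / f"{run}.tsv"
        write_trace(traces[2], str(p))
        files.append(p.read_bytes() + (tmp_path / f"{run}.tsv.meta.json").read_bytes())
    assert files[0] == files[1]


def test_trace_round_trip_is_exact(tmp_path, short_protocol):
    trace, _ = _one_trace(short_protocol)
    path = str(tmp_path / "trace.tsv")
    write_trace(trace, path)
    back = read_trace(path)
    assert np.array_equal(back.x, trace.x)
    assert np.array_equal(back.y, trace.y)
    assert np.array_equal(back.times, trace.times)
    assert back.metadata["molecule_id"] == trace.molecule_id


def test_scientific_notation_coordinates_parse(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("frame\ttime_s\tx_nm\ty_nm\n0\t0.0\t1e-3\t-2.5E2\n1\t0.1\t3.0\t4.0\n")
    (tmp_path / "t.tsv.meta.json").write_text(
        '{"format_version": "1.0", "molecule_id": "m", "protocol": {}}\n'
    )
    t = read_trace(str(path))
    assert t.x[0] == pytest.approx(1e-3) and t.y[0] == pytest.approx(-250.0)


def test_malformed_rows_and_missing_metadata_rejected(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("frame\ttime_s\tx_nm\ty_nm\n0\t0.0\t1.0\n")
    (tmp_path / "bad.tsv.meta.json").write_text(
        '{"format_version": "1.0", "molecule_id": "m", "protocol": {}}\n'
    )
    with pytest.raises(ValueError, match="row 2"):
        read_trace(str(p))

    q = tmp_path / "cols.tsv"
    q.write_text("frame\ttime_s\tx_nm\n0\t0.0\t1.0\n")
    (tmp_path / "cols.tsv.meta.json").write_text(
        '{"format_version": "1.0", "molecule_id": "m", "protocol": {}}\n'
    )
    with pytest.raises(ValueError, match="missing"):
        read_trace(str(q))

    r = tmp_path / "nometa.tsv"
    r.write_text("frame\ttime_s\tx_nm\ty_nm\n")
    with pytest.raises(ValueError, match="sidecar"):
        read_trace(str(r))


def test_cohort_truth_table_consistent_with_paths(short_protocol):
    scheme = default_scheme("Flpe", "direct")
    traces, paths, truth = simulate_cohort(scheme, short_protocol, 6, seed=4)
    assert len(traces) == len(paths) == len(truth) == 6
    for path, rec in zip(paths, truth):
        assert rec["class"] == path.true_class()
        assert rec["post_sds_state"] == path.post_sds_state.value
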