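"""Cohort-level orchestration: simulate -> analyze -> recover.

``run_analyze`` drives the full trace-analysis chain (windowed BM, smoothing,
QC, level calling, dwell extraction, classification, kinetic fits) over a set
of raw traces and aggregates cohort statistics.  ``run_recover`` closes the
loop: it simulates a cohort with known rate constants, analyzes it blind, and
reports the relative error of every recovered rate against the ground truth —
the package's parameter-recovery harness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fitting, preprocess, segment, simulate
from .scheme import ExperimentProtocol, KineticScheme

__all__ = ["CohortSummary", "RecoveryReport", "run_analyze", "run_recover"]


@dataclass
class CohortSummary:
    """Aggregate results of analyzing one cohort of traces."""

    n_total: int
    n_qc_passed: int
    n_responded: int  # left the HIGH level at least once before SDS
    class_counts: dict  # ComplexClass label -> count (QC-passed molecules)
    synapsed_low_fraction: float  # post-SDS LOW among synapsed molecules
    kinetic_table: pd.DataFrame
    qc_failures: dict  # reason -> count
    per_molecule: pd.DataFrame  # id, qc_pass, class, post_sds
    dwells: segment.DwellSet
    # share of recombinase-bound time spent at the bound (non-productive /
    # pre-synaptic) level rather than the synapsed level -- the
    # amplitude-population analogue of a "non-productive fraction"
    bound_occupancy: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_qc_passed": self.n_qc_passed,
            "n_responded": self.n_responded,
            "class_counts": dict(self.class_counts),
            "synapsed_low_fraction": self.synapsed_low_fraction,
            "bound_occupancy": self.bound_occupancy,
            "qc_failures": dict(self.qc_failures),
            "kinetic_table": json.loads(self.kinetic_table.to_json(orient="index")),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def run_analyze(
    traces,
    level_model: segment.LevelModel,
    qc_config: preprocess.QCConfig,
    protocol: ExperimentProtocol,
    fit_config: fitting.FitConfig = fitting.FitConfig(),
    orientation: str | None = None,
    calibrate_baseline: bool = True,
) -> CohortSummary:
    """Analyze a cohort of raw traces end to end.

    Deterministic given its inputs.  Molecules failing QC are excluded from
    segmentation, classification and dwell pools (their failure reasons are
    tallied), mirroring the molecule-attrition bookkeeping of a TPM assay.
    With ``calibrate_baseline`` (default) the level ladder is shifted to each
    molecule's own protein-free baseline before level calling, absorbing
    bead/tether amplitude heterogeneity.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("run_analyze requires at least one trace")
    expected_high = level_model.levels[0].mean
    orientation = orientation or traces[0].metadata.get("orientation", "direct")

    qc_fail: dict = {}
    rows = []
    dwell_sets = []
    n_pass = n_resp = 0
    class_counts = {c: 0 for c in segment.COMPLEX_CLASSES}
    n_syn = n_syn_low = 0
    t_bound = t_synapsed = 0.0

    for trace in traces:
        bm_raw = preprocess.compute_bm(trace)
        bm = preprocess.smooth_five_point(bm_raw)
        qc = preprocess.apply_qc(bm, qc_config, protocol.t_flp_add, expected_high)
        if not qc.passed:
            for r in qc.reasons:
                qc_fail[r] = qc_fail.get(r, 0) + 1
            rows.append((trace.molecule_id, False, None, None))
            continue
        model = level_model
        if calibrate_baseline and len(model.levels) > 1:
            baseline = float(bm.bm[bm.time_mid < protocol.t_flp_add].mean())
            model = model.calibrated(baseline)
        if len(model.levels) > 2:
            # level-resolution check: a molecule whose amplitude bias
            # compresses the calibrated bound-synapsed gap to less than
            # ~3x the windowed-BM noise (or 60% of the substrate's nominal
            # gap, whichever is smaller -- the nominal geometry is what the
            # experiment accepted by design) cannot be idealized reliably
            # and is excluded
            low, nxt = model.levels[-1], model.levels[-2]
            nom = level_model.levels[-2].mean - level_model.levels[-1].mean
            sd_pt = low.mean / math.sqrt(4.0 * bm_raw.window_frames)
            if nxt.mean - low.mean < min(3.0 * sd_pt, 0.6 * nom):
                qc_fail["level_resolution"] = qc_fail.get("level_resolution", 0) + 1
                rows.append((trace.molecule_id, False, None, None))
                continue
        n_pass += 1
        # level calling runs on the unsmoothed windowed series: the windows
        # are statistically independent, so the persistence rule controls
        # false transitions, while five-point smoothing would attenuate
        # short state visits below detectability (QC and endpoint calls use
        # the smoothed series as usual).
        seg = segment.call_levels(bm_raw, model)
        endpoint = segment.post_sds_level(bm, model, protocol.t_sds)
        for run in seg.runs:
            span = min(run.t_end, protocol.t_sds) - max(run.t_start, protocol.t_flp_add)
            if span > 0:
                if run.label == segment.LEVEL_BOUND:
                    t_bound += span
                elif run.label == segment.LEVEL_SYNAPSED:
                    t_synapsed += span
        dwells = segment.extract_dwells(seg, protocol)
        dwells.orientation = orientation
        cls = segment.classify_molecule(seg, dwells, orientation, endpoint)
        class_counts[cls.label] += 1
        responded = cls.label != "unbound"
        n_resp += responded
        if cls.label in ("wayward", "synaptic", "ambiguous"):
            n_syn += 1
            n_syn_low += endpoint == "LOW"
        dwell_sets.append(dwells)
        rows.append((trace.molecule_id, True, cls.label, endpoint))

    if dwell_sets:
        all_dwells = segment.DwellSet.concat(dwell_sets)
    else:
        all_dwells = segment.DwellSet(
            pd.DataFrame(columns=segment.DWELL_COLUMNS), orientation=orientation
        )
    table = fitting.compile_kinetic_table(
        all_dwells, protocol.flp_concentration, fit_config
    )
    return CohortSummary(
        n_total=len(traces),
        n_qc_passed=n_pass,
        n_responded=n_resp,
        class_counts=class_counts,
        synapsed_low_fraction=(n_syn_low / n_syn) if n_syn else float("nan"),
        bound_occupancy=(
            t_bound / (t_bound + t_synapsed) if (t_bound + t_synapsed) > 0 else float("nan")
        ),
        kinetic_table=table,
        qc_failures=qc_fail,
        per_molecule=pd.DataFrame(rows, columns=["molecule_id", "qc_pass", "class", "post_sds"]),
        dwells=all_dwells,
    )


# rates compared by the recovery harness: (name, truth getter, table lookup)
def _recovery_targets(scheme: KineticScheme, c: float, table: pd.DataFrame):
    second = lambda row, col: table.loc[row, col]  # noqa: E731
    targets = [
        ("k_f_np", scheme.k_f_np, second("non_productive", "kf")),
        ("k_d_np", scheme.k_d_np, second("non_productive", "kd")),
        ("k_f_ps", scheme.k_f_ps, second("pre_synaptic", "kf")),
    ]
    if scheme.orientation == "inverted":
        targets.append(("k_f_synapse", scheme.k_f_synaptic, second("synaptic", "kf")))
    else:
        targets += [
            ("k_f_wayward", scheme.k_f_wayward, second("wayward", "kf")),
            ("k_f_synaptic", scheme.k_f_synaptic, second("synaptic", "kf")),
        ]
    targets.append(("k_d_wayward", scheme.k_d_wayward, second("wayward", "kd")))
    return targets


@dataclass
class RecoveryReport:
    """Per-rate recovery outcome of a simulate-then-analyze round trip."""

    entries: pd.DataFrame  # rate, truth, estimate, rel_error, tolerance, passed
    all_passed: bool
    underpowered: bool
    seed: int
    n_molecules: int
    summary: CohortSummary

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "n_molecules": self.n_molecules,
                "all_passed": bool(self.all_passed),
                "underpowered": bool(self.underpowered),
                "entries": json.loads(self.entries.to_json(orient="records")),
            },
            indent=1,
            sort_keys=True,
        )


def run_recover(
    scheme: KineticScheme,
    protocol: ExperimentProtocol,
    n_molecules: int,
    seed: int,
    tolerance: float = 0.15,
    emission: simulate.EmissionTable | None = None,
    fit_config: fitting.FitConfig = fitting.FitConfig(),
    min_events: int = 30,
) -> RecoveryReport:
    """Simulate a cohort with known rates, analyze it, compare.

    Each recovered rate must lie within ``tolerance`` relative error of the
    generating value.  Cohorts yielding fewer than ``min_events`` dwells for
    some transition are reported as underpowered rather than failed.
    """
    traces, _, _ = simulate.simulate_cohort(scheme, protocol, n_molecules, seed, emission)
    level_model = segment.default_level_model(scheme.variant, scheme.orientation)
    summary = run_analyze(
        traces,
        level_model,
        preprocess.QCConfig(),
        protocol,
        fit_config,
        orientation=scheme.orientation,
    )
    table = summary.kinetic_table
    c = protocol.flp_concentration

    rows = []
    underpowered = False
    for name, truth, est in _recovery_targets(scheme, c, table):
        n_events = 0
        if est is not None and not (isinstance(est, float) and math.isnan(est)):
            row = "non_productive" if "np" in name else (
                "pre_synaptic" if name == "k_f_ps" else (
                    "wayward" if "wayward" in name else "synaptic"))
            col = "n_d" if name.startswith("k_d") else "n_f"
            n_events = int(table.loc[row, col])
        if est is None or (isinstance(est, float) and math.isnan(est)) or n_events < min_events:
            underpowered = True
            rows.append((name, truth, est, None, tolerance, False))
            continue
        rel = abs(est - truth) / truth if truth > 0 else math.inf
        rows.append((name, truth, float(est), float(rel), tolerance, rel <= tolerance))

    entries = pd.DataFrame(
        rows, columns=["rate", "truth", "estimate", "rel_error", "tolerance", "passed"]
    )
    evaluated = entries[entries["rel_error"].notna()]
    all_passed = (not underpowered) and bool(evaluated["passed"].all())
    return RecoveryReport(
        entries=entries,
        all_passed=all_passed,
        underpowered=underpowered,
        seed=seed,
        n_molecules=n_molecules,
        summary=summary,
    )
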