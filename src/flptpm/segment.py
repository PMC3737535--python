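"""Trace idealization, dwell-time extraction and molecule classification.

Smoothed BM traces are idealized by thresholding against a per-substrate
ladder of amplitude levels (HIGH = protein-free tether, BOUND = recombinase
bound sites, SYNAPSED = paired sites) with midpoint thresholds and a minimum
run persistence; runs shorter than the persistence floor are absorbed into a
flanking run.  Dwell times are then read off the idealized runs, labelled by
their outcome and censored at the SDS quench, and each molecule is assigned a
complex class using the orientation-aware post-SDS endpoint logic:

* never left HIGH                          -> ``unbound``
* bound but never synapsed                 -> ``non_productive``
* synapsed, direct sites, post-SDS LOW     -> ``synaptic`` (covalent progress)
* synapsed, direct sites, post-SDS HIGH    -> ``wayward``
* synapsed, inverted sites, post-SDS LOW   -> ``synaptic`` (Holliday-trapped)
* synapsed, inverted sites, post-SDS HIGH  -> ``ambiguous`` (completed
  inversion and wayward complexes are indistinguishable per molecule; the
  split is recovered statistically by the bi-exponential dwell analysis)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import BMTrace
from .scheme import ExperimentProtocol

__all__ = [
    "Level",
    "LevelModel",
    "default_level_model",
    "SegmentedTrace",
    "DwellSet",
    "call_levels",
    "post_sds_level",
    "extract_dwells",
    "classify_molecule",
]

LEVEL_HIGH = "HIGH"
LEVEL_BOUND = "BOUND"
LEVEL_SYNAPSED = "SYNAPSED"


@dataclass(frozen=True)
class Level:
    label: str
    mean: float  # nm
    sd: float  # nm


@dataclass(frozen=True)
class LevelModel:
    """Ordered amplitude levels (descending mean) with midpoint thresholds."""

    levels: tuple  # tuple[Level], means strictly decreasing
    min_persistence: int = 3  # smoothed points
    post_sds_low_mean: float | None = None  # amplitude of the post-SDS LOW state

    def __post_init__(self) -> None:
        means = [lv.mean for lv in self.levels]
        if any(b >= a for a, b in zip(means, means[1:])):
            raise ValueError("level means must be strictly decreasing")
        if self.min_persistence < 1:
            raise ValueError("min_persistence must be >= 1")

    @property
    def thresholds(self) -> tuple:
        """Midpoints between adjacent level means (descending)."""
        means = [lv.mean for lv in self.levels]
        return tuple((a + b) / 2.0 for a, b in zip(means, means[1:]))

    @property
    def labels(self) -> tuple:
        return tuple(lv.label for lv in self.levels)

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Index of the level for each value; ties go to the lower level."""
        idx = np.zeros(len(values), dtype=int)
        for thr in self.thresholds:
            idx += values <= thr  # tie at threshold -> lower level
        return idx

    def between_sd(self, level: Level, window_frames: int = 40) -> float:
        """Between-molecule spread of a level after removing the windowed-BM
        estimator sampling noise (same variance decomposition the emission
        model uses)."""
        est_var = level.mean**2 / (4.0 * window_frames)
        return float(np.sqrt(max(level.sd**2 - est_var, 0.0)))

    def calibrated(self, baseline_mean: float, window_frames: int = 40, z_max: float = 3.0) -> "LevelModel":
        """Shift the level ladder to one molecule's own amplitude scale.

        Bead and tether heterogeneity give each molecule a persistent
        amplitude bias visible in its protein-free baseline.  The bias is
        expressed as a z-score of the top level's between-molecule spread
        (clamped to ``±z_max``) and propagated to every level via its own
        spread, keeping the ladder ordered for any plausible bias.
        """
        high = self.levels[0]
        sd_b = self.between_sd(high, window_frames)
        if sd_b <= 0:
            return self
        z = float(np.clip((baseline_mean - high.mean) / sd_b, -z_max, z_max))
        # keep the ladder ordered: cap |z| so every calibrated gap retains at
        # least 10% of its nominal width (levels with very different spreads,
        # e.g. a broad synapsed state, would otherwise cross)
        sds = [self.between_sd(lv, window_frames) for lv in self.levels]
        for (a, sa), (b, sb) in zip(
            zip(self.levels, sds), zip(self.levels[1:], sds[1:])
        ):
            gap, slope = a.mean - b.mean, sa - sb
            if slope == 0:
                continue
            z_cross = -0.9 * gap / slope  # z at which the gap shrinks to 10%
            if z_cross > 0:
                z = min(z, z_cross)
            else:
                z = max(z, z_cross)
        shifted = tuple(
            Level(lv.label, lv.mean + z * self.between_sd(lv, window_frames), lv.sd)
            for lv in self.levels
        )
        return LevelModel(shifted, self.min_persistence, self.post_sds_low_mean)


_LEVEL_DEFAULTS = {
    ("Flpe", "direct"): (
        (Level(LEVEL_HIGH, 82.3, 7.4), Level(LEVEL_BOUND, 59.2, 4.8), Level(LEVEL_SYNAPSED, 42.0, 6.1)),
        45.1,
    ),
    ("Flpe", "inverted"): (
        (Level(LEVEL_HIGH, 82.1, 8.3), Level(LEVEL_BOUND, 59.2, 4.8), Level(LEVEL_SYNAPSED, 48.3, 6.7)),
        48.3,
    ),
    ("Y343F", "direct"): (
        (Level(LEVEL_HIGH, 78.9, 7.9), Level(LEVEL_BOUND, 66.7, 3.6), Level(LEVEL_SYNAPSED, 51.0, 19.5)),
        None,
    ),
    ("Flpe", "single"): (
        (Level(LEVEL_HIGH, 79.8, 7.9), Level(LEVEL_BOUND, 64.8, 4.1)),
        None,
    ),
    ("Flpe", "none"): ((Level(LEVEL_HIGH, 83.4, 7.1),), None),
}


def default_level_model(variant: str, orientation: str, min_persistence: int = 3) -> LevelModel:
    """Measured level ladder for a characterized variant/orientation pair."""
    try:
        levels, low = _LEVEL_DEFAULTS[(variant, orientation)]
    except KeyError:
        raise ValueError(
            f"no default level model for variant={variant!r}, orientation={orientation!r}"
        ) from None
    return LevelModel(levels, min_persistence=min_persistence, post_sds_low_mean=low)


@dataclass
class Run:
    label: str
    t_start: float
    t_end: float
    i_start: int
    i_stop: int  # exclusive

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class SegmentedTrace:
    """Idealized level runs for one molecule."""

    runs: list  # list[Run], contiguous
    molecule_id: str
    dt: float
    post_sds: str | None = None  # "HIGH" | "LOW"
    metadata: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.runs[-1].t_end - self.runs[0].t_start if self.runs else 0.0

    def labels_per_point(self, n: int) -> np.ndarray:
        out = np.empty(n, dtype=object)
        for run in self.runs:
            out[run.i_start : run.i_stop] = run.label
        return out


def _merge_short_runs(idx: np.ndarray, model: LevelModel) -> np.ndarray:
    """Absorb runs shorter than min_persistence into a flanking run.

    The short run's points are relabelled to whichever flanking level's mean
    is nearer to the short run's own level mean; repeats until stable.
    """
    means = np.array([lv.mean for lv in model.levels])
    idx = idx.copy()
    while True:
        runs = _run_bounds(idx)
        if len(runs) <= 1:
            return idx
        short = [
            (b - a, k) for k, (a, b, _) in enumerate(runs) if b - a < model.min_persistence
        ]
        if not short:
            return idx
        _, k = min(short)
        a, b, lab = runs[k]
        neighbors = []
        if k > 0:
            neighbors.append(runs[k - 1][2])
        if k < len(runs) - 1:
            neighbors.append(runs[k + 1][2])
        target = min(neighbors, key=lambda nb: abs(means[nb] - means[lab]))
        idx[a:b] = target


def _merge_insignificant_runs(
    idx: np.ndarray,
    values: np.ndarray,
    model: LevelModel,
    window_frames: int,
    z_crit: float = 2.0,
) -> np.ndarray:
    """Absorb runs whose amplitude evidence does not support a transition.

    A run at level i sandwiched between runs of a single other level j is a
    claimed excursion; it is kept only when its mean amplitude lies on level
    i's side of the i|j midpoint by at least ``z_crit`` standard errors of
    the run mean (point noise = windowed-BM sampling noise mu/sqrt(4m), the
    windows being independent).  Marginal threshold-grazing excursions -
    noise, not transitions - are relabelled to the flanking level.

    The test assumes unsmoothed input: a genuine short excursion then spends
    its full amplitude at the target level (mean ~ one full step beyond the
    midpoint, kept with overwhelming probability), while a noise-induced
    threshold-grazing run hugs the midpoint and is absorbed.  On smoothed
    input short excursions are attenuated toward the threshold and this test
    would discard them.
    """
    means = np.array([lv.mean for lv in model.levels])
    idx = idx.copy()
    while True:
        runs = _run_bounds(idx)
        if len(runs) < 3:
            return idx
        worst = None
        for k in range(1, len(runs) - 1):
            a, b, lab = runs[k]
            left, right = runs[k - 1][2], runs[k + 1][2]
            if left != right or left == lab:
                continue
            mid = (means[lab] + means[left]) / 2.0
            sd_pt = means[lab] / math.sqrt(4.0 * window_frames)
            margin = abs(float(values[a:b].mean()) - mid)
            z = margin / (sd_pt / math.sqrt(b - a))
            if z < z_crit and (worst is None or z < worst[0]):
                worst = (z, k, left)
        if worst is None:
            return idx
        _, k, target = worst
        a, b, _ = runs[k]
        idx[a:b] = target


def _run_bounds(idx: np.ndarray):
    """(start, stop, label_index) triples of constant runs in idx."""
    edges = np.flatnonzero(np.diff(idx)) + 1
    bounds = np.concatenate(([0], edges, [len(idx)]))
    return [(int(a), int(b), int(idx[a])) for a, b in zip(bounds[:-1], bounds[1:])]


def call_levels(bm_trace: BMTrace, model: LevelModel) -> SegmentedTrace:
    """Idealize a smoothed BM trace into alternating level runs.

    Each point gets the level whose threshold interval contains it (ties to
    the lower level); runs shorter than ``min_persistence`` are merged into
    the flanking run with the nearer mean.  Run boundaries are placed halfway
    between adjacent window midtimes, so run durations sum to the trace span.
    """
    if len(bm_trace) == 0:
        raise ValueError("cannot segment an empty BM trace")
    idx = model.assign(bm_trace.bm)
    idx = _merge_short_runs(idx, model)
    idx = _merge_insignificant_runs(idx, bm_trace.bm, model, bm_trace.window_frames)
    idx = _merge_short_runs(idx, model)

    t = bm_trace.time_mid
    dt = bm_trace.dt
    runs = []
    for a, b, lab in _run_bounds(idx):
        t0 = t[a] - dt / 2.0
        t1 = t[b - 1] + dt / 2.0
        runs.append(Run(model.levels[lab].label, float(t0), float(t1), a, b))
    return SegmentedTrace(
        runs=runs,
        molecule_id=bm_trace.molecule_id,
        dt=dt,
        metadata=bm_trace.metadata,
    )


def post_sds_level(bm_trace: BMTrace, model: LevelModel, t_sds: float) -> str:
    """Classify the post-quench amplitude as ``"HIGH"`` or ``"LOW"``.

    Uses the median of the post-SDS windows against the midpoint between the
    model's top (parental) and bottom (synapsed/product) level means.  The
    first post-SDS windows may straddle the quench, so windows within one
    smoothing span of ``t_sds`` are ignored.
    """
    guard = 3.0 * bm_trace.dt
    sel = bm_trace.time_mid >= t_sds + guard
    if not np.any(sel):
        raise ValueError("no usable post-SDS windows in trace")
    med = float(np.median(bm_trace.bm[sel]))
    cut = (model.levels[0].mean + model.levels[-1].mean) / 2.0
    return "LOW" if med <= cut else "HIGH"


# ---------------------------------------------------------------------------
# dwell extraction
# ---------------------------------------------------------------------------

DWELL_COLUMNS = ["molecule_id", "dwell_type", "duration", "outcome", "censored", "t_start"]


@dataclass
class DwellSet:
    """Outcome-labelled dwell-time records for one or more molecules."""

    records: pd.DataFrame  # columns DWELL_COLUMNS
    orientation: str = "direct"
    variant: str = "Flpe"

    def __post_init__(self) -> None:
        # normalize dtypes so boolean masks behave on empty frames too
        self.records = self.records.astype(
            {"duration": float, "censored": bool}, errors="ignore"
        )
        if len(self.records) and (self.records["duration"] <= 0).any():
            raise ValueError("dwell durations must be > 0")

    def durations(self, dwell_type: str, outcome=None, include_censored=False) -> np.ndarray:
        df = self.records[self.records["dwell_type"] == dwell_type]
        if outcome is not None:
            df = df[df["outcome"].isin(outcome if isinstance(outcome, (list, tuple, set)) else [outcome])]
        if not include_censored:
            df = df[~df["censored"]]
        return df["duration"].to_numpy(dtype=float)

    @staticmethod
    def concat(dwellsets) -> "DwellSet":
        sets = list(dwellsets)
        if not sets:
            raise ValueError("cannot concatenate zero dwell sets")
        df = pd.concat([s.records for s in sets], ignore_index=True)
        return DwellSet(df, orientation=sets[0].orientation, variant=sets[0].variant)


def extract_dwells(segmented: SegmentedTrace, protocol: ExperimentProtocol) -> DwellSet:
    """Read outcome-labelled dwell times off an idealized trace.

    Dwell types, measured between recombinase addition and the SDS quench:

    * ``association`` - residence at HIGH before dropping to a bound level;
      the first dwell starts at ``t_flp_add``.  Outcome ``nonproductive`` or
      ``presynaptic`` according to what the following bound episode did, or
      ``unknown`` when that episode was itself cut off by SDS.
    * ``nonproductive`` - BOUND run that returned to HIGH.
    * ``presynaptic`` - BOUND run followed by SYNAPSED; outcome ``type_a``
      when that synapse later dissociated upward, ``type_b`` when it
      persisted to the quench.
    * ``synapsed`` - SYNAPSED run; outcome ``returns_high`` or
      ``persists_to_sds`` (censored).

    Runs truncated by ``t_sds`` are flagged censored and carry the truncated
    duration.
    """
    t0, t1 = protocol.t_flp_add, protocol.t_sds
    meta = segmented.metadata
    runs = [r for r in segmented.runs if r.t_end > t0 and r.t_start < t1]
    rows = []

    def clip(r: Run) -> tuple[float, float, bool]:
        a, b = max(r.t_start, t0), min(r.t_end, t1)
        return a, b, r.t_end > t1

    def synapse_outcome(k: int) -> tuple[str, bool]:
        _, _, cens = clip(runs[k])
        if cens or k == len(runs) - 1:
            return "persists_to_sds", True
        return "returns_high", False

    for k, r in enumerate(runs):
        a, b, cens = clip(r)
        if b <= a:
            continue
        nxt = runs[k + 1] if k < len(runs) - 1 and not cens else None
        if r.label == LEVEL_HIGH:
            if nxt is None:
                continue  # censored at-HIGH residence carries no event
            else:
                # destination resolved by what the bound episode did next
                if nxt.label == LEVEL_SYNAPSED:
                    outcome = "presynaptic"  # direct HIGH->SYNAPSED: synapsis seen
                else:
                    j = k + 2
                    if j >= len(runs) or clip(runs[k + 1])[2]:
                        outcome = "unknown"
                    elif runs[j].label == LEVEL_SYNAPSED:
                        outcome = "presynaptic"
                    else:
                        outcome = "nonproductive"
                rows.append((segmented.molecule_id, "association", b - a, outcome, False, a))
        elif r.label == LEVEL_BOUND:
            if nxt is None:
                rows.append((segmented.molecule_id, "nonproductive", b - a, "unknown", True, a))
            elif nxt.label == LEVEL_SYNAPSED:
                out, _ = synapse_outcome(k + 1)
                label = "type_a" if out == "returns_high" else "type_b"
                rows.append((segmented.molecule_id, "presynaptic", b - a, label, False, a))
            else:
                rows.append((segmented.molecule_id, "nonproductive", b - a, "decayed", False, a))
        elif r.label == LEVEL_SYNAPSED:
            out, cens_out = synapse_outcome(k)
            rows.append((segmented.molecule_id, "synapsed", b - a, out, cens_out, a))

    df = pd.DataFrame(rows, columns=DWELL_COLUMNS)
    return DwellSet(
        df,
        orientation=meta.get("orientation", "direct"),
        variant=meta.get("variant", "Flpe"),
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

COMPLEX_CLASSES = ("unbound", "non_productive", "wayward", "synaptic", "ambiguous")


@dataclass(frozen=True)
class ComplexClass:
    label: str
    evidence: dict

    def __post_init__(self) -> None:
        if self.label not in COMPLEX_CLASSES:
            raise ValueError(f"unknown complex class {self.label!r}")


def classify_molecule(
    segmented: SegmentedTrace,
    dwells: DwellSet,
    orientation: str,
    sds_endpoint: str | None,
) -> ComplexClass:
    """Assign the molecule's complex class from its run pattern + endpoint."""
    if sds_endpoint not in ("HIGH", "LOW"):
        raise ValueError("classification requires an SDS endpoint of HIGH or LOW")
    t1 = segmented.metadata.get("protocol", {}).get("t_sds", segmented.runs[-1].t_end)
    t0 = segmented.metadata.get("protocol", {}).get("t_flp_add", 0.0)
    labels = {
        r.label for r in segmented.runs if r.t_end > t0 and r.t_start < t1
    }
    evidence = {"sds_endpoint": sds_endpoint, "levels_visited": sorted(labels)}
    if labels <= {LEVEL_HIGH}:
        return ComplexClass("unbound", evidence)
    if LEVEL_SYNAPSED not in labels:
        return ComplexClass("non_productive", evidence)
    if sds_endpoint == "LOW":
        return ComplexClass("synaptic", evidence)
    if orientation == "inverted":
        return ComplexClass("ambiguous", evidence)
    return ComplexClass("wayward", evidence)
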