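"""Synthetic TPM experiment generator.

Produces stochastic state paths from a :class:`~flptpm.scheme.KineticScheme`,
renders them into per-frame bead positions with a Gaussian emission model, and
can inject the two artifact classes (stuck beads, anisotropic distortion) that
the quality-control filters are designed to catch.

Emission model
--------------
Each mechanistic state maps to a mean Brownian-motion (BM) amplitude mu (nm)
taken from measured per-substrate amplitude histograms.  Bead positions are
drawn per frame, per axis, as zero-mean Gaussians with sigma = mu_eff/sqrt(2),
so that the windowed BM statistic sqrt(s_x^2 + s_y^2) (Bessel-corrected
per-axis variances) has expectation ~mu_eff.  mu_eff = mu + z * sigma_b adds a
single per-molecule offset: z ~ N(0,1) drawn once per molecule, scaled by the
state's between-molecule spread sigma_b.  The tabulated spreads are the widths
of pooled BM histograms, which already contain the 40-frame estimator sampling
noise ~ mu/sqrt(160); sigma_b is therefore obtained by variance subtraction,
floored at zero, so that pooled simulated histograms reproduce the tabulated
widths without double counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scheme import ExperimentProtocol, KineticScheme, MoleculeState

__all__ = [
    "LevelEmission",
    "EmissionTable",
    "default_emission_table",
    "amplitude_for_length",
    "Segment",
    "StatePath",
    "RawTrace",
    "ArtifactSpec",
    "simulate_state_path",
    "emit_trace",
    "inject_artifacts",
    "simulate_cohort",
]

# Two-anchor tether-length calibration (bp -> nm): full-length substrate and
# the short linear excision-product mimic.
_LENGTH_ANCHORS = ((549.0, 45.1), (1168.0, 83.4))


def amplitude_for_length(bp: float) -> float:
    """Linear interpolation of BM amplitude (nm) from tether length (bp)."""
    (b0, a0), (b1, a1) = _LENGTH_ANCHORS
    return a0 + (a1 - a0) * (bp - b0) / (b1 - b0)


def nm_per_bp() -> float:
    """Slope of the two-anchor length calibration (nm of BM amplitude per bp)."""
    (b0, a0), (b1, a1) = _LENGTH_ANCHORS
    return (a1 - a0) / (b1 - b0)


@dataclass(frozen=True)
class LevelEmission:
    """One emission level: mean BM amplitude and total histogram spread (nm)."""

    mean: float
    spread: float

    def between_sd(self, window_frames: int = 40) -> float:
        """Between-molecule spread after removing estimator sampling noise."""
        est_var = self.mean**2 / (4.0 * window_frames)  # var of windowed BM
        return math.sqrt(max(self.spread**2 - est_var, 0.0))


@dataclass(frozen=True)
class EmissionTable:
    """Per-state emission levels for one substrate configuration."""

    orientation: str
    levels: dict  # MoleculeState -> LevelEmission
    # Emission of the resolved (post-recombination) Holliday sub-state before
    # SDS: for inverted sites the product synapse has dissociated and the
    # full-length inversion product moves at the parental amplitude.
    resolved_level: LevelEmission | None = None
    window_frames: int = 40

    def __post_init__(self) -> None:
        free = self.levels.get(MoleculeState.FREE)
        bound = self.levels.get(MoleculeState.NONPRODUCTIVE)
        syn = self.levels.get(MoleculeState.SYNAPSED_ACTIVE)
        if free is not None and bound is not None and not free.mean > bound.mean:
            raise ValueError("FREE level must exceed the bound level")
        if bound is not None and syn is not None and not bound.mean > syn.mean:
            raise ValueError("bound level must exceed the synapsed level")
        for lv in self.levels.values():
            if lv.mean < 0 or lv.spread < 0:
                raise ValueError("emission means and spreads must be >= 0")

    def level_for(self, state: MoleculeState, sub: str | None = None) -> LevelEmission:
        if (
            state is MoleculeState.HOLLIDAY_OR_PRODUCT
            and sub == "resolved"
            and self.resolved_level is not None
        ):
            return self.resolved_level
        return self.levels[state]


_F = MoleculeState.FREE
_NP = MoleculeState.NONPRODUCTIVE
_PS = MoleculeState.PRESYNAPTIC
_SW = MoleculeState.SYNAPSED_WAYWARD
_SA = MoleculeState.SYNAPSED_ACTIVE
_HJ = MoleculeState.HOLLIDAY_OR_PRODUCT
_PH = MoleculeState.POST_SDS_HIGH
_PL = MoleculeState.POST_SDS_LOW


def _table(free, bound, syn, post_low, resolved=None) -> dict:
    lv = {_F: free, _PH: free}
    if bound is not None:
        lv[_NP] = bound
        lv[_PS] = bound
    if syn is not None:
        lv[_SW] = syn
        lv[_SA] = syn
        lv[_HJ] = syn
    if post_low is not None:
        lv[_PL] = post_low
    return lv


_EMISSION_DEFAULTS: dict[tuple[str, str], EmissionTable] = {
    ("Flpe", "none"): EmissionTable(
        "none", _table(LevelEmission(83.4, 7.1), None, None, None)
    ),
    ("Flpe", "single"): EmissionTable(
        "single",
        _table(LevelEmission(79.8, 7.9), LevelEmission(64.8, 4.1), None, None),
    ),
    ("Flpe", "direct"): EmissionTable(
        "direct",
        _table(
            LevelEmission(82.3, 7.4),
            LevelEmission(59.2, 4.8),
            LevelEmission(42.0, 6.1),
            LevelEmission(45.1, 5.7),
        ),
    ),
    ("Flpe", "inverted"): EmissionTable(
        "inverted",
        _table(
            LevelEmission(82.1, 8.3),
            LevelEmission(59.2, 4.8),
            LevelEmission(48.3, 6.7),
            LevelEmission(48.3, 6.7),
        ),
        resolved_level=LevelEmission(82.1, 8.3),
    ),
    ("Y343F", "direct"): EmissionTable(
        "direct",
        _table(
            LevelEmission(78.9, 7.9),
            LevelEmission(66.7, 3.6),
            LevelEmission(51.0, 19.5),
            None,
        ),
    ),
}
_EMISSION_DEFAULTS[("Y343F", "none")] = _EMISSION_DEFAULTS[("Flpe", "none")]
_EMISSION_DEFAULTS[("Y343F", "single")] = EmissionTable(
    "single", _table(LevelEmission(78.9, 7.9), LevelEmission(66.7, 3.6), None, None)
)


def default_emission_table(variant: str, orientation: str) -> EmissionTable:
    """Measured per-substrate emission levels for a variant/orientation pair."""
    try:
        return _EMISSION_DEFAULTS[(variant, orientation)]
    except KeyError:
        raise ValueError(
            f"no default emission table for variant={variant!r}, "
            f"orientation={orientation!r}"
        ) from None


# ---------------------------------------------------------------------------
# state-path simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    state: MoleculeState
    t_start: float
    t_end: float
    sub: str | None = None  # HOLLIDAY_OR_PRODUCT sub-flag: "HJ" | "resolved"


@dataclass
class StatePath:
    """Ground-truth trajectory of one molecule through the reaction scheme."""

    molecule_id: str
    segments: list  # list[Segment], contiguous, covering [0, total_duration]
    scheme: KineticScheme
    protocol: ExperimentProtocol

    def state_at(self, t: float) -> Segment:
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                return seg
        return self.segments[-1]

    def visited(self, *states: MoleculeState) -> bool:
        return any(seg.state in states for seg in self.segments)

    @property
    def post_sds_state(self) -> MoleculeState:
        return self.segments[-1].state

    def true_class(self) -> str:
        """Molecule class per the complex taxonomy (ground truth)."""
        if not self.visited(_NP, _PS, _SW, _SA, _HJ):
            return "unbound"
        if not self.visited(_SW, _SA, _HJ):
            return "non_productive"
        if self.visited(_HJ):
            return "synaptic"
        return "wayward"


def _exp(rng: np.random.Generator, rate: float) -> float:
    return rng.exponential(1.0 / rate) if rate > 0 else math.inf


def simulate_state_path(
    scheme: KineticScheme,
    protocol: ExperimentProtocol,
    rng: np.random.Generator,
    molecule_id: str = "mol",
) -> StatePath:
    """Gillespie simulation of one molecule from t=0 through the SDS quench.

    The molecule is FREE until recombinase addition.  Association out of FREE
    is a competing-risks race between the two pseudo-first-order channels;
    pre-synaptic episodes follow the outcome-labelled mixture rule (outcome
    drawn with probability ``p_type_b``, dwell exponential at that outcome's
    rate).  The path is truncated at ``t_sds`` and mapped to a post-SDS state:
    for direct sites any covalent progress (``HOLLIDAY_OR_PRODUCT``) retains
    the low amplitude; for inverted sites only the un-resolved Holliday
    junction does, the resolved inversion product being restored to full
    length.
    """
    c = protocol.flp_concentration
    t_sds = protocol.t_sds
    segs: list[Segment] = []

    t = protocol.t_flp_add
    segs.append(Segment(_F, 0.0, min(t, t_sds)))
    state, sub = _F, None

    while t < t_sds:
        if state is _F:
            r_np = scheme.k_f_np * c
            r_ps = scheme.k_f_ps * c
            total = r_np + r_ps
            dwell = _exp(rng, total)
            if math.isfinite(dwell):
                nxt = _NP if rng.random() * total < r_np else _PS
            else:
                nxt = None
        elif state is _NP:
            dwell, nxt = _exp(rng, scheme.k_d_np), _F
        elif state is _PS:
            if rng.random() < scheme.p_type_b:
                dwell, nxt = _exp(rng, scheme.k_f_synaptic), _SA
            else:
                dwell, nxt = _exp(rng, scheme.k_f_wayward), _SW
        elif state is _SW:
            dwell, nxt = _exp(rng, scheme.k_d_wayward), _PS
        elif state is _SA:
            dwell, nxt = _exp(rng, scheme.k_first_chem), _HJ
        elif state is _HJ and sub == "HJ":
            dwell, nxt = _exp(rng, scheme.k_hj_resolve), _HJ
        else:  # HOLLIDAY_OR_PRODUCT, resolved: absorbing until SDS
            dwell, nxt = math.inf, None

        t_end = min(t + dwell, t_sds)
        if t_end > t:
            segs.append(Segment(state, t, t_end, sub))
        if t + dwell >= t_sds or nxt is None:
            break
        t = t + dwell
        if nxt is _HJ:
            sub = "resolved" if state is _HJ else "HJ"
        else:
            sub = None
        state = nxt

    # coalesce contiguous segments in the same (state, sub)
    merged: list[Segment] = []
    for seg in segs:
        if merged and merged[-1].state is seg.state and merged[-1].sub == seg.sub:
            merged[-1] = Segment(seg.state, merged[-1].t_start, seg.t_end, seg.sub)
        else:
            merged.append(seg)
    segs = merged

    # SDS mapping
    last = segs[-1]
    if last.state is _HJ:
        if scheme.orientation == "inverted":
            post = _PL if last.sub == "HJ" else _PH
        else:
            post = _PL
    else:
        post = _PH
    if protocol.t_post_sds > 0:
        segs.append(Segment(post, t_sds, t_sds + protocol.t_post_sds))
    return StatePath(molecule_id, segs, scheme, protocol)


# ---------------------------------------------------------------------------
# trace emission
# ---------------------------------------------------------------------------

TRACE_FORMAT_VERSION = "1.0"


@dataclass
class RawTrace:
    """Per-frame bead positions for one molecule, with protocol metadata."""

    frames: np.ndarray  # int frame index
    times: np.ndarray  # s, strictly increasing at 1/frame_rate
    x: np.ndarray  # nm
    y: np.ndarray  # nm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.frames)
        if not (len(self.times) == len(self.x) == len(self.y) == n):
            raise ValueError("frame, time, x and y arrays must have equal length")
        if n and not np.all(np.isfinite(self.x) & np.isfinite(self.y)):
            raise ValueError("bead coordinates must be finite")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def molecule_id(self) -> str:
        return self.metadata.get("molecule_id", "mol")

    def copy(self) -> "RawTrace":
        import copy as _copy

        return RawTrace(
            self.frames.copy(),
            self.times.copy(),
            self.x.copy(),
            self.y.copy(),
            _copy.deepcopy(self.metadata),
        )


_MIN_MU = 0.0  # effective amplitudes are floored at zero


def emit_trace(
    path: StatePath,
    emission: EmissionTable,
    protocol: ExperimentProtocol | None = None,
    rng: np.random.Generator | None = None,
    between_molecule: bool = True,
) -> RawTrace:
    """Render a state path into per-frame bead positions.

    One standard-normal deviate is drawn per molecule and scaled by each
    state's between-molecule spread, so a molecule keeps a consistent
    amplitude bias across its states.  State changes take effect at the frame
    boundary at or below the transition time.
    """
    if rng is None:
        raise ValueError("emit_trace requires a seeded numpy Generator")
    protocol = protocol or path.protocol
    fr = protocol.frame_rate
    n_frames = int(round(protocol.total_duration * fr))
    times = np.arange(n_frames) / fr

    z = rng.standard_normal() if between_molecule else 0.0

    # per-frame effective amplitude
    mu = np.empty(n_frames)
    for seg in path.segments:
        i0 = int(np.ceil(seg.t_start * fr - 1e-9))
        i1 = n_frames if seg.t_end >= times[-1] else int(np.ceil(seg.t_end * fr - 1e-9))
        if i1 <= i0:
            continue
        lv = emission.level_for(seg.state, seg.sub)
        mu[i0:i1] = max(lv.mean + z * lv.between_sd(emission.window_frames), _MIN_MU)

    sigma = mu / math.sqrt(2.0)
    x = rng.standard_normal(n_frames) * sigma
    y = rng.standard_normal(n_frames) * sigma

    meta = {
        "format_version": TRACE_FORMAT_VERSION,
        "molecule_id": path.molecule_id,
        "variant": path.scheme.variant,
        "orientation": path.scheme.orientation,
        "protocol": protocol.to_dict(),
        "truth": {
            "segments": [
                [seg.state.value, seg.t_start, seg.t_end, seg.sub]
                for seg in path.segments
            ],
            "class": path.true_class(),
            "post_sds_state": path.post_sds_state.value,
            "between_molecule_z": float(z),
        },
        "artifacts": [],
    }
    return RawTrace(np.arange(n_frames), times, x, y, meta)


@dataclass(frozen=True)
class ArtifactSpec:
    """Intervals of injected trace pathology.

    ``stuck``: list of (t_start, t_end) where the bead adheres to the surface
    (amplitude collapsed to ``stuck_amplitude`` nm, well under the 26 nm
    exclusion threshold).  ``distorted``: list of (t_start, t_end) where the x
    axis is scaled by ``distortion_ratio``, pushing sd_x/sd_y out of the
    accepted 0.8-1.2 band.
    """

    stuck: tuple = ()
    distorted: tuple = ()
    stuck_amplitude: float = 10.0
    distortion_ratio: float = 1.5

    def all_intervals(self):
        return [(t0, t1, "stuck") for (t0, t1) in self.stuck] + [
            (t0, t1, "distorted") for (t0, t1) in self.distorted
        ]


def inject_artifacts(
    trace: RawTrace, spec: ArtifactSpec, rng: np.random.Generator
) -> RawTrace:
    """Return a copy of ``trace`` with the artifacts of ``spec`` applied.

    Ground-truth annotations are appended to ``metadata["artifacts"]``.
    Overlapping intervals are rejected.
    """
    ivs = sorted(spec.all_intervals())
    for (a0, a1, _), (b0, b1, _) in zip(ivs, ivs[1:]):
        if b0 < a1:
            raise ValueError(f"artifact intervals overlap: [{a0},{a1}) and [{b0},{b1})")
    if not ivs:
        return trace.copy()

    out = trace.copy()
    sigma_stuck = spec.stuck_amplitude / math.sqrt(2.0)
    for t0, t1, kind in ivs:
        m = (out.times >= t0) & (out.times < t1)
        if kind == "stuck":
            out.x[m] = rng.standard_normal(m.sum()) * sigma_stuck
            out.y[m] = rng.standard_normal(m.sum()) * sigma_stuck
        else:
            out.x[m] *= spec.distortion_ratio
        out.metadata["artifacts"].append([kind, float(t0), float(t1)])
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


def simulate_cohort(
    scheme: KineticScheme,
    protocol: ExperimentProtocol,
    n_molecules: int,
    seed: int,
    emission: EmissionTable | None = None,
    artifact_fraction: float = 0.0,
    artifact_spec_factory=None,
):
    """Simulate ``n_molecules`` complete traces plus a hidden truth table.

    Deterministic given ``seed``: one root ``SeedSequence`` is spawned into
    independent per-molecule substreams.  Returns ``(traces, paths, truth)``
    where ``truth`` is a list of per-molecule dicts (id, class, post-SDS
    state, artifact annotations).

    ``artifact_fraction`` of the molecules (taken from the front of the
    cohort) receive artifacts built by ``artifact_spec_factory(i, protocol)``
    (default: one stuck and one distorted interval during the baseline-free
    part of the reaction window).
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    emission = emission or default_emission_table(scheme.variant, scheme.orientation)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_molecules)
    n_artifact = int(round(artifact_fraction * n_molecules))

    if artifact_spec_factory is None:

        def artifact_spec_factory(i, proto):
            t0 = proto.t_flp_add + 100.0 + (i % 7) * 30.0
            kind_stuck = i % 2 == 0
            if kind_stuck:
                return ArtifactSpec(stuck=((t0, t0 + 20.0),))
            return ArtifactSpec(distorted=((t0, t0 + 60.0),))

    traces, paths, truth = [], [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        path = simulate_state_path(scheme, protocol, rng, molecule_id=f"mol{i:04d}")
        trace = emit_trace(path, emission, protocol, rng)
        if i < n_artifact:
            trace = inject_artifacts(trace, artifact_spec_factory(i, protocol), rng)
        traces.append(trace)
        paths.append(path)
        truth.append(
            {
                "molecule_id": path.molecule_id,
                "class": path.true_class(),
                "post_sds_state": path.post_sds_state.value,
                "artifacts": list(trace.metadata["artifacts"]),
            }
        )
    return traces, paths, truth
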