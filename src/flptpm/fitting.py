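"""Histogram fits: Gaussian amplitude peaks and exponential dwell decays.

All fits are unweighted least squares on histogram counts, the procedure used
throughout single-molecule TPM work (an optional Poisson weighting and an
additive-baseline term are available as flags).  A maximum-likelihood oracle
for exponential data (k = 1/mean) is exposed for cross-checks.

Dwell-time decays are fitted to

    y(t) = A1 * exp(-k1 * t)                       (single)
    y(t) = A1 * exp(-k1 * t) + A2 * exp(-k2 * t)   (bi, k1 > k2)

and the bi-exponential additionally reports component *fractions* (the share
of dwells in each component, amplitude/rate normalized) so that the fast
fraction is directly comparable to mixture weights.  Model selection between
the two implements the irreversibility test: the bi-exponential is accepted
only when it clearly improves the fit (delta R^2), separates the rates, and
assigns both components non-trivial weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Histogram",
    "GaussianFit",
    "DecayFit",
    "ModelChoice",
    "ModelSelectionThresholds",
    "build_dwell_histogram",
    "fit_gaussian",
    "fit_single_exponential",
    "fit_biexponential",
    "select_decay_model",
    "exponential_rate_mle",
    "compile_kinetic_table",
]


@dataclass
class Histogram:
    edges: np.ndarray  # strictly increasing, right-open bins
    counts: np.ndarray
    normalization: str = "counts"  # "counts" | "density"

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.counts) + 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def n_nonempty(self) -> int:
        return int(np.count_nonzero(self.counts))

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def build_dwell_histogram(dwells, bin_width: float | None = None) -> Histogram:
    """Right-open dwell-time histogram from 0 to the longest dwell.

    Default bin width is ``max(2 s, range/25)``.  For strongly bimodal dwell
    mixtures pass an explicit (smaller) width so the fast component spans
    several bins.
    """
    d = np.asarray(dwells, dtype=float)
    if d.size == 0:
        raise ValueError("cannot histogram an empty dwell set")
    if np.any(d < 0):
        raise ValueError("dwell times must be >= 0")
    rng = float(d.max())
    if bin_width is None:
        bin_width = max(2.0, rng / 25.0)
    n_bins = max(1, int(math.ceil(rng / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    return Histogram(edges=edges, counts=counts.astype(float))


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _r_squared_weighted(y: np.ndarray, yhat: np.ndarray) -> float:
    """R^2 with inverse-variance (Poisson) weights.

    Unweighted R^2 of a count histogram is dominated by the densely populated
    early bins and saturates near one for any single decaying component; the
    Poisson-weighted version gives the sparse tail its statistical due and is
    the discriminating statistic used for model choice.
    """
    w = 1.0 / np.maximum(y, 1.0)
    ybar = float(np.sum(w * y) / np.sum(w))
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


# ---------------------------------------------------------------------------
# Gaussian amplitude fits
# ---------------------------------------------------------------------------


@dataclass
class GaussianComponent:
    mean: float
    sd: float
    weight: float  # fraction of total area
    amplitude: float  # raw peak height in count units


@dataclass
class GaussianFit:
    n_components: int
    components: list  # list[GaussianComponent], descending mean
    r_squared: float
    histogram: Histogram

    @property
    def means(self) -> list:
        return [c.mean for c in self.components]


def _gauss(x, a, m, s):
    return a * np.exp(-((x - m) ** 2) / (2.0 * s**2))


def fit_gaussian(amplitudes, n_components: int = 1, bin_width: float | None = None) -> GaussianFit:
    """Least-squares 1- or 2-Gaussian fit to an amplitude histogram.

    Two-component fits are initialized from the two largest well-separated
    histogram modes.  Components are reported in descending mean; weights sum
    to one.  Degenerate (all-equal) input is rejected.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 30:
        raise ValueError(f"need >= 30 amplitude samples, got {a.size}")
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if np.ptp(a) == 0:
        raise ValueError("amplitude sample is degenerate (all values equal)")

    if bin_width is None:
        edges = np.histogram_bin_edges(a, bins="fd")
    else:
        edges = np.arange(a.min(), a.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(a, bins=edges)
    hist = Histogram(edges=edges, counts=counts.astype(float))
    x, y = hist.centers, hist.counts

    if n_components == 1:
        p0 = [y.max(), float(a.mean()), float(a.std(ddof=1))]
        popt, _ = curve_fit(
            _gauss, x, y, p0=p0, bounds=([0, -np.inf, 1e-9], [np.inf, np.inf, np.inf]), maxfev=20000
        )
        yhat = _gauss(x, *popt)
        comps = [GaussianComponent(popt[1], popt[2], 1.0, popt[0])]
    else:
        # initialize from the two highest smoothed-histogram modes
        ys = np.convolve(y, np.ones(3) / 3.0, mode="same")
        order = np.argsort(ys)[::-1]
        m1 = x[order[0]]
        min_sep = max(np.ptp(x) / 6.0, 2 * hist.bin_width)
        m2 = next((x[i] for i in order[1:] if abs(x[i] - m1) >= min_sep), x[order[1]])
        s0 = max(float(a.std(ddof=1)) / 2.0, hist.bin_width)

        def model(t, a1, mu1, s1, a2, mu2, s2):
            return _gauss(t, a1, mu1, s1) + _gauss(t, a2, mu2, s2)

        p0 = [ys[order[0]], m1, s0, ys[order[0]] / 2.0, m2, s0]
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=p0,
            bounds=([0, -np.inf, 1e-9, 0, -np.inf, 1e-9], [np.inf] * 6),
            maxfev=40000,
        )
        yhat = model(x, *popt)
        areas = [popt[0] * popt[2], popt[3] * popt[5]]
        tot = sum(areas)
        comps = [
            GaussianComponent(popt[1], popt[2], areas[0] / tot, popt[0]),
            GaussianComponent(popt[4], popt[5], areas[1] / tot, popt[3]),
        ]
        comps.sort(key=lambda c: -c.mean)

    return GaussianFit(n_components, comps, _r_squared(y, yhat), hist)


# ---------------------------------------------------------------------------
# exponential decay fits
# ---------------------------------------------------------------------------


@dataclass
class DecayFit:
    model: str  # "single" | "bi"
    a1: float  # raw amplitude of the fast (or only) component
    k1: float  # s^-1; for "bi", k1 > k2
    a2: float | None = None
    k2: float | None = None
    se_k1: float | None = None
    se_k2: float | None = None
    fraction_fast: float | None = None  # share of dwells in the k1 component
    r_squared: float = float("nan")
    r_squared_weighted: float = float("nan")
    n_dwells: int = 0
    converged: bool = True
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.model == "bi" and self.k2 is not None and not self.k1 > self.k2:
            raise ValueError("bi-exponential components must be ordered k1 > k2")


def exponential_rate_mle(dwells) -> tuple[float, float]:
    """Censoring-free maximum-likelihood rate and its standard error."""
    d = np.asarray(dwells, dtype=float)
    if d.size == 0 or d.mean() <= 0:
        raise ValueError("need positive dwell times")
    k = 1.0 / float(d.mean())
    return k, k / math.sqrt(d.size)


def _single(t, a, k):
    return a * np.exp(-k * t)


def _double(t, a1, k1, a2, k2):
    return a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _hist_mean(hist: Histogram) -> float:
    if hist.total == 0:
        raise ValueError("histogram is empty")
    return float(np.sum(hist.centers * hist.counts) / hist.total)


def fit_single_exponential(hist: Histogram, weighted: bool = False) -> DecayFit:
    """Nonlinear least squares of ``A1 exp(-k1 t)`` to histogram counts."""
    if hist.n_nonempty < 5:
        raise ValueError(f"need >= 5 nonempty bins, got {hist.n_nonempty}")
    x, y = hist.centers, hist.counts
    k0 = 1.0 / max(_hist_mean(hist), 1e-12)
    a0 = float(y[np.nonzero(y)[0][0]]) * math.exp(k0 * float(x[np.nonzero(y)[0][0]]))
    sigma = np.sqrt(np.maximum(y, 1.0)) if weighted else None
    try:
        popt, pcov = curve_fit(
            _single, x, y, p0=[a0, k0], sigma=sigma,
            bounds=([0, 1e-15], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError:
        return DecayFit("single", a0, k0, r_squared=float("nan"),
                        n_dwells=int(hist.total), converged=False, flags=["no_convergence"])
    se = np.sqrt(np.diag(pcov))
    yhat = _single(x, *popt)
    return DecayFit(
        "single", float(popt[0]), float(popt[1]), se_k1=float(se[1]),
        fraction_fast=1.0, r_squared=_r_squared(y, yhat),
        r_squared_weighted=_r_squared_weighted(y, yhat),
        n_dwells=int(hist.total),
    )


def _poisson_refine(x: np.ndarray, y: np.ndarray, popt):
    """Polish a two-exponential histogram fit by binned Poisson likelihood.

    Unweighted least squares is nearly blind to the sparse tail bins that
    carry all the information about the slow component; maximizing the
    Poisson likelihood of the bin counts weights them correctly (slow-rate
    scatter drops about six-fold on mixture data).
    """
    from scipy.optimize import minimize

    p0 = np.log(np.maximum(popt, 1e-300))

    def nll(logp):
        lam = np.maximum(_double(x, *np.exp(logp)), 1e-12)
        return float(np.sum(lam - y * np.log(lam)))

    res = minimize(
        nll, p0, method="Nelder-Mead",
        options=dict(maxiter=5000, xatol=1e-9, fatol=1e-11),
    )
    out = np.exp(res.x)
    return out if np.all(np.isfinite(out)) else popt


def fit_biexponential(
    hist: Histogram, weighted: bool = False, poisson_refine: bool = True
) -> DecayFit:
    """Two-exponential fit ``A1 exp(-k1 t) + A2 exp(-k2 t)`` of a histogram.

    Multi-start least squares (starting rate pairs bracket the
    single-exponential estimate by factors {5, 1/5}; the best
    sum-of-squares start wins) followed by a binned Poisson-likelihood
    polish (see :func:`_poisson_refine`; disable with
    ``poisson_refine=False``).  Components are ordered ``k1 > k2`` and the
    fraction of dwells in the fast component
    (``(A1/k1) / (A1/k1 + A2/k2)``) is reported alongside the raw
    amplitudes.  Rate-degenerate or boundary-stuck solutions are flagged.
    """
    if hist.n_nonempty < 8:
        raise ValueError(f"need >= 8 nonempty bins, got {hist.n_nonempty}")
    x, y = hist.centers, hist.counts
    single = fit_single_exponential(hist, weighted=weighted)
    k0 = single.k1 if single.converged else 1.0 / max(_hist_mean(hist), 1e-12)
    a0 = single.a1
    sigma = np.sqrt(np.maximum(y, 1.0)) if weighted else None

    starts = [
        (a0 * 0.7, 5.0 * k0, a0 * 0.3, k0 / 5.0),
        (a0 * 0.9, 5.0 * k0, a0 * 0.1, k0 / 5.0),
        (a0 * 0.5, 2.0 * k0, a0 * 0.5, k0 / 2.0),
        (a0 * 0.9, k0, a0 * 0.1, k0 / 10.0),
    ]
    best = None
    for p0 in starts:
        try:
            popt, pcov = curve_fit(
                _double, x, y, p0=list(p0), sigma=sigma,
                bounds=([0, 1e-15, 0, 1e-15], [np.inf] * 4), maxfev=40000,
            )
        except RuntimeError:
            continue
        ssr = float(np.sum((y - _double(x, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        return DecayFit("bi", a0, 2 * k0, a2=0.0, k2=k0 / 2.0, n_dwells=int(hist.total),
                        converged=False, flags=["no_convergence"])

    _, popt, pcov = best
    if poisson_refine:
        popt = _poisson_refine(x, y, np.asarray(popt, dtype=float))
    a1, k1, a2, k2 = (float(v) for v in popt)
    se = np.sqrt(np.abs(np.diag(pcov)))
    se1, se2 = float(se[1]), float(se[3])
    if k1 < k2:
        a1, k1, a2, k2 = a2, k2, a1, k1
        se1, se2 = se2, se1
    flags = []
    if k2 > 0 and k1 / k2 < 1.2:
        flags.append("rate_degenerate")
    n1, n2 = a1 / k1, a2 / k2
    frac = n1 / (n1 + n2) if (n1 + n2) > 0 else float("nan")
    if min(a1, a2) <= 1e-12 or not np.isfinite(frac):
        flags.append("boundary_stuck")
    if k1 <= k2:
        k1 = k2 * (1 + 1e-9)
    yhat = _double(x, a1, k1, a2, k2)
    return DecayFit(
        "bi", a1, k1, a2=a2, k2=k2, se_k1=se1, se_k2=se2,
        fraction_fast=frac, r_squared=_r_squared(y, yhat),
        r_squared_weighted=_r_squared_weighted(y, yhat),
        n_dwells=int(hist.total), flags=flags,
    )


@dataclass(frozen=True)
class ModelSelectionThresholds:
    min_delta_r2: float = 0.03
    min_rate_ratio: float = 3.0
    min_fraction: float = 0.05


@dataclass
class ModelChoice:
    chosen: str  # "single" | "bi"
    delta_r2: float
    rate_ratio: float
    min_fraction: float
    thresholds: ModelSelectionThresholds


def select_decay_model(
    single_fit: DecayFit,
    bi_fit: DecayFit,
    thresholds: ModelSelectionThresholds = ModelSelectionThresholds(),
) -> ModelChoice:
    """Choose between the exponential models (parsimony default: single).

    The bi-exponential wins only if it improves the Poisson-weighted R^2 by
    at least ``min_delta_r2``, separates the rates by ``min_rate_ratio``,
    carries at least ``min_fraction`` of the dwells in each component, and is
    unflagged.
    """
    delta = bi_fit.r_squared_weighted - single_fit.r_squared_weighted
    ratio = bi_fit.k1 / bi_fit.k2 if bi_fit.k2 else float("inf")
    frac = bi_fit.fraction_fast
    mn = min(frac, 1.0 - frac) if frac is not None and np.isfinite(frac) else 0.0
    ok = (
        bi_fit.converged
        and not bi_fit.flags
        and delta >= thresholds.min_delta_r2
        and ratio >= thresholds.min_rate_ratio
        and mn >= thresholds.min_fraction
    )
    return ModelChoice("bi" if ok else "single", float(delta), float(ratio), float(mn), thresholds)


# ---------------------------------------------------------------------------
# kinetic table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Settings for dwell-histogram rate estimation.

    ``dead_time_s`` is the trim point of the truncated-MLE rate estimates:
    dwells below it are depleted by the detection floor, while the
    exponential tail above it is shift-invariant in the rate.
    ``detection_dead_time_s`` is the shortest reliably detected state visit
    (the three-point persistence floor of 40-frame windows, ~3.5 windows):
    state visits below it go unseen and merge their neighbouring dwells into
    sums.  With ``missed_event_correction`` the table applies first-order
    corrections for these merges (undercounted non-productive associations,
    and mean inflation of the free, non-productive and pre-synaptic dwell
    pools by invisibly short intervening visits).
    """

    bin_width: float | None = None
    dead_time_s: float = 8.0
    detection_dead_time_s: float = 4.7
    weighted: bool = False
    min_dwells: int = 10
    missed_event_correction: bool = True


def _trim_dead_time(hist: Histogram, dead_time: float) -> Histogram:
    keep = hist.centers >= dead_time
    if keep.all() or (~keep).all():
        return hist
    first = int(np.argmax(keep))
    return Histogram(edges=hist.edges[first:], counts=hist.counts[first:])


@dataclass
class _RateEstimate:
    k1: float
    se_k1: float


def _rate_from_dwells(dwells: np.ndarray, cfg: FitConfig):
    """Rate of a dwell pool by the truncated-exponential MLE.

    Dwells above the trim point ``dead_time_s`` follow the (shifted)
    exponential tail unaffected by the detection floor, so
    k = 1/(mean(d | d > T) - T) with SE ~ k/sqrt(n_tail) -- the
    maximum-likelihood analogue of fitting only the histogram tail, and
    considerably more efficient at per-transition cohort pool sizes.
    """
    if len(dwells) < cfg.min_dwells:
        return None
    tail = dwells[dwells > cfg.dead_time_s]
    if len(tail) < cfg.min_dwells:
        return None
    excess = float(tail.mean()) - cfg.dead_time_s
    if excess <= 0:
        return None
    k = 1.0 / excess
    return _RateEstimate(k, k / math.sqrt(len(tail)))


def compile_kinetic_table(
    dwells,
    flp_concentration: float,
    fit_config: FitConfig = FitConfig(),
):
    """Estimate the per-step rate constants from a cohort's dwell records.

    Returns a ``pandas.DataFrame`` indexed by complex type with columns
    ``kf``, ``kf_se``, ``kf_units``, ``kd``, ``kd_se``, ``n_f``, ``n_d``
    (``None``/0 where a cohort provides no events), mirroring the layout of a
    per-complex kinetic summary:

    * association dwells give a pooled pseudo-first-order exit rate, split
      between the non-productive and pre-synaptic channels by the observed
      destination fractions (the correct decomposition under competing
      risks), then divided by [Flp] into M^-1 s^-1;
    * non-productive decays and (direct-site) type-a/type-b pre-synaptic
      dwells give first-order rates directly;
    * synapsed dwells that return upward give the wayward dissociation rate
      for direct sites, and for inverted sites are fitted bi-exponentially,
      the fast component reported as the wayward decay and the slow one as
      the recombination rate ``k_r``.
    """
    import pandas as pd

    cfg = fit_config
    c = flp_concentration
    rows = {
        t: dict(kf=None, kf_se=None, kf_units=None, kd=None, kd_se=None, n_f=0, n_d=0)
        for t in ("non_productive", "wayward", "pre_synaptic", "synaptic")
    }

    tau = cfg.detection_dead_time_s if cfg.missed_event_correction else 0.0

    def p_short(k: float) -> float:
        return -math.expm1(-k * tau) if tau > 0 and k > 0 else 0.0

    def mean_short(k: float) -> float:
        # E[X | X < tau] for X ~ Exp(k)
        p = p_short(k)
        return 1.0 / k - tau * math.exp(-k * tau) / p if p > 0 else 0.0

    # raw tail-MLE estimates
    np_d = dwells.durations("nonproductive", outcome="decayed")
    np_fit = _rate_from_dwells(np_d, cfg)
    assoc_known = dwells.records[
        (dwells.records["dwell_type"] == "association")
        & (~dwells.records["censored"])
        & (dwells.records["outcome"].isin(["nonproductive", "presynaptic"]))
    ]
    assoc_fit = _rate_from_dwells(assoc_known["duration"].to_numpy(float), cfg)
    n_np = int((assoc_known["outcome"] == "nonproductive").sum())
    n_ps = int((assoc_known["outcome"] == "presynaptic").sum())

    # First-order missed-event corrections, solved as a short fixed point:
    # a free dwell is invisibly extended when the next non-productive visit
    # is shorter than the detection floor (probability f_np * p_short(kd_np),
    # adding a full extra free dwell plus the short visit), and symmetrically
    # for non-productive dwells split by invisibly brief free excursions;
    # undetected short visits also remove their association events from the
    # non-productive destination count.
    k_np = np_fit.k1 if np_fit else None
    k_tot = assoc_fit.k1 if assoc_fit else None
    f_np = n_np / (n_np + n_ps) if (n_np + n_ps) > 0 else None
    if k_np and k_tot and f_np is not None and tau > 0:
        k_np_c, k_tot_c, f_c = k_np, k_tot, f_np
        for _ in range(4):
            # visible non-productive visits: not below the floor themselves,
            # nor glued onto the previous visit by an invisibly short free gap
            detect = math.exp(-k_np_c * tau) * (1.0 - f_c * p_short(k_tot_c))
            n_np_eff = n_np / max(detect, 1e-6)
            f_c = n_np_eff / (n_np_eff + n_ps)
            m = f_c * p_short(k_np_c)
            inv = (1.0 / k_tot - m * mean_short(k_np_c)) / (1.0 + m)
            k_tot_c = 1.0 / max(inv, 1e-12)
            m = f_c * p_short(k_tot_c)
            inv = (1.0 / k_np - m * mean_short(k_tot_c)) / (1.0 + m)
            k_np_c = 1.0 / max(inv, 1e-12)
    else:
        k_np_c, k_tot_c, f_c = k_np, k_tot, f_np

    if np_fit is not None:
        se = np_fit.se_k1 * (k_np_c / np_fit.k1)
        rows["non_productive"].update(kd=k_np_c, kd_se=se, n_d=len(np_d))

    if assoc_fit is not None and f_c is not None and c > 0:
        n_tot = n_np + n_ps
        for f_dest, n_dest, row in ((f_c, n_np, "non_productive"), (1.0 - f_c, n_ps, "pre_synaptic")):
            k2 = k_tot_c * f_dest / c
            var = (f_dest / c) ** 2 * (assoc_fit.se_k1 * k_tot_c / assoc_fit.k1) ** 2
            var += (k_tot_c / c) ** 2 * f_dest * (1 - f_dest) / n_tot
            rows[row].update(kf=k2, kf_se=math.sqrt(var), kf_units="M^-1 s^-1", n_f=n_dest)

    # pre-synaptic -> synapse formation rates.  A pre-synaptic dwell can be
    # invisibly prepended by the preceding non-productive visit when the
    # intervening free excursion is below the detection floor; subtract the
    # expected prepended length.
    def _ps_rate(durations):
        fit = _rate_from_dwells(durations, cfg)
        if fit is None:
            return None
        if k_np_c and k_tot_c and f_c is not None and tau > 0:
            q = f_c * p_short(k_tot_c)
            inv = max(1.0 / fit.k1 - q * (1.0 / k_np_c + mean_short(k_tot_c)), 1e-12)
            k = 1.0 / inv
            return _RateEstimate(k, fit.se_k1 * k / fit.k1)
        return fit

    if dwells.orientation == "inverted":
        ps = dwells.durations("presynaptic", outcome=("type_a", "type_b"))
        fit = _ps_rate(ps)
        if fit is not None:
            rows["synaptic"].update(kf=fit.k1, kf_se=fit.se_k1, kf_units="s^-1", n_f=len(ps))
    else:
        ps_a = dwells.durations("presynaptic", outcome="type_a")
        fit = _ps_rate(ps_a)
        if fit is not None:
            rows["wayward"].update(kf=fit.k1, kf_se=fit.se_k1, kf_units="s^-1", n_f=len(ps_a))
        ps_b = dwells.durations("presynaptic", outcome="type_b")
        fit = _ps_rate(ps_b)
        if fit is not None:
            rows["synaptic"].update(kf=fit.k1, kf_se=fit.se_k1, kf_units="s^-1", n_f=len(ps_b))

    # synapsed-state decays.  For inverted sites the pool mixes wayward
    # dissociation with completed recombination, so it is fitted
    # bi-exponentially (fast component: wayward decay; slow: recombination);
    # if the two components are not resolvable the single-exponential rate
    # is reported as the wayward decay alone.
    syn = dwells.durations("synapsed", outcome="returns_high")
    if dwells.orientation == "inverted":
        if len(syn) >= cfg.min_dwells:
            hist = _trim_dead_time(
                build_dwell_histogram(syn, cfg.bin_width or 10.0), cfg.dead_time_s
            )
            if hist.n_nonempty >= 8:
                bi = fit_biexponential(hist, weighted=cfg.weighted)
                single = fit_single_exponential(hist, weighted=cfg.weighted)
                choice = select_decay_model(single, bi)
                if choice.chosen == "bi":
                    rows["wayward"].update(kd=bi.k1, kd_se=bi.se_k1, n_d=len(syn))
                    rows["synaptic"].update(kd=bi.k2, kd_se=bi.se_k2, n_d=len(syn))
                elif single.converged:
                    rows["wayward"].update(kd=single.k1, kd_se=single.se_k1, n_d=len(syn))
    else:
        fit = _rate_from_dwells(syn, cfg)
        if fit is not None:
            rows["wayward"].update(kd=fit.k1, kd_se=fit.se_k1, n_d=len(syn))

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "complex"
    return table
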