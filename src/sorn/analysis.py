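"""Statistics of simulated (or experimental) rasters and weight tables.

Covers the full analysis surface of the model study: firing irregularity
(inter-spike intervals, coefficients of variation, pairwise correlations),
log-binned weight histograms and lognormal fits, connectivity-phase
classification, synapse-lifetime power laws, weight-change and fluctuation
statistics, rich-get-richer STDP curves, activity return maps and the
Gibrat proportionate-growth null model.

Everything here is a pure function of recorded data: re-running an
analysis on a stored record is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .engine import SimulationRecord, SynapseEvent, StdpLog, INITIAL, ALIVE

__all__ = [
    "InsufficientDataError", "EmptyDataError",
    "LogBinnedHistogram", "DistributionFit", "IsiCvStats",
    "isi_cv_stats", "pairwise_correlations", "weight_histogram",
    "fit_lognormal", "fit_exponential", "phase_classify", "lifetimes",
    "fit_power_law", "weight_change_stats", "stdp_conditional_curves",
    "fluctuation_vs_weight", "top_share", "activity_return_map",
    "gibrat_null",
]


class EmptyDataError(ValueError):
    """No data survives the requested filtering."""


class InsufficientDataError(ValueError):
    """Too few data points for a reliable fit."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class LogBinnedHistogram:
    """Histogram with bin edges uniform on the log scale.

    ``density`` is count divided by the *linear* bin width, so that
    sum(density * width) equals ``n_included`` exactly — the convention
    used when comparing model weights with EPSP-amplitude histograms.
    """

    edges: np.ndarray        # linear-domain edges, len n_bins+1
    counts: np.ndarray
    density: np.ndarray
    n_included: int
    exclusion: float

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centers."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)


@dataclass
class DistributionFit:
    """A fitted distribution family with parameters and goodness of fit."""

    family: str              # "lognormal" | "exponential" | "power_law"
    params: dict
    gof: float | None        # one-sample KS statistic where defined
    n: int


@dataclass
class IsiCvStats:
    """Per-unit inter-spike-interval statistics.

    Units with fewer than ``min_isis`` intervals are excluded from the CV
    summaries and listed in ``excluded_units``; units that never spike are
    additionally listed in ``silent_units``.
    """

    isis: list[np.ndarray]
    rates: np.ndarray        # per-unit exponential-fit rate (1/mean ISI)
    cv: np.ndarray           # NaN for excluded units
    mean_cv: float
    n_units_included: int
    excluded_units: np.ndarray
    silent_units: np.ndarray


# ---------------------------------------------------------------------------
# firing statistics


def isi_cv_stats(raster: np.ndarray, washout: int = 3000,
                 min_isis: int = 3) -> IsiCvStats:
    """Inter-spike intervals, exponential-fit rates and CVs per unit.

    ISIs are the gaps between consecutive spikes of one unit after the
    washout.  The exponential-fit rate is the maximum-likelihood rate
    1/mean(ISI).  CV = sd(ISI)/mean(ISI); a CV near one is the signature
    of Poisson-like irregular firing.
    """
    raster = np.asarray(raster)
    if raster.shape[0] <= washout:
        raise ValueError("raster shorter than washout")
    post = raster[washout:]
    n_units = post.shape[1]
    isis, cv, rates = [], np.full(n_units, np.nan), np.full(n_units, np.nan)
    excluded, silent = [], []
    for u in range(n_units):
        t = np.flatnonzero(post[:, u])
        gaps = np.diff(t)
        isis.append(gaps)
        if t.size == 0:
            silent.append(u)
        if gaps.size >= 1:
            rates[u] = 1.0 / gaps.mean()
        if gaps.size >= min_isis:
            cv[u] = gaps.std() / gaps.mean()
        else:
            excluded.append(u)
    included = ~np.isnan(cv)
    return IsiCvStats(isis=isis, rates=rates, cv=cv,
                      mean_cv=float(cv[included].mean()) if included.any()
                      else float("nan"),
                      n_units_included=int(included.sum()),
                      excluded_units=np.array(excluded, int),
                      silent_units=np.array(silent, int))


def pairwise_correlations(raster: np.ndarray, washout: int = 3000,
                          ) -> np.ndarray:
    """Pearson correlations between all binary spike trains.

    Entries involving a constant train (a unit that always or never
    fires after washout) are undefined and flagged as NaN.
    """
    raster = np.asarray(raster, float)
    post = raster[washout:]
    if post.shape[0] < 2:
        raise ValueError("need at least 2 recorded steps after washout")
    sd = post.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(post.T)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    return corr


def activity_return_map(raster_exc: np.ndarray, washout: int = 3000) -> dict:
    """Return-map points (a(t), a(t+1)) of the active excitatory fraction.

    The summary reports the post-washout minimum, maximum and the number
    of completely silent steps — the diagnostics used to judge whether
    homeostasis keeps activity alive and bounded.
    """
    raster_exc = np.asarray(raster_exc)
    a = raster_exc[washout:].mean(axis=1)
    if a.size < 2:
        raise ValueError("need at least 2 steps after washout")
    return {
        "a_t": a[:-1],
        "a_next": a[1:],
        "min_activity": float(a.min()),
        "max_activity": float(a.max()),
        "n_silent_steps": int(np.sum(a == 0)),
        "n_steps": int(a.size),
    }


# ---------------------------------------------------------------------------
# weight distributions


def _retained(weights, exclusion) -> np.ndarray:
    w = np.asarray(weights, float).ravel()
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    return w[w > exclusion]


def weight_histogram(weights, exclusion: float = 1e-4,
                     n_bins: int = 30) -> LogBinnedHistogram:
    """Log-binned weight histogram with linear-width density.

    Weights at or below ``exclusion`` are dropped, mimicking the detection
    limit of spine-imaging experiments; the bin edges are uniform in
    log10 between the smallest and largest retained weight.
    """
    w = _retained(weights, exclusion)
    if w.size == 0:
        raise EmptyDataError("no weights above the exclusion threshold")
    lo, hi = w.min(), w.max()
    if lo == hi:  # degenerate support: one bin around the common value
        edges = np.array([lo * 0.999, hi * 1.001])
    else:
        edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
        edges[0] *= 1 - 1e-12
        edges[-1] *= 1 + 1e-12
    counts, _ = np.histogram(w, bins=edges)
    density = counts / np.diff(edges)
    return LogBinnedHistogram(edges=edges, counts=counts, density=density,
                              n_included=int(w.size), exclusion=exclusion)


def fit_lognormal(weights, exclusion: float = 1e-4) -> DistributionFit:
    """Maximum-likelihood lognormal fit to weights above the exclusion.

    mu and sigma are the mean and sd of log-weights; the goodness of fit
    is the one-sample Kolmogorov-Smirnov statistic against the fitted
    lognormal.
    """
    w = _retained(weights, exclusion)
    if w.size < 10:
        raise InsufficientDataError(
            f"need >= 10 retained weights, got {w.size}")
    logw = np.log(w)
    mu = float(logw.mean())
    sigma = float(logw.std())
    ks = stats.kstest(w, stats.lognorm(s=sigma, scale=np.exp(mu)).cdf)
    return DistributionFit(family="lognormal",
                           params={"mu": mu, "sigma": sigma},
                           gof=float(ks.statistic), n=int(w.size))


def fit_exponential(data, exclusion: float = 0.0) -> DistributionFit:
    """Maximum-likelihood exponential fit (rate = 1/mean) with KS gof."""
    w = _retained(data, exclusion)
    if w.size < 10:
        raise InsufficientDataError(
            f"need >= 10 retained values, got {w.size}")
    rate = float(1.0 / w.mean())
    ks = stats.kstest(w, stats.expon(scale=1.0 / rate).cdf)
    return DistributionFit(family="exponential", params={"rate": rate},
                           gof=float(ks.statistic), n=int(w.size))


def top_share(weights, share: float = 0.5) -> float:
    """Minimal fraction of the largest weights summing to ``share`` of total.

    The experimental benchmark: roughly 20% of synapses carry 50% of the
    total synaptic weight.
    """
    w = np.asarray(weights, float).ravel()
    w = w[w > 0]
    if w.size == 0:
        raise EmptyDataError("no positive weights")
    if not 0 < share <= 1:
        raise ValueError("share must lie in (0, 1]")
    w = np.sort(w)[::-1]
    csum = np.cumsum(w)
    k = int(np.searchsorted(csum, share * csum[-1]) + 1)
    return k / w.size


# ---------------------------------------------------------------------------
# connectivity phases


def phase_classify(connection_fraction: np.ndarray, window: int = 1000,
                   slope_tol: float | None = None) -> list[dict]:
    """Label connectivity phases as decay / growth / stable segments.

    The series is cut into non-overlapping windows; each window's linear
    slope (per step) is compared against ``slope_tol`` and contiguous
    windows with the same label are merged.  When ``slope_tol`` is None
    it is set to twice the standard deviation of the window slopes in the
    final quarter of the series — the regime-noise scale once the network
    has settled.  Segments are dicts with ``label``, ``start``, ``end``
    (step indices, end exclusive) and ``mean_slope``.
    """
    cf = np.asarray(connection_fraction, float)
    if cf.size < 2 * window:
        raise ValueError("series must span at least two windows")
    n_win = cf.size // window
    t = np.arange(window, dtype=float)
    slopes = [np.polyfit(t, cf[k * window:(k + 1) * window], 1)[0]
              for k in range(n_win)]
    if slope_tol is None:
        tail = slopes[(3 * n_win) // 4:]
        slope_tol = 2.0 * float(np.std(tail)) if len(tail) > 1 \
            else 2.0 * abs(slopes[-1])
        slope_tol = max(slope_tol, 1e-12)   # guard against exact-flat input
    labels = ["decay" if s < -slope_tol
              else "growth" if s > slope_tol else "stable" for s in slopes]
    segments = []
    for k, lab in enumerate(labels):
        if segments and segments[-1]["label"] == lab:
            segments[-1]["end"] = (k + 1) * window
            segments[-1]["_slopes"].append(slopes[k])
        else:
            segments.append({"label": lab, "start": k * window,
                             "end": (k + 1) * window, "_slopes": [slopes[k]]})
    for s in segments:
        s["mean_slope"] = float(np.mean(s.pop("_slopes")))
    return segments


# ---------------------------------------------------------------------------
# synapse lifetimes


def lifetimes(events: list[SynapseEvent], horizon: int | None = None,
              ) -> np.ndarray:
    """Lifetimes (death - birth) of structurally created synapses.

    Synapses present at t=0 are excluded (their birth time is unknown),
    as are synapses still alive at the horizon (right censoring) — the
    stable backbone has effectively unbounded lifetimes and would
    otherwise dominate the fit.
    """
    out = []
    for e in events:
        if e.birth_step == INITIAL:
            continue
        if e.death_step == ALIVE:
            continue
        if horizon is not None and (e.death_step > horizon
                                    or e.birth_step > horizon):
            continue
        out.append(e.death_step - e.birth_step)
    return np.asarray(out, dtype=np.int64)


def _discrete_powerlaw_mle(x: np.ndarray, xmin: int) -> float:
    """Discrete power-law exponent via Hurwitz-zeta maximum likelihood."""
    s = np.log(x).sum()
    n = x.size

    def nll(alpha):
        return n * np.log(special.zeta(alpha, xmin)) + alpha * s / 1.0

    res = optimize.minimize_scalar(nll, bounds=(1.01, 8.0), method="bounded")
    return float(res.x)


def _ks_powerlaw(x: np.ndarray, alpha: float, xmin: int) -> float:
    ux, cnt = np.unique(x.astype(int), return_counts=True)
    emp_cdf = np.cumsum(cnt) / x.size
    k = np.arange(int(xmin), int(ux.max()) + 1, dtype=float)
    cdf = np.cumsum(k ** (-alpha) / special.zeta(alpha, xmin))
    return float(np.max(np.abs(emp_cdf - cdf[ux - int(xmin)])))


def _select_xmin(x: np.ndarray, min_tail: int = 100) -> int:
    """KS-minimizing lower cutoff (Clauset-style xmin selection).

    For each candidate cutoff, fit the exponent by maximum likelihood on
    the tail and score the fit by its KS distance; the cutoff with the
    smallest distance wins.  Candidates leaving fewer than ``min_tail``
    samples are skipped.
    """
    qs = np.unique(np.quantile(x, np.linspace(0.0, 0.9, 40)).astype(int))
    best_xmin, best_ks = int(x.min()), np.inf
    for xm in qs[qs >= 1]:
        tail = x[x >= xm]
        if tail.size < min_tail:
            continue
        alpha = _discrete_powerlaw_mle(tail.astype(float), int(xm))
        ks = _ks_powerlaw(tail, alpha, int(xm))
        if ks < best_ks:
            best_ks, best_xmin = ks, int(xm)
    return best_xmin


def fit_power_law(lifetime_samples, xmin: int | None = 2) -> DistributionFit:
    """Power-law fit of the lifetime distribution, exponent reported twice.

    The primary estimate is the discrete maximum-likelihood exponent for
    samples >= xmin; a least-squares slope of the log-binned log-density
    is reported alongside.  With ``xmin=None`` the cutoff is selected by
    the standard KS-minimization procedure — appropriate for synapse
    lifetimes, whose smallest values are dominated by the waiting time to
    the first weight kick rather than by the scale-free diffusion tail.
    The exponent is reported as a positive magnitude (the density falls
    as x^-alpha; for diffusing synapses the expectation is alpha = 3/2).
    """
    x = np.asarray(lifetime_samples)
    if xmin is None:
        if x.size < 100:
            raise InsufficientDataError(
                f"need >= 100 samples for xmin selection, got {x.size}")
        xmin = _select_xmin(x[x >= 1])
    x = x[x >= xmin].astype(float)
    if x.size < 100:
        raise InsufficientDataError(
            f"need >= 100 samples >= xmin, got {x.size}")
    alpha = _discrete_powerlaw_mle(x, int(xmin))
    hist = weight_histogram(x, exclusion=xmin - 0.5, n_bins=15)
    ok = hist.density > 0
    slope = float(np.polyfit(np.log10(hist.centers[ok]),
                             np.log10(hist.density[ok]), 1)[0])
    ks = _ks_powerlaw(x, alpha, int(xmin)) if x.max() < 10**6 else None
    return DistributionFit(
        family="power_law",
        params={"alpha_mle": alpha, "alpha_lsq": -slope, "xmin": int(xmin)},
        gof=ks, n=int(x.size))


# ---------------------------------------------------------------------------
# weight dynamics


def weight_change_stats(snapshot_a: np.ndarray, snapshot_b: np.ndarray,
                        mode: str = "relative") -> dict:
    """Weight changes between two snapshots, split into populations.

    Synapses present in both snapshots ("persisting") get B/A (relative
    mode) or B-A (absolute); synapses present only in A are "eliminated",
    only in B "newborn".  Presence means weight > 0.
    """
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    a = np.asarray(snapshot_a, float)
    b = np.asarray(snapshot_b, float)
    if a.shape != b.shape:
        raise ValueError("snapshots must have identical shape")
    in_a, in_b = a > 0, b > 0
    both = in_a & in_b
    w_a, w_b = a[both], b[both]
    change = w_b / w_a if mode == "relative" else w_b - w_a
    return {
        "mode": mode,
        "persisting_w_a": w_a,
        "persisting_w_b": w_b,
        "persisting_change": change,
        "eliminated_w_a": a[in_a & ~in_b],
        "newborn_w_b": b[in_b & ~in_a],
        "n_persisting": int(both.sum()),
        "n_eliminated": int((in_a & ~in_b).sum()),
        "n_newborn": int((in_b & ~in_a).sum()),
    }


def stdp_conditional_curves(stdp_log: StdpLog, snapshots: dict[int, np.ndarray],
                            bins: np.ndarray) -> dict:
    """Potentiation/depression probability per synaptic-weight bin.

    For each starting-weight bin: the fraction of synapse-steps whose STDP
    change was positive (potentiation), negative (depression), and the net
    (n_pos - n_neg) / n_total.  Synapse-step totals per bin are estimated
    from the periodic snapshots (each snapshot's occupancy counts for the
    steps until the next one).  Rising potentiation with weight while
    depression stays flat is the rich-get-richer signature.  Empty bins
    are NaN.
    """
    if stdp_log is None or len(stdp_log) == 0:
        raise EmptyDataError("record has no STDP delta log "
                             "(record flag 'stdp_deltas')")
    bins = np.asarray(bins, float)
    steps = sorted(snapshots)
    if len(steps) < 2:
        raise InsufficientDataError("need >= 2 snapshots")
    lo, hi = steps[0], steps[-1]
    n_total = np.zeros(bins.size - 1)
    for s0, s1 in zip(steps[:-1], steps[1:]):
        w = snapshots[s0]
        ws = w[w > 0]
        n_total += np.histogram(ws, bins=bins)[0] * (s1 - s0)
    sel = (stdp_log.step > lo) & (stdp_log.step <= hi)
    wb = stdp_log.w_before[sel]
    dv = stdp_log.delta[sel]
    n_pos = np.histogram(wb[dv > 0], bins=bins)[0]
    n_neg = np.histogram(wb[dv < 0], bins=bins)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        pot = np.where(n_total > 0, n_pos / n_total, np.nan)
        dep = np.where(n_total > 0, n_neg / n_total, np.nan)
        net = np.where(n_total > 0, (n_pos - n_neg) / n_total, np.nan)
    return {"bin_edges": bins, "bin_centers": 0.5 * (bins[:-1] + bins[1:]),
            "pot_fraction": pot, "dep_fraction": dep, "net_fraction": net,
            "n_total": n_total, "n_pos": n_pos, "n_neg": n_neg}


def fluctuation_vs_weight(snapshots: dict[int, np.ndarray],
                          bins: np.ndarray) -> dict:
    """Mean absolute weight change between consecutive snapshots, by weight.

    Pairs consecutive snapshots; every synapse existing at the start of an
    interval contributes |w_end - w_start| to its starting-weight bin
    (weights that vanish contribute their full size).  Growing
    fluctuations with weight reproduce the experimentally observed
    multiplicative-like dynamics.
    """
    bins = np.asarray(bins, float)
    steps = sorted(snapshots)
    if len(steps) < 2:
        raise InsufficientDataError("need >= 2 snapshots")
    w_start, absdiff = [], []
    for s0, s1 in zip(steps[:-1], steps[1:]):
        a, b = snapshots[s0], snapshots[s1]
        m = a > 0
        w_start.append(a[m])
        absdiff.append(np.abs(b[m] - a[m]))
    w_start = np.concatenate(w_start)
    absdiff = np.concatenate(absdiff)
    idx = np.digitize(w_start, bins) - 1
    mean_abs = np.full(bins.size - 1, np.nan)
    counts = np.zeros(bins.size - 1, int)
    for k in range(bins.size - 1):
        m = idx == k
        counts[k] = m.sum()
        if counts[k]:
            mean_abs[k] = absdiff[m].mean()
    return {"bin_edges": bins, "bin_centers": 0.5 * (bins[:-1] + bins[1:]),
            "mean_abs_change": mean_abs, "counts": counts}


# ---------------------------------------------------------------------------
# Gibrat proportionate-growth null model


def gibrat_null(n_synapses: int, n_steps: int, growth_sd: float,
                normalize: bool, rng: np.random.Generator,
                record_every: int = 1, w0: np.ndarray | None = None,
                ) -> np.ndarray:
    """Proportionate-growth (Gibrat) weight trajectories.

    Each weight is multiplied per step by exp(eps), eps ~ N(0, growth_sd);
    with ``normalize`` the vector is rescaled to sum to one each step
    (the multiplicative-scaling analogue).  Without normalization the
    variance of log-weights grows as growth_sd^2 * t without bound; with
    it, the distribution stays lognormal-like and bounded.  Returns the
    recorded trajectories, shape (n_recorded + 1, n_synapses), first row
    the initial weights.
    """
    if growth_sd < 0:
        raise ValueError("growth_sd must be >= 0")
    w = (np.full(n_synapses, 1.0 / n_synapses) if w0 is None
         else np.asarray(w0, float).copy())
    out = [w.copy()]
    for t in range(1, n_steps + 1):
        if growth_sd > 0:
            w = w * np.exp(rng.normal(0.0, growth_sd, n_synapses))
        if normalize:
            w = w / w.sum()
        if t % record_every == 0 or t == n_steps:
            out.append(w.copy())
    return np.array(out)
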