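"""Trajectory-level statistics: velocities, run lengths, MSD, dwell times,
photobleaching step counts and brightness-mixture stoichiometry."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic_data import Track

__all__ = [
    "MsdCurve",
    "PowerLawFit",
    "ExpFit",
    "GaussFit",
    "MixtureFit",
    "TrackTooShortError",
    "track_velocity",
    "track_velocities",
    "fit_gaussian",
    "fit_exponential",
    "compute_msd",
    "fit_power_law",
    "fit_msd_linear",
    "diffusion_table",
    "count_bleach_steps",
    "fit_brightness_mixture",
    "assign_size",
    "track_brightness",
    "dwell_times",
]

MIN_VELOCITY_FRAMES = 5


class TrackTooShortError(ValueError):
    pass


@dataclass
class MsdCurve:
    """Ensemble mean-squared displacement vs lag time."""

    lag_s: np.ndarray
    msd_nm2: np.ndarray
    counts: np.ndarray     # displacement pairs averaged per lag
    n_tracks: np.ndarray | None = None  # tracks contributing per lag


@dataclass
class PowerLawFit:
    """Fit of msd = a * t^n (+ static offset)."""

    a: float                     # nm^2 / s^n
    n: float
    a_se: float
    n_se: float
    n_lags: int
    offset_nm2: float = 0.0      # static localization-error plateau
    d_um2_s: float | None = None  # a/2, reported only when n is near 1


@dataclass
class ExpFit:
    """Exponential MLE with right-censoring."""

    mean: float
    se: float
    n_obs: int
    n_censored: int


@dataclass
class GaussFit:
    mean: float
    sd: float
    n: int
    loglik: float


@dataclass
class MixtureFit:
    """Gaussian mixture with means k*mu1 and sds sqrt(k)*sigma1, k=1..K."""

    mu1: float
    sigma1: float
    weights: np.ndarray
    n_components: int
    n_iter: int
    loglik: float


# ---------------------------------------------------------------------------
# velocities and simple distribution fits


def track_velocity(track: Track) -> float:
    """Least-squares slope of position vs time (nm/s, minus-end positive)."""
    if track.time_s.size < MIN_VELOCITY_FRAMES:
        raise TrackTooShortError(
            f"track {track.track_id}: {track.time_s.size} < {MIN_VELOCITY_FRAMES} frames"
        )
    slope, _ = np.polyfit(track.time_s, track.position_nm, 1)
    return float(slope)


def track_velocities(tracks: list[Track]) -> pd.DataFrame:
    """Per-track velocities; short tracks are excluded with a reason code."""
    rows = []
    for tr in tracks:
        try:
            rows.append(
                {"track_id": tr.track_id, "velocity_nm_s": track_velocity(tr),
                 "excluded": False, "reason": ""}
            )
        except TrackTooShortError:
            rows.append(
                {"track_id": tr.track_id, "velocity_nm_s": np.nan,
                 "excluded": True, "reason": "too_short"}
            )
    return pd.DataFrame(rows)


def fit_gaussian(values) -> GaussFit:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need >= 2 observations")
    mean = float(values.mean())
    sd = float(values.std(ddof=0))  # ML estimate
    if sd <= 0:
        raise ValueError("zero variance: Gaussian fit degenerate")
    ll = float(
        -0.5 * values.size * np.log(2 * np.pi * sd**2)
        - ((values - mean) ** 2).sum() / (2 * sd**2)
    )
    return GaussFit(mean, sd, values.size, ll)


def fit_exponential(values, censored=None) -> ExpFit:
    """Censored exponential MLE: mean = sum(all values) / n_uncensored."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.any(values < 0):
        raise ValueError("values must be non-empty and non-negative")
    if censored is None:
        censored = np.zeros(values.size, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    n_unc = int((~censored).sum())
    if n_unc == 0:
        raise ValueError("all observations censored: mean not identifiable")
    mean = float(values.sum() / n_unc)
    return ExpFit(mean=mean, se=mean / np.sqrt(n_unc), n_obs=values.size,
                  n_censored=int(censored.sum()))


# ---------------------------------------------------------------------------
# MSD


def compute_msd(
    tracks: list[Track],
    max_lag_fraction: float = 0.25,
    lifetime_filter: tuple[float, float] | None = None,
    min_track_fraction: float = 0.5,
) -> MsdCurve:
    """Count-weighted ensemble MSD over all pair offsets.

    Every track contributes time-averaged squared displacements at lags up
    to ``max_lag_fraction`` of its own duration (overlapping-window
    estimates beyond that are dominated by a handful of increments); the
    ensemble curve is the pooled mean weighted by pair counts.  Lags to
    which fewer than ``min_track_fraction`` of the tracks contribute are
    dropped — in populations with broad lifetime spread the long-lag tail
    samples only the longest-lived (for directed motion: slowest) molecules
    and systematically bends the curve.  ``lifetime_filter=(lo, hi)`` keeps
    only tracks with duration inside the window (diffusive-state analyses).
    """
    if not tracks:
        raise ValueError("no tracks")
    if lifetime_filter is not None:
        lo, hi = lifetime_filter
        tracks = [t for t in tracks if lo <= t.duration <= hi]
        if not tracks:
            raise ValueError("no tracks pass the lifetime filter")
    dts = {round(t.frame_interval, 9) for t in tracks}
    if len(dts) > 1:
        raise ValueError(f"mixed frame intervals: {sorted(dts)}")
    dt = tracks[0].frame_interval
    caps = [max(1, int(np.floor((t.time_s.size - 1) * max_lag_fraction)))
            for t in tracks]
    max_lag = max(caps)

    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    n_contrib = np.zeros(max_lag + 1, dtype=int)
    for tr, cap in zip(tracks, caps):
        x = tr.position_nm
        for k in range(1, min(cap, x.size - 1) + 1):
            d = x[k:] - x[:-k]
            sums[k] += float(d @ d)
            counts[k] += d.size
            n_contrib[k] += 1
    keep = (counts[1:] > 0) & (n_contrib[1:] >= min_track_fraction * len(tracks))
    if not keep.any():  # degenerate: fall back to any populated lag
        keep = counts[1:] > 0
    lags = np.arange(1, max_lag + 1)[keep] * dt
    return MsdCurve(lag_s=lags, msd_nm2=sums[1:][keep] / counts[1:][keep],
                    counts=counts[1:][keep], n_tracks=n_contrib[1:][keep])


def fit_power_law(msd: MsdCurve, offset: bool = True) -> PowerLawFit:
    """Weighted nonlinear least squares of ``a * t^n (+ c)`` to an MSD curve.

    Pair counts set the weights with a multiplicative noise model: the SD of
    an MSD estimate scales with its value, so sigma = value / sqrt(count).
    The additive constant ``c`` (fitted by default) absorbs the static
    localization-error plateau ``2*sigma_loc^2`` that otherwise biases the
    exponent at short lags.  When the exponent lands in [0.8, 1.2] the
    diffusion coefficient D = a/2 is also reported, converted to um^2/s.
    """
    keep = msd.msd_nm2 > 0
    lag, val, cnt = msd.lag_s[keep], msd.msd_nm2[keep], msd.counts[keep]
    if lag.size < 4:
        raise ValueError("need >= 4 positive MSD points")
    # log-log line as starting point
    b, loga = np.polyfit(np.log(lag), np.log(val), 1)
    sigma = val / np.sqrt(cnt)
    if offset:
        popt, pcov = curve_fit(
            lambda t, a, n, c: a * np.power(t, n) + c,
            lag, val, p0=(float(np.exp(loga)), float(b), 0.0),
            sigma=sigma, absolute_sigma=False, maxfev=50000,
        )
        c = float(popt[2])
    else:
        popt, pcov = curve_fit(
            lambda t, a, n: a * np.power(t, n),
            lag, val, p0=(float(np.exp(loga)), float(b)),
            sigma=sigma, absolute_sigma=False, maxfev=50000,
        )
        c = 0.0
    a, n = float(popt[0]), float(popt[1])
    a_se, n_se = [float(np.sqrt(pcov[i, i])) for i in (0, 1)]
    d = a / 2.0 * 1e-6 if 0.8 <= n <= 1.2 else None  # nm^2/s -> um^2/s
    return PowerLawFit(a=a, n=n, a_se=a_se, n_se=n_se, n_lags=lag.size,
                       offset_nm2=c, d_um2_s=d)


def fit_msd_linear(msd: MsdCurve, n_lags: int = 4) -> tuple[float, float]:
    """Linear MSD fit over the first ``n_lags`` lags; returns (D um^2/s, intercept nm^2).

    The free intercept absorbs static localization noise (2*sigma_loc^2).
    """
    if msd.lag_s.size < n_lags:
        raise ValueError(f"need >= {n_lags} lags")
    lag = msd.lag_s[:n_lags]
    val = msd.msd_nm2[:n_lags]
    w = msd.counts[:n_lags].astype(float)
    slope, intercept = np.polyfit(lag, val, 1, w=np.sqrt(w))
    return float(slope / 2.0 * 1e-6), float(intercept)


def diffusion_table(d_values: dict[str, dict[str, float | None]]) -> pd.DataFrame:
    """Tabulate D per state for two constructs and their fold-ratio.

    ``d_values`` maps state -> {"wt": D, "mutant": D} (um^2/s, None for a
    missing measurement -> NA row entries).
    """
    rows = []
    for state, dd in d_values.items():
        wt = dd.get("wt")
        mut = dd.get("mutant")
        ratio = (mut / wt) if (wt and mut is not None) else np.nan
        rows.append(
            {"state": state,
             "d_wt_um2_s": np.nan if wt is None else wt,
             "d_mutant_um2_s": np.nan if mut is None else mut,
             "mutant_to_wt_ratio": ratio}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# photobleaching steps


def _best_split(y: np.ndarray) -> tuple[int, float]:
    """Best change point by squared-error reduction; returns (index, gain)."""
    n = y.size
    csum = np.cumsum(y)
    csum2 = np.cumsum(y * y)
    total = csum2[-1] - csum[-1] ** 2 / n
    best_i, best_gain = -1, 0.0
    for i in range(1, n):
        left = csum2[i - 1] - csum[i - 1] ** 2 / i
        right = (csum2[-1] - csum2[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        gain = total - left - right
        if gain > best_gain:
            best_i, best_gain = i, gain
    return best_i, best_gain


def count_bleach_steps(
    trace,
    frame_interval: float = 1.0,
    max_steps: int = 8,
) -> tuple[int, list[float]]:
    """Count downward intensity steps by binary segmentation with BIC stop.

    Change points are added greedily while they lower
    ``n*log(SSE/n) + 2*k*log(n)`` (two parameters, level and location, per
    step).  Returns the number of downward level transitions and their
    times.
    """
    y = np.asarray(trace, dtype=float)
    if y.size < 10:
        raise ValueError("trace too short (need >= 10 samples)")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")

    breaks: list[int] = []

    def sse(seg: np.ndarray) -> float:
        return float(((seg - seg.mean()) ** 2).sum())

    n = y.size
    while len(breaks) < max_steps:
        bounds = [0] + sorted(breaks) + [n]
        cur_sse = sum(sse(y[a:b]) for a, b in zip(bounds[:-1], bounds[1:]))
        best = None
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < 2:
                continue
            i, gain = _best_split(y[a:b])
            if i > 0 and (best is None or gain > best[1]):
                best = (a + i, gain)
        if best is None:
            break
        new_sse = max(cur_sse - best[1], 1e-300)
        k_old, k_new = len(breaks), len(breaks) + 1
        bic_old = n * np.log(max(cur_sse, 1e-300) / n) + 2 * k_old * np.log(n)
        bic_new = n * np.log(new_sse / n) + 2 * k_new * np.log(n)
        if bic_new >= bic_old:
            break
        breaks.append(best[0])

    bounds = [0] + sorted(breaks) + [n]
    means = [y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    down = [
        sorted(breaks)[i] * frame_interval
        for i in range(len(means) - 1)
        if means[i + 1] < means[i]
    ]
    return len(down), down


# ---------------------------------------------------------------------------
# brightness mixture


def track_brightness(track: Track, n_frames: int = 3) -> float:
    """Initial brightness: mean intensity over the first ``n_frames`` frames."""
    return float(track.intensity[:n_frames].mean())


def fit_brightness_mixture(
    values,
    n_components: int = 4,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureFit:
    """EM fit of a quantized-brightness mixture.

    Component k (k = 1..K) is Normal(k*mu1, sqrt(k)*sigma1): a complex of k
    fluorophores has k-fold mean brightness and k-fold variance.  Only mu1,
    sigma1 and the weights are free.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 * n_components:
        raise ValueError("too few brightness values for the mixture")
    k = np.arange(1, n_components + 1)
    mu1 = float(np.percentile(x, 25))
    if mu1 <= 0:
        mu1 = float(np.abs(x).mean()) or 1.0
    sigma1 = max(float(x.std() / n_components), 1e-12)
    w = np.full(n_components, 1.0 / n_components)

    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        mu = k * mu1
        sd = np.sqrt(k) * sigma1
        log_pdf = (
            -0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
            - np.log(sd[None, :])
            - 0.5 * np.log(2 * np.pi)
            + np.log(np.maximum(w[None, :], 1e-300))
        )
        m = log_pdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(log_pdf - lse[:, None])

        w = resp.mean(axis=0)
        mu1 = float((resp * x[:, None]).sum() / (resp * k[None, :]).sum())
        var1 = float(
            (resp * (x[:, None] - k[None, :] * mu1) ** 2 / k[None, :]).sum()
            / resp.sum()
        )
        sigma1 = max(np.sqrt(var1), 1e-12)
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            return MixtureFit(mu1, sigma1, w, n_components, it, ll)
        prev_ll = ll
    raise RuntimeError(
        f"EM did not converge in {max_iter} iterations "
        f"(last loglik {prev_ll:.3f}, mu1 {mu1:.3f})"
    )


def assign_size(brightness: float, fit: MixtureFit) -> int:
    """Most probable component (posterior arg-max) for one brightness value."""
    k = np.arange(1, fit.n_components + 1)
    mu = k * fit.mu1
    sd = np.sqrt(k) * fit.sigma1
    log_post = (
        -0.5 * ((brightness - mu) / sd) ** 2 - np.log(sd) + np.log(fit.weights)
    )
    return int(k[np.argmax(log_post)])


# ---------------------------------------------------------------------------
# dwell times


def dwell_times(
    tracks: list[Track],
    movie_end_s: float | None = None,
) -> ExpFit:
    """Exponential MLE of track residence durations.

    A track is censored if flagged so, or if it persists to the movie end.
    """
    if not tracks:
        raise ValueError("empty track selection")
    durations = np.array([t.duration for t in tracks])
    censored = np.array(
        [
            t.censored
            or (movie_end_s is not None and t.time_s[-1] >= movie_end_s - 1e-9)
            for t in tracks
        ]
    )
    return fit_exponential(durations, censored)
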