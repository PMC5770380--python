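"""Millisecond-to-second smFRET analysis of two-channel camera traces.

Covers the immobilized-molecule side of the pipeline: trace selection by
photobleaching criteria, per-frame FRET efficiency with bleach masking,
Gaussian population fits of pooled efficiency histograms, donor-acceptor
cross-correlation with exponential relaxation fits, injection (compaction)
kinetics, and the fraction of dynamic traces.

The selection criteria mirror the standard curation of 100-ms-frame
smTIRF data: a minimum initial total signal, a minimum pre-bleach span,
single-step bleaching with donor/acceptor anti-correlation, and a donor
bleach within the acquisition so the background is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .kinetics import DomainError

__all__ = [
    "TIRFTrace",
    "SelectionCriteria",
    "PopulationFit",
    "TraceCorrelation",
    "detect_bleach_step",
    "select_traces",
    "efficiency_trace",
    "fit_population_gaussians",
    "trace_cross_correlation",
    "fit_injection_kinetics",
    "dynamic_trace_fraction",
    "traces_to_tsv",
    "traces_from_tsv",
]


@dataclass
class TIRFTrace:
    """Framed two-channel intensity series with bleach annotations."""

    trace_id: int
    frame_time: float
    donor: np.ndarray
    acceptor: np.ndarray
    donor_bleach_frame: int | None = None
    acceptor_bleach_frame: int | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, float)
        self.acceptor = np.asarray(self.acceptor, float)
        if len(self.donor) != len(self.acceptor):
            raise DomainError("channels must have equal length")
        if self.frame_time <= 0:
            raise DomainError("frame_time must be positive")

    def __len__(self) -> int:
        return len(self.donor)

    @property
    def first_bleach_frame(self) -> int | None:
        cands = [f for f in (self.donor_bleach_frame, self.acceptor_bleach_frame) if f is not None]
        return min(cands) if cands else None

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_time


def traces_to_tsv(traces: list[TIRFTrace], path) -> None:
    frames = []
    for t in traces:
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": t.trace_id,
                    "frame": np.arange(len(t)),
                    "donor": t.donor,
                    "acceptor": t.acceptor,
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.17g")


def traces_from_tsv(path, frame_time: float = 0.1) -> list[TIRFTrace]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            TIRFTrace(
                trace_id=int(tid),
                frame_time=frame_time,
                donor=grp["donor"].to_numpy(),
                acceptor=grp["acceptor"].to_numpy(),
            )
        )
    return out


def detect_bleach_step(
    signal: np.ndarray, min_step_sigma: float = 5.0
) -> int | None:
    """Single downward-step change point by a two-sided cumulative-sum scan.

    Returns the frame index of the largest mean drop if its size exceeds
    ``min_step_sigma`` times the frame noise s.d. (estimated from first
    differences), else None.
    """
    x = np.asarray(signal, float)
    n = len(x)
    if n < 4:
        return None
    noise = np.median(np.abs(np.diff(x))) / (np.sqrt(2.0) * 0.6745)  # robust sd
    csum = np.cumsum(x)
    k = np.arange(1, n)
    mean_left = csum[:-1] / k
    mean_right = (csum[-1] - csum[:-1]) / (n - k)
    step = mean_left - mean_right
    # weight by sqrt of effective samples to avoid edge artifacts
    score = step * np.sqrt(k * (n - k) / n)
    best = int(np.argmax(score))
    if noise <= 0:
        noise = 1e-12
    if step[best] > min_step_sigma * noise:
        return best + 1
    return None


def _ensure_annotated(trace: TIRFTrace, min_step_sigma: float = 5.0) -> TIRFTrace:
    if trace.donor_bleach_frame is not None or trace.acceptor_bleach_frame is not None:
        return trace
    t = TIRFTrace(
        trace.trace_id, trace.frame_time, trace.donor, trace.acceptor,
        detect_bleach_step(trace.donor, min_step_sigma),
        detect_bleach_step(trace.acceptor, min_step_sigma),
        trace.condition,
    )
    return t


@dataclass(frozen=True)
class SelectionCriteria:
    """Trace curation thresholds applied in order (1-4).

    1. initial donor + beta-corrected acceptor total > ``min_initial_total``
       counts over baseline;
    2. at least ``min_prebleach_span`` seconds before the first bleach
       (10 s for injection runs);
    3. single-step bleaching; if the acceptor bleaches first the donor
       must rise to the pre-bleach total (anti-correlation check);
    4. donor bleach within ``require_donor_bleach_within`` seconds so the
       background level is unambiguous.
    """

    min_initial_total: float = 600.0
    min_prebleach_span: float = 5.0
    require_single_step: bool = True
    require_donor_bleach_within: float = 120.0
    anticorrelation_check: bool = True
    beta: float = 0.1
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    n_initial_frames: int = 10
    anticorrelation_tolerance: float = 0.25  # relative


def _initial_total(trace: TIRFTrace, c: SelectionCriteria) -> float:
    n0 = min(c.n_initial_frames, len(trace))
    d = trace.donor[:n0].mean() - c.background_donor
    a = trace.acceptor[:n0].mean() - c.background_acceptor
    return float(d + (a - c.beta * d))


def select_traces(
    traces: list[TIRFTrace], criteria: SelectionCriteria
) -> tuple[list[TIRFTrace], list[tuple[TIRFTrace, str]]]:
    """Apply the four curation criteria; rejects carry the first failing code.

    Traces without bleach annotations are annotated with the cumulative-sum
    step finder first.  Deterministic and order-independent.
    """
    accepted, rejected = [], []
    for raw in traces:
        tr = _ensure_annotated(raw)
        if _initial_total(tr, criteria) <= criteria.min_initial_total:
            rejected.append((tr, "initial_total"))
            continue
        first = tr.first_bleach_frame
        span = (first if first is not None else len(tr)) * tr.frame_time
        if span < criteria.min_prebleach_span:
            rejected.append((tr, "prebleach_span"))
            continue
        if criteria.require_single_step and criteria.anticorrelation_check:
            ab, db = tr.acceptor_bleach_frame, tr.donor_bleach_frame
            if ab is not None and (db is None or ab < db):
                # donor must recover to the pre-bleach total after acceptor loss
                pre_n = min(ab, 50)
                d_pre = tr.donor[ab - pre_n : ab].mean() - criteria.background_donor
                a_pre = tr.acceptor[ab - pre_n : ab].mean() - criteria.background_acceptor
                total_pre = d_pre + (a_pre - criteria.beta * d_pre)
                stop = db if db is not None else len(tr)
                post_n = max(stop - ab, 1)
                d_post = tr.donor[ab : min(ab + post_n, stop)].mean() - criteria.background_donor
                if total_pre > 0 and abs(d_post - total_pre) / total_pre > criteria.anticorrelation_tolerance:
                    rejected.append((tr, "single_step"))
                    continue
        db = tr.donor_bleach_frame
        if db is None or db * tr.frame_time > criteria.require_donor_bleach_within:
            rejected.append((tr, "donor_bleach_window"))
            continue
        accepted.append(tr)
    return accepted, rejected


def efficiency_trace(
    trace: TIRFTrace,
    beta: float = 0.1,
    gamma: float = 1.0,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame FRET efficiency and a validity mask.

    ``E_t = A'_t / (A'_t + gamma * D_t)`` with the acceptor corrected for
    background and donor bleed-through; frames at and after the first
    bleach are masked invalid.
    """
    d = trace.donor - background_donor
    a = trace.acceptor - background_acceptor - beta * d
    denom = a + gamma * d
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(denom > 0, a / denom, np.nan)
    mask = np.isfinite(e)
    first = trace.first_bleach_frame
    if first is not None:
        mask[first:] = False
    if not mask.any():
        raise DomainError("trace has no valid frames")
    return e, mask


@dataclass
class PopulationFit:
    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    stderr_means: np.ndarray
    bin_edges: np.ndarray
    histogram: np.ndarray
    redchi: float


def fit_population_gaussians(
    e_samples: np.ndarray,
    n_components: int,
    bin_width: float = 0.02,
    e_range: tuple[float, float] = (-0.2, 1.2),
    seed: int = 0,
) -> PopulationFit:
    """Least-squares fit of ``n_components`` Gaussians to the binned
    efficiency histogram (mirrors population analysis with s.e.m. bars).

    Deterministic: component means start at evenly spaced sample quantiles.
    """
    import lmfit

    e = np.asarray(e_samples, float)
    e = e[np.isfinite(e)]
    if len(e) < 500:
        raise DomainError("need at least 500 efficiency samples")
    edges = np.arange(e_range[0], e_range[1] + bin_width / 2, bin_width)
    hist, _ = np.histogram(e, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    sigma_bins = np.sqrt(np.maximum(hist, 1.0))

    qs = np.quantile(e, np.linspace(0.15, 0.85, n_components))
    params = lmfit.Parameters()
    for i in range(n_components):
        params.add(f"amp{i}", value=hist.max() / n_components, min=0.0)
        params.add(f"mu{i}", value=float(qs[i]), min=e_range[0], max=e_range[1])
        params.add(f"sig{i}", value=0.08, min=bin_width / 2, max=0.5)

    def model(p):
        out = np.zeros_like(centers)
        for i in range(n_components):
            out = out + p[f"amp{i}"] * np.exp(
                -0.5 * ((centers - p[f"mu{i}"]) / p[f"sig{i}"]) ** 2
            )
        return out

    def resid(p):
        return (model(p) - hist) / sigma_bins

    res = lmfit.minimize(resid, params, method="leastsq")
    p = res.params
    amps = np.array([p[f"amp{i}"].value for i in range(n_components)])
    mus = np.array([p[f"mu{i}"].value for i in range(n_components)])
    sigs = np.array([p[f"sig{i}"].value for i in range(n_components)])
    errs = np.array(
        [p[f"mu{i}"].stderr if p[f"mu{i}"].stderr is not None else np.nan for i in range(n_components)]
    )
    areas = amps * sigs
    weights = areas / areas.sum() if areas.sum() > 0 else np.full(n_components, 1.0 / n_components)
    order = np.argsort(mus)
    return PopulationFit(
        means=mus[order],
        sigmas=sigs[order],
        weights=weights[order],
        stderr_means=errs[order],
        bin_edges=edges,
        histogram=hist,
        redchi=float(res.redchi),
    )


@dataclass
class TraceCorrelation:
    lags: np.ndarray  # seconds, lag 0 included in the curve but not fits
    pooled: np.ndarray
    sem: np.ndarray
    per_trace: np.ndarray  # (n_traces, n_lags)
    fit_amplitudes: np.ndarray
    fit_times: np.ndarray
    fit_shares: np.ndarray
    per_trace_amplitude: np.ndarray
    per_trace_amplitude_se: np.ndarray


def _trace_cc(d: np.ndarray, a: np.ndarray, max_lag: int) -> np.ndarray:
    x = d - d.mean()
    y = a - a.mean()
    n = len(x)
    denom = np.std(x) * np.std(y)
    out = np.full(max_lag + 1, np.nan)
    for k in range(0, min(max_lag, n - 2) + 1):
        out[k] = np.mean(x[: n - k] * y[k:]) / denom if denom > 0 else np.nan
    return out


def trace_cross_correlation(
    traces: list[TIRFTrace],
    max_lag: float = 5.0,
    n_exp: int = 1,
    beta: float = 0.0,
) -> TraceCorrelation:
    """Donor-acceptor cross-correlation of mean-subtracted signals.

    Per trace the normalized cross-covariance is computed over the valid
    (pre-bleach) frames; the pooled curve is the trace average with
    s.e.m., fitted with one or two exponentials over lags >= 1 frame
    (lag 0 carries the shot-noise spike and is excluded).  Anti-correlated
    FRET dynamics produce negative amplitudes.
    """
    if len(traces) < 1:
        raise DomainError("need at least one trace")
    frame_time = traces[0].frame_time
    max_k = int(round(max_lag / frame_time))
    rows = []
    for tr in traces:
        stop = tr.first_bleach_frame if tr.first_bleach_frame is not None else len(tr)
        d = tr.donor[:stop]
        a = tr.acceptor[:stop] - beta * tr.donor[:stop]
        if stop < 10:
            continue
        rows.append(_trace_cc(d, a, max_k))
    per = np.array(rows)
    pooled = np.nanmean(per, axis=0)
    nvalid = np.sum(np.isfinite(per), axis=0)
    sem = np.nanstd(per, axis=0) / np.sqrt(np.maximum(nvalid, 1))
    lags = np.arange(max_k + 1) * frame_time

    fit_lags = lags[1:]
    fit_y = pooled[1:]
    fit_w = np.where(sem[1:] > 0, 1.0 / sem[1:], 0.0)
    good = np.isfinite(fit_y) & (fit_w > 0)

    def one_exp(t, a0, tr_):
        return a0 * np.exp(-t / tr_)

    def two_exp(t, a0, t0, a1, t1):
        return a0 * np.exp(-t / t0) + a1 * np.exp(-t / t1)

    amp_guess = fit_y[good][0] if good.any() else -0.01
    try:
        if n_exp == 1:
            popt, _ = curve_fit(
                one_exp, fit_lags[good], fit_y[good], sigma=1.0 / fit_w[good],
                p0=[amp_guess, max(2 * frame_time, 0.2)],
                bounds=([-np.inf, frame_time / 10], [np.inf, 100.0]), maxfev=10000,
            )
            amps, times = np.array([popt[0]]), np.array([popt[1]])
        else:
            popt, _ = curve_fit(
                two_exp, fit_lags[good], fit_y[good], sigma=1.0 / fit_w[good],
                p0=[amp_guess, max(2 * frame_time, 0.1), amp_guess / 2, 1.0],
                bounds=([-np.inf, frame_time / 10, -np.inf, frame_time / 10], [np.inf, 100.0, np.inf, 100.0]),
                maxfev=20000,
            )
            amps, times = np.array([popt[0], popt[2]]), np.array([popt[1], popt[3]])
    except RuntimeError:
        amps = np.array([np.nan] * n_exp)
        times = np.array([np.nan] * n_exp)
    shares = np.abs(amps) / np.abs(amps).sum() if np.isfinite(amps).all() and np.abs(amps).sum() > 0 else np.full(n_exp, np.nan)

    # per-trace amplitude at the pooled relaxation time (linear estimator)
    t_ref = times[np.argmax(np.abs(amps))] if np.isfinite(times).any() else 0.2
    basis = np.exp(-fit_lags / t_ref)
    denom = (basis**2).sum()
    pt_amp = np.full(len(per), np.nan)
    pt_se = np.full(len(per), np.nan)
    for i, row in enumerate(per):
        y = row[1:]
        ok = np.isfinite(y)
        if ok.sum() < 3:
            continue
        b = basis[ok]
        d2 = (b**2).sum()
        pt_amp[i] = (y[ok] * b).sum() / d2
        resid = y[ok] - pt_amp[i] * b
        pt_se[i] = np.sqrt((resid**2).sum() / max(ok.sum() - 1, 1) / d2)
    return TraceCorrelation(
        lags=lags, pooled=pooled, sem=sem, per_trace=per,
        fit_amplitudes=amps, fit_times=times, fit_shares=shares,
        per_trace_amplitude=pt_amp, per_trace_amplitude_se=pt_se,
    )


def dynamic_trace_fraction(corr: TraceCorrelation, threshold: float = 3.0) -> float:
    """Fraction of traces whose fitted |amplitude| exceeds ``threshold``
    times its standard error."""
    ok = np.isfinite(corr.per_trace_amplitude) & np.isfinite(corr.per_trace_amplitude_se)
    if not ok.any():
        return 0.0
    dyn = np.abs(corr.per_trace_amplitude[ok]) > threshold * corr.per_trace_amplitude_se[ok]
    return float(dyn.mean())


def fit_injection_kinetics(
    traces: list[TIRFTrace],
    t_inject: float,
    beta: float = 0.1,
    gamma: float = 1.0,
    background_donor: float = 0.0,
    background_acceptor: float = 0.0,
    shift_threshold: float = 0.15,
    settle_time: float | None = None,
) -> dict:
    """Injection (compaction) kinetics from traces aligned to an injection.

    Traces are classified as responders when their mean efficiency after
    the injection exceeds the pre-injection mean by ``shift_threshold``.
    The responder-averaged efficiency is fitted with a single-exponential
    approach to the post-injection plateau; returns the time constant with
    a 95% CI and the responder fraction.
    """
    if not traces:
        raise DomainError("no traces given")
    ft = traces[0].frame_time
    f_inj = int(round(t_inject / ft))
    responders = []
    for tr in traces:
        e, mask = efficiency_trace(tr, beta, gamma, background_donor, background_acceptor)
        pre = e[:f_inj][mask[:f_inj]]
        post = e[f_inj:][mask[f_inj:]]
        if len(pre) < 3 or len(post) < 3:
            continue
        if post.mean() - pre.mean() > shift_threshold:
            responders.append(np.where(mask, e, np.nan))
    frac = len(responders) / len(traces)
    if not responders:
        return {"tau": np.nan, "tau_ci95": np.nan, "responder_fraction": 0.0, "n_responders": 0}
    n_frames = max(len(r) for r in responders)
    stack = np.full((len(responders), n_frames), np.nan)
    for i, r in enumerate(responders):
        stack[i, : len(r)] = r
    mean_e = np.nanmean(stack, axis=0)
    t = np.arange(n_frames) * ft
    post = t >= t_inject
    tt = t[post] - t_inject
    yy = mean_e[post]
    ok = np.isfinite(yy)

    def rise(x, e_inf, de, tau):
        return e_inf - de * np.exp(-x / tau)

    p0 = [np.nanmean(yy[-10:]), np.nanmean(yy[-10:]) - yy[ok][0], 1.0]
    popt, pcov = curve_fit(
        rise, tt[ok], yy[ok], p0=p0,
        bounds=([-0.5, -2.0, ft / 10], [1.5, 2.0, 1000.0]), maxfev=20000,
    )
    tau = float(popt[2])
    tau_se = float(np.sqrt(pcov[2, 2]))
    return {
        "tau": tau,
        "tau_ci95": 1.96 * tau_se,
        "responder_fraction": frac,
        "n_responders": len(responders),
        "plateau": float(popt[0]),
        "mean_trace": mean_e,
        "times": t,
    }
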