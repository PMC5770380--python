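"""Dynamic photon distribution analysis (dynPDA).

PDA predicts the exact shot-noise-limited shape of FRET proximity-ratio
histograms: conditioned on the total photon count n of a time window, the
acceptor count of a conformationally static molecule is binomial at that
species' corrected detection probability.  Dynamic PDA extends this to
molecules exchanging between species inside the window: conditioned on
the occupancy fractions of the states during the window, photons are
still split binomially, now at the brightness-weighted time-averaged
detection probability.  Integrating the binomial over the occupancy-time
law of the kinetic model (analytic for two-state exchange, Monte-Carlo
otherwise) yields the histogram of a dynamic species -- the bridged
"in-between" populations that rates are fitted from, in direct analogy to
NMR relaxation-dispersion lineshapes.

The fit axis is the uncorrected proximity ratio S_R / (S_G + S_R); all
instrumental corrections live in the forward map, which keeps the count
statistics exact.  Fitting minimizes a pooled Pearson chi-square jointly
over several window durations (and conditions), which is what makes
exchange rates identifiable: each window duration probes the kinetics at
a different ratio of window to relaxation time.

Kinetic schemes with a disconnected exchanging graph (e.g. two
independent register branches sharing no transitions) are handled as
mixtures over the connected components, with branch weights as model
parameters; within each component the stationary law applies.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import binom as binom_dist
from scipy.stats import qmc

from .kinetics import (
    DomainError,
    KineticModel,
    ModelError,
    communicating_classes,
    occupancy_fraction_density,
    sample_occupancies,
    stationary_distribution,
    submodel,
)
from .synthetic import CalibrationConfig, acceptor_probability

__all__ = [
    "TimeWindowData",
    "PDAModel",
    "FitSpec",
    "FitResult",
    "slice_time_windows",
    "window_histogram",
    "pda_predict_histogram",
    "simulate_windows",
    "fit_kinetic_model",
    "compare_models",
    "subsample_uncertainty",
    "species_population_summary",
]

_P_GRID = np.linspace(0.0, 1.0, 601)
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(201)
_GL_X = 0.5 * (_GL_NODES + 1.0)
_GL_W = 0.5 * _GL_WEIGHTS


@dataclass
class TimeWindowData:
    """Fixed-duration photon-count windows cut from bursts."""

    dt: float
    s_g: np.ndarray
    s_r: np.ndarray
    burst_id: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.s_g = np.asarray(self.s_g, int)
        self.s_r = np.asarray(self.s_r, int)
        self.burst_id = np.asarray(self.burst_id, int)
        if np.any(self.s_g < 0) or np.any(self.s_r < 0):
            raise DomainError("window counts must be non-negative")

    def __len__(self) -> int:
        return len(self.s_g)

    @property
    def totals(self) -> np.ndarray:
        return self.s_g + self.s_r

    @property
    def proximity_ratio(self) -> np.ndarray:
        tot = self.totals
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.s_r / tot, np.nan)

    def subset(self, mask: np.ndarray) -> "TimeWindowData":
        return TimeWindowData(self.dt, self.s_g[mask], self.s_r[mask], self.burst_id[mask], self.condition)


def slice_time_windows(bursts, stream, dt: float, condition: str = "") -> TimeWindowData:
    """Cut each burst into consecutive non-overlapping windows of ``dt``.

    Windows start at the burst start; a trailing remainder shorter than
    ``dt`` is discarded.  Donor-excitation photons only when PIE slots are
    present.
    """
    from .synthetic import CHANNEL_ACCEPTOR, CHANNEL_DONOR, SLOT_DONOR_EXC

    if dt <= 0:
        raise DomainError("dt must be positive")
    sg, sr, bid = [], [], []
    pie = stream.has_pie
    for ib, b in enumerate(bursts):
        t = stream.macro_time[b.index_start : b.index_stop] - b.start
        chan = stream.channel[b.index_start : b.index_stop]
        slot = stream.slot[b.index_start : b.index_stop]
        keep = np.ones(len(t), bool) if not pie else (slot == SLOT_DONOR_EXC)
        n_win = int((b.stop - b.start) / dt)
        if n_win == 0:
            continue
        widx = (t / dt).astype(int)
        ok = keep & (widx < n_win)
        for w in range(n_win):
            m = ok & (widx == w)
            sg.append(int((chan[m] == CHANNEL_DONOR).sum()))
            sr.append(int((chan[m] == CHANNEL_ACCEPTOR).sum()))
            bid.append(ib)
    return TimeWindowData(dt, np.array(sg, int), np.array(sr, int), np.array(bid, int), condition)


@dataclass
class PDAModel:
    """Forward model for window-count histograms.

    ``model`` carries the FRET species, exchange rates, connectivity and
    the static (non-exchanging) subpopulation.  ``branch_weights`` gives
    the probability that an exchanging molecule belongs to each connected
    component of the exchanging graph (normalized; defaults to a single
    component).  ``sigma_app`` (Angstrom, per species) adds apparent
    Gaussian distance broadening.
    """

    model: KineticModel
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    donor_only_fraction: float = 0.0
    branch_weights: np.ndarray | None = None
    sigma_app: np.ndarray | None = None
    mc_samples: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        classes = communicating_classes(self.model)
        if self.branch_weights is None:
            self.branch_weights = np.full(len(classes), 1.0 / len(classes))
        self.branch_weights = np.asarray(self.branch_weights, float)
        if len(self.branch_weights) != len(classes):
            raise ModelError("branch_weights must match the number of exchanging components")
        if np.any(self.branch_weights < 0):
            raise ModelError("branch_weights must be non-negative")
        s = self.branch_weights.sum()
        if s <= 0:
            raise ModelError("branch_weights must not all vanish")
        self.branch_weights = self.branch_weights / s
        if not (0.0 <= self.donor_only_fraction < 1.0):
            raise ModelError("donor_only_fraction must lie in [0, 1)")
        if self.sigma_app is not None:
            self.sigma_app = np.asarray(self.sigma_app, float)

    @property
    def classes(self) -> list[np.ndarray]:
        return communicating_classes(self.model)

    def detection_probabilities(self) -> np.ndarray:
        return acceptor_probability(self.model.efficiencies, self.calibration)

    def _species_spectrum(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(p values, weights) for one species incl. distance broadening."""
        sp = self.model.species[i]
        if self.sigma_app is None or self.sigma_app[i] <= 0:
            return (
                np.array([acceptor_probability(np.array([sp.efficiency]), self.calibration)[0]]),
                np.array([1.0]),
            )
        nodes, w = np.polynomial.hermite_e.hermegauss(9)
        r = np.maximum(sp.distance + self.sigma_app[i] * nodes, 1.0)
        e = 1.0 / (1.0 + (r / sp.pair.forster_radius) ** 6)
        return acceptor_probability(e, self.calibration), w / w.sum()

    def component_spectra(self, dt: float) -> list[tuple[float, np.ndarray, np.ndarray]]:
        """All mixture components as (weight, p values, p weights).

        Static molecules contribute per-species deltas; each exchanging
        component contributes its occupancy-integrated spectrum (analytic
        two-state law or seeded Monte-Carlo); donor-only molecules an
        E = 0 delta.
        """
        m = self.model
        out = []
        w_d0 = self.donor_only_fraction
        w_static = (1.0 - w_d0) * m.static_fraction
        w_dyn = (1.0 - w_d0) * (1.0 - m.static_fraction)
        if w_d0 > 0:
            p0 = acceptor_probability(np.array([0.0]), self.calibration)
            out.append((w_d0, p0, np.array([1.0])))
        if w_static > 0:
            sw = m.default_static_weights()
            for i in range(m.n_states):
                if sw[i] > 0:
                    p, pw = self._species_spectrum(i)
                    out.append((w_static * sw[i], p, pw))
        if w_dyn > 0:
            q = m.brightnesses
            for cls, bw in zip(self.classes, self.branch_weights):
                if bw <= 0:
                    continue
                weight = w_dyn * bw
                if len(cls) == 1:
                    p, pw = self._species_spectrum(int(cls[0]))
                    out.append((weight, p, pw))
                    continue
                sub = submodel(m, cls)
                p_states, pw_states = zip(*(self._species_spectrum(int(i)) for i in cls))
                # single representative p per state (mean over broadening)
                p_mean = np.array([float(np.dot(p_, w_)) for p_, w_ in zip(p_states, pw_states)])
                q_cls = q[cls]
                if len(cls) == 2:
                    dens = occupancy_fraction_density(sub, dt)
                    x = _GL_X
                    wq = dens.pdf(x) * _GL_W
                    xs = np.concatenate([[0.0], x, [1.0]])
                    ws = np.concatenate([[dens.mass_at_zero], wq, [dens.mass_at_one]])
                    f1 = q_cls[0] * xs / (q_cls[0] * xs + q_cls[1] * (1.0 - xs))
                    p_eff = f1 * p_mean[0] + (1.0 - f1) * p_mean[1]
                    tot = ws.sum()
                    out.append((weight, p_eff, ws / tot))
                else:
                    rng = np.random.default_rng(
                        self.seed + int(1e6 * dt) + int(cls.sum())
                    )
                    occ = sample_occupancies(sub, dt, self.mc_samples, rng=rng)
                    wq = occ * q_cls[None, :]
                    f = wq / wq.sum(axis=1, keepdims=True)
                    p_eff = f @ p_mean
                    hist, edges = np.histogram(p_eff, bins=_P_GRID)
                    centers = (edges[:-1] + edges[1:]) / 2
                    nz = hist > 0
                    out.append((weight, centers[nz], hist[nz] / hist.sum()))
        tot = sum(w for w, _, _ in out)
        return [(w / tot, p, pw) for w, p, pw in out]

    def species_populations(self) -> np.ndarray:
        """Combined (static + dynamic) species populations, summing to 1
        over the FRET-labeled molecules (donor-only excluded)."""
        m = self.model
        pops = m.static_fraction * m.default_static_weights()
        w_dyn = 1.0 - m.static_fraction
        for cls, bw in zip(self.classes, self.branch_weights):
            if len(cls) == 1:
                pops[cls[0]] += w_dyn * bw
            else:
                pi = stationary_distribution(submodel(m, cls))
                pops[cls] += w_dyn * bw * pi
        return pops


# -- cached binomial bin matrices -------------------------------------------

_BINOM_CACHE: dict = {}


def _edges_key(edges: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(edges).tobytes()).hexdigest()[:12]


def _binom_bin_matrix(n: int, edges: np.ndarray) -> np.ndarray:
    """(len(_P_GRID), n_bins) matrix: P(S_R/n in bin | p) on the fixed p grid.

    Bin convention: proximity ratio r/n falls in [lo, hi); the last bin is
    closed above.
    """
    key = (n, _edges_key(edges))
    hit = _BINOM_CACHE.get(key)
    if hit is not None:
        return hit
    # counts r in bin [lo, hi): ceil(lo*n) <= r <= ceil(hi*n) - 1
    kl = np.ceil(edges * n - 1e-9).astype(int)
    kl = np.clip(kl, 0, n + 1)
    hi_counts = kl[1:] - 1
    lo_counts = kl[:-1]
    hi_counts = hi_counts.copy()
    hi_counts[-1] = n  # close the top bin
    p = _P_GRID[:, None]
    cdf_hi = binom_dist.cdf(hi_counts[None, :], n, p)
    cdf_lo = binom_dist.cdf(lo_counts[None, :] - 1, n, p)
    mat = cdf_hi - cdf_lo
    _BINOM_CACHE[key] = mat
    return mat


def _spectrum_to_grid(p: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Linear-interpolation deposit of a (p, weight) spectrum onto _P_GRID."""
    grid_w = np.zeros(len(_P_GRID))
    step = _P_GRID[1] - _P_GRID[0]
    pos = np.clip(p, 0.0, 1.0) / step
    i0 = np.minimum(pos.astype(int), len(_P_GRID) - 2)
    frac = pos - i0
    np.add.at(grid_w, i0, w * (1.0 - frac))
    np.add.at(grid_w, i0 + 1, w * frac)
    return grid_w


def pda_predict_histogram(
    pda_model: PDAModel,
    dt: float,
    total_counts: np.ndarray | dict,
    edges: np.ndarray | int = 41,
) -> np.ndarray:
    """Predicted probability histogram over the proximity ratio.

    ``total_counts`` is either the array of observed window totals (the
    empirical count distribution) or a mapping ``{n: weight}``.  The
    output sums to 1.
    """
    if isinstance(edges, int):
        edges = np.linspace(0.0, 1.0, edges + 1)
    if isinstance(total_counts, dict):
        ns = np.array(sorted(total_counts), int)
        nw = np.array([total_counts[n] for n in ns], float)
    else:
        tc = np.asarray(total_counts, int)
        ns, counts = np.unique(tc, return_counts=True)
        nw = counts.astype(float)
    nw = nw / nw.sum()
    spectra = pda_model.component_spectra(dt)
    grid_w = np.zeros(len(_P_GRID))
    for w, p, pw in spectra:
        grid_w += w * _spectrum_to_grid(p, pw)
    out = np.zeros(len(edges) - 1)
    for n, weight in zip(ns, nw):
        if n <= 0:
            continue
        mat = _binom_bin_matrix(int(n), edges)
        out += weight * (grid_w @ mat)
    s = out.sum()
    if s > 0:
        out = out / s
    return out


def simulate_windows(
    pda_model: PDAModel,
    dt: float,
    n_windows: int,
    mean_total: float = 40.0,
    min_total: int = 10,
    seed: int = 0,
    condition: str = "",
) -> TimeWindowData:
    """Brute-force Monte-Carlo window generator (and PDA oracle).

    Per window: draw the mixture component, the total photon count
    (Poisson around ``mean_total`` conditioned on ``min_total``), the
    trajectory occupancy via exact Gillespie sampling, and split photons
    binomially at the brightness-weighted time-averaged detection
    probability.  This makes no use of the analytic occupancy law, so it
    serves as the independent oracle for :func:`pda_predict_histogram`.
    """
    rng = np.random.default_rng(seed)
    m = pda_model.model
    calib = pda_model.calibration
    p_states = pda_model.detection_probabilities()
    q = m.brightnesses
    w_d0 = pda_model.donor_only_fraction
    w_static = (1.0 - w_d0) * m.static_fraction
    classes = pda_model.classes

    totals = rng.poisson(mean_total, n_windows)
    bad = totals < min_total
    while bad.any():
        totals[bad] = rng.poisson(mean_total, int(bad.sum()))
        bad = totals < min_total

    u = rng.random(n_windows)
    is_d0 = u < w_d0
    is_static = (~is_d0) & (u < w_d0 + w_static)
    is_dyn = ~(is_d0 | is_static)

    p_eff = np.empty(n_windows)
    p_eff[is_d0] = acceptor_probability(np.array([0.0]), calib)[0]
    n_static = int(is_static.sum())
    if n_static:
        sw = m.default_static_weights()
        st = rng.choice(m.n_states, n_static, p=sw)
        p_eff[is_static] = p_states[st]
    n_dyn = int(is_dyn.sum())
    if n_dyn:
        which = rng.choice(len(classes), n_dyn, p=pda_model.branch_weights)
        p_dyn = np.empty(n_dyn)
        for c, cls in enumerate(classes):
            sel = which == c
            k = int(sel.sum())
            if k == 0:
                continue
            if len(cls) == 1:
                p_dyn[sel] = p_states[cls[0]]
                continue
            sub = submodel(m, cls)
            occ = sample_occupancies(sub, dt, k, rng=rng)
            wq = occ * q[cls][None, :]
            f = wq / wq.sum(axis=1, keepdims=True)
            p_dyn[sel] = f @ p_states[cls]
        p_eff[is_dyn] = p_dyn
    s_r = rng.binomial(totals, p_eff)
    return TimeWindowData(dt, totals - s_r, s_r, np.arange(n_windows), condition)


def window_histogram(
    data: TimeWindowData, edges: np.ndarray | int = 41, min_total: int = 10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(histogram counts, edges, retained totals) of the proximity ratio."""
    if isinstance(edges, int):
        edges = np.linspace(0.0, 1.0, edges + 1)
    tot = data.totals
    keep = tot >= min_total
    sr = data.s_r[keep]
    n = tot[keep]
    # integer count-threshold mapping, identical to the prediction's bin
    # convention (r/n in [lo, hi), top bin closed) -- a floating-point
    # comparison of r/n against the edges would split exact-edge windows
    # inconsistently between observation and model
    hist = np.zeros(len(edges) - 1)
    for nv in np.unique(n):
        kl = np.ceil(edges * nv - 1e-9).astype(int)
        sel = n == nv
        idx = np.clip(np.searchsorted(kl, sr[sel], side="right") - 1, 0, len(edges) - 2)
        np.add.at(hist, idx, 1.0)
    return hist, edges, n


@dataclass
class FitSpec:
    """Which PDAModel parameters are free in a fit.

    ``free_rates`` lists (i, j) transitions whose rates float on a log
    scale (default: every allowed transition).  Efficiencies stay fixed
    unless listed in ``free_efficiencies``.
    """

    free_rates: list | None = None
    free_branch_weights: bool = False
    free_static_fraction: bool = False
    free_donor_only: bool = False
    free_efficiencies: list = field(default_factory=list)
    rate_bounds: tuple[float, float] = (1.0, 1e6)
    n_starts: int = 5

    def resolved_rates(self, model: KineticModel) -> list:
        if self.free_rates is not None:
            return list(self.free_rates)
        mask = model.connectivity_mask
        return [(i, j) for i in range(model.n_states) for j in range(model.n_states) if mask[i, j]]


def _logit(x):
    x = np.clip(x, 1e-9, 1 - 1e-9)
    return np.log(x / (1 - x))


def _expit(y):
    return 1.0 / (1.0 + np.exp(-y))


def _pack(pda_model: PDAModel, spec: FitSpec) -> tuple[np.ndarray, list]:
    names, vals = [], []
    m = pda_model.model
    for i, j in spec.resolved_rates(m):
        names.append(f"rate_{i}_{j}")
        vals.append(np.log(max(m.rate_matrix[i, j], spec.rate_bounds[0])))
    if spec.free_branch_weights:
        for c in range(len(pda_model.branch_weights) - 1):
            names.append(f"branch_{c}")
            vals.append(_logit(pda_model.branch_weights[c]))
    if spec.free_static_fraction:
        names.append("static_fraction")
        vals.append(_logit(m.static_fraction))
    if spec.free_donor_only:
        names.append("donor_only_fraction")
        vals.append(_logit(pda_model.donor_only_fraction))
    for i in spec.free_efficiencies:
        names.append(f"e_{i}")
        vals.append(_logit(m.species[i].efficiency))
    return np.array(vals), names


def _unpack(p: np.ndarray, names: list, template: PDAModel, spec: FitSpec) -> PDAModel:
    m = template.model
    k = m.rate_matrix.copy()
    np.fill_diagonal(k, 0.0)
    species = list(m.species)
    branch = template.branch_weights.copy()
    static_fraction = m.static_fraction
    donor_only = template.donor_only_fraction
    free_branch_raw = []
    for name, v in zip(names, p):
        if name.startswith("rate_"):
            _, i, j = name.split("_")
            k[int(i), int(j)] = np.exp(v)
        elif name.startswith("branch_"):
            free_branch_raw.append((int(name.split("_")[1]), v))
        elif name == "static_fraction":
            static_fraction = _expit(v)
        elif name == "donor_only_fraction":
            donor_only = _expit(v)
        elif name.startswith("e_"):
            i = int(name.split("_")[1])
            species[i] = replace(species[i], efficiency=float(_expit(v)), distance=None)
    if free_branch_raw:
        # stick-breaking over components: last weight absorbs the rest
        w = branch.copy()
        raw = dict(free_branch_raw)
        rem = 1.0
        for c in range(len(w) - 1):
            frac = _expit(raw.get(c, _logit(w[c] / max(rem, 1e-12))))
            w[c] = rem * frac
            rem -= w[c]
        w[-1] = max(rem, 0.0)
        branch = w
    model = KineticModel(
        species=species,
        rate_matrix=k,
        connectivity_mask=m.connectivity_mask,
        static_fraction=static_fraction,
        static_weights=m.static_weights,
    )
    return replace(template, model=model, branch_weights=branch, donor_only_fraction=donor_only)


def _pooling(obs: np.ndarray, min_expected: float = 5.0) -> list[np.ndarray]:
    """Adjacent-bin pooling so every pooled bin holds >= min_expected counts."""
    groups, cur, acc = [], [], 0.0
    for i, c in enumerate(obs):
        cur.append(i)
        acc += c
        if acc >= min_expected:
            groups.append(np.array(cur))
            cur, acc = [], 0.0
    if cur:
        if groups:
            groups[-1] = np.concatenate([groups[-1], np.array(cur)])
        else:
            groups.append(np.array(cur))
    return groups


@dataclass
class FitResult:
    params: dict
    pda_model: PDAModel
    redchi: float
    chi2: float
    dof: int
    per_histogram_redchi: list
    n_windows: int
    seed: int
    starts: list = field(default_factory=list)

    def relaxation_times(self) -> dict:
        """Relaxation times of each exchanging component of the fit."""
        out = {}
        m = self.pda_model.model
        for c, cls in enumerate(communicating_classes(m)):
            if len(cls) > 1:
                from .kinetics import relaxation_times as _rt

                out[f"component_{c}"] = _rt(submodel(m, cls))
        return out


def _prepare_datasets(datasets, edges, min_total):
    prep = []
    for d in datasets:
        hist, ed, totals = window_histogram(d, edges, min_total)
        groups = _pooling(hist)
        prep.append({"dt": d.dt, "hist": hist, "edges": ed, "totals": totals, "groups": groups})
    return prep


def _chi2_parts(pda_model: PDAModel, prep) -> tuple[float, int, list]:
    chi2, dof, per = 0.0, 0, []
    for d in prep:
        pred = pda_predict_histogram(pda_model, d["dt"], d["totals"], d["edges"])
        nw = d["hist"].sum()
        c2, nb = 0.0, 0
        for g in d["groups"]:
            o = d["hist"][g].sum()
            e = max(nw * pred[g].sum(), 1e-12)
            c2 += (o - e) ** 2 / e
            nb += 1
        chi2 += c2
        dof += nb
        per.append(c2 / max(nb, 1))
    return chi2, dof, per


def _residuals(pda_model: PDAModel, prep) -> np.ndarray:
    out = []
    for d in prep:
        pred = pda_predict_histogram(pda_model, d["dt"], d["totals"], d["edges"])
        nw = d["hist"].sum()
        for g in d["groups"]:
            o = d["hist"][g].sum()
            e = max(nw * pred[g].sum(), 1e-12)
            out.append((o - e) / np.sqrt(e))
    return np.array(out)


def fit_kinetic_model(
    datasets: list[TimeWindowData],
    template: PDAModel,
    spec: FitSpec | None = None,
    edges: np.ndarray | int = 41,
    min_total: int = 10,
    seed: int = 0,
) -> FitResult:
    """Global Pearson-chi-square fit of a kinetic model to window histograms.

    All datasets (typically several window durations of one measurement)
    are fitted simultaneously with one parameter set.  Deterministic
    multi-start local minimization: a seeded Latin-hypercube of start
    points in the free-parameter space, each refined by least squares on
    the signed Pearson residuals; the best run is reported with all
    starts logged.
    """
    spec = spec or FitSpec()
    prep = _prepare_datasets(datasets, edges, min_total)
    p0, names = _pack(template, spec)
    if len(p0) == 0:
        raise DomainError("no free parameters")
    lo_rate, hi_rate = np.log(spec.rate_bounds[0]), np.log(spec.rate_bounds[1])
    lo = np.array([lo_rate if n.startswith("rate_") else -8.0 for n in names])
    hi = np.array([hi_rate if n.startswith("rate_") else 8.0 for n in names])

    def resid(p):
        return _residuals(_unpack(p, names, template, spec), prep)

    sampler = qmc.LatinHypercube(d=len(p0), seed=seed)
    starts = [p0]
    if spec.n_starts > 1:
        pts = sampler.random(spec.n_starts - 1)
        for row in pts:
            starts.append(lo + row * (hi - lo))
    best, log = None, []
    for s, st in enumerate(starts):
        try:
            res = least_squares(resid, st, bounds=(lo, hi), max_nfev=400, diff_step=1e-3)
        except Exception:
            continue
        log.append({"start": s, "cost": float(res.cost), "x": res.x.tolist()})
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("every fit start failed")
    fitted = _unpack(best.x, names, template, spec)
    chi2, nbins, per = _chi2_parts(fitted, prep)
    dof = max(nbins - len(names), 1)
    params = dict(zip(names, best.x))
    readable = {}
    for n, v in params.items():
        if n.startswith("rate_"):
            readable[n] = float(np.exp(v))
        elif n.startswith(("branch_", "static", "donor", "e_")):
            readable[n] = float(_expit(v))
    return FitResult(
        params=readable,
        pda_model=fitted,
        redchi=chi2 / dof,
        chi2=chi2,
        dof=dof,
        per_histogram_redchi=per,
        n_windows=int(sum(len(d) for d in datasets)),
        seed=seed,
        starts=log,
    )


def compare_models(
    datasets: list[TimeWindowData],
    templates: list[tuple[str, PDAModel, FitSpec | None]],
    edges: np.ndarray | int = 41,
    min_total: int = 10,
    seed: int = 0,
    equivalence_band: float = 0.05,
) -> pd.DataFrame:
    """Fit each candidate connectivity and rank by global reduced chi^2.

    Templates within ``equivalence_band`` (relative) of the best are
    flagged as statistically equivalent.  Deterministic under the seed.
    """
    if len(templates) < 2:
        raise DomainError("need at least two model templates")
    rows = []
    for name, tmpl, spec in templates:
        fit = fit_kinetic_model(datasets, tmpl, spec, edges, min_total, seed)
        rows.append({"model": name, "redchi": fit.redchi, "chi2": fit.chi2, "dof": fit.dof, "fit": fit})
    df = pd.DataFrame(rows).sort_values("redchi", kind="stable").reset_index(drop=True)
    best = df["redchi"].iloc[0]
    df["equivalent_to_best"] = df["redchi"] <= best * (1.0 + equivalence_band)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def subsample_uncertainty(
    datasets: list[TimeWindowData],
    template: PDAModel,
    spec: FitSpec | None = None,
    fraction: float = 0.7,
    replicates: int = 3,
    seed: int = 0,
    edges: np.ndarray | int = 41,
    min_total: int = 10,
) -> dict:
    """Parameter s.d. from repeated fits of random data subsets.

    Defaults follow the standard protocol: three fits, each on a random
    70% of the windows.
    """
    rng = np.random.default_rng(seed)
    fits = []
    for r in range(replicates):
        subs = []
        for d in datasets:
            n = len(d)
            take = rng.choice(n, size=max(int(fraction * n), 1), replace=False)
            subs.append(d.subset(np.sort(take)))
        fits.append(fit_kinetic_model(subs, template, spec, edges, min_total, seed=seed + 1 + r))
    names = fits[0].params.keys()
    sd = {n: float(np.std([f.params[n] for f in fits], ddof=1)) for n in names}
    rts = [f.relaxation_times() for f in fits]
    sd_rt = {}
    for comp in rts[0]:
        arr = np.array([r[comp] for r in rts])
        sd_rt[comp] = arr.std(axis=0, ddof=1)
    return {"param_sd": sd, "relaxation_time_sd": sd_rt, "fits": fits}


def species_population_summary(
    fits: dict | list, conditions: list[str] | None = None
) -> pd.DataFrame:
    """Combined per-species populations (static + dynamic) per condition.

    Accepts ``{condition: FitResult}`` or a list of FitResult.  Rows sum
    to 1 over species; the static/dynamic split is kept as sub-columns.
    """
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(conditions[i] if conditions else str(i), f) for i, f in enumerate(fits)]
    rows = []
    for cond, fit in items:
        pm = fit.pda_model if isinstance(fit, FitResult) else fit
        m = pm.model
        names = [s.name for s in m.species]
        total = pm.species_populations()
        static_part = m.static_fraction * m.default_static_weights()
        row = {"condition": cond}
        for i, nm in enumerate(names):
            row[nm] = total[i]
            row[f"{nm}_static"] = static_part[i]
            row[f"{nm}_dynamic"] = total[i] - static_part[i]
        rows.append(row)
    return pd.DataFrame(rows)
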