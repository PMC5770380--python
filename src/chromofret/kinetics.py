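"""Kinetic and photophysical primitives for multi-state FRET systems.

A chromatin fiber (or any biomolecule carrying a donor/acceptor pair) is
described as a continuous-time Markov process over a small set of FRET
species, each defined by an inter-dye distance.  This module provides the
distance <-> efficiency map of Forster theory, rate-matrix utilities
(stationary law, relaxation times), an exact Gillespie trajectory sampler,
and the analytic occupancy-time law of a two-state exchange process inside
a fixed observation window -- the kernel of dynamic photon distribution
analysis.

Units: rates are per second and times are seconds throughout the kinetic
layer; nanoseconds appear only for fluorescence lifetimes and micro-times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import i0e, i1e

__all__ = [
    "DomainError",
    "ModelError",
    "DyePair",
    "FRETSpecies",
    "KineticModel",
    "StateTrajectory",
    "OccupancyDensity",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "relaxation_times",
    "stationary_distribution",
    "sample_trajectory",
    "occupancy_fraction_density",
    "communicating_classes",
    "submodel",
]


class DomainError(ValueError):
    """An argument is outside the physical domain of an operation."""


class ModelError(ValueError):
    """A kinetic model violates a structural requirement (e.g. reducibility)."""


@dataclass(frozen=True)
class DyePair:
    """A donor/acceptor dye pair.

    Parameters
    ----------
    forster_radius:
        Forster radius R0 in Angstrom (distance of 50% transfer efficiency).
    donor_lifetime:
        Unquenched donor fluorescence lifetime tau0 in nanoseconds.
    label:
        Free-text name, e.g. ``"Alexa568/647"``.
    """

    forster_radius: float
    donor_lifetime: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.forster_radius <= 0:
            raise DomainError("forster_radius must be positive")
        if self.donor_lifetime <= 0:
            raise DomainError("donor_lifetime must be positive")


#: Alexa Fluor 568 / Alexa Fluor 647: large R0 suited to long distances.
ALEXA568_647 = DyePair(forster_radius=82.0, donor_lifetime=3.6, label="Alexa568/647")
#: Alexa Fluor 488 / Alexa Fluor 647: shorter R0, resolves compact states.
ALEXA488_647 = DyePair(forster_radius=52.0, donor_lifetime=4.0, label="Alexa488/647")


def efficiency_from_distance(r_da: float | np.ndarray, pair: DyePair) -> float | np.ndarray:
    """FRET efficiency for an inter-dye distance: E = 1 / (1 + (R/R0)^6)."""
    r = np.asarray(r_da, dtype=float)
    if np.any(r <= 0):
        raise DomainError("inter-dye distance must be positive")
    out = 1.0 / (1.0 + (r / pair.forster_radius) ** 6)
    return float(out) if np.isscalar(r_da) else out


def distance_from_efficiency(e: float | np.ndarray, pair: DyePair) -> float | np.ndarray:
    """Exact inverse of :func:`efficiency_from_distance`, valid for 0 < E < 1."""
    ea = np.asarray(e, dtype=float)
    if np.any((ea <= 0) | (ea >= 1)):
        raise DomainError("efficiency must lie strictly between 0 and 1")
    out = pair.forster_radius * (1.0 / ea - 1.0) ** (1.0 / 6.0)
    return float(out) if np.isscalar(e) else out


@dataclass(frozen=True)
class FRETSpecies:
    """One structural state observed through its FRET efficiency.

    Either the distance or the efficiency may be given; the other is
    derived through the attached dye pair.  ``relative_brightness`` scales
    the detected photon flux of the species (quantum-yield and quenching
    differences); 1.0 means equal to the reference.
    """

    name: str
    pair: DyePair
    distance: float | None = None
    efficiency: float | None = None
    relative_brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.relative_brightness <= 0:
            raise DomainError("relative_brightness must be positive")
        if self.distance is None and self.efficiency is None:
            raise DomainError("give distance or efficiency")
        if self.distance is None:
            object.__setattr__(
                self, "distance", distance_from_efficiency(self.efficiency, self.pair)
            )
        elif self.efficiency is None:
            object.__setattr__(
                self, "efficiency", efficiency_from_distance(self.distance, self.pair)
            )
        e = self.efficiency
        if not (0.0 <= e <= 1.0):
            raise DomainError("efficiency outside [0, 1]")

    @property
    def donor_lifetime(self) -> float:
        """Quenched donor lifetime tau_D(A) = tau0 * (1 - E), in ns."""
        return self.pair.donor_lifetime * (1.0 - self.efficiency)


def _check_generator(k: np.ndarray, mask: np.ndarray) -> None:
    n = k.shape[0]
    if k.shape != (n, n):
        raise ModelError("rate matrix must be square")
    off = k.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ModelError("off-diagonal rates must be non-negative")
    if np.any(off[~mask] != 0):
        raise ModelError("forbidden transitions must have rate exactly 0")
    if not np.allclose(k.sum(axis=1), 0.0, atol=1e-9 * max(1.0, np.abs(k).max())):
        raise ModelError("rows of the generator must sum to zero")


def _components(mask: np.ndarray) -> list[np.ndarray]:
    """Connected components of the undirected allowed-transition graph."""
    n = mask.shape[0]
    sym = mask | mask.T
    seen = np.zeros(n, bool)
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        stack, comp = [s], []
        seen[s] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.nonzero(sym[u])[0]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(np.array(sorted(comp)))
    return comps


def _is_irreducible(k: np.ndarray) -> bool:
    """Strong connectivity of the directed graph of positive rates."""
    n = k.shape[0]
    if n == 1:
        return True
    adj = k > 0
    np.fill_diagonal(adj, False)

    def reach(a: np.ndarray) -> np.ndarray:
        r = np.zeros(n, bool)
        r[0] = True
        stack = [0]
        while stack:
            u = stack.pop()
            for v in np.nonzero(a[u])[0]:
                if not r[v]:
                    r[v] = True
                    stack.append(v)
        return r

    return bool(reach(adj).all() and reach(adj.T).all())


@dataclass
class KineticModel:
    """FRET species, exchange rate matrix, and a non-exchanging subpopulation.

    Parameters
    ----------
    species:
        Ordered FRET species; index i in the rate matrix refers to
        ``species[i]``.
    rate_matrix:
        Generator K in 1/s, row convention: ``K[i, j]`` (i != j) is the
        rate i -> j; the diagonal is minus the row sum of off-diagonals
        (filled in automatically if passed as zeros).
    connectivity_mask:
        Boolean adjacency of allowed transitions.  Defaults to "every
        nonzero rate is allowed".  A masked-out pair must carry rate 0.
    static_fraction:
        Fraction of molecules that never exchange; their state is drawn
        from ``static_weights`` (defaults to the stationary law where that
        is defined, else uniform per component).
    static_weights:
        Probability vector over species for the static subpopulation.
    """

    species: Sequence[FRETSpecies]
    rate_matrix: np.ndarray
    connectivity_mask: np.ndarray | None = None
    static_fraction: float = 0.0
    static_weights: np.ndarray | None = None
    #: set False for deliberately non-equilibrium schemes (e.g. an
    #: absorbing compaction model after an injection)
    require_irreducible: bool = True

    def __post_init__(self) -> None:
        k = np.array(self.rate_matrix, dtype=float)
        n = len(self.species)
        if k.shape != (n, n):
            raise ModelError("rate matrix shape does not match species count")
        # allow callers to leave the diagonal at zero
        off = k.copy()
        np.fill_diagonal(off, 0.0)
        np.fill_diagonal(k, 0.0)
        k -= np.diag(off.sum(axis=1))
        if self.connectivity_mask is None:
            mask = off > 0
        else:
            mask = np.array(self.connectivity_mask, dtype=bool)
            np.fill_diagonal(mask, False)
        _check_generator(k, mask)
        if not (0.0 <= self.static_fraction <= 1.0):
            raise ModelError("static_fraction must lie in [0, 1]")
        if self.require_irreducible:
            for comp in _components(mask):
                if len(comp) > 1 and not _is_irreducible(k[np.ix_(comp, comp)]):
                    raise ModelError(
                        "each connected component of the exchanging graph must be irreducible"
                    )
        self.rate_matrix = k
        self.connectivity_mask = mask
        if self.static_weights is not None:
            w = np.asarray(self.static_weights, dtype=float)
            if w.shape != (n,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ModelError("static_weights must be a probability vector over species")
            self.static_weights = w

    @property
    def n_states(self) -> int:
        return len(self.species)

    @property
    def efficiencies(self) -> np.ndarray:
        return np.array([s.efficiency for s in self.species])

    @property
    def brightnesses(self) -> np.ndarray:
        return np.array([s.relative_brightness for s in self.species])

    def exit_rates(self) -> np.ndarray:
        return -np.diag(self.rate_matrix)

    def require_connected(self) -> None:
        if len(_components(self.connectivity_mask)) != 1:
            raise ModelError("exchanging graph is disconnected")

    def default_static_weights(self) -> np.ndarray:
        if self.static_weights is not None:
            return self.static_weights
        try:
            return stationary_distribution(self)
        except ModelError:
            return np.full(self.n_states, 1.0 / self.n_states)


def communicating_classes(model: KineticModel) -> list[np.ndarray]:
    """Connected components (state index arrays) of the exchanging graph."""
    return _components(model.connectivity_mask)


def submodel(model: KineticModel, states: Sequence[int]) -> KineticModel:
    """Restriction of a model to a subset of states (one exchanging branch)."""
    idx = np.asarray(states, dtype=int)
    k = model.rate_matrix[np.ix_(idx, idx)].copy()
    np.fill_diagonal(k, 0.0)
    return KineticModel(
        species=[model.species[i] for i in idx],
        rate_matrix=k,
        connectivity_mask=model.connectivity_mask[np.ix_(idx, idx)],
    )


def stationary_distribution(model: KineticModel) -> np.ndarray:
    """Equilibrium occupancies: the left null vector of K, normalized to 1.

    Raises :class:`ModelError` if the exchanging graph is not irreducible
    (disconnected two-branch schemes have no unique stationary law; handle
    each branch via :func:`submodel`).
    """
    model.require_connected()
    k = model.rate_matrix
    n = k.shape[0]
    if n == 1:
        return np.array([1.0])
    # solve pi K = 0 with sum(pi) = 1 as an augmented least-squares system
    a = np.vstack([k.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.any(pi <= -1e-12):
        raise ModelError("stationary distribution has non-positive entries")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def relaxation_times(model: KineticModel) -> np.ndarray:
    """Relaxation times -1/lambda for the nonzero eigenvalues of K, ascending.

    For a two-state model this is exactly ``1 / (k12 + k21)``.
    """
    model.require_connected()
    lam = np.linalg.eigvals(model.rate_matrix)
    lam = np.real(lam)  # generators of irreducible chains relevant here
    scale = max(1.0, np.abs(lam).max())
    nonzero = lam[np.abs(lam) > 1e-12 * scale]
    if len(nonzero) != model.n_states - 1:
        raise ModelError("unexpected eigenvalue multiplicity at zero")
    return np.sort(-1.0 / nonzero)


@dataclass
class StateTrajectory:
    """Piecewise-constant state path: state ``states[i]`` holds on
    ``[jump_times[i], jump_times[i+1])`` (last segment runs to ``duration``)."""

    jump_times: np.ndarray
    states: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.jump_times, float)
        s = np.asarray(self.states, int)
        if len(t) != len(s) or len(t) == 0 or t[0] != 0.0:
            raise ModelError("trajectory must start at time 0 with one state per segment")
        if np.any(np.diff(t) <= 0):
            raise ModelError("jump times must be strictly increasing")
        if t[-1] >= self.duration:
            raise ModelError("last jump must precede the duration")
        self.jump_times = t
        self.states = s

    def state_at(self, times: np.ndarray) -> np.ndarray:
        """State index at each query time in [0, duration)."""
        idx = np.searchsorted(self.jump_times, times, side="right") - 1
        return self.states[idx]

    def occupancy(self, n_states: int) -> np.ndarray:
        """Fraction of the duration spent in each state."""
        bounds = np.append(self.jump_times, self.duration)
        seg = np.diff(bounds)
        out = np.zeros(n_states)
        np.add.at(out, self.states, seg)
        return out / self.duration


def sample_trajectory(
    model: KineticModel,
    duration: float,
    rng: np.random.Generator | int | None = None,
    initial_state: int | None = None,
) -> StateTrajectory:
    """Exact Gillespie sample of the exchange process over ``duration`` seconds.

    The initial state is drawn from the stationary law unless overridden
    (non-equilibrium injections pass ``initial_state``).
    """
    if duration <= 0:
        raise DomainError("duration must be positive")
    rng = np.random.default_rng(rng)
    if initial_state is None:
        try:
            p0 = stationary_distribution(model)
        except ModelError:  # disconnected or absorbing: fall back
            p0 = model.default_static_weights()
        state = int(rng.choice(model.n_states, p=p0))
    else:
        state = int(initial_state)
    k = model.rate_matrix
    exit_rates = model.exit_rates()
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        rate = exit_rates[state]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        row = k[state].copy()
        row[state] = 0.0
        state = int(rng.choice(model.n_states, p=row / rate))
        times.append(t)
        states.append(state)
    return StateTrajectory(np.array(times), np.array(states), duration)


def sample_occupancies(
    model: KineticModel,
    duration: float,
    n_samples: int,
    rng: np.random.Generator | int | None = None,
    initial_states: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized Gillespie: (n_samples, n_states) occupancy fractions.

    Equivalent in law to repeated :func:`sample_trajectory` + ``occupancy``
    but runs all windows in parallel; used by the Monte-Carlo PDA kernel.
    """
    rng = np.random.default_rng(rng)
    n = model.n_states
    k = model.rate_matrix
    exit_rates = model.exit_rates()
    # per-state cumulative transition law
    probs = k.copy()
    np.fill_diagonal(probs, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = probs / exit_rates[:, None]
    probs[exit_rates <= 0] = 0.0
    cumprobs = np.cumsum(probs, axis=1)

    if initial_states is None:
        p0 = stationary_distribution(model)
        state = rng.choice(n, size=n_samples, p=p0)
    else:
        state = np.array(initial_states, dtype=int)
        if state.shape != (n_samples,):
            raise DomainError("initial_states must have length n_samples")
    t = np.zeros(n_samples)
    occ = np.zeros((n_samples, n))
    active = exit_rates[state] > 0
    occ[np.arange(n_samples), state] = duration  # overwritten below for movers
    occ[active] = 0.0
    t_active = t[active]
    s_active = state[active]
    idx_active = np.nonzero(active)[0]
    while len(idx_active) > 0:
        dwell = rng.exponential(1.0 / exit_rates[s_active])
        t_new = t_active + dwell
        done = t_new >= duration
        # credit the (possibly truncated) sojourn to the current state
        credit = np.where(done, duration - t_active, dwell)
        np.add.at(occ, (idx_active, s_active), credit)
        keep = ~done
        idx_active = idx_active[keep]
        if len(idx_active) == 0:
            break
        t_active = t_new[keep]
        s_cur = s_active[keep]
        u = rng.random(len(idx_active))
        s_active = (u[:, None] > cumprobs[s_cur]).sum(axis=1)
        # guard against fp rounding past the last column
        s_active = np.minimum(s_active, n - 1)
    return occ / duration


@dataclass
class OccupancyDensity:
    """Law of the fraction of a window spent in state 0 of a 2-state model.

    ``mass_at_one`` / ``mass_at_zero`` are the probabilities of never
    leaving state 0 / state 1; ``pdf`` is the continuous density on (0, 1).
    """

    mass_at_zero: float
    mass_at_one: float
    window: float
    k01: float
    k10: float

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        a, b, big_t = self.k01, self.k10, self.window
        pi0 = b / (a + b)
        pi1 = a / (a + b)
        t = x * big_t
        s = big_t - t
        z = 2.0 * np.sqrt(a * b * t * s)
        # exponentially scaled Bessels keep this stable for large rate*T
        expo = np.exp(-a * t - b * s + z)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (
                pi0 * (np.sqrt(a * b * t / np.maximum(s, 1e-300)) * i1e(z) + a * i0e(z))
                + pi1 * (np.sqrt(a * b * s / np.maximum(t, 1e-300)) * i1e(z) + b * i0e(z))
            )
        out = expo * term * big_t  # density in x (Jacobian dT1/dx = T)
        out[(x <= 0) | (x >= 1)] = 0.0
        return out

    def total_mass(self) -> float:
        from scipy.integrate import quad

        cont, _ = quad(lambda x: float(self.pdf(np.array([x]))[0]), 0.0, 1.0,
                       epsabs=1e-12, epsrel=1e-12, limit=200)
        return self.mass_at_zero + self.mass_at_one + cont

    def grid_weights(self, nodes: np.ndarray, gl_weights: np.ndarray) -> np.ndarray:
        """Quadrature weights of the continuous part on supplied GL nodes."""
        return self.pdf(nodes) * gl_weights

    def sample_cdf(self, x: np.ndarray) -> np.ndarray:
        """CDF on a grid (for KS-style comparisons), including point masses."""
        x = np.asarray(x, float)
        fine = np.linspace(0.0, 1.0, 8001)
        pdf = self.pdf(fine)
        cdf_cont = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(fine))])
        c = np.interp(x, fine, cdf_cont)
        out = self.mass_at_zero + c
        out = np.where(x >= 1.0, out + self.mass_at_one, out)
        out = np.where(x < 0.0, 0.0, out)
        return out


def occupancy_fraction_density(model: KineticModel, window: float) -> OccupancyDensity:
    """Analytic law of the time fraction spent in state 0 over a window.

    Only defined for exactly two exchanging states (the dynamic-PDA kernel);
    larger models fall back to Monte-Carlo via :func:`sample_occupancies`.
    The point masses are ``pi0 * exp(-k01 T)`` at 1 and ``pi1 * exp(-k10 T)``
    at 0; the continuous part follows from summing over jump counts, which
    yields modified Bessel functions of the products of the two rates.
    """
    if model.n_states != 2:
        raise ModelError("analytic occupancy law requires exactly 2 exchanging states")
    if window <= 0:
        raise DomainError("window must be positive")
    k01 = model.rate_matrix[0, 1]
    k10 = model.rate_matrix[1, 0]
    if k01 <= 0 or k10 <= 0:
        raise ModelError("both exchange rates must be positive")
    pi0 = k10 / (k01 + k10)
    pi1 = k01 / (k01 + k10)
    return OccupancyDensity(
        mass_at_zero=pi1 * np.exp(-k10 * window),
        mass_at_one=pi0 * np.exp(-k01 * window),
        window=window,
        k01=k01,
        k10=k10,
    )


def model_to_config(model: KineticModel) -> dict:
    """Serialize a model to a plain config block (exact round trip)."""
    return {
        "species": [
            {
                "name": s.name,
                "distance": s.distance,
                "relative_brightness": s.relative_brightness,
                "pair": {
                    "forster_radius": s.pair.forster_radius,
                    "donor_lifetime": s.pair.donor_lifetime,
                    "label": s.pair.label,
                },
            }
            for s in model.species
        ],
        "rates": [
            f"{i},{j},{float(model.rate_matrix[i, j])!r}"
            for i in range(model.n_states)
            for j in range(model.n_states)
            if i != j and model.rate_matrix[i, j] != 0
        ],
        "static_fraction": model.static_fraction,
        "static_weights": None if model.static_weights is None else list(model.static_weights),
    }


def model_from_config(cfg: dict) -> KineticModel:
    """Inverse of :func:`model_to_config`."""
    species = []
    for s in cfg["species"]:
        pair = DyePair(**s["pair"])
        species.append(
            FRETSpecies(
                name=s["name"],
                pair=pair,
                distance=s.get("distance"),
                efficiency=s.get("efficiency"),
                relative_brightness=s.get("relative_brightness", 1.0),
            )
        )
    n = len(species)
    k = np.zeros((n, n))
    for entry in cfg.get("rates", []):
        i, j, rate = entry.split(",")
        k[int(i), int(j)] = float(rate)
    sw = cfg.get("static_weights")
    return KineticModel(
        species=species,
        rate_matrix=k,
        static_fraction=cfg.get("static_fraction", 0.0),
        static_weights=None if sw is None else np.asarray(sw, float),
    )


def two_state_model(
    s0: FRETSpecies,
    s1: FRETSpecies,
    relaxation_time: float,
    population0: float = 0.5,
    static_fraction: float = 0.0,
) -> KineticModel:
    """Convenience constructor from a relaxation time and an equilibrium split.

    ``1/t_R = k01 + k10`` and ``population0 = k10 / (k01 + k10)``.
    """
    if not (0 < population0 < 1):
        raise DomainError("population0 must lie in (0, 1)")
    ktot = 1.0 / relaxation_time
    k01 = ktot * (1.0 - population0)
    k10 = ktot * population0
    return KineticModel(
        species=[s0, s1],
        rate_matrix=np.array([[0.0, k01], [k10, 0.0]]),
        static_fraction=static_fraction,
    )
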