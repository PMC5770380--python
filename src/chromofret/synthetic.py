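"""Synthetic confocal photon streams and TIRF camera traces with ground truth.

The confocal simulator emulates freely diffusing molecules crossing a
focus: each transit is a top-hat intensity envelope of exponentially
distributed duration, during which photons arrive as a Poisson process
whose routing between the donor and acceptor detection channels follows
the instantaneous FRET species (via the transfer efficiency, detection
ratio gamma and spectral crosstalk alpha).  Micro-times are exponential
fluorescence decays convolved with a Gaussian instrument response, laid
out in a pulsed-interleaved-excitation (PIE) frame when enabled.  A
configurable fraction of molecules is donor-only, and a configurable
static fraction never exchanges states.

The TIRF simulator produces two-channel traces at a fixed frame time with
slow two-state switching, single-step photobleaching of either dye,
camera-style noise, and optional injection experiments in which a
responder fraction of traces changes its kinetic model at the injection
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    DomainError,
    DyePair,
    KineticModel,
    sample_trajectory,
    stationary_distribution,
)

CHANNEL_DONOR = 0
CHANNEL_ACCEPTOR = 1
SLOT_DONOR_EXC = 0
SLOT_ACCEPTOR_EXC = 1
SLOT_NONE = -1

#: PIE frame: two 32 MHz pulse trains shifted by half a 31.25 ns period.
DEFAULT_PERIOD_NS = 31.25
DEFAULT_SLOT_OFFSET_NS = 15.625


@dataclass
class PhotonStream:
    """Time-tagged photon records with channel and excitation-slot labels.

    macro_time is in seconds (sorted), micro_time in ns within the
    excitation period, channel is 0 (donor) / 1 (acceptor), slot is
    0 (donor excitation), 1 (acceptor excitation) or -1 (non-PIE data).
    """

    macro_time: np.ndarray
    micro_time: np.ndarray
    channel: np.ndarray
    slot: np.ndarray
    period_ns: float = DEFAULT_PERIOD_NS
    slot_offset_ns: float = DEFAULT_SLOT_OFFSET_NS
    duration: float | None = None

    def __post_init__(self) -> None:
        self.macro_time = np.asarray(self.macro_time, float)
        self.micro_time = np.asarray(self.micro_time, float)
        self.channel = np.asarray(self.channel, np.int8)
        self.slot = np.asarray(self.slot, np.int8)
        n = len(self.macro_time)
        if not (len(self.micro_time) == len(self.channel) == len(self.slot) == n):
            raise DomainError("photon record arrays must share one length")
        if n and np.any(np.diff(self.macro_time) < 0):
            raise DomainError("macro_time must be sorted")
        if n and (self.micro_time.min() < 0 or self.micro_time.max() >= self.period_ns):
            raise DomainError("micro_time must lie in [0, period)")
        if self.duration is None:
            self.duration = float(self.macro_time[-1]) if n else 0.0

    def __len__(self) -> int:
        return len(self.macro_time)

    @property
    def has_pie(self) -> bool:
        return bool(np.any(self.slot != SLOT_NONE))

    def subset(self, mask: np.ndarray) -> "PhotonStream":
        return PhotonStream(
            self.macro_time[mask],
            self.micro_time[mask],
            self.channel[mask],
            self.slot[mask],
            self.period_ns,
            self.slot_offset_ns,
            self.duration,
        )

    def channel_times(self, channel: int, slot: int | None = SLOT_DONOR_EXC) -> np.ndarray:
        """Macro-times of one detection channel, optionally one PIE slot."""
        m = self.channel == channel
        if slot is not None and self.has_pie:
            m &= self.slot == slot
        return self.macro_time[m]

    # -- tabular dialect (bit-exact round trip) --------------------------
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "macro_time_s": self.macro_time,
                "micro_time_ns": self.micro_time,
                "channel": self.channel,
                "slot": self.slot,
            }
        )
        with open(path, "w") as fh:
            fh.write(
                f"# period_ns={self.period_ns!r} slot_offset_ns={self.slot_offset_ns!r} "
                f"duration={self.duration!r}\n"
            )
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "PhotonStream":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        return cls(
            df["macro_time_s"].to_numpy(),
            df["micro_time_ns"].to_numpy(),
            df["channel"].to_numpy(),
            df["slot"].to_numpy(),
            period_ns=float(meta["period_ns"]),
            slot_offset_ns=float(meta["slot_offset_ns"]),
            duration=float(meta["duration"]),
        )

    # -- Photon-HDF5-style container ------------------------------------
    def to_hdf5(self, path) -> None:
        """Write a minimal Photon-HDF5-style layout (photon_data group)."""
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("photon_data")
            g.create_dataset("timestamps", data=self.macro_time)
            g.create_dataset("nanotimes", data=self.micro_time)
            g.create_dataset("detectors", data=self.channel)
            g.create_dataset("excitation_slots", data=self.slot)
            g.attrs["timestamps_unit"] = 1.0  # seconds
            g.attrs["period_ns"] = self.period_ns
            g.attrs["slot_offset_ns"] = self.slot_offset_ns
            g.attrs["duration"] = self.duration

    @classmethod
    def from_hdf5(cls, path) -> "PhotonStream":
        import h5py

        with h5py.File(path, "r") as f:
            g = f["photon_data"]
            return cls(
                g["timestamps"][()],
                g["nanotimes"][()],
                g["detectors"][()],
                g["excitation_slots"][()],
                period_ns=float(g.attrs["period_ns"]),
                slot_offset_ns=float(g.attrs["slot_offset_ns"]),
                duration=float(g.attrs["duration"]),
            )


@dataclass(frozen=True)
class CalibrationConfig:
    """Instrumental imperfections shared by simulator and corrections.

    alpha: fraction of detected donor-dye signal appearing in the acceptor
    channel (spectral crosstalk).  gamma: acceptor/donor detection-
    efficiency ratio.  Background rates are counts/s per channel.
    """

    alpha: float = 0.0
    gamma: float = 1.0
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    donor_only_fraction: float = 0.0
    irf_width_ns: float = 0.0
    irf_offset_ns: float = 0.0
    acceptor_lifetime_ns: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0) or not (0.0 <= self.donor_only_fraction < 1.0):
            raise DomainError("fractions must lie in [0, 1)")
        if self.gamma <= 0:
            raise DomainError("gamma must be positive")
        if min(self.background_donor, self.background_acceptor) < 0:
            raise DomainError("background rates must be non-negative")


def acceptor_probability(e: np.ndarray, calib: CalibrationConfig) -> np.ndarray:
    """Probability that a detected fluorescence photon falls in the acceptor
    channel, given species efficiency E: the forward map mirrored exactly by
    the burst corrections (gamma at routing, alpha after routing)."""
    e = np.asarray(e, dtype=float)
    red = e * calib.gamma + (1.0 - e) * calib.alpha
    return red / (red + (1.0 - e))


def detected_weight(e: np.ndarray, calib: CalibrationConfig) -> np.ndarray:
    """Relative detected flux of a species vs an E=0, gamma=1 reference."""
    e = np.asarray(e, dtype=float)
    return (1.0 - e) * (1.0 + calib.alpha) + e * calib.gamma


@dataclass(frozen=True)
class ConfocalSimConfig:
    mean_burst_duration: float = 1.5e-3
    molecule_brightness: float = 8e4  # detected counts/s at focus, E=0 ref
    burst_count: int = 2000
    mean_gap: float = 10e-3
    direct_excitation_brightness: float = 0.8  # PIE red-slot flux, rel. units
    pie: bool = False
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    pair: DyePair | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_burst_duration <= 0 or self.molecule_brightness <= 0:
            raise DomainError("durations and brightness must be positive")


@dataclass
class BurstTruth:
    """Ground truth for one simulated molecule transit."""

    t_start: float
    t_stop: float
    donor_only: bool
    static: bool
    occupancy: np.ndarray  # fraction of transit per species
    true_e: float  # brightness-weighted species-average efficiency


@dataclass
class GroundTruth:
    model: KineticModel
    bursts: list[BurstTruth]

    def table(self) -> pd.DataFrame:
        rows = []
        for b in self.bursts:
            rows.append(
                {
                    "t_start": b.t_start,
                    "t_stop": b.t_stop,
                    "donor_only": b.donor_only,
                    "static": b.static,
                    "true_e": b.true_e,
                    **{f"occ_{i}": o for i, o in enumerate(b.occupancy)},
                }
            )
        return pd.DataFrame(rows)


def simulate_bursts(
    model: KineticModel, cfg: ConfocalSimConfig
) -> tuple[PhotonStream, GroundTruth]:
    """Simulate a photon stream of single-molecule transits.

    Each molecule transit is a top-hat envelope of exponential duration.
    Photons are Poisson within each kinetic segment at the species'
    brightness, routed donor/acceptor by the species efficiency together
    with gamma and alpha, with micro-times drawn from the emitting
    species' exponential decay plus Gaussian IRF jitter.  A
    ``donor_only_fraction`` of molecules emits at E = 0.  With PIE, the
    acceptor-excitation slot carries direct acceptor photons for
    dual-labeled molecules only, enabling stoichiometry-based rejection.
    """
    if model.n_states == 0:
        raise DomainError("model must contain at least one species")
    calib = cfg.calibration
    pair = cfg.pair or model.species[0].pair
    rng = np.random.default_rng(cfg.seed)
    n_states = model.n_states
    e_states = model.efficiencies
    q_states = model.brightnesses
    tau_states = np.array([s.donor_lifetime for s in model.species])
    p_red = acceptor_probability(e_states, calib)
    w_det = detected_weight(e_states, calib)
    rate_states = cfg.molecule_brightness * q_states * w_det / (1.0 + calib.alpha)

    period = DEFAULT_PERIOD_NS
    slot_off = DEFAULT_SLOT_OFFSET_NS
    donor_slot_available = slot_off if cfg.pie else period

    static_w = model.default_static_weights()
    pi = None
    if n_states > 1:
        try:
            pi = stationary_distribution(model)
        except Exception:
            pi = static_w

    macro, micro, chan, slot = [], [], [], []
    truths: list[BurstTruth] = []
    t_cursor = 0.0
    for _ in range(cfg.burst_count):
        t_cursor += rng.exponential(cfg.mean_gap)
        dur = rng.exponential(cfg.mean_burst_duration)
        donor_only = rng.random() < calib.donor_only_fraction
        static = (not donor_only) and (rng.random() < model.static_fraction)
        if donor_only:
            seg_states = np.array([0])
            seg_bounds = np.array([0.0, dur])
            seg_e = np.array([0.0])
            seg_rate = np.array([cfg.molecule_brightness])
            seg_pred = np.array([acceptor_probability(np.array([0.0]), calib)[0]])
            seg_tau = np.array([pair.donor_lifetime])
            occ = np.zeros(n_states)
        else:
            if static or n_states == 1:
                s0 = int(rng.choice(n_states, p=static_w)) if n_states > 1 else 0
                seg_states = np.array([s0])
                seg_bounds = np.array([0.0, dur])
            else:
                traj = sample_trajectory(model, dur, rng=rng)
                seg_states = traj.states
                seg_bounds = np.append(traj.jump_times, dur)
            seg_e = e_states[seg_states]
            seg_rate = rate_states[seg_states]
            seg_pred = p_red[seg_states]
            seg_tau = tau_states[seg_states]
            occ = np.zeros(n_states)
            np.add.at(occ, seg_states, np.diff(seg_bounds))
            occ /= dur
        seg_dur = np.diff(seg_bounds)
        n_per_seg = rng.poisson(seg_rate * seg_dur)
        n_tot = int(n_per_seg.sum())
        if n_tot:
            seg_idx = np.repeat(np.arange(len(seg_states)), n_per_seg)
            t_in_seg = rng.random(n_tot) * seg_dur[seg_idx] + seg_bounds[:-1][seg_idx]
            is_red = rng.random(n_tot) < seg_pred[seg_idx]
            # crosstalk photons in red are donor-emitted: decide emission origin
            e_seg = seg_e[seg_idx]
            red_w = e_seg * calib.gamma + (1.0 - e_seg) * calib.alpha
            with np.errstate(invalid="ignore", divide="ignore"):
                p_fret_given_red = np.where(red_w > 0, e_seg * calib.gamma / np.maximum(red_w, 1e-300), 0.0)
            from_acceptor = is_red & (rng.random(n_tot) < p_fret_given_red)
            mt = np.empty(n_tot)
            nd = int((~from_acceptor).sum())
            mt[~from_acceptor] = rng.exponential(seg_tau[seg_idx][~from_acceptor]) + calib.irf_offset_ns
            mt[from_acceptor] = (
                rng.exponential(calib.acceptor_lifetime_ns, n_tot - nd) + calib.irf_offset_ns
            )
            if calib.irf_width_ns > 0:
                mt += rng.normal(0.0, calib.irf_width_ns, n_tot)
            mt = np.mod(mt, donor_slot_available)
            macro.append(t_cursor + t_in_seg)
            micro.append(mt)
            chan.append(np.where(is_red, CHANNEL_ACCEPTOR, CHANNEL_DONOR))
            slot.append(np.full(n_tot, SLOT_DONOR_EXC if cfg.pie else SLOT_NONE, np.int8))
        if cfg.pie and not donor_only:
            rate_rr = cfg.molecule_brightness * cfg.direct_excitation_brightness
            n_rr = rng.poisson(rate_rr * dur)
            if n_rr:
                t_rr = t_cursor + rng.random(n_rr) * dur
                mt_rr = rng.exponential(calib.acceptor_lifetime_ns, n_rr) + calib.irf_offset_ns
                if calib.irf_width_ns > 0:
                    mt_rr += rng.normal(0.0, calib.irf_width_ns, n_rr)
                mt_rr = slot_off + np.mod(mt_rr, period - slot_off)
                macro.append(t_rr)
                micro.append(mt_rr)
                chan.append(np.full(n_rr, CHANNEL_ACCEPTOR, np.int8))
                slot.append(np.full(n_rr, SLOT_ACCEPTOR_EXC, np.int8))
        # brightness-weighted species-average corrected efficiency
        if donor_only:
            true_e = 0.0
        else:
            wq = occ * q_states
            true_e = float((wq * e_states).sum() / wq.sum()) if wq.sum() > 0 else float(e_states[0])
        truths.append(BurstTruth(t_cursor, t_cursor + dur, donor_only, static, occ, true_e))
        t_cursor += dur

    total_t = t_cursor + rng.exponential(cfg.mean_gap)
    for ch, bg_rate in (
        (CHANNEL_DONOR, calib.background_donor),
        (CHANNEL_ACCEPTOR, calib.background_acceptor),
    ):
        n_bg = rng.poisson(bg_rate * total_t)
        if n_bg:
            mt_bg = rng.random(n_bg) * period
            macro.append(rng.random(n_bg) * total_t)
            micro.append(mt_bg)
            chan.append(np.full(n_bg, ch, np.int8))
            if cfg.pie:  # slot follows the micro-time gate
                s = np.where(mt_bg < slot_off, SLOT_DONOR_EXC, SLOT_ACCEPTOR_EXC).astype(np.int8)
            else:
                s = np.full(n_bg, SLOT_NONE, np.int8)
            slot.append(s)

    if macro:
        macro_a = np.concatenate(macro)
        order = np.argsort(macro_a, kind="stable")
        stream = PhotonStream(
            macro_a[order],
            np.concatenate(micro)[order],
            np.concatenate(chan)[order],
            np.concatenate(slot)[order],
            period_ns=period,
            slot_offset_ns=slot_off,
            duration=total_t,
        )
    else:
        stream = PhotonStream(
            np.empty(0), np.empty(0), np.empty(0, np.int8), np.empty(0, np.int8),
            duration=total_t,
        )
    return stream, GroundTruth(model, truths)


def simulate_telegraph_stream(
    model: KineticModel,
    brightness: float,
    duration: float,
    calib: CalibrationConfig | None = None,
    seed: int = 0,
) -> PhotonStream:
    """Photon stream from one molecule held in focus (no transits).

    The molecule's state follows the kinetic model for the whole record;
    photons are Poisson within each kinetic segment and routed
    donor/acceptor by the instantaneous species, which makes the channel
    autocorrelations single-exponential telegraph correlations with the
    model's relaxation times -- the reference signal for FCS validation.
    """
    calib = calib or CalibrationConfig()
    rng = np.random.default_rng(seed)
    e_states = model.efficiencies
    q_states = model.brightnesses
    p_red = acceptor_probability(e_states, calib)
    w_det = detected_weight(e_states, calib)
    rates = brightness * q_states * w_det / (1.0 + calib.alpha)
    if model.n_states == 2:
        # fast path: a two-state chain alternates deterministically, so
        # dwell times can be drawn in bulk
        k01 = model.rate_matrix[0, 1]
        k10 = model.rate_matrix[1, 0]
        s0 = int(rng.random() < k01 / (k01 + k10))  # stationary start
        n_guess = int(duration * (k01 + k10) / 2 * 1.2) + 64
        dwells = np.empty(0)
        while dwells.sum() < duration:
            states_blk = (np.arange(len(dwells), len(dwells) + n_guess) + s0) % 2
            new = rng.exponential(np.where(states_blk == 0, 1.0 / k01, 1.0 / k10))
            dwells = np.concatenate([dwells, new])
        bounds = np.concatenate([[0.0], np.cumsum(dwells)])
        stop = int(np.searchsorted(bounds, duration))
        seg_bounds = np.concatenate([bounds[:stop], [duration]])
        seg_states = (np.arange(len(seg_bounds) - 1) + s0) % 2
    elif model.n_states > 1:
        traj = sample_trajectory(model, duration, rng=rng)
        seg_states = traj.states
        seg_bounds = np.append(traj.jump_times, duration)
    else:
        seg_states = np.array([0])
        seg_bounds = np.array([0.0, duration])
    seg_dur = np.diff(seg_bounds)
    n_per_seg = rng.poisson(rates[seg_states] * seg_dur)
    n_tot = int(n_per_seg.sum())
    seg_idx = np.repeat(np.arange(len(seg_states)), n_per_seg)
    t = rng.random(n_tot) * seg_dur[seg_idx] + seg_bounds[:-1][seg_idx]
    is_red = rng.random(n_tot) < p_red[seg_states][seg_idx]
    tau_states = np.array([s.donor_lifetime for s in model.species])
    mt = np.mod(rng.exponential(np.where(is_red, calib.acceptor_lifetime_ns,
                                          tau_states[seg_states][seg_idx])), DEFAULT_PERIOD_NS)
    order = np.argsort(t, kind="stable")
    return PhotonStream(
        t[order], mt[order],
        np.where(is_red, CHANNEL_ACCEPTOR, CHANNEL_DONOR)[order].astype(np.int8),
        np.full(n_tot, SLOT_NONE, np.int8),
        duration=duration,
    )


# ---------------------------------------------------------------------------
# TIRF traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TIRFSimConfig:
    frame_time: float = 0.1
    trace_length: int = 1200
    n_traces: int = 100
    total_initial_counts: float = 1000.0  # per frame, above background
    bleach_rate_donor: float = 1.0 / 60.0  # 1/s
    bleach_rate_acceptor: float = 1.0 / 40.0
    background_donor: float = 50.0  # counts/frame
    background_acceptor: float = 50.0
    beta: float = 0.1  # donor -> acceptor camera bleed-through
    gamma: float = 1.0
    read_noise: float = 0.0  # Gaussian s.d., counts
    gain: float = 1.0
    poisson_noise: bool = True
    injection_time: float | None = None
    responder_fraction: float = 1.0
    post_model: KineticModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_time <= 0:
            raise DomainError("frame_time must be positive")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise DomainError("responder_fraction must lie in [0, 1]")


@dataclass
class TraceTruth:
    state_e: np.ndarray  # per-frame frame-averaged efficiency
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    is_responder: bool
    static_state: int | None


def _frame_efficiencies(model, dur, frame_time, n_frames, rng, initial_state=None):
    """Frame-integrated efficiency of one trajectory over [0, dur)."""
    traj = sample_trajectory(model, dur, rng=rng, initial_state=initial_state)
    e_states = model.efficiencies
    bounds = np.append(traj.jump_times, dur)
    edges = np.arange(n_frames + 1) * frame_time
    e_frames = np.zeros(n_frames)
    # overlap of each kinetic segment with each frame
    for s, t0, t1 in zip(traj.states, bounds[:-1], bounds[1:]):
        f0 = int(t0 / frame_time)
        f1 = min(int(np.ceil(t1 / frame_time)), n_frames)
        for f in range(f0, f1):
            ov = min(t1, edges[f + 1]) - max(t0, edges[f])
            if ov > 0:
                e_frames[f] += ov * e_states[s]
    last_state = traj.states[-1]
    return e_frames / frame_time, last_state


def simulate_tirf_traces(
    model: KineticModel, cfg: TIRFSimConfig
) -> tuple[list, list[TraceTruth]]:
    """Simulate immobilized-molecule camera traces.

    Per frame, donor and acceptor mean counts follow the current state's
    frame-averaged efficiency (anti-correlated by construction).  Each
    dye photobleaches in a single step at an exponential time; after an
    acceptor bleach the donor mean returns to the pre-bleach total.  With
    an injection configured, a ``responder_fraction`` of traces switches
    to ``post_model`` at ``injection_time``.
    Returns (traces, ground truth); traces are :class:`chromofret.tirf.TIRFTrace`.
    """
    from .tirf import TIRFTrace

    rng = np.random.default_rng(cfg.seed)
    n_frames = cfg.trace_length
    dur = n_frames * cfg.frame_time
    traces, truths = [], []
    for i in range(cfg.n_traces):
        responder = (
            cfg.injection_time is not None and rng.random() < cfg.responder_fraction
        )
        static_state = None
        if cfg.injection_time is not None:
            t_inj = cfg.injection_time
            n_pre = int(round(t_inj / cfg.frame_time))
            e_pre, last = _frame_efficiencies(model, n_pre * cfg.frame_time, cfg.frame_time, n_pre, rng)
            if responder and cfg.post_model is not None:
                e_post, _ = _frame_efficiencies(
                    cfg.post_model, dur - n_pre * cfg.frame_time, cfg.frame_time,
                    n_frames - n_pre, rng, initial_state=0,
                )
            else:
                e_post, _ = _frame_efficiencies(
                    model, dur - n_pre * cfg.frame_time, cfg.frame_time,
                    n_frames - n_pre, rng, initial_state=int(last),
                )
            e_frames = np.concatenate([e_pre, e_post])
        elif model.static_fraction > 0 and rng.random() < model.static_fraction:
            static_state = int(rng.choice(model.n_states, p=model.default_static_weights()))
            e_frames = np.full(n_frames, model.efficiencies[static_state])
        else:
            e_frames, _ = _frame_efficiencies(model, dur, cfg.frame_time, n_frames, rng)

        t_bleach_a = rng.exponential(1.0 / cfg.bleach_rate_acceptor) if cfg.bleach_rate_acceptor > 0 else np.inf
        t_bleach_d = rng.exponential(1.0 / cfg.bleach_rate_donor) if cfg.bleach_rate_donor > 0 else np.inf
        f_a = int(min(t_bleach_a / cfg.frame_time, 2 * n_frames))
        f_d_raw = int(min(t_bleach_d / cfg.frame_time, 2 * n_frames))
        tot = cfg.total_initial_counts
        d_mean = np.full(n_frames, cfg.background_donor, float)
        a_mean = np.full(n_frames, cfg.background_acceptor, float)
        if f_a <= f_d_raw:  # acceptor bleaches first (or never, both > length)
            fa = min(f_a, n_frames)
            # donor bleach clock keeps running; donor dies at its own time
            fd = min(f_d_raw, n_frames)
            live_d = np.arange(n_frames) < fd
            live_a = np.arange(n_frames) < fa
            e_eff = np.where(live_a, e_frames, 0.0)
            d_sig = np.where(live_d, tot * (1.0 - e_eff), 0.0)
            a_sig = np.where(live_d & live_a, tot * cfg.gamma * e_eff, 0.0)
            donor_bleach = fd if fd < n_frames else None
            acceptor_bleach = fa if fa < n_frames else None
        else:  # donor first: everything goes dark (no FRET excitation)
            fd = min(f_d_raw, n_frames)
            live = np.arange(n_frames) < fd
            d_sig = np.where(live, tot * (1.0 - e_frames), 0.0)
            a_sig = np.where(live, tot * cfg.gamma * e_frames, 0.0)
            donor_bleach = fd if fd < n_frames else None
            acceptor_bleach = None
        a_mean = a_mean + a_sig + cfg.beta * d_sig
        d_mean = d_mean + d_sig
        if cfg.poisson_noise:
            d_obs = rng.poisson(d_mean / cfg.gain) * cfg.gain
            a_obs = rng.poisson(a_mean / cfg.gain) * cfg.gain
        else:
            d_obs, a_obs = d_mean.copy(), a_mean.copy()
        if cfg.read_noise > 0:
            d_obs = d_obs + rng.normal(0.0, cfg.read_noise, n_frames)
            a_obs = a_obs + rng.normal(0.0, cfg.read_noise, n_frames)
        traces.append(
            TIRFTrace(
                trace_id=i,
                frame_time=cfg.frame_time,
                donor=np.asarray(d_obs, float),
                acceptor=np.asarray(a_obs, float),
                donor_bleach_frame=donor_bleach,
                acceptor_bleach_frame=acceptor_bleach,
            )
        )
        truths.append(TraceTruth(e_frames, donor_bleach, acceptor_bleach, responder, static_state))
    return traces, truths
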