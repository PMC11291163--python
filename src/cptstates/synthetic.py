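"""Synthetic rCPT sessions with known ground truth.

Generates paired behavior + calcium-trace datasets that emulate the
statistical structure of 45-minute touchscreen continuous-performance
sessions recorded at 10 Hz:

* a two-state (engaged/disengaged) latent Markov chain at frame resolution
  that gates the per-trial response probability,
* stage-2/stage-3 trial schedules (stimulus duration + limited hold,
  randomized ITIs, correction trials after false alarms),
* event-locked activity bumps in configurable up-/down-modulated neuron
  subsets, centered on the screen touch,
* state-dependent, spatially decaying pairwise correlation structure built
  from assembly factors, realized exactly through a Gaussian factor model
  with covariance (block assembly structure ⊙ exponential distance kernel),
* an exponential calcium-indicator kernel plus additive white noise.

Every downstream stage of the package can therefore be validated against
known modulated-neuron sets, latent state sequences and correlation targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .behavior import BehaviorSession
from .core import CalciumTraceSet
from . import io as _io

ENGAGED, DISENGAGED = 0, 1


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic session generator.

    Dwell times, correlation targets and the within/between tuples are
    ordered (engaged, disengaged).  ``event_effect_size`` and
    ``state_shift_sd`` are expressed in units of the per-neuron baseline SD
    (background + noise, before event structure is added).
    ``spatial_decay_rate`` uses the negative-k convention: correlations fall
    off as exp(k·d) with d in µm.
    """

    n_neurons: int = 150
    session_length_s: float = 2700.0
    frame_rate_hz: float = 10.0
    stage: str = "stage3"
    stimulus_duration_s: float = 2.0
    limited_hold_s: float = 2.5
    iti_choices_s: tuple = (2.0, 3.0)
    p_target: float | None = None  # default: 0.5 for stage3, 1.0 otherwise
    state_mean_dwell_s: tuple = (60.0, 60.0)
    p_respond_engaged: float = 0.9
    p_respond_disengaged: float = 0.05
    frac_up: float = 0.2
    frac_down: float = 0.1
    event_effect_size: float = 2.0
    frac_state_mod: float = 0.5
    state_shift_sd: float = 1.0
    corr_assemblies: int = 2
    within_assembly_corr: tuple = (0.25, 0.35)
    between_assembly_corr: tuple = (0.05, 0.10)
    spatial_decay_rate: float = -0.005
    fov_size_um: float = 450.0
    calcium_tau_s: float = 0.7
    noise_sd: float = 0.3
    min_latency_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_target is None:
            self.p_target = 0.5 if self.stage == "stage3" else 1.0
        probs = [
            self.p_target,
            self.p_respond_engaged,
            self.p_respond_disengaged,
            self.frac_up,
            self.frac_down,
            self.frac_state_mod,
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities/fractions must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if self.session_length_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("session length and frame rate must be positive")
        if self.calcium_tau_s <= 0 or any(d <= 0 for d in self.state_mean_dwell_s):
            raise ValueError("dwell times and calcium tau must be positive")
        for w, b in zip(self.within_assembly_corr, self.between_assembly_corr):
            if not (0.0 <= b <= w < 1.0):
                raise ValueError(
                    "need 0 <= between_assembly_corr <= within_assembly_corr < 1 per state"
                )

    @property
    def n_frames(self) -> int:
        return int(round(self.session_length_s * self.frame_rate_hz))

    @property
    def response_window_s(self) -> float:
        return self.stimulus_duration_s + self.limited_hold_s


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    state_sequence: np.ndarray  # per-frame, 0 = engaged, 1 = disengaged
    up_neurons: np.ndarray
    down_neurons: np.ndarray
    state_mod_neurons: np.ndarray
    assembly_assignment: dict  # state -> per-neuron assembly id
    event_times: list = field(default_factory=list)  # (time_s, event_type)

    def to_dict(self) -> dict:
        return {
            "state_sequence": self.state_sequence.tolist(),
            "up_neurons": self.up_neurons.tolist(),
            "down_neurons": self.down_neurons.tolist(),
            "state_mod_neurons": self.state_mod_neurons.tolist(),
            "assembly_assignment": {
                str(k): np.asarray(v).tolist() for k, v in self.assembly_assignment.items()
            },
            "event_times": [(float(t), e) for t, e in self.event_times],
        }


def generate_state_sequence(
    n_frames: int, mean_dwell_frames: tuple, rng: np.random.Generator
) -> np.ndarray:
    """Two-state Markov chain sampled as alternating geometric dwells.

    Stay probability per frame is 1 − 1/dwell, so dwell lengths are geometric
    with the configured mean; the chain starts in a state drawn from the
    stationary distribution.
    """
    d0, d1 = float(mean_dwell_frames[0]), float(mean_dwell_frames[1])
    states = np.empty(n_frames, dtype=int)
    s = int(rng.random() < d1 / (d0 + d1))  # stationary start
    t = 0
    while t < n_frames:
        dwell = rng.geometric(1.0 / (d0 if s == ENGAGED else d1))
        states[t : t + dwell] = s
        t += dwell
        s = 1 - s
    return states


def _simulate_trials(config: SyntheticConfig, states: np.ndarray, rng: np.random.Generator):
    """Run the touchscreen schedule against the latent state sequence."""
    rate = config.frame_rate_hz
    window = config.response_window_s
    trials, rewards = [], []
    t = 5.0  # settling time before the first trial
    correction_pending = False
    n_frames = len(states)
    while t + window < config.session_length_s - 1.0:
        if correction_pending:
            stim, correction = "S-", True
        else:
            stim = "S+" if rng.random() < config.p_target else "S-"
            correction = False
        frame = min(int(np.floor(t * rate)), n_frames - 1)
        p_resp = (
            config.p_respond_engaged
            if states[frame] == ENGAGED
            else config.p_respond_disengaged
        )
        responded = rng.random() < p_resp
        if responded:
            latency = rng.uniform(config.min_latency_s, window)
            resp_t = t + latency
            outcome = "hit" if stim == "S+" else "FA"
        else:
            resp_t = np.nan
            outcome = "miss" if stim == "S+" else "CR"
        trials.append(
            {
                "trial_index": len(trials),
                "stimulus": stim,
                "onset_s": t,
                "response_s": resp_t,
                "outcome": outcome,
                "correction": correction,
            }
        )
        iti = (
            rng.choice(config.iti_choices_s)
            if config.stage == "stage3"
            else config.iti_choices_s[0]
        )
        if outcome == "hit":
            collect = resp_t + rng.uniform(0.5, 2.0)
            rewards.append(collect)
            t = collect + iti
        elif outcome == "FA":
            t = resp_t + iti
        else:
            t = t + window + iti
        correction_pending = outcome == "FA"
    return pd.DataFrame(trials), rewards


def _state_covariance_cholesky(
    config: SyntheticConfig, distances: np.ndarray, assignment: np.ndarray, state: int
) -> np.ndarray:
    """Cholesky factor of the target background correlation for one state.

    Off-diagonal target: (within or between assembly level) × exp(k·d);
    diagonal 1.  The matrix is PSD as a sum of Schur products of PSD terms.
    """
    w = config.within_assembly_corr[state]
    b = config.between_assembly_corr[state]
    same = (assignment[:, None] == assignment[None, :]).astype(float)
    decay = np.exp(config.spatial_decay_rate * distances)
    sigma = (b + (w - b) * same) * decay
    np.fill_diagonal(sigma, 1.0)
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return np.linalg.cholesky(sigma + 1e-8 * np.eye(len(sigma)))


def _calcium_filter(x: np.ndarray, tau_s: float, rate: float) -> np.ndarray:
    """Causal exponential indicator kernel (unit peak), applied along time."""
    a = np.exp(-1.0 / (tau_s * rate))
    return lfilter([1.0], [1.0, -a], x, axis=-1)


def _raised_cosine_bumps(
    event_frames: np.ndarray, n_frames: int, width_s: float, rate: float
) -> np.ndarray:
    """Unit-peak raised-cosine bumps of the given width at each event frame."""
    half = int(round(width_s * rate / 2))
    kernel = 0.5 * (1.0 + np.cos(np.pi * np.arange(-half, half + 1) / half))
    out = np.zeros(n_frames)
    for f in event_frames:
        lo, hi = f - half, f + half + 1
        klo, khi = max(0, -lo), len(kernel) - max(0, hi - n_frames)
        out[max(0, lo) : min(n_frames, hi)] += kernel[klo:khi]
    return out


def generate_session(config: SyntheticConfig):
    """Simulate one session.

    Returns
    -------
    (BehaviorSession, CalciumTraceSet, GroundTruth)
    """
    rng = np.random.default_rng(config.seed)
    n, T, rate = config.n_neurons, config.n_frames, config.frame_rate_hz
    dwell_frames = tuple(d * rate for d in config.state_mean_dwell_s)
    states = generate_state_sequence(T, dwell_frames, rng)
    trials, reward_times = _simulate_trials(config, states, rng)

    centroids = rng.uniform(0.0, config.fov_size_um, size=(n, 2))
    diff = centroids[:, None, :] - centroids[None, :, :]
    distances = np.sqrt((diff**2).sum(-1))

    # assembly membership per state: nearest of k random spatial centers
    assignment = {}
    for s in (ENGAGED, DISENGAGED):
        centers = rng.uniform(0.0, config.fov_size_um, size=(config.corr_assemblies, 2))
        d2 = ((centroids[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        assignment[s] = np.argmin(d2, axis=1)

    # correlated background: per-state Gaussian factors with exact target corr
    z = rng.standard_normal((n, T))
    core = np.empty_like(z)
    for s in (ENGAGED, DISENGAGED):
        mask = states == s
        if mask.any():
            L = _state_covariance_cholesky(config, distances, assignment[s], s)
            core[:, mask] = L @ z[:, mask]
    background = _calcium_filter(core, config.calcium_tau_s, rate)
    traces = background + config.noise_sd * rng.standard_normal((n, T))
    base_sd = traces.std(axis=1)

    # planted modulated subsets
    order = rng.permutation(n)
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    up = np.sort(order[:n_up])
    down = np.sort(order[n_up : n_up + n_down])
    state_mod = np.sort(
        rng.choice(n, size=int(round(config.frac_state_mod * n)), replace=False)
    )

    # event-locked raised-cosine bumps at the touch, through the same kernel
    resp = trials.loc[trials["outcome"].isin(["hit", "FA"]), "response_s"].to_numpy(float)
    if len(resp) and config.event_effect_size != 0.0:
        ev_frames = np.floor(resp * rate).astype(int)
        ev_frames = ev_frames[(ev_frames >= 0) & (ev_frames < T)]
        bump = _raised_cosine_bumps(ev_frames, T, width_s=2.0, rate=rate)
        single = _raised_cosine_bumps(np.array([T // 2]), T, 2.0, rate)
        peak_gain = _calcium_filter(single, config.calcium_tau_s, rate).max()
        amp = np.zeros(n)
        amp[up] = 1.0
        amp[down] = -1.0
        scale = config.event_effect_size * base_sd / peak_gain
        traces += (amp * scale)[:, None] * _calcium_filter(
            bump, config.calcium_tau_s, rate
        )[None, :]

    # state-gated mean shift (elevated when engaged) on a neuron subset
    if config.state_shift_sd != 0.0 and len(state_mod):
        shift = np.zeros(n)
        shift[state_mod] = config.state_shift_sd * base_sd[state_mod]
        traces += shift[:, None] * (states == ENGAGED)[None, :]

    trace_set = CalciumTraceSet(
        traces=traces, frame_rate_hz=rate, centroids_um=centroids
    )
    session = BehaviorSession(
        trials=trials, session_length_s=config.session_length_s, stage=config.stage
    )
    event_rows = _io.session_to_events(
        session,
        window_s=config.response_window_s,
        extra_events=pd.DataFrame(
            {
                "time_s": reward_times,
                "event_type": "reward_collect",
                "correction_flag": False,
            }
        ),
    )
    truth = GroundTruth(
        state_sequence=states,
        up_neurons=up,
        down_neurons=down,
        state_mod_neurons=state_mod,
        assembly_assignment=assignment,
        event_times=[(float(t), e) for t, e in zip(event_rows["time_s"], event_rows["event_type"])],
    )
    return session, trace_set, truth


def generate_null_traces(
    n_neurons: int,
    n_frames: int,
    seed: int,
    ar_coef: float = 0.8,
    frame_rate_hz: float = 10.0,
    fov_size_um: float = 450.0,
) -> CalciumTraceSet:
    """Stationary AR(1) noise with no event-locked structure.

    Unit marginal variance regardless of the autoregressive coefficient, so
    calibration runs are comparable across coefficients.
    """
    if n_neurons <= 0 or n_frames <= 0:
        raise ValueError("n_neurons and n_frames must be positive")
    if not (-1.0 < ar_coef < 1.0):
        raise ValueError("ar_coef must lie in (-1, 1) for stationarity")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_neurons, n_frames))
    x = lfilter([np.sqrt(1.0 - ar_coef**2)], [1.0, -ar_coef], eps, axis=-1)
    centroids = rng.uniform(0.0, fov_size_um, size=(n_neurons, 2))
    return CalciumTraceSet(traces=x, frame_rate_hz=frame_rate_hz, centroids_um=centroids)


def generate_cohort(
    config: SyntheticConfig,
    n_animals: int,
    base_seed: int,
    response_jitter: float = 0.0,
):
    """Independent per-animal sessions with deterministically derived seeds.

    ``response_jitter`` scales multiplicative uniform jitter applied to the
    per-state response probabilities, creating inter-animal variability.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_animals + 1) % (2**31)
    jit_rng = np.random.default_rng(seeds[-1])
    out = []
    for i in range(n_animals):
        cfg = SyntheticConfig(**{**asdict(config), "seed": int(seeds[i])})
        if response_jitter > 0.0:
            u = jit_rng.uniform(-1.0, 1.0, size=2)
            cfg.p_respond_engaged = float(
                np.clip(config.p_respond_engaged * (1 + response_jitter * u[0]), 0, 1)
            )
            cfg.p_respond_disengaged = float(
                np.clip(config.p_respond_disengaged * (1 + response_jitter * u[1]), 0, 1)
            )
        out.append(generate_session(cfg))
    return out


def write_session(
    session: BehaviorSession,
    traces: CalciumTraceSet,
    truth: GroundTruth,
    outdir: str | Path,
) -> dict:
    """Write the standard delimited-text bundle for one session."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traces": outdir / "traces.csv",
        "centroids": outdir / "centroids.csv",
        "events": outdir / "events.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    _io.write_traces(traces, paths["traces"])
    _io.write_centroids(traces, paths["centroids"])
    events = pd.DataFrame(
        [(t, e, False) for t, e in truth.event_times],
        columns=["time_s", "event_type", "correction_flag"],
    )
    # correction flags live on the trial table; regenerate the full stream
    events = _io.session_to_events(
        session,
        extra_events=events[events["event_type"] == "reward_collect"],
    )
    _io.write_events(events, paths["events"])
    _io.write_json(truth.to_dict(), paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
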