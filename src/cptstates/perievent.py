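"""Peri-event modulation classification against a circular-permutation null.

Each neuron's Δ activity is the mean (over events) difference between its
average z-scored activity in a post-event and a pre-event statistical
window.  The null distribution is built by circularly shifting all event
times together relative to the trace (one shared uniform offset per
shuffle), which preserves both the trace autostructure and the inter-event
intervals.  A two-tailed test at level α labels neurons up-, down- or
non-modulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehaviorSession
from .core import CalciumTraceSet, time_to_frame

LABELS = ("up", "down", "non")


@dataclass
class PeriEventWindows:
    """Analysis windows (s) and test settings.

    The visual window is the stretch extracted for averaging/display; the
    statistical windows are the pre/post stretches entering Δ.  Frame
    conversion floors times at the frame rate; windows are half-open
    [start, end).
    """

    visual_pre_s: float = 8.0
    visual_post_s: float = 8.0
    stat_pre_start_s: float = 3.0
    stat_pre_end_s: float = 0.0
    stat_post_start_s: float = 0.0
    stat_post_end_s: float = 3.0
    n_shuffles: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.stat_pre_start_s < self.stat_pre_end_s:
            raise ValueError("stat_pre_start_s must be >= stat_pre_end_s")
        if self.stat_post_end_s < self.stat_post_start_s:
            raise ValueError("stat_post_end_s must be >= stat_post_start_s")
        if (
            self.visual_pre_s < self.stat_pre_start_s
            or self.visual_post_s < self.stat_post_end_s
        ):
            raise ValueError("visual windows must contain the statistical windows")

    def frames(self, rate: float) -> dict:
        return {
            "vis_pre": int(round(self.visual_pre_s * rate)),
            "vis_post": int(round(self.visual_post_s * rate)),
            "pre_a": int(round(self.stat_pre_start_s * rate)),
            "pre_b": int(round(self.stat_pre_end_s * rate)),
            "post_a": int(round(self.stat_post_start_s * rate)),
            "post_b": int(round(self.stat_post_end_s * rate)),
        }


@dataclass
class PeriEventResult:
    """Per-neuron modulation results for one event type / alignment."""

    neuron_ids: np.ndarray
    delta: np.ndarray
    null_deltas: np.ndarray  # (n_neurons, n_shuffles)
    boot_p: np.ndarray
    labels: np.ndarray  # "up" | "down" | "non"
    mean_trace: np.ndarray  # (n_neurons, visual-window frames), z-units
    n_events: int
    n_dropped: int
    alpha: float

    def proportions(self) -> dict:
        n = len(self.labels)
        return {lab: float(np.mean(self.labels == lab)) for lab in LABELS} | {"n": n}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.neuron_ids,
                "delta": self.delta,
                "boot_p": self.boot_p,
                "label": self.labels,
            }
        )


def zscore_traces(ts: CalciumTraceSet) -> CalciumTraceSet:
    """Per-neuron z-score over the full session.

    Zero-variance neurons cannot be standardized; they are dropped with a
    warning (ids preserved on the survivors).
    """
    sd = ts.traces.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance neuron(s) from z-scoring"
        )
    sub = ts.subset(np.nonzero(keep)[0])
    mu = sub.traces.mean(axis=1, keepdims=True)
    sd = sub.traces.std(axis=1, keepdims=True)
    return CalciumTraceSet(
        traces=(sub.traces - mu) / sd,
        frame_rate_hz=sub.frame_rate_hz,
        centroids_um=sub.centroids_um,
        neuron_ids=sub.neuron_ids,
    )


def extract_peri_event(
    ts: CalciumTraceSet, event_times_s: np.ndarray, windows: PeriEventWindows
):
    """Slice the visual window around each event.

    Events whose full visual window does not fit inside the session are
    dropped (no padding) and counted.

    Returns
    -------
    tensor : ndarray (n_kept_events, n_neurons, vis_pre + 1 + vis_post)
    kept : boolean mask over the input events
    """
    f = windows.frames(ts.frame_rate_hz)
    frames = time_to_frame(event_times_s, ts.frame_rate_hz)
    kept = (frames - f["vis_pre"] >= 0) & (frames + f["vis_post"] < ts.n_frames)
    frames = frames[kept]
    if frames.size == 0:
        raise ValueError("no events with a full visual window inside the session")
    offsets = np.arange(-f["vis_pre"], f["vis_post"] + 1)
    tensor = ts.traces[:, frames[:, None] + offsets[None, :]]  # (n, ev, L)
    return np.transpose(tensor, (1, 0, 2)), kept


def delta_activity(tensor: np.ndarray, windows: PeriEventWindows, frame_rate_hz: float):
    """Δ = mean over events of (post-window mean − pre-window mean) per neuron."""
    f = windows.frames(frame_rate_hz)
    c = f["vis_pre"]  # event frame within the visual slice
    pre = tensor[:, :, c - f["pre_a"] : c - f["pre_b"]].mean(axis=2)
    post = tensor[:, :, c + f["post_a"] : c + f["post_b"]].mean(axis=2)
    return (post - pre).mean(axis=0)


def _delta_at_offsets(
    traces: np.ndarray,
    event_frames: np.ndarray,
    windows: PeriEventWindows,
    frame_rate_hz: float,
    offsets: np.ndarray,
    chunk: int = 200,
) -> np.ndarray:
    """Δ for circularly shifted event frames, wrap-around windows.

    Window sums come from a cumulative sum over a circularly padded copy of
    the trace, so shifted events near the session edges wrap rather than
    being dropped (keeping the null size fixed across shuffles).
    """
    n, T = traces.shape
    f = windows.frames(frame_rate_hz)
    pad = max(f["pre_a"], f["post_b"])
    ext = np.concatenate([traces[:, T - pad :], traces, traces[:, :pad]], axis=1)
    cs = np.concatenate([np.zeros((n, 1)), np.cumsum(ext, axis=1)], axis=1)
    npre = f["pre_a"] - f["pre_b"]
    npost = f["post_b"] - f["post_a"]
    out = np.empty((n, len(offsets)))
    for lo in range(0, len(offsets), chunk):
        off = offsets[lo : lo + chunk]
        base = (event_frames[None, :] + off[:, None]) % T + pad  # (m, ev)
        pre = (cs[:, base - f["pre_b"]] - cs[:, base - f["pre_a"]]) / npre
        post = (cs[:, base + f["post_b"]] - cs[:, base + f["post_a"]]) / npost
        out[:, lo : lo + len(off)] = (post - pre).mean(axis=2)
    return out


def circular_permutation_null(
    ts: CalciumTraceSet,
    event_times_s: np.ndarray,
    windows: PeriEventWindows,
    exhaustive: bool = False,
) -> np.ndarray:
    """Null Δ distribution from circular shifts of the event times.

    Each shuffle draws one uniform offset in [1, T−1] frames and shifts all
    events by it modulo the session length; the same offset applies to every
    neuron within a shuffle.  With ``exhaustive=True`` all T−1 offsets are
    enumerated instead of sampled.
    """
    T = ts.n_frames
    f = windows.frames(ts.frame_rate_hz)
    if T <= f["pre_a"] + f["post_b"]:
        raise ValueError("session shorter than the statistical window span")
    frames = time_to_frame(event_times_s, ts.frame_rate_hz) % T
    if exhaustive:
        offsets = np.arange(1, T)
    else:
        rng = np.random.default_rng(windows.seed)
        offsets = rng.integers(1, T, size=windows.n_shuffles)
    return _delta_at_offsets(ts.traces, frames, windows, ts.frame_rate_hz, offsets)


def classify_modulation(
    delta: np.ndarray, null_deltas: np.ndarray, alpha: float = 0.05
):
    """Two-tailed bootstrap classification.

    boot_p is the plain fraction of null Δ values ≥ the observed Δ (ties
    count as ≥); up-modulated if boot_p < α/2, down-modulated if
    boot_p > 1 − α/2, non-modulated otherwise.
    """
    boot_p = (null_deltas >= delta[:, None]).mean(axis=1)
    labels = np.full(len(delta), "non", dtype=object)
    labels[boot_p < alpha / 2.0] = "up"
    labels[boot_p > 1.0 - alpha / 2.0] = "down"
    return boot_p, labels


def _event_times_for(
    session: BehaviorSession, event_type: str, alignment: str
) -> np.ndarray:
    outcomes = {"hit": ["hit"], "fa": ["FA"], "any": ["hit", "FA"]}[event_type]
    t = session.trials[session.trials["outcome"].isin(outcomes)]
    col = "response_s" if alignment == "touch" else "onset_s"
    times = t[col].to_numpy(float)
    return np.sort(times[~np.isnan(times)])


def classify_perievent(
    ts: CalciumTraceSet,
    session: BehaviorSession,
    event_type: str = "hit",
    alignment: str = "touch",
    windows: PeriEventWindows | None = None,
) -> PeriEventResult:
    """Full pipeline: z-score → extract → Δ → circular null → labels.

    ``event_type`` ∈ {hit, fa, any}; ``alignment`` anchors the windows to the
    screen touch or the stimulus onset of the same responsive trials.
    """
    if windows is None:
        windows = PeriEventWindows()
    if event_type not in ("hit", "fa", "any"):
        raise ValueError("event_type must be one of hit, fa, any")
    if alignment not in ("touch", "stimulus"):
        raise ValueError("alignment must be 'touch' or 'stimulus'")
    times = _event_times_for(session, event_type, alignment)
    if times.size == 0:
        raise ValueError(f"session has no {event_type} events")
    tsz = zscore_traces(ts)
    tensor, kept = extract_peri_event(tsz, times, windows)
    delta = delta_activity(tensor, windows, tsz.frame_rate_hz)
    null = circular_permutation_null(tsz, times[kept], windows)
    boot_p, labels = classify_modulation(delta, null, windows.alpha)
    return PeriEventResult(
        neuron_ids=tsz.neuron_ids,
        delta=delta,
        null_deltas=null,
        boot_p=boot_p,
        labels=labels,
        mean_trace=tensor.mean(axis=0),
        n_events=int(kept.sum()),
        n_dropped=int((~kept).sum()),
        alpha=windows.alpha,
    )


def modulation_overlap(labels_a: np.ndarray, labels_b: np.ndarray) -> dict:
    """Venn counts of up/down modulation between two classifications.

    Both label vectors must cover the same neurons in the same order.
    """
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must cover the same neuron set")
    out = {}
    for lab in ("up", "down"):
        a, b = labels_a == lab, labels_b == lab
        out[lab] = {
            "only_a": int((a & ~b).sum()),
            "only_b": int((~a & b).sum()),
            "both": int((a & b).sum()),
        }
    return out
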