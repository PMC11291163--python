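"""Behavioral scoring for the rodent continuous performance test (rCPT).

Sessions are sequences of discrimination trials: a target (S+) or non-target
(S−) appears on a touchscreen for a stimulus-duration window plus a limited
hold.  A touch on S+ is a hit, a touch on S− a false alarm (FA); withheld
responses are misses (S+) or correct rejections (CR).  This module computes
outcome counts, signal-detection scores (d′ and criterion c), response-latency
series, disengagement periods (latency peaks), and the stage-advancement
decisions used during training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

TRIAL_COLUMNS = [
    "trial_index",
    "stimulus",  # "S+" or "S-"
    "onset_s",
    "response_s",  # NaN when no touch
    "outcome",  # hit | miss | FA | CR
    "correction",  # bool: correction trial (re-presented S− after a FA)
]

ACTIVE_OUTCOMES = ("hit", "FA")


@dataclass
class BehaviorSession:
    """Ordered trial records for one rCPT session."""

    trials: pd.DataFrame
    session_length_s: float
    stage: str = "stage3"

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trials table missing columns: {missing}")
        t = self.trials
        onsets = t["onset_s"].to_numpy(float)
        if len(onsets) and not np.all(np.diff(onsets) > 0):
            raise ValueError("trial onsets must be strictly increasing")
        resp = t["response_s"].to_numpy(float)
        has_resp = ~np.isnan(resp)
        if np.any(resp[has_resp] < onsets[has_resp]):
            raise ValueError("response_s must be >= onset_s")
        bad_splus = t[(t["stimulus"] == "S+") & ~t["outcome"].isin(["hit", "miss"])]
        bad_sminus = t[(t["stimulus"] == "S-") & ~t["outcome"].isin(["FA", "CR"])]
        if len(bad_splus) or len(bad_sminus):
            raise ValueError("outcomes inconsistent with stimulus identity")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def response_times(self, outcomes=ACTIVE_OUTCOMES) -> np.ndarray:
        """Times (s) of active responses (hits and FAs by default), sorted."""
        t = self.trials
        sel = t[t["outcome"].isin(outcomes)]["response_s"].to_numpy(float)
        return np.sort(sel[~np.isnan(sel)])

    def event_times(self, outcome: str) -> np.ndarray:
        """Event timestamps for one outcome: response time for hit/FA,
        end of the response window is not recorded, so misses/CRs use onset."""
        t = self.trials
        sel = t[t["outcome"] == outcome]
        if outcome in ACTIVE_OUTCOMES:
            out = sel["response_s"].to_numpy(float)
        else:
            out = sel["onset_s"].to_numpy(float)
        return np.sort(out[~np.isnan(out)])


@dataclass
class SessionScore:
    """Signal-detection summary of one session (correction trials excluded)."""

    hits: int
    misses: int
    FAs: int
    CRs: int
    HR: float
    FAR: float
    d_prime: float
    c: float
    mean_latency_hit_s: float
    mean_latency_FA_s: float
    rate_corrected: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class DisengagementPeriods:
    """Inter-response latency peaks exceeding the session threshold.

    The threshold is mean(latency) + 2·SD(latency) computed over the session's
    inter-response interval series; each period spans the gap between the two
    responses that bracket it.
    """

    latencies_s: np.ndarray
    threshold_s: float
    periods: list = field(default_factory=list)  # list of (start_s, end_s)

    @property
    def total_duration_s(self) -> float:
        return float(sum(e - s for s, e in self.periods))


def _corrected_rate(k: int, n: int) -> tuple[float, bool]:
    """Proportion k/n with a log-linear correction when the rate is 0 or 1,
    keeping the normal quantile finite."""
    if n == 0:
        return np.nan, False
    p = k / n
    if p in (0.0, 1.0):
        return (k + 0.5) / (n + 1), True
    return p, False


def score_session(session: BehaviorSession, require_both: bool | None = None) -> SessionScore:
    """Compute outcome counts, hit/FA rates, d′ and criterion c.

    Correction trials (re-presented S− after a false alarm) are excluded from
    all counts.  Rates at 0 or 1 are log-linearly corrected so z stays finite.
    d′ = z(HR) − z(FAR); c = −(z(HR) + z(FAR))/2 with z the standard-normal
    quantile.

    Parameters
    ----------
    require_both:
        If True, raise when either stimulus class is absent.  Defaults to
        True for stage-3 sessions and False otherwise (stage 1/2 sessions
        have no S− trials; their FAR, d′ and c are NaN).
    """
    if require_both is None:
        require_both = session.stage == "stage3"
    t = session.trials[~session.trials["correction"].astype(bool)]
    hits = int((t["outcome"] == "hit").sum())
    misses = int((t["outcome"] == "miss").sum())
    fas = int((t["outcome"] == "FA").sum())
    crs = int((t["outcome"] == "CR").sum())
    n_splus, n_sminus = hits + misses, fas + crs
    if require_both and (n_splus == 0 or n_sminus == 0):
        raise ValueError(
            f"cannot score: {n_splus} S+ and {n_sminus} S- non-correction trials"
        )
    hr, corr_h = _corrected_rate(hits, n_splus)
    far, corr_f = _corrected_rate(fas, n_sminus)
    if np.isnan(hr) or np.isnan(far):
        d_prime = c = np.nan
    else:
        zh, zf = norm.ppf(hr), norm.ppf(far)
        d_prime = zh - zf
        c = -(zh + zf) / 2.0

    def _mean_latency(outcome: str) -> float:
        sel = t[t["outcome"] == outcome]
        lat = (sel["response_s"] - sel["onset_s"]).to_numpy(float)
        return float(np.mean(lat)) if len(lat) else np.nan

    return SessionScore(
        hits=hits,
        misses=misses,
        FAs=fas,
        CRs=crs,
        HR=hr,
        FAR=far,
        d_prime=d_prime,
        c=c,
        mean_latency_hit_s=_mean_latency("hit"),
        mean_latency_FA_s=_mean_latency("FA"),
        rate_corrected=corr_h or corr_f,
    )


def response_latency_series(session: BehaviorSession) -> np.ndarray:
    """Inter-response intervals (s) between consecutive active responses.

    Hits and FAs are merged in time order; misses and CRs do not contribute.
    Fewer than two active responses yields an empty series with a warning.
    """
    times = session.response_times()
    if len(times) < 2:
        warnings.warn("fewer than 2 active responses; latency series is empty")
        return np.empty(0)
    return np.diff(times)


def detect_disengagement_periods(
    latencies_s: np.ndarray, response_times_s: np.ndarray | None = None
) -> DisengagementPeriods:
    """Identify non-responsive periods as latency peaks above mean + 2·SD.

    ``response_times_s`` (the n+1 response timestamps bounding the n
    intervals) locates each period in session time; without it, spans are
    reported on a cumulative clock starting at zero.  SD is the sample (n−1)
    standard deviation.
    """
    latencies_s = np.asarray(latencies_s, dtype=float)
    if len(latencies_s) < 2:
        raise ValueError("need at least 2 inter-response intervals")
    sd = float(np.std(latencies_s, ddof=1))
    threshold = float(np.mean(latencies_s)) + 2.0 * sd
    if sd == 0.0:
        warnings.warn("zero-variance latency series; threshold equals the mean")
    if response_times_s is None:
        response_times_s = np.concatenate([[0.0], np.cumsum(latencies_s)])
    else:
        response_times_s = np.asarray(response_times_s, dtype=float)
        if len(response_times_s) != len(latencies_s) + 1:
            raise ValueError("response_times_s must bound the latency series")
    periods = [
        (float(response_times_s[i]), float(response_times_s[i + 1]))
        for i in np.nonzero(latencies_s > threshold)[0]
    ]
    return DisengagementPeriods(latencies_s=latencies_s, threshold_s=threshold, periods=periods)


def disengagement_from_session(session: BehaviorSession) -> DisengagementPeriods:
    """Convenience wrapper: latency series and periods from a session."""
    times = session.response_times()
    lat = response_latency_series(session)
    return detect_disengagement_periods(lat, response_times_s=times)


@dataclass
class StageDecision:
    met: bool
    session_index: int | None  # 0-based index of the session meeting criterion
    criterion: str


def check_stage_criteria(
    scores: list[SessionScore], stage: str, recording_gate: bool = False
) -> StageDecision:
    """Stage-advancement / recording-gate decisions over chronological scores.

    Stages 1–2 advance after ≥60 hits in two consecutive sessions; the
    recording gate for moving past a stage-2 recording session is ≥55 hits in
    that single session.  Stage 3 advances after d′ ≥ 0.6 on two consecutive
    sessions.
    """
    if not scores:
        raise ValueError("scores list is empty")
    if recording_gate:
        ok = np.array([s.hits >= 55 for s in scores])
        idx = int(np.argmax(ok)) if ok.any() else None
        return StageDecision(bool(ok.any()), idx, "hits >= 55 in recording session")
    if stage in ("stage1", "stage2"):
        vals = np.array([s.hits for s in scores], dtype=float)
        thresh, crit = 60.0, "hits >= 60 on two consecutive sessions"
    elif stage == "stage3":
        vals = np.array([s.d_prime for s in scores], dtype=float)
        thresh, crit = 0.6, "d' >= 0.6 on two consecutive sessions"
    else:
        raise ValueError(f"unknown stage {stage!r}")
    ok = vals >= thresh
    pairs = ok[:-1] & ok[1:]
    if pairs.any():
        return StageDecision(True, int(np.argmax(pairs)) + 1, crit)
    return StageDecision(False, None, crit)
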