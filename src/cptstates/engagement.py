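"""Engagement-state inference from population activity with a Gaussian HMM.

Pipeline: truncate the session, z-score each neuron, smooth with a centered
1-s moving average, reduce with PCA, and fit a diagonal-covariance Gaussian
HMM to the leading component scores.  The decoded state that captures the
larger share of behavioral-response frames is labeled "engaged"; the
other, which preferentially contains latency-peak (non-responsive) periods,
is "disengaged".  Model selection (state count), contiguous three-fold
cross-validation and event-conditioned state posteriors mirror the standard
validation battery for this model class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy import stats
from sklearn.decomposition import PCA

from .behavior import BehaviorSession, DisengagementPeriods
from .core import CalciumTraceSet, time_to_frame


@dataclass
class HmmConfig:
    """Preprocessing and fitting parameters.

    ``truncate_s`` keeps the first 45 min of recording; smoothing uses a
    10-frame (1 s at 10 Hz) center-aligned moving average.  PCA retains
    ``n_pcs_retained`` components for the variance QC while the HMM is fit
    on the first ``n_pcs_hmm`` scores.  EM runs up to ``max_iter`` iterations
    with ``n_restarts`` seeded restarts, keeping the best train likelihood.
    """

    truncate_s: float = 2700.0
    smooth_window_frames: int = 10
    n_pcs_retained: int = 45
    n_pcs_hmm: int = 10
    n_states: int = 2
    max_iter: int = 200
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs_hmm > self.n_pcs_retained:
            raise ValueError("n_pcs_hmm must not exceed n_pcs_retained")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")


@dataclass
class PreprocessedPCs:
    pcs: np.ndarray  # (n_frames, n_pcs_hmm)
    cumulative_variance_retained: float
    frame_rate_hz: float


@dataclass
class StateModel:
    """Fitted diagonal-covariance Gaussian HMM in PC space."""

    hmm: GaussianHMM
    n_states: int
    means: np.ndarray
    covars: np.ndarray
    transmat: np.ndarray
    startprob: np.ndarray
    log_likelihood: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "means": self.means.tolist(),
            "covars": self.covars.tolist(),
            "transmat": self.transmat.tolist(),
            "startprob": self.startprob.tolist(),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
        }


@dataclass
class StateSequence:
    states: np.ndarray  # per-frame label in {0..n_states-1}
    frame_rate_hz: float
    engaged_label: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.states)

    def occupancy(self) -> np.ndarray:
        return np.bincount(self.states, minlength=int(self.states.max()) + 1) / len(
            self.states
        )


@dataclass
class EngagementStats:
    """Event-conditioned state posteriors and engagement summaries."""

    posteriors: pd.DataFrame  # rows: event types; columns: state indices
    engaged_label: int
    p_responses_engaged: float
    disengagement_posterior: np.ndarray | None
    p_periods_disengaged: float | None
    n_event_frames: dict

    def to_dict(self) -> dict:
        return {
            "posteriors": {
                str(k): v for k, v in self.posteriors.to_dict(orient="index").items()
            },
            "engaged_label": int(self.engaged_label),
            "p_responses_engaged": float(self.p_responses_engaged),
            "disengagement_posterior": None
            if self.disengagement_posterior is None
            else self.disengagement_posterior.tolist(),
            "p_periods_disengaged": None
            if self.p_periods_disengaged is None
            else float(self.p_periods_disengaged),
            "n_event_frames": self.n_event_frames,
        }


def preprocess_for_hmm(ts: CalciumTraceSet, config: HmmConfig) -> PreprocessedPCs:
    """Truncate → z-score → centered moving average → PCA scores."""
    n_keep = int(round(config.truncate_s * ts.frame_rate_hz))
    if ts.n_frames < n_keep:
        warnings.warn(
            f"session shorter than {config.truncate_s} s; using all {ts.n_frames} frames"
        )
        n_keep = ts.n_frames
    x = ts.traces[:, :n_keep]
    sd = x.std(axis=1)
    if np.all(sd == 0):
        raise ValueError("all neurons are constant over the truncated session")
    if np.any(sd == 0):
        warnings.warn(f"excluding {int((sd == 0).sum())} zero-variance neuron(s)")
        x = x[sd > 0]
    z = stats.zscore(x, axis=1)
    smoothed = (
        pd.DataFrame(z.T)
        .rolling(config.smooth_window_frames, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )  # (frames, neurons)
    n_comp = min(config.n_pcs_retained, *smoothed.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(smoothed)
    n_hmm = min(config.n_pcs_hmm, n_comp)
    if n_hmm < config.n_pcs_hmm:
        warnings.warn(f"only {n_hmm} PCs available; requested {config.n_pcs_hmm}")
    return PreprocessedPCs(
        pcs=scores[:, :n_hmm],
        cumulative_variance_retained=float(pca.explained_variance_ratio_.sum()),
        frame_rate_hz=ts.frame_rate_hz,
    )


def _restart_seeds(config: HmmConfig, n: int) -> np.ndarray:
    return np.random.SeedSequence(config.seed).generate_state(n) % (2**31)


def fit_hmm(pcs: np.ndarray, config: HmmConfig, n_states: int | None = None) -> StateModel:
    """EM fit with seeded restarts; the best train log-likelihood wins."""
    pcs = np.asarray(pcs, dtype=float)
    if not np.isfinite(pcs).all():
        raise ValueError("PC matrix contains non-finite values")
    k = config.n_states if n_states is None else n_states
    best = None
    for s in _restart_seeds(config, config.n_restarts):
        model = GaussianHMM(
            n_components=k,
            covariance_type="diag",
            n_iter=config.max_iter,
            random_state=int(s),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(pcs)
            ll = float(model.score(pcs))
        if best is None or ll > best[1]:
            best = (model, ll)
    model, ll = best
    return StateModel(
        hmm=model,
        n_states=k,
        means=model.means_,
        covars=model.covars_,
        transmat=model.transmat_,
        startprob=model.startprob_,
        log_likelihood=ll,
        converged=bool(model.monitor_.converged),
    )


def select_state_count(
    pcs: np.ndarray, config: HmmConfig, ks: tuple = (1, 2, 3)
) -> pd.DataFrame:
    """Train log-likelihood per candidate state count (shared seed policy)."""
    if not len(ks):
        raise ValueError("ks must be non-empty")
    rows = []
    for k in ks:
        m = fit_hmm(pcs, config, n_states=k)
        rows.append({"n_states": k, "log_likelihood": m.log_likelihood, "converged": m.converged})
    return pd.DataFrame(rows)


def crossvalidate_hmm(pcs: np.ndarray, config: HmmConfig, folds: int = 3) -> pd.DataFrame:
    """Contiguous forward-chaining cross-validation.

    The session is cut into four equal contiguous quarters (remainder frames
    appended to the last).  Fold f trains on the first f quarters and tests
    on quarter f+1, so the model always trains strictly on the past.
    Log-likelihoods are reported per frame for comparability.
    """
    T = len(pcs)
    q = T // 4
    if q < 2 * config.n_states:
        raise ValueError("too few frames per quarter for cross-validation")
    bounds = [0, q, 2 * q, 3 * q, T]
    rows = []
    for f in range(1, folds + 1):
        train = pcs[: bounds[f]]
        test = pcs[bounds[f] : bounds[f + 1]]
        m = fit_hmm(train, config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(
                {
                    "fold": f,
                    "train_ll_per_frame": float(m.hmm.score(train)) / len(train),
                    "test_ll_per_frame": float(m.hmm.score(test)) / len(test),
                    "n_train": len(train),
                    "n_test": len(test),
                }
            )
    return pd.DataFrame(rows)


def decode_states(
    model: StateModel, pcs: np.ndarray, method: str = "viterbi", frame_rate_hz: float = 10.0
) -> StateSequence:
    """Most-probable state path (Viterbi) or per-frame posterior argmax."""
    pcs = np.asarray(pcs, dtype=float)
    if pcs.shape[1] != model.means.shape[1]:
        raise ValueError("PC dimensionality does not match the fitted model")
    if method == "viterbi":
        states = model.hmm.predict(pcs)
    elif method == "posterior":
        states = model.hmm.predict_proba(pcs).argmax(axis=1)
    else:
        raise ValueError("method must be 'viterbi' or 'posterior'")
    return StateSequence(states=states, frame_rate_hz=frame_rate_hz)


def _event_frames(times_s: np.ndarray, rate: float, n_frames: int) -> np.ndarray:
    frames = np.unique(time_to_frame(times_s, rate))
    return frames[(frames >= 0) & (frames < n_frames)]


def event_state_posteriors(
    seq: StateSequence,
    session: BehaviorSession,
    frame_rate_hz: float = 10.0,
    periods: DisengagementPeriods | None = None,
) -> EngagementStats:
    """Fraction of event frames spent in each decoded state.

    Hit, Mistake (false alarm) and Any (their union) timestamps are floored
    to frame indices and binarized; P(state i | event type) is the fraction
    of those frames decoded in state i.  The engaged label is the state with
    the larger share of Any-response frames.  When disengagement periods are
    supplied, the same tabulation runs over all frames inside them.
    """
    states = seq.states
    n = len(states)
    k = int(states.max()) + 1
    frame_sets = {
        "hit": _event_frames(session.event_times("hit"), frame_rate_hz, n),
        "mistake": _event_frames(session.event_times("FA"), frame_rate_hz, n),
    }
    frame_sets["any"] = np.union1d(frame_sets["hit"], frame_sets["mistake"])
    rows, counts = {}, {}
    for name, frames in frame_sets.items():
        counts[name] = int(len(frames))
        if len(frames) == 0:
            warnings.warn(f"no {name} events inside the decoded span")
            rows[name] = np.full(k, np.nan)
        else:
            rows[name] = np.bincount(states[frames], minlength=k) / len(frames)
    post = pd.DataFrame(rows).T
    if counts["any"] == 0:
        raise ValueError("no responses inside the decoded span")
    engaged = int(np.nanargmax(post.loc["any"].to_numpy()))
    dis_post, p_dis = None, None
    if periods is not None and periods.periods:
        mask = np.zeros(n, dtype=bool)
        for s, e in periods.periods:
            lo = max(0, int(np.floor(s * frame_rate_hz)))
            hi = min(n, int(np.floor(e * frame_rate_hz)) + 1)
            mask[lo:hi] = True
        dis_post = np.bincount(states[mask], minlength=k) / mask.sum()
        # probability of latency-peak frames landing outside the engaged state
        p_dis = float(1.0 - dis_post[engaged])
    return EngagementStats(
        posteriors=post,
        engaged_label=engaged,
        p_responses_engaged=float(post.loc["any"].iloc[engaged]),
        disengagement_posterior=dis_post,
        p_periods_disengaged=p_dis,
        n_event_frames=counts,
    )


def correlate_engagement_with_behavior(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (and two-sided p) of P(responses | engaged) vs each metric.

    ``per_animal`` must contain a ``p_responses_engaged`` column; every other
    numeric column is treated as a behavioral metric (latency mean/CV,
    criterion c, and the count-based null comparators).
    """
    if len(per_animal) < 3:
        raise ValueError("need at least 3 animals for correlation")
    x = per_animal["p_responses_engaged"].to_numpy(float)
    rows = []
    for col in per_animal.columns:
        if col == "p_responses_engaged":
            continue
        y = per_animal[col].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"metric": col, "r": np.nan, "p": np.nan, "constant": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"metric": col, "r": float(r), "p": float(p), "constant": False})
    return pd.DataFrame(rows)
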