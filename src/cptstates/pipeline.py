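"""End-to-end orchestration: simulate/load → score → peri-event → HMM → network.

A run is driven by a single :class:`RunConfig` (YAML-serializable, round-
trippable) holding either a synthetic-generator block or paths to real
delimited-text inputs, per-stage parameter blocks, an output directory and
one global seed that determines every stochastic stage.  Each run writes a
manifest with SHA-256 hashes of all outputs plus a machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import engagement as eng
from . import io as _io
from . import network as net
from . import perievent as pe
from . import synthetic as syn

log = logging.getLogger("cptstates")

ALL_STAGES = ("behavior", "perievent", "engagement", "network")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    outdir: str = "cptstates_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    synthetic: dict | None = field(default_factory=dict)
    inputs: dict | None = None  # {"traces": ..., "centroids": ..., "events": ...}
    session_length_s: float = 2700.0
    stage_name: str = "stage3"
    perievent: dict = field(default_factory=dict)
    hmm: dict = field(default_factory=dict)
    network: dict = field(default_factory=lambda: {"n_perm": 2000})
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("provide exactly one of synthetic config or input paths")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(paths: dict) -> dict:
    """Shape/consistency checks on a real-input bundle.

    Verifies that files parse, trace columns match centroid rows by cell id,
    and event times are monotone; reports per-file pass/fail with the first
    offending row where applicable.
    """
    report: dict = {"files": {}, "ok": True}

    def fail(name, msg):
        report["files"][name] = {"ok": False, "error": msg}
        report["ok"] = False

    traces = centroids = events = None
    for name in ("traces", "centroids", "events"):
        p = paths.get(name)
        if p is None or not Path(p).exists():
            fail(name, "missing file")
            continue
        try:
            if name == "traces":
                traces = pd.read_csv(p)
            elif name == "centroids":
                centroids = _io.read_centroids(p)
            else:
                events = _io.read_events(p)
            report["files"][name] = {"ok": True}
        except Exception as e:  # parse error with context
            fail(name, f"parse error: {e}")
    if traces is not None and centroids is not None:
        if set(traces.columns) != set(centroids["cell_id"].astype(str)) and len(
            traces.columns
        ) != len(centroids):
            fail("centroids", "trace columns do not match centroid rows")
    if events is not None:
        t = events["time_s"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            row = int(np.nonzero(np.diff(t) < 0)[0][0]) + 1
            fail("events", f"event times out of order at row {row}")
    return report


def _load_or_simulate(config: RunConfig):
    if config.synthetic is not None:
        cfg = syn.SyntheticConfig(**{"seed": config.seed, **config.synthetic})
        session, traces, truth = syn.generate_session(cfg)
        return session, traces, truth
    rep = validate_inputs(config.inputs)
    if not rep["ok"]:
        raise ValueError(f"input validation failed: {rep}")
    traces = _io.read_traces(config.inputs["traces"])
    traces = _io.attach_centroids(traces, _io.read_centroids(config.inputs["centroids"]))
    events = _io.read_events(config.inputs["events"])
    session = _io.events_to_session(
        events, session_length_s=config.session_length_s, stage=config.stage_name
    )
    return session, traces, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    outputs: dict[str, Path] = {}
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    try:
        session, traces, truth = _load_or_simulate(config)
        if config.synthetic is not None:
            paths = syn.write_session(session, traces, truth, outdir / "synthetic")
            outputs.update({f"synthetic_{k}": Path(v) for k, v in paths.items()})

        disengagement = None
        if "behavior" in config.stages:
            log.info("behavior scoring")
            score = bhv.score_session(session)
            disengagement = bhv.disengagement_from_session(session)
            summary["behavior"] = score.to_dict() | {
                "disengagement_threshold_s": disengagement.threshold_s,
                "n_disengagement_periods": len(disengagement.periods),
            }
            p = outdir / "session_score.json"
            _io.write_json(summary["behavior"], p)
            outputs["session_score"] = p

        if "perievent" in config.stages:
            windows = pe.PeriEventWindows(**{"seed": config.seed, **config.perievent})
            props = {}
            for etype in ("hit", "fa"):
                for alignment in ("touch", "stimulus"):
                    log.info("perievent %s/%s", etype, alignment)
                    try:
                        res = pe.classify_perievent(
                            traces, session, etype, alignment, windows
                        )
                    except ValueError as e:
                        log.warning("skipping %s/%s: %s", etype, alignment, e)
                        continue
                    key = f"{etype}_{alignment}"
                    p = outdir / f"perievent_{key}.csv"
                    res.to_frame().to_csv(p, index=False, float_format="%.6g")
                    outputs[f"perievent_{key}"] = p
                    props[key] = res.proportions()
            summary["perievent_proportions"] = props
            p = outdir / "perievent_proportions.json"
            _io.write_json(props, p)
            outputs["perievent_proportions"] = p

        seq = stats = None
        if "engagement" in config.stages:
            log.info("engagement HMM")
            hmm_cfg = eng.HmmConfig(**{"seed": config.seed, **config.hmm})
            pcs = eng.preprocess_for_hmm(traces, hmm_cfg)
            ll_table = eng.select_state_count(pcs.pcs, hmm_cfg)
            cv = eng.crossvalidate_hmm(pcs.pcs, hmm_cfg)
            model = eng.fit_hmm(pcs.pcs, hmm_cfg)
            seq = eng.decode_states(model, pcs.pcs)
            stats = eng.event_state_posteriors(
                seq, session, traces.frame_rate_hz, periods=disengagement
            )
            seq.engaged_label = stats.engaged_label
            frames = np.arange(seq.n_frames)
            seq_df = pd.DataFrame(
                {
                    "frame": frames,
                    "time_s": frames / traces.frame_rate_hz,
                    "state": seq.states,
                    "engaged_flag": (seq.states == stats.engaged_label).astype(int),
                }
            )
            for name, obj in (
                ("state_sequence.csv", seq_df),
                ("hmm_state_count.csv", ll_table),
                ("hmm_crossval.csv", cv),
            ):
                p = outdir / name
                obj.to_csv(p, index=False, float_format="%.6g")
                outputs[name.removesuffix(".csv")] = p
            p = outdir / "hmm_model.json"
            _io.write_json(model.to_dict(), p)
            outputs["hmm_model"] = p
            p = outdir / "engagement_stats.json"
            _io.write_json(stats.to_dict(), p)
            outputs["engagement_stats"] = p
            summary["engagement"] = {
                "engaged_label": stats.engaged_label,
                "p_responses_engaged": stats.p_responses_engaged,
                "p_periods_disengaged": stats.p_periods_disengaged,
                "cumulative_variance_retained": pcs.cumulative_variance_retained,
                "log_likelihood_by_k": ll_table.set_index("n_states")[
                    "log_likelihood"
                ].to_dict(),
            }

        if "network" in config.stages:
            if seq is None:
                raise RuntimeError("network stage requires the engagement stage")
            if traces.centroids_um is None:
                raise ValueError("network stage requires centroid coordinates")
            log.info("correlation networks")
            net_cfg = {"n_perm": 2000, "k_grid": [2, 3, 4, 5, 6]} | config.network
            trunc = traces.traces[:, : seq.n_frames]
            ts = type(traces)(
                trunc, traces.frame_rate_hz, traces.centroids_um, traces.neuron_ids
            )
            dist = ts.pairwise_distances_um()
            state_names = {"engaged": stats.engaged_label, "disengaged": 1 - stats.engaged_label}
            mats, summary_net = {}, {}
            for name, label in state_names.items():
                mask = seq.states == label
                classes, mat = net.classify_pair_correlations(
                    ts, mask, n_perm=net_cfg["n_perm"], seed=config.seed
                )
                mats[name] = mat
                k_sel, assign, sil = net.cluster_states(
                    mat, k_grid=net_cfg["k_grid"], seed=config.seed
                )
                table = net.pair_table(mat, dist, classes, assign)
                p = outdir / f"pairs_{name}.csv"
                table.to_csv(p, index=False, float_format="%.6g")
                outputs[f"pairs_{name}"] = p
                metrics = net.cluster_metrics(assign, ts.centroids_um)
                p = outdir / f"clusters_{name}.csv"
                metrics.to_csv(p, index=False, float_format="%.6g")
                outputs[f"clusters_{name}"] = p
                fits = {}
                for cat in ("positive", "negative"):
                    sel = table[table["class"] == cat]
                    if len(sel) >= 10:
                        fits[cat] = net.fit_correlation_decay(
                            sel["r"].to_numpy(),
                            sel["distance_um"].to_numpy(),
                            category=cat,
                            seed=config.seed,
                        ).to_dict()
                summary_net[name] = {
                    "k_selected": int(k_sel),
                    "decay_fits": fits,
                    "n_significant_positive": int((table["class"] == "positive").sum()),
                    "n_significant_negative": int((table["class"] == "negative").sum()),
                }
                mats[name + "_assign"] = assign
            d_pos, p_pos, _ = net.compare_state_distributions(
                mats["engaged"][np.triu_indices(ts.n_neurons, 1)],
                mats["disengaged"][np.triu_indices(ts.n_neurons, 1)],
            )
            coupling = net.compare_cluster_coupling(
                mats["engaged"], mats["disengaged"], mats["disengaged_assign"], dist
            )
            p = outdir / "cluster_coupling.csv"
            coupling.to_csv(p, index=False, float_format="%.6g")
            outputs["cluster_coupling"] = p
            summary["network"] = summary_net | {"ks_all_pairs": {"D": d_pos, "p": p_pos}}
    finally:
        log.removeHandler(fh)
        fh.close()

    summary_path = outdir / "summary.json"
    _io.write_json(summary, summary_path)
    manifest = {
        "config": config.to_dict(),
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in sorted(outputs.items())},
        "summary": {"path": str(summary_path), "sha256": _sha256(summary_path)},
    }
    _io.write_json(manifest, outdir / "manifest.json")
    return summary
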