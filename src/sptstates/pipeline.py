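"""End-to-end workflow: fit -> summarize -> segment -> classify, with
schema-versioned JSON results and reproducible provenance."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import rnn
from .hdphmm import HdpHmmConfig, PosteriorChain, fit
from .segments import extract_segments, state_type_probability
from .summarize import ChainSummary, estimate_num_states, summarize_chain
from .tracks import TrackSet, read_tracks, _jsonable

logger = logging.getLogger(__name__)

RESULTS_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything needed to re-run an analysis bit-identically."""

    tracks_path: str | None = None
    tau: float | None = None
    hdphmm: HdpHmmConfig = field(default_factory=HdpHmmConfig)
    classifier_model: str | None = None  # path to a TrainedModel, or None
    regressor_model: str | None = None
    min_segment_steps: int = 40
    seed: int | None = None
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["hdphmm"] = self.hdphmm.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["hdphmm"] = HdpHmmConfig.from_dict(d["hdphmm"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Analysis outputs plus provenance."""

    summary: ChainSummary
    n_states: int
    state_labels_modal: list
    type_probabilities: dict | None
    alpha_estimates: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        s = self.summary
        return _jsonable(
            {
                "schema_version": RESULTS_SCHEMA_VERSION,
                "n_states": self.n_states,
                "states": [
                    {
                        "d_x_um2_s": s.d_x[i],
                        "d_y_um2_s": s.d_y[i],
                        "d_x_sd": s.d_x_sd[i],
                        "d_y_sd": s.d_y_sd[i],
                        "weight": s.weights[i],
                        "weight_sd": s.weights_sd[i],
                    }
                    for i in range(s.n_states)
                ],
                "transition_matrix": s.transition_matrix,
                "type_probabilities": self.type_probabilities,
                "alpha_estimates": self.alpha_estimates,
                "provenance": self.provenance,
            }
        )


def write_results(bundle: ResultBundle, path: str | Path) -> Path:
    """Persist a bundle as schema-versioned JSON (9 significant digits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    text = json.dumps(_round_floats(bundle.to_dict()), indent=1)
    path.write_text(text)
    return path


def read_results(path: str | Path) -> dict:
    d = json.loads(Path(path).read_text())
    if "schema_version" not in d:
        raise ValueError("results file lacks a schema_version field")
    return d


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.9g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v) for v in obj]
    return obj


def run_pipeline(
    config: RunConfig, tracks: TrackSet | None = None
) -> tuple[ResultBundle, PosteriorChain]:
    """Execute the full workflow described by ``config``.

    Stages: load tracks (unless given), fit the sticky HDP-HMM, summarize
    the chain, then — when a classifier model is configured — extract
    same-state segments from the modal-count sample closest to the
    posterior-mean parameters and classify their diffusion types.  A stage
    failure aborts with the stage name attached.
    """
    stage = "load"
    try:
        if tracks is None:
            if config.tracks_path is None:
                raise ValueError("no tracks given and no tracks_path configured")
            tracks = read_tracks(config.tracks_path, tau=config.tau)
        stage = "fit"
        hdp_cfg = config.hdphmm
        if hdp_cfg.seed is None and config.seed is not None:
            hdp_cfg = HdpHmmConfig.from_dict({**hdp_cfg.to_dict(), "seed": config.seed})
        chain = fit(tracks, hdp_cfg)
        stage = "summarize"
        summary = summarize_chain(chain)
        n_states, _, _ = estimate_num_states(chain)
        rep = _representative_sample(chain, n_states)
        labels = chain.state_sequences(rep)
        type_probs = None
        alpha_est = None
        if config.classifier_model is not None:
            stage = "classify"
            model = rnn.TrainedModel.load(config.classifier_model)
            batch = extract_segments(tracks, labels, config.min_segment_steps)
            probs = rnn.classify_segments(model, batch)
            type_probs = state_type_probability(batch, probs, rnn.CLASS_NAMES)
            if config.regressor_model is not None:
                reg = rnn.TrainedModel.load(config.regressor_model)
                _, alpha_est = rnn.regress_alpha(reg, batch)
        provenance = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "sticky_kappa": chain.diagnostics.get("sticky_kappa"),
            "n_retained_samples": len(chain),
        }
        bundle = ResultBundle(
            summary=summary,
            n_states=n_states,
            state_labels_modal=[z.tolist() for z in labels.labels],
            type_probabilities=type_probs,
            alpha_estimates=alpha_est,
            provenance=provenance,
        )
        return bundle, chain
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e


def _representative_sample(chain: PosteriorChain, n_states: int):
    """Retained sample with the modal state count and highest likelihood."""
    modal = [s for s in chain.samples if s.occupied_count == n_states]
    return max(modal, key=lambda s: s.log_likelihood)
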