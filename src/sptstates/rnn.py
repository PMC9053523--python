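"""Two-layer LSTM sequence models for diffusion-type analysis (pure NumPy).

Two heads share one architecture — LSTM(100) -> LSTM(50) -> dense:

* a 4-way softmax classifier over (BM, FBM, CTRW, LW) for fixed-length
  normalized track segments, and
* a scalar regressor estimating the anomalous exponent alpha.

Inputs are normalized 2D coordinate sequences (zero mean, unit pooled
variance — see :mod:`sptstates.segments`), one position per time step.
Training uses Adam on cross-entropy / mean-squared-error with full
backpropagation through time, global-norm gradient clipping and early
stopping on a held-out split; everything is deterministic under the spec's
seed.  Segments longer than the network's input length are split into
non-overlapping windows whose probabilities are averaged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .segments import SegmentBatch, normalize_batch

logger = logging.getLogger(__name__)

CLASS_NAMES = ("BM", "FBM", "CTRW", "LW")

DTYPE = np.float32  # float64 available for, e.g., gradient verification

# valid anomalous-exponent range per diffusion type (used to clip regression)
ALPHA_RANGES = {"FBM": (0.05, 1.95), "CTRW": (0.05, 1.0), "BM": (1.0, 1.0)}


@dataclass
class ClassifierSpec:
    """Architecture + training-corpus description for one network."""

    input_steps: int = 40  # displacements per window; T+1 positions are fed
    hidden: tuple[int, int] = (100, 50)
    task: str = "classify"  # or "regress"
    n_per_class: int = 20000
    alpha_range: tuple[float, float] = (0.1, 1.9)
    max_epochs: int = 30
    batch_size: int = 256
    learning_rate: float = 2e-3
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_steps < 20:
            raise ValueError("input_steps must be >= 20")
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden layer widths must be positive")
        if self.task not in ("classify", "regress"):
            raise ValueError("task must be 'classify' or 'regress'")


# ---------------------------------------------------------------------------
# LSTM forward / backward


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _init_layer(rng, in_dim, hid):
    lim_x = np.sqrt(6.0 / (in_dim + 4 * hid))
    lim_h = np.sqrt(6.0 / (hid + 4 * hid))
    b = np.zeros(4 * hid, dtype=DTYPE)
    b[hid : 2 * hid] = 1.0  # forget-gate bias
    return {
        "Wx": rng.uniform(-lim_x, lim_x, (in_dim, 4 * hid)).astype(DTYPE),
        "Wh": rng.uniform(-lim_h, lim_h, (hid, 4 * hid)).astype(DTYPE),
        "b": b,
    }


def init_params(spec: ClassifierSpec) -> dict:
    rng = np.random.default_rng(spec.seed)
    h1, h2 = spec.hidden
    out_dim = len(CLASS_NAMES) if spec.task == "classify" else 1
    p = {"l1": _init_layer(rng, 2, h1), "l2": _init_layer(rng, h1, h2)}
    lim = np.sqrt(6.0 / (h2 + out_dim))
    p["Wo"] = rng.uniform(-lim, lim, (h2, out_dim)).astype(DTYPE)
    p["bo"] = np.zeros(out_dim, dtype=DTYPE)
    return p


def _lstm_forward(layer, X):
    """X: (B, T, in) -> H: (B, T, hid) plus the cache needed for BPTT."""
    B, T, _ = X.shape
    hid = layer["Wh"].shape[0]
    H = np.empty((B, T, hid), dtype=DTYPE)
    h = np.zeros((B, hid), dtype=DTYPE)
    c = np.zeros((B, hid), dtype=DTYPE)
    gates = np.empty((T, B, 4 * hid), dtype=DTYPE)
    cs = np.empty((T, B, hid), dtype=DTYPE)
    tanhc = np.empty((T, B, hid), dtype=DTYPE)
    c_prevs = np.empty((T, B, hid), dtype=DTYPE)
    h_prevs = np.empty((T, B, hid), dtype=DTYPE)
    for t in range(T):
        a = X[:, t] @ layer["Wx"] + h @ layer["Wh"] + layer["b"]
        i = _sigmoid(a[:, :hid])
        f = _sigmoid(a[:, hid : 2 * hid])
        g = np.tanh(a[:, 2 * hid : 3 * hid])
        o = _sigmoid(a[:, 3 * hid :])
        c_prevs[t] = c
        h_prevs[t] = h
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        H[:, t] = h
        gates[t, :, :hid] = i
        gates[t, :, hid : 2 * hid] = f
        gates[t, :, 2 * hid : 3 * hid] = g
        gates[t, :, 3 * hid :] = o
        cs[t] = c
        tanhc[t] = tc
    cache = {"X": X, "gates": gates, "cs": cs, "tanhc": tanhc,
             "c_prevs": c_prevs, "h_prevs": h_prevs}
    return H, cache


def _lstm_backward(layer, cache, dH):
    """dH: (B, T, hid) upstream gradient on every hidden output."""
    X = cache["X"]
    B, T, in_dim = X.shape
    hid = layer["Wh"].shape[0]
    dWx = np.zeros_like(layer["Wx"])
    dWh = np.zeros_like(layer["Wh"])
    db = np.zeros_like(layer["b"])
    dX = np.empty_like(X)
    dh_next = np.zeros((B, hid), dtype=DTYPE)
    dc_next = np.zeros((B, hid), dtype=DTYPE)
    for t in range(T - 1, -1, -1):
        g4 = cache["gates"][t]
        i, f = g4[:, :hid], g4[:, hid : 2 * hid]
        g, o = g4[:, 2 * hid : 3 * hid], g4[:, 3 * hid :]
        tc = cache["tanhc"][t]
        dh = dH[:, t] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * cache["c_prevs"][t]
        dc_next = dc * f
        da = np.empty((B, 4 * hid), dtype=DTYPE)
        da[:, :hid] = di * i * (1.0 - i)
        da[:, hid : 2 * hid] = df * f * (1.0 - f)
        da[:, 2 * hid : 3 * hid] = dg * (1.0 - g * g)
        da[:, 3 * hid :] = do * o * (1.0 - o)
        dWx += X[:, t].T @ da
        dWh += cache["h_prevs"][t].T @ da
        db += da.sum(axis=0)
        dX[:, t] = da @ layer["Wx"].T
        dh_next = da @ layer["Wh"].T
    return dX, {"Wx": dWx, "Wh": dWh, "b": db}


def _forward(params, X, want_cache=False):
    H1, c1 = _lstm_forward(params["l1"], X)
    H2, c2 = _lstm_forward(params["l2"], H1)
    out = H2[:, -1] @ params["Wo"] + params["bo"]
    if want_cache:
        return out, (c1, c2, H2)
    return out


def _backward(params, caches, dout):
    c1, c2, H2 = caches
    grads = {
        "Wo": H2[:, -1].T @ dout,
        "bo": dout.sum(axis=0),
    }
    dH2 = np.zeros_like(H2)
    dH2[:, -1] = dout @ params["Wo"].T
    dH1, g2 = _lstm_backward(params["l2"], c2, dH2)
    _, g1 = _lstm_backward(params["l1"], c1, dH1)
    grads["l1"] = g1
    grads["l2"] = g2
    return grads


def _flatten(tree, prefix=""):
    for k, v in tree.items():
        if isinstance(v, dict):
            yield from _flatten(v, prefix + k + ".")
        else:
            yield prefix + k, v


class _Adam:
    def __init__(self, params, lr, clip=5.0):
        self.lr, self.clip = lr, clip
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in _flatten(params)}
        self.v = {k: np.zeros_like(v) for k, v in _flatten(params)}

    def step(self, params, grads):
        flat_g = dict(_flatten(grads))
        norm = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in flat_g.values()))
        scale = min(1.0, self.clip / (norm + 1e-12))
        self.t += 1
        flat_p = dict(_flatten(params))
        for k, g in flat_g.items():
            g = g * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            flat_p[k] -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(DTYPE)


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    params: dict
    history: dict = field(default_factory=dict)
    confusion_matrix: np.ndarray | None = None
    holdout_metric: float | None = None

    def save(self, path: str | Path) -> None:
        path = Path(path)
        flat = dict(_flatten(self.params))
        np.savez(path.with_suffix(".npz"), **flat)
        manifest = {
            "spec": asdict(self.spec),
            "history": self.history,
            "holdout_metric": self.holdout_metric,
            "confusion_matrix": None
            if self.confusion_matrix is None
            else self.confusion_matrix.tolist(),
            "classes": list(CLASS_NAMES),
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        spec_d = manifest["spec"]
        spec_d["hidden"] = tuple(spec_d["hidden"])
        spec_d["alpha_range"] = tuple(spec_d["alpha_range"])
        spec = ClassifierSpec(**spec_d)
        flat = np.load(path.with_suffix(".npz"))
        params: dict = {}
        for k, v in flat.items():
            node = params
            parts = k.split(".")
            for p in parts[:-1]:
                node = node.setdefault(p, {})
            node[parts[-1]] = v
        cm = manifest.get("confusion_matrix")
        return cls(
            spec,
            params,
            manifest.get("history", {}),
            None if cm is None else np.asarray(cm),
            manifest.get("holdout_metric"),
        )


def _prepare_inputs(X: np.ndarray) -> np.ndarray:
    """Normalize raw coordinate windows and cast for the network."""
    return normalize_batch(np.asarray(X, dtype=np.float64)).astype(DTYPE)


def _epoch_minibatches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_classifier(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, holdout_fraction: float = 0.1
) -> TrainedModel:
    """Train the 4-class diffusion-type network on labeled coordinate windows.

    ``X`` is (N, T+1, 2) raw coordinates (normalized internally); ``y``
    holds integer class labels indexing :data:`CLASS_NAMES`.  The corpus
    must be balanced to within 10% between classes.  Returns the trained
    model with a held-out confusion matrix and accuracy.
    """
    y = np.asarray(y, dtype=np.int64)
    counts = np.bincount(y, minlength=len(CLASS_NAMES))
    if counts.max() > 1.1 * max(counts.min(), 1):
        raise ValueError(f"class imbalance exceeds 10%: counts {counts.tolist()}")
    return _train(spec, X, y, holdout_fraction)


def train_alpha_regressor(
    spec: ClassifierSpec, X: np.ndarray, alpha: np.ndarray, holdout_fraction: float = 0.1
) -> TrainedModel:
    """Train the scalar anomalous-exponent regression network."""
    if spec.task != "regress":
        raise ValueError("spec.task must be 'regress'")
    return _train(spec, X, np.asarray(alpha, dtype=DTYPE), holdout_fraction)


def _train(spec, X, y, holdout_fraction):
    rng = np.random.default_rng(spec.seed + 1)
    Xn = _prepare_inputs(X)
    keep = np.isfinite(Xn).all(axis=(1, 2))
    Xn, y = Xn[keep], y[keep]
    n = Xn.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(holdout_fraction * n))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    params = init_params(spec)
    opt = _Adam(params, spec.learning_rate)
    classify = spec.task == "classify"
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = None
    bad_epochs = 0
    for epoch in range(spec.max_epochs):
        losses = []
        for idx in _epoch_minibatches(train_idx.size, spec.batch_size, rng):
            batch = train_idx[idx]
            out, caches = _forward(params, Xn[batch], want_cache=True)
            if classify:
                out64 = out.astype(np.float64)
                out64 -= out64.max(axis=1, keepdims=True)
                p = np.exp(out64)
                p /= p.sum(axis=1, keepdims=True)
                loss = -np.mean(np.log(p[np.arange(batch.size), y[batch]] + 1e-12))
                dout = p
                dout[np.arange(batch.size), y[batch]] -= 1.0
                dout = (dout / batch.size).astype(DTYPE)
            else:
                resid = out[:, 0] - y[batch]
                loss = float(np.mean(resid**2))
                dout = (2.0 * resid[:, None] / batch.size).astype(DTYPE)
            grads = _backward(params, caches, dout)
            opt.step(params, grads)
            losses.append(float(loss))
        val_loss = _eval_loss(params, Xn[val_idx], y[val_idx], classify, spec.batch_size)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        logger.info("epoch %d: train %.4f val %.4f", epoch, history["train_loss"][-1], val_loss)
        if val_loss < best_val - 1e-5:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in _flatten(params)}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= spec.patience:
                break
    if best_params is not None:
        for k, v in _flatten(params):
            v[...] = best_params[k]
    model = TrainedModel(spec, params, history)
    if classify:
        pred = predict(model, Xn[val_idx], already_normalized=True).argmax(axis=1)
        cm = np.zeros((len(CLASS_NAMES), len(CLASS_NAMES)), dtype=np.int64)
        np.add.at(cm, (y[val_idx], pred), 1)
        model.confusion_matrix = cm
        model.holdout_metric = float(np.trace(cm) / cm.sum())
    else:
        est = predict(model, Xn[val_idx], already_normalized=True)[:, 0]
        model.holdout_metric = float(np.mean(np.abs(est - y[val_idx])))
    return model


def _eval_loss(params, X, y, classify, batch_size):
    losses, weights = [], []
    for start in range(0, X.shape[0], batch_size):
        xb, yb = X[start : start + batch_size], y[start : start + batch_size]
        out = _forward(params, xb)
        if classify:
            out64 = out.astype(np.float64)
            out64 -= out64.max(axis=1, keepdims=True)
            p = np.exp(out64)
            p /= p.sum(axis=1, keepdims=True)
            losses.append(-np.mean(np.log(p[np.arange(yb.size), yb] + 1e-12)))
        else:
            losses.append(float(np.mean((out[:, 0] - yb) ** 2)))
        weights.append(yb.size)
    return float(np.average(losses, weights=weights))


def predict(model: TrainedModel, X: np.ndarray, already_normalized: bool = False) -> np.ndarray:
    """Network outputs for raw coordinate windows (softmax probs or alpha)."""
    Xn = X.astype(DTYPE) if already_normalized else _prepare_inputs(X)
    outs = []
    for start in range(0, Xn.shape[0], 512):
        out = _forward(model.params, Xn[start : start + 512])
        if model.spec.task == "classify":
            out = out.astype(np.float64)
            out -= out.max(axis=1, keepdims=True)
            p = np.exp(out)
            out = p / p.sum(axis=1, keepdims=True)
        outs.append(out)
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# Segment-level inference


def _segment_windows(xy: np.ndarray, input_steps: int) -> np.ndarray:
    """Non-overlapping ``input_steps``-step windows (trailing rest dropped)."""
    n_windows = (xy.shape[0] - 1) // input_steps
    if n_windows == 0:
        return np.empty((0, input_steps + 1, 2))
    return np.stack(
        [xy[w * input_steps : (w + 1) * input_steps + 1] for w in range(n_windows)]
    )


def classify_segments(model: TrainedModel, batch: SegmentBatch) -> np.ndarray:
    """Per-segment class probabilities, (n_segments, 4).

    Segments longer than the network input are split into non-overlapping
    windows whose probabilities are averaged (equal window lengths, so a
    plain mean); segments shorter than the input are rejected with a NaN
    row.  Inference is deterministic: identical segments give identical
    probabilities.
    """
    T = model.spec.input_steps
    rows = np.full((len(batch), len(CLASS_NAMES)), np.nan)
    all_windows, owners = [], []
    for i, seg in enumerate(batch):
        w = _segment_windows(seg.xy, T)
        if w.shape[0] == 0:
            continue
        all_windows.append(w)
        owners.extend([i] * w.shape[0])
    if not all_windows:
        return rows
    probs = predict(model, np.concatenate(all_windows, axis=0))
    owners = np.asarray(owners)
    for i in np.unique(owners):
        rows[i] = probs[owners == i].mean(axis=0)
    return rows


def regress_alpha(
    model: TrainedModel, batch: SegmentBatch, diffusion_type: str = "FBM"
) -> tuple[np.ndarray, dict[int, float]]:
    """Per-segment and length-weighted per-state anomalous-exponent estimates.

    Estimates are clipped to the valid alpha range of ``diffusion_type``.
    Returns ``(per_segment, {state: weighted mean})``; only BM-free types
    have a regression model (BM has alpha = 1 by definition, LW none).
    """
    if diffusion_type not in ALPHA_RANGES or diffusion_type == "BM":
        raise ValueError(f"no regression model applies to type {diffusion_type!r}")
    lo, hi = ALPHA_RANGES[diffusion_type]
    T = model.spec.input_steps
    est = np.full(len(batch), np.nan)
    all_windows, owners = [], []
    for i, seg in enumerate(batch):
        w = _segment_windows(seg.xy, T)
        if w.shape[0] == 0:
            continue
        all_windows.append(w)
        owners.extend([i] * w.shape[0])
    if all_windows:
        vals = predict(model, np.concatenate(all_windows, axis=0))[:, 0]
        owners = np.asarray(owners)
        for i in np.unique(owners):
            est[i] = np.clip(vals[owners == i].mean(), lo, hi)
    per_state: dict[int, float] = {}
    for state in batch.states():
        idx = [i for i, s in enumerate(batch.segments) if s.state == state]
        ok = [i for i in idx if np.isfinite(est[i])]
        if not ok:
            continue
        lengths = np.array([batch.segments[i].n_steps for i in ok], dtype=float)
        per_state[int(state)] = float(np.average(est[ok], weights=lengths))
    return est, per_state


# ---------------------------------------------------------------------------
# Training corpora (simulated; all classes balanced by construction)


def make_classification_corpus(
    n_per_class: int,
    n_steps: int,
    rng: np.random.Generator,
    alpha_fbm: tuple[float, float] = (0.1, 1.9),
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced labeled corpus of raw coordinate windows, (4n, T+1, 2).

    Normalization makes the classes scale-free, so unit coefficients are
    used: BM steps are standard Gaussian; FBM draws its exponent uniformly
    from ``alpha_fbm``; CTRW draws alpha in (0.1, 1.0); LW draws alpha in
    (1.0, 2.0).  Labels index :data:`CLASS_NAMES`.
    """
    from .anomalous import fgn_increments, simulate_ctrw, simulate_lw

    T = n_steps
    X = np.empty((4 * n_per_class, T + 1, 2))
    y = np.repeat(np.arange(4), n_per_class)
    # BM
    steps = rng.standard_normal((n_per_class, T, 2))
    X[:n_per_class, 0] = 0
    X[:n_per_class, 1:] = np.cumsum(steps, axis=1)
    # FBM: per-track alpha; group tracks into a few alpha buckets for speed
    alphas = rng.uniform(*alpha_fbm, size=n_per_class)
    fbm = np.empty((n_per_class, T, 2))
    for i, a in enumerate(alphas):
        inc = fgn_increments(a / 2.0, T, 2, rng)
        fbm[i] = inc.T
    X[n_per_class : 2 * n_per_class, 0] = 0
    X[n_per_class : 2 * n_per_class, 1:] = np.cumsum(fbm, axis=1)
    # CTRW
    for i in range(n_per_class):
        a = rng.uniform(0.1, 1.0)
        X[2 * n_per_class + i] = simulate_ctrw(a + 1.0, 1.0, T, 1.0, rng)
    # LW
    for i in range(n_per_class):
        a = rng.uniform(1.0, 2.0)
        X[3 * n_per_class + i] = simulate_lw(3.0 - a, 1.0, T, 1.0, rng)
    return X, y


def make_fbm_regression_corpus(
    n_tracks: int,
    n_steps: int,
    rng: np.random.Generator,
    alpha_range: tuple[float, float] = (0.1, 1.9),
) -> tuple[np.ndarray, np.ndarray]:
    """FBM windows with uniformly drawn anomalous exponents, for regression."""
    from .anomalous import fgn_increments

    X = np.empty((n_tracks, n_steps + 1, 2))
    alphas = rng.uniform(*alpha_range, size=n_tracks)
    for i, a in enumerate(alphas):
        inc = fgn_increments(a / 2.0, n_steps, 2, rng)
        X[i, 0] = 0
        X[i, 1:] = np.cumsum(inc.T, axis=0)
    return X, alphas
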