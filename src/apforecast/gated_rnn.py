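"""LSTM and GRU sequence-to-sequence regressors trained by BPTT with Adam.

Both cells follow the standard gated formulations: the LSTM keeps a cell
state c_t guarded by input/forget/output gates, and the GRU merges input
and forget into a single update gate acting directly on the hidden state
(roughly three-quarters the trainable weights of an LSTM of equal width).
A fully connected layer maps the (top-layer) hidden state to the
next-step voltage; training minimizes mean squared one-step-ahead error.

Gradients are computed by exact backpropagation through time, vectorized
over mini-batches of fixed-length windows cut from the training sequence
(truncated BPTT).  Forecasting is recursive: the hidden state is warmed
on the observed series teacher-forced, then each predicted voltage is fed
back as the next input while exogenous stimulus channels come from their
known timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GatedSpec",
    "TrainConfig",
    "GatedModel",
    "lstm_step",
    "gru_step",
    "train_seq2seq",
    "forecast_recursive",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GatedSpec:
    """Architecture of a gated recurrent regressor."""

    cell_kind: str = "lstm"  # "lstm" | "gru"
    n_hidden: int = 100
    n_layers: int = 1
    n_inputs: int = 1

    def __post_init__(self) -> None:
        if self.cell_kind not in ("lstm", "gru"):
            raise ValueError("cell_kind must be 'lstm' or 'gru'")
        if self.n_hidden < 1 or self.n_layers < 1 or self.n_inputs < 1:
            raise ValueError("n_hidden, n_layers, n_inputs must be >= 1")

    @property
    def n_gates(self) -> int:
        return 4 if self.cell_kind == "lstm" else 3


@dataclass(frozen=True)
class TrainConfig:
    """Adam-based training configuration.

    Defaults follow common toolbox settings: Adam with beta1 0.9,
    beta2 0.999, eps 1e-8, and at most 30 epochs.  The sequence is cut
    into windows of ``window`` samples advanced by ``stride`` (truncated
    BPTT); ``window = 0`` trains on the full sequence in one window.
    """

    learning_rate: float = 5e-3
    max_epochs: int = 30
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    lr_drop_factor: float = 1.0  # per-period multiplier; 1.0 = constant rate
    lr_drop_period: int = 10
    window: int = 128
    stride: int = 32
    batch_size: int = 32
    loss_burn_in: int = 24
    train_noise: float = 0.0  # sigma of noise on the fed-back voltage slot
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def init_params(spec: GatedSpec, seed: int) -> dict:
    """Glorot-uniform input weights, orthogonal recurrent weights, zero
    biases; one (W, U, b) triple per layer plus the dense readout."""
    rng = np.random.default_rng(seed)
    params: dict = {"layers": [], "spec": spec}
    H, G = spec.n_hidden, spec.n_gates
    for layer in range(spec.n_layers):
        n_in = spec.n_inputs if layer == 0 else H
        limit = np.sqrt(6.0 / (n_in + H))
        W = rng.uniform(-limit, limit, size=(G * H, n_in))
        U = np.concatenate(
            [np.linalg.qr(rng.standard_normal((H, H)))[0] for _ in range(G)],
            axis=0)
        b = np.zeros(G * H)
        params["layers"].append({"W": W, "U": U, "b": b})
    limit = np.sqrt(6.0 / (H + 1))
    params["Wy"] = rng.uniform(-limit, limit, size=(1, H))
    params["by"] = np.zeros(1)
    return params


def n_trainable(params: dict) -> int:
    total = 0
    for lp in params["layers"]:
        total += lp["W"].size + lp["U"].size + lp["b"].size
    return total + params["Wy"].size + params["by"].size


# --------------------------------------------------------------------------
# single-step cell maps (batched over leading axis)
# --------------------------------------------------------------------------

def lstm_step(lp: dict, x: np.ndarray, h_prev: np.ndarray,
              c_prev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update: gates by sigmoid, candidate by tanh,
    c_t = f*c + i*c~, h_t = tanh(c_t)*o."""
    H = h_prev.shape[-1]
    a = x @ lp["W"].T + h_prev @ lp["U"].T + lp["b"]
    i = _sigmoid(a[..., 0:H])
    f = _sigmoid(a[..., H:2 * H])
    o = _sigmoid(a[..., 2 * H:3 * H])
    g = np.tanh(a[..., 3 * H:4 * H])
    c = f * c_prev + i * g
    h = np.tanh(c) * o
    return h, c


def gru_step(lp: dict, x: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
    """One GRU update: update/reset gates by sigmoid, candidate by tanh,
    h_t = (1-z)*h + z*h~."""
    H = h_prev.shape[-1]
    az = x @ lp["W"][0:H].T + h_prev @ lp["U"][0:H].T + lp["b"][0:H]
    ar = (x @ lp["W"][H:2 * H].T + h_prev @ lp["U"][H:2 * H].T
          + lp["b"][H:2 * H])
    z = _sigmoid(az)
    r = _sigmoid(ar)
    ah = (x @ lp["W"][2 * H:3 * H].T
          + (r * h_prev) @ lp["U"][2 * H:3 * H].T + lp["b"][2 * H:3 * H])
    g = np.tanh(ah)
    return (1.0 - z) * h_prev + z * g


# --------------------------------------------------------------------------
# batched forward/backward over windows
# --------------------------------------------------------------------------

def _forward(params: dict, X: np.ndarray) -> tuple[np.ndarray, list]:
    """Run all layers over a batch of windows.

    X has shape (B, T, n_inputs); returns predictions (B, T) and the cache
    needed for backpropagation.
    """
    spec: GatedSpec = params["spec"]
    B, T, _ = X.shape
    H = spec.n_hidden
    caches = []
    inp = X
    for lp in params["layers"]:
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        hs = np.empty((B, T, H))
        for t in range(T):
            x = inp[:, t]
            if spec.cell_kind == "lstm":
                a = x @ lp["W"].T + h @ lp["U"].T + lp["b"]
                i = _sigmoid(a[:, 0:H])
                f = _sigmoid(a[:, H:2 * H])
                o = _sigmoid(a[:, 2 * H:3 * H])
                g = np.tanh(a[:, 3 * H:4 * H])
                c_new = f * c + i * g
                h_new = np.tanh(c_new) * o
                steps.append((x, h, c, i, f, o, g, c_new))
                h, c = h_new, c_new
            else:
                az = x @ lp["W"][0:H].T + h @ lp["U"][0:H].T + lp["b"][0:H]
                ar = (x @ lp["W"][H:2 * H].T + h @ lp["U"][H:2 * H].T
                      + lp["b"][H:2 * H])
                z = _sigmoid(az)
                r = _sigmoid(ar)
                ah = (x @ lp["W"][2 * H:3 * H].T
                      + (r * h) @ lp["U"][2 * H:3 * H].T
                      + lp["b"][2 * H:3 * H])
                g = np.tanh(ah)
                h_new = (1.0 - z) * h + z * g
                steps.append((x, h, z, r, g))
                h = h_new
            hs[:, t] = h
        caches.append((steps, hs))
        inp = hs
    y = inp @ params["Wy"].T[..., 0] + params["by"][0]
    return y, caches


def _backward(params: dict, X: np.ndarray, caches: list, dy: np.ndarray
              ) -> dict:
    """Exact BPTT gradients for the mean-squared loss derivative ``dy``."""
    spec: GatedSpec = params["spec"]
    B, T, _ = X.shape
    H = spec.n_hidden
    grads: dict = {"layers": [
        {k: np.zeros_like(v) for k, v in lp.items()}
        for lp in params["layers"]],
        "Wy": np.zeros_like(params["Wy"]),
        "by": np.zeros_like(params["by"])}
    top_hs = caches[-1][1]
    grads["Wy"][0] = np.einsum("bt,bth->h", dy, top_hs)
    grads["by"][0] = dy.sum()
    # gradient flowing into each layer's hidden sequence
    dh_seq = dy[..., None] * params["Wy"][0]
    for li in range(len(params["layers"]) - 1, -1, -1):
        lp = params["layers"][li]
        gl = grads["layers"][li]
        steps, _ = caches[li]
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dx_seq = np.empty((B, T, steps[0][0].shape[1]))
        for t in range(T - 1, -1, -1):
            dh = dh_seq[:, t] + dh_next
            if spec.cell_kind == "lstm":
                x, h_prev, c_prev, i, f, o, g, c_new = steps[t]
                tc = np.tanh(c_new)
                dc = dc_next + dh * o * (1.0 - tc * tc)
                do = dh * tc
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                da = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
                     dg * (1 - g * g)], axis=1)
                gl["W"] += da.T @ x
                gl["U"] += da.T @ h_prev
                gl["b"] += da.sum(axis=0)
                dh_next = da @ lp["U"]
                dc_next = dc * f
                dx_seq[:, t] = da @ lp["W"]
            else:
                x, h_prev, z, r, g = steps[t]
                dz = dh * (g - h_prev)
                dg = dh * z
                dah = dg * (1.0 - g * g)
                dr = (dah @ lp["U"][2 * H:3 * H]) * h_prev
                daz = dz * z * (1 - z)
                dar = dr * r * (1 - r)
                da = np.concatenate([daz, dar, dah], axis=1)
                gl["W"] += da.T @ x
                gl["b"] += da.sum(axis=0)
                gl["U"][0:H] += daz.T @ h_prev
                gl["U"][H:2 * H] += dar.T @ h_prev
                gl["U"][2 * H:3 * H] += dah.T @ (r * h_prev)
                dh_next = (dh * (1.0 - z) + daz @ lp["U"][0:H]
                           + dar @ lp["U"][H:2 * H]
                           + (dah @ lp["U"][2 * H:3 * H]) * r)
                dx_seq[:, t] = da @ lp["W"]
        dh_seq = dx_seq  # feeds the layer below
    return grads


def _loss_and_grads(params: dict, X: np.ndarray, Y: np.ndarray,
                    burn_in: int = 0) -> tuple[float, dict]:
    """MSE loss and gradients; the first ``burn_in`` steps of each window
    are excluded from the loss so the zero-initialized hidden state's
    transient does not pollute the gradient."""
    y, caches = _forward(params, X)
    err = y - Y
    if burn_in > 0:
        burn_in = min(burn_in, err.shape[1] - 1)
        err[:, :burn_in] = 0.0
    n_counted = err.shape[0] * (err.shape[1] - burn_in)
    loss = float(np.sum(err * err) / n_counted)
    dy = 2.0 * err / n_counted
    return loss, _backward(params, X, caches, dy)


@dataclass
class GatedModel:
    """Trained gated RNN with its architecture and training provenance."""

    spec: GatedSpec
    params: dict
    config: TrainConfig
    loss_history: list = field(default_factory=list)

    @property
    def n_trainable(self) -> int:
        return n_trainable(self.params)


class _Adam:
    def __init__(self, config: TrainConfig):
        self.cfg = config
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float | None = None) -> None:
        self.t += 1
        cfg = self.cfg
        rate = cfg.learning_rate if lr is None else lr
        b1t = 1.0 - cfg.beta1 ** self.t
        b2t = 1.0 - cfg.beta2 ** self.t

        def update(key, p, g):
            m = self.m.setdefault(key, np.zeros_like(p))
            v = self.v.setdefault(key, np.zeros_like(p))
            m *= cfg.beta1
            m += (1 - cfg.beta1) * g
            v *= cfg.beta2
            v += (1 - cfg.beta2) * g * g
            p -= rate * (m / b1t) / (np.sqrt(v / b2t) + cfg.eps)

        for li, (lp, gl) in enumerate(zip(params["layers"], grads["layers"])):
            for k in ("W", "U", "b"):
                update((li, k), lp[k], gl[k])
        update("Wy", params["Wy"], grads["Wy"])
        update("by", params["by"], grads["by"])


def _make_windows(T: int, window: int, stride: int) -> np.ndarray:
    if window <= 0 or window >= T:
        return np.array([0])
    starts = np.arange(0, T - window + 1, max(stride, 1))
    if starts[-1] != T - window:
        starts = np.append(starts, T - window)
    return starts


def train_seq2seq(
    spec: GatedSpec, inputs: np.ndarray, targets: np.ndarray,
    config: TrainConfig,
) -> GatedModel:
    """Train a one-step-ahead regressor on an input/target sequence.

    ``inputs`` has shape (T, n_inputs) and ``targets`` (T,), where row t
    maps to the voltage at t+1.  The sequence is cut into overlapping
    windows; each Adam update uses a mini-batch of windows, and an epoch
    is one shuffled pass over all windows.  Aborts on non-finite loss.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    targets = np.asarray(targets, dtype=float)
    T = inputs.shape[0]
    if inputs.shape[1] != spec.n_inputs:
        raise ValueError("input width does not match spec.n_inputs")
    if targets.shape != (T,):
        raise ValueError("targets must align with inputs")
    params = init_params(spec, config.seed)
    opt = _Adam(config)
    rng = np.random.default_rng(config.seed + 7)
    window = config.window if 0 < config.window < T else T
    starts = _make_windows(T, window, config.stride)
    loss_history = []
    for epoch in range(config.max_epochs):
        lr = config.learning_rate * config.lr_drop_factor ** (
            epoch // config.lr_drop_period)
        order = rng.permutation(len(starts))
        epoch_losses = []
        for b0 in range(0, len(order), config.batch_size):
            batch = starts[order[b0:b0 + config.batch_size]]
            X = np.stack([inputs[s:s + window] for s in batch])
            Y = np.stack([targets[s:s + window] for s in batch])
            if config.train_noise > 0:
                # perturb the voltage input slot so the recursive forecast
                # tolerates its own prediction error
                X = X.copy()
                X[:, :, -1] += config.train_noise * rng.standard_normal(
                    X.shape[:2])
            loss, grads = _loss_and_grads(
                params, X, Y, 0 if window >= T else config.loss_burn_in)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at update {opt.t}")
            opt.step(params, grads, lr)
            epoch_losses.append(loss)
        loss_history.append(float(np.mean(epoch_losses)))
    return GatedModel(spec, params, config, loss_history)


def save_gated(model: GatedModel, path) -> None:
    """Checkpoint weights as .npz with a JSON manifest alongside."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    arrays = {"Wy": model.params["Wy"], "by": model.params["by"]}
    for li, lp in enumerate(model.params["layers"]):
        for key in ("W", "U", "b"):
            arrays[f"layer{li}_{key}"] = lp[key]
    np.savez(path, **arrays)
    manifest = {"spec": asdict(model.spec), "config": asdict(model.config),
                "final_loss": (model.loss_history[-1]
                               if model.loss_history else None)}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_gated(path) -> GatedModel:
    import json
    from pathlib import Path

    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    spec = GatedSpec(**manifest["spec"])
    config = TrainConfig(**manifest["config"])
    data = np.load(path if path.suffix == ".npz"
                   else path.with_suffix(".npz"))
    params: dict = {"spec": spec, "Wy": data["Wy"], "by": data["by"],
                    "layers": []}
    for li in range(spec.n_layers):
        params["layers"].append({k: data[f"layer{li}_{k}"]
                                 for k in ("W", "U", "b")})
    return GatedModel(spec, params, config)


def _warm_states(model: GatedModel, inputs: np.ndarray) -> list:
    """Teacher-forced pass returning per-layer (h, c) states."""
    spec = model.spec
    H = spec.n_hidden
    states = [[np.zeros(H), np.zeros(H)] for _ in spec.n_layers * [0]]
    for x in inputs:
        cur = x
        for li, lp in enumerate(model.params["layers"]):
            h, c = states[li]
            if spec.cell_kind == "lstm":
                h, c = lstm_step(lp, cur, h, c)
            else:
                h = gru_step(lp, cur, h)
            states[li] = [h, c]
            cur = h
    return states


def forecast_recursive(
    model: GatedModel,
    warm_inputs: np.ndarray,
    exogenous: np.ndarray | None,
    n_steps: int,
    v_init: float,
) -> np.ndarray:
    """Closed-loop forecast with the voltage input slot fed back.

    The hidden (and cell) states are first warmed by a teacher-forced pass
    over ``warm_inputs`` (typically the training segment).  Then, at each
    of ``n_steps`` steps, the input is [exogenous[k]..., v] with v the
    previous prediction; the network output becomes the next prediction.
    The interface mirrors the ESN closed-loop forecaster.
    """
    spec = model.spec
    warm_inputs = np.atleast_2d(np.asarray(warm_inputs, dtype=float))
    states = _warm_states(model, warm_inputs)
    n_exo = spec.n_inputs - 1
    if n_exo:
        if exogenous is None:
            raise ValueError(f"model expects {n_exo} exogenous channel(s)")
        exogenous = np.asarray(exogenous, dtype=float).reshape(n_steps, n_exo)
    preds = np.empty(n_steps)
    v = float(v_init)
    for k in range(n_steps):
        x = np.empty(spec.n_inputs)
        if n_exo:
            x[:n_exo] = exogenous[k]
        x[-1] = v
        cur = x
        for li, lp in enumerate(model.params["layers"]):
            h, c = states[li]
            if spec.cell_kind == "lstm":
                h, c = lstm_step(lp, cur, h, c)
            else:
                h = gru_step(lp, cur, h)
            states[li] = [h, c]
            cur = h
        y = float((model.params["Wy"] @ cur)[0] + model.params["by"][0])
        if not np.isfinite(y):
            raise FloatingPointError(f"forecast diverged at step {k}")
        preds[k] = y
        v = y
    return preds
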