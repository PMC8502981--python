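"""Echo state networks: baseline, clustered, and physics-informed hybrid.

The reservoir is a fixed random recurrent network; only a linear readout
is trained, by ridge (Tikhonov) regression on teacher-forced states.  The
leaky state update is

    h_t = (1 - alpha) h_{t-1} + alpha * tanh(W_in x_t + W h_{t-1})

and the readout is y_t = W_out [x_t; h_t; 1].  Closed-loop forecasting
feeds each predicted voltage back into the input's voltage slot while
exogenous slots (stimulus timing, knowledge-based model voltage) come
from known channels.  Input ordering for the hybrid variant is
[stimulus, V_KB, V]; the voltage slot is always last.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .dataset import DatasetSplit
from .ionic_models import MSConfig, StimulusProtocol, simulate_ms

__all__ = [
    "ReservoirSpec",
    "ESNModel",
    "HybridConfig",
    "build_reservoir",
    "build_input_weights",
    "step_state",
    "collect_states",
    "fit_readout",
    "train_esn",
    "forecast_closed_loop",
    "hybrid_forecast",
]


@dataclass(frozen=True)
class ReservoirSpec:
    """Reservoir construction hyperparameters.

    ``n_clusters = 1`` gives the baseline Erdos-Renyi topology; larger
    values build sparsely inter-connected sub-reservoirs (clustered ESN).
    Defaults are the tuned desk-scale configuration; every field is
    searchable by the evaluation grid.
    """

    n_neurons: int = 100
    connect_prob: float = 0.05
    spectral_radius: float = 0.9
    input_scale: float = 1.0
    leaking_rate: float = 0.25
    ridge_beta: float = 1e-3
    n_clusters: int = 1
    inter_cluster_prob: float = 0.01
    train_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.connect_prob <= 1:
            raise ValueError("connect_prob must lie in (0, 1]")
        if self.spectral_radius <= 0:
            raise ValueError("spectral_radius must be > 0")
        if not 0 <= self.leaking_rate <= 1:
            raise ValueError("leaking_rate must lie in [0, 1]")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")


@dataclass
class ESNModel:
    """Reservoir weights, leaky rate, trained readout, and current state."""

    W_in: np.ndarray
    W: np.ndarray
    alpha: float
    ridge_beta: float
    spec: ReservoirSpec
    W_out: np.ndarray | None = None
    h: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.h is None:
            self.h = np.zeros(self.W.shape[0])

    @property
    def n_inputs(self) -> int:
        return self.W_in.shape[1]

    def reset_state(self) -> None:
        self.h = np.zeros(self.W.shape[0])


def build_reservoir(spec: ReservoirSpec, max_redraws: int = 10) -> np.ndarray:
    """Random reservoir matrix scaled to the target spectral radius.

    Edges follow a directed Erdos-Renyi draw with probability
    ``connect_prob`` (within clusters) and ``inter_cluster_prob`` (between
    clusters, when ``n_clusters > 1``); nonzero weights are Uniform(-1, 1).
    The matrix is rescaled so its spectral radius equals
    ``spec.spectral_radius`` exactly, which (for values below one) enforces
    the echo state property in practice.  An all-zero draw is redrawn.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neurons
    sizes = [n // spec.n_clusters] * spec.n_clusters
    sizes[-1] += n - sum(sizes)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    cluster_of = np.empty(n, dtype=int)
    for c in range(spec.n_clusters):
        cluster_of[bounds[c]:bounds[c + 1]] = c
    same = cluster_of[:, None] == cluster_of[None, :]
    prob = np.where(same, spec.connect_prob, spec.inter_cluster_prob)
    for _ in range(max_redraws):
        mask = rng.random((n, n)) < prob
        weights = rng.uniform(-1.0, 1.0, size=(n, n))
        W = np.where(mask, weights, 0.0)
        radius = float(np.max(np.abs(np.linalg.eigvals(W))))
        if radius > 0:
            return W * (spec.spectral_radius / radius)
    raise RuntimeError("reservoir draw has zero spectral radius; "
                       "increase connect_prob or n_neurons")


def build_input_weights(spec: ReservoirSpec, n_inputs: int) -> np.ndarray:
    """Dense input weights, Uniform(-input_scale, input_scale).

    Drawn from an offset of the reservoir seed so reservoir and input
    matrices are independent but jointly reproducible.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    return rng.uniform(-spec.input_scale, spec.input_scale,
                       size=(spec.n_neurons, n_inputs))


def make_esn(spec: ReservoirSpec, n_inputs: int) -> ESNModel:
    """Assemble an untrained ESN from a spec."""
    return ESNModel(W_in=build_input_weights(spec, n_inputs),
                    W=build_reservoir(spec),
                    alpha=spec.leaking_rate,
                    ridge_beta=spec.ridge_beta,
                    spec=spec)


def step_state(model: ESNModel, x_t: np.ndarray) -> np.ndarray:
    """Advance the leaky reservoir state by one input and return it."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (model.n_inputs,):
        raise ValueError(f"expected input of length {model.n_inputs}")
    pre = model.W_in @ x_t + model.W @ model.h
    h = (1.0 - model.alpha) * model.h + model.alpha * np.tanh(pre)
    if not np.all(np.isfinite(h)):
        raise FloatingPointError("reservoir state diverged")
    model.h = h
    return h


def collect_states(
    model: ESNModel, inputs: np.ndarray, n_washout_rows: int
) -> np.ndarray:
    """Teacher-forced pass producing design rows [x_t; h_t; 1].

    The first ``n_washout_rows`` rows are discarded so the retained states
    no longer remember the arbitrary initial reservoir state.  A constant
    column is appended as a bias term for the linear readout.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    T = inputs.shape[0]
    if T == 0:
        raise ValueError("inputs must be nonempty")
    if n_washout_rows >= T:
        raise ValueError("washout must leave at least one row")
    n = model.W.shape[0]
    rows = np.empty((T - n_washout_rows, inputs.shape[1] + n + 1))
    for t in range(T):
        h = step_state(model, inputs[t])
        if t >= n_washout_rows:
            rows[t - n_washout_rows] = np.concatenate(
                [inputs[t], h, [1.0]])
    return rows


def fit_readout(
    design: np.ndarray, targets: np.ndarray, ridge_beta: float
) -> np.ndarray:
    """Closed-form Tikhonov-regularized least squares readout.

    Solves (D^T D + beta I) w = D^T y.  With beta = 0 the normal equations
    must be well conditioned or the fit is rejected.
    """
    design = np.asarray(design, dtype=float)
    targets = np.asarray(targets, dtype=float)
    gram = design.T @ design
    if ridge_beta > 0:
        gram = gram + ridge_beta * np.eye(gram.shape[0])
    else:
        if np.linalg.cond(gram) > 1e12:
            raise np.linalg.LinAlgError(
                "singular normal equations; use ridge_beta > 0")
    w = linalg.solve(gram, design.T @ targets, assume_a="sym")
    return w


def train_esn(
    spec: ReservoirSpec,
    inputs: np.ndarray,
    targets: np.ndarray,
    n_washout_rows: int,
) -> ESNModel:
    """Build an ESN, run the teacher-forced pass, and fit the readout.

    ``inputs[t]`` must predict ``targets[t]`` (one-step-ahead pairs are the
    caller's responsibility).  The model is returned with its state warmed
    to the end of the training inputs, ready for closed-loop forecasting.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    model = make_esn(spec, inputs.shape[1])
    design = collect_states(model, inputs, n_washout_rows)
    model.W_out = fit_readout(design, targets[n_washout_rows:],
                              spec.ridge_beta)
    return model


def forecast_closed_loop(
    model: ESNModel,
    exogenous: np.ndarray | None,
    n_steps: int,
    v_init: float,
) -> np.ndarray:
    """Recursive multi-step forecast with the voltage slot fed back.

    At step k the input is [exogenous[k]..., v] where v is the previous
    prediction (``v_init`` for the first step, normally the last observed
    training voltage).  Exogenous channels (stimulus, knowledge-based
    voltage) must be supplied for all ``n_steps``; the voltage slot is the
    last input component.  Returns the n_steps predictions in order.
    """
    if model.W_out is None:
        raise ValueError("model has no trained readout")
    n_exo = model.n_inputs - 1
    if n_exo:
        if exogenous is None:
            raise ValueError(f"model expects {n_exo} exogenous channel(s)")
        exogenous = np.atleast_2d(np.asarray(exogenous, dtype=float))
        if exogenous.ndim == 2 and exogenous.shape[0] == 1 and n_steps > 1:
            exogenous = exogenous.T
        if exogenous.shape[0] < n_steps:
            raise ValueError("exogenous channels shorter than n_steps")
    preds = np.empty(n_steps)
    v = float(v_init)
    for k in range(n_steps):
        x = np.empty(model.n_inputs)
        if n_exo:
            x[:n_exo] = exogenous[k]
        x[-1] = v
        h = step_state(model, x)
        y = float(model.W_out @ np.concatenate([x, h, [1.0]]))
        if not np.isfinite(y):
            raise FloatingPointError(f"forecast diverged at step {k}")
        preds[k] = y
        v = y
    return preds


def save_esn(model: ESNModel, path) -> None:
    """Checkpoint an ESN (weights, readout, spec) to HDF5."""
    import json

    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("W_in", data=model.W_in)
        fh.create_dataset("W", data=model.W)
        if model.W_out is not None:
            fh.create_dataset("W_out", data=model.W_out)
        fh.create_dataset("h", data=model.h)
        fh.attrs["spec"] = json.dumps(
            {f.name: getattr(model.spec, f.name)
             for f in model.spec.__dataclass_fields__.values()})


def load_esn(path) -> ESNModel:
    import json

    import h5py

    with h5py.File(path, "r") as fh:
        spec = ReservoirSpec(**json.loads(fh.attrs["spec"]))
        model = ESNModel(
            W_in=fh["W_in"][:], W=fh["W"][:], alpha=spec.leaking_rate,
            ridge_beta=spec.ridge_beta, spec=spec,
            W_out=fh["W_out"][:] if "W_out" in fh else None,
            h=fh["h"][:])
    return model


@dataclass(frozen=True)
class HybridConfig:
    """Knowledge-based channel configuration for the hybrid ESN.

    The Mitchell-Schaeffer model is integrated on the dataset's own pacing
    protocol and sampled at every train/test grid time, forming the u2
    input channel; u1 is the stimulus and u3 the (fed-back) voltage.
    """

    kb_model: MSConfig = field(default_factory=MSConfig)
    kb_stim_amplitude: float = 0.2
    kb_scale: float = 0.05


def kb_voltage_on_grid(
    hybrid: HybridConfig,
    protocol: StimulusProtocol,
    grid_times: np.ndarray,
) -> np.ndarray:
    """Knowledge-based model voltage sampled at arbitrary grid times."""
    proto = StimulusProtocol(protocol.pulse_times, protocol.pulse_duration,
                             hybrid.kb_stim_amplitude)
    t_end = float(np.max(grid_times)) + hybrid.kb_model.dt
    kb = simulate_ms(hybrid.kb_model, proto, t_end=t_end)
    return np.interp(grid_times, kb.times, kb.voltage)


def _series_inputs(split: DatasetSplit,
                   kb: np.ndarray | None) -> tuple[np.ndarray, np.ndarray,
                                                   int, int]:
    """One-step-ahead (inputs, targets) over the full series.

    Input row t is [stim_t, (kb_{t+1},) v_t]; target t is v_{t+1}.  The
    knowledge-based channel is aligned with the *forecast target* time:
    since the kb model runs on the known stimulus protocol, its voltage at
    the time being predicted is available and is the informative value (a
    kb model matched to the data generator then makes the readout exact).
    Returns (X, y, washout_rows, n_train_rows): washout_rows covers the
    warmup beats, and rows up to washout+n_train_rows the training beats.
    """
    full = split.full
    cols = []
    if full.stimulus is not None:
        cols.append(full.stimulus[:-1])
    if kb is not None:
        cols.append(kb[1:])
    cols.append(full.voltage[:-1])
    X = np.column_stack(cols)
    y_all = full.voltage[1:]
    n_pre = len(split.pre_train)
    n_train = len(split.train)
    return X, y_all, n_pre, n_train


def train_forecast_esn(
    split: DatasetSplit,
    spec: ReservoirSpec,
    kb: np.ndarray | None = None,
) -> np.ndarray:
    """End-to-end train + closed-loop forecast over the test segment.

    ``kb`` is the optional knowledge-based voltage on the full grid (the
    hybrid input channel).  Returns predicted voltage at every test grid
    time.
    """
    X, y, n_washout, n_train = _series_inputs(split, kb)
    i_split = n_washout + n_train  # first test index in the full series
    model = make_esn(spec, X.shape[1])
    X_tf = X[:i_split - 1]
    if spec.train_noise > 0:
        # noise on the fed-back voltage slot during teacher forcing, the
        # standard trick to immunize the closed loop against its own
        # prediction error
        noise_rng = np.random.default_rng(spec.seed + 2_000_003)
        X_tf = X_tf.copy()
        X_tf[:, -1] += spec.train_noise * noise_rng.standard_normal(
            X_tf.shape[0])
    design = collect_states(model, X_tf, n_washout)
    model.W_out = fit_readout(design, y[n_washout:i_split - 1],
                              spec.ridge_beta)
    n_test = len(y) - (i_split - 1)
    exo = X[i_split - 1:, :-1] if X.shape[1] > 1 else None
    v_init = X[i_split - 1, -1]
    return forecast_closed_loop(model, exo, n_test, v_init)


def hybrid_forecast(
    split: DatasetSplit,
    hybrid: HybridConfig,
    spec: ReservoirSpec,
    protocol: StimulusProtocol,
) -> np.ndarray:
    """Hybrid (physics-informed) ESN forecast of the test segment.

    Runs the knowledge-based Mitchell-Schaeffer model on the dataset's
    stimulus protocol, samples it on the full grid, and trains/forecasts
    with the three-channel input [stimulus; V_KB; V].
    """
    if split.full.stimulus is None:
        raise ValueError("hybrid ESN requires a stimulus channel")
    kb = kb_voltage_on_grid(hybrid, protocol, split.full.times)
    return train_forecast_esn(split, spec, kb=hybrid.kb_scale * kb)
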