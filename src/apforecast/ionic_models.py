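"""Cell-model simulators producing irregular action-potential time series.

Three deterministic ODE models, all integrated by forward Euler:

* Fenton-Karma (FK) three-variable model (Fenton & Karma 1998), using the
  Beeler-Reuter fitting ("parameter set 3" of Fenton, Cherry, Hastings &
  Evans 2002), paced with cycle lengths drawn from a normal distribution
  -- stochastic irregular alternans.
* Noble (1962) four-variable Purkinje model whose anionic conductance is
  slaved to the z variable of a time-rescaled chaotic Lorenz system --
  chaotic beat-to-beat variability without external pacing.
* Mitchell-Schaeffer two-variable model in the Corrado-Niederer (2016)
  formulation -- the simplified knowledge-based model used by the hybrid
  echo state network.

Voltages are dimensionless in FK and MS (upstroke ~1); Noble voltage is in
mV and is rescaled downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .dataset import SampledSeries

__all__ = [
    "SimulationDiverged",
    "StimulusProtocol",
    "FKConfig",
    "NobleLorenzConfig",
    "MSConfig",
    "make_random_cl_protocol",
    "square_pulse_current",
    "simulate_fk",
    "simulate_noble_lorenz",
    "simulate_ms",
]


class SimulationDiverged(RuntimeError):
    """Raised when an integration leaves its physical bounds."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Square-pulse pacing protocol.

    Pulses occupy half-open intervals ``[onset, onset + pulse_duration)``.
    """

    pulse_times: np.ndarray
    pulse_duration: float = 2.0
    pulse_amplitude: float = 0.4

    def __post_init__(self) -> None:
        object.__setattr__(self, "pulse_times",
                           np.asarray(self.pulse_times, dtype=float))
        if len(self.pulse_times) and not np.all(np.diff(self.pulse_times) > 0):
            raise ValueError("pulse_times must be strictly increasing")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be > 0")
        if self.pulse_amplitude < 0:
            raise ValueError("pulse_amplitude must be >= 0")

    @property
    def t_last(self) -> float:
        return float(self.pulse_times[-1]) if len(self.pulse_times) else 0.0


def make_random_cl_protocol(
    n_beats: int,
    mean_cl: float = 320.0,
    sd_cl: float = 50.0,
    duration: float = 2.0,
    amplitude: float = 0.4,
    seed: int = 0,
    *,
    floor: float = 290.0,
    t_first: float = 50.0,
    max_redraws: int = 1000,
) -> StimulusProtocol:
    """Pacing protocol with cycle lengths drawn from Normal(mean_cl, sd_cl).

    Intervals below ``floor`` are redrawn.  The default floor is the
    measured 1:1 capture boundary of the Fenton-Karma model used here
    (after a long beat, stimuli arriving sooner than ~290 ms fall into the
    refractory period and fail to elicit a full action potential), so
    every delivered pulse produces exactly one beat.
    """
    if n_beats <= 0:
        raise ValueError("n_beats must be positive")
    if mean_cl <= 0 or mean_cl <= duration:
        raise ValueError("mean_cl must exceed the pulse duration")
    if sd_cl < 0:
        raise ValueError("sd_cl must be >= 0")
    rng = np.random.default_rng(seed)
    intervals = np.empty(n_beats - 1)
    redraws = 0
    for i in range(n_beats - 1):
        cl = rng.normal(mean_cl, sd_cl)
        while cl < floor:
            redraws += 1
            if redraws > max_redraws:
                raise ValueError("too many cycle-length redraws below floor")
            cl = rng.normal(mean_cl, sd_cl)
        intervals[i] = cl
    onsets = t_first + np.concatenate([[0.0], np.cumsum(intervals)])
    return StimulusProtocol(onsets, duration, amplitude)


def square_pulse_current(t, protocol: StimulusProtocol):
    """Stimulus current at time(s) ``t``: amplitude inside a pulse, else 0."""
    t = np.asarray(t, dtype=float)
    onsets = protocol.pulse_times
    i = np.searchsorted(onsets, t, side="right") - 1
    valid = i >= 0
    inside = np.zeros(t.shape, dtype=bool)
    inside[valid] = t[valid] < onsets[i[valid]] + protocol.pulse_duration
    out = np.where(inside, protocol.pulse_amplitude, 0.0)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Fenton-Karma
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FKConfig:
    """Fenton-Karma parameters, defaulting to the Beeler-Reuter fitting
    (set 3 of Fenton, Cherry, Hastings & Evans, Chaos 2002)."""

    tau_v_plus: float = 3.33
    tau_v1_minus: float = 1250.0
    tau_v2_minus: float = 19.6
    tau_w_plus: float = 870.0
    tau_w_minus: float = 41.0
    tau_d: float = 0.25
    tau_0: float = 12.5
    tau_r: float = 33.33
    tau_si: float = 29.0
    k: float = 10.0
    u_c_si: float = 0.85
    u_c: float = 0.13
    u_v: float = 0.04
    dt: float = 0.1
    initial_state: tuple[float, float, float] = (0.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for name in ("tau_v_plus", "tau_v1_minus", "tau_v2_minus",
                     "tau_w_plus", "tau_w_minus", "tau_d", "tau_0", "tau_r",
                     "tau_si"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@njit(cache=True)
def _fk_kernel(n_steps, dt, stim, u0, v0, w0,
               tau_v_plus, tau_v1_minus, tau_v2_minus, tau_w_plus,
               tau_w_minus, tau_d, tau_0, tau_r, tau_si, k, u_c_si, u_c,
               u_v):  # pragma: no cover - exercised via simulate_fk
    u_out = np.empty(n_steps + 1)
    u, v, w = u0, v0, w0
    u_out[0] = u
    g_lo = min(v, w)
    g_hi = max(v, w)
    for i in range(n_steps):
        p = 1.0 if u >= u_c else 0.0
        q = 1.0 if u >= u_v else 0.0
        tau_v_minus = q * tau_v1_minus + (1.0 - q) * tau_v2_minus
        j_fi = -v * p * (1.0 - u) * (u - u_c) / tau_d
        j_so = u * (1.0 - p) / tau_0 + p / tau_r
        j_si = -w * (1.0 + math.tanh(k * (u - u_c_si))) / (2.0 * tau_si)
        du = -(j_fi + j_so + j_si) + stim[i]
        dv = (1.0 - p) * (1.0 - v) / tau_v_minus - p * v / tau_v_plus
        dw = (1.0 - p) * (1.0 - w) / tau_w_minus - p * w / tau_w_plus
        u += dt * du
        v += dt * dv
        w += dt * dw
        u_out[i + 1] = u
        if v < g_lo:
            g_lo = v
        if w < g_lo:
            g_lo = w
        if v > g_hi:
            g_hi = v
        if w > g_hi:
            g_hi = w
        if not (math.isfinite(u) and -0.5 < u < 2.0):
            return u_out[: i + 2], g_lo, g_hi, 1
    return u_out, g_lo, g_hi, 0


def simulate_fk(
    config: FKConfig, protocol: StimulusProtocol, t_end: float | None = None
) -> SampledSeries:
    """Integrate the FK model under a pacing protocol by forward Euler.

    Returns a uniform-grid series (spacing ``config.dt``) with the voltage
    variable u and the stimulus channel.  The model's upstroke is already
    normalized so u peaks near 1; no downstream rescaling is needed.
    """
    dt = config.dt
    if dt > protocol.pulse_duration:
        raise ValueError("dt must not exceed the pulse duration")
    if t_end is None:
        t_end = protocol.t_last + 500.0
    if t_end < protocol.t_last + protocol.pulse_duration:
        raise ValueError("t_end must cover all pulses")
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    stim = square_pulse_current(times[:-1], protocol)
    u0, v0, w0 = config.initial_state
    u, gate_lo, gate_hi, flag = _fk_kernel(
        n_steps, dt, stim, u0, v0, w0,
        config.tau_v_plus, config.tau_v1_minus, config.tau_v2_minus,
        config.tau_w_plus, config.tau_w_minus, config.tau_d, config.tau_0,
        config.tau_r, config.tau_si, config.k, config.u_c_si, config.u_c,
        config.u_v)
    if flag:
        raise SimulationDiverged(
            f"FK integration left physical bounds at t={len(u) * dt:.1f} ms")
    stim_full = square_pulse_current(times, protocol)
    meta = {"model": "fenton_karma", "dt": dt,
            "pulse_amplitude": protocol.pulse_amplitude,
            "pulse_duration": protocol.pulse_duration,
            "gate_range": (gate_lo, gate_hi)}
    return SampledSeries(times, u, stim_full, meta)


# --------------------------------------------------------------------------
# Noble 1962 driven by a slow Lorenz system
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NobleLorenzConfig:
    """Noble (1962) Purkinje model coupled to a time-rescaled Lorenz system.

    The three Lorenz equations are multiplied by ``lorenz_time_factor`` so
    one Lorenz time unit spans 1/factor ms; the Noble anionic conductance
    follows g(z) = g_at_60 * z / 60 (clipped at 0), making beat timing and
    duration chaotic.  Noble voltage is in mV, capacitance 12 uF/cm^2.
    """

    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    lorenz_time_factor: float = 1e-3
    g_at_60: float = 0.2
    capacitance: float = 12.0
    dt: float = 0.02
    record_dt: float = 0.1
    burn_in: float = 5000.0
    initial_voltage: float = -87.0
    initial_lorenz: tuple[float, float, float] = (1.0, 1.0, 25.0)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.record_dt <= 0:
            raise ValueError("dt and record_dt must be > 0")
        if self.lorenz_time_factor <= 0:
            raise ValueError("lorenz_time_factor must be > 0")


@njit(cache=True)
def _safe_exp_ratio(a, y, s):  # pragma: no cover
    # a * y / (exp(y / s) - 1) with the removable singularity at y = 0.
    if abs(y) < 1e-7:
        return a * s
    return a * y / (math.exp(y / s) - 1.0)


@njit(cache=True)
def _noble_lorenz_kernel(n_steps, dt, record_every, V0, m0, h0, n0,
                         x0, y0, z0, sigma, rho, beta, tf, g60, cm,
                         freeze_anion):  # pragma: no cover
    n_rec = n_steps // record_every + 1
    v_out = np.empty(n_rec)
    z_out = np.empty(n_rec)
    V, m, h, n = V0, m0, h0, n0
    x, y, z = x0, y0, z0
    v_out[0] = V
    z_out[0] = z
    j = 1
    for i in range(n_steps):
        # Lorenz, slowed so its oscillations span hundreds of ms
        dx = tf * sigma * (y - x)
        dy = tf * (x * (rho - z) - y)
        dz = tf * (x * y - beta * z)
        # Noble 1962 rate constants (V in mV, rates in 1/ms)
        am = _safe_exp_ratio(0.1, -V - 48.0, 15.0)
        bm = _safe_exp_ratio(0.12, V + 8.0, 5.0)
        ah = 0.17 * math.exp((-V - 90.0) / 20.0)
        bh = 1.0 / (1.0 + math.exp((-V - 42.0) / 10.0))
        an = _safe_exp_ratio(0.0001, -V - 50.0, 10.0)
        bn = 0.002 * math.exp((-V - 90.0) / 80.0)
        g_na = 400.0 * m * m * m * h + 0.14
        g_k1 = 1.2 * math.exp((-V - 90.0) / 50.0) \
            + 0.015 * math.exp((V + 90.0) / 60.0)
        g_k2 = 1.2 * n * n * n * n
        i_na = g_na * (V - 40.0)
        i_k = (g_k1 + g_k2) * (V + 100.0)
        g_an = 0.0 if freeze_anion else max(g60 * z / 60.0, 0.0)
        i_an = g_an * (V + 60.0)
        V += dt * (-(i_na + i_k + i_an) / cm)
        m += dt * (am * (1.0 - m) - bm * m)
        h += dt * (ah * (1.0 - h) - bh * h)
        n += dt * (an * (1.0 - n) - bn * n)
        x += dt * dx
        y += dt * dy
        z += dt * dz
        if (i + 1) % record_every == 0:
            v_out[j] = V
            z_out[j] = z
            j += 1
        if not math.isfinite(V) or V < -150.0 or V > 100.0:
            return v_out[:j], z_out[:j], 1
    return v_out[:j], z_out[:j], 0


def _noble_gate_steady_state(V: float) -> tuple[float, float, float]:
    def ratio(a, y, s):
        return a * s if abs(y) < 1e-7 else a * y / (math.exp(y / s) - 1.0)

    am = ratio(0.1, -V - 48.0, 15.0)
    bm = ratio(0.12, V + 8.0, 5.0)
    ah = 0.17 * math.exp((-V - 90.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp((-V - 42.0) / 10.0))
    an = ratio(0.0001, -V - 50.0, 10.0)
    bn = 0.002 * math.exp((-V - 90.0) / 80.0)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def simulate_noble_lorenz(
    config: NobleLorenzConfig,
    t_end: float,
    *,
    freeze_anion: bool = False,
) -> SampledSeries:
    """Co-integrate Noble 1962 with the slowed Lorenz system.

    The cell beats autonomously (no stimulus channel); the chaotic z
    variable modulates the anionic conductance and hence beat timing and
    duration.  The first ``config.burn_in`` ms are discarded so the
    trajectory starts near the attractor.  ``freeze_anion`` zeroes the
    coupling, leaving the Noble model autonomous (for decoupling checks).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    dt = config.dt
    record_every = max(int(round(config.record_dt / dt)), 1)
    total = t_end + config.burn_in
    n_steps = int(round(total / dt))
    m0, h0, n0 = _noble_gate_steady_state(config.initial_voltage)
    x0, y0, z0 = config.initial_lorenz
    v, _, flag = _noble_lorenz_kernel(
        n_steps, dt, record_every, config.initial_voltage, m0, h0, n0,
        x0, y0, z0, config.sigma, config.rho, config.beta,
        config.lorenz_time_factor, config.g_at_60, config.capacitance,
        freeze_anion)
    if flag:
        raise SimulationDiverged("Noble-Lorenz integration diverged")
    times = np.arange(len(v)) * dt * record_every
    keep = times >= config.burn_in
    meta = {"model": "noble_lorenz", "dt": dt, "record_dt": config.record_dt,
            "burn_in": config.burn_in}
    return SampledSeries(times[keep] - config.burn_in, v[keep], None, meta)


# --------------------------------------------------------------------------
# Mitchell-Schaeffer (Corrado-Niederer formulation)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MSConfig:
    """Corrado-Niederer update of the Mitchell-Schaeffer two-variable model.

    The inward current uses v(v - v_gate)(1 - v) so the rest state is
    stable (no spurious pacemaking); defaults are the values used with the
    hybrid forecaster: tau_in 0.3 ms, tau_out 6 ms, tau_open 120 ms,
    tau_close 150 ms, v_gate 0.13.
    """

    tau_in: float = 0.3
    tau_out: float = 6.0
    tau_open: float = 120.0
    tau_close: float = 150.0
    v_gate: float = 0.13
    dt: float = 0.1
    initial_state: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("tau_in", "tau_out", "tau_open", "tau_close"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.v_gate <= 1:
            raise ValueError("v_gate must lie in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@njit(cache=True)
def _ms_kernel(n_steps, dt, stim, v0, h0, tau_in, tau_out, tau_open,
               tau_close, v_gate):  # pragma: no cover
    v_out = np.empty(n_steps + 1)
    v, h = v0, h0
    v_out[0] = v
    g_lo = h
    g_hi = h
    for i in range(n_steps):
        j_in = h * v * (v - v_gate) * (1.0 - v) / tau_in
        j_out = -v / tau_out
        dv = j_in + j_out + stim[i]
        dh = (1.0 - h) / tau_open if v < v_gate else -h / tau_close
        v += dt * dv
        h += dt * dh
        v_out[i + 1] = v
        if h < g_lo:
            g_lo = h
        if h > g_hi:
            g_hi = h
        if not (math.isfinite(v) and -0.5 < v < 2.0):
            return v_out[: i + 2], g_lo, g_hi, 1
    return v_out, g_lo, g_hi, 0


def simulate_ms(
    config: MSConfig, protocol: StimulusProtocol, t_end: float | None = None
) -> SampledSeries:
    """Integrate the Mitchell-Schaeffer model under a pacing protocol.

    Produces [0, 1]-scale action potentials aligned with the protocol that
    also paces the data being forecast; this is the knowledge-based channel
    of the hybrid echo state network.
    """
    dt = config.dt
    if dt > protocol.pulse_duration:
        raise ValueError("dt must not exceed the pulse duration")
    if t_end is None:
        t_end = protocol.t_last + 500.0
    if t_end < protocol.t_last + protocol.pulse_duration:
        raise ValueError("t_end must cover all pulses")
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    stim = square_pulse_current(times[:-1], protocol)
    v0, h0 = config.initial_state
    v, gate_lo, gate_hi, flag = _ms_kernel(
        n_steps, dt, stim, v0, h0, config.tau_in, config.tau_out,
        config.tau_open, config.tau_close, config.v_gate)
    if flag:
        raise SimulationDiverged("Mitchell-Schaeffer integration diverged")
    stim_full = square_pulse_current(times, protocol)
    meta = {"model": "mitchell_schaeffer", "dt": dt,
            "gate_range": (gate_lo, gate_hi)}
    return SampledSeries(times, v, stim_full, meta)
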