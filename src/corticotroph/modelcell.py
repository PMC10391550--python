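"""Minimal conductance-based model corticotroph.

A three-variable pituitary-cell model (membrane potential V, delayed
rectifier activation n, A-current inactivation h) that rests near −51 mV,
fires noise-driven single spikes at the low rates typical of corticotrophs,
depolarizes and speeds up under a CRH-like applied current, and — when a
fast BK-type conductance is added in closed loop — transitions to
pseudo-plateau bursting.  The currents are

    C dV/dt = −[ gCa·m∞(V)(V−VCa) + gK·n(V−VK) + gA·a∞(V)·h(V−VK)
                 + gL(V−VL) ] + I_app + I_noise + I_inject

with logistic steady-state activations x∞(V) = 1/(1+exp((vx−V)/sx)) and
first-order gating kinetics.  Units: nS·mV = pA and pA/pF = mV/ms, so all
terms are consistent without conversion factors.  Stochastic drive is an
Ornstein–Uhlenbeck current (10 ms correlation time) integrated by
Euler–Maruyama with a mandatory seed.

All parameter values here are calibrations of this package (chosen to
reproduce the qualitative corticotroph phenotypes), not measured constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

try:
    from numba import njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

from .events import Trace

__all__ = [
    "CellParams",
    "SimResult",
    "derivatives",
    "simulate",
    "crh_stimulus",
    "B_LIKE",
    "A_LIKE",
]

_BLOWUP_MV = 200.0


@dataclass(frozen=True)
class CellParams:
    """Model-cell parameters (pF, nS, mV, ms, pA)."""

    C: float = 3.0          # membrane capacitance, pF
    gCa: float = 2.5        # Ca conductance (instantaneous activation), nS
    VCa: float = 60.0
    vm: float = -18.0
    sm: float = 8.0
    gK: float = 4.0         # delayed rectifier, nS
    VK: float = -75.0
    vn: float = -5.0
    sn: float = 10.0
    tau_n: float = 60.0     # ms
    gA: float = 0.0         # A-type K current, nS (0 for the B-like preset)
    va: float = -20.0
    sa: float = 10.0
    vh: float = -65.0
    sh: float = -5.0        # negative slope: h inactivates with depolarization
    tau_h: float = 20.0     # ms
    gL: float = 0.8         # leak, nS
    VL: float = -56.0
    I_app: float = 0.0      # CRH-like applied current, pA
    noise_amp: float = 1.2  # stationary sd of the OU noise current, pA
    tau_noise: float = 10.0 # OU correlation time, ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("capacitance must be positive")
        for g in (self.gCa, self.gK, self.gA, self.gL):
            if g < 0:
                raise ValueError("conductances must be non-negative")
        if self.tau_n <= 0 or self.tau_h <= 0 or self.tau_noise <= 0:
            raise ValueError("time constants must be positive")

    def _vector(self) -> np.ndarray:
        return np.array([self.C, self.gCa, self.VCa, self.vm, self.sm,
                         self.gK, self.VK, self.vn, self.sn, self.tau_n,
                         self.gA, self.va, self.sa, self.vh, self.sh,
                         self.tau_h, self.gL, self.VL, self.I_app,
                         self.noise_amp, self.tau_noise], dtype=np.float64)


def _logistic(v: float, mid: float, slope: float) -> float:
    return 1.0 / (1.0 + math.exp((mid - v) / slope))


def derivatives(state: tuple[float, float, float], params: CellParams,
                I_inject: float = 0.0) -> tuple[float, float, float]:
    """(dV/dt, dn/dt, dh/dt) in (mV/ms, 1/ms, 1/ms) for state (V, n, h)."""
    V, n, h = state
    if not all(map(math.isfinite, state)):
        raise FloatingPointError(f"non-finite state {state}")
    m_inf = _logistic(V, params.vm, params.sm)
    a_inf = _logistic(V, params.va, params.sa)
    n_inf = _logistic(V, params.vn, params.sn)
    h_inf = _logistic(V, params.vh, params.sh)
    I_ion = (params.gCa * m_inf * (V - params.VCa)
             + params.gK * n * (V - params.VK)
             + params.gA * a_inf * h * (V - params.VK)
             + params.gL * (V - params.VL))
    dV = (-I_ion + params.I_app + I_inject) / params.C
    dn = (n_inf - n) / params.tau_n
    dh = (h_inf - h) / params.tau_h
    return dV, dn, dh


@njit(cache=True)
def _core(p, duration_ms, dt_ms, stride, seed,
          gBK, vf, sf, tauBK, VK_bk, v0, n0, h0, f0):  # pragma: no cover
    """Fixed-step Euler–Maruyama loop; BK clamp fused in (gBK=0 disables).

    The BK activation f is advanced every step regardless of gBK so a gBK=0
    run is bit-identical to an unclamped one.
    """
    (C, gCa, VCa, vm, sm, gK, VK, vn, sn, tau_n,
     gA, va, sa, vh, sh, tau_h, gL, VL, I_app,
     noise_amp, tau_noise) = (p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7],
                              p[8], p[9], p[10], p[11], p[12], p[13], p[14],
                              p[15], p[16], p[17], p[18], p[19], p[20])
    np.random.seed(seed)
    n_steps = int(duration_ms / dt_ms)
    n_rec = n_steps // stride
    V_rec = np.empty(n_rec)
    n_rec_arr = np.empty(n_rec)
    f_rec = np.empty(n_rec)
    ibk_rec = np.empty(n_rec)
    V, n, h, f = v0, n0, h0, f0
    eta = 0.0
    ou_a = 1.0 - dt_ms / tau_noise
    ou_b = noise_amp * math.sqrt(2.0 * dt_ms / tau_noise)
    k = 0
    for i in range(n_steps):
        I_bk = gBK * f * (VK_bk - V)
        if i % stride == 0 and k < n_rec:
            V_rec[k] = V
            n_rec_arr[k] = n
            f_rec[k] = f
            ibk_rec[k] = I_bk
            k += 1
        m_inf = 1.0 / (1.0 + math.exp((vm - V) / sm))
        a_inf = 1.0 / (1.0 + math.exp((va - V) / sa))
        n_inf = 1.0 / (1.0 + math.exp((vn - V) / sn))
        h_inf = 1.0 / (1.0 + math.exp((vh - V) / sh))
        f_inf = 1.0 / (1.0 + math.exp((vf - V) / sf))
        I_ion = (gCa * m_inf * (V - VCa) + gK * n * (V - VK)
                 + gA * a_inf * h * (V - VK) + gL * (V - VL))
        dV = (-I_ion + I_app + eta + I_bk) / C
        V = V + dt_ms * dV
        n = n + dt_ms * (n_inf - n) / tau_n
        h = h + dt_ms * (h_inf - h) / tau_h
        f = f + dt_ms * (f_inf - f) / tauBK
        if f < 0.0:
            f = 0.0
        elif f > 1.0:
            f = 1.0
        if noise_amp > 0.0:
            eta = ou_a * eta + ou_b * np.random.standard_normal()
        if abs(V) > _BLOWUP_MV:
            return V_rec[:k], n_rec_arr[:k], f_rec[:k], ibk_rec[:k], i
    return V_rec, n_rec_arr, f_rec, ibk_rec, -1


@dataclass
class SimResult:
    """Voltage trace plus gating/clamp time courses from one simulation."""

    trace: Trace
    n: np.ndarray
    f: np.ndarray
    i_bk_pa: np.ndarray
    dt_ms: float

    @property
    def v_mv(self) -> np.ndarray:
        return self.trace.v_mv

    @property
    def t_ms(self) -> np.ndarray:
        return self.trace.t_s * 1000.0


def _steady_state(params: CellParams, v0: float = -55.0) -> tuple[float, float, float]:
    n0 = _logistic(v0, params.vn, params.sn)
    h0 = _logistic(v0, params.vh, params.sh)
    return v0, n0, h0


def simulate(params: CellParams, duration_ms: float, dt_ms: float = 0.05,
             record_fs_hz: float = 10_000.0,
             clamp_hook=None,
             _bk: tuple[float, float, float, float, float] | None = None,
             v0: float | None = None) -> SimResult:
    """Integrate the model cell with fixed-step Euler–Maruyama.

    The output is decimated to ``record_fs_hz``.  ``clamp_hook(t_ms, v_mv)``,
    when given, is called once per step and its return value (pA) is added
    to that step's current — this generic path runs in pure Python and is
    intended for short runs and cross-checks; the BK clamp has a fused fast
    path used by the dynclamp module.
    """
    if dt_ms > 0.1:
        raise ValueError("dt must be <= 0.1 ms (<= 100 us)")
    stride = max(1, int(round(1000.0 / record_fs_hz / dt_ms)))
    V0, n0, h0 = _steady_state(params, -55.0 if v0 is None else v0)
    if clamp_hook is not None:
        return _simulate_python(params, duration_ms, dt_ms, stride,
                                clamp_hook, V0, n0, h0)
    gBK, vf, sf, tauBK, VK_bk = _bk if _bk is not None else (0.0, -10.0, 2.0, 2.0, params.VK)
    f0 = _logistic(V0, vf, sf)
    V_rec, n_rec, f_rec, ibk_rec, blew = _core(
        params._vector(), duration_ms, dt_ms, stride, params.seed,
        gBK, vf, sf, tauBK, VK_bk, V0, n0, h0, f0)
    if blew >= 0:
        raise FloatingPointError(
            f"|V| exceeded {_BLOWUP_MV} mV at step {blew} "
            f"(t = {blew * dt_ms:.3f} ms) with params {params}")
    fs = 1000.0 / (dt_ms * stride)
    trace = Trace(v_mv=V_rec, fs_hz=fs,
                  metadata={"fs_hz": fs, "seed": params.seed, "model": True})
    return SimResult(trace=trace, n=n_rec, f=f_rec, i_bk_pa=ibk_rec,
                     dt_ms=dt_ms)


def _simulate_python(params: CellParams, duration_ms: float, dt_ms: float,
                     stride: int, clamp_hook, V, n, h) -> SimResult:
    rng_seed = params.seed
    np.random.seed(rng_seed)
    n_steps = int(duration_ms / dt_ms)
    recs_v, recs_n = [], []
    eta = 0.0
    ou_a = 1.0 - dt_ms / params.tau_noise
    ou_b = params.noise_amp * math.sqrt(2.0 * dt_ms / params.tau_noise)
    for i in range(n_steps):
        if i % stride == 0:
            recs_v.append(V)
            recs_n.append(n)
        I_inject = float(clamp_hook(i * dt_ms, V))
        dV, dn, dh = derivatives((V, n, h), params, I_inject + eta)
        V += dt_ms * dV
        n += dt_ms * dn
        h += dt_ms * dh
        if params.noise_amp > 0.0:
            eta = ou_a * eta + ou_b * np.random.standard_normal()
        if abs(V) > _BLOWUP_MV:
            raise FloatingPointError(
                f"|V| exceeded {_BLOWUP_MV} mV at step {i} with params {params}")
    fs = 1000.0 / (dt_ms * stride)
    v_arr = np.asarray(recs_v)
    trace = Trace(v_mv=v_arr, fs_hz=fs,
                  metadata={"fs_hz": fs, "seed": rng_seed, "model": True})
    return SimResult(trace=trace, n=np.asarray(recs_n),
                     f=np.zeros_like(v_arr), i_bk_pa=np.zeros_like(v_arr),
                     dt_ms=dt_ms)


def crh_stimulus(params: CellParams, level: float,
                 max_depolarizing_pa: float = 1.5) -> CellParams:
    """CRH-like drive: scale the applied depolarizing current by ``level``.

    At level 1 the B-like preset depolarizes by roughly 3-6 mV (measured by
    the three-point membrane-potential estimator) and fires more events.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must lie in [0, 1]")
    if level == 0.0:
        return params
    return replace(params, I_app=params.I_app + level * max_depolarizing_pa)


# Presets.  B-like: no A-current, shallow AHP (~10-15 mV), noise-driven
# single spiking near 0.5 Hz, transitions to pseudo-plateau bursting when a
# BK conductance is added in closed loop.  A-like: A-current sharpening the
# spike plus a strong delayed rectifier with an exaggerated K driving force,
# giving the deep (>25 mV) AHP and resistance to BK-induced bursting that
# characterize A-type cells; the deep VK is a calibration device, not a
# physiological estimate.
B_LIKE = CellParams()
A_LIKE = replace(B_LIKE, gA=3.0, gCa=3.0, gK=7.0, VK=-105.0, tau_n=40.0,
                 noise_amp=2.4)
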