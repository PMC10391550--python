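"""BK-conductance dynamic clamp.

The clamp reads the membrane potential each time step, advances the BK
activation f by forward Euler on

    tauBK * df/dt = f_inf(V) - f,    f_inf(V) = 1 / (1 + exp((vf - V)/sf)),

and injects I_BK = gBK * f * (VK - V) back into the cell on the next step.
Typical parameters: gBK 0.5-2 nS, vf = -10 mV, sf = 2 mV, tauBK = 2 ms,
with a fixed step of 21 us (at most 100 us).  Above the K reversal the
injected current is hyperpolarizing (negative), which is what converts
single spikes into pseudo-plateau bursts in burst-competent cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import modelcell
from .modelcell import CellParams, SimResult, crh_stimulus

__all__ = [
    "BKParams",
    "BKClampResult",
    "f_inf",
    "euler_step_f",
    "bk_current",
    "run_closed_loop",
]


@dataclass(frozen=True)
class BKParams:
    """BK clamp parameters (nS, mV, ms, us)."""

    gBK: float = 1.0
    vf: float = -10.0
    sf: float = 2.0
    tauBK: float = 2.0
    VK: float = -75.0
    dt_us: float = 21.0

    def __post_init__(self) -> None:
        if self.gBK < 0:
            raise ValueError("gBK must be non-negative")
        if self.sf <= 0:
            raise ValueError("sf must be positive")
        if self.tauBK <= 0:
            raise ValueError("tauBK must be positive")
        if not 0 < self.dt_us <= 100:
            raise ValueError("step must be in (0, 100] us")

    @property
    def dt_ms(self) -> float:
        return self.dt_us / 1000.0


def f_inf(V: float, vf: float = -10.0, sf: float = 2.0) -> float:
    """Steady-state BK activation: logistic in V, range (0, 1)."""
    if sf <= 0:
        raise ValueError("sf must be positive")
    return 1.0 / (1.0 + math.exp((vf - V) / sf))


def euler_step_f(f: float, V: float, dt_ms: float, params: BKParams) -> float:
    """One forward-Euler step of the activation ODE, clipped to [0, 1]."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    if dt_ms > params.tauBK:
        raise ValueError(f"step {dt_ms} ms exceeds tauBK {params.tauBK} ms "
                         "(unstable)")
    f_new = f + dt_ms * (f_inf(V, params.vf, params.sf) - f) / params.tauBK
    return min(1.0, max(0.0, f_new))


def bk_current(f: float, V: float, params: BKParams) -> float:
    """Injected BK current I_BK = gBK * f * (VK - V), in pA."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    return params.gBK * f * (params.VK - V)


@dataclass
class BKClampResult:
    """Audit record of a closed-loop run (arrays on the recording grid)."""

    sim: SimResult
    bk: BKParams
    cell: CellParams

    def __post_init__(self) -> None:
        f = self.sim.f
        if f.size and (f.min() < 0.0 or f.max() > 1.0):
            raise ValueError("BK activation left [0, 1]")

    @property
    def t_ms(self) -> np.ndarray:
        return self.sim.t_ms

    @property
    def v_mv(self) -> np.ndarray:
        return self.sim.v_mv

    @property
    def f(self) -> np.ndarray:
        return self.sim.f

    @property
    def i_bk_pa(self) -> np.ndarray:
        return self.sim.i_bk_pa

    @property
    def injected_charge_pc(self) -> float:
        """Total injected charge, pC (integral of I_BK over time)."""
        return float(np.trapezoid(self.i_bk_pa, self.t_ms)) / 1000.0

    @property
    def mean_abs_i_bk_pa(self) -> float:
        return float(np.mean(np.abs(self.i_bk_pa))) if self.i_bk_pa.size else 0.0


def run_closed_loop(cell: CellParams, bk: BKParams,
                    duration_s: float = 30.0, crh_level: float = 0.0,
                    seed: int | None = None) -> BKClampResult:
    """Simulate the model cell with the BK clamp in closed loop.

    Cell and clamp share the clamp's fixed step; with gBK = 0 the voltage
    trace is bit-identical to an unclamped simulation at the same step and
    seed.  Output is decimated to ~10 kHz.
    """
    params = crh_stimulus(cell, crh_level)
    if seed is not None:
        from dataclasses import replace
        params = replace(params, seed=seed)
    sim = modelcell.simulate(params, duration_ms=duration_s * 1000.0,
                             dt_ms=bk.dt_ms,
                             _bk=(bk.gBK, bk.vf, bk.sf, bk.tauBK, bk.VK))
    return BKClampResult(sim=sim, bk=bk, cell=params)
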