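"""Whole-cell patch-clamp circuit simulation and capacitance extraction.

The cell under voltage clamp is modelled as the classical three-element
network: pipette series resistance ``R_s`` feeding a membrane with
resistance ``R_m`` in parallel with a voltage-dependent capacitance,
optionally shunted by a single-barrier channel conductance.  The
membrane charge is

    Q(V) = C_lin * V + Q_max * b(V),        C(V) = dQ/dV,

so charge balance gives the governing equation

    C(V_m) dV_m/dt = (V_cmd - V_m)/R_s - (V_m - E_off)/R_m - I_barrier(V_m),

with the recorded (amplifier) current ``(V_cmd - V_m)/R_s``.  This is
what allows capacitive currents produced by a ramp command to be
computed and subtracted from recordings to reveal the ionic component,
and what generates test data for the dual-sine capacitance estimator.

Dual-sine capacitance extraction: a command of two superposed sinusoids
at f1 and 2*f1 riding on a slow ramp (or hold) yields, by synchronous
detection over windows of an integer number of f1 cycles, the complex
admittances Y(f1) and Y(2f1).  Writing Z = 1/Y = R_s + R_m/(1 + i a),
a = omega R_m C_m, the imaginary parts at the two frequencies give

    r = Im Z(2 f1) / Im Z(f1) = 2 (1 + a^2) / (1 + 4 a^2),
    a^2 = (2 - r) / (4 r - 2),            (valid for 0.5 < r < 2)
    R_m = -Im Z(f1) (1 + a^2) / a,
    C_m = a / (omega_1 R_m),
    R_s = Re Z(f1) - R_m / (1 + a^2).

This closed-form inversion of the three-element circuit is derived here
from the circuit algebra (commercial acquisition software implements an
equivalent, unpublished solve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .barrier import BarrierParams
from .constants import thermal_voltage_mV
from .exceptions import DomainError
from .nlc import BoltzmannParams, cm_model
from .noise import Trace

__all__ = [
    "PatchModel",
    "Protocol",
    "SimulationResult",
    "DualSineResult",
    "simulate_recording",
    "capacitive_current",
    "correct_capacitive",
    "dual_sine_capacitance",
    "membrane_charge",
    "hold_steady_state",
]

#: default step-protocol levels, mV
DEFAULT_STEP_LEVELS = tuple(range(-150, 151, 20))


def membrane_charge(v, params: BoltzmannParams):
    """Total membrane charge Q(V) = C_lin V + Q_max b(V), fC."""
    from scipy.special import expit

    v = np.asarray(v, dtype=float)
    vt = thermal_voltage_mV(params.temperature)
    b = expit(params.z * (v - params.v_h) / vt)
    out = params.c_lin * v + params.q_max * b
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PatchModel:
    """Three-element patch-clamp circuit with NLC and optional channel leak.

    Attributes
    ----------
    r_series : float
        Pipette series resistance, MOhm.
    r_membrane : float
        Ohmic membrane (seal/leak) resistance, MOhm.
    boltzmann : BoltzmannParams
        Voltage-dependent membrane capacitance.
    barrier : BarrierParams, optional
        Channel conductance in parallel with R_m; ``g`` is interpreted
        in pS (absolute, not density) inside the circuit.
    reversal_offset : float
        Reversal potential of the ohmic leak, mV.
    """

    r_series: float = 5.0
    r_membrane: float = 500.0
    boltzmann: BoltzmannParams = field(
        default_factory=lambda: BoltzmannParams(304.8, -96.26, 0.74, 15.0))
    barrier: BarrierParams | None = None
    reversal_offset: float = 0.0

    def __post_init__(self):
        if self.r_series <= 0 or self.r_membrane <= 0:
            raise DomainError("resistances must be > 0 MOhm")


@dataclass(frozen=True)
class Protocol:
    """A voltage-command protocol.

    ``kind`` is one of:

    - ``"hold"``: constant ``v_hold`` for ``duration``;
    - ``"ramp"``: optional settle at ``v_start`` then linear ramp to
      ``v_end`` over ``duration``;
    - ``"step"``: from ``v_hold``, each entry of ``levels`` for
      ``step_duration`` with a ``step_duration`` return to ``v_hold``
      in between;
    - ``"dual_sine"``: sinusoids ``amp1 sin(2 pi f1 t) +
      amp2 sin(4 pi f1 t)`` superposed on a hold or ramp base.

    ``dt`` is the sampling interval in seconds.
    """

    kind: str
    dt: float = 1e-5
    duration: float = 0.1
    v_hold: float = 0.0
    v_start: float = -150.0
    v_end: float = 150.0
    settle: float = 0.0
    levels: tuple = DEFAULT_STEP_LEVELS
    step_duration: float = 0.05
    amp1: float = 10.0
    amp2: float = 10.0
    f1: float = 390.625
    base: str = "hold"  # for dual_sine: "hold" or "ramp"

    def __post_init__(self):
        if self.kind not in ("hold", "ramp", "step", "dual_sine"):
            raise DomainError(f"unknown protocol kind {self.kind!r}")
        if self.dt <= 0 or self.duration <= 0 or self.step_duration <= 0:
            raise DomainError("dt and durations must be > 0")

    @property
    def total_duration(self) -> float:
        if self.kind == "step":
            return (2 * len(self.levels) + 1) * self.step_duration
        base = self.duration + (self.settle if self.kind in ("ramp", "dual_sine") else 0)
        return base

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration / self.dt))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def command(self, t) -> np.ndarray:
        """Command voltage at times ``t`` (s), mV."""
        t = np.asarray(t, dtype=float)
        if self.kind == "hold":
            return np.full_like(t, self.v_hold)
        if self.kind == "ramp":
            return self._ramp(t)
        if self.kind == "step":
            period = 2 * self.step_duration
            seg = np.floor(t / self.step_duration).astype(int)
            v = np.full_like(t, self.v_hold)
            active = (seg % 2 == 1)
            idx = np.clip((seg - 1) // 2, 0, len(self.levels) - 1)
            v[active] = np.asarray(self.levels, dtype=float)[idx[active]]
            v[seg >= 2 * len(self.levels)] = self.v_hold
            return v
        # dual_sine
        base = self._ramp(t) if self.base == "ramp" else np.full_like(t, self.v_hold)
        w1 = 2 * math.pi * self.f1
        return base + self.amp1 * np.sin(w1 * t) + self.amp2 * np.sin(2 * w1 * t)

    def _ramp(self, t):
        tt = np.clip(t - self.settle, 0.0, self.duration)
        return self.v_start + (self.v_end - self.v_start) * tt / self.duration


@dataclass
class SimulationResult:
    """Output of :func:`simulate_recording`."""

    command: Trace
    v_membrane: Trace
    current: Trace
    n_substeps: int = 1

    @property
    def time(self) -> np.ndarray:
        return self.command.time


def _rhs_factory(model: PatchModel):
    """Scalar dV_m/dt (mV/s) and recorded-current helpers in working units."""
    bp = model.boltzmann
    vt = thermal_voltage_mV(bp.temperature)
    zvt = bp.z / vt
    qz = bp.q_max * bp.z / vt
    rs, rm, eoff = model.r_series, model.r_membrane, model.reversal_offset
    bar = model.barrier
    if bar is not None:
        vt_q = thermal_voltage_mV(bar.temperature) / bar.q
        gpre = bar.g * vt_q * 1e-3
        d, p = bar.delta, bar.p_rel

    def dvdt(vm: float, vcmd: float) -> float:
        # mV/MOhm = nA -> *1e3 pA; pA/pF = V/s -> *1e3 mV/s
        i_net = 1e3 * (vcmd - vm) / rs - 1e3 * (vm - eoff) / rm
        if bar is not None:
            # clamp exponents: transiently unstable coarse integrations must
            # produce large-but-finite slopes for the divergence detector
            u = min(max(vm / vt_q, -200.0), 200.0)
            i_net -= gpre * (p * math.exp((1.0 - d) * u) - math.exp(-d * u))
        x = zvt * (vm - bp.v_h)
        if x < -60.0 or x > 60.0:
            c = bp.c_lin
        else:
            b = 1.0 / (1.0 + math.exp(-x))
            c = bp.c_lin + qz * b * (1.0 - b)
        return 1e3 * i_net / c

    return dvdt


def simulate_recording(model: PatchModel, protocol: Protocol,
                       rel_tol: float = 1e-3, max_substeps: int = 32) -> SimulationResult:
    """Integrate the clamp circuit under a protocol.

    Classical 4th-order Runge-Kutta on the charge-balance equation with
    automatic substep refinement: the number of substeps per sample is
    doubled until step-halving changes the membrane-voltage trace by
    less than ``rel_tol`` of the command span.  The recorded current is
    ``(V_cmd - V_m)/R_s``.

    Raises
    ------
    DomainError
        If the membrane voltage still moves by more than 5 mV per
        integration substep at the refinement cap (the sampling
        interval is too coarse for the circuit's time constant).
    """
    t = protocol.times()
    vcmd = protocol.command(t)
    span = max(float(vcmd.max() - vcmd.min()), 1.0)
    dvdt = _rhs_factory(model)

    def integrate(n_sub: int) -> tuple[np.ndarray | None, float]:
        # command precomputed on the half-substep grid for RK4 stages;
        # returns (trace, max |dV| per substep) or (None, ...) on blow-up
        fine_t = np.arange(2 * n_sub * (t.size - 1) + 1) * (protocol.dt / (2 * n_sub))
        vc = protocol.command(fine_t)
        h = protocol.dt / n_sub
        vm = np.empty(t.size)
        vm[0] = v = float(vcmd[0])  # start clamped at the initial command
        max_dv = 0.0
        k = 0  # index into fine grid (half-substep resolution)
        for i in range(1, t.size):
            for _ in range(n_sub):
                c0, c1, c2 = vc[k], vc[k + 1], vc[k + 2]
                k1 = dvdt(v, c0)
                k2 = dvdt(v + 0.5 * h * k1, c1)
                k3 = dvdt(v + 0.5 * h * k2, c1)
                k4 = dvdt(v + h * k3, c2)
                dv = h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
                if not abs(dv) < 1e4:  # unstable at this resolution
                    return None, float("inf")
                max_dv = max(max_dv, abs(dv))
                v += dv
                k += 2
            vm[i] = v
        return vm, max_dv

    n_sub = 1
    prev, prev_dv = integrate(n_sub)
    while True:
        if n_sub >= max_substeps:
            vm, max_dv = prev, prev_dv
            break
        n_sub *= 2
        vm, max_dv = integrate(n_sub)
        if vm is not None and prev is not None and \
                np.max(np.abs(vm - prev)) < rel_tol * span:
            break
        prev, prev_dv = vm, max_dv
    if vm is None or max_dv > 5.0:
        raise DomainError(
            "membrane voltage changes more than 5 mV per integration step at "
            f"the refinement cap (n_substeps = {n_sub}); use a smaller "
            "protocol dt"
        )
    i_rec = 1e3 * (vcmd - vm) / model.r_series  # pA
    hold = float(vcmd[0])
    meta = dict(dt=protocol.dt, holding_potential=hold)
    return SimulationResult(
        command=Trace(vcmd, label="command (mV)", **meta),
        v_membrane=Trace(vm, label="membrane voltage (mV)", **meta),
        current=Trace(i_rec, label="recorded current", **meta),
        n_substeps=n_sub,
    )


def capacitive_current(boltzmann: BoltzmannParams, v_of_t: Trace) -> Trace:
    """Capacitive current I_cap(t) = C(V(t)) dV/dt, pA.

    ``v_of_t`` holds the membrane voltage in mV; the derivative uses
    centered finite differences (one-sided at the endpoints).
    """
    v = v_of_t.samples
    dvdt = np.gradient(v, v_of_t.dt)  # mV/s
    icap = cm_model(v, boltzmann) * dvdt * 1e-3  # pF * mV/s -> *1e-3 pA
    return Trace(icap, dt=v_of_t.dt, holding_potential=v_of_t.holding_potential,
                 label="capacitive current")


def correct_capacitive(recorded: Trace, model: PatchModel,
                       protocol: Protocol) -> Trace:
    """Remove the modelled capacitive current from a recording.

    The circuit model is simulated under the protocol to obtain the
    membrane-voltage waveform; the capacitive current it implies
    (linear + NLC components) is subtracted from ``recorded``, leaving
    the ionic contributions.
    """
    if recorded.n != protocol.n_samples:
        raise DomainError(
            f"recorded trace has {recorded.n} samples but the protocol "
            f"defines {protocol.n_samples}"
        )
    sim = simulate_recording(model, protocol)
    icap = capacitive_current(model.boltzmann, sim.v_membrane)
    return Trace(recorded.samples - icap.samples, dt=recorded.dt,
                 holding_potential=recorded.holding_potential,
                 label=(recorded.label + " (capacitive-corrected)").strip())


def hold_steady_state(model: PatchModel, v_cmd: float) -> tuple[float, float]:
    """Algebraic steady state at a held command: (V_m, recorded current pA)."""
    from scipy.optimize import brentq

    from .barrier import barrier_current

    def net(vm):
        i = 1e3 * (v_cmd - vm) / model.r_series - 1e3 * (
            vm - model.reversal_offset) / model.r_membrane
        if model.barrier is not None:
            i -= barrier_current(vm, model.barrier)
        return i

    # net current is strictly decreasing in V_m, so the root is unique
    lo, hi = sorted((v_cmd, model.reversal_offset))
    vm = brentq(net, lo - 400.0, hi + 400.0, xtol=1e-12)
    return vm, 1e3 * (v_cmd - vm) / model.r_series


@dataclass
class DualSineResult:
    """Windowed circuit estimates from dual-sine admittance analysis."""

    t_mid: np.ndarray
    v_dc: np.ndarray        # window-mean command, mV
    i_dc: np.ndarray        # window-mean recorded current, pA
    c_m: np.ndarray         # pF
    r_s: np.ndarray         # MOhm
    r_m: np.ndarray         # MOhm
    valid: np.ndarray       # bool per window
    f1: float

    @property
    def v_m_dc(self) -> np.ndarray:
        """Window DC membrane potential: command minus the I*R_s drop, mV."""
        return self.v_dc - self.i_dc * self.r_s * 1e-3  # pA*MOhm = uV

    def to_cv_curve(self):
        """Valid windows as a C-V relation on the membrane-potential axis."""
        from .nlc import CVCurve

        return CVCurve(self.v_m_dc[self.valid], self.c_m[self.valid])


def dual_sine_capacitance(recorded: Trace, command: Trace,
                          f1: float) -> DualSineResult:
    """Time-resolved (C_m, R_s, R_m) by dual-sine synchronous detection.

    ``command`` must contain sinusoids at ``f1`` and ``2*f1``; windows
    are one f1 cycle long and must hold an integer number of samples.
    Windows where the two admittances are indistinguishable (or the
    circuit solve leaves the physical branch) are flagged invalid.
    """
    if recorded.n != command.n or recorded.dt != command.dt:
        raise DomainError("recorded and command traces must share the sampling grid")
    dt = recorded.dt
    win = int(round(1.0 / (f1 * dt)))
    if abs(win * f1 * dt - 1.0) > 1e-9:
        raise DomainError(
            f"f1 = {f1} Hz does not give an integer number of samples per "
            f"cycle at dt = {dt} s"
        )
    n_win = recorded.n // win
    if n_win < 1:
        raise DomainError("trace shorter than one f1 cycle")
    i_w = recorded.samples[: n_win * win].reshape(n_win, win)
    v_w = command.samples[: n_win * win].reshape(n_win, win)
    tt = np.arange(win) * dt
    w1t = 2 * np.pi * f1 * tt
    # joint least-squares harmonic estimation per window: a DC + linear-trend
    # column pair absorbs the slow (ramp) component, which is not orthogonal
    # to single-cycle sinusoids and would otherwise leak into the phasors
    design = np.column_stack([
        np.ones(win), tt - tt.mean(),
        np.cos(w1t), np.sin(w1t), np.cos(2 * w1t), np.sin(2 * w1t),
    ])
    solver = np.linalg.pinv(design)                  # (6, win)
    ci = solver @ i_w.T                              # coefficients x windows
    cv = solver @ v_w.T
    I1, I2 = ci[2] - 1j * ci[3], ci[4] - 1j * ci[5]  # pA (complex phasors)
    V1, V2 = cv[2] - 1j * cv[3], cv[4] - 1j * cv[5]  # mV (complex phasors)

    with np.errstate(divide="ignore", invalid="ignore"):
        y1 = I1 / V1 * 1e-9  # pA/mV = nS -> S
        y2 = I2 / V2 * 1e-9
        z1, z2 = 1.0 / y1, 1.0 / y2                  # Ohm
        valid = np.abs(y1 - y2) > 1e-3 * np.maximum(np.abs(y1), np.abs(y2))
        r = np.imag(z2) / np.imag(z1)
        with np.errstate(invalid="ignore"):
            a2 = (2.0 - r) / (4.0 * r - 2.0)
        valid &= np.isfinite(a2) & (a2 > 0) & (np.imag(z1) < 0)
        a = np.sqrt(np.where(valid, a2, 1.0))
        rm = -np.imag(z1) * (1.0 + a2) / a            # Ohm
        w1 = 2 * np.pi * f1
        cm = a / (w1 * rm)                            # F
        rs = np.real(z1) - rm / (1.0 + a2)            # Ohm
        valid &= np.isfinite(rm) & (rm > 0) & np.isfinite(cm) & (cm > 0)

    t_mid = (np.arange(n_win) + 0.5) * win * dt
    return DualSineResult(
        t_mid=t_mid, v_dc=v_w.mean(axis=1), i_dc=i_w.mean(axis=1),
        c_m=np.where(valid, cm / 1e-12, np.nan),
        r_s=np.where(valid, rs / 1e6, np.nan),
        r_m=np.where(valid, rm / 1e6, np.nan),
        valid=valid, f1=f1,
    )
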