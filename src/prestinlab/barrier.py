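"""Single-barrier (Eyring rate-theory) channel I-V model.

A channel with one large central energy barrier at electrical distance
``delta`` across the membrane field carries outward and inward
unidirectional fluxes that each grow exponentially with the fraction of
the field they traverse.  The macroscopic current is

    I(V) = g * (kT / (q e0)) * [ P * exp((1-delta) q e0 V / kT)
                                 - exp(-delta q e0 V / kT) ],

where ``g`` is the slope conductance at E = 0 (exactly so when P = 1),
``q`` the apparent charge of the permeating step, and ``P`` the relative
permeability of the ions carrying outward current compared to those
carrying inward current.  For P = 1 and delta = 0.5 this reduces to the
symmetric hyperbolic-sine relation
``I = 2 g (kT/q e0) sinh(q e0 V / 2kT)``.

The zero-current (reversal) potential has the closed form
``E_rev = -(kT / q e0) * ln(P)``.

Note on provenance of the functional form: the display equation in the
source methods is reconstructed here from its variable glossary (slope
conductance at E = 0, electrical distance, relative permeability) and
the stated sinh limiting case, with the normalization chosen so that
``dI/dV`` at 0 mV equals ``g [P(1-delta) + delta]`` (hence exactly ``g``
when P = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import ROOM_TEMPERATURE, thermal_voltage_mV
from .exceptions import DomainError, FitError
from .nlc import _stderr_from_jacobian

__all__ = [
    "BarrierParams",
    "IVCurve",
    "barrier_current",
    "barrier_reversal",
    "SingleBarrierIV",
    "SingleBarrierIVResults",
    "fit_barrier",
]

#: guard against exp overflow: |q e0 V / kT| above this raises
_MAX_EXPONENT = 50.0

#: resolvable relative-permeability window during fitting.  |ln P| maps to a
#: reversal potential -(kT/q e0) ln P; ratios beyond 1e±4 put the reversal far
#: outside any practical command range, so a fit drifting there has no
#: interior optimum and is treated as failed rather than silently extrapolated.
P_REL_BOUNDS = (1e-4, 1e4)

_PARAM_NAMES = ("g", "q", "delta", "p_rel")


@dataclass(frozen=True)
class BarrierParams:
    """Single-barrier channel parameters.

    Attributes
    ----------
    g : float
        Slope conductance at E = 0; pS/pF when fitted to current
        density, pS otherwise.
    q : float
        Apparent charge of the permeating ion step, elementary charges.
    delta : float
        Electrical distance of the barrier, in (0, 1).
    p_rel : float
        Relative permeability of outward- vs inward-carrying ions.
    temperature : float
        Absolute temperature, K.
    """

    g: float
    q: float
    delta: float
    p_rel: float = 1.0
    temperature: float = ROOM_TEMPERATURE

    def __post_init__(self):
        if not np.isfinite([self.g, self.q, self.delta, self.p_rel]).all():
            raise DomainError("BarrierParams fields must be finite")
        if self.g < 0:
            raise DomainError(f"g must be >= 0, got {self.g}")
        if self.q <= 0:
            raise DomainError(f"q must be > 0, got {self.q}")
        if not 0 < self.delta < 1:
            raise DomainError(f"delta must be in (0, 1), got {self.delta}")
        if self.p_rel <= 0:
            raise DomainError(f"p_rel must be > 0, got {self.p_rel}")
        if self.temperature <= 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")


@dataclass
class IVCurve:
    """A current-voltage relation (pA, or pA/pF when density-normalized)."""

    v: np.ndarray
    i: np.ndarray
    density_normalized: bool = True

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.v.shape != self.i.shape or self.v.ndim != 1:
            raise DomainError("v and i must be 1-d arrays of equal length")
        if not (np.isfinite(self.v).all() and np.isfinite(self.i).all()):
            raise DomainError("IVCurve contains non-finite values")
        order = np.argsort(self.v)
        self.v, self.i = self.v[order], self.i[order]

    def __len__(self) -> int:
        return self.v.size


def barrier_current(v, params: BarrierParams):
    """Current of the single-barrier model at potential ``v`` (mV).

    Sign convention: outward membrane current positive,
    V = V_in - V_out.  Units follow the convention of ``g``.
    """
    v = np.asarray(v, dtype=float)
    if not np.isfinite(v).all():
        raise DomainError("barrier_current: non-finite voltage")
    vt_q = thermal_voltage_mV(params.temperature) / params.q  # mV
    u = v / vt_q
    if np.any(np.abs(u) > _MAX_EXPONENT):
        vbad = float(np.asarray(v).ravel()[np.argmax(np.abs(u))])
        raise DomainError(
            f"barrier_current overflow guard: |q e0 V/kT| > {_MAX_EXPONENT} "
            f"at V = {vbad} mV"
        )
    d = params.delta
    out = params.g * vt_q * 1e-3 * (
        params.p_rel * np.exp((1.0 - d) * u) - np.exp(-d * u)
    )
    # g[pS] * V[mV] = 1e-15 A; results are in pA (or pA/pF), hence *1e-3
    return out if out.ndim else float(out)


def barrier_reversal(params: BarrierParams) -> float:
    """Zero-current potential E_rev = -(kT / q e0) ln(P), mV."""
    vt_q = thermal_voltage_mV(params.temperature) / params.q
    return -vt_q * float(np.log(params.p_rel))


class SingleBarrierIV:
    """Single-barrier I-V model bound to a measured curve.

    Parameters
    ----------
    v, i : array_like
        Voltage (mV) and current (pA or pA/pF) samples.
    density_normalized : bool
        Whether ``i`` is normalized to linear capacitance (then ``g`` is
        in pS/pF).
    fix : dict, optional
        Parameters held fixed during the fit, e.g. ``{"q": 0.75}`` to
        reproduce a reduced apparent voltage dependence.
    """

    def __init__(self, v, i, density_normalized: bool = True,
                 fix: dict[str, float] | None = None,
                 temperature: float = ROOM_TEMPERATURE):
        self.curve = IVCurve(np.asarray(v), np.asarray(i), density_normalized)
        self.fix = dict(fix or {})
        unknown = set(self.fix) - set(_PARAM_NAMES)
        if unknown:
            raise DomainError(f"cannot fix unknown parameter(s): {sorted(unknown)}")
        self.temperature = float(temperature)

    @classmethod
    def from_curve(cls, curve: IVCurve, fix=None, temperature=ROOM_TEMPERATURE):
        return cls(curve.v, curve.i, curve.density_normalized, fix, temperature)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, v_col: str = "v_mV",
                       i_col: str = "i_pA_per_pF", **kw):
        return cls(df[v_col].to_numpy(), df[i_col].to_numpy(), **kw)

    def _default_init(self) -> dict[str, float]:
        v, i = self.curve.v, self.curve.i
        # slope near 0 mV for g; asymmetry of the extremes for P
        core = np.abs(v) <= 60
        if core.sum() >= 2:
            g0 = max(float(np.polyfit(v[core], i[core], 1)[0]) * 1e3, 1e-3)
        else:
            g0 = max(float((i[-1] - i[0]) / (v[-1] - v[0])) * 1e3, 1e-3)
        ratio = abs(i[-1]) / max(abs(i[0]), 1e-12)
        return {"g": g0, "q": 0.75, "delta": 0.5,
                "p_rel": float(np.clip(ratio, 1e-2, 1e2))}

    def fit(self, init: dict[str, float] | None = None) -> "SingleBarrierIVResults":
        """Least-squares fit; free parameters are optimized in log/logit
        space so positivity and the delta in (0,1) constraint hold by
        construction.

        Raises
        ------
        FitError
            On fewer than 5 points or optimizer failure (the last
            iterate is attached to the error diagnostics).
        """
        curve = self.curve
        if len(curve) < 5:
            raise FitError(f"need >= 5 points to fit the barrier model, got {len(curve)}")
        start = self._default_init()
        if init:
            start.update(init)
        start.update(self.fix)
        free = [n for n in _PARAM_NAMES if n not in self.fix]
        if not free:
            raise FitError("all parameters fixed; nothing to fit")

        def pack(vals: dict) -> np.ndarray:
            x = []
            for n in free:
                if n == "delta":
                    d = np.clip(vals[n], 1e-4, 1 - 1e-4)
                    x.append(np.log(d / (1 - d)))
                else:
                    x.append(np.log(max(vals[n], 1e-12)))
            return np.asarray(x)

        def unpack(x: np.ndarray) -> dict[str, float]:
            vals = dict(self.fix)
            for n, xi in zip(free, x):
                if n == "delta":
                    vals[n] = 1.0 / (1.0 + np.exp(-xi))
                else:
                    vals[n] = float(np.exp(np.clip(xi, -40, 40)))
            return vals

        def resid(x):
            vals = unpack(x)
            p = BarrierParams(vals["g"], vals["q"], vals["delta"], vals["p_rel"],
                              self.temperature)
            return barrier_current(curve.v, p) - curve.i

        sol = least_squares(resid, pack(start), method="lm",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise FitError(f"barrier fit did not converge: {sol.message}",
                           diagnostics={"last_iterate": unpack(sol.x)})
        vals = unpack(sol.x)
        if "p_rel" in free and not (
                P_REL_BOUNDS[0] <= vals["p_rel"] <= P_REL_BOUNDS[1]):
            raise FitError(
                "relative permeability ran to the boundary "
                f"(P = {vals['p_rel']:.3g}): the reversal potential is not "
                "resolvable from the sampled voltage range",
                diagnostics={"last_iterate": vals, "sse": float(2.0 * sol.cost)},
            )
        params = BarrierParams(vals["g"], vals["q"], vals["delta"], vals["p_rel"],
                               self.temperature)
        # delta-method back-transform of log/logit-space standard errors
        se_t = _stderr_from_jacobian(sol.jac, sol.fun, n_params=len(free))
        bse = {}
        for n, se in zip(free, se_t):
            if n == "delta":
                d = vals[n]
                bse[n] = se * d * (1 - d)
            else:
                bse[n] = se * vals[n]
        for n in self.fix:
            bse[n] = 0.0
        return SingleBarrierIVResults(
            model=self, params=params, sse=float(2.0 * sol.cost),
            bse=bse, nobs=len(curve), fixed=dict(self.fix),
        )


@dataclass
class SingleBarrierIVResults:
    """Fit results for :class:`SingleBarrierIV`."""

    model: SingleBarrierIV
    params: BarrierParams
    sse: float
    bse: dict[str, float]
    nobs: int
    fixed: dict[str, float] = field(default_factory=dict)

    def predict(self, v=None):
        if v is None:
            v = self.model.curve.v
        return barrier_current(v, self.params)

    @property
    def reversal_potential(self) -> float:
        """Analytic zero-current potential of the fitted model, mV."""
        return barrier_reversal(self.params)

    def summary(self) -> str:
        p = self.params
        unit_g = "pS/pF" if self.model.curve.density_normalized else "pS"
        rows = []
        for name, val, unit in (("g", p.g, unit_g), ("q", p.q, "e0"),
                                ("delta", p.delta, ""), ("P", p.p_rel, "")):
            key = "p_rel" if name == "P" else name
            tag = "(fixed)" if key in self.fixed else f"{self.bse[key]:>10.3g}"
            rows.append(f"{name:<8}{val:>12.4g}{tag:>12}  {unit}")
        return "\n".join([
            "Single-barrier I-V fit",
            "=" * 42,
            f"{'n points':<14}{self.nobs:>10d}",
            f"{'SSE':<14}{self.sse:>14.6g}",
            "-" * 42,
            f"{'param':<8}{'value':>12}{'std err':>12}",
            *rows,
            "-" * 42,
            f"{'E_rev':<8}{self.reversal_potential:>12.4g}{'':>12}  mV",
        ])

    def to_dict(self) -> dict:
        p = self.params
        return {"g": p.g, "q": p.q, "delta": p.delta, "p_rel": p.p_rel,
                "e_rev_mV": self.reversal_potential, "sse": self.sse,
                "nobs": self.nobs, "stderr": dict(self.bse),
                "fixed": dict(self.fixed)}

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.model.curve.v
        vv = np.linspace(v.min(), v.max(), 400)
        ax.plot(v, self.model.curve.i, "o", ms=4, label="data")
        ax.plot(vv, self.predict(vv), "-", label="single-barrier fit")
        ax.axhline(0, color="0.7", lw=0.5)
        ax.set_xlabel("V (mV)")
        ax.set_ylabel("I (pA/pF)" if self.model.curve.density_normalized else "I (pA)")
        ax.legend()
        return ax


def fit_barrier(curve: IVCurve, fixed: dict[str, float] | None = None,
                init: dict[str, float] | None = None,
                temperature: float = ROOM_TEMPERATURE) -> SingleBarrierIVResults:
    """Fit the single-barrier model to an I-V curve.

    ``fixed`` holds any of {"g", "q", "delta", "p_rel"} at a prescribed
    value (e.g. ``{"q": 0.75}``).
    """
    return SingleBarrierIV.from_curve(curve, fixed, temperature).fit(init)
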