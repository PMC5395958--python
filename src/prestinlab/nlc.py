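"""Two-state Boltzmann model of nonlinear membrane capacitance (NLC).

Prestin, the outer-hair-cell motor protein, moves an effective charge
``z*e0`` across the membrane field as it switches between two
conformations.  The resulting voltage-dependent ("nonlinear")
capacitance is the derivative of the two-state Boltzmann charge
transfer:

    C_m(V) = C_lin + Q_max * (z e0 / kT) * b(V) * (1 - b(V)),
    b(V)   = 1 / (1 + exp(-z e0 (V - V_h) / kT)),

where ``Q_max`` is the maximum nonlinear charge (fC), ``V_h`` the
voltage of peak capacitance (mV), ``z`` the unitary valence, and
``C_lin`` the voltage-independent (linear) capacitance (pF).  The
derived quantities are the specific charge density
``Q_sp = Q_max / C_lin`` (fC/pF), the number of voltage-sensing
molecules ``N = Q_max / (z e0)``, and the per-molecule unitary current
``i = I_cell / N`` obtained by normalizing a whole-cell current to N.

The fitting surface follows the Model/Results idiom: build a
:class:`NonlinearCapacitance` model from a measured C-V relation and
call :meth:`~NonlinearCapacitance.fit`; the returned
:class:`NonlinearCapacitanceResults` carries parameter estimates,
standard errors, the residual SSE and a ``summary()`` table.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .constants import ELEMENTARY_CHARGE, FEMTO, ROOM_TEMPERATURE, thermal_voltage_mV
from .exceptions import DomainError, FitError

__all__ = [
    "BoltzmannParams",
    "CVCurve",
    "cm_model",
    "specific_charge",
    "channel_count",
    "unitary_from_whole_cell",
    "NonlinearCapacitance",
    "NonlinearCapacitanceResults",
    "fit_nlc",
]

#: optimizer bounds on the valence; published prestin values span ~0.5-1.0
Z_BOUNDS = (0.05, 3.0)


@dataclass(frozen=True)
class BoltzmannParams:
    """Parameters of the two-state Boltzmann NLC model.

    Attributes
    ----------
    q_max : float
        Maximum nonlinear charge transfer, fC.
    v_h : float
        Voltage at peak capacitance / half-maximal charge transfer, mV.
    z : float
        Unitary valence (elementary charges moved per sensor).
    c_lin : float
        Linear (voltage-independent) membrane capacitance, pF.
    temperature : float
        Absolute temperature, K.
    """

    q_max: float
    v_h: float
    z: float
    c_lin: float
    temperature: float = ROOM_TEMPERATURE

    def __post_init__(self):
        if not np.isfinite([self.q_max, self.v_h, self.z, self.c_lin]).all():
            raise DomainError("BoltzmannParams fields must be finite")
        if self.q_max < 0:
            raise DomainError(f"q_max must be >= 0 fC, got {self.q_max}")
        if self.z <= 0:
            raise DomainError(f"z must be > 0, got {self.z}")
        if self.c_lin <= 0:
            raise DomainError(f"c_lin must be > 0 pF, got {self.c_lin}")
        if self.temperature <= 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def q_sp(self) -> float:
        """Specific charge density Q_max / C_lin, fC/pF."""
        return self.q_max / self.c_lin


@dataclass
class CVCurve:
    """A capacitance-voltage relation: C_m (pF) sampled on a voltage grid (mV)."""

    v: np.ndarray
    cm: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.cm = np.asarray(self.cm, dtype=float)
        if self.v.shape != self.cm.shape or self.v.ndim != 1:
            raise DomainError("v and cm must be 1-d arrays of equal length")
        if not (np.isfinite(self.v).all() and np.isfinite(self.cm).all()):
            raise DomainError("CVCurve contains non-finite values")
        order = np.argsort(self.v)
        self.v = self.v[order]
        self.cm = self.cm[order]
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)[order]
        if np.any(np.diff(self.v) <= 0):
            raise DomainError("voltage grid contains duplicates")

    def __len__(self) -> int:
        return self.v.size


def cm_model(v, params: BoltzmannParams):
    """Membrane capacitance C_m(V) of the two-state Boltzmann model, pF.

    Parameters
    ----------
    v : float or array_like
        Membrane potential, mV.
    params : BoltzmannParams

    Notes
    -----
    With charge in fC and voltage in mV, fC/mV = pF, so
    ``C_m = c_lin + q_max * z / V_T * b(1-b)`` with the thermal voltage
    ``V_T = kT/e0`` in mV.  The peak value, at ``V = v_h``, is
    ``c_lin + q_max*z/(4 V_T)``.
    """
    v = np.asarray(v, dtype=float)
    if not np.isfinite(v).all():
        raise DomainError("cm_model: voltage contains non-finite values")
    vt = thermal_voltage_mV(params.temperature)
    b = expit(params.z * (v - params.v_h) / vt)
    out = params.c_lin + params.q_max * params.z / vt * b * (1.0 - b)
    return out if out.ndim else float(out)


def specific_charge(params: BoltzmannParams) -> float:
    """Specific charge density Q_sp = Q_max / C_lin, fC/pF."""
    return params.q_sp


def channel_count(params: BoltzmannParams) -> float:
    """Number of charge-moving molecules N = Q_max / (z e0).

    ``Q_max`` counts the total gating charge; dividing by the charge
    moved per molecule gives the molecule (channel) count used to
    normalize whole-cell currents.
    """
    if params.q_max == 0:
        raise DomainError("channel_count undefined for q_max = 0 (no molecules)")
    return params.q_max * FEMTO / (params.z * ELEMENTARY_CHARGE)


def unitary_from_whole_cell(i_cell_pA: float, params: BoltzmannParams) -> float:
    """Per-molecule unitary current, fA, from a whole-cell current (pA).

    ``i = I_cell / N`` with N from :func:`channel_count`; the sign of
    the whole-cell current is preserved.
    """
    n = channel_count(params)  # raises on q_max == 0
    return i_cell_pA * 1e3 / n  # pA -> fA is *1000


# ---------------------------------------------------------------------------
# fitting


class NonlinearCapacitance:
    """Two-state Boltzmann NLC model bound to a measured C-V relation.

    Parameters
    ----------
    v : array_like
        Voltage grid, mV.
    cm : array_like
        Measured membrane capacitance, pF.
    weights : array_like, optional
        Per-point weights applied to the residuals.
    temperature : float
        Bath temperature, K.

    Examples
    --------
    >>> model = NonlinearCapacitance(v, cm)
    >>> res = model.fit()
    >>> res.params.v_h, res.bse["v_h"]
    """

    def __init__(self, v, cm, weights=None, temperature: float = ROOM_TEMPERATURE):
        self.curve = CVCurve(np.asarray(v), np.asarray(cm), weights)
        self.temperature = float(temperature)

    @classmethod
    def from_curve(cls, curve: CVCurve, temperature: float = ROOM_TEMPERATURE):
        return cls(curve.v, curve.cm, curve.weights, temperature)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, v_col: str = "v_mV",
                       cm_col: str = "cm_pF", **kw):
        return cls(df[v_col].to_numpy(), df[cm_col].to_numpy(), **kw)

    # -- initialization ----------------------------------------------------
    def _default_init(self) -> BoltzmannParams:
        """Deterministic peak-based starting point.

        c_lin from the observed minimum, v_h from the argmax, z = 0.8,
        and q_max from inverting the peak formula
        peak - c_lin = q_max * z / (4 V_T).
        """
        v, cm = self.curve.v, self.curve.cm
        vt = thermal_voltage_mV(self.temperature)
        c_lin0 = float(cm.min())
        v_h0 = float(v[np.argmax(cm)])
        z0 = 0.8
        amp = max(float(cm.max() - c_lin0), 1e-6)
        q_max0 = 4.0 * vt / z0 * amp
        return BoltzmannParams(q_max0, v_h0, z0, max(c_lin0, 1e-6),
                               self.temperature)

    def fit(self, init: BoltzmannParams | None = None) -> "NonlinearCapacitanceResults":
        """Weighted least-squares fit of the Boltzmann-derivative model.

        Raises
        ------
        FitError
            If fewer than 6 points are supplied, the curve is strictly
            monotone (no capacitance peak to resolve), or the optimizer
            fails to converge.
        """
        curve = self.curve
        if len(curve) < 6:
            raise FitError(f"need >= 6 points to fit NLC, got {len(curve)}")
        dcm = np.diff(curve.cm)
        if np.all(dcm > 0) or np.all(dcm < 0):
            raise FitError(
                "capacitance is strictly monotone over the sampled range; "
                "no NLC peak is resolvable",
                diagnostics={"cm_range": (float(curve.cm.min()), float(curve.cm.max()))},
            )
        p0 = init if init is not None else self._default_init()
        w = np.ones(len(curve)) if curve.weights is None else np.sqrt(curve.weights)

        span = curve.v.max() - curve.v.min()
        lo = [0.0, curve.v.min() - 2 * span, Z_BOUNDS[0], 1e-9]
        hi = [np.inf, curve.v.max() + 2 * span, Z_BOUNDS[1], np.inf]
        x0 = np.clip([p0.q_max, p0.v_h, p0.z, p0.c_lin], lo, hi)

        def resid(x):
            p = BoltzmannParams(x[0], x[1], x[2], x[3], self.temperature)
            return w * (cm_model(curve.v, p) - curve.cm)

        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            raise FitError(f"NLC fit did not converge: {sol.message}",
                           diagnostics={"x": sol.x.tolist()})
        params = BoltzmannParams(*sol.x, self.temperature)
        sse = float(2.0 * sol.cost)
        bse = _stderr_from_jacobian(sol.jac, sol.fun, n_params=4)
        warns: list[str] = []
        if not (curve.v.min() <= params.v_h <= curve.v.max()):
            warns.append(
                f"fitted peak V_h = {params.v_h:.1f} mV lies outside the sampled "
                f"range [{curve.v.min():.0f}, {curve.v.max():.0f}] mV; parameters "
                "are extrapolated"
            )
            _warnings.warn(warns[-1], RuntimeWarning, stacklevel=2)
        return NonlinearCapacitanceResults(
            model=self, params=params, sse=sse,
            bse=dict(zip(("q_max", "v_h", "z", "c_lin"), bse)),
            nobs=len(curve), warnings=warns,
        )


def _stderr_from_jacobian(jac, fun, n_params) -> np.ndarray:
    """Asymptotic standard errors from the least-squares Jacobian."""
    dof = max(fun.size - n_params, 1)
    s2 = float(fun @ fun) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(n_params, np.nan)
    return se


@dataclass
class NonlinearCapacitanceResults:
    """Fit results for :class:`NonlinearCapacitance`."""

    model: NonlinearCapacitance
    params: BoltzmannParams
    sse: float
    bse: dict[str, float]
    nobs: int
    warnings: list[str] = field(default_factory=list)

    @property
    def q_sp(self) -> float:
        """Specific charge density Q_max/C_lin of the fit, fC/pF."""
        return self.params.q_sp

    def n_molecules(self) -> float:
        return channel_count(self.params)

    def unitary_current(self, i_cell_pA: float) -> float:
        """Whole-cell current (pA) normalized per molecule, fA."""
        return unitary_from_whole_cell(i_cell_pA, self.params)

    def predict(self, v=None):
        if v is None:
            v = self.model.curve.v
        return cm_model(v, self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.curve.cm - self.predict()

    def summary(self) -> str:
        p, se = self.params, self.bse
        lines = [
            "Two-state Boltzmann NLC fit",
            "=" * 42,
            f"{'n points':<14}{self.nobs:>10d}",
            f"{'SSE (pF^2)':<14}{self.sse:>14.6g}",
            f"{'temperature':<14}{p.temperature:>10.2f} K",
            "-" * 42,
            f"{'param':<8}{'value':>12}{'std err':>12}",
            f"{'Q_max':<8}{p.q_max:>12.4g}{se['q_max']:>12.3g}  fC",
            f"{'V_h':<8}{p.v_h:>12.4g}{se['v_h']:>12.3g}  mV",
            f"{'z':<8}{p.z:>12.4g}{se['z']:>12.3g}",
            f"{'C_lin':<8}{p.c_lin:>12.4g}{se['c_lin']:>12.3g}  pF",
            "-" * 42,
            f"{'Q_sp':<8}{self.q_sp:>12.4g}{'':>12}  fC/pF",
            f"{'N':<8}{self.n_molecules():>12.4g}{'':>12}  molecules",
        ]
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        p = self.params
        return {
            "q_max_fC": p.q_max, "v_h_mV": p.v_h, "z": p.z, "c_lin_pF": p.c_lin,
            "q_sp_fC_per_pF": self.q_sp, "temperature_K": p.temperature,
            "sse": self.sse, "nobs": self.nobs,
            "stderr": dict(self.bse), "warnings": list(self.warnings),
        }

    def plot(self, ax=None):
        """Data with the fitted curve overlaid; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        v = self.model.curve.v
        vv = np.linspace(v.min(), v.max(), 400)
        ax.plot(v, self.model.curve.cm, "o", ms=3, label="data")
        ax.plot(vv, self.predict(vv), "-", label="Boltzmann fit")
        ax.set_xlabel("V (mV)")
        ax.set_ylabel("C_m (pF)")
        ax.legend()
        return ax


def fit_nlc(curve: CVCurve, init: BoltzmannParams | None = None,
            temperature: float = ROOM_TEMPERATURE) -> NonlinearCapacitanceResults:
    """Fit the Boltzmann-derivative NLC model to a C-V curve.

    Functional wrapper around
    ``NonlinearCapacitance.from_curve(curve).fit(init)``.
    """
    return NonlinearCapacitance.from_curve(curve, temperature).fit(init)
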