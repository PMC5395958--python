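"""Synthetic-data generators for every input the analysis consumes.

The generators reproduce the statistical structure the analysis
assumes, so every stage of the pipeline is testable without laboratory
data:

- C-V curves: the Boltzmann-derivative capacitance plus i.i.d. Gaussian
  noise (:func:`gen_cv_curve`);
- I-V curves: the single-barrier current plus Gaussian noise scaled to
  the maximum current (:func:`gen_iv_curve`);
- patch current records (:func:`gen_channel_noise`): a superposition of
  many independent two-state (open/closed) channels whose switching
  rates are log-uniform over several decades.  Each channel is a random
  telegraph process contributing a Lorentzian spectrum with corner
  lambda/(2 pi); summing Lorentzians with log-uniform corner rates is
  the classical construction of an approximately 1/f spectrum.  Shot
  noise (density 2 <I> e0) and white instrument noise ride on top, and
  the lot is passed through a 4-pole 10 kHz Bessel filter emulating the
  acquisition chain.  Because the fluctuations come from genuine
  open/closed switching, the ensemble mean (n i p), variance
  (n i^2 p (1-p)) and unitary current are physically meaningful and
  consistent with the assumptions of the sigma^2/<I> estimator;
- whole experiments (:func:`gen_patch_experiment`): replicate patches
  at -50/0/+50 mV holding; the 0 mV records carry instrument noise only
  and serve as the background condition.

All randomness flows from ``GeneratorSpec.seed``; per-patch generators
are split off the master seed with numpy's SeedSequence spawning
(counter-based), so outputs are bit-reproducible and patches are
statistically independent.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .barrier import BarrierParams, IVCurve, barrier_current
from .constants import ELEMENTARY_CHARGE, PICO
from .exceptions import DomainError
from .nlc import BoltzmannParams, CVCurve, cm_model
from .noise import Trace

__all__ = ["GeneratorSpec", "PatchExperiment", "gen_cv_curve", "gen_iv_curve",
           "gen_channel_noise", "gen_patch_experiment",
           "CL_BARRIER", "SCN_BARRIER", "WT_BOLTZMANN"]

#: single-barrier parameter sets for the two anion conditions
CL_BARRIER = BarrierParams(g=46.3, q=0.75, delta=0.467, p_rel=1.0)
SCN_BARRIER = BarrierParams(g=92.8, q=0.75, delta=0.339, p_rel=6.18)

#: wild-type NLC parameters (Q_sp 20.32 fC/pF at C_lin = 15 pF)
WT_BOLTZMANN = BoltzmannParams(q_max=20.32 * 15.0, v_h=-96.26, z=0.74, c_lin=15.0)

#: default C-V sampling grid: 136 points over -160..110 mV
DEFAULT_CV_GRID = np.linspace(-160.0, 110.0, 136)

#: default I-V grid: -150..150 mV in 20 mV steps
DEFAULT_IV_GRID = np.arange(-150.0, 151.0, 20.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground-truth parameters and noise levels for the generators.

    Attributes
    ----------
    seed : int
        Master seed; fixed seed gives byte-identical outputs.
    boltzmann, barrier :
        True NLC and channel-model parameters.
    noise_sd_cv : float
        Additive Gaussian noise on C-V curves, pF.
    noise_frac_iv : float
        I-V noise s.d. as a fraction of max |I|.
    n_channels : int
        Two-state channels per patch.
    unitary_current_fA : float
        Open-channel current magnitude, fA (sign set by the holding
        potential).
    open_probability : float
        Stationary open probability, in (0, 1).
    rate_range_hz : (float, float)
        Log-uniform range of channel relaxation rates lambda =
        k_open + k_close, Hz; must lie within (1e-2, 1e4).  The default
        lower bound keeps lambda * duration >= ~2 so even the slowest
        channels equilibrate within one record (the time-domain variance
        then estimates the ensemble variance); the four-decade span
        straddles the 0.1-100 Hz band where the summed spectrum is
        approximately 1/f.
    instrument_noise_sd_pA : float
        White instrument noise, pA rms (before filtering).
    n_samples, dt :
        Record length (samples) and sampling interval (s).
    n_patches : int
        Replicate patches per condition.
    holding_potentials_mV :
        Potentials of a patch experiment; 0 mV is the background.
    """

    seed: int = 0
    boltzmann: BoltzmannParams = WT_BOLTZMANN
    barrier: BarrierParams = CL_BARRIER
    noise_sd_cv: float = 0.05
    noise_frac_iv: float = 0.02
    n_channels: int = 10_000
    unitary_current_fA: float = 2.0
    open_probability: float = 0.1
    rate_range_hz: tuple[float, float] = (0.2, 2000.0)
    instrument_noise_sd_pA: float = 0.3
    n_samples: int = 1_061_306
    dt: float = 1e-5
    bessel_corner_hz: float = 10_000.0
    n_patches: int = 11
    holding_potentials_mV: tuple[float, ...] = (-50.0, 0.0, 50.0)

    def __post_init__(self):
        if not 0.0 <= self.open_probability < 1.0:
            raise DomainError("open_probability must be in [0, 1)")
        lo, hi = self.rate_range_hz
        if not (1e-2 <= lo < hi <= 1e4):
            raise DomainError("rate_range_hz must be increasing within (1e-2, 1e4) Hz")
        if hi / lo <= 10.0:
            _warnings.warn(
                "switching-rate range spans one decade or less: the summed "
                "spectrum will be Lorentzian-like rather than 1/f",
                RuntimeWarning, stacklevel=3,
            )
        if self.dt <= 0 or self.n_samples < 2:
            raise DomainError("need dt > 0 and n_samples >= 2")

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed))

    def expected_mean_pA(self) -> float:
        """Ensemble mean channel current n i p (magnitude), pA."""
        return self.n_channels * self.unitary_current_fA * 1e-3 * self.open_probability

    def expected_variance_A2(self) -> float:
        """Ensemble variance n i^2 p (1-p), A^2."""
        i = self.unitary_current_fA * 1e-15
        p = self.open_probability
        return self.n_channels * i * i * p * (1.0 - p)


def gen_cv_curve(spec: GeneratorSpec, v_grid=None,
                 rng: np.random.Generator | None = None) -> CVCurve:
    """A C-V curve: Boltzmann-derivative model + Gaussian noise."""
    v = np.asarray(DEFAULT_CV_GRID if v_grid is None else v_grid, dtype=float)
    rng = spec.rng() if rng is None else rng
    cm = cm_model(v, spec.boltzmann)
    if spec.noise_sd_cv > 0:
        cm = cm + rng.normal(0.0, spec.noise_sd_cv, size=v.size)
    return CVCurve(v, cm)


def gen_iv_curve(spec: GeneratorSpec, v_grid=None,
                 rng: np.random.Generator | None = None) -> IVCurve:
    """An I-V curve: single-barrier model + noise scaled to max |I|."""
    v = np.asarray(DEFAULT_IV_GRID if v_grid is None else v_grid, dtype=float)
    rng = spec.rng() if rng is None else rng
    i = barrier_current(v, spec.barrier)
    if spec.noise_frac_iv > 0:
        sd = spec.noise_frac_iv * np.max(np.abs(i))
        i = i + rng.normal(0.0, sd, size=v.size)
    return IVCurve(v, i, density_normalized=True)


def _telegraph_occupancy(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    """Number of open channels at each sample time.

    Each channel is a stationary two-state Markov process with opening
    rate k_o = p*lambda and closing rate k_c = (1-p)*lambda, lambda
    drawn log-uniform over ``rate_range_hz``.  Open/close transition
    times are accumulated as +1/-1 increments on the sample grid.
    """
    n, dt = spec.n_samples, spec.dt
    total_t = n * dt
    p = spec.open_probability
    lam = np.exp(rng.uniform(np.log(spec.rate_range_hz[0]),
                             np.log(spec.rate_range_hz[1]), spec.n_channels))
    start_open = rng.random(spec.n_channels) < p
    incr = np.zeros(n + 1, dtype=np.int64)
    starts_all: list[np.ndarray] = []
    ends_all: list[np.ndarray] = []
    for j in range(spec.n_channels):
        k_o = p * lam[j]
        k_c = (1.0 - p) * lam[j]
        open0 = bool(start_open[j])
        # expected number of dwells plus safety margin
        mean_rate = 2.0 * p * (1.0 - p) * lam[j]
        m = int(mean_rate * total_t + 5.0 * np.sqrt(mean_rate * total_t + 1.0)) + 8
        scale_open, scale_closed = 1.0 / k_c, 1.0 / k_o
        bounds = np.empty(0)
        t0 = 0.0
        while True:
            u = rng.exponential(size=m)
            if open0 ^ (bounds.size % 2 == 1):
                u[0::2] *= scale_open
                u[1::2] *= scale_closed
            else:
                u[0::2] *= scale_closed
                u[1::2] *= scale_open
            seg = t0 + np.cumsum(u)
            bounds = np.concatenate([bounds, seg])
            if bounds[-1] >= total_t:
                break
            t0 = bounds[-1]
            m = max(m // 2, 8)
        edges = np.concatenate([[0.0], bounds])
        if open0:
            starts, ends = edges[0::2], edges[1::2]
        else:
            starts, ends = edges[1::2], edges[2::2]
        k = min(starts.size, ends.size)
        starts, ends = starts[:k], ends[:k]
        keep = starts < total_t
        starts, ends = starts[keep], np.minimum(ends[keep], total_t)
        starts_all.append(starts)
        ends_all.append(ends)
    s_idx = np.ceil(np.concatenate(starts_all) / dt).astype(np.int64)
    e_idx = np.ceil(np.concatenate(ends_all) / dt).astype(np.int64)
    np.add.at(incr, np.clip(s_idx, 0, n), 1)
    np.add.at(incr, np.clip(e_idx, 0, n), -1)
    return np.cumsum(incr[:n])


def gen_channel_noise(spec: GeneratorSpec, holding_mV: float = 50.0,
                      rng: np.random.Generator | None = None,
                      label: str = "", noise_free: bool = False) -> Trace:
    """A patch current record: telegraph channels + shot + instrument noise.

    The unitary current magnitude is ``spec.unitary_current_fA`` with
    the sign of the holding potential (zero holding, or
    ``open_probability = 0``, yields instrument noise only).  The summed
    trace is low-pass filtered with a 4-pole Bessel at
    ``spec.bessel_corner_hz``.  With ``noise_free=True`` the raw channel
    current is returned alone (no shot/instrument noise, no filter) so
    its mean and variance can be checked against the ensemble formulas
    n*i*p and n*i^2*p*(1-p) directly.
    """
    rng = spec.rng() if rng is None else rng
    n = spec.n_samples
    i_unit_pA = spec.unitary_current_fA * 1e-3 * float(np.sign(holding_mV))
    if holding_mV != 0.0 and spec.open_probability > 0.0:
        occ = _telegraph_occupancy(spec, rng)
        x = occ * i_unit_pA
        mean_pA = spec.expected_mean_pA() * np.sign(holding_mV)
    else:
        x = np.zeros(n)
        mean_pA = 0.0
    if not noise_free:
        # shot noise of the mean current: one-sided density 2 e0 |I|
        shot_var_A2 = 2.0 * ELEMENTARY_CHARGE * abs(mean_pA) * PICO / (2.0 * spec.dt)
        sd_white = float(np.hypot(spec.instrument_noise_sd_pA,
                                  np.sqrt(shot_var_A2) / PICO))
        if sd_white > 0:
            x = x + rng.normal(0.0, sd_white, size=n)
        sos = _signal.bessel(4, spec.bessel_corner_hz, fs=1.0 / spec.dt,
                             output="sos")
        x = _signal.sosfilt(sos, x)
    return Trace(x, dt=spec.dt, holding_potential=holding_mV,
                 label=label or f"synthetic patch @ {holding_mV:g} mV",
                 filter_corner_hz=None if noise_free else spec.bessel_corner_hz,
                 filter_type=None if noise_free else "bessel4")


@dataclass
class PatchExperiment:
    """Replicate synthetic patches at several holding potentials.

    ``patches[k][v]`` is the Trace of patch ``k`` at potential ``v``;
    ``truth`` records the generator's programmed parameters for
    recovery testing.
    """

    patches: list[dict[float, Trace]]
    truth: dict

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    def traces_at(self, holding_mV: float) -> list[Trace]:
        return [p[holding_mV] for p in self.patches]


def gen_patch_experiment(spec: GeneratorSpec) -> PatchExperiment:
    """Replicate patches at each holding potential of the spec.

    Per-patch/per-potential RNG streams are spawned deterministically
    from the master seed, so each patch is independent yet the whole
    experiment is reproducible.
    """
    seq = np.random.SeedSequence(spec.seed)
    children = seq.spawn(spec.n_patches * len(spec.holding_potentials_mV))
    patches = []
    k = 0
    for ip in range(spec.n_patches):
        rec: dict[float, Trace] = {}
        for v in spec.holding_potentials_mV:
            rng = np.random.default_rng(children[k])
            k += 1
            rec[v] = gen_channel_noise(
                spec, holding_mV=v, rng=rng,
                label=f"patch {ip} @ {v:g} mV",
            )
        patches.append(rec)
    truth = {
        "unitary_current_fA": spec.unitary_current_fA,
        "open_probability": spec.open_probability,
        "n_channels": spec.n_channels,
        "expected_mean_pA": spec.expected_mean_pA(),
        "expected_variance_A2": spec.expected_variance_A2(),
        "seed": spec.seed,
    }
    return PatchExperiment(patches=patches, truth=truth)
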