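"""Stationary noise analysis of patch-clamp current recordings.

The workflow estimates the unitary current of channels too small to
resolve as discrete events.  For each excised-patch record held at a
test potential:

1. a full-length Hamming-windowed periodogram is computed
   (:func:`compute_psd`), one record per spectrum, spectra averaged
   across replicate patches (:func:`average_spectra`);
2. the averaged spectrum at 0 mV holding is taken as the instrumentation
   background and subtracted pointwise (:func:`subtract_background`);
3. the excess variance is the integral of the subtracted spectrum over
   0.1-1000 Hz after removal of the calculated shot-noise density
   2*I*e0 (:func:`band_variance`);
4. the unitary current estimate is the ratio sigma^2 / <I>
   (:func:`unitary_current`).

The estimator assumes channels switch between open and closed states
with low open probability and that the fluctuations are confined to the
integration band; it is deliberately rough (order-of-magnitude), which
is why end-to-end checks in this package use a factor-of-two criterion.
Power-law (approximately 1/f) spectra, the signature of a broad
distribution of relaxation times, are characterized by
:func:`fit_power_law`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal
from scipy.stats import linregress

from .constants import ELEMENTARY_CHARGE, PICO
from .exceptions import DomainError, GridMismatchError

__all__ = [
    "Trace",
    "SpectrumRecord",
    "NoiseEstimate",
    "compute_psd",
    "average_spectra",
    "subtract_background",
    "shot_noise_density",
    "band_variance",
    "unitary_current",
    "fit_power_law",
    "analyze_patch_set",
]


@dataclass
class Trace:
    """A uniformly sampled current record.

    Attributes
    ----------
    samples : ndarray
        Current, pA.
    dt : float
        Sampling interval, s.
    holding_potential : float
        Command potential during the record, mV.
    label : str
        Free-text condition label (e.g. solution).
    filter_corner_hz, filter_type : optional
        Acquisition filter metadata.
    """

    samples: np.ndarray
    dt: float
    holding_potential: float = 0.0
    label: str = ""
    filter_corner_hz: float | None = None
    filter_type: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise DomainError(f"dt must be > 0 s, got {self.dt}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise DomainError("trace needs >= 2 samples in a 1-d array")
        if not np.isfinite(self.samples).all():
            raise DomainError("trace contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length, s."""
        return self.n * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def mean_current(self) -> float:
        """<I>, pA."""
        return float(self.samples.mean())


@dataclass
class SpectrumRecord:
    """One-sided power spectral density of a current record.

    ``psd`` is in A^2/Hz on a strictly increasing frequency grid with
    the DC bin removed.  Values may be negative after background
    subtraction; ``has_negative`` flags this.
    """

    freqs: np.ndarray
    psd: np.ndarray
    resolution: float
    n_averaged: int = 1
    holding_potential: float = 0.0

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.shape != self.psd.shape:
            raise DomainError("freqs and psd must have equal shape")
        if self.freqs.size and (self.freqs[0] <= 0 or np.any(np.diff(self.freqs) <= 0)):
            raise DomainError("frequency grid must be strictly increasing and > 0")
        if not np.isfinite(self.psd).all():
            raise DomainError("psd contains non-finite values")

    @property
    def has_negative(self) -> bool:
        return bool(np.any(self.psd < 0))


@dataclass
class NoiseEstimate:
    """Result of the variance/mean unitary-current estimate."""

    variance: float  # A^2
    mean_current: float  # pA
    unitary_current_fA: float
    band: tuple[float, float]
    n_patches: int = 1
    label: str = ""

    def summary(self) -> str:
        return "\n".join([
            "Stationary noise analysis",
            "=" * 46,
            f"{'condition':<22}{self.label}",
            f"{'patches averaged':<22}{self.n_patches}",
            f"{'band (Hz)':<22}{self.band[0]:g} - {self.band[1]:g}",
            f"{'variance (A^2)':<22}{self.variance:.3e}",
            f"{'<I> (pA)':<22}{self.mean_current:.3g}",
            f"{'sigma^2/<I> (fA)':<22}{self.unitary_current_fA:.3g}",
        ])


def compute_psd(trace: Trace, segment_averaged: bool = False) -> SpectrumRecord:
    """One-sided PSD of a current trace, A^2/Hz.

    A single full-length Hamming-windowed periodogram (mean removed
    before windowing, window power compensated, DC bin dropped); the
    frequency resolution is 1/(n*dt).  With ``segment_averaged=True`` a
    Welch estimate on 8 half-overlapping segments is returned instead
    (coarser grid, smoother estimate).

    Raises
    ------
    DomainError
        For traces shorter than 1024 samples.
    """
    if trace.n < 1024:
        raise DomainError(f"trace too short for spectral analysis: {trace.n} < 1024")
    x = trace.samples * PICO  # -> A
    fs = 1.0 / trace.dt
    if segment_averaged:
        nper = trace.n // 4
        f, p = _signal.welch(x, fs=fs, window="hamming", nperseg=nper,
                             detrend="constant")
    else:
        f, p = _signal.periodogram(x, fs=fs, window="hamming", detrend="constant")
    keep = f > 0
    return SpectrumRecord(
        freqs=f[keep], psd=p[keep], resolution=1.0 / (trace.n * trace.dt),
        n_averaged=1, holding_potential=trace.holding_potential,
    )


def _check_grids(a: SpectrumRecord, b: SpectrumRecord):
    if a.freqs.shape != b.freqs.shape or not np.allclose(
            a.freqs, b.freqs, rtol=1e-10, atol=0):
        raise GridMismatchError("spectra have different frequency grids")


def average_spectra(records: list[SpectrumRecord]) -> SpectrumRecord:
    """Pointwise mean of spectra on identical grids; n_averaged sums."""
    if not records:
        raise DomainError("average_spectra: empty list")
    first = records[0]
    for rec in records[1:]:
        _check_grids(first, rec)
    psd = np.mean([r.psd for r in records], axis=0)
    return SpectrumRecord(
        freqs=first.freqs.copy(), psd=psd, resolution=first.resolution,
        n_averaged=sum(r.n_averaged for r in records),
        holding_potential=first.holding_potential,
    )


def subtract_background(spec: SpectrumRecord, background: SpectrumRecord) -> SpectrumRecord:
    """Pointwise difference spectrum; negative values are preserved.

    The background is conventionally the averaged spectrum at 0 mV
    holding, where the channels under study carry (almost) no current.
    """
    _check_grids(spec, background)
    return replace(spec, freqs=spec.freqs.copy(), psd=spec.psd - background.psd)


def shot_noise_density(mean_current_pA: float) -> float:
    """Shot-noise density 2 * |I| * e0 of a mean current, A^2/Hz."""
    return 2.0 * abs(mean_current_pA) * PICO * ELEMENTARY_CHARGE


def band_variance(spec: SpectrumRecord, f_lo: float = 0.1, f_hi: float = 1000.0,
                  mean_current_pA: float = 0.0) -> float:
    """Band-limited excess variance, A^2.

    Trapezoidal integral of (psd - shot_noise_density) over
    [f_lo, f_hi] on the native linear grid.  Negative post-subtraction
    densities are retained (clipping would bias the variance upward).
    """
    if not f_lo < f_hi:
        raise DomainError(f"need f_lo < f_hi, got ({f_lo}, {f_hi})")
    if f_lo < spec.freqs[0] or f_hi > spec.freqs[-1]:
        raise DomainError(
            f"band [{f_lo}, {f_hi}] Hz outside spectrum grid "
            f"[{spec.freqs[0]:.3g}, {spec.freqs[-1]:.3g}] Hz"
        )
    mask = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    excess = spec.psd[mask] - shot_noise_density(mean_current_pA)
    return float(np.trapezoid(excess, spec.freqs[mask]))


def unitary_current(variance_A2: float, mean_current_pA: float) -> float:
    """Unitary-current estimate i = sigma^2 / <I>, fA.

    The sign follows the mean current.  A zero mean is rejected: the
    estimator is undefined at the reversal potential.
    """
    if mean_current_pA == 0:
        raise DomainError("unitary_current undefined for zero mean current")
    return variance_A2 / (mean_current_pA * PICO) * 1e15


def fit_power_law(spec: SpectrumRecord, band: tuple[float, float] = (0.1, 100.0),
                  n_log_bins: int | None = 40) -> tuple[float, float]:
    """Power-law fit S(f) = A * f^-alpha over ``band``.

    Ordinary least squares in log f - log S space.  By default the raw
    periodogram is first averaged into ``n_log_bins`` logarithmically
    spaced bins, which symmetrizes the heavily skewed single-bin
    scatter; pass ``n_log_bins=None`` to regress on raw bins.

    Returns
    -------
    (amplitude, alpha)
        ``amplitude`` is S(1 Hz); ``alpha`` is positive for decaying
        spectra.

    Raises
    ------
    DomainError
        If non-positive densities remain in the band (suggests wider
        averaging before fitting).
    """
    f_lo, f_hi = band
    mask = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if mask.sum() < 4:
        raise DomainError("fewer than 4 spectral points in the fit band")
    f, s = spec.freqs[mask], spec.psd[mask]
    if n_log_bins is not None:
        edges = np.geomspace(f_lo, f_hi, n_log_bins + 1)
        idx = np.clip(np.searchsorted(edges, f, side="right") - 1, 0, n_log_bins - 1)
        cnt = np.bincount(idx, minlength=n_log_bins)
        good = cnt > 0
        s = np.bincount(idx, weights=s, minlength=n_log_bins)[good] / cnt[good]
        f = np.exp(np.bincount(idx, weights=np.log(f), minlength=n_log_bins)[good]
                   / cnt[good])
    if np.any(s <= 0):
        raise DomainError(
            "non-positive spectral densities in the fit band; average more "
            "records (or more log bins) before fitting a power law"
        )
    res = linregress(np.log10(f), np.log10(s))
    return float(10.0 ** res.intercept), float(-res.slope)


def analyze_patch_set(
    test_traces: list[Trace],
    background_traces: list[Trace],
    f_lo: float = 0.1,
    f_hi: float = 1000.0,
    label: str = "",
) -> NoiseEstimate:
    """Full pipeline on replicate patches at one test potential.

    Per-record periodograms are averaged within the test and the 0-mV
    background groups, the background is subtracted, shot noise removed
    and the band variance divided by the mean test current.
    """
    if len(test_traces) != len(background_traces):
        raise DomainError("need matching numbers of test and background records")
    spec = average_spectra([compute_psd(t) for t in test_traces])
    bg = average_spectra([compute_psd(t) for t in background_traces])
    diff = subtract_background(spec, bg)
    i_mean = float(np.mean([t.mean_current() for t in test_traces]))
    var = band_variance(diff, f_lo, f_hi, mean_current_pA=i_mean)
    return NoiseEstimate(
        variance=var, mean_current=i_mean,
        unitary_current_fA=unitary_current(var, i_mean),
        band=(f_lo, f_hi), n_patches=len(test_traces), label=label,
    )
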