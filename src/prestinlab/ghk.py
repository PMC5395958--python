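"""Nernst and Goldman-Hodgkin-Katz (GHK) reversal potentials.

The GHK voltage equation gives the zero-current potential of a membrane
permeant to several monovalent ions:

    E_rev = (kT/e0) * ln[ (sum_cations P_c [c]_out + sum_anions P_a [a]_in)
                          / (sum_cations P_c [c]_in + sum_anions P_a [a]_out) ]

with relative permeabilities P expressed against a reference ion
(P_ref = 1).  :func:`solve_permeability_ratio` inverts the equation for
a single unknown ratio given a measured reversal potential, which is
how permeability ratios such as P_Cl/P_K are inferred from ion
substitution experiments.

Only valences +/-1 enter the GHK sums (the standard monovalent form);
divalent species may be carried in a :class:`SolutionComposition` for
bookkeeping but are excluded from the reversal computation.  Activity
coefficients are taken as 1, i.e. concentrations are used directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import ROOM_TEMPERATURE, thermal_voltage_mV
from .exceptions import DomainError

__all__ = [
    "Ion",
    "SolutionComposition",
    "nernst",
    "ghk_reversal",
    "solve_permeability_ratio",
]


@dataclass(frozen=True)
class Ion:
    """One ionic species with inside/outside concentrations in mM."""

    name: str
    valence: int
    conc_in: float
    conc_out: float

    def __post_init__(self):
        if self.conc_in < 0 or self.conc_out < 0:
            raise DomainError(f"{self.name}: concentrations must be >= 0 mM")
        if self.valence == 0:
            raise DomainError(f"{self.name}: valence must be non-zero")


@dataclass
class SolutionComposition:
    """Inside/outside ionic composition of a recording configuration."""

    ions: list[Ion]
    temperature: float = ROOM_TEMPERATURE

    def __post_init__(self):
        names = [ion.name for ion in self.ions]
        if len(set(names)) != len(names):
            raise DomainError("duplicate ion names in solution")

    def __getitem__(self, name: str) -> Ion:
        for ion in self.ions:
            if ion.name == name:
                return ion
        raise KeyError(name)

    @property
    def monovalent(self) -> list[Ion]:
        return [ion for ion in self.ions if abs(ion.valence) == 1]


def nernst(ion: Ion, temperature: float = ROOM_TEMPERATURE) -> float:
    """Nernst equilibrium potential E = (kT / z e0) ln([out]/[in]), mV."""
    if ion.conc_in <= 0 or ion.conc_out <= 0:
        raise DomainError(
            f"nernst({ion.name}): both concentrations must be > 0 mM"
        )
    vt = thermal_voltage_mV(temperature)
    return vt / ion.valence * float(np.log(ion.conc_out / ion.conc_in))


def _ghk_sums(solution: SolutionComposition, perms: dict[str, float]):
    num = den = 0.0
    n_permeant = 0
    for ion in solution.monovalent:
        p = perms.get(ion.name, 0.0)
        if p < 0:
            raise DomainError(f"permeability of {ion.name} must be >= 0")
        if p == 0:
            continue
        n_permeant += 1
        if ion.valence > 0:
            num += p * ion.conc_out
            den += p * ion.conc_in
        else:
            num += p * ion.conc_in
            den += p * ion.conc_out
    return num, den, n_permeant


def ghk_reversal(solution: SolutionComposition, perms: dict[str, float]) -> float:
    """GHK reversal potential, mV.

    ``perms`` maps ion name to relative permeability; ions absent from
    the map are treated as impermeant.  With a single permeant ion the
    result equals that ion's Nernst potential exactly.
    """
    num, den, n_permeant = _ghk_sums(solution, perms)
    if n_permeant == 0:
        raise DomainError("no permeant monovalent ion in solution")
    if num <= 0 or den <= 0:
        raise DomainError(
            f"GHK sums must be > 0 (got numerator {num}, denominator {den}); "
            "each side needs at least one permeant ion at non-zero concentration"
        )
    vt = thermal_voltage_mV(solution.temperature)
    return vt * float(np.log(num / den))


def solve_permeability_ratio(
    e_rev_mV: float,
    solution: SolutionComposition,
    numerator_ion: str,
    reference_ion: str,
    fixed_perms: dict[str, float] | None = None,
) -> float:
    """Permeability ratio P_numerator/P_reference from a measured E_rev.

    All permeabilities other than the numerator ion's are held fixed
    (reference at 1, plus any supplied in ``fixed_perms``); the single
    unknown is solved by bisection on a bracket widened geometrically
    from [1e-4, 1e4].

    Raises
    ------
    DomainError
        If the target potential is outside the attainable range of the
        model (no sign change over the widened bracket), or if E_rev is
        insensitive to the ratio (degenerate, e.g. symmetric solutions).
    """
    perms = {reference_ion: 1.0}
    perms.update(fixed_perms or {})
    perms.setdefault(reference_ion, 1.0)

    def f(log10_ratio: float) -> float:
        p = dict(perms)
        p[numerator_ion] = 10.0 ** log10_ratio
        return ghk_reversal(solution, p) - e_rev_mV

    lo, hi = -4.0, 4.0
    flo, fhi = f(lo), f(hi)
    if abs(fhi - flo) < 1e-9:
        raise DomainError(
            "reversal potential is insensitive to the permeability ratio "
            "(degenerate solution composition); the ratio is unidentifiable"
        )
    n_widen = 0
    while flo * fhi > 0 and n_widen < 6:
        lo -= 4.0
        hi += 4.0
        flo, fhi = f(lo), f(hi)
        n_widen += 1
    if flo * fhi > 0:
        attainable = sorted((f(lo) + e_rev_mV, f(hi) + e_rev_mV))
        raise DomainError(
            f"E_rev = {e_rev_mV} mV is not attainable for any ratio in "
            f"[1e{lo:.0f}, 1e{hi:.0f}]; attainable range is "
            f"[{attainable[0]:.2f}, {attainable[1]:.2f}] mV"
        )
    root = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    return 10.0 ** root
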