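"""Delimited-text file formats and run configuration.

Data formats (all plain text, '#'-prefixed metadata, comma or tab
delimited, auto-detected):

- traces: header keys ``dt_s`` (required), ``holding_mV`` (required),
  ``label``, ``filter_corner_hz``, ``filter_type``; columns
  ``t_s,i_pA``;
- C-V tables: columns ``v_mV,cm_pF``;
- I-V tables: columns ``v_mV,i_pA`` or ``v_mV,i_pA_per_pF`` (the
  density flag is inferred from the header);
- spectra: columns ``f_hz,psd_a2_per_hz``.

Configuration is TOML; :class:`RunConfig` round-trips (write -> read ->
equal) and unknown keys are rejected with their dotted location.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .barrier import IVCurve
from .exceptions import ParseError
from .ghk import Ion, SolutionComposition
from .nlc import CVCurve
from .noise import SpectrumRecord, Trace

__all__ = [
    "read_trace", "write_trace", "read_table", "write_table",
    "read_spectrum", "write_spectrum", "RunConfig", "read_config",
    "write_config", "solution_from_config",
]

_FLOAT_FMT = "%.12g"  # round-trip identity to 12 significant digits


def _read_text(path) -> tuple[dict, list[str], int]:
    """Split a delimited file into (metadata, data lines, first data lineno)."""
    meta: dict[str, str] = {}
    rows: list[str] = []
    first = 0
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        if not rows:
            first = lineno
        rows.append(s)
    if not rows:
        raise ParseError(f"{path}: no data rows found")
    return meta, rows, first


def _parse_rows(rows: list[str], path, first_lineno: int) -> tuple[list[str], np.ndarray]:
    sep = "\t" if "\t" in rows[0] else ","
    header = [h.strip() for h in rows[0].split(sep)]
    ncol = len(header)
    data = np.empty((len(rows) - 1, ncol))
    for k, row in enumerate(rows[1:]):
        parts = row.split(sep)
        if len(parts) != ncol:
            raise ParseError(
                f"{path}:{first_lineno + 1 + k}: expected {ncol} fields, "
                f"got {len(parts)}"
            )
        try:
            data[k] = [float(p) for p in parts]
        except ValueError as exc:
            raise ParseError(f"{path}:{first_lineno + 1 + k}: {exc}") from exc
    return header, data


def read_trace(path) -> Trace:
    """Read a current trace; requires ``dt_s`` and ``holding_mV`` metadata."""
    meta, rows, first = _read_text(path)
    for key in ("dt_s", "holding_mV"):
        if key not in meta:
            raise ParseError(f"{path}: missing required metadata key '{key}'")
    header, data = _parse_rows(rows, path, first)
    if "i_pA" not in header:
        raise ParseError(f"{path}: trace file must have an 'i_pA' column, got {header}")
    corner = meta.get("filter_corner_hz")
    return Trace(
        samples=data[:, header.index("i_pA")],
        dt=float(meta["dt_s"]),
        holding_potential=float(meta["holding_mV"]),
        label=meta.get("label", ""),
        filter_corner_hz=float(corner) if corner is not None else None,
        filter_type=meta.get("filter_type"),
    )


def write_trace(trace: Trace, path) -> None:
    lines = [
        f"# dt_s = {trace.dt:.12g}",
        f"# holding_mV = {trace.holding_potential:.12g}",
    ]
    if trace.label:
        lines.append(f"# label = {trace.label}")
    if trace.filter_corner_hz is not None:
        lines.append(f"# filter_corner_hz = {trace.filter_corner_hz:.12g}")
    if trace.filter_type:
        lines.append(f"# filter_type = {trace.filter_type}")
    lines.append("t_s,i_pA")
    t = trace.time
    lines += [f"{ti:.12g},{xi:.12g}" for ti, xi in zip(t, trace.samples)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path) -> CVCurve | IVCurve:
    """Read a C-V or I-V table; dispatch on the header column names."""
    meta, rows, first = _read_text(path)
    header, data = _parse_rows(rows, path, first)
    if "v_mV" not in header:
        raise ParseError(f"{path}: table must have a 'v_mV' column, got {header}")
    v = data[:, header.index("v_mV")]
    if "cm_pF" in header:
        return CVCurve(v, data[:, header.index("cm_pF")])
    if "i_pA_per_pF" in header:
        return IVCurve(v, data[:, header.index("i_pA_per_pF")], density_normalized=True)
    if "i_pA" in header:
        return IVCurve(v, data[:, header.index("i_pA")], density_normalized=False)
    raise ParseError(
        f"{path}: ambiguous table header {header}; accepted value columns are "
        "'cm_pF', 'i_pA' or 'i_pA_per_pF'"
    )


def write_table(curve: CVCurve | IVCurve, path) -> None:
    if isinstance(curve, CVCurve):
        header, y = "v_mV,cm_pF", curve.cm
    else:
        header = "v_mV,i_pA_per_pF" if curve.density_normalized else "v_mV,i_pA"
        y = curve.i
    lines = [header] + [f"{v:.12g},{x:.12g}" for v, x in zip(curve.v, y)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path) -> SpectrumRecord:
    meta, rows, first = _read_text(path)
    header, data = _parse_rows(rows, path, first)
    if header[:2] != ["f_hz", "psd_a2_per_hz"]:
        raise ParseError(f"{path}: spectrum columns must be f_hz,psd_a2_per_hz")
    return SpectrumRecord(
        freqs=data[:, 0], psd=data[:, 1],
        resolution=float(meta.get("resolution_hz", data[1, 0] - data[0, 0])),
        n_averaged=int(meta.get("n_averaged", 1)),
        holding_potential=float(meta.get("holding_mV", 0.0)),
    )


def write_spectrum(spec: SpectrumRecord, path) -> None:
    lines = [
        f"# resolution_hz = {spec.resolution:.12g}",
        f"# n_averaged = {spec.n_averaged}",
        f"# holding_mV = {spec.holding_potential:.12g}",
        "f_hz,psd_a2_per_hz",
    ]
    lines += [f"{f:.12g},{p:.12g}" for f, p in zip(spec.freqs, spec.psd)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Run-level configuration (TOML on disk).

    ``solutions`` maps a name to a list of ion tables
    (``{ion, valence, in_mM, out_mM}``); ``fit`` holds fixed-parameter
    maps; ``noise_band`` is the variance-integration band in Hz.
    """

    temperature: float = 296.15
    seed: int = 0
    verbosity: int = 0
    noise_band: tuple[float, float] = (0.1, 1000.0)
    solutions: dict = field(default_factory=dict)
    protocols: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)

    def to_toml(self) -> str:
        out = [
            f"temperature = {self.temperature}",
            f"seed = {self.seed}",
            f"verbosity = {self.verbosity}",
            f"noise_band = [{self.noise_band[0]}, {self.noise_band[1]}]",
        ]
        for section, table in (("solutions", self.solutions),
                               ("protocols", self.protocols),
                               ("fit", self.fit)):
            for name, entry in table.items():
                if section == "solutions":
                    for ion in entry:
                        out.append(f"\n[[{section}.{name}]]")
                        out += [f'ion = "{ion["ion"]}"',
                                f"valence = {ion['valence']}",
                                f"in_mM = {ion['in_mM']}",
                                f"out_mM = {ion['out_mM']}"]
                else:
                    out.append(f"\n[{section}.{name}]")
                    for k, v in entry.items():
                        if isinstance(v, str):
                            out.append(f'{k} = "{v}"')
                        elif isinstance(v, (list, tuple)):
                            out.append(f"{k} = [{', '.join(str(x) for x in v)}]")
                        else:
                            out.append(f"{k} = {v}")
        return "\n".join(out) + "\n"


_TOP_KEYS = {"temperature", "seed", "verbosity", "noise_band",
             "solutions", "protocols", "fit"}
_ION_KEYS = {"ion", "valence", "in_mM", "out_mM"}


def read_config(path) -> RunConfig:
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown configuration key(s) {sorted(unknown)}")
    cfg = RunConfig()
    cfg.temperature = float(raw.get("temperature", cfg.temperature))
    cfg.seed = int(raw.get("seed", cfg.seed))
    cfg.verbosity = int(raw.get("verbosity", cfg.verbosity))
    band = raw.get("noise_band", list(cfg.noise_band))
    cfg.noise_band = (float(band[0]), float(band[1]))
    for name, ions in raw.get("solutions", {}).items():
        for k, ion in enumerate(ions):
            bad = set(ion) - _ION_KEYS
            if bad:
                raise ParseError(
                    f"{path}: unknown key(s) {sorted(bad)} at solutions.{name}[{k}]"
                )
        cfg.solutions[name] = [dict(ion) for ion in ions]
    cfg.protocols = {k: dict(v) for k, v in raw.get("protocols", {}).items()}
    cfg.fit = {k: dict(v) for k, v in raw.get("fit", {}).items()}
    return cfg


def write_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(cfg.to_toml())


def solution_from_config(cfg: RunConfig, name: str) -> SolutionComposition:
    """Build a :class:`SolutionComposition` from a named config block."""
    if name not in cfg.solutions:
        raise ParseError(f"no solution named {name!r} in configuration")
    ions = [Ion(d["ion"], int(d["valence"]), float(d["in_mM"]), float(d["out_mM"]))
            for d in cfg.solutions[name]]
    return SolutionComposition(ions, temperature=cfg.temperature)
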