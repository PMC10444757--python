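"""Wavelength-sampled spectra.

The package's basic container is :class:`Spectrum`: a quantity sampled on a
strictly increasing wavelength grid (nanometres).  Four kinds of quantity are
distinguished because they carry different range constraints:

``counts``
    raw spectrometer counts (non-negative, arbitrary scale),
``transmittance_percent``
    percent transmission, clipped to [0, 100] (see :func:`clip_transmittance`),
``absorbance``
    relative absorbance (non-negative),
``sensitivity``
    peak-normalised spectral sensitivity in [0, 1].

Spectra are deliberately dumb: resampling is plain linear interpolation and
never extrapolates, so any disagreement between instrument grids has to be
resolved explicitly by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumKind",
    "KINDS",
    "resample",
    "clip_transmittance",
    "uniform_grid",
    "read_spectrum",
    "write_spectrum",
]

log = logging.getLogger(__name__)

SpectrumKind = str
KINDS = ("counts", "transmittance_percent", "absorbance", "sensitivity")


@dataclass(frozen=True)
class Spectrum:
    """A real-valued quantity sampled on a strictly increasing nm grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing 1-D wavelength grid in nanometres.
    values
        Sampled values, same length as the grid.
    kind
        One of ``counts``, ``transmittance_percent``, ``absorbance``,
        ``sensitivity``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = "counts"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if wl.size != vals.size:
            raise ValueError(
                f"grid length {wl.size} != values length {vals.size}"
            )
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.kind not in KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "transmittance_percent" and (
            vals.min() < 0.0 or vals.max() > 100.0
        ):
            raise ValueError(
                "transmittance_percent values must lie in [0, 100]; "
                "apply clip_transmittance() first"
            )
        if self.kind == "sensitivity" and (vals.min() < 0.0 or vals.max() > 1.0 + 1e-12):
            raise ValueError("sensitivity values must lie in [0, 1]")
        wl.setflags(write=False)
        vals.setflags(write=False)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    # -- conveniences -------------------------------------------------------
    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def value_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated value at a single wavelength (no extrapolation)."""
        lo, hi = self.span
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside span [{lo}, {hi}] nm"
            )
        return float(np.interp(wavelength_nm, self.wavelengths_nm, self.values))

    def with_values(self, values: np.ndarray, kind: SpectrumKind | None = None) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, np.asarray(values, dtype=float),
                        kind if kind is not None else self.kind)

    def restrict(self, lo_nm: float, hi_nm: float) -> "Spectrum":
        """Samples with lo <= wavelength <= hi."""
        mask = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        if mask.sum() < 2:
            raise ValueError(
                f"window [{lo_nm}, {hi_nm}] nm retains fewer than two samples"
            )
        return Spectrum(self.wavelengths_nm[mask], self.values[mask], self.kind)


def uniform_grid(lo_nm: float, hi_nm: float, step_nm: float) -> np.ndarray:
    """Uniform grid from lo to hi inclusive.

    The number of samples is ``floor((hi - lo) / step) + 1``; the grid is
    built with :func:`numpy.linspace` so the endpoints are exact.
    """
    if not (hi_nm > lo_nm and step_nm > 0):
        raise ValueError("need hi > lo and step > 0")
    n = int(np.floor((hi_nm - lo_nm) / step_nm + 1e-9)) + 1
    return np.linspace(lo_nm, lo_nm + (n - 1) * step_nm, n)


def resample(spec: Spectrum, grid: Union[np.ndarray, Iterable[float]]) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid.

    The target grid must lie within the source span; extrapolation is an
    error because the instruments this package models report nothing outside
    their scan window.
    """
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid,
                      dtype=float)
    lo, hi = spec.span
    if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
        raise ValueError(
            f"resample target [{grid[0]}, {grid[-1]}] nm extends beyond the "
            f"source span [{lo}, {hi}] nm"
        )
    vals = np.interp(grid, spec.wavelengths_nm, spec.values)
    return Spectrum(grid, vals, spec.kind)


def clip_transmittance(values: np.ndarray) -> np.ndarray:
    """Clip raw percent-transmittance values into [0, 100].

    Measurement noise can push sample counts above the unpigmented reference,
    producing T > 100%; those points are physically meaningless and are
    clipped.  Clipping events are counted and logged at DEBUG level.
    """
    values = np.asarray(values, dtype=float)
    n_clip = int(np.sum((values < 0.0) | (values > 100.0)))
    if n_clip:
        log.debug("clipped %d transmittance samples into [0, 100]", n_clip)
    return np.clip(values, 0.0, 100.0)


# -- text I/O ----------------------------------------------------------------
#
# Two-column delimited text, `wavelength_nm<sep>value`, tab or comma
# separated; lines starting with '#' are headers.  The writer emits
# tab-separated values with a `# kind=` header so kind round-trips.

def read_spectrum(path: Union[str, Path], kind: SpectrumKind | None = None) -> Spectrum:
    path = Path(path)
    wavelengths: list[float] = []
    values: list[float] = []
    file_kind: SpectrumKind | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("kind="):
                    file_kind = body.split("=", 1)[1].strip()
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {line!r}")
            wavelengths.append(float(parts[0]))
            values.append(float(parts[1]))
    resolved = kind or file_kind or "counts"
    return Spectrum(np.asarray(wavelengths), np.asarray(values), resolved)


def write_spectrum(spec: Spectrum, path: Union[str, Path]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# kind={spec.kind}\n")
        for wl, v in zip(spec.wavelengths_nm, spec.values):
            fh.write(f"{wl:.6g}\t{v:.10g}\n")
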