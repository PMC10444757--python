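"""Microspectrophotometry (MSP) of chromatophores.

A microspectrophotometer passes white light through a single pigment-bearing
skin cell (chromatophore) and through nearby unpigmented tissue as a
reference; the ratio of the two count spectra is the cell's percent
transmittance T(lambda).  This module turns collections of such paired scans
into per-pigment-type summaries:

* the mean +/- s.e.m. transmittance spectrum per chromatophore type
  (melanophore, erythrophore, xanthophore),
* the *transition wavelength* of types showing a sharp low-to-high
  transmittance step: the wavelength where the tangent at the point of
  steepest slope intersects zero transmittance,
* the *SWS1-weighted attenuation*: the fractional reduction of
  short-wavelength quantal catch a photoreceptor beneath the cell would
  suffer, computed as 1 - integral(T*S*E) / integral(100*S*E) with S a
  visual-pigment sensitivity template and E the illuminant.

The interface follows the model/results idiom: build a
:class:`ChromatophoreMSP` model from scans (or a scan directory), call
``fit()`` and read estimates off the returned :class:`MSPResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra import (
    Spectrum,
    clip_transmittance,
    read_spectrum,
    resample,
    uniform_grid,
    write_spectrum,
)
from .templates import a1_template

__all__ = [
    "CHROMATOPHORE_TYPES",
    "MSPScan",
    "TypeSummary",
    "ChromatophoreMSP",
    "MSPResults",
    "transmittance",
    "average_by_type",
    "transition_wavelength",
    "sws1_attenuation",
    "read_scan_directory",
]

log = logging.getLogger(__name__)

CHROMATOPHORE_TYPES = ("melanophore", "erythrophore", "xanthophore")

#: instrument scan window, nm
INSTRUMENT_WINDOW = (400.0, 700.0)
#: default analysis grid: instrument window at ~0.3 nm optical resolution
DEFAULT_STEP_NM = 0.3
#: SWS1 quantal-catch integration window, nm (template-weighted region
#: intersected with the instrument range)
ATTENUATION_WINDOW = (400.0, 500.0)
#: default smoothing window for slope estimation, nm
SMOOTH_WINDOW_NM = 5.0
#: minimum peak slope (%/nm) for a transition to be declared
MIN_TRANSITION_SLOPE = 0.2
DEFAULT_LAMBDA_MAX_NM = 415.0


def default_grid() -> np.ndarray:
    lo, hi = INSTRUMENT_WINDOW
    return uniform_grid(lo, hi, DEFAULT_STEP_NM)


@dataclass(frozen=True)
class MSPScan:
    """One cell's paired sample/reference count scans plus metadata."""

    sample: Spectrum
    reference: Spectrum
    cell_id: str
    fish_id: str
    chromatophore_type: str

    def __post_init__(self) -> None:
        if self.chromatophore_type not in CHROMATOPHORE_TYPES:
            raise ValueError(
                f"unknown chromatophore type {self.chromatophore_type!r}; "
                f"expected one of {CHROMATOPHORE_TYPES}"
            )
        for name, spec in (("sample", self.sample), ("reference", self.reference)):
            if spec.kind != "counts":
                raise ValueError(f"{name} scan must have kind='counts'")


def transmittance(scan: MSPScan, grid: Optional[np.ndarray] = None) -> Spectrum:
    """Percent transmittance of the chromatophore alone.

    T(lambda) = 100 * sample / reference on a common grid (the default grid
    intersected with both scans' spans), clipped into [0, 100].  A
    non-positive reference count anywhere on the window is an error — the
    ratio is undefined there — reported with the offending wavelength.
    """
    if grid is None:
        lo = max(scan.sample.span[0], scan.reference.span[0], INSTRUMENT_WINDOW[0])
        hi = min(scan.sample.span[1], scan.reference.span[1], INSTRUMENT_WINDOW[1])
        if hi <= lo:
            raise ValueError("sample and reference scans do not overlap on the window")
        grid = uniform_grid(lo, hi, DEFAULT_STEP_NM)
    sample = resample(scan.sample, grid)
    reference = resample(scan.reference, grid)
    bad = reference.values <= 0.0
    if bad.any():
        wl = grid[np.argmax(bad)]
        raise ValueError(
            f"reference count <= 0 at {wl:.1f} nm (cell {scan.cell_id}); "
            "transmittance undefined"
        )
    ratio = 100.0 * sample.values / reference.values
    return Spectrum(grid, clip_transmittance(ratio), kind="transmittance_percent")


@dataclass(frozen=True)
class TypeSummary:
    """Per-chromatophore-type summary of the MSP fit."""

    chromatophore_type: str
    mean_T: Spectrum
    sem_T: Spectrum
    n_cells: int
    transition_nm: Optional[float] = None
    attenuation_fraction: Optional[float] = None


def average_by_type(
    scans: Sequence[MSPScan],
    grid: Optional[np.ndarray] = None,
    chromatophore_type: Optional[str] = None,
) -> TypeSummary:
    """Pointwise mean and s.e.m. of per-cell transmittance spectra.

    Restricts to ``chromatophore_type`` when given (all scans must then be
    of one type otherwise).  The s.e.m. uses the sample standard deviation
    (ddof=1) over cells; a single cell yields s.e.m. 0.
    """
    if chromatophore_type is not None:
        scans = [s for s in scans if s.chromatophore_type == chromatophore_type]
    else:
        types = {s.chromatophore_type for s in scans}
        if len(types) > 1:
            raise ValueError(
                "scans of multiple types given without a type selector"
            )
    if not scans:
        raise ValueError("no scans to average")
    if grid is None:
        grid = default_grid()
    ctype = scans[0].chromatophore_type
    stack = np.vstack([transmittance(s, grid).values for s in scans])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return TypeSummary(
        chromatophore_type=ctype,
        mean_T=Spectrum(grid, clip_transmittance(mean), "transmittance_percent"),
        sem_T=Spectrum(grid, sem, "absorbance"),  # unit-free non-negative container
        n_cells=n,
    )


def _savgol_window(step_nm: float, window_nm: float, n: int, polyorder: int) -> int:
    w = int(round(window_nm / step_nm))
    w = max(w, polyorder + 2)
    if w % 2 == 0:
        w += 1
    if w > n:
        raise ValueError("smoothing window exceeds the spectrum length")
    return w


def transition_wavelength(
    mean_T: Spectrum,
    smooth_window_nm: float = SMOOTH_WINDOW_NM,
    polyorder: int = 2,
    min_slope: float = MIN_TRANSITION_SLOPE,
) -> Optional[float]:
    """Transition wavelength of a low-to-high transmittance step.

    The spectrum is smoothed by a local quadratic (Savitzky-Golay) filter,
    the wavelength lambda0 of maximum slope dT/dlambda is located, and the
    reported transition is the x-intercept of the tangent line there:

        lambda_t = lambda0 - T(lambda0) / T'(lambda0),

    i.e. where the extrapolated steep limb would cross zero transmittance.
    Returns ``None`` when the maximum slope falls below ``min_slope`` (%/nm)
    — the melanophore case, whose transmittance rises slowly and uniformly
    with no transition to report.
    """
    grid = mean_T.wavelengths_nm
    if len(grid) < 50:
        raise ValueError("need at least 50 samples to locate a transition")
    steps = np.diff(grid)
    step = steps[0]
    if not np.allclose(steps, step, rtol=1e-6, atol=1e-9):
        raise ValueError("transition estimation requires a uniform grid")
    w = _savgol_window(step, smooth_window_nm, len(grid), polyorder)
    smooth = savgol_filter(mean_T.values, w, polyorder)
    slope = savgol_filter(mean_T.values, w, polyorder, deriv=1, delta=step)
    i = int(np.argmax(slope))
    if slope[i] < min_slope:
        return None
    return float(grid[i] - smooth[i] / slope[i])


def sws1_attenuation(
    mean_T: Spectrum,
    template: Spectrum,
    illuminant: Optional[Spectrum] = None,
    window: tuple[float, float] = ATTENUATION_WINDOW,
) -> float:
    """Fractional reduction of template-weighted quantal catch.

    1 - integral(T*S*E) / integral(100*S*E) over ``window`` (trapezoid
    rule), with S the sensitivity template and E the illuminant (flat
    equal-quantum by default).  0 means the cell removes nothing over the
    opsin's sensitivity band; 1 means it removes everything.
    """
    lo = max(window[0], mean_T.span[0], template.span[0])
    hi = min(window[1], mean_T.span[1], template.span[1])
    if illuminant is not None:
        lo = max(lo, illuminant.span[0])
        hi = min(hi, illuminant.span[1])
    if hi <= lo:
        raise ValueError("attenuation window does not overlap the spectra")
    grid = mean_T.restrict(lo, hi).wavelengths_nm
    T = resample(mean_T, grid).values
    S = resample(template, grid).values
    E = np.ones_like(grid) if illuminant is None else resample(illuminant, grid).values
    denom = np.trapezoid(100.0 * S * E, grid)
    if denom == 0.0:
        raise ValueError("template-illuminant product integrates to zero")
    return float(1.0 - np.trapezoid(T * S * E, grid) / denom)


class ChromatophoreMSP:
    """Chromatophore transmittance model for a collection of MSP scans.

    Parameters
    ----------
    scans
        MSP scans, any mix of chromatophore types.
    grid
        Common analysis grid; defaults to 400-700 nm at 0.3 nm.
    smooth_window_nm, min_slope
        Transition-estimator configuration (see
        :func:`transition_wavelength`).
    """

    def __init__(
        self,
        scans: Sequence[MSPScan],
        grid: Optional[np.ndarray] = None,
        smooth_window_nm: float = SMOOTH_WINDOW_NM,
        min_slope: float = MIN_TRANSITION_SLOPE,
    ) -> None:
        if not scans:
            raise ValueError("no scans supplied")
        self.scans = list(scans)
        self.grid = default_grid() if grid is None else np.asarray(grid, float)
        self.smooth_window_nm = smooth_window_nm
        self.min_slope = min_slope

    @classmethod
    def from_directory(cls, directory: Union[str, Path], **kwargs) -> "ChromatophoreMSP":
        return cls(read_scan_directory(directory), **kwargs)

    @property
    def types_present(self) -> tuple[str, ...]:
        present = {s.chromatophore_type for s in self.scans}
        return tuple(t for t in CHROMATOPHORE_TYPES if t in present)

    def fit(
        self,
        lambda_max_nm: float = DEFAULT_LAMBDA_MAX_NM,
        illuminant: Optional[Spectrum] = None,
    ) -> "MSPResults":
        """Average scans per type and estimate transitions and attenuations.

        ``lambda_max_nm`` selects the A1 sensitivity template used for the
        attenuation weighting (default 415 nm, the violet SWS1 estimate).
        """
        template = a1_template(lambda_max_nm, self.grid)
        summaries: dict[str, TypeSummary] = {}
        for ctype in self.types_present:
            base = average_by_type(self.scans, self.grid, ctype)
            summaries[ctype] = TypeSummary(
                chromatophore_type=ctype,
                mean_T=base.mean_T,
                sem_T=base.sem_T,
                n_cells=base.n_cells,
                transition_nm=transition_wavelength(
                    base.mean_T, self.smooth_window_nm, min_slope=self.min_slope
                ),
                attenuation_fraction=sws1_attenuation(
                    base.mean_T, template, illuminant
                ),
            )
        return MSPResults(self, summaries, lambda_max_nm)


class MSPResults:
    """Per-type transmittance summaries produced by :meth:`ChromatophoreMSP.fit`."""

    def __init__(
        self,
        model: ChromatophoreMSP,
        summaries: dict[str, TypeSummary],
        lambda_max_nm: float,
    ) -> None:
        self.model = model
        self.summaries = summaries
        self.lambda_max_nm = lambda_max_nm

    def __getitem__(self, chromatophore_type: str) -> TypeSummary:
        return self.summaries[chromatophore_type]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ctype, s in self.summaries.items():
            rows.append(
                {
                    "chromatophore_type": ctype,
                    "n_cells": s.n_cells,
                    "transition_nm": s.transition_nm,
                    "attenuation_fraction": s.attenuation_fraction,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.to_frame().copy()
        frame["transition_nm"] = frame["transition_nm"].map(
            lambda v: "absent" if v is None or pd.isna(v) else f"{v:.1f}"
        )
        frame["attenuation_fraction"] = frame["attenuation_fraction"].map(
            lambda v: f"{v:.3f}"
        )
        header = (
            "Chromatophore MSP summary "
            f"(SWS1 template lambda_max = {self.lambda_max_nm:.0f} nm)"
        )
        return header + "\n" + frame.to_string(index=False)

    def save(self, directory: Union[str, Path]) -> None:
        """Write the summary table and the mean/s.e.m. spectra as text files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "type_summary.tsv", sep="\t", index=False)
        for ctype, s in self.summaries.items():
            write_spectrum(s.mean_T, directory / f"{ctype}_mean_T.tsv")
            write_spectrum(s.sem_T, directory / f"{ctype}_sem_T.tsv")

    def plot(self, path: Optional[Union[str, Path]] = None):
        """Mean +/- s.e.m. transmittance per type, with the template overlaid."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        colors = {"melanophore": "black", "erythrophore": "red", "xanthophore": "gold"}
        fig, ax = plt.subplots(figsize=(6, 4))
        for ctype, s in self.summaries.items():
            wl = s.mean_T.wavelengths_nm
            ax.plot(wl, s.mean_T.values, color=colors.get(ctype, "gray"), label=ctype)
            ax.fill_between(
                wl,
                s.mean_T.values - s.sem_T.values,
                s.mean_T.values + s.sem_T.values,
                color=colors.get(ctype, "gray"),
                alpha=0.2,
                linewidth=0,
            )
        template = a1_template(self.lambda_max_nm, self.model.grid)
        ax.plot(
            template.wavelengths_nm,
            100.0 * template.values,
            "--",
            color="gray",
            label=f"A1 template ({self.lambda_max_nm:.0f} nm), scaled",
        )
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("transmittance (%)")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


# -- scan directory I/O ------------------------------------------------------
#
# Layout: a manifest TSV (cell_id, fish_id, chromatophore_type, sample_path,
# reference_path) plus per-cell 2-column spectrum files, paths relative to
# the manifest.

MANIFEST_NAME = "manifest.tsv"


def read_scan_directory(directory: Union[str, Path]) -> list[MSPScan]:
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"no {MANIFEST_NAME} in {directory}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"cell_id", "fish_id", "chromatophore_type", "sample_path", "reference_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if manifest.empty:
        raise ValueError(f"manifest {manifest_path} lists no scans")
    scans = []
    for row in manifest.itertuples(index=False):
        scans.append(
            MSPScan(
                sample=read_spectrum(directory / row.sample_path, kind="counts"),
                reference=read_spectrum(directory / row.reference_path, kind="counts"),
                cell_id=str(row.cell_id),
                fish_id=str(row.fish_id),
                chromatophore_type=str(row.chromatophore_type),
            )
        )
    return scans
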