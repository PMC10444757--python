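"""Vitamin-A1 visual pigment absorbance template.

A visual pigment's normalised absorbance spectrum is, to good approximation,
a universal function of ``x = log10(lambda / lambda_max)``: the alpha band of
every vitamin-A1 pigment has the same shape in log-wavelength, shifted by its
peak wavelength.  This module implements the modified log-Gaussian form of
that alpha band,

    S(x) = exp(-a0 * x**2 * (1 + a1*x + a2*x**2)),

with the A1 rhodopsin coefficients a0 = 380, a1 = 6.09 and a2 = 3*a1**2/8
(Stavenga-type template).  With a2 fixed at 3*a1**2/8 the quartic
``1 + a1*x + a2*x**2`` is positive for every x, so the curve is globally
unimodal with its single maximum, exactly 1, at lambda_max.

Only the alpha band is produced by default; the small ultraviolet beta band
is omitted because the dermal-photoreception analyses here fit a single
alpha-band curve.  Outside a stated validity window in lambda/lambda_max the
template is set to zero (the closed form is an empirical fit near the band,
not a physical tail model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum

__all__ = ["OpsinTemplate", "a1_template", "A1_COEFFS", "VALIDITY_RATIO"]

log = logging.getLogger(__name__)

#: alpha-band coefficients (a0, a1, a2) of the modified log-Gaussian.
A1_COEFFS = (380.0, 6.09, 3.0 * 6.09**2 / 8.0)

#: validity window of the closed form, as lambda / lambda_max; outside this
#: the evaluated template is 0 (the curve there is < 1e-7 anyway).
VALIDITY_RATIO = (0.7, 1.3)

LAMBDA_MAX_RANGE = (330.0, 650.0)
GRID_RANGE = (300.0, 800.0)


def _alpha_band(ratio: np.ndarray) -> np.ndarray:
    """Normalised alpha-band absorbance at wavelength ratio lambda/lambda_max."""
    a0, a1, a2 = A1_COEFFS
    x = np.log10(ratio)
    return np.exp(-a0 * x**2 * (1.0 + a1 * x + a2 * x**2))


@dataclass(frozen=True)
class OpsinTemplate:
    """A1 visual-pigment template parameterised by its peak wavelength.

    Parameters
    ----------
    lambda_max_nm
        Wavelength of peak sensitivity in nm, within [330, 650].
    chromophore
        Fixed tag ``"A1"`` (retinal); A2 porphyropsin templates are not
        implemented.
    """

    lambda_max_nm: float
    chromophore: str = "A1"

    def __post_init__(self) -> None:
        lo, hi = LAMBDA_MAX_RANGE
        if not (lo <= self.lambda_max_nm <= hi):
            raise ValueError(
                f"lambda_max {self.lambda_max_nm} nm outside supported "
                f"range [{lo}, {hi}] nm"
            )
        if self.chromophore != "A1":
            raise ValueError("only the A1 chromophore template is implemented")

    def __call__(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Evaluate the peak-normalised sensitivity at the given wavelengths."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        ratio = wl / self.lambda_max_nm
        vals = _alpha_band(ratio)
        lo, hi = VALIDITY_RATIO
        outside = (ratio < lo) | (ratio > hi)
        if outside.any():
            log.warning(
                "%d wavelengths outside the template validity window "
                "(lambda/lambda_max in [%.2f, %.2f]); returning 0 there",
                int(outside.sum()), lo, hi,
            )
            vals = np.where(outside, 0.0, vals)
        return vals

    def evaluate(self, grid_nm: np.ndarray) -> Spectrum:
        grid = np.asarray(grid_nm, dtype=float)
        glo, ghi = GRID_RANGE
        if grid[0] < glo or grid[-1] > ghi:
            raise ValueError(
                f"template grid [{grid[0]}, {grid[-1]}] nm outside supported "
                f"range [{glo}, {ghi}] nm"
            )
        return Spectrum(grid, self(grid), kind="sensitivity")


def a1_template(lambda_max_nm: float, grid_nm: np.ndarray) -> Spectrum:
    """Peak-normalised A1 sensitivity spectrum on the given grid.

    Thin functional wrapper over :class:`OpsinTemplate`.
    """
    return OpsinTemplate(lambda_max_nm).evaluate(np.asarray(grid_nm, dtype=float))
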