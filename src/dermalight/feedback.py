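"""Chromatophore-over-photoreceptor optical feedback model.

Dermal SWS1 photoreceptors sit directly beneath chromatophores, so the
light they catch is filtered by whatever pigment the overlying cell has
dispersed.  This module makes that relationship quantitative as a static
input-output map: given a pigment dispersion state d in [0, 1] (0 = fully
aggregated, pigment withdrawn from the light path; 1 = fully dispersed),
the effective transmittance over the photoreceptor is an areal-coverage
mixture of clear aperture and dispersed pigment,

    T_eff(lambda; d) = 100 * (1 - d) + d * T_dispersed(lambda),

and the feedback signal is the relative SWS1 quantal catch

    relative_catch(d) = 1 - attenuation(T_eff(d); template, illuminant),

which equals 1 at d = 0 and decreases monotonically as pigment disperses.
Linear areal mixing is the default because dispersion spreads pigment over
a larger covered area rather than lengthening the optical path; a
Beer-Lambert alternative, T_eff = 100 * (T_dispersed/100)**d, treating d as
optical-density scaling, is available via ``mode="od"``.

No kinetics and no neural transduction are modelled: the activation
characteristics of the dermal receptors and their coupling back to
chromatophores are unknown, so this is the optical front end only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .msp import sws1_attenuation
from .spectra import Spectrum, clip_transmittance

__all__ = [
    "DispersionState",
    "FeedbackSignal",
    "effective_transmittance",
    "feedback_curve",
]

MIXING_MODES = ("areal", "od")


@dataclass(frozen=True)
class DispersionState:
    """Scalar pigment dispersion fraction of one chromatophore type."""

    d: float
    chromatophore_type: str = "melanophore"

    def __post_init__(self) -> None:
        if not (0.0 <= self.d <= 1.0):
            raise ValueError(f"dispersion fraction {self.d} outside [0, 1]")


@dataclass(frozen=True)
class FeedbackSignal:
    """Relative SWS1 quantal catch under one dispersion state."""

    relative_catch: float
    state: DispersionState


def effective_transmittance(
    state: DispersionState,
    dispersed_T: Spectrum,
    mode: str = "areal",
) -> Spectrum:
    """Transmittance over the photoreceptor at dispersion fraction d."""
    if mode not in MIXING_MODES:
        raise ValueError(f"unknown mixing mode {mode!r}; expected {MIXING_MODES}")
    if dispersed_T.kind != "transmittance_percent":
        raise ValueError("dispersed_T must be a transmittance_percent spectrum")
    d = state.d
    if mode == "areal":
        values = 100.0 * (1.0 - d) + d * dispersed_T.values
    else:
        values = 100.0 * np.power(dispersed_T.values / 100.0, d)
    return Spectrum(dispersed_T.wavelengths_nm, clip_transmittance(values),
                    kind="transmittance_percent")


def feedback_curve(
    dispersed_T: Spectrum,
    d_grid: Sequence[float] | np.ndarray,
    template: Spectrum,
    illuminant: Optional[Spectrum] = None,
    mode: str = "areal",
    chromatophore_type: str = "melanophore",
) -> list[FeedbackSignal]:
    """Relative SWS1 quantal catch across a grid of dispersion states.

    ``relative_catch(d) = 1 - sws1_attenuation(T_eff(d), template,
    illuminant)``; strictly decreasing in d whenever the dispersed pigment
    absorbs anywhere under the template.
    """
    signals = []
    for d in np.asarray(d_grid, dtype=float):
        state = DispersionState(float(d), chromatophore_type)
        T_eff = effective_transmittance(state, dispersed_T, mode)
        catch = 1.0 - sws1_attenuation(T_eff, template, illuminant)
        signals.append(FeedbackSignal(relative_catch=float(catch), state=state))
    return signals
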