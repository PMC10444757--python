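"""Synthetic MSP scans and fixture opsin sequences.

The study conditions this generator emulates: three chromatophore pigment
classes measured by single-cell microspectrophotometry over 400-700 nm at
~0.3 nm resolution, 20 cells per type per fish across 3 fish (n = 60 cells
per type), with a quartz-halogen white-light source.

Pigment optics
--------------
Dispersed-pigment transmittance is modelled per type as

* melanophore:   T(lambda) = T400 + k * (lambda - 400)           (slow, uniform rise)
* erythrophore / xanthophore:
                 T(lambda) = T_lo + (T_hi - T_lo) / (1 + exp(-(lambda - m)/s))

i.e. a sharp logistic step from a short-wavelength floor T_lo to a
long-wavelength plateau T_hi.  The floor is required: a yellow or red
pigment cell still passes a measurable fraction of violet light, and the
observed short-wavelength attenuations (~50-90%) are far from total.

The default parameters were calibrated once, by one-dimensional
root-finding against this package's own estimators, so that the noiseless
pipeline reproduces the study-scale transition wavelengths (~550 nm
erythrophore, ~488 nm xanthophore, none for melanophores) and SWS1-weighted
attenuations (~0.90 / 0.85 / 0.50).  They ship as the packaged defaults.

Noise model
-----------
Counts carry multiplicative Gaussian noise (coefficient of variation ``cv``,
default 0.03) — spectrometer counts at bright-lamp levels are gain-scaled,
not shot-limited — with a Poisson mode available.  Each cell additionally
gets a lognormal optical-density multiplier (sigma = 0.1) emulating
biological variation in pigment density across cells.  All randomness
derives from one master seed via per-cell spawned streams, so any subset of
cells is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .msp import CHROMATOPHORE_TYPES, MANIFEST_NAME, MSPScan
from .spectra import Spectrum, uniform_grid, write_spectrum
from .tuning import SubstitutionRecord, bovine_reference

__all__ = [
    "PigmentModel",
    "LinearPigment",
    "LogisticPigment",
    "default_pigment_models",
    "GeneratorConfig",
    "lamp_counts",
    "generate_scans",
    "write_scan_directory",
    "generate_fixture_sequences",
    "DEFAULT_FIXTURE_SUBSTITUTIONS",
]


# -- pigment transmittance models -------------------------------------------

@dataclass(frozen=True)
class PigmentModel:
    chromatophore_type: str

    def transmittance_percent(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def spectrum(self, grid_nm: np.ndarray) -> Spectrum:
        grid = np.asarray(grid_nm, dtype=float)
        return Spectrum(grid, self.transmittance_percent(grid),
                        kind="transmittance_percent")

    @property
    def tangent_intercept_nm(self) -> Optional[float]:
        """Closed-form transition wavelength implied by the model, if any."""
        return None


@dataclass(frozen=True)
class LinearPigment(PigmentModel):
    """Melanophore-style slow uniform rise: T = T400 + k*(lambda - 400)."""

    T400: float = 7.0
    k: float = 0.0667  # %/nm; well below the transition-slope threshold

    def transmittance_percent(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        return np.clip(self.T400 + self.k * (wl - 400.0), 0.0, 100.0)


@dataclass(frozen=True)
class LogisticPigment(PigmentModel):
    """Sharp low-to-high step: T = T_lo + (T_hi - T_lo)/(1 + exp(-(l - m)/s))."""

    midpoint_nm: float = 560.0
    scale_nm: float = 8.0
    T_hi: float = 90.0
    T_lo: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.T_lo < self.T_hi <= 100.0):
            raise ValueError("need 0 <= T_lo < T_hi <= 100")
        if self.scale_nm <= 0:
            raise ValueError("logistic scale must be positive")

    def transmittance_percent(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        z = (wl - self.midpoint_nm) / self.scale_nm
        return self.T_lo + (self.T_hi - self.T_lo) / (1.0 + np.exp(-z))

    @property
    def tangent_intercept_nm(self) -> Optional[float]:
        # max slope at m where T = (T_hi+T_lo)/2 and T' = (T_hi-T_lo)/(4s)
        return self.midpoint_nm - 2.0 * self.scale_nm * (
            (self.T_hi + self.T_lo) / (self.T_hi - self.T_lo)
        )


def default_pigment_models() -> dict[str, PigmentModel]:
    """Packaged dispersed-pigment defaults (calibrated; see module docstring)."""
    return {
        "melanophore": LinearPigment("melanophore", T400=7.94, k=0.0667),
        "erythrophore": LogisticPigment(
            "erythrophore", midpoint_nm=572.51, scale_nm=8.0, T_hi=90.0, T_lo=15.0
        ),
        "xanthophore": LogisticPigment(
            "xanthophore", midpoint_nm=520.63, scale_nm=5.0, T_hi=95.0, T_lo=50.0
        ),
    }


# -- scan generation ---------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic MSP acquisition."""

    n_fish: int = 3
    cells_per_fish_per_type: int = 20
    grid_lo_nm: float = 400.0
    grid_hi_nm: float = 700.0
    grid_step_nm: float = 0.3
    reference_mean_counts: float = 20000.0
    noise_cv: float = 0.03
    noise_model: str = "gaussian"  # or "poisson"
    jitter_sigma: float = 0.1  # lognormal sigma of the per-cell OD multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 1 or self.cells_per_fish_per_type < 1:
            raise ValueError("need at least one fish and one cell per fish")
        if self.reference_mean_counts <= 0:
            raise ValueError("reference counts must be positive")
        if self.noise_cv < 0 or self.jitter_sigma < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def grid(self) -> np.ndarray:
        return uniform_grid(self.grid_lo_nm, self.grid_hi_nm, self.grid_step_nm)


def lamp_counts(config: GeneratorConfig) -> np.ndarray:
    """Smooth lamp-shaped mean count spectrum (3000 K quartz-halogen-like).

    A Planck radiance curve at 3000 K, scaled so its mean over the grid is
    ``reference_mean_counts``; absolute scale is arbitrary since
    transmittance is a ratio.
    """
    wl_m = config.grid * 1e-9
    h, c, kB, T = 6.626e-34, 2.998e8, 1.381e-23, 3000.0
    radiance = wl_m**-5 / (np.exp(h * c / (wl_m * kB * T)) - 1.0)
    return radiance * (config.reference_mean_counts / radiance.mean())


def _cell_rng(config: GeneratorConfig, type_index: int, fish: int, cell: int
              ) -> np.random.Generator:
    # one deterministic stream per cell so any subset is reproducible
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed,
                               spawn_key=(type_index, fish, cell))
    )


def _noisy(counts: np.ndarray, config: GeneratorConfig,
           rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "poisson":
        return rng.poisson(np.maximum(counts, 0.0)).astype(float)
    if config.noise_cv == 0.0:
        return counts.copy()
    return counts * (1.0 + config.noise_cv * rng.standard_normal(counts.shape))


def generate_scans(
    config: Optional[GeneratorConfig] = None,
    pigment_models: Optional[dict[str, PigmentModel]] = None,
) -> list[MSPScan]:
    """Generate the full synthetic scan set (bit-identical under a fixed seed).

    Per cell: reference = lamp counts + noise; sample = lamp counts times
    the cell's transmittance (pigment model raised to a lognormal per-cell
    optical-density power) + noise.
    """
    config = config or GeneratorConfig()
    pigment_models = pigment_models or default_pigment_models()
    grid = config.grid
    lamp = lamp_counts(config)
    scans: list[MSPScan] = []
    for type_index, ctype in enumerate(CHROMATOPHORE_TYPES):
        if ctype not in pigment_models:
            continue
        T_model = pigment_models[ctype].transmittance_percent(grid) / 100.0
        for fish in range(1, config.n_fish + 1):
            for cell in range(1, config.cells_per_fish_per_type + 1):
                rng = _cell_rng(config, type_index, fish, cell)
                if config.jitter_sigma > 0.0:
                    od_mult = rng.lognormal(mean=0.0, sigma=config.jitter_sigma)
                else:
                    od_mult = 1.0
                T_cell = np.power(T_model, od_mult)
                reference = _noisy(lamp, config, rng)
                sample = _noisy(lamp * T_cell, config, rng)
                scans.append(
                    MSPScan(
                        sample=Spectrum(grid, sample, "counts"),
                        reference=Spectrum(grid, reference, "counts"),
                        cell_id=f"{ctype[:4]}_f{fish}_c{cell:02d}",
                        fish_id=f"fish{fish}",
                        chromatophore_type=ctype,
                    )
                )
    return scans


def write_scan_directory(scans: Sequence[MSPScan],
                         directory: Union[str, Path]) -> Path:
    """Write scans in the manifest + per-cell spectrum file layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in scans:
        sample_path = f"{scan.cell_id}_sample.tsv"
        reference_path = f"{scan.cell_id}_reference.tsv"
        write_spectrum(scan.sample, directory / sample_path)
        write_spectrum(scan.reference, directory / reference_path)
        rows.append(
            {
                "cell_id": scan.cell_id,
                "fish_id": scan.fish_id,
                "chromatophore_type": scan.chromatophore_type,
                "sample_path": sample_path,
                "reference_path": reference_path,
            }
        )
    pd.DataFrame(rows).to_csv(directory / MANIFEST_NAME, sep="\t", index=False)
    return directory


# -- fixture opsin sequences -------------------------------------------------

#: substitutions separating the dermal query from the anchor in the default
#: fixture pair: serine->cysteine at bovine site 97, methionine->valine at 116.
DEFAULT_FIXTURE_SUBSTITUTIONS = (
    SubstitutionRecord(97, "S", "C"),
    SubstitutionRecord(116, "M", "V"),
)

# residues placed on the bovine backbone to give the anchor fixture an
# SWS1-like tuning-site content (sites not listed keep the bovine residue)
_ANCHOR_SITE_RESIDUES = {86: "F", 90: "S", 93: "T", 97: "S", 116: "M", 118: "T"}

# background differences away from every tuning site, so the fixtures are
# SWS1-like rather than literally the bovine reference (synthetic sequences;
# they emulate tuning-site content, not any real SWS1 gene)
_BACKGROUND_SUBS = {
    4: "S", 8: "T", 33: "V", 63: "I", 150: "S",
    201: "A", 230: "S", 280: "T", 320: "A", 340: "S",
}


def _anchor_fixture_residues() -> str:
    _, bovine = bovine_reference()
    residues = list(bovine)
    for pos, res in {**_BACKGROUND_SUBS, **_ANCHOR_SITE_RESIDUES}.items():
        residues[pos - 1] = res
    return "".join(residues)


def generate_fixture_sequences(
    substitutions: Sequence[SubstitutionRecord] = DEFAULT_FIXTURE_SUBSTITUTIONS,
) -> list[tuple[str, str]]:
    """A synthetic SWS1-like sequence pair differing at given bovine positions.

    Returns ``[(anchor_id, anchor_seq), (query_id, query_seq)]``: the query
    is the anchor with each substitution applied at its bovine-numbered
    position.  The fixtures share the bovine backbone (hence align to it
    gaplessly), carry SWS1-like residues at the tuning sites, and emulate
    tuning-site content only — they are not real opsin gene sequences.
    """
    anchor = _anchor_fixture_residues()
    query = list(anchor)
    for record in substitutions:
        if not (1 <= record.site <= len(anchor)):
            raise ValueError(
                f"substitution site {record.site} outside the reference "
                f"(1-{len(anchor)})"
            )
        have = query[record.site - 1]
        if have != record.ref_residue:
            raise ValueError(
                f"fixture has {have} at bovine site {record.site}, not "
                f"{record.ref_residue}; cannot apply {record.notation}"
            )
        query[record.site - 1] = record.alt_residue
    return [
        ("sws1_anchor_synthetic", anchor),
        ("sws1_query_synthetic", "".join(query)),
    ]
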