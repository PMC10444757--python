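# Methods

`dermalight` models a dermal photoreception system found in color-changing
fish: putative SWS1-opsin photoreceptors lying directly beneath skin
chromatophores, whose quantal catch is modulated by how much pigment the
overlying cell has dispersed. The package covers four linked analyses —
sequence-based spectral-sensitivity estimation, visual-pigment template
evaluation, microspectrophotometry (MSP) processing, and the
dispersion-feedback model — plus a synthetic-data generator that stands in
for raw scans and sequences, which are not distributed.

## Visual pigment template

The normalised absorbance of a vitamin-A1 pigment's alpha band is treated
as a universal function of `x = log10(lambda / lambda_max)`:

    S(x) = exp(-a0 x^2 (1 + a1 x + a2 x^2)),
    a0 = 380, a1 = 6.09, a2 = 3 a1^2 / 8.

With `a2 = 3 a1^2/8` the quartic in the exponent is positive definite, so
the curve has a single global maximum of exactly 1 at `lambda_max` and the
shape-invariance property `S_a(a r) = S_b(b r)` holds to machine precision.
The beta band (a small ultraviolet shoulder near 350 nm) is omitted: every
quantity computed here weights the 400–500 nm window, where the beta band
of a 415-nm pigment contributes nothing, and the analyses fit a single
alpha-band curve. Outside `lambda/lambda_max` in [0.7, 1.3] the closed
form is an extrapolation we do not trust; the template returns 0 there
with a logged warning (the curve is below 1e-7 at the window edges, so
this choice never moves an integral).

A deliberate caveat: this modified log-Gaussian form and the
rational-exponential (Govardovskii-type) A1 form used as an independent
cross-check in the test suite genuinely disagree by up to ~0.051 on the
long-wavelength limb (near 468 nm for a 415-nm pigment); the log-Gaussian
limb is slightly shallower. Within 380–440 nm they agree to better than
0.02. Neither form is adjusted toward the other.

## Tuning-site analysis and lambda_max estimation

Residue positions are reported in bovine rhodopsin (RH1) numbering: the
query opsin is globally aligned (Needleman–Wunsch, BLOSUM62, gap open 10 /
extend 1) to the packaged 348-residue bovine RH1 sequence and each residue
inherits the bovine position it pairs with. Ciliary opsins are conserved
enough that the numbering is insensitive to the scoring details; ties take
the aligner's first optimal path.

Substitutions are called at a 13-site table of known SWS1 tuning positions
(bovine numbering: 46, 49, 52, 86, 90, 93, 97, 109, 113, 114, 116, 118,
265). The membership of this list is *reconstructed* from the
site-directed-mutagenesis literature and ships as editable YAML
configuration, not as a fixed constant. Sites falling in an alignment gap
are reported as uncallable rather than substituted.

`lambda_max` is estimated anchor-plus-shift: the measured `lambda_max` of a
close homolog plus the sum of the tabulated shift intervals of the
substitutions separating the two sequences. Shipped shift entries:
M116V = [-3, 0] nm; S97C = [-1, 0] nm (a small blue-leaning effect; the
exact value is configurable, as the substitution has not been measured
directly). Substitutions absent from the table get a zero-centred ±3 nm
interval and a low-confidence flag. The point estimate keeps the anchor
value whenever the summed interval contains zero — a net shift of nothing
is then consistent with the data — and falls back to the interval midpoint
otherwise. The point is also checked against the 360–440 nm range of all
known vertebrate SWS1 pigments and the result carried as a boolean flag.

## MSP processing

Per cell, percent transmittance is `T = 100 * sample / reference`
(reference taken through unpigmented tissue), computed on a common
400–700 nm grid at 0.3 nm and clipped to [0, 100] (noise can push sample
counts above the reference; clipping events are logged). Per type, cells
are averaged pointwise; uncertainty is the standard error over cells
(ddof = 1). The modelling default grid elsewhere is 350–700 nm at 0.5 nm,
since the 415-nm template extends below the instrument's 400-nm cut-on.

**Transition wavelength.** The mean spectrum is smoothed with a local
quadratic (Savitzky–Golay) filter, window ≈ 5 nm — at 0.3 nm sampling,
finite differences of the raw mean are noise-dominated — and the
wavelength `lambda0` of maximum slope is located. The reported transition
is the x-intercept of the tangent there, `lambda0 - T(lambda0) /
T'(lambda0)`, i.e. where the extrapolated steep limb crosses zero
transmittance. For a logistic step with midpoint `m`, scale `s`, floor
`T_lo` and plateau `T_hi` this has the closed form
`m - 2s (T_hi + T_lo)/(T_hi - T_lo)` (`m - 2s` for a bare logistic), which
the test suite uses as an exact oracle. The intercept is second-order
insensitive to where on the grid the slope maximum lands, so no sub-grid
peak refinement is needed. If the maximum smoothed slope is below
0.2 %/nm (configurable) no transition is declared — melanophores, whose
transmittance rises slowly and uniformly, must return "absent".

**SWS1-weighted attenuation.** The fractional reduction of quantal catch
for a photoreceptor under the cell:
`1 - trapz(T S E) / trapz(100 S E)` over 400–500 nm (the template-weighted
region intersected with the instrument range), with S the 415-nm A1
template and E a flat equal-quantum illuminant by default (a tabulated
illuminant may be supplied).

## Feedback model

The dispersion state `d` in [0, 1] (0 = fully aggregated, 1 = fully
dispersed) sets the effective filter over the photoreceptor by areal
mixing, `T_eff = 100 (1 - d) + d T_dispersed`: dispersion spreads pigment
over a larger covered area rather than lengthening the optical path, so
coverage, not optical density, scales with `d`. A Beer–Lambert
alternative, `T_eff = 100 (T/100)^d`, is available (`mode="od"`). The
feedback signal is `relative_catch(d) = 1 - attenuation(T_eff(d))`; it is
1 at `d = 0` by construction, agrees with the MSP attenuation at `d = 1`
to machine precision, and decreases monotonically in `d`. No kinetics and
no neural transduction are modelled — the activation characteristics of
the dermal receptors are unknown — so the model is a static optical
input–output map with a single chromatophore layer (stacked-layer serial
filtering is out of scope).

## Synthetic data generator

The generator emulates the study conditions: 3 fish × 20 cells per type
(n = 60 per type), 400–700 nm at 0.3 nm, a 3000 K quartz-halogen lamp
shape for the reference counts. Dispersed-pigment transmittance per type:

| type | model | defaults |
|---|---|---|
| melanophore | `T = T400 + k (lambda - 400)` | `T400 = 7.94`, `k = 0.0667` %/nm |
| erythrophore | logistic floor→plateau | `m = 572.51`, `s = 8`, `T_hi = 90`, `T_lo = 15` |
| xanthophore | logistic floor→plateau | `m = 520.63`, `s = 5`, `T_hi = 95`, `T_lo = 50` |

The short-wavelength floor `T_lo` is essential, not cosmetic: a red or
yellow pigment cell still passes a measurable fraction of violet light,
and a bare logistic whose steep limb intersects zero near 550 nm would
transmit essentially nothing below 500 nm, forcing the SWS1-weighted
attenuation to ~1 instead of the observed ~0.85/0.50. The defaults above
were calibrated once, by one-dimensional root-finding against the
package's own estimators, so that the noiseless default pipeline returns
transitions of 550.0 and 488.0 nm, no melanophore transition, and
attenuations of 0.900/0.850/0.500; they ship as the packaged configuration
and are not per-run tuning knobs.

Noise is multiplicative Gaussian on counts (cv = 0.03 by default;
spectrometer counts at bright-lamp levels are gain-scaled rather than
shot-limited), with a Poisson mode available. Each cell gets a lognormal
optical-density multiplier (sigma = 0.1) applied as a power on fractional
transmittance, emulating pigment-density variation across cells while
keeping T in [0, 100]. The per-cell variance of the original measurements
is unreported (only the s.e.m. is known), so sigma = 0.1 is a plausible
default, flagged as such. All randomness derives from a single master
seed through per-cell spawned streams, so any subset of cells is
bit-reproducible on its own.

What the generator does *not* emulate: wavelength-dependent instrument
response drift, dark-current error, focus or stray-light artifacts,
scattering by non-pigment organelles, and between-fish systematic
differences. Passing tests therefore demonstrate that the estimators are
correct and unbiased under the stated noise model at the study's
replication — not that they are robust to every artifact of real scans.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at the study's
own scale (60 cells per type, 1001-point spectra); repeated-seed
properties use 50 independent replicates of the full noisy experiment for
the two stepped pigment types. These sizes run in seconds. Tolerances in
the tests come from closed forms where available (logistic oracle, exact
endpoint identities at 1e-12) and from the printed study-scale values
elsewhere (±5 nm on transitions, ±0.05 on attenuations). Degenerate
inputs are errors, not silent defaults: empty scan sets, non-uniform
grids for slope estimation, non-positive reference counts, extrapolating
resamples, and out-of-range dispersion fractions or anchor wavelengths
all raise with the offending value named.

## Known limitations

* The anchor `lambda_max` and the homolog identity are inputs; no database
  homology search is performed.
* The 13-site tuning table is a reconstruction; users with a preferred
  site list should supply their own YAML.
* Attenuation integrates from 400 nm (instrument cut-on), excluding the
  template's tail below 400 nm; reported attenuations are therefore
  specific to the measured window.
* The feedback model is optical only, single-layer, and static.
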