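# SWS1 spectral tuning sites, bovine rhodopsin numbering.
#
# The 13-site default list below is reconstructed from the site-directed
# mutagenesis literature on vertebrate SWS1 opsins (Yokoyama-style reviews);
# the set is editable configuration, not a fixed constant of the package.
# Sites 86, 90 and 93 carry the large ultraviolet<->violet switches; the
# remainder tune by a few nanometres at most.
#
# `shifts` lists known substitution effects as lambda_max intervals in nm
# (low <= high; negative = blue shift).  Substitutions absent from the list
# are assigned a zero-centred interval of +/- default_shift_halfwidth_nm and
# flagged low-confidence.
sites: [46, 49, 52, 86, 90, 93, 97, 109, 113, 114, 116, 118, 265]
shifts:
  - {site: 97, from: S, to: C, low: -1.0, high: 0.0}
  - {site: 116, from: M, to: V, low: -3.0, high: 0.0}
default_shift_halfwidth_nm: 3.0
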