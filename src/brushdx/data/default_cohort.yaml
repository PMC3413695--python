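# Packaged generator defaults, calibrated to the published 119-patient
# brush-cytology cohort (72 malignant / 47 benign biliary strictures)
# that this simulator emulates.  Field provenance:
#   dct_moments  — reported group means +/- SDs of deltaCt (cycles) per
#                  marker and group
#   spearman     — reported within-group Spearman rank correlations for
#                  HOXB7 / NEK2 / IGF2BP3; FOXM1 and KIF2C correlations
#                  are unreported and default to independence (0)
#   cytology     — reported routine-cytology category counts.  Malignant:
#                  12 positive, 19 suspicious, 22 negative, 19
#                  indeterminate (split 10 atypical / 9 inadequate by
#                  assumption).  Benign: 7 false positives, 40 negative;
#                  the positive/suspicious split of the 7 is unreported
#                  and all are placed in "positive", which reproduces the
#                  identical 40/47 specificity of both cytology read-outs.
#   reference_ct — N(18, 1.5^2) cycles, a typical housekeeping-gene
#                  abundance; NOT a reported value (it cancels in deltaCt)
n_malignant: 72
n_benign: 47
markers: [HOXB7, NEK2, IGF2BP3, FOXM1, KIF2C]
dct_moments:
  malignant:
    HOXB7:   {mean: 8.34,  sd: 3.08}
    NEK2:    {mean: 8.60,  sd: 1.86}
    IGF2BP3: {mean: 9.58,  sd: 2.87}
    FOXM1:   {mean: 9.41,  sd: 1.83}
    KIF2C:   {mean: 10.28, sd: 2.04}
  benign:
    HOXB7:   {mean: 11.13, sd: 2.51}
    NEK2:    {mean: 9.91,  sd: 1.81}
    IGF2BP3: {mean: 13.08, sd: 2.38}
    FOXM1:   {mean: 10.00, sd: 1.23}
    KIF2C:   {mean: 11.13, sd: 1.55}
spearman:
  malignant:
    - [HOXB7, NEK2,    0.259]
    - [HOXB7, IGF2BP3, 0.602]
    - [NEK2,  IGF2BP3, 0.333]
  benign:
    - [HOXB7, NEK2,    0.158]
    - [HOXB7, IGF2BP3, -0.086]
    - [NEK2,  IGF2BP3, 0.273]
cytology_counts:
  malignant: {positive: 12, suspicious: 19, atypical: 10, negative: 22, inadequate: 9}
  benign:    {positive: 7,  suspicious: 0,  atypical: 0,  negative: 40, inadequate: 0}
reference_ct: {mean: 18.0, sd: 1.5}
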