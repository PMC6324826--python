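"""Shared genotype codes and default thresholds."""

# Integer genotype codes used in every in-memory GenotypeMatrix.
# HOM_RECURRENT: homozygous for the recurrent-parent (parent-2) allele.
HET = 1
HOM_RECURRENT = 0
MISSING = -1

GENOTYPE_LABELS = {HET: "het", HOM_RECURRENT: "hom", MISSING: "missing"}
GENOTYPE_CODES = {v: k for k, v in GENOTYPE_LABELS.items()}

# Genotype-calling defaults (configurable everywhere they are used).
DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_MINOR_FRACTION = 0.15
DEFAULT_HOM_MAX_NONRECURRENT_FRACTION = 0.05

# Analysis defaults.
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_CLASS_SIZE = 3
DEFAULT_EXPRESSION_FLOOR_CPM = 1.0
DEFAULT_CV_RATIO_LOW = 0.25
DEFAULT_CV_RATIO_HIGH = 4.0
DEFAULT_PSEUDOCOUNT = 1.0

# Map positions are stored in BED-like files as integer coordinates with
# this many base pairs per Morgan (documented convention for round-trips).
BP_PER_MORGAN = 1_000_000
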