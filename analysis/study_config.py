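"""Shared configuration of the synthetic family-GWAS study.

One place defines the simulated cohort, its planted truths (risk loci,
QC artifacts, differentially expressed genes, directed eQTL genes) and
the file layout, so every numbered driver operates on the same study.
Bulky intermediate data lives under scratch/; small result tables under
results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"

SEED = 20170

# cohort: ascertained nuclear families plus unrelated cases/controls
N_FAMILIES = 300
N_CHILDREN = 2
N_UNREL_CASES = 100
N_UNREL_CONTROLS = 100
N_MARKERS = 2000
LD_BLOCK = 10
BLOCK_R = 0.85

# planted risk loci: (marker index, relative risk, model)
RISK_LOCI = [(400, 1.8, "additive"), (1100, 2.0, "dominant"), (1700, 2.2, "recessive")]

# planted QC artifacts
MISSING_SAMPLE_RATE = 0.04
N_ADMIXED = 2
ADMIX_SHIFT = 0.25
MENDEL_CHILD_ERRORS = 150
HET_OUTLIER_FRACTION = 1 / 400
HET_FACTOR = 3.0

# annotation
N_GENES = 400
GENE_LENGTH = 60_000
N_SETS_PER_SOURCE = 30

# expression study (case/control sizes mirror the polyp tissue series)
N_EXPR_CASES = 20
N_EXPR_CONTROLS = 17
EXPR_NOISE_SD = 0.3
N_DE_GENES = 40
DE_LOG2FC = 1.2

# eQTL catalogues
N_CATALOGUE_GENES = 350
SNPS_PER_GENE = (10, 40)
N_NULL_GENES = 500
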