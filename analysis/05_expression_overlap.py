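"""Differential expression of the polyp-tissue series and target overlap.

Welch t-tests per probe with Benjamini-Hochberg control (FDR < 0.05),
then intersection of the significant genes with the enrichment-stage
target list, reporting each overlapping gene through its most
significant probe with log2 fold change and fold change.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import study_config as cfg
from fampoly.expression import (
    differential_expression,
    overlap_with_targets,
    significant_genes,
)
from fampoly.io_plink import read_expression


def main() -> None:
    expr, groups, probe_map = read_expression(cfg.SCRATCH)
    targets = (cfg.RESULTS / "04_target_genes.txt").read_text().split()
    truths = json.loads((cfg.SCRATCH / "planted_truths.json").read_text())

    de = differential_expression(expr, groups)
    de_genes = significant_genes(de, probe_map, fdr=0.05)
    overlap = overlap_with_targets(de, probe_map, targets, fdr=0.05)

    (cfg.SCRATCH / "de_genes.txt").write_text("\n".join(de_genes) + "\n")
    overlap.to_csv(cfg.RESULTS / "05_target_de_overlap.tsv", sep="\t", index=False)
    (cfg.RESULTS / "05_overlap_genes.txt").write_text(
        "\n".join(overlap["gene"]) + "\n"
    )

    planted = set(truths["de_genes"])
    called = set(de_genes)
    sens = len(called & planted) / len(planted)
    print(f"{len(de_genes)} genes differentially expressed (BH FDR < 0.05)")
    print(f"planted DE genes recovered: {sens:.2f}")
    print(f"{len(overlap)} of {len(targets)} target genes overlap the DE set")


if __name__ == "__main__":
    main()
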