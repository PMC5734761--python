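"""Simulate the synthetic study: cohort, reference panel, annotation,
expression series and eQTL catalogues, with known planted truths.

Writes PLINK text files and TSVs under scratch/study/ and a summary of
the planted truths under results/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd

import study_config as cfg
from fampoly.io_plink import write_dataset, write_ped_map
from fampoly.simulate import (
    ArtifactSpec,
    CohortSpec,
    EqtlCatalogueSpec,
    ExpressionSpec,
    inject_qc_artifacts,
    simulate_cohort,
    simulate_eqtl_catalogue,
    simulate_expression_matrix,
    simulate_gene_annotation,
    simulate_reference_panel,
)


def main() -> None:
    rng = np.random.default_rng(cfg.SEED)
    cfg.SCRATCH.mkdir(parents=True, exist_ok=True)
    cfg.RESULTS.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(
        CohortSpec(
            n_families=cfg.N_FAMILIES,
            n_children=cfg.N_CHILDREN,
            n_unrelated_cases=cfg.N_UNREL_CASES,
            n_unrelated_controls=cfg.N_UNREL_CONTROLS,
            n_markers=cfg.N_MARKERS,
            ld_block_length=cfg.LD_BLOCK,
            within_block_r=cfg.BLOCK_R,
            risk_loci=cfg.RISK_LOCI,
            baseline_prevalence=0.15,
            seed=cfg.SEED,
        )
    )
    # QC artifacts planted on known samples
    iids = cohort.samples["iid"]
    artifact_spec = ArtifactSpec(
        missing_rates={iids.iloc[10]: cfg.MISSING_SAMPLE_RATE},
        het_outlier_fraction=cfg.HET_OUTLIER_FRACTION,
        het_factor=cfg.HET_FACTOR,
        mendel_error_counts={"F00005_C1": cfg.MENDEL_CHILD_ERRORS},
        admixed_samples=["UU00003", "UU00042"],  # singletons reach the PCA stage
        admix_shift=cfg.ADMIX_SHIFT,
        admix_direction_seed=cfg.SEED + 9,
        seed=cfg.SEED + 1,
    )
    dirty, artifact_log = inject_qc_artifacts(cohort, artifact_spec)

    # reference panel: a matching subgroup plus a divergent population on
    # the same allele-shift axis as the planted admixed samples
    reference = simulate_reference_panel(
        cohort, n_samples=120, seed=cfg.SEED + 2,
        n_divergent=40, divergence_shift=0.5, direction_seed=cfg.SEED + 9,
    )

    genes, raw_sets = simulate_gene_annotation(
        cohort.markers,
        n_genes=cfg.N_GENES,
        gene_length=cfg.GENE_LENGTH,
        n_sets=2 * cfg.N_SETS_PER_SOURCE,
        seed=cfg.SEED + 3,
    )
    # two collections, mimicking GO- and KEGG-style sources; two sets are
    # replaced by "pathways" of genes near the planted risk loci so the
    # enrichment stage has a recoverable truth
    near_risk: list[str] = []
    for locus, _, _ in cfg.RISK_LOCI:
        chrom = int(cohort.markers["chrom"].iloc[locus])
        pos = int(cohort.markers["pos"].iloc[locus])
        near_risk += genes[
            (genes["chrom"] == chrom)
            & (genes["start"] < pos + 400_000)
            & (genes["end"] > pos - 400_000)
        ]["gene"].tolist()
    near_risk = list(dict.fromkeys(near_risk))
    decoys = [g for g in genes["gene"] if g not in near_risk]
    planted_sets = {
        "GO_RISK": near_risk + decoys[:3],
        "KEGG_RISK": near_risk + decoys[3:6],
    }
    names = list(raw_sets)
    go_sets = {f"GO_{k}": v for k, v in list(raw_sets.items())[: cfg.N_SETS_PER_SOURCE]}
    kegg_sets = {
        f"KEGG_{k}": v for k, v in list(raw_sets.items())[cfg.N_SETS_PER_SOURCE :]
    }
    go_sets["GO_RISK"] = planted_sets["GO_RISK"]
    kegg_sets["KEGG_RISK"] = planted_sets["KEGG_RISK"]

    # expression: probes map 1:1 onto annotation genes; DE planted for a
    # subset that includes the risk-pathway genes
    de_candidates = list(
        dict.fromkeys(planted_sets["GO_RISK"] + planted_sets["KEGG_RISK"])
    )
    other = [g for g in genes["gene"] if g not in de_candidates]
    de_genes = de_candidates + other[: max(0, cfg.N_DE_GENES - len(de_candidates))]
    gene_order = genes["gene"].tolist()
    de_probes = [
        (gene_order.index(g), cfg.DE_LOG2FC * (1 if i % 2 else -1))
        for i, g in enumerate(de_genes)
    ]
    expression = simulate_expression_matrix(
        ExpressionSpec(
            n_case_samples=cfg.N_EXPR_CASES,
            n_control_samples=cfg.N_EXPR_CONTROLS,
            n_probes=len(gene_order),
            de_probes=de_probes,
            noise_sd=cfg.EXPR_NOISE_SD,
            probe_to_gene=gene_order,
            seed=cfg.SEED + 4,
        )
    )

    # eQTL catalogues over the cohort's markers; the DE risk genes carry a
    # planted directed signal (their down-regulating alleles ride the
    # case-enriched alleles at the risk loci's LD blocks)
    planted_eqtl = {g: "down_in_cases" for g in de_candidates[:3]}
    blood = simulate_eqtl_catalogue(
        EqtlCatalogueSpec(
            n_genes=cfg.N_CATALOGUE_GENES,
            snps_per_gene=cfg.SNPS_PER_GENE,
            significant_fraction=0.8,
            tissues=("blood",),
            seed=cfg.SEED + 5,
        ),
        cohort.markers,
        cohort=dirty,
        planted=planted_eqtl,
    )
    muther = simulate_eqtl_catalogue(
        EqtlCatalogueSpec(
            n_genes=cfg.N_CATALOGUE_GENES,
            snps_per_gene=cfg.SNPS_PER_GENE,
            significant_fraction=0.8,
            tissues=("LCL", "skin"),
            seed=cfg.SEED + 6,
        ),
        cohort.markers,
        cohort=dirty,
        planted=planted_eqtl,
    )

    write_dataset(
        cfg.SCRATCH,
        cohort=dirty,
        catalogue=blood,
        expression=expression,
        genes=genes,
        gene_sets={**go_sets, **kegg_sets},
    )
    muther.to_csv(cfg.SCRATCH / "eqtl_muther.tsv", sep="\t", index=False)
    write_ped_map(reference, cfg.SCRATCH / "reference")
    from fampoly.io_plink import write_gmt

    write_gmt(go_sets, cfg.SCRATCH / "sets_go.gmt")
    write_gmt(kegg_sets, cfg.SCRATCH / "sets_kegg.gmt")

    truths = {
        "risk_loci": [
            {"snp": cohort.markers["snp"].iloc[i], "rr": rr, "model": m}
            for i, rr, m in cfg.RISK_LOCI
        ],
        "artifacts": artifact_log,
        "de_genes": sorted(de_genes),
        "planted_eqtl_genes": sorted(planted_eqtl),
        "risk_pathways": {k: sorted(v) for k, v in planted_sets.items()},
    }
    (cfg.SCRATCH / "planted_truths.json").write_text(json.dumps(truths, indent=2))
    summary = pd.DataFrame(
        {
            "quantity": [
                "samples", "markers", "families", "affected", "de_genes",
                "catalogue_genes",
            ],
            "value": [
                dirty.n_samples, dirty.n_markers, cfg.N_FAMILIES,
                int(dirty.affected.sum()), len(de_genes), cfg.N_CATALOGUE_GENES,
            ],
        }
    )
    summary.to_csv(cfg.RESULTS / "01_study_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"study written to {cfg.SCRATCH}")


if __name__ == "__main__":
    main()
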