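"""Quality control of the simulated cohort.

Applies the sample filters (missingness > 2%, heterozygosity beyond 3 SD,
> 100 Mendelian errors), the marker filters (missingness > 2%, > 3
Mendelian errors, monomorphic), LD pruning (r^2 < 0.2) and the PCA
ancestry-outlier removal (E > 5 SD_E against the reference panel), then
checks the recovered failures against the planted artifact log.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

import study_config as cfg
from fampoly.io_plink import read_ped_map, write_ped_map
from fampoly.qc import run_qc


def main() -> None:
    cohort = read_ped_map(cfg.SCRATCH / "cohort")
    reference = read_ped_map(cfg.SCRATCH / "reference")
    truths = json.loads((cfg.SCRATCH / "planted_truths.json").read_text())

    main_group = reference.samples.loc[
        reference.samples["fid"] == "REF_MAIN", "iid"
    ].tolist()
    filtered, reports = run_qc(cohort, reference, reference_group=main_group)
    write_ped_map(filtered, cfg.SCRATCH / "filtered")

    sample_report = reports["samples"]
    removed = sample_report.index[~sample_report["retained"]].tolist()
    anc = reports.get("ancestry")
    removed_anc = anc.index[anc["ancestry_fail"]].tolist() if anc is not None else []

    planted_bad = (
        list(truths["artifacts"]["missing"])
        + truths["artifacts"]["het_outliers"]
        + list(truths["artifacts"]["mendel"])
    )
    print(f"samples removed by filters : {removed}")
    print(f"samples removed by ancestry: {removed_anc}")
    print(f"planted artifact samples   : {sorted(planted_bad)}")
    print(f"planted admixed samples    : {sorted(truths['artifacts']['admixed'])}")
    print(
        f"retained {filtered.n_samples}/{cohort.n_samples} samples, "
        f"{filtered.n_markers}/{cohort.n_markers} markers"
    )

    summary = pd.DataFrame(
        {
            "stage": ["input", "after_qc"],
            "samples": [cohort.n_samples, filtered.n_samples],
            "markers": [cohort.n_markers, filtered.n_markers],
        }
    )
    summary.to_csv(cfg.RESULTS / "02_qc_summary.tsv", sep="\t", index=False)
    sample_report[~sample_report["retained"]].to_csv(
        cfg.RESULTS / "02_qc_failed_samples.tsv", sep="\t"
    )


if __name__ == "__main__":
    main()
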