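"""Sample and marker quality control, LD pruning and ancestry outliers.

Filter order follows the study design: sample filters first (missingness,
heterozygosity, Mendelian errors), then marker filters (missingness,
Mendelian errors, monomorphic loci), then LD pruning and PCA-based
ancestry-outlier removal against a reference panel.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from fampoly.cohort import MISSING, PedigreeCohort

# thresholds of the study protocol
SAMPLE_MISS_MAX = 0.02
HET_K_SD = 3.0
SAMPLE_MENDEL_MAX = 100
MARKER_MISS_MAX = 0.02
MARKER_MENDEL_MAX = 3
LD_R2_MAX = 0.2
ANCESTRY_K_SD = 5.0


# ---------------------------------------------------------------------------
# sample-level statistics
# ---------------------------------------------------------------------------


def sample_missingness(cohort: PedigreeCohort) -> pd.Series:
    """Per-sample missing-call fraction (missing calls / total markers)."""
    if cohort.n_markers == 0:
        raise ValueError("cannot compute missingness with zero markers")
    frac = (cohort.genotypes == MISSING).mean(axis=1)
    return pd.Series(frac, index=cohort.samples["iid"].to_numpy(), name="miss_frac")


def heterozygosity_rates(cohort: PedigreeCohort) -> pd.Series:
    """Heterozygous calls / non-missing calls, per sample."""
    g = cohort.genotypes
    called = (g != MISSING).sum(axis=1)
    het = (g == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        rate = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return pd.Series(rate, index=cohort.samples["iid"].to_numpy(), name="het_rate")


def heterozygosity_filter(
    cohort: PedigreeCohort, k_sd: float = HET_K_SD
) -> tuple[list[str], pd.DataFrame]:
    """Remove samples whose het rate is more than ``k_sd`` SDs from the mean.

    Single pass: mean and SD are computed once over all samples.  If the
    SD is zero (all rates identical) every sample is retained.
    """
    rate = heterozygosity_rates(cohort)
    if rate.notna().sum() < 2:
        raise ValueError("heterozygosity filter needs >= 2 callable samples")
    mu, sd = rate.mean(), rate.std(ddof=0)
    if sd == 0 or np.isnan(sd):
        warnings.warn("zero heterozygosity variance; retaining all samples")
        z = pd.Series(0.0, index=rate.index)
    else:
        z = (rate - mu) / sd
    report = pd.DataFrame({"het_rate": rate, "het_z": z})
    report["het_fail"] = z.abs() > k_sd
    retained = report.index[~report["het_fail"]].tolist()
    return retained, report


# ---------------------------------------------------------------------------
# Mendelian errors
# ---------------------------------------------------------------------------

def _trio_error_table() -> np.ndarray:
    """err[p1, p2, c] for dosages 0..2: 1 if child impossible for parents."""
    err = np.zeros((3, 3, 3), dtype=np.int8)
    for p1 in range(3):
        for p2 in range(3):
            t1 = {0, 1} if p1 == 1 else {p1 // 2}
            t2 = {0, 1} if p2 == 1 else {p2 // 2}
            possible = {a + b for a in t1 for b in t2}
            for c in range(3):
                err[p1, p2, c] = int(c not in possible)
    return err


_TRIO_ERR = _trio_error_table()
# duo rule: child must carry >= 1 allele transmissible from the parent
_DUO_ERR = np.zeros((3, 3), dtype=np.int8)
_DUO_ERR[0, 2] = 1  # parent hom a2, child hom a1
_DUO_ERR[2, 0] = 1  # parent hom a1, child hom a2


def mendel_errors(
    cohort: PedigreeCohort,
) -> tuple[pd.Series, pd.Series]:
    """Per-sample and per-marker Mendelian-inconsistency counts.

    Trio rules apply when both parents are genotyped at a marker, duo
    rules when exactly one is.  Each error increments the child, every
    genotyped parent of that child, and the marker (once per erroneous
    child call).
    """
    idx = cohort.sample_index()
    iids = cohort.samples["iid"].to_numpy()
    fathers = cohort.samples["father"].to_numpy()
    mothers = cohort.samples["mother"].to_numpy()
    # resolve parent row indices; parents absent from the table count as
    # ungenotyped everywhere
    known = set(idx.index)
    g = cohort.genotypes
    per_sample = np.zeros(cohort.n_samples, dtype=np.int64)
    per_marker = np.zeros(cohort.n_markers, dtype=np.int64)

    _check_acyclic(iids, fathers, mothers)

    for s in range(cohort.n_samples):
        fi = int(idx[fathers[s]]) if fathers[s] in known else -1
        mi = int(idx[mothers[s]]) if mothers[s] in known else -1
        if fi < 0 and mi < 0:
            continue
        c = g[s]
        cm = c != MISSING
        f_ok = (g[fi] != MISSING) & cm if fi >= 0 else np.zeros_like(cm)
        m_ok = (g[mi] != MISSING) & cm if mi >= 0 else np.zeros_like(cm)
        both = f_ok & m_ok
        err = np.zeros(cohort.n_markers, dtype=np.int8)
        if both.any():
            err[both] = _TRIO_ERR[g[fi][both], g[mi][both], c[both]]
        only_f = f_ok & ~both
        if only_f.any():
            err[only_f] = _DUO_ERR[g[fi][only_f], c[only_f]]
        only_m = m_ok & ~both
        if only_m.any():
            err[only_m] = _DUO_ERR[g[mi][only_m], c[only_m]]
        n_err = err.sum()
        if n_err:
            per_marker += err
            per_sample[s] += n_err
            if fi >= 0:
                per_sample[fi] += int(err[f_ok].sum())
            if mi >= 0:
                per_sample[mi] += int(err[m_ok].sum())
    return (
        pd.Series(per_sample, index=iids, name="mendel_errors"),
        pd.Series(
            per_marker, index=cohort.markers["snp"].to_numpy(), name="mendel_errors"
        ),
    )


def _check_acyclic(iids, fathers, mothers) -> None:
    parent_of = {i: (f, m) for i, f, m in zip(iids, fathers, mothers)}
    for start in iids:
        seen = set()
        stack = [start]
        while stack:
            cur = stack.pop()
            if cur in seen:
                raise ValueError(f"circular pedigree involving {cur}")
            seen.add(cur)
            f, m = parent_of.get(cur, ("0", "0"))
            stack.extend(p for p in (f, m) if p != "0" and p in parent_of)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def sample_filters(
    cohort: PedigreeCohort,
    miss_max: float = SAMPLE_MISS_MAX,
    het_k_sd: float = HET_K_SD,
    mendel_max: int = SAMPLE_MENDEL_MAX,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the three sample filters; returns retained IIDs and a report."""
    miss = sample_missingness(cohort)
    _, het_report = heterozygosity_filter(cohort, het_k_sd)
    mend, _ = mendel_errors(cohort)
    report = pd.DataFrame(
        {
            "miss_frac": miss,
            "het_rate": het_report["het_rate"],
            "het_z": het_report["het_z"],
            "mendel_errors": mend,
        }
    )
    report["miss_fail"] = report["miss_frac"] > miss_max
    report["het_fail"] = het_report["het_fail"]
    report["mendel_fail"] = report["mendel_errors"] > mendel_max
    report["retained"] = ~(
        report["miss_fail"] | report["het_fail"] | report["mendel_fail"]
    )
    return report.index[report["retained"]].tolist(), report


def marker_filters(
    cohort: PedigreeCohort,
    miss_max: float = MARKER_MISS_MAX,
    mendel_max: int = MARKER_MENDEL_MAX,
) -> tuple[list[str], pd.DataFrame]:
    """Marker filters: missingness > ``miss_max``, Mendelian errors >
    ``mendel_max``, or monomorphic (MAF computed on non-missing calls = 0).
    All inequalities are strict, matching the protocol's wording."""
    g = cohort.genotypes
    miss = (g == MISSING).mean(axis=0)
    _, mend = mendel_errors(cohort)
    maf = cohort.minor_allele_frequency()
    report = pd.DataFrame(
        {
            "miss_frac": miss,
            "mendel_errors": mend.to_numpy(),
            "maf": maf,
        },
        index=cohort.markers["snp"].to_numpy(),
    )
    report["miss_fail"] = report["miss_frac"] > miss_max
    report["mendel_fail"] = report["mendel_errors"] > mendel_max
    report["mono_fail"] = ~(report["maf"] > 0)  # MAF 0 or all-missing
    report["retained"] = ~(
        report["miss_fail"] | report["mendel_fail"] | report["mono_fail"]
    )
    return report.index[report["retained"]].tolist(), report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _imputed_dosage(g: np.ndarray) -> np.ndarray:
    """Float dosage matrix with per-marker mean imputation of missing."""
    x = g.astype(float)
    x[g == MISSING] = np.nan
    means = np.nanmean(x, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    rr, cc = np.nonzero(np.isnan(x))
    x[rr, cc] = means[cc]
    return x


def pairwise_r2(g: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of mean-imputed dosage columns."""
    x = _imputed_dosage(g)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.nan
    c = (x.T @ x) / len(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = c / np.outer(sd, sd)
    r2 = r**2
    np.fill_diagonal(r2, 1.0)
    return np.nan_to_num(r2, nan=0.0)


def ld_prune(
    cohort: PedigreeCohort,
    r2_max: float = LD_R2_MAX,
    window: int = 50,
    step: int = 5,
) -> list[str]:
    """Greedy windowed LD pruning on genotype-dosage correlation.

    Within each window of the currently retained markers, any pair with
    r^2 >= ``r2_max`` loses its lower-MAF member (tie: drop the later
    position) until no violating pair remains; the window then slides by
    ``step`` retained markers.  Passes repeat until no marker is dropped,
    so on output no within-window pair of retained markers violates the
    threshold.  Markers must be ordered by (chromosome, position).
    """
    order = np.lexsort(
        (cohort.markers["pos"].to_numpy(), cohort.markers["chrom"].to_numpy())
    )
    maf = cohort.minor_allele_frequency()
    keep = np.ones(cohort.n_markers, dtype=bool)
    chroms = cohort.markers["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        chrom_order = order[chroms[order] == chrom]
        changed = True
        while changed:
            changed = False
            current = chrom_order[keep[chrom_order]]
            for start in range(0, len(current), step):
                win = current[start : start + window]
                win = win[keep[win]]
                if len(win) < 2:
                    continue
                r2 = pairwise_r2(cohort.genotypes[:, win])
                active = np.ones(len(win), dtype=bool)
                while True:
                    sub = np.where(active)[0]
                    viol = None
                    for ii in range(len(sub)):
                        for jj in range(ii + 1, len(sub)):
                            if r2[sub[ii], sub[jj]] >= r2_max:
                                viol = (sub[ii], sub[jj])
                                break
                        if viol:
                            break
                    if viol is None:
                        break
                    a, b = viol
                    ma, mb = maf[win[a]], maf[win[b]]
                    # drop lower MAF; tie -> later position (b is later)
                    drop = b if (mb < ma or mb == ma) else a
                    active[drop] = False
                if (~active).any():
                    keep[win[~active]] = False
                    changed = True
    snp = cohort.markers["snp"].to_numpy()
    return [snp[j] for j in order if keep[j]]


# ---------------------------------------------------------------------------
# GRM / PCA ancestry
# ---------------------------------------------------------------------------


def standardized_dosages(g: np.ndarray, freq: np.ndarray | None = None) -> np.ndarray:
    """(g - 2f) / sqrt(2f(1-f)) with mean imputation; monomorphic columns
    are dropped (returned matrix may have fewer columns)."""
    x = _imputed_dosage(g)
    if freq is None:
        freq = x.mean(axis=0) / 2.0
    keep = (freq > 0) & (freq < 1)
    x = x[:, keep]
    f = freq[keep]
    return (x - 2 * f) / np.sqrt(2 * f * (1 - f))


def grm(g: np.ndarray, freq: np.ndarray | None = None) -> np.ndarray:
    """Genomic relationship matrix Z Z^T / m from standardized dosages."""
    z = standardized_dosages(g, freq)
    if z.shape[1] == 0:
        raise ValueError("no polymorphic markers for GRM")
    return (z @ z.T) / z.shape[1]


def pca_scores(g: np.ndarray, n_components: int = 3) -> np.ndarray:
    """Sample scores on the first principal components of the GRM."""
    k = grm(g)
    vals, vecs = np.linalg.eigh(k)
    order = np.argsort(vals)[::-1][:n_components]
    return vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))


def ancestry_outlier_filter(
    cohort: PedigreeCohort,
    reference: PedigreeCohort,
    k_sd: float = ANCESTRY_K_SD,
    n_components: int = 3,
    reference_group: list[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Remove study samples far from the reference centroid in PC space.

    Joint PCA of pooled, standardized study + reference dosages on the
    markers shared by SNP id; E is the Euclidean distance of each study
    sample's score vector to the mean score of the designated reference
    subgroup (``reference_group`` IIDs; default: all reference samples);
    a study sample is removed iff E > ``k_sd`` times the SD of E over
    study samples (single pass).
    """
    shared = [
        s
        for s in cohort.markers["snp"]
        if s in set(reference.markers["snp"])
    ]
    if not shared:
        raise ValueError("no shared markers between study and reference cohorts")
    study = cohort.subset(marker_ids=shared)
    ref = reference.subset(marker_ids=shared)
    # orient the reference's allele-1 dosages to the study's labels
    # (text formats do not pin which allele is allele 1)
    from fampoly.io_plink import align_alleles

    ref = align_alleles(ref, study.markers)
    pooled = np.vstack([study.genotypes, ref.genotypes])
    scores = pca_scores(pooled, n_components)
    n_study = study.n_samples
    if reference_group is None:
        group_mask = np.ones(ref.n_samples, dtype=bool)
    else:
        group_mask = ref.samples["iid"].isin(set(reference_group)).to_numpy()
        if not group_mask.any():
            raise ValueError("reference_group matches no reference samples")
    centroid = scores[n_study:][group_mask].mean(axis=0)
    e = np.linalg.norm(scores[:n_study] - centroid, axis=1)
    sd_e = e.std(ddof=0)
    fail = e > k_sd * sd_e if sd_e > 0 else np.zeros(n_study, dtype=bool)
    report = pd.DataFrame(
        {"E": e, "ancestry_fail": fail},
        index=cohort.samples["iid"].to_numpy(),
    )
    return report.index[~fail].tolist(), report


# ---------------------------------------------------------------------------
# pipeline convenience
# ---------------------------------------------------------------------------


def run_qc(
    cohort: PedigreeCohort,
    reference: PedigreeCohort | None = None,
    reference_group: list[str] | None = None,
) -> tuple[PedigreeCohort, dict[str, pd.DataFrame]]:
    """Full QC chain: sample filters, marker filters, then (optionally)
    LD pruning + ancestry outliers.  Returns the filtered cohort and the
    per-stage reports."""
    retained_samples, sample_report = sample_filters(cohort)
    stage1 = cohort.subset(sample_ids=retained_samples)
    retained_markers, marker_report = marker_filters(stage1)
    stage2 = stage1.subset(marker_ids=retained_markers)
    reports = {"samples": sample_report, "markers": marker_report}
    if reference is not None:
        pruned = ld_prune(stage2)
        pruned_cohort = stage2.subset(marker_ids=pruned)
        retained, anc_report = ancestry_outlier_filter(
            pruned_cohort, reference, reference_group=reference_group
        )
        stage2 = stage2.subset(sample_ids=retained)
        reports["ancestry"] = anc_report
        reports["pruned_markers"] = pd.DataFrame({"snp": pruned})
    return stage2, reports
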