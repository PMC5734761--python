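"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure of the study's inputs:
nuclear families with fair Mendelian transmission and planted risk loci,
LD-blocked markers, per-gene eQTL SNP catalogues with signed effects,
and probe-level expression with planted log2 fold changes.  They are the
only source of data for the test suite and the analysis drivers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fampoly.cohort import MISSING, PedigreeCohort


class ConfigurationError(ValueError):
    """Raised when a simulation spec contains an invalid field."""


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: Inheritance codings used by the multiplicative disease model.  The coding
#: maps allele-1 dosage (allele 1 is the risk allele) to a risk exponent.
_RISK_CODING = {
    "additive": np.array([0, 1, 2]),
    "dominant": np.array([0, 1, 1]),
    "recessive": np.array([0, 0, 1]),
}


@dataclass
class CohortSpec:
    """Configuration of a simulated pedigreed case/control cohort.

    Families are nuclear: two genotyped parents and ``n_children``
    children.  Unrelated cases and controls are ascertained singletons.
    Markers come in LD blocks generated by first-order haplotype copying:
    within a block each allele copies the previous marker's allele with
    probability ``within_block_r``, else it is a fresh draw at the block's
    allele frequency, giving tunable pairwise r^2.
    """

    n_families: int = 100
    n_children: int = 2
    n_unrelated_cases: int = 0
    n_unrelated_controls: int = 0
    n_markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_length: int = 1
    within_block_r: float = 0.0
    risk_loci: list[tuple[int, float, str]] = field(default_factory=list)
    baseline_prevalence: float = 0.3
    ascertain_affected_child: bool = True
    chrom_count: int = 22
    marker_spacing_bp: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 0:
            raise ConfigurationError("n_families must be >= 0")
        if self.n_children < 0:
            raise ConfigurationError("n_children must be >= 0")
        if self.n_unrelated_cases < 0 or self.n_unrelated_controls < 0:
            raise ConfigurationError("unrelated sample counts must be >= 0")
        if self.n_markers <= 0:
            raise ConfigurationError("n_markers must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.ld_block_length < 1:
            raise ConfigurationError("ld_block_length must be >= 1")
        if not (0.0 <= self.within_block_r <= 1.0):
            raise ConfigurationError("within_block_r must be in [0, 1]")
        if not (0.0 < self.baseline_prevalence < 1.0):
            raise ConfigurationError("baseline_prevalence must be in (0, 1)")
        for idx, rr, model in self.risk_loci:
            if not (0 <= idx < self.n_markers):
                raise ConfigurationError(f"risk locus index {idx} >= n_markers")
            if rr <= 0:
                raise ConfigurationError("relative risk must be > 0")
            if model not in _RISK_CODING:
                raise ConfigurationError(f"unknown inheritance model {model!r}")


def _marker_table(spec: CohortSpec, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Marker metadata plus the per-marker allele-1 frequency.

    One frequency is drawn per LD block (uniform on ``maf_range``) so the
    copying process is stationary within the block.  Allele 1 is the minor
    allele; allele labels are biallelic SNP letters.
    """
    m = spec.n_markers
    n_blocks = -(-m // spec.ld_block_length)
    block_f = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=n_blocks)
    block_of = np.arange(m) // spec.ld_block_length
    freqs = block_f[block_of]

    chroms = 1 + (np.arange(m) * spec.chrom_count) // m
    # positions restart at each chromosome; irregular spacing as on a real
    # array (uniform jitter around the nominal spacing)
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, spec.chrom_count + 1):
        sel = chroms == c
        gaps = rng.uniform(0.2, 1.8, size=sel.sum()) * spec.marker_spacing_bp
        pos[sel] = np.cumsum(gaps).astype(np.int64) + 1
    pairs = np.array([["A", "G"], ["C", "T"], ["A", "C"], ["G", "T"]])
    which = rng.integers(0, len(pairs), size=m)
    markers = pd.DataFrame(
        {
            "snp": [f"snp{i:06d}" for i in range(m)],
            "chrom": chroms,
            "pos": pos,
            "a1": pairs[which, 0],
            "a2": pairs[which, 1],
        }
    )
    return markers, freqs


def _sample_haplotypes(
    rng: np.random.Generator, n_hap: int, freqs: np.ndarray, block_of: np.ndarray, r: float
) -> np.ndarray:
    """First-order copying haplotypes: (n_hap, n_markers) uint8 of allele-1."""
    m = len(freqs)
    h = np.empty((n_hap, m), dtype=np.uint8)
    fresh = rng.random((n_hap, m)) < freqs  # stationary draw at each marker
    copy = rng.random((n_hap, m)) < r
    h[:, 0] = fresh[:, 0]
    for j in range(1, m):
        if block_of[j] == block_of[j - 1]:
            h[:, j] = np.where(copy[:, j], h[:, j - 1], fresh[:, j])
        else:
            h[:, j] = fresh[:, j]
    return h


def _penetrance(dosage: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """Multiplicative relative-risk penetrance, capped at 1."""
    pen = np.full(dosage.shape[0], spec.baseline_prevalence)
    for idx, rr, model in spec.risk_loci:
        x = _RISK_CODING[model][dosage[:, idx]]
        pen = pen * rr ** x
    return np.minimum(pen, 1.0)


def _transmit(
    rng: np.random.Generator, hap_a: np.ndarray, hap_b: np.ndarray
) -> np.ndarray:
    """Fair Mendelian transmission: per marker pick one parental allele."""
    pick = rng.random(hap_a.shape) < 0.5
    return np.where(pick, hap_a, hap_b).astype(np.uint8)


def simulate_cohort(spec: CohortSpec) -> PedigreeCohort:
    """Simulate a pedigreed cohort per the spec's generative model.

    Founder haplotypes are drawn at Hardy-Weinberg from block-correlated
    haplotypes; children inherit one allele per parent by fair Mendelian
    transmission; affection status is drawn from a multiplicative-risk
    model on the risk loci.  With ``ascertain_affected_child`` families
    are rejection-sampled until at least one child is affected, emulating
    recruitment through an affected index patient.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    markers, freqs = _marker_table(spec, rng)
    block_of = np.arange(spec.n_markers) // spec.ld_block_length
    m = spec.n_markers

    rows: list[tuple] = []
    genos: list[np.ndarray] = []

    # --- families (batched rejection sampling on the ascertainment rule) ---
    kept = 0
    guard = 0
    while kept < spec.n_families:
        guard += 1
        if guard > 10_000:
            raise ConfigurationError(
                "ascertainment rejection sampling failed to produce families; "
                "baseline_prevalence too small for the requested design"
            )
        batch = max(spec.n_families - kept, 8)
        fh = _sample_haplotypes(rng, 2 * batch, freqs, block_of, spec.within_block_r)
        mh = _sample_haplotypes(rng, 2 * batch, freqs, block_of, spec.within_block_r)
        fat = (fh[0::2] + fh[1::2]).astype(np.int8)  # (batch, m)
        mot = (mh[0::2] + mh[1::2]).astype(np.int8)
        kids = []
        for _ in range(spec.n_children):
            from_f = _transmit(rng, fh[0::2], fh[1::2])
            from_m = _transmit(rng, mh[0::2], mh[1::2])
            kids.append((from_f + from_m).astype(np.int8))
        fat_aff = rng.random(batch) < _penetrance(fat, spec)
        mot_aff = rng.random(batch) < _penetrance(mot, spec)
        kid_aff = [rng.random(batch) < _penetrance(k, spec) for k in kids]
        if spec.ascertain_affected_child and spec.n_children > 0:
            ok = np.any(np.array(kid_aff), axis=0)
        else:
            ok = np.ones(batch, dtype=bool)
        for b in np.nonzero(ok)[0]:
            if kept >= spec.n_families:
                break
            fid = f"F{kept:05d}"
            pa, ma = f"{fid}_P1", f"{fid}_P2"
            rows.append((fid, pa, "0", "0", 1, 2 if fat_aff[b] else 1))
            genos.append(fat[b])
            rows.append((fid, ma, "0", "0", 2, 2 if mot_aff[b] else 1))
            genos.append(mot[b])
            for c in range(spec.n_children):
                sex = int(rng.integers(1, 3))
                rows.append(
                    (fid, f"{fid}_C{c + 1}", pa, ma, sex, 2 if kid_aff[c][b] else 1)
                )
                genos.append(kids[c][b])
            kept += 1

    # --- unrelated singletons, ascertained case/control ---
    need_cases, need_controls = spec.n_unrelated_cases, spec.n_unrelated_controls
    n_case = n_ctrl = 0
    guard = 0
    while n_case < need_cases or n_ctrl < need_controls:
        guard += 1
        if guard > 10_000:
            raise ConfigurationError(
                "case/control ascertainment failed; prevalence too extreme"
            )
        batch = max(64, 2 * (need_cases - n_case) + (need_controls - n_ctrl))
        h = _sample_haplotypes(rng, 2 * batch, freqs, block_of, spec.within_block_r)
        g = (h[0::2] + h[1::2]).astype(np.int8)
        aff = rng.random(batch) < _penetrance(g, spec)
        for b in range(batch):
            if aff[b] and n_case < need_cases:
                iid = f"UC{n_case:05d}"
                rows.append((iid, iid, "0", "0", int(rng.integers(1, 3)), 2))
                genos.append(g[b])
                n_case += 1
            elif not aff[b] and n_ctrl < need_controls:
                iid = f"UU{n_ctrl:05d}"
                rows.append((iid, iid, "0", "0", int(rng.integers(1, 3)), 1))
                genos.append(g[b])
                n_ctrl += 1

    samples = pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
    )
    genotypes = (
        np.vstack(genos) if genos else np.empty((0, m), dtype=np.int8)
    )
    return PedigreeCohort(
        samples=samples,
        markers=markers,
        genotypes=genotypes,
        meta={"spec": dataclasses.asdict(spec), "allele1_freq": freqs},
    )


def simulate_case_control_shift(
    n_cases: int,
    n_controls: int,
    n_markers: int,
    maf: float = 0.3,
    shifted: dict[int, float] | None = None,
    seed: int = 0,
) -> PedigreeCohort:
    """Unrelated case/control cohort with direct allele-frequency shifts.

    ``shifted`` maps marker index -> additive shift of the allele-1
    frequency in cases (frequency is clipped to [0.01, 0.99]).  Used to
    construct directed-eQTL scenarios where the case/control frequency
    difference, not a penetrance model, is the quantity of interest.
    """
    rng = np.random.default_rng(seed)
    shifted = shifted or {}
    f_ctrl = np.full(n_markers, maf)
    f_case = f_ctrl.copy()
    for idx, d in shifted.items():
        f_case[idx] = np.clip(f_case[idx] + d, 0.01, 0.99)
    g_case = rng.binomial(2, f_case, size=(n_cases, n_markers)).astype(np.int8)
    g_ctrl = rng.binomial(2, f_ctrl, size=(n_controls, n_markers)).astype(np.int8)
    rows = [(f"UC{i:05d}", f"UC{i:05d}", "0", "0", 1, 2) for i in range(n_cases)]
    rows += [(f"UU{i:05d}", f"UU{i:05d}", "0", "0", 2, 1) for i in range(n_controls)]
    samples = pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
    )
    markers = pd.DataFrame(
        {
            "snp": [f"snp{i:06d}" for i in range(n_markers)],
            "chrom": np.ones(n_markers, dtype=int),
            "pos": (np.arange(n_markers) + 1) * 10_000,
            "a1": "A",
            "a2": "G",
        }
    )
    return PedigreeCohort(
        samples=samples,
        markers=markers,
        genotypes=np.vstack([g_case, g_ctrl]),
    )


def allele_shift_direction(n_markers: int, seed: int) -> np.ndarray:
    """Deterministic per-marker +/-1 shift directions, shared between a
    divergent reference subpopulation and admixed study samples so that
    both sit on the same ancestry axis."""
    return np.where(
        np.random.default_rng(seed).random(n_markers) < 0.5, 1.0, -1.0
    )


def simulate_reference_panel(
    cohort: PedigreeCohort,
    n_samples: int = 120,
    seed: int = 0,
    n_divergent: int = 0,
    divergence_shift: float = 0.3,
    direction_seed: int | None = None,
) -> PedigreeCohort:
    """Unrelated reference panel for ancestry PCA.

    The first ``n_samples - n_divergent`` samples (family id ``REF_MAIN``)
    are drawn from the cohort's own allele frequencies and LD model — the
    analog of the matching continental reference subgroup.  The remaining
    ``n_divergent`` samples (``REF_OTHER``) come from a population whose
    frequencies are shifted by ``divergence_shift`` along the directions
    of :func:`allele_shift_direction`, giving the joint PCA a real
    ancestry axis.  Requires a cohort produced by :func:`simulate_cohort`
    (its generating frequencies are carried in ``meta``).
    """
    if "allele1_freq" not in cohort.meta:
        raise ConfigurationError(
            "reference panel requires a simulated cohort with stored frequencies"
        )
    if n_divergent > n_samples:
        raise ConfigurationError("n_divergent exceeds n_samples")
    rng = np.random.default_rng(seed)
    freqs = np.asarray(cohort.meta["allele1_freq"])
    spec = cohort.meta.get("spec", {})
    block_len = int(spec.get("ld_block_length", 1))
    r = float(spec.get("within_block_r", 0.0))
    block_of = np.arange(len(freqs)) // block_len
    n_main = n_samples - n_divergent
    h = _sample_haplotypes(rng, 2 * n_main, freqs, block_of, r)
    g_main = (h[0::2] + h[1::2]).astype(np.int8)
    parts = [g_main]
    if n_divergent:
        direction = allele_shift_direction(
            len(freqs), seed if direction_seed is None else direction_seed
        )
        f_other = np.clip(freqs + divergence_shift * direction, 0.01, 0.99)
        h2 = _sample_haplotypes(rng, 2 * n_divergent, f_other, block_of, r)
        parts.append((h2[0::2] + h2[1::2]).astype(np.int8))
    rows = [
        ("REF_MAIN", f"REFM{i:05d}", "0", "0", int(rng.integers(1, 3)), 1)
        for i in range(n_main)
    ] + [
        ("REF_OTHER", f"REFO{i:05d}", "0", "0", int(rng.integers(1, 3)), 1)
        for i in range(n_divergent)
    ]
    samples = pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
    )
    return PedigreeCohort(
        samples=samples, markers=cohort.markers.copy(), genotypes=np.vstack(parts)
    )


# ---------------------------------------------------------------------------
# QC artifact injection
# ---------------------------------------------------------------------------


@dataclass
class ArtifactSpec:
    """Planted QC failures, logged so tests can assert exact recovery.

    ``missing_rates`` maps IID -> per-call missingness probability.
    ``het_outlier_fraction`` of samples get their heterozygosity inflated
    (factor > 1: homozygous calls become heterozygous) or deflated
    (factor < 1: heterozygous calls become homozygous).
    ``mendel_error_counts`` maps a child IID -> number of calls to corrupt
    into parent-inconsistent genotypes.  ``admixed_fraction`` of samples
    get their genotypes redrawn at shifted allele frequencies, emulating
    non-European admixture.
    """

    missing_rates: dict[str, float] = field(default_factory=dict)
    het_outlier_fraction: float = 0.0
    het_factor: float = 1.0
    mendel_error_counts: dict[str, int] = field(default_factory=dict)
    admixed_fraction: float = 0.0
    admixed_samples: list[str] | None = None  # explicit IIDs override fraction
    admix_shift: float = 0.3
    admix_direction_seed: int | None = None  # share axis with a reference pop
    seed: int = 0

    def validate(self, cohort: PedigreeCohort) -> None:
        for iid, rate in self.missing_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ConfigurationError(f"missing rate for {iid} not in [0, 1]")
        if not (0.0 <= self.het_outlier_fraction <= 1.0):
            raise ConfigurationError("het_outlier_fraction must be in [0, 1]")
        if not (0.0 <= self.admixed_fraction <= 1.0):
            raise ConfigurationError("admixed_fraction must be in [0, 1]")
        if self.het_factor < 0:
            raise ConfigurationError("het_factor must be >= 0")
        known = set(cohort.samples["iid"])
        for iid in (
            set(self.missing_rates) | set(self.mendel_error_counts)
        ) - known:
            raise ConfigurationError(f"unknown sample {iid} in artifact spec")


def inject_qc_artifacts(
    cohort: PedigreeCohort, spec: ArtifactSpec
) -> tuple[PedigreeCohort, dict]:
    """Apply planted QC failures; the input cohort is left unmodified.

    Returns the corrupted cohort and a log dict with the exact sample IDs
    and genotype positions touched by each artifact class.
    """
    spec.validate(cohort)
    rng = np.random.default_rng(spec.seed)
    out = cohort.copy()
    g = out.genotypes
    idx = out.sample_index()
    log: dict = {
        "missing": {},
        "het_outliers": [],
        "mendel": {},
        "admixed": [],
    }

    # heterozygosity outliers
    n_het = int(round(spec.het_outlier_fraction * cohort.n_samples))
    if n_het > 0:
        chosen = rng.choice(cohort.n_samples, size=n_het, replace=False)
        for s in chosen:
            row = g[s]
            if spec.het_factor > 1.0:
                q = min(1.0, spec.het_factor - 1.0)
                flip = (row != 1) & (row != MISSING) & (rng.random(len(row)) < q)
                row[flip] = 1
            elif spec.het_factor < 1.0:
                q = 1.0 - spec.het_factor
                flip = (row == 1) & (rng.random(len(row)) < q)
                row[flip] = np.where(rng.random(flip.sum()) < 0.5, 0, 2)
            log["het_outliers"].append(out.samples["iid"].iloc[s])

    # admixed samples: redraw at shifted allele frequencies (consistent
    # per-marker shift direction so admixed samples form one PCA cluster)
    if spec.admixed_samples is not None:
        chosen = [int(idx[iid]) for iid in spec.admixed_samples]
    else:
        n_adm = int(round(spec.admixed_fraction * cohort.n_samples))
        chosen = (
            rng.choice(cohort.n_samples, size=n_adm, replace=False)
            if n_adm > 0
            else []
        )
    if len(chosen) > 0:
        f = cohort.allele1_frequency()
        if spec.admix_direction_seed is not None:
            direction = allele_shift_direction(
                cohort.n_markers, spec.admix_direction_seed
            )
        else:
            direction = np.where(rng.random(cohort.n_markers) < 0.5, 1.0, -1.0)
        f_shift = np.clip(f + spec.admix_shift * direction, 0.01, 0.99)
        for s in chosen:
            g[s] = rng.binomial(2, f_shift).astype(np.int8)
            log["admixed"].append(out.samples["iid"].iloc[s])

    # Mendel errors: corrupt child calls into parent-impossible dosages
    for iid, count in spec.mendel_error_counts.items():
        s = int(idx[iid])
        fa, mo = out.samples.loc[s, ["father", "mother"]]
        if fa == "0" or mo == "0":
            raise ConfigurationError(f"{iid} has no genotyped parents")
        fi, mi = int(idx[fa]), int(idx[mo])
        # a corrupt call is constructible unless both parents are het
        eligible = np.nonzero(
            (g[fi] != MISSING) & (g[mi] != MISSING)
            & ~((g[fi] == 1) & (g[mi] == 1))
        )[0]
        if count > len(eligible):
            raise ConfigurationError(
                f"cannot inject {count} Mendel errors into {iid}: only "
                f"{len(eligible)} eligible markers"
            )
        chosen = rng.choice(eligible, size=count, replace=False)
        for j in chosen:
            pf, pm = int(g[fi, j]), int(g[mi, j])
            possible = {
                tf + tm
                for tf in ({0, 1} if pf == 1 else {pf // 2})
                for tm in ({0, 1} if pm == 1 else {pm // 2})
            }
            bad = [d for d in (0, 1, 2) if d not in possible]
            g[s, j] = bad[int(rng.integers(0, len(bad)))]
        log["mendel"][iid] = sorted(int(j) for j in chosen)

    # missingness (applied last so planted errors can be masked, which the
    # recovery tolerance in the tests accounts for)
    for iid, rate in spec.missing_rates.items():
        s = int(idx[iid])
        mask = rng.random(cohort.n_markers) < rate
        g[s, mask] = MISSING
        log["missing"][iid] = sorted(int(j) for j in np.nonzero(mask)[0])

    return out, log


# ---------------------------------------------------------------------------
# eQTL catalogue simulation
# ---------------------------------------------------------------------------


@dataclass
class EqtlCatalogueSpec:
    """Per-gene lists of regulatory SNPs with signed effects.

    With ``tissues=["LCL", "skin"]`` the catalogue mimics a multi-tissue
    resource (one record per tissue per SNP-gene pair, no FDR column);
    with a single tissue label an FDR column is emitted, mimicking a
    blood meta-analysis catalogue.  ``significant_fraction`` of records
    get small p-values (and FDR below 0.5 in the blood dialect).
    """

    n_genes: int = 50
    snps_per_gene: tuple[int, int] = (5, 30)
    effect_size_sd: float = 0.3
    significant_fraction: float = 0.5
    tissues: tuple[str, ...] = ("blood",)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        lo, hi = self.snps_per_gene
        if not (1 <= lo <= hi):
            raise ConfigurationError("snps_per_gene bounds must satisfy 1 <= lo <= hi")
        if self.effect_size_sd <= 0:
            raise ConfigurationError("effect_size_sd must be > 0")
        if not (0.0 <= self.significant_fraction <= 1.0):
            raise ConfigurationError("significant_fraction must be in [0, 1]")
        if not self.tissues:
            raise ConfigurationError("at least one tissue label required")


def simulate_eqtl_catalogue(
    spec: EqtlCatalogueSpec,
    markers: pd.DataFrame,
    cohort: PedigreeCohort | None = None,
    planted: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Simulate an eQTL catalogue over the given marker table.

    Returns a DataFrame with columns ``snp, gene, effect_allele, beta, p,
    tissue`` plus ``fdr`` in the single-tissue (blood-like) dialect.
    Effect direction is independent of case/control status unless
    ``planted`` requests it: ``planted`` maps a gene name to
    ``"down_in_cases"`` (down-regulating alleles are the case-enriched
    alleles, up-regulating ones the control-enriched alleles) or
    ``"up_in_cases"`` (the reverse); this requires ``cohort`` for the
    observed case/control frequencies.
    """
    spec.validate()
    planted = planted or {}
    if planted and cohort is None:
        raise ConfigurationError("planted directed genes require a cohort")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.snps_per_gene
    if hi > len(markers):
        raise ConfigurationError(
            f"snps_per_gene upper bound {hi} exceeds marker count {len(markers)}"
        )
    blood = len(spec.tissues) == 1

    f_case = f_ctrl = None
    if cohort is not None:
        f_case = cohort.allele1_frequency(cohort.affected)
        f_ctrl = cohort.allele1_frequency(cohort.unaffected)
        marker_pos = cohort.marker_index()

    recs: list[dict] = []
    gene_names = [f"GENE{i:04d}" for i in range(spec.n_genes)]
    gene_iter = list(planted) + [g for g in gene_names if g not in planted]
    for gene in gene_iter:
        is_planted = gene in planted
        n_snps = int(rng.integers(lo, hi + 1))
        snp_rows = rng.choice(len(markers), size=n_snps, replace=False)
        for j in snp_rows:
            snp = markers["snp"].iloc[j]
            a1, a2 = markers["a1"].iloc[j], markers["a2"].iloc[j]
            beta = float(rng.normal(0.0, spec.effect_size_sd))
            if beta == 0.0:
                beta = spec.effect_size_sd
            sig = rng.random() < spec.significant_fraction
            p = float(10 ** rng.uniform(-6, np.log10(0.05))) if sig else float(
                rng.uniform(np.nextafter(0, 1), 1.0)
            )
            if is_planted:
                k = int(marker_pos[snp])
                case_enriched = a1 if f_case[k] > f_ctrl[k] else a2
                other = a2 if case_enriched == a1 else a1
                down = beta < 0
                want_case_allele = (
                    down if planted[gene] == "down_in_cases" else not down
                )
                allele = case_enriched if want_case_allele else other
                beta = abs(beta) if not down else -abs(beta)
                # keep effects sized above the multi-tissue filter floor
                if abs(beta) < 0.01:
                    beta = np.sign(beta) * 0.01
            else:
                allele = a1 if rng.random() < 0.5 else a2
            for tissue in spec.tissues:
                rec = {
                    "snp": snp,
                    "gene": gene,
                    "effect_allele": allele,
                    "beta": beta if tissue == spec.tissues[0] else float(
                        rng.normal(0.0, spec.effect_size_sd)
                    ),
                    "p": p if tissue == spec.tissues[0] else float(
                        rng.uniform(np.nextafter(0, 1), 1.0)
                    ),
                    "tissue": tissue,
                }
                if blood:
                    rec["fdr"] = (
                        float(rng.uniform(0.0, 0.5)) if sig
                        else float(rng.uniform(0.5, 1.0))
                    )
                recs.append(rec)
    cols = ["snp", "gene", "effect_allele", "beta", "p", "tissue"] + (
        ["fdr"] if blood else []
    )
    return pd.DataFrame(recs, columns=cols)


# ---------------------------------------------------------------------------
# expression matrix simulation
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSpec:
    """Probe-level log2 expression for a case/control comparison.

    Intensities are Gaussian on the log2 scale around a per-probe
    baseline; probes listed in ``de_probes`` are shifted by the stated
    log2 fold change in cases.  ``probes_per_gene`` consecutive probes
    map to one gene unless an explicit ``probe_to_gene`` list is given.
    """

    n_case_samples: int = 20
    n_control_samples: int = 17
    n_probes: int = 1000
    de_probes: list[tuple[int, float]] = field(default_factory=list)
    noise_sd: float = 0.3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    probes_per_gene: int = 1
    probe_to_gene: list[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_case_samples < 2 or self.n_control_samples < 2:
            raise ConfigurationError("need >= 2 samples per group")
        if self.n_probes <= 0:
            raise ConfigurationError("n_probes must be > 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        for idx, _ in self.de_probes:
            if not (0 <= idx < self.n_probes):
                raise ConfigurationError(f"de_probes index {idx} >= n_probes")
        if self.probe_to_gene is not None and len(self.probe_to_gene) != self.n_probes:
            raise ConfigurationError("probe_to_gene length must equal n_probes")


def simulate_expression_matrix(
    spec: ExpressionSpec,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Return (expression probes x samples, group labels, probe->gene map)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_case_samples + spec.n_control_samples
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_probes)
    x = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_probes, n))
    for idx, lfc in spec.de_probes:
        x[idx, : spec.n_case_samples] += lfc
    sample_ids = [f"case{i:03d}" for i in range(spec.n_case_samples)] + [
        f"ctrl{i:03d}" for i in range(spec.n_control_samples)
    ]
    probe_ids = [f"probe{i:05d}" for i in range(spec.n_probes)]
    expr = pd.DataFrame(x, index=probe_ids, columns=sample_ids)
    groups = pd.Series(
        ["case"] * spec.n_case_samples + ["control"] * spec.n_control_samples,
        index=sample_ids,
        name="group",
    )
    if spec.probe_to_gene is not None:
        genes = list(spec.probe_to_gene)
    else:
        genes = [
            f"GENE{i // spec.probes_per_gene:04d}" for i in range(spec.n_probes)
        ]
    probe_map = pd.DataFrame({"probe": probe_ids, "gene": genes})
    return expr, groups, probe_map


# ---------------------------------------------------------------------------
# gene coordinates / gene sets
# ---------------------------------------------------------------------------


def simulate_gene_annotation(
    markers: pd.DataFrame,
    n_genes: int = 200,
    gene_length: int = 20_000,
    n_sets: int = 30,
    genes_per_set: tuple[int, int] = (5, 25),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Random gene coordinates over the marker-bearing genome plus GMT sets.

    Genes are placed uniformly on each chromosome's marker-covered span
    (BED convention, 0-based half-open).  Gene sets are uniform draws of
    gene names.
    """
    rng = np.random.default_rng(seed)
    chroms = markers["chrom"].unique()
    spans = {
        c: int(markers.loc[markers["chrom"] == c, "pos"].max()) + gene_length
        for c in chroms
    }
    total = sum(spans.values())
    names = [f"GENE{i:04d}" for i in range(n_genes)]
    rows = []
    for name in names:
        c = rng.choice(chroms, p=[spans[c] / total for c in chroms])
        start = int(rng.integers(0, max(spans[c] - gene_length, 1)))
        rows.append((c, start, start + gene_length, name))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
    lo, hi = genes_per_set
    hi = min(hi, n_genes)
    lo = min(lo, hi)
    sets = {
        f"SET{i:03d}": sorted(
            rng.choice(names, size=int(rng.integers(lo, hi + 1)), replace=False)
        )
        for i in range(n_sets)
    }
    return genes, sets
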