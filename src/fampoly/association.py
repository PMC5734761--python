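"""Family-aware genome-wide association scans.

Two methods:

* ``dfam_scan`` — a stratified Cochran–Mantel–Haenszel test combining,
  per marker, (a) TDT transmissions from heterozygous genotyped parents
  to affected children, (b) within-sibship hypergeometric contrasts for
  families without genotyped parents, and (c) a single allelic 2x2
  stratum for unrelated cases and controls.  The CMH statistic is
  T = (sum(O - E))^2 / sum(V) with a chi-square(1) p-value.

* ``emmax_scan`` — an EMMAX-style mixed model: variance components are
  fit once by REML on the null model y = mu + g + e with
  Var = sigma_g^2 K + sigma_e^2 I, then each marker is tested by
  generalized least squares on the eigenbasis of K, under additive,
  dominant and recessive codings; the smallest of the three p-values is
  assigned to the marker, together with the winning model label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from fampoly.cohort import MISSING, PedigreeCohort
from fampoly.qc import grm


# ---------------------------------------------------------------------------
# DFAM-style stratified CMH
# ---------------------------------------------------------------------------


def _family_structure(cohort: PedigreeCohort) -> dict:
    """Classify samples into trio children, sibship clusters and unrelateds.

    A family whose two parents appear in the sample table contributes TDT
    strata through its affected children; a multi-person family without
    two genotyped parents contributes a sibship stratum; singletons form
    the unrelated stratum.
    """
    idx = cohort.sample_index()
    known = set(idx.index)
    s = cohort.samples
    trio_children = []  # (child_row, father_row, mother_row), affected only
    sib_clusters = []  # (member_rows, affected_mask) per family
    unrelated_rows = []
    for fid, grp in s.groupby("fid", sort=False):
        if len(grp) == 1:
            unrelated_rows.append(int(grp.index[0]))
            continue
        has_parent_pair = False
        for row in grp.itertuples():
            if row.father in known and row.mother in known:
                has_parent_pair = True
                if row.phenotype == 2:
                    trio_children.append(
                        (int(row.Index), int(idx[row.father]), int(idx[row.mother]))
                    )
        if not has_parent_pair:
            members = [int(i) for i in grp.index]
            aff = (grp["phenotype"].to_numpy() == 2)
            if aff.any() and (grp["phenotype"].to_numpy() == 1).any():
                sib_clusters.append((members, aff))
    return {
        "trio_children": trio_children,
        "sib_clusters": sib_clusters,
        "unrelated_rows": unrelated_rows,
    }


def dfam_scan(cohort: PedigreeCohort) -> pd.DataFrame:
    """Stratified CMH association test for every marker.

    Returns a DataFrame with columns ``snp, chrom, pos, a1, a2, p, obs,
    exp, informative``; ``obs``/``exp`` are the observed and null-expected
    allele-1 counts in affected individuals summed over strata.  Markers
    with zero total variance get p = 1 and ``informative = False``.
    """
    struct = _family_structure(cohort)
    g = cohort.genotypes
    m = cohort.n_markers
    O = np.zeros(m)
    E = np.zeros(m)
    V = np.zeros(m)

    # --- (a) TDT stratum: transmissions from het parents to affected kids
    tk = struct["trio_children"]
    if tk:
        c_rows = np.array([t[0] for t in tk])
        f_rows = np.array([t[1] for t in tk])
        m_rows = np.array([t[2] for t in tk])
        C, F, M = g[c_rows], g[f_rows], g[m_rows]
        valid = (C != MISSING) & (F != MISSING) & (M != MISSING)
        n_het = ((F == 1).astype(int) + (M == 1).astype(int)) * valid
        forced = ((F == 2).astype(int) + (M == 2).astype(int)) * valid
        o = np.clip(np.where(valid, C, 0) - forced, 0, n_het)
        O += (o * (n_het > 0)).sum(axis=0)
        E += (n_het / 2.0).sum(axis=0)
        V += (n_het / 4.0).sum(axis=0)

    # --- (b) sibship strata: hypergeometric draw of affected allele slots
    for members, aff in struct["sib_clusters"]:
        rows = np.array(members)
        G = g[rows]
        called = G != MISSING
        aff_col = aff[:, None]
        n_aff_called = (called & aff_col).sum(axis=0)
        n_una_called = (called & ~aff_col).sum(axis=0)
        A = 2.0 * (n_aff_called + n_una_called)  # total alleles
        a_draw = 2.0 * n_aff_called
        K1 = np.where(called, G, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(A > 0, K1 / np.maximum(A, 1), 0.0)
            e = a_draw * frac
            v = np.where(
                A > 1,
                a_draw * frac * (1 - frac) * (A - a_draw) / np.maximum(A - 1, 1),
                0.0,
            )
        informative = (n_aff_called > 0) & (n_una_called > 0) & (v > 0)
        o = (np.where(called & aff_col, G, 0)).sum(axis=0).astype(float)
        O += np.where(informative, o, 0.0)
        E += np.where(informative, e, 0.0)
        V += np.where(informative, v, 0.0)

    # --- (c) unrelated stratum: single allelic case/control 2x2
    ur = struct["unrelated_rows"]
    if ur:
        rows = np.array(ur)
        G = g[rows]
        pheno = cohort.samples["phenotype"].to_numpy()[rows]
        case = (pheno == 2)[:, None]
        ctrl = (pheno == 1)[:, None]
        called = G != MISSING
        a_case = 2.0 * (called & case).sum(axis=0)
        a_ctrl = 2.0 * (called & ctrl).sum(axis=0)
        A = a_case + a_ctrl
        K1 = np.where(called & (case | ctrl), G, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(A > 0, K1 / np.maximum(A, 1), 0.0)
            e = a_case * frac
            v = np.where(
                A > 1,
                a_case * a_ctrl * frac * (1 - frac) / np.maximum(A - 1, 1),
                0.0,
            )
        informative = (a_case > 0) & (a_ctrl > 0) & (v > 0)
        o = np.where(called & case, G, 0).sum(axis=0).astype(float)
        O += np.where(informative, o, 0.0)
        E += np.where(informative, e, 0.0)
        V += np.where(informative, v, 0.0)

    with np.errstate(invalid="ignore", divide="ignore"):
        T = np.where(V > 0, (O - E) ** 2 / np.maximum(V, 1e-300), 0.0)
    p = np.where(V > 0, stats.chi2.sf(T, df=1), 1.0)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    out = cohort.markers[["snp", "chrom", "pos", "a1", "a2"]].copy()
    out["p"] = p
    out["obs"] = O
    out["exp"] = E
    out["informative"] = V > 0
    return out


def dfam_test(cohort: PedigreeCohort, snp: str) -> pd.Series:
    """Single-marker convenience wrapper around :func:`dfam_scan`."""
    sub = cohort.subset(marker_ids=[snp])
    return dfam_scan(sub).iloc[0]


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------


def kinship_matrix(cohort: PedigreeCohort) -> tuple[np.ndarray, list[str]]:
    """Standardized-dosage GRM (monomorphic markers skipped with warning)."""
    maf = cohort.minor_allele_frequency()
    if np.any(maf == 0):
        warnings.warn(
            f"{int((maf == 0).sum())} monomorphic markers skipped in kinship"
        )
    k = grm(cohort.genotypes)
    return k, cohort.samples["iid"].tolist()


# ---------------------------------------------------------------------------
# EMMAX
# ---------------------------------------------------------------------------


@dataclass
class NullModel:
    """REML fit of y = mu + g + e with Var = sigma_g^2 K + sigma_e^2 I."""

    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    y_rot: np.ndarray

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, y_rot: np.ndarray,
                     x_rot: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = lam + delta
    wi = 1.0 / w
    xtwx = x_rot.T @ (wi[:, None] * x_rot)
    xtwy = x_rot.T @ (wi * y_rot)
    beta = np.linalg.solve(xtwx, xtwy)
    resid = y_rot - x_rot @ beta
    n, p = len(y_rot), x_rot.shape[1]
    rss = float(resid @ (wi * resid))
    if rss <= 0:
        return np.inf
    sigma_g2 = rss / (n - p)
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sigma_g2) + 1)
        + np.sum(np.log(w))
        + np.linalg.slogdet(xtwx)[1]
        - np.linalg.slogdet(x_rot.T @ x_rot)[1]
    )
    return -ll


def emmax_fit_null(phenotype: np.ndarray, kinship: np.ndarray) -> NullModel:
    """REML variance components on the eigenbasis of the kinship matrix.

    The binary phenotype is treated as quantitative.  Optimization is a
    grid plus bounded scalar search over log(delta), delta = sigma_e^2 /
    sigma_g^2; boundary solutions (delta -> inf) reduce the downstream
    GLS to ordinary least squares.
    """
    y = np.asarray(phenotype, dtype=float)
    if np.std(y) == 0:
        raise ValueError("phenotype is constant; association is undefined")
    k = np.asarray(kinship, dtype=float)
    if not np.allclose(k, k.T, atol=1e-10):
        raise ValueError("kinship matrix is not symmetric")
    lam, u = np.linalg.eigh(k)
    if lam.min() < -1e-6:
        lam = lam + abs(lam.min()) + 1e-8  # jitter for numerically non-PSD K
    lam = np.maximum(lam, 0.0)
    y_rot = u.T @ y
    x_rot = u.T @ np.ones((len(y), 1))
    grid = np.linspace(-10, 10, 41)
    vals = [_reml_neg_loglik(ld, lam, y_rot, x_rot) for ld in grid]
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(lo, hi), args=(lam, y_rot, x_rot), method="bounded"
    )
    delta = float(np.exp(res.x))
    w = lam + delta
    wi = 1.0 / w
    xtwx = x_rot.T @ (wi[:, None] * x_rot)
    beta = np.linalg.solve(xtwx, x_rot.T @ (wi * y_rot))
    resid = y_rot - x_rot @ beta
    sigma_g2 = float(resid @ (wi * resid)) / (len(y) - 1)
    return NullModel(
        sigma_g2=sigma_g2,
        sigma_e2=delta * sigma_g2,
        delta=delta,
        eigenvalues=lam,
        eigenvectors=u,
        y_rot=y_rot,
    )


_CODINGS = {
    "ADD": np.array([0.0, 1.0, 2.0]),
    "DOM": np.array([0.0, 1.0, 1.0]),
    "REC": np.array([0.0, 0.0, 1.0]),
}


def emmax_scan(cohort: PedigreeCohort, null: NullModel) -> pd.DataFrame:
    """Per-marker GLS scan under additive/dominant/recessive codings.

    For each coding the marker effect is estimated by weighted least
    squares on the rotated data (weights 1/(lambda_i + delta)); the Wald
    p-value uses a t reference with n - 2 degrees of freedom.  The
    reported p is the minimum over the codings that are testable (a
    coding constant across samples is skipped); if none is testable the
    marker gets p = 1.  No multiplicity adjustment is applied to the
    min-p convention; this makes the scan anti-conservative by design
    and is recorded in the output metadata.
    """
    g = cohort.genotypes
    n, m = g.shape
    u = null.eigenvectors
    wi = 1.0 / (null.eigenvalues + null.delta)
    y_rot = null.y_rot
    ones_rot = u.T @ np.ones(n)

    s_hh = float(ones_rot @ (wi * ones_rot))
    s_hy = float(ones_rot @ (wi * y_rot))

    best_p = np.ones(m)
    best_beta = np.full(m, np.nan)
    best_model = np.full(m, "", dtype=object)

    missing = g == MISSING
    for label, coding in _CODINGS.items():
        x = coding[np.clip(g, 0, 2)].astype(float)
        x[missing] = np.nan
        mu = np.nanmean(x, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        ii, jj = np.nonzero(np.isnan(x))
        x[ii, jj] = mu[jj]
        testable = x.std(axis=0) > 0
        if not testable.any():
            continue
        x_rot = u.T @ x  # (n, m)
        s_xx = (x_rot * wi[:, None] * x_rot).sum(axis=0)
        s_xh = (x_rot * (wi * ones_rot)[:, None]).sum(axis=0)
        s_xy = (x_rot * (wi * y_rot)[:, None]).sum(axis=0)
        det = s_xx * s_hh - s_xh**2
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = (s_xy * s_hh - s_xh * s_hy) / det
            alpha = (s_xx * s_hy - s_xh * s_xy) / det
        resid = (wi[:, None] * (y_rot[:, None] - x_rot * beta - np.outer(ones_rot, alpha))
                 * (y_rot[:, None] - x_rot * beta - np.outer(ones_rot, alpha)))
        rss = resid.sum(axis=0)
        dof = n - 2
        with np.errstate(invalid="ignore", divide="ignore"):
            sigma2 = rss / dof
            se = np.sqrt(sigma2 * s_hh / det)
            tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        p = np.where(testable & np.isfinite(p), p, np.nan)
        better = ~np.isnan(p) & ((p < best_p) | (best_model == ""))
        best_p = np.where(better, p, best_p)
        best_beta = np.where(better, beta, best_beta)
        best_model = np.where(better, label, best_model)

    out = cohort.markers[["snp", "chrom", "pos", "a1", "a2"]].copy()
    out["p"] = np.clip(best_p, np.nextafter(0, 1), 1.0)
    out["beta"] = best_beta
    out["model"] = best_model
    out["informative"] = best_model != ""
    out.attrs["min_p_convention"] = (
        "minimum p over ADD/DOM/REC without multiplicity adjustment"
    )
    return out


def emmax_association(cohort: PedigreeCohort) -> pd.DataFrame:
    """Convenience: kinship, null REML fit, then the three-coding scan."""
    k, _ = kinship_matrix(cohort)
    y = (cohort.samples["phenotype"].to_numpy() == 2).astype(float)
    null = emmax_fit_null(y, k)
    return emmax_scan(cohort, null)


def manhattan_table(results: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready coordinates: marker, chromosome, position, -log10 p."""
    out = results[["snp", "chrom", "pos"]].copy()
    out["neglog10_p"] = -np.log10(results["p"].to_numpy())
    return out
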