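"""Pedigreed genotype container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.  Dosages are counts of allele 1,
#: so 0 is a valid call and must never double as "missing".
MISSING: int = -1

SAMPLE_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]
MARKER_COLUMNS = ["snp", "chrom", "pos", "a1", "a2"]


@dataclass
class PedigreeCohort:
    """Samples with family links plus a marker x sample genotype matrix.

    Attributes
    ----------
    samples
        One row per individual with columns ``fid, iid, father, mother,
        sex, phenotype``.  ``father``/``mother`` are IIDs or ``"0"`` for
        founders; ``sex`` is 1 (male) / 2 (female) / 0 (unknown);
        ``phenotype`` is 2 (affected) / 1 (unaffected) / 0 (unknown),
        the PLINK convention.
    markers
        One row per marker: ``snp, chrom, pos, a1, a2``.
    genotypes
        ``int8`` array of shape (n_samples, n_markers) holding the
        allele-1 dosage (0/1/2) or :data:`MISSING`.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    genotypes: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {g.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        self.genotypes = g

    # -- basic dimensions -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    # -- derived masks ----------------------------------------------------
    @property
    def affected(self) -> np.ndarray:
        return (self.samples["phenotype"].to_numpy() == 2)

    @property
    def unaffected(self) -> np.ndarray:
        return (self.samples["phenotype"].to_numpy() == 1)

    @property
    def is_founder(self) -> np.ndarray:
        s = self.samples
        return ((s["father"] == "0") & (s["mother"] == "0")).to_numpy()

    def sample_index(self) -> pd.Series:
        """IID -> row index (IIDs are unique cohort-wide)."""
        return pd.Series(
            np.arange(self.n_samples), index=self.samples["iid"].to_numpy()
        )

    def marker_index(self) -> pd.Series:
        return pd.Series(
            np.arange(self.n_markers), index=self.markers["snp"].to_numpy()
        )

    # -- subsetting --------------------------------------------------------
    def subset(self, sample_ids=None, marker_ids=None) -> "PedigreeCohort":
        """Return a new cohort restricted to the given IIDs / SNP ids.

        Order of the provided id lists is preserved.
        """
        rows = np.arange(self.n_samples)
        cols = np.arange(self.n_markers)
        if sample_ids is not None:
            rows = self.sample_index().loc[list(sample_ids)].to_numpy()
        if marker_ids is not None:
            cols = self.marker_index().loc[list(marker_ids)].to_numpy()
        return PedigreeCohort(
            samples=self.samples.iloc[rows],
            markers=self.markers.iloc[cols],
            genotypes=self.genotypes[np.ix_(rows, cols)].copy(),
            meta=dict(self.meta),
        )

    def copy(self) -> "PedigreeCohort":
        return PedigreeCohort(
            samples=self.samples.copy(),
            markers=self.markers.copy(),
            genotypes=self.genotypes.copy(),
            meta=dict(self.meta),
        )

    # -- allele bookkeeping ------------------------------------------------
    def allele1_frequency(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Per-marker allele-1 frequency over non-missing calls.

        ``mask`` optionally restricts the computation to a subset of
        samples.  Markers with no callable genotypes yield ``nan``.
        """
        g = self.genotypes if mask is None else self.genotypes[mask]
        called = g != MISSING
        counts = np.where(called, g, 0).sum(axis=0)
        denom = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)

    def minor_allele_frequency(self, mask: np.ndarray | None = None) -> np.ndarray:
        f = self.allele1_frequency(mask)
        return np.minimum(f, 1.0 - f)
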