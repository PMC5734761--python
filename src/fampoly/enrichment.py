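"""LD-interval construction and matched-permutation gene-set enrichment.

The top association hits are merged into intervals of SNPs in high LD
(pairwise r^2 above a threshold, transitively closed), intervals are
mapped to genes, and each gene set's interval overlap count is compared
with random genomic regions matched in length and SNP density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fampoly.cohort import PedigreeCohort
from fampoly.qc import pairwise_r2


# ---------------------------------------------------------------------------
# top SNP selection
# ---------------------------------------------------------------------------


def select_top_snps(results: pd.DataFrame, k: int = 1000) -> pd.DataFrame:
    """The ``k`` markers with the smallest p; ties broken in genome order."""
    if len(results) < k:
        warnings.warn(
            f"only {len(results)} results available; taking all (requested {k})"
        )
        k = len(results)
    ordered = results.sort_values(
        ["p", "chrom", "pos"], kind="mergesort"
    ).head(k)
    return ordered.reset_index(drop=True)


# ---------------------------------------------------------------------------
# LD intervals
# ---------------------------------------------------------------------------


@dataclass
class LDInterval:
    """A genomic interval spanned by top SNPs connected by high LD.

    ``start``/``end`` are 1-based inclusive base-pair positions;
    ``snp_density`` is the number of array markers inside [start, end]
    divided by the interval length.
    """

    chrom: int
    start: int
    end: int
    members: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def density(self, marker_positions: np.ndarray) -> float:
        inside = np.searchsorted(marker_positions, self.end, side="right") - \
            np.searchsorted(marker_positions, self.start, side="left")
        return inside / self.length


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_ld_intervals(
    top: pd.DataFrame, cohort: PedigreeCohort, r2_min: float = 0.25
) -> list[LDInterval]:
    """Merge top markers into intervals by transitive pairwise r^2 > r2_min.

    Connected components of the same-chromosome LD graph become intervals
    spanning [min bp, max bp] of their members; a singleton becomes a
    1-bp interval at its own position.  The result is independent of the
    input order of the top markers.
    """
    top = top.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    snps = top["snp"].tolist()
    sub = cohort.subset(marker_ids=snps)
    uf = _UnionFind(len(top))
    for chrom, grp in top.groupby("chrom"):
        rows = grp.index.to_numpy()
        if len(rows) < 2:
            continue
        r2 = pairwise_r2(sub.genotypes[:, rows])
        ii, jj = np.nonzero(np.triu(r2 > r2_min, k=1))
        for a, b in zip(rows[ii], rows[jj]):
            uf.union(int(a), int(b))
    groups: dict[int, list[int]] = {}
    for i in range(len(top)):
        groups.setdefault(uf.find(i), []).append(i)
    intervals = []
    for members in groups.values():
        pos = top.loc[members, "pos"]
        intervals.append(
            LDInterval(
                chrom=int(top.loc[members[0], "chrom"]),
                start=int(pos.min()),
                end=int(pos.max()),
                members=top.loc[members, "snp"].tolist(),
            )
        )
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def intervals_table(intervals: list[LDInterval], cohort: PedigreeCohort) -> pd.DataFrame:
    pos_by_chrom = {
        c: np.sort(g["pos"].to_numpy())
        for c, g in cohort.markers.groupby("chrom")
    }
    rows = [
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "length": iv.length,
            "n_snps": len(iv.members),
            "snp_density": iv.density(pos_by_chrom.get(iv.chrom, np.array([]))),
            "members": ",".join(iv.members),
        }
        for iv in intervals
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# interval -> gene overlap
# ---------------------------------------------------------------------------


def map_intervals_to_genes(
    intervals: list[LDInterval], genes: pd.DataFrame, pad_bp: int = 0
) -> dict[int, list[str]]:
    """Overlaps between intervals and (padded) genes.

    Genes use the BED convention (0-based half-open); the 1-based
    inclusive interval [start, end] is treated as the half-open
    [start, end + 1) on the same axis, so a gene starting exactly at
    ``end`` still overlaps.  Returns interval index -> gene names.
    """
    out: dict[int, list[str]] = {}
    for i, iv in enumerate(intervals):
        sel = genes[genes["chrom"] == iv.chrom]
        gs = sel["start"].to_numpy() - pad_bp
        ge = sel["end"].to_numpy() + pad_bp
        hit = (gs < iv.end + 1) & (ge > iv.start)
        out[i] = sel.loc[hit, "gene"].tolist()
    return out


# ---------------------------------------------------------------------------
# matched-permutation enrichment
# ---------------------------------------------------------------------------


@dataclass
class GenomeModel:
    """Chromosome lengths and sorted marker positions for null placement."""

    chrom_lengths: dict[int, int]
    marker_positions: dict[int, np.ndarray]

    @classmethod
    def from_cohort(cls, cohort: PedigreeCohort, tail_bp: int = 100_000) -> "GenomeModel":
        lengths, positions = {}, {}
        for c, grp in cohort.markers.groupby("chrom"):
            p = np.sort(grp["pos"].to_numpy())
            positions[int(c)] = p
            lengths[int(c)] = int(p.max()) + tail_bp
        return cls(chrom_lengths=lengths, marker_positions=positions)

    def flat_markers(self) -> tuple[np.ndarray, np.ndarray]:
        """All markers as parallel (chromosome, position) arrays; sampling
        a uniform index weights chromosomes by marker count."""
        if not hasattr(self, "_flat"):
            chroms = np.concatenate(
                [np.full(len(p), c) for c, p in self.marker_positions.items()]
            )
            pos = np.concatenate(list(self.marker_positions.values()))
            self._flat = (chroms, pos)
        return self._flat


@dataclass
class SetEnrichmentResult:
    name: str
    observed: int
    empirical_p: float
    contributing_genes: list[str]


def _density(positions: np.ndarray, start: int, end: int) -> float:
    n = np.searchsorted(positions, end, side="right") - np.searchsorted(
        positions, start, side="left"
    )
    return n / (end - start + 1)


def _place_matched(
    rng: np.random.Generator,
    genome: GenomeModel,
    template: LDInterval,
    template_density: float,
    length_tol: float,
    density_tol: float,
    max_tries: int = 200,
) -> tuple[int, int, int]:
    """One random region matched to the template in length and SNP density.

    Regions keep the template's exact length (trivially inside the length
    tolerance) and are anchored on a random array marker (uniform over
    markers, uniform offset within the region), mirroring the observed
    intervals, which always contain markers; a placement is accepted when
    its SNP density is within ``density_tol`` (relative) of the
    template's.  After ``max_tries`` rejections the tolerance is relaxed
    stepwise with a warning.
    """
    flat_chrom, flat_pos = genome.flat_markers()
    tol = density_tol
    while True:
        anchors = rng.integers(0, len(flat_pos), size=max_tries)
        offsets = rng.integers(0, template.length, size=max_tries)
        for anchor, offset in zip(anchors, offsets):
            c = int(flat_chrom[anchor])
            start = int(flat_pos[anchor]) - int(offset)
            start = max(1, min(start, genome.chrom_lengths[c] - template.length + 1))
            if start < 1:
                continue
            end = start + template.length - 1
            d = _density(genome.marker_positions[c], start, end)
            lo = template_density * (1 - tol)
            hi = template_density * (1 + tol)
            if lo <= d <= hi:
                return c, start, end
        tol *= 1.5
        warnings.warn(
            f"no matched placement found; relaxing density tolerance to {tol:.3f}"
        )
        if tol > 100:
            raise RuntimeError("matched placement impossible for template interval")


def _overlap_genes_fast(
    chrom: int, start: int, end: int, genes_by_chrom: dict
) -> set[str]:
    entry = genes_by_chrom.get(chrom)
    if entry is None:
        return set()
    gs, ge, names = entry
    hit = (gs < end + 1) & (ge > start)
    return set(names[hit])


def enrichment_test(
    intervals: list[LDInterval],
    gene_sets: dict[str, list[str]],
    genes: pd.DataFrame,
    genome: GenomeModel,
    R: int = 50_000,
    seed: int = 0,
    pad_bp: int = 0,
    length_tol: float = 0.10,
    density_tol: float = 0.10,
) -> pd.DataFrame:
    """INRICH-style matched-permutation enrichment for every gene set.

    The observed statistic per set is the number of intervals overlapping
    at least one member gene.  Each of the ``R`` null replicates places
    one random, length- and density-matched region per observed interval
    and recomputes the statistic; the empirical p is
    (1 + #{replicates >= observed}) / (R + 1).
    """
    if R <= 0:
        raise ValueError("R must be >= 1 for an empirical p-value")
    rng = np.random.default_rng(seed)
    genes_by_chrom = {
        int(c): (
            grp["start"].to_numpy() - pad_bp,
            grp["end"].to_numpy() + pad_bp,
            grp["gene"].to_numpy(),
        )
        for c, grp in genes.groupby("chrom")
    }
    set_members = {name: set(m) for name, m in gene_sets.items()}

    obs_genes = [
        _overlap_genes_fast(iv.chrom, iv.start, iv.end, genes_by_chrom)
        for iv in intervals
    ]
    observed = {
        name: sum(1 for gg in obs_genes if gg & members)
        for name, members in set_members.items()
    }
    contributing = {
        name: sorted(set.union(set(), *(gg & members for gg in obs_genes)))
        for name, members in set_members.items()
    }

    densities = [
        iv.density(genome.marker_positions.get(iv.chrom, np.array([])))
        for iv in intervals
    ]
    exceed = {name: 0 for name in set_members}
    for _ in range(R):
        rep_genes = []
        for iv, dens in zip(intervals, densities):
            c, s, e = _place_matched(
                rng, genome, iv, dens, length_tol, density_tol
            )
            rep_genes.append(_overlap_genes_fast(c, s, e, genes_by_chrom))
        for name, members in set_members.items():
            stat = sum(1 for gg in rep_genes if gg & members)
            if stat >= observed[name]:
                exceed[name] += 1
    rows = [
        {
            "set": name,
            "observed": observed[name],
            "empirical_p": (1 + exceed[name]) / (R + 1),
            "contributing_genes": ",".join(contributing[name]),
        }
        for name in set_members
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["empirical_p", "set"], kind="mergesort")
        .reset_index(drop=True)
    )


def assemble_target_genes(
    runs: list[pd.DataFrame], top_n: int = 20
) -> list[str]:
    """Union of contributing genes from each run's top gene sets.

    Per run, sets are ranked by ascending empirical p (ties by descending
    observed overlap, then name); the genes of the top ``top_n`` sets
    that overlap any interval of that run are collected, then the union
    across runs is deduplicated and sorted.
    """
    genes: set[str] = set()
    for run in runs:
        ranked = run.sort_values(
            ["empirical_p", "observed", "set"],
            ascending=[True, False, True],
            kind="mergesort",
        ).head(top_n)
        for entry in ranked["contributing_genes"]:
            if entry:
                genes.update(entry.split(","))
    return sorted(genes)
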