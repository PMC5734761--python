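"""Readers and writers for the pipeline's on-disk formats.

PLINK text (.ped/.map) and binary (.bed/.bim/.fam, SNP-major, 2-bit
codes), BED gene coordinates (0-based half-open), GMT gene-set
collections, and TSV eQTL catalogues / expression matrices.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from fampoly.cohort import MISSING, PedigreeCohort

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------


def write_ped_map(cohort: PedigreeCohort, prefix: str | Path) -> None:
    """Write ``<prefix>.ped`` and ``<prefix>.map``.

    Missing genotypes are encoded as ``0 0``; dosage d of allele 1 is
    written as d copies of a1 and (2-d) copies of a2.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mk = cohort.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in mk.iterrows():
            fh.write(f"{r.chrom}\t{r.snp}\t0\t{r.pos}\n")
    a1 = mk["a1"].to_numpy()
    a2 = mk["a2"].to_numpy()
    g = cohort.genotypes
    # per-dosage allele pair strings, built column-wise
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, s in cohort.samples.iterrows():
            pairs = np.empty(cohort.n_markers, dtype=object)
            row = g[i]
            pairs[row == MISSING] = "0 0"
            for d in (0, 1, 2):
                sel = row == d
                if d == 0:
                    pairs[sel] = [f"{x} {x}" for x in a2[sel]]
                elif d == 2:
                    pairs[sel] = [f"{x} {x}" for x in a1[sel]]
                else:
                    pairs[sel] = [f"{x} {y}" for x, y in zip(a1[sel], a2[sel])]
            fh.write(
                f"{s.fid} {s.iid} {s.father} {s.mother} {s.sex} {s.phenotype} "
                + " ".join(pairs)
                + "\n"
            )


def read_ped_map(prefix: str | Path) -> PedigreeCohort:
    """Read ``<prefix>.ped`` / ``<prefix>.map`` into a cohort.

    Allele 1 / allele 2 assignment follows the marker's observed alleles
    in first-seen order unless both alleles of the written pair convention
    are recoverable; a marker with a single observed allele gets ``"0"``
    as its allele 2 placeholder.
    """
    prefix = Path(prefix)
    mp = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": int, "snp": str, "pos": int},
    )
    m = len(mp)
    fams, genos = [], []
    allele_codes: list[dict[str, int]] = [dict() for _ in range(m)]
    raw_rows = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 6 + 2 * m:
                raise ValueError(
                    f"malformed .ped line for {toks[1] if len(toks) > 1 else '?'}:"
                    f" expected {6 + 2 * m} fields, got {len(toks)}"
                )
            fams.append(toks[:6])
            raw_rows.append(toks[6:])
            for j in range(m):
                for al in toks[6 + 2 * j : 8 + 2 * j]:
                    if al != "0" and al not in allele_codes[j]:
                        if len(allele_codes[j]) >= 2:
                            raise ValueError(
                                f"marker {mp.snp[j]} has >2 alleles in .ped"
                            )
                        allele_codes[j][al] = len(allele_codes[j])
    a1 = [next(iter(c), "0") for c in allele_codes]
    a2 = [
        list(c)[1] if len(c) > 1 else "0" for c in allele_codes
    ]
    for toks in raw_rows:
        row = np.empty(m, dtype=np.int8)
        for j in range(m):
            x, y = toks[2 * j], toks[2 * j + 1]
            if x == "0" or y == "0":
                row[j] = MISSING
            else:
                row[j] = (x == a1[j]) + (y == a1[j])
        genos.append(row)
    samples = pd.DataFrame(
        fams, columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
    )
    samples["sex"] = samples["sex"].astype(int)
    samples["phenotype"] = samples["phenotype"].astype(int)
    markers = mp[["snp", "chrom", "pos"]].copy()
    markers["a1"] = a1
    markers["a2"] = a2
    genotypes = (
        np.vstack(genos) if genos else np.empty((0, m), dtype=np.int8)
    )
    return PedigreeCohort(samples=samples, markers=markers, genotypes=genotypes)


# ---------------------------------------------------------------------------
# PLINK binary (.bed/.bim/.fam)
# ---------------------------------------------------------------------------

# 2-bit codes, SNP-major: 00 = hom a1 (dosage 2), 01 = missing,
# 10 = het, 11 = hom a2 (dosage 0)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_bed_bim_fam(cohort: PedigreeCohort, prefix: str | Path) -> None:
    """Write PLINK binary (SNP-major, magic bytes 0x6c 0x1b 0x01)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for _, s in cohort.samples.iterrows():
            fh.write(f"{s.fid} {s.iid} {s.father} {s.mother} {s.sex} {s.phenotype}\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, r in cohort.markers.iterrows():
            fh.write(f"{r.chrom}\t{r.snp}\t0\t{r.pos}\t{r.a1}\t{r.a2}\n")
    n = cohort.n_samples
    codes = np.empty((cohort.n_markers, n), dtype=np.uint8)
    g = cohort.genotypes
    for d, c in _DOSAGE_TO_CODE.items():
        codes[(g == d).T] = c
    n_bytes = (n + 3) // 4
    packed = np.zeros((cohort.n_markers, n_bytes), dtype=np.uint8)
    for k in range(4):
        cols = np.arange(k, n, 4)
        packed[:, : len(cols)] |= codes[:, cols] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_bed_bim_fam(prefix: str | Path) -> PedigreeCohort:
    prefix = Path(prefix)
    samples = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    markers = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str, "a1": str, "a2": str},
    )[["snp", "chrom", "pos", "a1", "a2"]]
    n, m = len(samples), len(markers)
    with open(prefix.with_suffix(".bed"), "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed: bad magic bytes {magic!r}")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    raw = raw.reshape(m, n_bytes)
    geno = np.empty((m, n), dtype=np.int8)
    for k in range(4):
        cols = np.arange(k, n, 4)
        geno[:, cols] = _CODE_TO_DOSAGE[(raw[:, : len(cols)] >> (2 * k)) & 0b11]
    return PedigreeCohort(samples=samples, markers=markers, genotypes=geno.T.copy())


# ---------------------------------------------------------------------------
# genes (BED), gene sets (GMT), TSV tables
# ---------------------------------------------------------------------------


def align_alleles(cohort: PedigreeCohort, reference: pd.DataFrame) -> PedigreeCohort:
    """Flip allele-1/allele-2 labels (and dosages) to match a reference.

    .ped files do not record which allele is allele 1, so a round-tripped
    cohort may come back with the two labels swapped on some markers; this
    restores the reference orientation so genotype matrices compare
    bit-for-bit.  Raises if a marker's alleles do not match the reference.
    """
    out = cohort.copy()
    ref = reference.set_index("snp")
    for j, r in out.markers.iterrows():
        ra1, ra2 = ref.loc[r.snp, ["a1", "a2"]]
        if (r.a1, r.a2) == (ra1, ra2):
            continue
        observed = {a for a in (r.a1, r.a2) if a != "0"}
        if not observed <= {ra1, ra2}:
            raise ValueError(
                f"marker {r.snp}: alleles {r.a1}/{r.a2} incompatible with "
                f"reference {ra1}/{ra2}"
            )
        if r.a1 == ra2 or r.a2 == ra1:  # swapped orientation
            col = out.genotypes[:, j]
            nm = col != MISSING
            col[nm] = 2 - col[nm]
        out.markers.loc[j, ["a1", "a2"]] = [ra1, ra2]
    return out


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene coordinates as BED (0-based half-open)."""
    genes[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) < 4:
                raise ValueError(f"{path}: malformed BED line {ln}: need 4 columns")
            try:
                start, end = int(toks[1]), int(toks[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {ln}: {exc}") from exc
            if start > end:
                raise ValueError(f"{path}: malformed BED line {ln}: start > end")
            rows.append((toks[0], start, end, toks[3]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    # chromosome labels may be numeric or "chrN"; keep numeric where possible
    try:
        df["chrom"] = df["chrom"].astype(int)
    except ValueError:
        pass
    return df


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na"] + list(members)) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            toks = line.rstrip("\n").split("\t")
            if len(toks) < 3:
                continue
            sets[toks[0]] = list(dict.fromkeys(toks[2:]))  # unique, keep order
    return sets


def write_eqtl_catalogue(catalogue: pd.DataFrame, path: str | Path) -> None:
    catalogue.to_csv(path, sep="\t", index=False)


def read_eqtl_catalogue(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "gene": str})
    required = {"snp", "gene", "effect_allele", "beta", "p", "tissue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing eQTL columns {sorted(missing)}")
    return df


def write_expression(
    expr: pd.DataFrame, groups: pd.Series, probe_map: pd.DataFrame, directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr.to_csv(directory / "expression.tsv", sep="\t", index_label="probe")
    groups.rename("group").to_csv(
        directory / "groups.tsv", sep="\t", index_label="sample"
    )
    probe_map.to_csv(directory / "probe_map.tsv", sep="\t", index=False)


def read_expression(
    directory: str | Path,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    directory = Path(directory)
    expr = pd.read_csv(directory / "expression.tsv", sep="\t", index_col="probe")
    groups = pd.read_csv(directory / "groups.tsv", sep="\t", index_col="sample")[
        "group"
    ]
    probe_map = pd.read_csv(directory / "probe_map.tsv", sep="\t")
    return expr, groups, probe_map


def write_dataset(
    directory: str | Path,
    cohort: PedigreeCohort | None = None,
    catalogue: pd.DataFrame | None = None,
    expression: tuple[pd.DataFrame, pd.Series, pd.DataFrame] | None = None,
    genes: pd.DataFrame | None = None,
    gene_sets: dict[str, list[str]] | None = None,
    binary: bool = False,
) -> dict[str, str]:
    """Write a full synthetic dataset; returns a manifest of paths."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create dataset directory {directory}: {exc}") from exc
    manifest: dict[str, str] = {}
    if cohort is not None:
        write_ped_map(cohort, directory / "cohort")
        manifest["ped"] = str(directory / "cohort.ped")
        manifest["map"] = str(directory / "cohort.map")
        if binary:
            write_bed_bim_fam(cohort, directory / "cohort")
            manifest["bed"] = str(directory / "cohort.bed")
    if catalogue is not None:
        write_eqtl_catalogue(catalogue, directory / "eqtl.tsv")
        manifest["eqtl"] = str(directory / "eqtl.tsv")
    if expression is not None:
        write_expression(*expression, directory)
        manifest["expression"] = str(directory / "expression.tsv")
    if genes is not None:
        write_gene_bed(genes, directory / "genes.bed")
        manifest["genes"] = str(directory / "genes.bed")
    if gene_sets is not None:
        write_gmt(gene_sets, directory / "gene_sets.gmt")
        manifest["gene_sets"] = str(directory / "gene_sets.gmt")
    return manifest
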