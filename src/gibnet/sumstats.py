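"""Reading, harmonizing and writing GWAS summary statistics and LD scores.

The on-disk dialect is the ldsc-style whitespace/tab-delimited text table:
mandatory columns ``SNP A1 A2 N Z``, optional ``CHR BP MAF``.  LD-score
tables carry ``CHR SNP BP L2``.  All downstream modules consume the
:class:`SumStatsPanel` produced by :func:`harmonize_panel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def _numeric(series: "pd.Series") -> "pd.Series":
    """Exact string-to-double conversion (pd.to_numeric can lose the last ulp)."""

    def conv(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return np.nan

    return series.map(conv)

_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class EmptyInputError(ValueError):
    """No usable rows survive parsing or filtering."""


@dataclass(frozen=True)
class SnpRecord:
    """One GWAS summary row: a signed Z-statistic for one SNP in one study.

    ``a1`` is the effect allele (the allele whose dose increases the
    phenotype when ``z`` is positive); ``maf`` is the minor allele
    frequency and is only needed by the per-SNP variance step of the
    latent GWAS.
    """

    snp_id: str
    a1: str
    a2: str
    n: float
    z: float
    chrom: int | None = None
    bp: int | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.a1 == self.a2:
            raise ValueError(f"{self.snp_id}: identical alleles {self.a1}/{self.a2}")
        if not self.n > 0:
            raise ValueError(f"{self.snp_id}: sample size must be positive, got {self.n}")
        if self.maf is not None and not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: MAF {self.maf} outside (0, 0.5]")
        if self.chrom is not None and not (1 <= self.chrom <= 22):
            raise ValueError(f"{self.snp_id}: chromosome {self.chrom} outside autosomes 1-22")

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.a1, self.a2}) in _PALINDROMIC


@dataclass
class SumStatsPanel:
    """Per-SNP Z-statistics aligned across P phenotypes.

    Alleles are harmonized to a single reference orientation, so ``z[j, p]``
    for every phenotype ``p`` refers to the same effect allele ``a1[j]``.
    """

    phenotype_names: list[str]
    snp_id: np.ndarray          # (M,) str
    chrom: np.ndarray           # (M,) int
    bp: np.ndarray              # (M,) int
    a1: np.ndarray              # (M,) str
    a2: np.ndarray              # (M,) str
    maf: np.ndarray             # (M,) float, NaN when unknown
    z: np.ndarray               # (M, P)
    n: np.ndarray               # (M, P)

    def __post_init__(self) -> None:
        m, p = self.z.shape
        if len(self.phenotype_names) != p:
            raise ValueError("phenotype_names does not match z columns")
        if self.n.shape != (m, p):
            raise ValueError("n and z shapes differ")
        if len(np.unique(self.snp_id)) != m:
            raise ValueError("duplicate SNP ids in panel")

    @property
    def n_snps(self) -> int:
        return self.z.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.z.shape[1]

    def index_of(self, phenotype: str) -> int:
        try:
            return self.phenotype_names.index(phenotype)
        except ValueError:
            raise KeyError(f"unknown phenotype {phenotype!r}") from None

    def column(self, phenotype: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (z, n) vectors for one phenotype."""
        j = self.index_of(phenotype)
        return self.z[:, j], self.n[:, j]

    def subset(self, mask: np.ndarray) -> "SumStatsPanel":
        return SumStatsPanel(
            phenotype_names=list(self.phenotype_names),
            snp_id=self.snp_id[mask],
            chrom=self.chrom[mask],
            bp=self.bp[mask],
            a1=self.a1[mask],
            a2=self.a2[mask],
            maf=self.maf[mask],
            z=self.z[mask],
            n=self.n[mask],
        )

    def records(self, phenotype: str) -> list[SnpRecord]:
        """Materialize one phenotype's column as SnpRecord rows."""
        j = self.index_of(phenotype)
        out = []
        for i in range(self.n_snps):
            maf = self.maf[i]
            out.append(
                SnpRecord(
                    snp_id=str(self.snp_id[i]),
                    a1=str(self.a1[i]),
                    a2=str(self.a2[i]),
                    n=float(self.n[i, j]),
                    z=float(self.z[i, j]),
                    chrom=int(self.chrom[i]),
                    bp=int(self.bp[i]),
                    maf=None if np.isnan(maf) else float(maf),
                )
            )
        return out


@dataclass
class LdScoreTable:
    """LD scores: for SNP j, l2 is the sum of r^2 with nearby SNPs (>= 1)."""

    snp_id: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    l2: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.l2 < 1.0):
            raise ValueError("LD scores below 1 (a SNP tags itself with r^2 = 1)")
        if len(np.unique(self.snp_id)) != len(self.snp_id):
            raise ValueError("duplicate SNP ids in LD-score table")

    def __len__(self) -> int:
        return len(self.snp_id)


def read_sumstats(path: str | Path, phenotype_name: str) -> list[SnpRecord]:
    """Read one phenotype's ldsc-style summary statistics file.

    Rows with non-numeric Z or N are dropped with a logged count; alleles
    are uppercased.  Raises :class:`SchemaError` when a mandatory column is
    absent and :class:`EmptyInputError` when no row parses.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    df.columns = [c.upper() for c in df.columns]
    for col in ("SNP", "A1", "A2", "N", "Z"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    n_raw = len(df)
    if n_raw == 0:
        raise EmptyInputError(f"{path}: no data rows for {phenotype_name}")
    z = _numeric(df["Z"])
    n = _numeric(df["N"])
    ok = z.notna() & n.notna()
    dropped = int((~ok).sum())
    if dropped:
        log.info("%s: dropped %d rows with non-numeric Z or N", phenotype_name, dropped)
    df = df[ok]
    if df.empty:
        raise EmptyInputError(f"{path}: zero parseable rows for {phenotype_name}")

    chrom = _numeric(df["CHR"]) if "CHR" in df else None
    bp = _numeric(df["BP"]) if "BP" in df else None
    maf = _numeric(df["MAF"]) if "MAF" in df else None

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        idx = df.index[i]
        records.append(
            SnpRecord(
                snp_id=str(row.SNP),
                a1=str(row.A1).upper(),
                a2=str(row.A2).upper(),
                n=float(n[idx]),
                z=float(z[idx]),
                chrom=None if chrom is None or pd.isna(chrom[idx]) else int(chrom[idx]),
                bp=None if bp is None or pd.isna(bp[idx]) else int(bp[idx]),
                maf=None if maf is None or pd.isna(maf[idx]) else float(maf[idx]),
            )
        )
    return records


def harmonize_panel(
    per_phenotype_records: Sequence[Sequence[SnpRecord]],
    phenotype_names: Sequence[str] | None = None,
    reference: int = 0,
) -> SumStatsPanel:
    """Align allele orientation across phenotypes and intersect SNP sets.

    The reference phenotype fixes the orientation.  A phenotype whose
    (a1, a2) equals the reference's (a2, a1) has its z sign flipped;
    strand-ambiguous palindromic SNPs (A/T, C/G) and allele sets matching
    neither orientation are dropped.  Harmonizing twice is a no-op.
    """
    n_pheno = len(per_phenotype_records)
    if n_pheno < 1:
        raise ValueError("need at least one phenotype")
    if not (0 <= reference < n_pheno):
        raise ValueError(f"reference index {reference} out of range")
    if phenotype_names is None:
        phenotype_names = [f"pheno{i + 1}" for i in range(n_pheno)]

    maps: list[dict[str, SnpRecord]] = []
    for recs in per_phenotype_records:
        seen: dict[str, SnpRecord] = {}
        dup = 0
        for r in recs:
            if r.snp_id in seen:
                dup += 1
                continue
            seen[r.snp_id] = r
        if dup:
            log.info("dropped %d duplicate rsIDs (kept first occurrence)", dup)
        maps.append(seen)

    common = [sid for sid in maps[reference] if all(sid in m for m in maps)]
    if not common:
        raise EmptyInputError("no SNPs shared across all phenotypes")

    n_palindromic = n_mismatch = n_nochrom = 0
    kept_ids, chroms, bps, a1s, a2s, mafs = [], [], [], [], [], []
    zs, ns = [], []
    for sid in common:
        ref = maps[reference][sid]
        if ref.is_palindromic:
            n_palindromic += 1
            continue
        if ref.chrom is None:
            n_nochrom += 1
            continue
        row_z = np.empty(n_pheno)
        row_n = np.empty(n_pheno)
        ok = True
        for p, m in enumerate(maps):
            r = m[sid]
            if (r.a1, r.a2) == (ref.a1, ref.a2):
                row_z[p] = r.z
            elif (r.a1, r.a2) == (ref.a2, ref.a1):
                row_z[p] = -r.z
            else:
                ok = False
                break
            row_n[p] = r.n
        if not ok:
            n_mismatch += 1
            continue
        kept_ids.append(sid)
        chroms.append(ref.chrom)
        bps.append(ref.bp if ref.bp is not None else -1)
        a1s.append(ref.a1)
        a2s.append(ref.a2)
        mafs.append(np.nan if ref.maf is None else ref.maf)
        zs.append(row_z)
        ns.append(row_n)

    if n_palindromic or n_mismatch or n_nochrom:
        log.info(
            "harmonization dropped %d palindromic, %d allele-mismatch, %d chromosome-less SNPs",
            n_palindromic, n_mismatch, n_nochrom,
        )
    if not kept_ids:
        raise EmptyInputError("harmonization removed every shared SNP")

    return SumStatsPanel(
        phenotype_names=list(phenotype_names),
        snp_id=np.array(kept_ids, dtype=object),
        chrom=np.array(chroms, dtype=int),
        bp=np.array(bps, dtype=int),
        a1=np.array(a1s, dtype=object),
        a2=np.array(a2s, dtype=object),
        maf=np.array(mafs, dtype=float),
        z=np.vstack(zs),
        n=np.vstack(ns),
    )


def qc_filter(panel: SumStatsPanel, min_n: float = 0.0, max_abs_z: float = np.inf) -> SumStatsPanel:
    """Drop SNPs failing a per-phenotype sample-size floor or |z| cap."""
    if min_n < 0 or max_abs_z <= 0:
        raise ValueError("thresholds must be positive")
    keep = (panel.n >= min_n).all(axis=1) & (np.abs(panel.z) <= max_abs_z).all(axis=1)
    removed = int((~keep).sum())
    if removed:
        log.info("qc_filter removed %d of %d SNPs", removed, panel.n_snps)
    if not keep.any():
        raise EmptyInputError("qc_filter removed every SNP")
    return panel.subset(keep)


def write_sumstats(panel: SumStatsPanel, phenotype: str, path: str | Path) -> None:
    """Write one phenotype's column in the ldsc dialect; round-trips losslessly."""
    if panel.n_snps == 0:
        raise EmptyInputError("refusing to write an empty panel")
    j = panel.index_of(phenotype)
    with open(path, "w") as fh:
        fh.write("SNP\tCHR\tBP\tA1\tA2\tMAF\tN\tZ\n")
        for i in range(panel.n_snps):
            maf = panel.maf[i]
            fh.write(
                "\t".join(
                    [
                        str(panel.snp_id[i]),
                        str(panel.chrom[i]),
                        str(panel.bp[i]),
                        str(panel.a1[i]),
                        str(panel.a2[i]),
                        "NA" if np.isnan(maf) else repr(float(maf)),
                        repr(float(panel.n[i, j])),
                        repr(float(panel.z[i, j])),
                    ]
                )
                + "\n"
            )


def read_ldscores(path: str | Path) -> LdScoreTable:
    """Read an LD-score table with columns CHR SNP BP L2."""
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    df.columns = [c.upper() for c in df.columns]
    for col in ("CHR", "SNP", "BP", "L2"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    if df.empty:
        raise EmptyInputError(f"{path}: empty LD-score table")
    return LdScoreTable(
        snp_id=df["SNP"].to_numpy(dtype=object),
        chrom=_numeric(df["CHR"]).to_numpy(dtype=int),
        bp=_numeric(df["BP"]).to_numpy(dtype=int),
        l2=_numeric(df["L2"]).to_numpy(dtype=float),
    )


def write_ldscores(table: LdScoreTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("CHR\tSNP\tBP\tL2\n")
        for i in range(len(table)):
            fh.write(
                f"{table.chrom[i]}\t{table.snp_id[i]}\t{table.bp[i]}\t{repr(float(table.l2[i]))}\n"
            )
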