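"""LD reference panels: genotype I/O, pairwise LD and P-value clumping.

The LD correlation r between two SNPs is the Pearson correlation of their
allele counts in a reference sample.  Instruments for Mendelian randomization
are selected by greedy P-value-ranked clumping: the most significant SNP
becomes an index, neighbours within a window whose r^2 with it exceeds a
threshold are discarded, and the process repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class LDError(ValueError):
    pass


@dataclass
class GenotypePanel:
    """Reference genotypes: individuals x SNPs allele counts (0/1/2, NaN missing).

    ``counts[i, j]`` is the number of copies of SNP j's ``count_allele`` carried
    by individual i.  Variant metadata rows align with the columns of ``counts``.
    """

    sample_ids: list[str]
    variants: pd.DataFrame = field(repr=False)  # snp_id, chrom, bp, count_allele, other_allele
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.sample_ids), len(self.variants)):
            raise LDError("genotype matrix shape does not match metadata")
        vals = self.counts[np.isfinite(self.counts)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise LDError("allele counts must be 0, 1, 2 or missing")
        if self.variants["snp_id"].duplicated().any():
            raise LDError("duplicate snp_id in panel")
        self.variants = self.variants.reset_index(drop=True)
        self._index = {s: j for j, s in enumerate(self.variants["snp_id"])}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def snp_ids(self) -> list[str]:
        return self.variants["snp_id"].tolist()

    def column(self, snp_id: str) -> np.ndarray:
        return self.counts[:, self._index[snp_id]]


@dataclass
class LDMatrix:
    """Symmetric SNP x SNP Pearson correlation matrix with SNP labels.

    Sign convention follows each SNP's harmonized effect allele: flipping a
    SNP's counted allele negates its row and column.
    """

    snp_ids: list[str]
    r: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise LDError("LD matrix shape does not match SNP list")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise LDError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise LDError("LD matrix diagonal must be 1")
        if np.nanmax(np.abs(self.r)) > 1.0 + 1e-8:
            raise LDError("|r| must be <= 1")
        self.r = np.asarray(self.r, float)
        self._index = {s: j for j, s in enumerate(self.snp_ids)}

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        try:
            idx = [self._index[s] for s in snp_ids]
        except KeyError as e:
            raise LDError(f"SNP {e.args[0]} not in LD matrix") from None
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)].copy())

    def corr(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam and plain-text genotype I/O
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit codes, counts of the A1 allele
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a SNP-major PLINK .bed/.bim/.fam fileset; counts the A1 allele."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        Path(str(prefix) + ".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "bp", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        Path(str(prefix) + ".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    n, m = len(fam), len(bim)
    data = Path(str(prefix) + ".bed").read_bytes()
    if data[:3] != _BED_MAGIC:
        raise LDError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(data[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * m:
        raise LDError(f"{prefix}.bed: unexpected size")
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, little-endian within a byte
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    counts = _BED_DECODE[codes.reshape(m, -1)[:, :n]].T  # individuals x SNPs
    variants = pd.DataFrame(
        {
            "snp_id": bim["snp_id"].astype(str),
            "chrom": bim["chrom"].astype(str),
            "bp": bim["bp"].astype(int),
            "count_allele": bim["a1"].astype(str).str.upper(),
            "other_allele": bim["a2"].astype(str).str.upper(),
        }
    )
    return GenotypePanel(fam["iid"].tolist(), variants, counts)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write a panel as PLINK .bed/.bim/.fam (SNP-major; A1 = counted allele)."""
    prefix = Path(prefix)
    v = panel.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"], "snp_id": v["snp_id"], "cm": 0, "bp": v["bp"],
            "a1": v["count_allele"], "a2": v["other_allele"],
        }
    )
    bim.to_csv(Path(str(prefix) + ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.sample_ids, "iid": panel.sample_ids,
            "father": 0, "mother": 0, "sex": 0, "pheno": -9,
        }
    )
    fam.to_csv(Path(str(prefix) + ".fam"), sep="\t", header=False, index=False)
    n, m = panel.counts.shape
    code = np.full((m, n), 1, dtype=np.uint8)  # 01 = missing
    g = panel.counts.T
    code[g == 2.0] = 0b00
    code[g == 1.0] = 0b10
    code[g == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        code = np.concatenate([code, np.zeros((m, pad), np.uint8)], axis=1)
    shifts = np.arange(4) * 2
    packed = (code.reshape(m, -1, 4) << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    Path(str(prefix) + ".bed").write_bytes(_BED_MAGIC + packed.tobytes())


def read_genotype_text(path: str | Path) -> GenotypePanel:
    """Read a plain-text genotype matrix: individuals x SNPs, 0/1/2, NA missing.

    First row is a header of SNP ids; optional leading ``IID`` column carries
    sample ids.  Positions default to the column order (bp = 1, 2, ...); a
    companion ``<path>.bim`` file, if present, supplies real coordinates.
    """
    path = Path(path)
    tbl = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    if tbl.columns[0].upper() in ("IID", "ID", "SAMPLE"):
        sample_ids = tbl.iloc[:, 0].astype(str).tolist()
        tbl = tbl.iloc[:, 1:]
    else:
        sample_ids = [f"i{k}" for k in range(len(tbl))]
    counts = tbl.to_numpy(float)
    bim_path = path.with_suffix(path.suffix + ".bim")
    if bim_path.exists():
        bim = pd.read_csv(
            bim_path, sep=r"\s+", header=None,
            names=["chrom", "snp_id", "cm", "bp", "a1", "a2"], dtype={"chrom": str},
        ).set_index("snp_id")
        chrom = [str(bim.loc[s, "chrom"]) for s in tbl.columns]
        bp = [int(bim.loc[s, "bp"]) for s in tbl.columns]
        a1 = [str(bim.loc[s, "a1"]) for s in tbl.columns]
        a2 = [str(bim.loc[s, "a2"]) for s in tbl.columns]
    else:
        chrom = ["1"] * len(tbl.columns)
        bp = list(range(1, len(tbl.columns) + 1))
        a1 = ["A"] * len(tbl.columns)
        a2 = ["G"] * len(tbl.columns)
    variants = pd.DataFrame(
        {"snp_id": list(tbl.columns), "chrom": chrom, "bp": bp,
         "count_allele": a1, "other_allele": a2}
    )
    return GenotypePanel(sample_ids, variants, counts)


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square LD matrix from text: header row of SNP ids, then rows of r."""
    tbl = pd.read_csv(path, sep=r"\s+")
    return LDMatrix(list(tbl.columns), tbl.to_numpy(float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, columns=ld.snp_ids).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD computation and clumping
# ---------------------------------------------------------------------------


def compute_ld(
    panel: GenotypePanel,
    snp_ids: Sequence[str] | None = None,
    effect_alleles: Mapping[str, str] | None = None,
) -> LDMatrix:
    """Pairwise Pearson correlation of allele counts from a reference panel.

    Missing genotypes are handled pairwise-complete.  If ``effect_alleles``
    maps a SNP to an allele differing from the panel's counted allele, that
    SNP's counts are reflected (2 - count) first, tying the sign of r to the
    harmonized effect alleles.
    """
    if snp_ids is None:
        snp_ids = panel.snp_ids
    missing = [s for s in snp_ids if s not in panel._index]
    if missing:
        raise LDError(f"SNP(s) not in panel: {missing[:5]}")
    cols = []
    for sid in snp_ids:
        g = panel.column(sid).astype(float).copy()
        if effect_alleles is not None:
            j = panel._index[sid]
            counted = panel.variants.loc[j, "count_allele"]
            other = panel.variants.loc[j, "other_allele"]
            want = effect_alleles.get(sid, counted)
            if want == other:
                g = 2.0 - g
            elif want != counted:
                raise LDError(f"effect allele {want} matches neither allele of {sid}")
        finite = g[np.isfinite(g)]
        if finite.size < 2 or np.nanstd(finite) == 0:
            raise LDError(f"monomorphic or empty SNP in reference: {sid}")
        cols.append(g)
    G = np.column_stack(cols)
    m = G.shape[1]
    if not np.isnan(G).any():
        r = np.corrcoef(G, rowvar=False)
        r = np.atleast_2d(r)
    else:
        r = np.eye(m)
        for i in range(m):
            for j in range(i + 1, m):
                ok = np.isfinite(G[:, i]) & np.isfinite(G[:, j])
                if ok.sum() < 2:
                    raise LDError(
                        f"fewer than 2 complete individuals for pair "
                        f"({snp_ids[i]}, {snp_ids[j]})"
                    )
                xi, xj = G[ok, i], G[ok, j]
                if xi.std() == 0 or xj.std() == 0:
                    raise LDError(f"monomorphic pairwise-complete SNP in ({snp_ids[i]}, {snp_ids[j]})")
                r[i, j] = r[j, i] = np.corrcoef(xi, xj)[0, 1]
    np.fill_diagonal(r, 1.0)
    return LDMatrix(list(snp_ids), np.clip(r, -1.0, 1.0))


def clump(
    dataset,
    ld_source: GenotypePanel | LDMatrix,
    p_thresh: float = 5e-8,
    r2_thresh: float = 0.05,
    window_kb: float = 1000.0,
) -> list[str]:
    """Greedy P-value-ranked clumping; returns index SNP ids in selection order.

    Among SNPs with p < ``p_thresh``, repeatedly take the smallest-p
    unassigned SNP as an index and discard unassigned SNPs on the same
    chromosome within +/- ``window_kb`` kb whose r^2 with it is >=
    ``r2_thresh``.  Ties in p break by smaller bp, then snp_id.  SNPs not
    covered by the LD source are dropped with a log message.
    """
    t = dataset.table
    sig = t[t["pval"] < p_thresh].copy()
    if sig.empty:
        return []
    if isinstance(ld_source, LDMatrix):
        covered = set(ld_source.snp_ids)
    else:
        covered = set(ld_source.snp_ids)
    drop = ~sig["snp_id"].isin(covered)
    if drop.any():
        logger.info("clump: %d significant SNP(s) not in LD reference, dropped", int(drop.sum()))
        sig = sig[~drop]
    if sig.empty:
        return []
    sig = sig.sort_values(["pval", "bp", "snp_id"], kind="mergesort")

    ids = sig["snp_id"].tolist()
    chrom = sig["chrom"].astype(str).tolist()
    bp = sig["bp"].astype(int).tolist()
    if isinstance(ld_source, LDMatrix):
        ld = ld_source.submatrix(ids) if set(ids) != set(ld_source.snp_ids) or ids != ld_source.snp_ids else ld_source
        def r2(i: int, j: int) -> float:
            return ld.corr(ids[i], ids[j]) ** 2
    else:
        cache: dict[tuple[int, int], float] = {}
        def r2(i: int, j: int) -> float:
            key = (min(i, j), max(i, j))
            if key not in cache:
                gi = ld_source.column(ids[i])
                gj = ld_source.column(ids[j])
                ok = np.isfinite(gi) & np.isfinite(gj)
                cache[key] = float(np.corrcoef(gi[ok], gj[ok])[0, 1]) ** 2
            return cache[key]

    window_bp = window_kb * 1000.0
    unassigned = list(range(len(ids)))
    index_snps: list[str] = []
    while unassigned:
        idx = unassigned.pop(0)  # smallest p among the unassigned
        index_snps.append(ids[idx])
        survivors = []
        for j in unassigned:
            same_chrom = chrom[j] == chrom[idx]
            near = abs(bp[j] - bp[idx]) <= window_bp
            if same_chrom and near and r2(idx, j) >= r2_thresh:
                continue
            survivors.append(j)
        unassigned = survivors
    return index_snps
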