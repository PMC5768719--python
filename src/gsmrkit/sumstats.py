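"""GWAS summary-statistic I/O, standardization, harmonization and meta-analysis.

A :class:`SummaryDataset` wraps one trait's per-SNP association records in the
GCTA-COJO ``.ma`` text dialect (columns ``SNP A1 A2 freq b se p N``).  Effects
are per-allele: SD units for quantitative traits, logOR for binary traits.
Harmonization aligns the outcome dataset's effects to the exposure's effect
alleles so per-SNP ratios b_zy/b_zx are formed on a common allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

TraitType = Literal["quantitative", "binary"]


class SumstatsError(ValueError):
    """Malformed or inconsistent summary-statistic input."""


class HarmonizationError(SumstatsError):
    """No SNPs survive allele harmonization."""


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association record for a single trait."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float
    chrom: str = ""
    bp: int = 0

    def validate(self) -> None:
        if not (0.0 < self.eaf < 1.0) and not math.isnan(self.eaf):
            raise SumstatsError(f"{self.snp_id}: eaf {self.eaf} outside (0,1)")
        if not self.se > 0:
            raise SumstatsError(f"{self.snp_id}: se {self.se} must be > 0")
        if not (0.0 < self.pval <= 1.0):
            raise SumstatsError(f"{self.snp_id}: p {self.pval} outside (0,1]")
        if self.effect_allele == self.other_allele:
            raise SumstatsError(f"{self.snp_id}: identical alleles")
        if not (self.n > 0 or math.isnan(self.n)):
            raise SumstatsError(f"{self.snp_id}: N {self.n} must be > 0")


@dataclass
class SummaryDataset:
    """Per-SNP GWAS summary statistics for one trait.

    Backed by a pandas DataFrame with columns
    ``snp_id, chrom, bp, effect_allele, other_allele, eaf, beta, se, pval, n``,
    one row per SNP, ``snp_id`` unique, row order preserved from input.
    """

    trait_name: str
    trait_type: TraitType
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        dup = self.table["snp_id"][self.table["snp_id"].duplicated()]
        if len(dup):
            raise SumstatsError(
                f"duplicate SNP id(s) in {self.trait_name}: {sorted(set(dup))[:5]}"
            )
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def subset(self, snp_ids: Sequence[str]) -> "SummaryDataset":
        keep = self.table[self.table["snp_id"].isin(set(snp_ids))]
        return SummaryDataset(self.trait_name, self.trait_type, keep.copy())

    def record(self, snp_id: str) -> SummaryRecord:
        row = self.table.loc[self.table["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(snp_id)
        r = row.iloc[0]
        return SummaryRecord(
            snp_id=r["snp_id"], effect_allele=r["effect_allele"],
            other_allele=r["other_allele"], eaf=float(r["eaf"]),
            beta=float(r["beta"]), se=float(r["se"]), pval=float(r["pval"]),
            n=float(r["n"]), chrom=str(r["chrom"]), bp=int(r["bp"]),
        )

    @classmethod
    def from_arrays(
        cls,
        trait_name: str,
        trait_type: TraitType,
        snp_id: Sequence[str],
        effect_allele: Sequence[str],
        other_allele: Sequence[str],
        eaf: Sequence[float],
        beta: Sequence[float],
        se: Sequence[float],
        pval: Sequence[float],
        n: Sequence[float],
        chrom: Sequence[str] | None = None,
        bp: Sequence[int] | None = None,
    ) -> "SummaryDataset":
        m = len(snp_id)
        tbl = pd.DataFrame(
            {
                "snp_id": list(snp_id),
                "chrom": list(chrom) if chrom is not None else ["1"] * m,
                "bp": list(bp) if bp is not None else list(range(1, m + 1)),
                "effect_allele": list(effect_allele),
                "other_allele": list(other_allele),
                "eaf": np.asarray(eaf, float),
                "beta": np.asarray(beta, float),
                "se": np.asarray(se, float),
                "pval": np.asarray(pval, float),
                "n": np.asarray(n, float),
            }
        )
        ds = cls(trait_name, trait_type, tbl)
        ds.validate()
        return ds

    def validate(self, z_p_tol: float = 0.05) -> None:
        """Check record invariants; z-vs-p consistency within rounding.

        The |z| implied by p is compared with |beta/se| on the z scale; a
        relative discrepancy above ``z_p_tol`` (on |z| > 1) raises.
        """
        t = self.table
        bad = t["se"] <= 0
        if bad.any():
            raise SumstatsError(f"non-positive se at {t.loc[bad, 'snp_id'].tolist()[:5]}")
        bad = ~((t["pval"] > 0) & (t["pval"] <= 1))
        if bad.any():
            raise SumstatsError(f"p outside (0,1] at {t.loc[bad, 'snp_id'].tolist()[:5]}")
        known_freq = t["eaf"].notna()
        bad = known_freq & ~((t["eaf"] > 0) & (t["eaf"] < 1))
        if bad.any():
            raise SumstatsError(f"eaf outside (0,1) at {t.loc[bad, 'snp_id'].tolist()[:5]}")
        bad = t["effect_allele"] == t["other_allele"]
        if bad.any():
            raise SumstatsError(f"identical alleles at {t.loc[bad, 'snp_id'].tolist()[:5]}")
        from scipy import stats

        z_obs = (t["beta"] / t["se"]).abs()
        # p floored at float-min can understate z; only check moderate z
        with np.errstate(divide="ignore"):
            z_from_p = np.abs(stats.norm.isf(t["pval"].to_numpy() / 2.0))
        checkable = (z_obs > 1.0) & (z_obs < 30.0) & np.isfinite(z_from_p)
        rel = np.abs(z_from_p - z_obs) / np.maximum(z_obs, 1.0)
        bad = checkable & (rel > z_p_tol)
        if bad.any():
            raise SumstatsError(
                "beta/se inconsistent with p at "
                f"{t.loc[bad, 'snp_id'].tolist()[:5]}"
            )


def read_ma(
    path: str | Path,
    trait_type: TraitType = "quantitative",
    trait_name: str | None = None,
    lenient: bool = False,
) -> SummaryDataset:
    """Read a GCTA-COJO ``.ma`` file (header ``SNP A1 A2 freq b se p N``).

    Extra columns are ignored; ``NA`` is treated as missing (allowed only for
    freq and N).  Malformed numeric rows fail fast unless ``lenient``, in
    which case they are skipped with a logged line number.  Optional ``chr``
    and ``bp`` columns, when present, populate coordinates.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=r"\s+", dtype=str, na_values=["NA", "na", "NaN"])
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c in MA_COLUMNS if c not in raw.columns]
    if missing:
        raise SumstatsError(f"{path.name}: missing required column(s) {missing}")
    name = trait_name or path.stem
    if raw.empty:
        logger.warning("%s: header-only file, empty dataset", path.name)
        return SummaryDataset(
            name, trait_type,
            pd.DataFrame(columns=["snp_id", "chrom", "bp", "effect_allele",
                                  "other_allele", "eaf", "beta", "se", "pval", "n"]),
        )

    def col(num_name: str, required: bool) -> np.ndarray:
        s = pd.to_numeric(raw[num_name], errors="coerce")
        if required:
            bad = s.isna() & raw[num_name].notna() | raw[num_name].isna()
            if bad.any():
                lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based + header
                if not lenient:
                    raise SumstatsError(
                        f"{path.name}: non-numeric {num_name} at line(s) {lines[:5]}"
                    )
                logger.warning("%s: skipping %d malformed row(s) at lines %s",
                               path.name, int(bad.sum()), lines[:5])
        return s.to_numpy(float)

    b = col("b", True)
    se = col("se", True)
    p = col("p", True)
    freq = col("freq", False)
    n = col("N", False)
    tbl = pd.DataFrame(
        {
            "snp_id": raw["SNP"].astype(str),
            "chrom": raw["chr"].astype(str) if "chr" in raw.columns else "0",
            "bp": pd.to_numeric(raw["bp"], errors="coerce").fillna(0).astype(int)
            if "bp" in raw.columns else 0,
            "effect_allele": raw["A1"].astype(str).str.upper(),
            "other_allele": raw["A2"].astype(str).str.upper(),
            "eaf": freq,
            "beta": b,
            "se": se,
            "pval": p,
            "n": n,
        }
    )
    if lenient:
        ok = np.isfinite(b) & np.isfinite(se) & np.isfinite(p)
        tbl = tbl[ok]
    if tbl["eaf"].isna().any() or tbl["n"].isna().any():
        logger.warning(
            "%s: %d row(s) missing freq/N; SD-unit standardization unavailable there",
            path.name, int((tbl["eaf"].isna() | tbl["n"].isna()).sum()),
        )
    ds = SummaryDataset(name, trait_type, tbl)
    ds.validate()
    return ds


def write_ma(dataset: SummaryDataset, path: str | Path) -> None:
    """Write a dataset in ``.ma`` format (tab-delimited, NA for missing)."""
    t = dataset.table
    out = pd.DataFrame(
        {
            "SNP": t["snp_id"],
            "A1": t["effect_allele"],
            "A2": t["other_allele"],
            "freq": t["eaf"],
            "b": t["beta"],
            "se": t["se"],
            "p": t["pval"],
            "N": t["n"],
            "chr": t["chrom"],
            "bp": t["bp"],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def standardize_from_z(
    z: float | np.ndarray, eaf: float | np.ndarray, n: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a z-statistic to an SD-unit effect and SE.

    beta = z / sqrt(2p(1-p)(n + z^2)),  se = 1 / sqrt(2p(1-p)(n + z^2)),
    with p the effect-allele frequency and n the sample size, so that
    beta/se reproduces z exactly.
    """
    z = np.asarray(z, float)
    eaf = np.asarray(eaf, float)
    n = np.asarray(n, float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise SumstatsError("eaf must lie strictly inside (0,1)")
    if np.any(n <= 0):
        raise SumstatsError("n must be > 0")
    denom = np.sqrt(2.0 * eaf * (1.0 - eaf) * (n + z**2))
    return z / denom, 1.0 / denom


def ivw_meta(
    b1: float | np.ndarray, se1: float | np.ndarray,
    b2: float | np.ndarray, se2: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-effect inverse-variance meta-analysis of two estimates."""
    b1, se1, b2, se2 = (np.asarray(v, float) for v in (b1, se1, b2, se2))
    if np.any(se1 <= 0) or np.any(se2 <= 0):
        raise SumstatsError("standard errors must be > 0")
    w1, w2 = 1.0 / se1**2, 1.0 / se2**2
    return (b1 * w1 + b2 * w2) / (w1 + w2), 1.0 / np.sqrt(w1 + w2)


@dataclass
class HarmonizedInstrumentSet:
    """Allele-aligned exposure and outcome effects for selected instruments.

    One row per SNP: exposure effect ``bzx`` and outcome effect ``bzy`` both
    refer to ``effect_allele``.  This is the unit of input to the GSMR and
    HEIDI estimators.
    """

    table: pd.DataFrame = field(repr=False)
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    COLUMNS = ["snp_id", "chrom", "bp", "effect_allele", "eaf",
               "bzx", "se_bzx", "p_zx", "bzy", "se_bzy", "p_zy", "n_x", "n_y"]

    def __post_init__(self) -> None:
        if self.table["snp_id"].duplicated().any():
            raise SumstatsError("duplicate snp_id in harmonized set")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def arrays(self) -> dict[str, np.ndarray]:
        t = self.table
        return {k: t[k].to_numpy() for k in ("bzx", "se_bzx", "bzy", "se_bzy", "p_zx")}

    def subset(self, snp_ids: Iterable[str]) -> "HarmonizedInstrumentSet":
        keep = set(snp_ids)
        return HarmonizedInstrumentSet(
            self.table[self.table["snp_id"].isin(keep)].copy(),
            self.exposure_name, self.outcome_name,
        )


def _is_palindromic(a1: str, a2: str) -> bool:
    return (a1, a2) in _PALINDROMIC_PAIRS


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    snp_ids: Sequence[str] | None = None,
    keep_palindromic: bool = False,
    palindrome_maf_limit: float = 0.4,
    freq_diff_max: float = 0.2,
    p_zx_max: float | None = None,
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect alleles.

    For each SNP present in both datasets the outcome record is matched to
    the exposure's allele pair directly or on the complementary strand; a
    swapped A1/A2 match flips the sign of ``bzy`` (and reflects eaf).
    Palindromic (A/T, C/G) SNPs cannot be strand-resolved: by default they
    are aligned by allele frequency when informative (min(eaf, 1-eaf) <=
    ``palindrome_maf_limit``) and dropped otherwise; ``keep_palindromic``
    retains frequency-ambiguous ones as-coded with a warning.  SNPs whose
    allele pairs are irreconcilable are dropped.  A post-alignment effect
    allele frequency difference above ``freq_diff_max`` triggers a warning
    (possible strand error).
    """
    if snp_ids is None:
        snp_ids = exposure.snp_ids
    exp_t = exposure.table.set_index("snp_id")
    out_t = outcome.table.set_index("snp_id")
    common = [s for s in snp_ids if s in exp_t.index and s in out_t.index]
    dropped_absent = len(snp_ids) - len(common)
    if dropped_absent:
        logger.info("harmonize: %d requested SNP(s) absent from one dataset", dropped_absent)

    rows = []
    n_flipped = n_pal_dropped = n_irrec = n_freq_warn = 0
    for sid in common:
        e = exp_t.loc[sid]
        o = out_t.loc[sid]
        ea1, ea2 = e["effect_allele"], e["other_allele"]
        oa1, oa2 = o["effect_allele"], o["other_allele"]
        bzy, eaf_y = float(o["beta"]), float(o["eaf"])
        palindromic = _is_palindromic(ea1, ea2)

        if (oa1, oa2) == (ea1, ea2):
            flip = False
        elif (oa1, oa2) == (ea2, ea1):
            flip = True
        elif not palindromic and (
            (_COMPLEMENT.get(oa1), _COMPLEMENT.get(oa2)) == (ea1, ea2)
        ):
            flip = False
        elif not palindromic and (
            (_COMPLEMENT.get(oa1), _COMPLEMENT.get(oa2)) == (ea2, ea1)
        ):
            flip = True
        else:
            n_irrec += 1
            continue

        if palindromic:
            maf = min(e["eaf"], 1.0 - e["eaf"]) if np.isfinite(e["eaf"]) else np.nan
            if not np.isfinite(maf) or maf > palindrome_maf_limit:
                if not keep_palindromic:
                    n_pal_dropped += 1
                    continue
                logger.warning("harmonize: retaining frequency-ambiguous palindromic SNP %s", sid)
            else:
                # strand unknowable from letters; align by frequency instead
                eaf_aligned = 1.0 - eaf_y if flip else eaf_y
                if np.isfinite(eaf_aligned) and (
                    (e["eaf"] - 0.5) * (eaf_aligned - 0.5) < 0
                ):
                    flip = not flip

        if flip:
            bzy = -bzy
            eaf_y = 1.0 - eaf_y
        if (
            np.isfinite(e["eaf"]) and np.isfinite(eaf_y)
            and abs(e["eaf"] - eaf_y) > freq_diff_max
        ):
            n_freq_warn += 1
            logger.warning(
                "harmonize: |eaf difference| %.2f > %.2f at %s",
                abs(e["eaf"] - eaf_y), freq_diff_max, sid,
            )
        n_flipped += int(flip)
        rows.append(
            {
                "snp_id": sid, "chrom": e["chrom"], "bp": int(e["bp"]),
                "effect_allele": ea1, "eaf": float(e["eaf"]),
                "bzx": float(e["beta"]), "se_bzx": float(e["se"]), "p_zx": float(e["pval"]),
                "bzy": bzy, "se_bzy": float(o["se"]), "p_zy": float(o["pval"]),
                "n_x": float(e["n"]), "n_y": float(o["n"]),
            }
        )
    logger.info(
        "harmonize: %d SNPs aligned (%d sign-flipped, %d palindromic dropped, "
        "%d irreconcilable)", len(rows), n_flipped, n_pal_dropped, n_irrec,
    )
    if not rows:
        raise HarmonizationError("no SNPs survive harmonization")
    tbl = pd.DataFrame(rows)
    if p_zx_max is not None:
        tbl = tbl[tbl["p_zx"] <= p_zx_max].reset_index(drop=True)
        if tbl.empty:
            raise HarmonizationError("no SNPs below the instrument p threshold")
    return HarmonizedInstrumentSet(tbl, exposure.trait_name, outcome.trait_name)


def write_harmonized(inst: HarmonizedInstrumentSet, path: str | Path) -> None:
    inst.table.to_csv(path, sep="\t", index=False, na_rep="NA")
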