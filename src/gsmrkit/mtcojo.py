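"""mtCOJO: multi-trait conditional GWAS from summary data.

Adjusts a target trait's per-SNP effects for the genetic values of t covariate
traits without individual-level data.  The marginal covariate-on-target
effects beta_xy (estimated by GSMR) are converted to joint effects

    b_xy = D^{-1/2} R_x^{-1} D^{1/2} beta_xy,

with D = diag(h2_SNP) and R_x the genetic-correlation matrix, and each SNP's
effect on the target is replaced by

    b_adj = b_zy - b_zx' b_xy,
    var(b_adj) = var(b_zy) + b_xy' V_zx b_xy - 2 b_xy' cov(b_zy, b_zx),

where V_zx and the covariance vector are assembled from the covariates'
standard errors and bivariate-LDSC intercepts (the product of sample-overlap
fraction and phenotypic correlation).  With no sample overlap the variance
reduces to var(b_zy) + b_xy' V_zx b_xy; with full same-sample overlap to
var(b_zy) - b_xy' V_zx b_xy.  The conditional test is T = b_adj^2 /
var(b_adj) on chi^2(1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .sumstats import SummaryDataset

logger = logging.getLogger(__name__)


class MtcojoError(ValueError):
    pass


@dataclass
class MtcojoInputs:
    """Externally estimated quantities the conditional adjustment consumes.

    h2: SNP-based heritability per covariate (diagonal of D).
    rg: t x t genetic-correlation matrix between covariates (R_x).
    beta_xy_marginal: marginal covariate-on-target effects (from GSMR).
    c_xy: target-covariate overlap intercepts rho * r_p (bivariate LDSC).
    c_xx: t x t covariate-covariate overlap intercepts (unit diagonal).
    """

    covariate_names: list[str]
    beta_xy_marginal: np.ndarray
    rg: np.ndarray
    h2: np.ndarray
    c_xy: np.ndarray | None = None
    c_xx: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = len(self.covariate_names)
        self.beta_xy_marginal = np.asarray(self.beta_xy_marginal, float)
        self.rg = np.atleast_2d(np.asarray(self.rg, float))
        self.h2 = np.asarray(self.h2, float)
        if self.c_xy is None:
            self.c_xy = np.zeros(t)
        self.c_xy = np.asarray(self.c_xy, float)
        if self.c_xx is None:
            self.c_xx = np.eye(t)
        self.c_xx = np.atleast_2d(np.asarray(self.c_xx, float))
        if self.beta_xy_marginal.shape != (t,) or self.h2.shape != (t,):
            raise MtcojoError("beta_xy/h2 length must match covariate count")
        if self.rg.shape != (t, t) or self.c_xx.shape != (t, t):
            raise MtcojoError("Rx and C_xx must be t x t")
        if not np.allclose(self.rg, self.rg.T) or not np.allclose(np.diag(self.rg), 1.0):
            raise MtcojoError("Rx must be symmetric with unit diagonal")
        if np.any(np.abs(self.rg) > 1 + 1e-9):
            raise MtcojoError("|genetic correlations| must be <= 1")
        if np.any((self.h2 <= 0) | (self.h2 > 1)):
            raise MtcojoError("h2 must lie in (0, 1]")
        if not np.allclose(self.c_xx, self.c_xx.T) or not np.allclose(np.diag(self.c_xx), 1.0):
            raise MtcojoError("C_xx must be symmetric with unit diagonal")
        if np.any(np.abs(self.c_xy) > 1 + 1e-9) or np.any(np.abs(self.c_xx) > 1 + 1e-9):
            raise MtcojoError("|overlap intercepts| must be <= 1")
        big = np.abs(self.rg - np.eye(t)) > 0.9
        if big.any():
            i, j = np.argwhere(big)[0]
            logger.warning(
                "near-collinear covariates %s and %s (|rg| > 0.9); risk of over-correction",
                self.covariate_names[i], self.covariate_names[j],
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MtcojoInputs":
        """Load covariate metadata from a YAML config.

        Keys: ``covariates`` (names, order-defining), ``h2``, ``rg``,
        ``beta_xy`` and optional ``c_xy``, ``c_xx``.
        """
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(
            covariate_names=list(cfg["covariates"]),
            beta_xy_marginal=np.asarray(cfg["beta_xy"], float),
            rg=np.asarray(cfg["rg"], float),
            h2=np.asarray(cfg["h2"], float),
            c_xy=np.asarray(cfg["c_xy"], float) if "c_xy" in cfg else None,
            c_xx=np.asarray(cfg["c_xx"], float) if "c_xx" in cfg else None,
        )


def marginal_to_joint(
    beta_xy: Sequence[float], rx: np.ndarray, h2: Sequence[float]
) -> np.ndarray:
    """Convert marginal covariate-on-target effects to joint effects.

    b = D^{-1/2} R_x^{-1} D^{1/2} beta with D = diag(h2).  Identity when
    R_x = I or t = 1 (the scale factors cancel).
    """
    beta = np.asarray(beta_xy, float)
    h2 = np.asarray(h2, float)
    rx = np.atleast_2d(np.asarray(rx, float))
    if np.any(h2 <= 0):
        raise MtcojoError("h2 must be > 0")
    t = len(beta)
    cond = np.linalg.cond(rx)
    if cond > 1e10:
        off = np.abs(rx - np.eye(t))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise MtcojoError(
            f"Rx is numerically singular (condition {cond:.1e}); "
            f"near-collinear covariate pair indices ({i}, {j}) with rg={rx[i, j]:.3f}"
        )
    d_sqrt = np.sqrt(h2)
    return (1.0 / d_sqrt) * np.linalg.solve(rx, d_sqrt * beta)


def conditional_effect(
    b_zy: float | np.ndarray, b_zx: np.ndarray, b_xy: np.ndarray
) -> np.ndarray:
    """Per-SNP conditional effect: b_adj = b_zy - sum_i b_zx(i) b_xy(i).

    ``b_zx`` may be a t-vector (one SNP) or an (n_snps, t) matrix.
    """
    b_zx = np.asarray(b_zx, float)
    b_xy = np.asarray(b_xy, float)
    if b_zx.ndim == 1:
        if b_zx.shape != b_xy.shape:
            raise MtcojoError("b_zx and b_xy length mismatch")
        return np.asarray(b_zy, float) - float(b_zx @ b_xy)
    if b_zx.shape[1] != b_xy.shape[0]:
        raise MtcojoError("b_zx columns must match b_xy length")
    return np.asarray(b_zy, float) - b_zx @ b_xy


def overlap_cov(
    se_a: float | np.ndarray, se_b: float | np.ndarray, intercept_c: float
) -> np.ndarray:
    """Sampling covariance between two traits' SNP effects from sample overlap.

    cov = c * se_a * se_b with c = rho * r_p, the bivariate-LDSC intercept
    (overlap fraction times phenotypic correlation).
    """
    if abs(intercept_c) > 1 + 1e-12:
        raise MtcojoError(f"|overlap intercept| must be <= 1, got {intercept_c}")
    se_a = np.asarray(se_a, float)
    se_b = np.asarray(se_b, float)
    if np.any(se_a <= 0) or np.any(se_b <= 0):
        raise MtcojoError("standard errors must be > 0")
    out = intercept_c * se_a * se_b
    return float(out) if out.ndim == 0 else out


def conditional_variance(
    var_zy: float,
    b_xy: np.ndarray,
    v_zx: np.ndarray,
    cov_vec: np.ndarray | None = None,
) -> float:
    """Sampling variance of the conditional SNP effect.

    var(b_adj) = var(b_zy) + b_xy' V_zx b_xy - 2 b_xy' cov(b_zy, b_zx).
    """
    b_xy = np.asarray(b_xy, float)
    v_zx = np.atleast_2d(np.asarray(v_zx, float))
    if cov_vec is None:
        cov_vec = np.zeros_like(b_xy)
    cov_vec = np.asarray(cov_vec, float)
    if not np.allclose(v_zx, v_zx.T):
        raise MtcojoError("V_zx must be symmetric")
    out = float(var_zy + b_xy @ v_zx @ b_xy - 2.0 * b_xy @ cov_vec)
    if out <= 0:
        raise MtcojoError(
            f"non-positive conditional variance ({out:.3e}); "
            "overlap intercepts are inconsistent with the SEs"
        )
    return out


def run_mtcojo(
    target: SummaryDataset,
    covariates: Sequence[SummaryDataset],
    inputs: MtcojoInputs,
    min_coverage: float = 0.8,
) -> SummaryDataset:
    """Adjust every target SNP for the covariates' genetic values.

    SNPs missing from any covariate dataset are skipped with a log message
    (no zero-imputation); coverage below ``min_coverage`` triggers a warning.
    Returned dataset carries (b_adj, se_adj, p_adj) with the target's alleles,
    frequencies and sample sizes; covariate effects are aligned to the
    target's effect allele per SNP before adjustment.
    """
    t = len(covariates)
    if t != len(inputs.covariate_names):
        raise MtcojoError(
            f"{t} covariate dataset(s) but config lists {len(inputs.covariate_names)}"
        )
    b_joint = marginal_to_joint(inputs.beta_xy_marginal, inputs.rg, inputs.h2)
    _warn_if_unstandardized(covariates)

    cov_tables = [c.table.set_index("snp_id") for c in covariates]
    rows = []
    n_skipped = 0
    for _, snp in target.table.iterrows():
        sid = snp["snp_id"]
        b_zx = np.empty(t)
        se_zx = np.empty(t)
        ok = True
        for k, ct in enumerate(cov_tables):
            if sid not in ct.index:
                ok = False
                break
            c = ct.loc[sid]
            sign = _allele_sign(snp, c)
            if sign == 0:
                ok = False
                break
            b_zx[k] = sign * c["beta"]
            se_zx[k] = c["se"]
        if not ok:
            n_skipped += 1
            continue
        b_adj = float(conditional_effect(snp["beta"], b_zx, b_joint))
        v_zx = inputs.c_xx * np.outer(se_zx, se_zx)  # unit diagonal -> variances
        cov_vec = inputs.c_xy * se_zx * snp["se"]
        var_adj = conditional_variance(snp["se"] ** 2, b_joint, v_zx, cov_vec)
        se_adj = float(np.sqrt(var_adj))
        p_adj = float(stats.chi2.sf(b_adj**2 / var_adj, df=1))
        rows.append(
            {
                "snp_id": sid, "chrom": snp["chrom"], "bp": snp["bp"],
                "effect_allele": snp["effect_allele"],
                "other_allele": snp["other_allele"], "eaf": snp["eaf"],
                "beta": b_adj, "se": se_adj, "pval": max(p_adj, 5e-324),
                "n": snp["n"],
            }
        )
    if n_skipped:
        logger.info("mtCOJO: %d SNP(s) skipped for incomplete covariate coverage", n_skipped)
    coverage = len(rows) / max(len(target.table), 1)
    if coverage < min_coverage:
        logger.warning(
            "mtCOJO: covariate coverage %.1f%% below %.0f%%",
            100 * coverage, 100 * min_coverage,
        )
    if not rows:
        raise MtcojoError("no target SNP has complete covariate coverage")
    return SummaryDataset(
        f"{target.trait_name}_adj", target.trait_type, pd.DataFrame(rows)
    )


def _allele_sign(target_row, cov_row) -> int:
    """+1 if the covariate effect is on the target's effect allele, -1 if on
    the other allele, 0 if the allele pairs are irreconcilable."""
    ta1, ta2 = target_row["effect_allele"], target_row["other_allele"]
    ca1, ca2 = cov_row["effect_allele"], cov_row["other_allele"]
    if (ca1, ca2) == (ta1, ta2):
        return 1
    if (ca1, ca2) == (ta2, ta1):
        return -1
    return 0


def _warn_if_unstandardized(covariates: Sequence[SummaryDataset]) -> None:
    """The derivation assumes covariates in SD units; flag likely violations.

    For a standardized trait se ~ 1/sqrt(2p(1-p)n), so the median of
    |b| sqrt(2p(1-p)n) should be close to the median |z|.
    """
    for ds in covariates:
        tt = ds.table
        finite = tt["eaf"].notna() & tt["n"].notna()
        if not finite.any():
            continue
        s = tt[finite]
        implied = (s["beta"].abs() * np.sqrt(2 * s["eaf"] * (1 - s["eaf"]) * s["n"])).median()
        z = (s["beta"] / s["se"]).abs().median()
        if z > 0 and not (0.2 < implied / z < 5.0):
            logger.warning(
                "covariate %s betas look unstandardized (implied/actual median |z| = %.2f)",
                ds.trait_name, implied / z,
            )
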