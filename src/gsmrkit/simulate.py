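"""Synthetic GWAS data with known causal structure.

Two generation paths feed the estimators:

* an individual-level path — genotypes with block LD, exposure/outcome
  phenotypes under a causal model with optional pleiotropy and reverse
  causation, and per-SNP association scans on two disjoint samples
  (the two-sample design); and
* a fast direct-sampling path — per-SNP effect estimates drawn from their
  asymptotic sampling distribution N(b_marginal, S R S), with S the diagonal
  of per-SNP standard errors 1/sqrt(2p(1-p)n) and R the LD correlation,
  exposure and outcome draws independent.

Ground truth (per-SNP effects, pleiotropic SNPs, the causal effect b_xy) is
recorded before noise so parameter recovery can be asserted exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldref import GenotypePanel, LDMatrix
from .sumstats import HarmonizedInstrumentSet, SummaryDataset

logger = logging.getLogger(__name__)

_ALLELES = ("A", "G")  # non-palindromic coding for all simulated SNPs


class SimError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated two-sample MR scenario.

    Defaults describe the reference scenario: m = 50 instruments each
    explaining 0.1% of exposure variance (5% in total), MAF uniform on
    (0.05, 0.5), independent instruments (block size 1), 50,000 individuals
    per sample, quantitative outcome, no pleiotropy, no reverse effect.
    """

    n_exposure: int = 50_000
    n_outcome: int = 50_000
    m: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_r: float = 0.0
    per_snp_h2: float = 0.001  # exposure variance explained per instrument
    b_xy_true: float = 0.0
    n_pleiotropic: int = 0
    pleiotropy_sd: float = 0.1  # SD of direct standardized effects on the outcome
    outcome_type: Literal["quantitative", "binary"] = "quantitative"
    prevalence: float = 0.1
    binary_model: Literal["logistic", "liability"] = "logistic"
    reverse_b: float = 0.0
    m_outcome: int = 0  # instruments acting directly on the outcome (reverse design)
    per_snp_h2_outcome: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise SimError("sample sizes must be > 0")
        if not (0 < self.prevalence < 1):
            raise SimError("prevalence must lie in (0,1)")
        if not (abs(self.ld_r) < 1):
            raise SimError("|within-block r| must be < 1")
        if self.ld_block_size < 1 or self.m < 1:
            raise SimError("m and block size must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5 + 1e-12):
            raise SimError("maf range must satisfy 0 < lo <= hi <= 0.5")
        h2 = self.per_snp_h2 * self.m
        if not (0 < h2 < 1):
            raise SimError(f"total instrument heritability {h2:.3f} outside (0,1)")


@dataclass
class SimTruth:
    """Ground truth recorded before sampling noise."""

    snp_ids: list[str]
    chrom: list[str]
    bp: list[int]
    maf: np.ndarray
    bzx: np.ndarray  # per-allele effects on the exposure, SD units
    bzy_direct: np.ndarray  # per-allele direct (pleiotropic/outcome-instrument) effects
    pleiotropic_ids: list[str]
    b_xy_true: float
    h2_x: float
    seed: int
    config: SimConfig | None = field(default=None, repr=False)


def _snp_positions(m: int, block_size: int) -> tuple[list[str], list[int]]:
    """Place blocks 10 Mb apart, SNPs within a block 10 kb apart."""
    ids, bp = [], []
    for j in range(m):
        block, within = divmod(j, block_size)
        ids.append(f"rs{j + 1}")
        bp.append(block * 10_000_000 + within * 10_000 + 1)
    return ids, bp


def make_truth(config: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Draw the true per-SNP effects for a scenario.

    Per-instrument explained variances are drawn from a unit-mean lognormal
    (sigma = 1) scaled by ``per_snp_h2`` — the heavy-tailed shape of real
    GWAS hit effect sizes, where a few loci dominate — with random sign,
    then converted to per-allele SD-unit effects; pleiotropic SNPs receive
    direct standardized outcome effects ~ N(0, pleiotropy_sd^2);
    outcome-only instruments (for reverse designs) follow the same recipe
    on the outcome.
    """
    rng = rng or np.random.default_rng(config.seed)
    m_total = config.m + config.m_outcome
    maf = rng.uniform(*config.maf_range, size=m_total)
    ids, bp = _snp_positions(m_total, config.ld_block_size)

    q2 = rng.lognormal(-0.5, 1.0, size=config.m) * config.per_snp_h2
    w = np.sqrt(q2) * rng.choice([-1.0, 1.0], size=config.m)  # standardized effects
    bzx = np.zeros(m_total)
    bzx[: config.m] = w / np.sqrt(2 * maf[: config.m] * (1 - maf[: config.m]))

    bzy_direct = np.zeros(m_total)
    pleio_ids: list[str] = []
    if config.n_pleiotropic:
        if config.n_pleiotropic > config.m:
            raise SimError("more pleiotropic SNPs than instruments")
        pick = rng.choice(config.m, size=config.n_pleiotropic, replace=False)
        wd = rng.normal(0.0, config.pleiotropy_sd, size=config.n_pleiotropic)
        bzy_direct[pick] = wd / np.sqrt(2 * maf[pick] * (1 - maf[pick]))
        pleio_ids = [ids[i] for i in sorted(pick)]
    if config.m_outcome:
        q2y = rng.lognormal(-0.5, 1.0, size=config.m_outcome) * config.per_snp_h2_outcome
        wy = np.sqrt(q2y) * rng.choice([-1.0, 1.0], size=config.m_outcome)
        sl = slice(config.m, m_total)
        bzy_direct[sl] = wy / np.sqrt(2 * maf[sl] * (1 - maf[sl]))

    if np.sum(q2) >= 1.0:
        raise SimError(f"realized instrument heritability {np.sum(q2):.2f} >= 1")
    return SimTruth(
        snp_ids=ids, chrom=["1"] * m_total, bp=bp, maf=maf, bzx=bzx,
        bzy_direct=bzy_direct, pleiotropic_ids=pleio_ids,
        b_xy_true=config.b_xy_true, h2_x=float(np.sum(q2)),
        seed=config.seed, config=config,
    )


def ld_matrix_from_config(truth: SimTruth) -> LDMatrix:
    """Block compound-symmetric LD implied by the scenario's ld_spec."""
    cfg = truth.config
    m = len(truth.snp_ids)
    r = np.eye(m)
    if cfg is not None and cfg.ld_block_size > 1 and cfg.ld_r != 0.0:
        for start in range(0, m, cfg.ld_block_size):
            stop = min(start + cfg.ld_block_size, m)
            r[start:stop, start:stop] = cfg.ld_r
        np.fill_diagonal(r, 1.0)
    return LDMatrix(list(truth.snp_ids), r)


# ---------------------------------------------------------------------------
# Individual-level path
# ---------------------------------------------------------------------------


def _tetrachoric_r(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation giving binary (haplotype) correlation target_r."""
    if target_r == 0.0:
        return 0.0
    tau = stats.norm.isf(maf)

    def gap(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [-tau, -tau], mean=[0, 0], cov=[[1, rho], [rho, 1]]
        )
        return (p11 - maf**2) / (maf * (1 - maf)) - target_r

    lo, hi = (-0.999, 0.0) if target_r < 0 else (0.0, 0.999)
    try:
        return float(optimize.brentq(gap, lo, hi, xtol=1e-6))
    except ValueError:
        raise SimError(
            f"infeasible LD r={target_r} at MAF {maf:.3f} (no latent correlation attains it)"
        )


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_size: int = 1,
    ld_r: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> GenotypePanel:
    """Hardy-Weinberg genotypes with compound-symmetric LD blocks.

    Each gamete's alleles within a block come from thresholding a latent
    one-factor Gaussian whose correlation is calibrated (tetrachorically) so
    the realized allele-count correlation matches ``ld_r``; blocks are
    mutually independent and share one MAF per block (drawn from
    ``maf_range``), as LD blocks of a common ancestry do.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.empty((n, m))
    mafs = np.empty(m)
    for start in range(0, m, ld_block_size):
        stop = min(start + ld_block_size, m)
        k = stop - start
        maf = rng.uniform(*maf_range)
        mafs[start:stop] = maf
        if k > 1 and ld_r != 0.0:
            lat = _tetrachoric_r(ld_r, maf)
            cs = np.full((k, k), lat)
            np.fill_diagonal(cs, 1.0)
            try:
                chol = np.linalg.cholesky(cs)
            except np.linalg.LinAlgError:
                raise SimError(
                    f"infeasible block correlation r={ld_r} for block size {k}"
                )
            tau = stats.norm.isf(maf)
            g = np.zeros((n, k))
            for _ in range(2):  # two independent gametes
                latent = rng.standard_normal((n, k)) @ chol.T
                g += (latent > tau).astype(float)
            counts[:, start:stop] = g
        else:
            counts[:, start:stop] = rng.binomial(2, maf, size=(n, k)).astype(float)
    ids, bp = _snp_positions(m, ld_block_size)
    variants = pd.DataFrame(
        {
            "snp_id": ids, "chrom": "1", "bp": bp,
            "count_allele": _ALLELES[0], "other_allele": _ALLELES[1],
        }
    )
    return GenotypePanel([f"i{k}" for k in range(n)], variants, counts)


def simulate_traits(
    panel: GenotypePanel, config: SimConfig, truth: SimTruth | None = None,
    rng: np.random.Generator | None = None,
    two_sample: bool = True,
) -> tuple[np.ndarray, np.ndarray, SimTruth]:
    """Exposure and outcome phenotypes on two disjoint samples.

    x = Z b_zx + e_x (unit total variance); quantitative
    y = b_xy x + Z d + e_y; a binary y is drawn from a logistic model on the
    same linear predictor with the intercept calibrated to the target
    prevalence (or from a liability threshold under the alternative model).
    A nonzero reverse effect c (outcome -> exposure) is handled by solving
    the simultaneous system x = g_x + c y + e_x, y = b x + g_y + e_y.

    Returns full-length phenotype vectors with NaN outside each trait's
    sample: the first ``n_exposure`` individuals form the exposure sample and
    the rest the outcome sample.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    if truth is None:
        truth = make_truth(config, np.random.default_rng(config.seed))
    n = panel.n_samples
    if n < config.n_exposure + config.n_outcome:
        raise SimError(
            f"panel has {n} individuals; need n_exposure + n_outcome = "
            f"{config.n_exposure + config.n_outcome}"
        )
    Z = panel.counts
    # re-express the standardized effects on the panel's realized genotype
    # scale, so heritabilities are exact whatever MAFs the panel drew
    scale_truth = np.sqrt(2.0 * truth.maf * (1.0 - truth.maf))
    sd_panel = Z.std(axis=0)
    if np.any(sd_panel == 0):
        raise SimError("monomorphic SNP in panel; cannot place effects")
    truth.bzx = truth.bzx * scale_truth / sd_panel
    truth.bzy_direct = truth.bzy_direct * scale_truth / sd_panel
    truth.maf = Z.mean(axis=0) / 2.0
    gx = Z @ truth.bzx
    gy_direct = Z @ truth.bzy_direct
    h2 = truth.h2_x
    if not (0 < h2 < 1):
        raise SimError(f"infeasible exposure heritability {h2:.3f}")
    ex = rng.normal(0.0, math.sqrt(1.0 - h2), size=n)
    b, c = config.b_xy_true, config.reverse_b

    if config.outcome_type == "quantitative":
        var_gy = float(np.var(gy_direct)) if np.any(truth.bzy_direct) else 0.0
        var_ey = max(1.0 - var_gy, 0.1)
        ey = rng.normal(0.0, math.sqrt(var_ey), size=n)
        det = 1.0 - b * c
        if abs(det) < 1e-9:
            raise SimError("b_xy * reverse_b = 1: degenerate feedback loop")
        # solve x = gx + c y + ex ; y = b x + gy + ey
        x = (gx + ex + c * (gy_direct + ey)) / det
        y = (b * (gx + ex) + gy_direct + ey) / det
    else:
        if c != 0.0:
            raise SimError("reverse effects are only supported for quantitative outcomes")
        x = gx + ex
        eta = b * x + gy_direct
        if config.binary_model == "logistic":
            alpha = _calibrate_intercept(eta, config.prevalence)
            y = (rng.uniform(size=n) < _sigmoid(alpha + eta)).astype(float)
        else:
            liab = eta + rng.normal(0.0, 1.0, size=n)
            thresh = np.quantile(liab, 1.0 - config.prevalence)
            y = (liab > thresh).astype(float)

    if not two_sample:  # full unmasked vectors, e.g. for oracle regressions
        return x, y, truth
    x_out = np.full(n, np.nan)
    y_out = np.full(n, np.nan)
    x_out[: config.n_exposure] = x[: config.n_exposure]
    y_out[config.n_exposure : config.n_exposure + config.n_outcome] = y[
        config.n_exposure : config.n_exposure + config.n_outcome
    ]
    return x_out, y_out, truth


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    def gap(a: float) -> float:
        return float(np.mean(_sigmoid(a + eta))) - prevalence

    return float(optimize.brentq(gap, -30.0, 30.0))


def gwas_scan(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    binary: bool = False,
    trait_name: str = "trait",
) -> SummaryDataset:
    """Per-SNP association scan: simple linear or logistic regression of the
    phenotype on allele count.  Individuals with missing phenotype or
    genotype are excluded per SNP; monomorphic SNPs are dropped with a log
    message.  Effects are reported on the panel's counted allele."""
    y_all = np.asarray(phenotype, float)
    rows = []
    v = panel.variants
    for j, sid in enumerate(panel.snp_ids):
        g = panel.counts[:, j]
        ok = np.isfinite(g) & np.isfinite(y_all)
        gj, yj = g[ok], y_all[ok]
        nn = int(ok.sum())
        if nn < 3 or gj.std() == 0:
            logger.info("gwas_scan: dropping monomorphic/empty SNP %s", sid)
            continue
        eaf = float(gj.mean() / 2.0)
        if binary:
            beta, se, p = _logistic_single(gj, yj)
        else:
            gc = gj - gj.mean()
            yc = yj - yj.mean()
            sxx = float(gc @ gc)
            beta = float(gc @ yc) / sxx
            rss = float(yc @ yc) - beta**2 * sxx
            se = math.sqrt(max(rss, 1e-300) / (nn - 2) / sxx)
            p = float(2.0 * stats.t.sf(abs(beta / se), df=nn - 2))
        rows.append(
            {
                "snp_id": sid, "chrom": v.loc[j, "chrom"], "bp": int(v.loc[j, "bp"]),
                "effect_allele": v.loc[j, "count_allele"],
                "other_allele": v.loc[j, "other_allele"],
                "eaf": eaf, "beta": beta, "se": se, "pval": max(p, 5e-324), "n": nn,
            }
        )
    return SummaryDataset(
        trait_name, "binary" if binary else "quantitative", pd.DataFrame(rows)
    )


def _logistic_single(g: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    import statsmodels.api as sm

    X = sm.add_constant(g)
    fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    return beta, se, float(2.0 * stats.norm.sf(abs(beta / se)))


# ---------------------------------------------------------------------------
# Direct-sampling path
# ---------------------------------------------------------------------------


def sample_sumstats_direct(
    truth: SimTruth,
    ld: LDMatrix | None,
    n_x: int,
    n_y: int,
    seed: int | np.random.Generator = 0,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> tuple[SummaryDataset, SummaryDataset]:
    """Draw exposure and outcome summary statistics from their asymptotic
    sampling distribution (no individual-level data).

    True marginal per-allele effects are R-weighted combinations of the joint
    effects (on the standardized-genotype scale); estimates are drawn as
    b_hat ~ N(b_marginal, S R S) with S = diag(1/sqrt(2p(1-p)n)).  Exposure
    and outcome draws are independent, matching a two-sample design.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = len(truth.snp_ids)
    maf = truth.maf
    scale = np.sqrt(2.0 * maf * (1.0 - maf))
    R = ld.r if ld is not None else np.eye(m)
    if ld is not None and ld.snp_ids != truth.snp_ids:
        raise SimError("LD matrix SNP order does not match truth")

    # standardized joint effects; a reverse effect c (outcome -> exposure)
    # enters through the structural solve of x = g_x + c y, y = b x + g_y
    w_gx = truth.bzx * scale
    w_gy = truth.bzy_direct * scale
    b = truth.b_xy_true
    c = truth.config.reverse_b if truth.config is not None else 0.0
    det = 1.0 - b * c
    if abs(det) < 1e-9:
        raise SimError("b_xy * reverse_b = 1: degenerate feedback loop")
    w_x = (w_gx + c * w_gy) / det
    w_y = (b * w_gx + w_gy) / det
    bx_marg = (R @ w_x) / scale
    by_marg = (R @ w_y) / scale
    se_x = 1.0 / (scale * math.sqrt(n_x))
    se_y = 1.0 / (scale * math.sqrt(n_y))

    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise SimError("implied LD covariance is not positive definite")
    bx_hat = bx_marg + se_x * (L @ rng.standard_normal(m))
    by_hat = by_marg + se_y * (L @ rng.standard_normal(m))

    def dataset(name: str, b: np.ndarray, se: np.ndarray, n: int) -> SummaryDataset:
        z = b / se
        p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324)
        return SummaryDataset.from_arrays(
            name, "quantitative",
            snp_id=truth.snp_ids,
            effect_allele=[_ALLELES[0]] * m, other_allele=[_ALLELES[1]] * m,
            eaf=maf, beta=b, se=se, pval=p, n=[n] * m,
            chrom=truth.chrom, bp=truth.bp,
        )

    return dataset(exposure_name, bx_hat, se_x, n_x), dataset(outcome_name, by_hat, se_y, n_y)


def harmonized_from_truth(
    truth: SimTruth,
    ld: LDMatrix | None,
    n_x: int,
    n_y: int,
    seed: int | np.random.Generator = 0,
    p_thresh: float | None = 5e-8,
    max_instruments: int | None = None,
    selection: Literal["estimated", "true"] = "estimated",
) -> HarmonizedInstrumentSet:
    """One direct-sampling replicate as a harmonized instrument set.

    Applies the exposure-side genome-wide-significance selection that defines
    an instrument (p_zx < ``p_thresh``; pass None to keep every SNP), then
    optionally truncates to the ``max_instruments`` smallest exposure
    p-values.  Selection never looks at the outcome.

    ``selection='estimated'`` thresholds the sampled p_zx — the applied
    workflow, subject to winner's curse near the threshold.
    ``selection='true'`` thresholds the noise-free p implied by the true
    marginal effect, the usual validation design in which the instrument set
    is fixed by the generative model and the estimator's own bias can be
    measured in isolation.
    """
    from .sumstats import harmonize

    exp, out = sample_sumstats_direct(truth, ld, n_x, n_y, seed)
    if selection == "true" and p_thresh is not None:
        maf = truth.maf
        scale = np.sqrt(2.0 * maf * (1.0 - maf))
        R = ld.r if ld is not None else np.eye(len(maf))
        c = truth.config.reverse_b if truth.config is not None else 0.0
        w_x = (truth.bzx * scale + c * truth.bzy_direct * scale) / (
            1.0 - truth.b_xy_true * c
        )
        true_z = (R @ w_x) * math.sqrt(n_x)
        z_crit = stats.norm.isf(p_thresh / 2.0)
        keep = [s for s, z in zip(truth.snp_ids, true_z) if abs(z) > z_crit]
        inst = harmonize(exp, out, keep)
    else:
        inst = harmonize(exp, out, p_zx_max=p_thresh)
    if max_instruments is not None and len(inst) > max_instruments:
        keep = (
            inst.table.sort_values(["p_zx", "snp_id"], kind="mergesort")
            .head(max_instruments)["snp_id"]
            .tolist()
        )
        inst = inst.subset(keep)
    return inst
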