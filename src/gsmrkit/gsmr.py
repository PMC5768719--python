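"""GSMR: generalized least squares over per-SNP Mendelian randomization ratios.

Each genome-wide-significant instrument i gives a ratio estimate
b_xy(i) = b_zy(i) / b_zx(i) of the causal effect of exposure x on outcome y.
The vector of ratios is approximately multivariate normal around the true
b_xy with covariance V, whose elements account both for sampling error in
b_zx and b_zy and for residual LD r between instruments.  GLS combines the
ratios into a single estimate

    b_xy_hat = (1' V^-1 1)^-1 1' V^-1 b_xy,   var = (1' V^-1 1)^-1,

tested against zero with T = b_xy_hat^2 / var ~ chi^2(1).  For a disease
outcome analysed on the logit scale, b_xy_hat is interpretable as the logOR
per SD of the exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ldref import GenotypePanel, LDError, LDMatrix, clump, compute_ld
from .sumstats import HarmonizedInstrumentSet, SummaryDataset, harmonize

logger = logging.getLogger(__name__)


class GsmrError(ValueError):
    pass


class InsufficientInstrumentsError(GsmrError):
    pass


@dataclass
class GsmrOptions:
    """Thresholds controlling instrument selection and estimation.

    gwas_p_thresh: genome-wide significance cutoff for exposure instruments.
    clump_r2 / clump_window_kb: LD clumping parameters (r^2 0.05, +/-1 Mb).
    min_instruments: rule-of-thumb minimum of near-independent instruments;
        enforced unless ``force`` is set.
    heidi_p_thresh: per-SNP pleiotropy-filter p-value cutoff.
    condition_limit: V condition number above which the GLS solve is refused.
    """

    gwas_p_thresh: float = 5e-8
    clump_r2: float = 0.05
    clump_window_kb: float = 1000.0
    min_instruments: int = 10
    heidi_p_thresh: float = 0.01
    condition_limit: float = 1e8
    heidi_enabled: bool = True
    force: bool = False
    keep_palindromic: bool = False
    freq_diff_max: float = 0.2

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("gwas_p_thresh", 0, 1), ("clump_r2", 0, 1), ("heidi_p_thresh", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise GsmrError(f"{name}={v} outside ({lo},{hi}]")
        if self.min_instruments < 1:
            raise GsmrError("min_instruments must be >= 1")
        if self.clump_window_kb <= 0 or self.condition_limit <= 0:
            raise GsmrError("window and condition limit must be positive")


@dataclass
class BxyEstimates:
    """Per-instrument ratio estimates and their delta-method variances."""

    snp_ids: list[str]
    bxy: np.ndarray
    var_bxy: np.ndarray

    def __len__(self) -> int:
        return len(self.snp_ids)

    def subset(self, snp_ids: Sequence[str]) -> "BxyEstimates":
        pos = {s: i for i, s in enumerate(self.snp_ids)}
        idx = [pos[s] for s in snp_ids]
        return BxyEstimates(list(snp_ids), self.bxy[idx].copy(), self.var_bxy[idx].copy())


@dataclass
class GsmrResult:
    """Outcome of one GSMR analysis in one direction."""

    exposure: str
    outcome: str
    bxy_hat: float
    se: float
    chi2: float
    pval: float
    n_instruments_input: int
    n_instruments_used: int
    flagged_pleiotropic: list[str]
    per_snp: BxyEstimates
    direction: Literal["forward", "reverse"] = "forward"
    options: GsmrOptions | None = None
    heidi_report: "object | None" = None  # heidi.HeidiReport when filtering ran

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "exposure": self.exposure, "outcome": self.outcome,
                "direction": self.direction, "bxy": self.bxy_hat, "se": self.se,
                "chi2": self.chi2, "p": self.pval,
                "n_snps_input": self.n_instruments_input,
                "n_snps_used": self.n_instruments_used,
                "n_pleiotropic": len(self.flagged_pleiotropic),
            }]
        )


def bxy_per_snp(inst: HarmonizedInstrumentSet) -> BxyEstimates:
    """Per-SNP ratio b_xy(i) = b_zy/b_zx with delta-method variance.

    The variance is computed in the stable form

        var = se_zy^2/b_zx^2 + b_xy^2 (se_zx^2/b_zx^2 - se_zx^4/b_zx^4),

    algebraically identical to the b_xy^2 [var_zx/b_zx^2 + var_zy/b_zy^2 -
    var_zx^2/b_zx^4] factorization but finite at b_zy = 0.
    """
    a = inst.arrays()
    bzx, se_zx, bzy, se_zy = a["bzx"], a["se_bzx"], a["bzy"], a["se_bzy"]
    zero = bzx == 0
    if zero.any():
        bad = [s for s, z in zip(inst.snp_ids, zero) if z]
        raise GsmrError(f"degenerate instrument(s) with b_zx = 0: {bad[:5]}")
    bxy = bzy / bzx
    vzx, vzy = se_zx**2, se_zy**2
    var = vzy / bzx**2 + bxy**2 * (vzx / bzx**2 - vzx**2 / bzx**4)
    return BxyEstimates(inst.snp_ids, bxy, var)


def _cov_bxy(
    bzx_i, se_zx_i, bzx_j, se_zx_j, se_zy_i, se_zy_j, bxy_i, bxy_j, r
):
    """Covariance of two ratio estimates under LD r (plug-in b_xy estimates)."""
    vzx_i, vzx_j = se_zx_i**2, se_zx_j**2
    term1 = r * se_zy_i * se_zy_j / (bzx_i * bzx_j)
    term2 = bxy_i * bxy_j * (
        r * se_zx_i * se_zx_j / (bzx_i * bzx_j)
        - vzx_i * vzx_j / (bzx_i**2 * bzx_j**2)
    )
    return term1 + term2


def build_V(
    inst: HarmonizedInstrumentSet,
    est: BxyEstimates,
    ld: LDMatrix | None = None,
    condition_limit: float = 1e8,
) -> np.ndarray:
    """Assemble the ratio-estimate covariance matrix V.

    Diagonal entries are the per-SNP delta-method variances; off-diagonals
    follow the delta-method covariance with the reference-panel LD correlation r
    (r = 0, i.e. diagonal V, when ``ld`` is None).  Raises when the condition
    number exceeds ``condition_limit``, naming the most correlated pairs.
    """
    m = len(est)
    a = inst.arrays()
    bzx, se_zx, se_zy = a["bzx"], a["se_bzx"], a["se_bzy"]
    if ld is None:
        R = np.eye(m)
    else:
        R = ld.submatrix(inst.snp_ids).r
    V = _cov_bxy(
        bzx[:, None], se_zx[:, None], bzx[None, :], se_zx[None, :],
        se_zy[:, None], se_zy[None, :], est.bxy[:, None], est.bxy[None, :], R,
    )
    np.fill_diagonal(V, est.var_bxy)
    V = (V + V.T) / 2.0
    cond = np.linalg.cond(V)
    if cond > condition_limit:
        off = np.abs(R - np.eye(m))
        pairs = np.dstack(np.unravel_index(np.argsort(off, axis=None)[::-1], off.shape))[0]
        worst = []
        for i, j in pairs[:6:2]:
            worst.append(f"({inst.snp_ids[i]}, {inst.snp_ids[j]}; r={R[i, j]:.3f})")
        raise GsmrError(
            f"V near-singular (condition number {cond:.2e} > {condition_limit:.0e}); "
            f"most correlated instrument pairs: {', '.join(worst)}"
        )
    return V


def gls_estimate(est: BxyEstimates, V: np.ndarray) -> tuple[float, float, float, float]:
    """GLS combination of the per-SNP ratios: (b_xy_hat, se, chi2, p).

    Uses a symmetric linear solve (no explicit inverse); p is the upper-tail
    chi^2(1) probability of T = b_xy_hat^2 / var.
    """
    m = len(est)
    ones = np.ones(m)
    try:
        c, low = _cho_factor(V)
        Vinv_1 = _cho_solve((c, low), ones)
        Vinv_b = _cho_solve((c, low), est.bxy)
    except np.linalg.LinAlgError as e:
        raise GsmrError(f"V is not positive definite: {e}") from None
    denom = float(ones @ Vinv_1)
    if denom <= 0:
        raise GsmrError("V is not positive definite (1'V^-1 1 <= 0)")
    bxy_hat = float(ones @ Vinv_b) / denom
    var = 1.0 / denom
    chi2 = bxy_hat**2 / var
    pval = float(stats.chi2.sf(chi2, df=1))
    return bxy_hat, float(np.sqrt(var)), float(chi2), pval


def _cho_factor(V):
    from scipy.linalg import cho_factor

    try:
        return cho_factor(V, lower=True)
    except Exception as e:  # scipy raises LinAlgError
        raise np.linalg.LinAlgError(str(e))


def _cho_solve(fac, b):
    from scipy.linalg import cho_solve

    return cho_solve(fac, b)


def run_gsmr(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld_source: GenotypePanel | LDMatrix | None,
    options: GsmrOptions | None = None,
    direction: Literal["forward", "reverse"] = "forward",
) -> GsmrResult:
    """Full pipeline: clump -> harmonize -> HEIDI filter -> build V -> GLS.

    Instruments are selected from the exposure only (p_zx below the
    genome-wide threshold after clumping); the outcome never informs
    selection.  With fewer than ``min_instruments`` survivors the run aborts
    unless ``options.force`` is set, in which case it proceeds with a loud
    warning.
    """
    options = options or GsmrOptions()
    if ld_source is not None:
        index_snps = clump(
            exposure, ld_source, p_thresh=options.gwas_p_thresh,
            r2_thresh=options.clump_r2, window_kb=options.clump_window_kb,
        )
    else:
        t = exposure.table
        index_snps = t.loc[t["pval"] < options.gwas_p_thresh, "snp_id"].tolist()
    if not index_snps:
        raise InsufficientInstrumentsError(
            f"no exposure SNPs below p < {options.gwas_p_thresh:g}"
        )
    inst = harmonize(
        exposure, outcome, index_snps,
        keep_palindromic=options.keep_palindromic,
        freq_diff_max=options.freq_diff_max,
        p_zx_max=options.gwas_p_thresh,
    )
    n_input = len(inst)
    _check_min_instruments(n_input, options)

    if isinstance(ld_source, LDMatrix):
        ld = ld_source.submatrix(inst.snp_ids)
    elif isinstance(ld_source, GenotypePanel):
        ld = compute_ld(
            ld_source, inst.snp_ids,
            effect_alleles=dict(zip(inst.table["snp_id"], inst.table["effect_allele"])),
        )
    else:
        ld = None

    est = bxy_per_snp(inst)
    flagged: list[str] = []
    report = None
    if options.heidi_enabled and len(inst) >= 2:
        from .heidi import heidi_filter

        inst, report = heidi_filter(
            inst, est, ld, threshold=options.heidi_p_thresh
        )
        flagged = list(report.flagged)
        if flagged:
            est = est.subset(inst.snp_ids)
            if ld is not None:
                ld = ld.submatrix(inst.snp_ids)
        _check_min_instruments(len(inst), options)

    V = build_V(inst, est, ld, condition_limit=options.condition_limit)
    bxy_hat, se, chi2, pval = gls_estimate(est, V)
    logger.info(
        "GSMR %s->%s: %d instruments in, %d used, %d flagged pleiotropic; "
        "bxy=%.4f (se %.4f), p=%.3e",
        exposure.trait_name, outcome.trait_name, n_input, len(inst), len(flagged),
        bxy_hat, se, pval,
    )
    return GsmrResult(
        exposure=exposure.trait_name, outcome=outcome.trait_name,
        bxy_hat=bxy_hat, se=se, chi2=chi2, pval=pval,
        n_instruments_input=n_input, n_instruments_used=len(inst),
        flagged_pleiotropic=flagged, per_snp=est, direction=direction,
        options=options, heidi_report=report,
    )


def _check_min_instruments(n: int, options: GsmrOptions) -> None:
    if n < options.min_instruments:
        msg = (
            f"only {n} instrument(s) available; fewer than the recommended "
            f"minimum of {options.min_instruments} near-independent instruments"
        )
        if not options.force:
            raise InsufficientInstrumentsError(msg + " (override with force=True)")
        logger.warning("%s — proceeding because force=True", msg)


def run_bidirectional(
    trait_a: SummaryDataset,
    trait_b: SummaryDataset,
    ld_source: GenotypePanel | LDMatrix | None,
    options: GsmrOptions | None = None,
) -> tuple[GsmrResult | None, GsmrResult | None]:
    """Forward (A-instruments on B) and reverse (B-instruments on A) GSMR.

    A direction that cannot satisfy instrument requirements is skipped with a
    logged reason; both failing is an error.  Overlap between the two
    instrument sets is reported (they are disjoint when each trait's
    instruments are distinct, as in a well-separated bidirectional design).
    """
    forward: GsmrResult | None = None
    reverse: GsmrResult | None = None
    errors = []
    try:
        forward = run_gsmr(trait_a, trait_b, ld_source, options, direction="forward")
    except (InsufficientInstrumentsError, GsmrError, LDError, ValueError) as e:
        logger.warning("forward direction skipped: %s", e)
        errors.append(f"forward: {e}")
    try:
        reverse = run_gsmr(trait_b, trait_a, ld_source, options, direction="reverse")
    except (InsufficientInstrumentsError, GsmrError, LDError, ValueError) as e:
        logger.warning("reverse direction skipped: %s", e)
        errors.append(f"reverse: {e}")
    if forward is None and reverse is None:
        raise GsmrError("neither direction feasible: " + "; ".join(errors))
    if forward is not None and reverse is not None:
        overlap = set(forward.per_snp.snp_ids) & set(reverse.per_snp.snp_ids)
        if overlap:
            logger.warning(
                "bidirectional instrument sets overlap at %d SNP(s): %s",
                len(overlap), sorted(overlap)[:5],
            )
    return forward, reverse


# ---------------------------------------------------------------------------
# Interpretation helpers
# ---------------------------------------------------------------------------


def logor_to_or(b: float | np.ndarray) -> float | np.ndarray:
    """Convert an effect on the logOR scale to an odds ratio: OR = exp(b)."""
    b = np.asarray(b, float)
    if not np.all(np.isfinite(b)):
        raise GsmrError("logOR must be finite")
    out = np.exp(b)
    return float(out) if out.ndim == 0 else out


def or_to_logor(odds_ratio: float | np.ndarray) -> float | np.ndarray:
    odds_ratio = np.asarray(odds_ratio, float)
    if np.any(odds_ratio <= 0):
        raise GsmrError("odds ratio must be > 0")
    out = np.log(odds_ratio)
    return float(out) if out.ndim == 0 else out


def aggregate_effect(
    log_or_per_sd: Sequence[float], x_sd: Sequence[float]
) -> float:
    """Aggregate odds ratio from simultaneous SD-changes in several risk factors.

    log(OR) = sum_i x_i log(OR_i): each factor i contributes its conditional
    logOR per SD times the SD change x_i, additively on the log scale.
    """
    log_or = np.asarray(log_or_per_sd, float)
    x = np.asarray(x_sd, float)
    if log_or.shape != x.shape:
        raise GsmrError(
            f"length mismatch: {log_or.shape} log-ORs vs {x.shape} SD changes"
        )
    return float(np.exp(np.sum(x * log_or)))


def bonferroni_threshold(fwer: float, n_tests: int) -> float:
    """Family-wise error control: per-test p threshold fwer / n_tests."""
    if not (0.0 < fwer < 1.0):
        raise GsmrError("fwer must lie in (0,1)")
    if n_tests < 1 or int(n_tests) != n_tests:
        raise GsmrError("n_tests must be a positive integer")
    return fwer / n_tests


# ---------------------------------------------------------------------------
# Comparator estimators (IVW, MR-Egger)
# ---------------------------------------------------------------------------


def _oriented(inst: HarmonizedInstrumentSet):
    """Flip instruments so b_zx > 0 (MR-Egger orientation convention)."""
    a = inst.arrays()
    sign = np.where(a["bzx"] < 0, -1.0, 1.0)
    return sign * a["bzx"], a["se_bzx"], sign * a["bzy"], a["se_bzy"]


def estimate_ivw(inst: HarmonizedInstrumentSet) -> tuple[float, float, float]:
    """Inverse-variance-weighted estimate: zero-intercept 1/se_zy^2-weighted
    regression of b_zy on b_zx.  Returns (slope, se, p)."""
    if len(inst) < 2:
        raise GsmrError("IVW requires >= 2 instruments")
    import statsmodels.api as sm

    bzx, _, bzy, se_zy = _oriented(inst)
    fit = sm.WLS(bzy, bzx[:, None], weights=1.0 / se_zy**2).fit()
    b = float(fit.params[0])
    se = float(fit.bse[0])
    # fixed-effect SE convention: scale out the residual variance estimate
    se /= np.sqrt(float(fit.scale))
    z = b / se
    return b, se, float(2.0 * stats.norm.sf(abs(z)))


def estimate_egger(
    inst: HarmonizedInstrumentSet,
) -> tuple[float, float, float, float]:
    """MR-Egger: weighted regression of b_zy on b_zx with a free intercept.

    Returns (slope, slope_se, intercept, intercept_p).  A nonzero intercept
    indicates directional pleiotropy.  Instruments are oriented so b_zx > 0.
    """
    if len(inst) < 3:
        raise GsmrError("MR-Egger requires >= 3 instruments")
    import statsmodels.api as sm

    bzx, _, bzy, se_zy = _oriented(inst)
    X = sm.add_constant(bzx)
    fit = sm.WLS(bzy, X, weights=1.0 / se_zy**2).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    slope_se = float(fit.bse[1])
    tstat = fit.params[0] / fit.bse[0]
    intercept_p = float(2.0 * stats.t.sf(abs(tstat), df=len(inst) - 2))
    return slope, slope_se, intercept, intercept_p
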