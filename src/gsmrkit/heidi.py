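"""HEIDI-outlier: per-instrument pleiotropy test against a robust target SNP.

Under a purely causal model every instrument's ratio estimate b_xy(i) has the
same expectation, so an instrument whose ratio deviates from that of a
well-chosen target SNP beyond its sampling error is putatively pleiotropic.
The target is the SNP most strongly associated with the exposure *within the
third quintile* of the b_xy distribution — strong enough for power, but not
an extreme ratio that might itself be a pleiotropic outlier.  Each SNP i is
tested with

    d_i = b_xy(i) - b_xy(target),
    var(d_i) = var(b_xy(i)) + var(b_xy(target)) - 2 cov(...),
    T = d_i^2 / var(d_i) ~ chi^2(1),

the covariance accounting for residual LD between SNP i and the target, and
SNPs with p < 0.01 are removed.  Under no pleiotropy this discards ~1% of
instruments by chance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gsmr import BxyEstimates, GsmrError, _cov_bxy
from .ldref import LDMatrix
from .sumstats import HarmonizedInstrumentSet

logger = logging.getLogger(__name__)


@dataclass
class HeidiReport:
    """Per-SNP heterogeneity test results and the removal decision."""

    target_snp_id: str
    table: pd.DataFrame = field(repr=False)  # snp_id, d, var_d, pval, flagged
    flagged: list[str] = field(default_factory=list)
    threshold: float = 0.01


def select_target(inst: HarmonizedInstrumentSet, est: BxyEstimates) -> str:
    """Pick the target SNP: strongest exposure association in the third
    quintile of the b_xy distribution.

    SNPs are ranked by b_xy (ascending, 1-based ranks); the third-quintile
    band is the ranks in (0.4 m, 0.6 m].  When no integer rank falls in that
    band (possible for small m) the median rank is used.  Within the band the
    SNP with the smallest exposure p-value wins; ties break by distance of
    b_xy from the median b_xy, then by snp_id.
    """
    m = len(est)
    if m == 0:
        raise GsmrError("empty instrument set")
    if m == 1:
        return est.snp_ids[0]
    p_zx = inst.table.set_index("snp_id").loc[est.snp_ids, "p_zx"].to_numpy()
    order = np.lexsort((est.snp_ids, est.bxy))  # bxy ascending, id tiebreak
    ranks_in_band = [
        k for k in range(1, m + 1) if 0.4 * m < k <= 0.6 * m
    ]
    if not ranks_in_band:
        ranks_in_band = [int(math.ceil(0.5 * m))]
    band_idx = [order[k - 1] for k in ranks_in_band]
    med = float(np.median(est.bxy))
    key = sorted(
        band_idx,
        key=lambda i: (p_zx[i], abs(est.bxy[i] - med), est.snp_ids[i]),
    )
    return est.snp_ids[key[0]]


def heidi_test(
    inst: HarmonizedInstrumentSet,
    est: BxyEstimates,
    target: str,
    ld: LDMatrix | None = None,
    threshold: float = 0.01,
) -> HeidiReport:
    """Test every instrument's b_xy deviation from the target SNP's.

    ``ld`` supplies the LD correlation between each SNP and the target
    (r = 0 assumed when None, i.e. fully independent instruments).  A SNP
    whose var(d) comes out non-positive (numerically inconsistent inputs) is
    conservatively retained and reported with p = NaN.
    """
    ids = est.snp_ids
    if target not in ids:
        raise GsmrError(f"target SNP {target} not among instruments")
    t_idx = ids.index(target)
    a = inst.arrays()
    bzx, se_zx, se_zy = a["bzx"], a["se_bzx"], a["se_bzy"]
    if ld is not None:
        r = ld.submatrix(ids).r[:, t_idx]
    else:
        r = np.zeros(len(ids))

    cov = _cov_bxy(
        bzx, se_zx, bzx[t_idx], se_zx[t_idx],
        se_zy, se_zy[t_idx], est.bxy, est.bxy[t_idx], r,
    )
    d = est.bxy - est.bxy[t_idx]
    var_d = est.var_bxy + est.var_bxy[t_idx] - 2.0 * cov
    with np.errstate(divide="ignore", invalid="ignore"):
        T = d**2 / var_d
        pval = stats.chi2.sf(T, df=1)
    indeterminate = var_d <= 0
    pval = np.where(indeterminate, np.nan, pval)
    d[t_idx], var_d[t_idx] = 0.0, np.nan
    pval[t_idx] = 1.0
    if indeterminate.any():
        bad = [ids[i] for i in np.flatnonzero(indeterminate) if i != t_idx]
        if bad:
            logger.warning(
                "HEIDI: non-positive var(d) at %s; retained as indeterminate", bad[:5]
            )
    flagged_mask = np.nan_to_num(pval, nan=1.0) < threshold
    flagged_mask[t_idx] = False
    flagged = [ids[i] for i in np.flatnonzero(flagged_mask)]
    tbl = pd.DataFrame(
        {"snp_id": ids, "d": d, "var_d": var_d, "pval": pval, "flagged": flagged_mask}
    )
    return HeidiReport(target, tbl, flagged, threshold)


def heidi_filter(
    inst: HarmonizedInstrumentSet,
    est: BxyEstimates | None = None,
    ld: LDMatrix | None = None,
    threshold: float = 0.01,
    iterate: bool = False,
) -> tuple[HarmonizedInstrumentSet, HeidiReport]:
    """Remove putatively pleiotropic instruments (single pass by default).

    Pure subset selection: retained SNPs keep their stored effects unchanged.
    ``iterate`` repeats target selection + testing until no SNP is removed.
    With fewer than 2 instruments the set passes through unchanged.
    """
    from .gsmr import bxy_per_snp

    if est is None:
        est = bxy_per_snp(inst)
    if len(inst) < 2:
        logger.warning("HEIDI: fewer than 2 instruments; nothing to test")
        report = HeidiReport(
            est.snp_ids[0] if len(est) else "",
            pd.DataFrame(columns=["snp_id", "d", "var_d", "pval", "flagged"]),
            [], threshold,
        )
        return inst, report

    all_flagged: list[str] = []
    current_inst, current_est, current_ld = inst, est, ld
    while True:
        target = select_target(current_inst, current_est)
        report = heidi_test(current_inst, current_est, target, current_ld, threshold)
        newly = report.flagged
        all_flagged.extend(newly)
        if len(current_inst) > 2 and len(newly) >= len(current_inst) - 1:
            # every testable (non-target) SNP deviates from the target
            raise GsmrError(
                "HEIDI flagged every instrument — the causal model is likely violated"
            )
        if newly:
            keep = [s for s in current_inst.snp_ids if s not in set(newly)]
            current_inst = current_inst.subset(keep)
            current_est = current_est.subset(keep)
            if current_ld is not None:
                current_ld = current_ld.submatrix(keep)
        if not (iterate and newly):
            break
    report.flagged = all_flagged
    if all_flagged:
        logger.info(
            "HEIDI-outlier removed %d of %d instrument(s): %s",
            len(all_flagged), len(inst), all_flagged[:10],
        )
    return current_inst, report
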