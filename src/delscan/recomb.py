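"""Recombination rate versus deleterious variation.

Per-interval recombination rates (cM/Mb) come from consecutive genetic-map
markers; intervals with negative rates or rates above 20 cM/Mb are excluded
as likely marker placement errors.  Nonsynonymous SNPs are assigned to
half-open intervals [start, end) and the per-interval proportion called
deleterious is related to the rate by Pearson correlation (interval level)
and logistic regression (SNP level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .formats_io import GeneticMap

MAX_RATE = 20.0  # cM/Mb; larger values indicate misplaced markers


@dataclass
class MapInterval:
    chrom: str
    bp_start: int
    bp_end: int
    cm_start: float
    cm_end: float
    rate: float  # cM/Mb
    n_nonsyn: int = 0
    n_deleterious: int = 0

    @property
    def proportion(self) -> float | None:
        if self.n_nonsyn == 0:
            return None
        return self.n_deleterious / self.n_nonsyn


@dataclass
class IntervalSet:
    intervals: list[MapInterval]
    n_excluded: int = 0
    out_of_map: list[str] = field(default_factory=list)


def interval_rates(gmap: GeneticMap) -> IntervalSet:
    """cM/Mb for each between-marker interval, applying the exclusion rules."""
    intervals: list[MapInterval] = []
    excluded = 0
    for chrom in gmap.chromosomes():
        markers = gmap.markers(chrom)
        if len(markers) < 2:
            import logging

            logging.getLogger("delscan").warning(
                "chromosome %s has < 2 markers; skipped", chrom
            )
            continue
        bp = markers["bp"].to_numpy()
        cm = markers["cM"].to_numpy()
        for i in range(len(bp) - 1):
            dbp = bp[i + 1] - bp[i]
            rate = (cm[i + 1] - cm[i]) / (dbp / 1e6)
            if rate < 0 or rate > MAX_RATE:
                excluded += 1
                continue
            intervals.append(
                MapInterval(
                    chrom, int(bp[i]), int(bp[i + 1]), float(cm[i]), float(cm[i + 1]), float(rate)
                )
            )
    return IntervalSet(intervals, n_excluded=excluded)


def overlay_deleterious(
    iset: IntervalSet,
    snp_positions: dict[str, tuple[str, int]],
    nonsyn_ids: set[str],
    deleterious_ids: set[str],
) -> IntervalSet:
    """Assign each nonsynonymous SNP to exactly one interval [start, end).

    ``snp_positions`` maps variant id -> (chrom, bp).  SNPs outside map
    bounds are recorded in ``out_of_map``, never silently dropped.
    """
    by_chrom: dict[str, list[MapInterval]] = {}
    for iv in iset.intervals:
        iv.n_nonsyn = 0
        iv.n_deleterious = 0
        by_chrom.setdefault(iv.chrom, []).append(iv)
    starts = {
        c: np.array([iv.bp_start for iv in ivs]) for c, ivs in by_chrom.items()
    }
    out = []
    for vid in sorted(nonsyn_ids):
        chrom, bp = snp_positions[vid]
        ivs = by_chrom.get(chrom)
        if ivs is None:
            out.append(vid)
            continue
        idx = int(np.searchsorted(starts[chrom], bp, side="right")) - 1
        if idx < 0 or bp >= ivs[idx].bp_end:
            out.append(vid)
            continue
        ivs[idx].n_nonsyn += 1
        if vid in deleterious_ids:
            ivs[idx].n_deleterious += 1
    iset.out_of_map = out
    return iset


def correlate(iset: IntervalSet) -> tuple[float, float, float]:
    """Pearson correlation of rate vs deleterious proportion over intervals.

    Returns (r, r^2, two-sided p).  Intervals without nonsynonymous SNPs are
    excluded; constant inputs raise ValueError.
    """
    pairs = [
        (iv.rate, iv.proportion)
        for iv in iset.intervals
        if iv.proportion is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 intervals with defined proportion")
    x, y = map(np.asarray, zip(*pairs))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in rate or proportion")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r) ** 2, float(p)


def logistic_fit(
    deleterious: np.ndarray, rate: np.ndarray
) -> tuple[float, float, float]:
    """Logit of per-SNP deleterious status on interval recombination rate.

    Maximum-likelihood fit (IRLS); returns (intercept, slope, Wald p for the
    slope).  Raises ValueError when only one outcome class is present or the
    data are completely separated.
    """
    y = np.asarray(deleterious, dtype=float)
    x = np.asarray(rate, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(x)
    try:
        fit = sm.Logit(y, X).fit(disp=0, tol=1e-8, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
        raise ValueError(f"logistic fit failed (separation?): {e}") from e
    if not fit.mle_retvals.get("converged", False):
        raise ValueError("logistic fit did not converge (possible separation)")
    intercept, slope = fit.params
    p_slope = float(fit.pvalues[1])
    return float(intercept), float(slope), p_slope


def intervals_to_frame(iset: IntervalSet) -> pd.DataFrame:
    rows = []
    for iv in iset.intervals:
        rows.append(
            {
                "chrom": iv.chrom,
                "bp_start": iv.bp_start,
                "bp_end": iv.bp_end,
                "cM_start": iv.cm_start,
                "cM_end": iv.cm_end,
                "rate_cM_per_Mb": iv.rate,
                "n_nonsyn": iv.n_nonsyn,
                "n_deleterious": iv.n_deleterious,
                "proportion": iv.proportion if iv.proportion is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)
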