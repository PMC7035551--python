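"""Error metrics, correlation, AAMI verdicts, rank tests and the γ sweep.

The accuracy of an estimator against the cuff reference is summarised by
the mean error ME, mean absolute difference MAD, sum of squared errors
SSE, the two dispersion statistics

    sigma = sqrt(SSE / (n - 1))        (about zero)
    SD    = sqrt((1/n) * sum (x_i - x_bar)^2)   (about the mean error)

the coefficient of variation c.v. = sigma / ME, and RMSE = sqrt(SSE / n).
Note the deliberate divisor asymmetry: sigma uses n-1 while SD uses n,
exactly as conventionally reported for this evaluation.  Device-acceptance
follows the AAMI criterion |ME| <= 5 mmHg and SD <= 8 mmHg (inclusive).

Model comparison uses the Kruskal-Wallis rank test with Dunn's multiple
comparisons (Bonferroni-corrected by default).  Both are implemented from
the rank formulas and are cross-checkable against standard library
routines.  The γ sweep recalibrates the dMK-BH model on a grid of the
vascular constant γ and traces pooled MAD against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import (
    CalibrationFailureError,
    CalibrationPlan,
    advanced_ptp_calibrate,
)
from .models import estimate_bp

__all__ = [
    "PairedSeries",
    "ErrorSummary",
    "AAMIVerdict",
    "GammaSweepResult",
    "error_summary",
    "pearson_correlation",
    "aami_verdict",
    "kruskal_wallis",
    "dunn_posthoc",
    "gamma_sensitivity_sweep",
    "default_gamma_grid",
]

AAMI_MEAN_LIMIT = 5.0  # mmHg
AAMI_SD_LIMIT = 8.0  # mmHg


@dataclass(frozen=True)
class PairedSeries:
    """Aligned estimated and cuff BP sequences for one channel."""

    bp_est: np.ndarray
    bp_cuf: np.ndarray

    def __post_init__(self) -> None:
        est = np.asarray(self.bp_est, float)
        cuf = np.asarray(self.bp_cuf, float)
        if est.shape != cuf.shape:
            raise ValueError("bp_est and bp_cuf must have equal length")
        object.__setattr__(self, "bp_est", est)
        object.__setattr__(self, "bp_cuf", cuf)

    @property
    def n(self) -> int:
        return self.bp_est.size

    @property
    def errors(self) -> np.ndarray:
        return self.bp_est - self.bp_cuf


@dataclass(frozen=True)
class ErrorSummary:
    """The seven agreement statistics for one model/channel."""

    me: float  # mmHg
    mad: float  # mmHg
    sse: float  # mmHg^2
    sigma: float  # mmHg, sqrt(SSE/(n-1))
    cv: float | None  # sigma/ME; None when ME == 0
    sd: float  # mmHg, 1/n divisor about the mean error
    rmse: float  # mmHg, sqrt(SSE/n)
    n: int


@dataclass(frozen=True)
class AAMIVerdict:
    """Pass/fail against the AAMI mean +/- SD acceptance bounds."""

    mean_ok: bool
    sd_ok: bool

    @property
    def passed(self) -> bool:
        return self.mean_ok and self.sd_ok


@dataclass(frozen=True)
class GammaSweepResult:
    """Pooled MAD as a function of the vascular constant γ."""

    grid: np.ndarray  # mmHg^-1
    mad_sbp: np.ndarray  # mmHg; NaN where calibration failed
    mad_dbp: np.ndarray

    @property
    def argmin_sbp(self) -> float:
        return float(self.grid[np.nanargmin(self.mad_sbp)])

    @property
    def argmin_dbp(self) -> float:
        return float(self.grid[np.nanargmin(self.mad_dbp)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gamma": self.grid, "mad_sbp": self.mad_sbp,
                             "mad_dbp": self.mad_dbp})


def error_summary(paired: PairedSeries) -> ErrorSummary:
    """Compute ME, MAD, SSE, sigma, c.v., SD and RMSE for a paired series.

    ``cv`` is reported as None when ME is exactly zero (the ratio is
    undefined); very small ME values produce the legitimately extreme
    c.v. magnitudes this statistic is known for.
    """
    n = paired.n
    if n < 2:
        raise ValueError("need at least two paired readings")
    x = paired.errors
    me = float(np.mean(x))
    mad = float(np.mean(np.abs(x)))
    sse = float(np.sum(x**2))
    sigma = math.sqrt(sse / (n - 1))
    cv = None if me == 0.0 else sigma / me
    sd = float(np.sqrt(np.mean((x - me) ** 2)))
    rmse = math.sqrt(sse / n)
    return ErrorSummary(me=me, mad=mad, sse=sse, sigma=sigma, cv=cv,
                        sd=sd, rmse=rmse, n=n)


def pearson_correlation(paired: PairedSeries) -> float:
    """Pooled product-moment correlation between estimated and cuff BP."""
    if paired.n < 3:
        raise ValueError("need at least three pairs for a correlation")
    if np.ptp(paired.bp_est) == 0 or np.ptp(paired.bp_cuf) == 0:
        raise ValueError("correlation undefined: zero variance in a sequence")
    return float(stats.pearsonr(paired.bp_est, paired.bp_cuf).statistic)


def aami_verdict(summary: ErrorSummary) -> AAMIVerdict:
    """AAMI acceptance: |ME| <= 5 mmHg and SD <= 8 mmHg, both inclusive."""
    return AAMIVerdict(mean_ok=abs(summary.me) <= AAMI_MEAN_LIMIT,
                       sd_ok=summary.sd <= AAMI_SD_LIMIT)


def _ranks_and_tie_correction(groups: Sequence[np.ndarray]) -> tuple[list[np.ndarray], float, int]:
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total) if n_total > 1 else 1.0
    split: list[np.ndarray] = []
    start = 0
    for g in groups:
        split.append(ranks[start:start + g.size])
        start += g.size
    return split, correction, n_total


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction.

    Returns ``(H, df, p)`` with df = number of groups - 1 and p from the
    chi-square approximation.  All-identical samples yield H = 0, p = 1.
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2 or any(a.size == 0 for a in arrs):
        raise ValueError("need at least two nonempty groups")
    rank_groups, correction, n = _ranks_and_tie_correction(arrs)
    h = (12.0 / (n * (n + 1))
         * sum(float(np.sum(r))**2 / r.size for r in rank_groups)
         - 3.0 * (n + 1))
    if correction == 0.0:  # every observation identical
        return 0.0, len(arrs) - 1, 1.0
    h /= correction
    df = len(arrs) - 1
    p = float(stats.chi2.sf(h, df))
    return float(h), df, p


def dunn_posthoc(groups: Sequence[Sequence[float]],
                 correction: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after Kruskal-Wallis.

    The pairwise statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))``
    with tie term ``T = sum(t^3 - t) / (12 (N - 1))``; two-sided p-values
    are adjusted for the number of pairs ("bonferroni", "holm" or "none").

    Returns a symmetric DataFrame of corrected p-values with a ``z``
    attribute-free layout (z-scores available via the ``.attrs['z']``
    DataFrame).
    """
    arrs = [np.asarray(g, float) for g in groups]
    if len(arrs) < 2 or any(a.size == 0 for a in arrs):
        raise ValueError("need at least two nonempty groups")
    rank_groups, _, n = _ranks_and_tie_correction(arrs)
    pooled = np.concatenate(arrs)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    mean_ranks = [float(np.mean(r)) for r in rank_groups]
    g = len(arrs)
    zmat = np.zeros((g, g))
    pvals = []
    idx_pairs = list(combinations(range(g), 2))
    for i, j in idx_pairs:
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / arrs[i].size + 1.0 / arrs[j].size)
        if var <= 0:  # all observations identical
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        zmat[i, j] = zmat[j, i] = z
        pvals.append(2.0 * stats.norm.sf(abs(z)))
    m = len(idx_pairs)
    pvals = np.asarray(pvals)
    if correction == "bonferroni":
        adj = np.minimum(pvals * m, 1.0)
    elif correction == "holm":
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        running = 0.0
        for rank, k in enumerate(order):
            running = max(running, (m - rank) * pvals[k])
            adj[k] = min(running, 1.0)
    elif correction == "none":
        adj = pvals
    else:
        raise ValueError(f"unknown correction {correction!r}")
    pmat = np.eye(g)
    for (i, j), p in zip(idx_pairs, adj):
        pmat[i, j] = pmat[j, i] = p
    labels = [f"group{i + 1}" for i in range(g)]
    out = pd.DataFrame(pmat, index=labels, columns=labels)
    out.attrs["z"] = pd.DataFrame(zmat, index=labels, columns=labels)
    return out


def default_gamma_grid() -> np.ndarray:
    """γ grid 0.0005 to 0.05 in steps of 0.0005 mmHg^-1."""
    return np.round(np.arange(1, 101) * 0.0005, 6)


def gamma_sensitivity_sweep(
    subjects: Sequence[tuple[CalibrationPlan, np.ndarray, np.ndarray, np.ndarray]],
    grid: np.ndarray | None = None,
) -> GammaSweepResult:
    """Trace pooled MAD of the dMK-BH model over a γ grid.

    Parameters
    ----------
    subjects
        One entry per subject: ``(plan, pat_bar, sbp_cuf, dbp_cuf)`` where
        ``plan`` is that subject's dMK-BH calibration plan and the arrays
        are the monitoring-segment windowed PATs with their cuff readings.
    grid
        γ values (mmHg^-1), strictly increasing, within (0, 0.1].

    For each γ the model is recalibrated per subject with that γ,
    evaluated on the subject's monitoring windows, and the absolute errors
    pooled across subjects; grid points where every subject's calibration
    fails are NaN.
    """
    grid = default_gamma_grid() if grid is None else np.asarray(grid, float)
    if np.any(grid <= 0) or np.any(grid > 0.1):
        raise ValueError("gamma grid must lie in (0, 0.1]")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("gamma grid must be strictly increasing")
    for plan, *_ in subjects:
        if plan.model != "dMK-BH":
            raise ValueError("gamma sweep applies to the dMK-BH model only")
    mad_sbp = np.full(grid.size, np.nan)
    mad_dbp = np.full(grid.size, np.nan)
    for gi, gamma in enumerate(grid):
        abs_err_s: list[np.ndarray] = []
        abs_err_d: list[np.ndarray] = []
        for plan, pat_bar, sbp_cuf, dbp_cuf in subjects:
            replan = CalibrationPlan(rounds=plan.rounds, model="dMK-BH", gamma=gamma)
            try:
                params, _ = advanced_ptp_calibrate(replan)
            except CalibrationFailureError:
                continue
            est = estimate_bp(params, np.asarray(pat_bar, float))
            abs_err_s.append(np.abs(np.asarray(est.sbp_est) - np.asarray(sbp_cuf, float)))
            abs_err_d.append(np.abs(np.asarray(est.dbp_est) - np.asarray(dbp_cuf, float)))
        if abs_err_s:
            mad_sbp[gi] = float(np.mean(np.concatenate(abs_err_s)))
            mad_dbp[gi] = float(np.mean(np.concatenate(abs_err_d)))
    return GammaSweepResult(grid=grid, mad_sbp=mad_sbp, mad_dbp=mad_dbp)
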