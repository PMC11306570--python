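"""Non-parametric inference for contagion scores.

Differential scores (mean response to large-pupil stimuli minus mean
response to small-pupil stimuli, per participant and gaze condition)
are tested against zero with Wilcoxon signed-rank tests, and related
to trait scores with full and semi-partial Spearman correlations.

The signed-rank test drops zero differences (Wilcoxon's policy;
Pratt's method available), mid-ranks ties, and reports
``W = min(W+, W-)``.  For n at or below ``exact_n_max`` the two-sided
p-value is exact, computed from the full null distribution of the
rank sum over all 2**n sign assignments (evaluated by dynamic
programming over doubled ranks so mid-ranks stay integral); larger n
uses the tie-corrected normal approximation with continuity
correction.  The effect size is r = Z / sqrt(n), signed by the
direction of the median difference.

Semi-partial correlations rank-transform every column, residualize
the covariates out of one side only (the trait side by default) by
least squares on ranks, and correlate the residuals with the ranks of
the other variable.  Confidence intervals use the Fisher transform
with SE = 1.03 / sqrt(n - 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DegenerateInputError


@dataclass
class DifferentialScore:
    participant: str
    modality: str
    condition: str
    mean_large: float
    mean_small: float
    diff: float  # mean_large - mean_small, by definition
    n_large: int = 0
    n_small: int = 0
    valid: bool = True


@dataclass
class WilcoxonResult:
    W: float
    n: int
    p_value: float
    effect_r: float
    method: str = "exact"

    def as_dict(self) -> dict:
        return {
            "W": self.W,
            "n": self.n,
            "p_value": self.p_value,
            "effect_r": self.effect_r,
            "method": self.method,
        }


@dataclass
class CorrelationResult:
    rho: float
    n: int
    ci95: tuple[float, float]
    p_value: float
    covariates: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "rho": self.rho,
            "n": self.n,
            "ci95": list(self.ci95),
            "p_value": self.p_value,
            "covariates": self.covariates,
        }


# ---------------------------------------------------------------------------
# differential scores


def differential_score(
    trials: pd.DataFrame,
    participant: str,
    modality: str,
    condition: str,
    value_col: str = "value",
) -> DifferentialScore:
    """Per-cell means over valid trials, then large minus small.

    ``trials`` must hold columns ``stim_pupil``, ``valid`` and the
    value column, already restricted to one participant/condition.
    """
    sub = trials[trials["valid"].astype(bool)]
    large = sub.loc[sub["stim_pupil"] == "large", value_col].to_numpy(float)
    small = sub.loc[sub["stim_pupil"] == "small", value_col].to_numpy(float)
    if len(large) == 0 or len(small) == 0:
        return DifferentialScore(
            participant, modality, condition, np.nan, np.nan, np.nan, len(large), len(small), False
        )
    ml, ms = float(large.mean()), float(small.mean())
    return DifferentialScore(
        participant, modality, condition, ml, ms, ml - ms, len(large), len(small)
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_null_cdf_counts(ranks2: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled rank sum over all sign patterns.

    ``ranks2`` are the doubled (hence integer) mid-ranks.  Entry ``s``
    of the result is the number of sign assignments with W+ * 2 == s.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    return dist


def wilcoxon_signed_rank(
    diffs,
    zero_method: str = "wilcox",
    exact_n_max: int = 25,
) -> WilcoxonResult:
    """Two-sided one-sample Wilcoxon signed-rank test on differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[np.isfinite(d)]
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        raise DegenerateInputError("all differences are zero")
    if zero_method == "wilcox":
        work = nonzero
    elif zero_method == "pratt":
        work = d
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")

    n = len(nonzero)
    ranks = sps.rankdata(np.abs(work))
    if zero_method == "pratt":
        keep = work != 0
        ranks = ranks[keep]
        work = work[keep]
    w_plus = float(ranks[work > 0].sum())
    w_minus = float(ranks[work < 0].sum())
    W = min(w_plus, w_minus)

    # normal approximation pieces (used for the effect size throughout)
    total = w_plus + w_minus
    mu = total / 2.0
    counts = np.unique(np.abs(work), return_counts=True)[1]
    m = len(work)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    sd = np.sqrt(var) if var > 0 else np.nan
    if np.isfinite(sd) and sd > 0:
        z = (W - mu + 0.5) / sd  # continuity-corrected, W <= mu by construction
    else:
        z = 0.0

    if n <= exact_n_max:
        ranks2 = np.rint(2 * ranks).astype(int)
        dist = _signed_rank_null_cdf_counts(ranks2)
        total2 = int(ranks2.sum())
        w2 = int(np.rint(2 * W))
        lo = dist[: w2 + 1].sum()
        hi = dist[total2 - w2 :].sum()
        p = min(1.0, (lo + hi) / 2.0 ** len(ranks2))
        method = "exact"
    else:
        p = min(1.0, 2.0 * sps.norm.cdf(z))
        method = "normal"

    direction = np.sign(np.median(nonzero))
    effect_r = float(direction * abs(z) / np.sqrt(n))
    return WilcoxonResult(W=W, n=n, p_value=float(p), effect_r=effect_r, method=method)


# ---------------------------------------------------------------------------
# Spearman correlations


def _spearman_ci(rho: float, n: int) -> tuple[float, float]:
    if n <= 3 or abs(rho) >= 1:
        return (-1.0, 1.0)
    z = np.arctanh(rho)
    se = 1.03 / np.sqrt(n - 3)
    return (float(np.tanh(z - 1.959963985 * se)), float(np.tanh(z + 1.959963985 * se)))


def _t_pvalue(rho: float, df: int) -> float:
    if df <= 0:
        return np.nan
    if abs(rho) >= 1:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    return float(2.0 * sps.t.sf(abs(t), df))


def spearman(x, y) -> CorrelationResult:
    """Full Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise DegenerateInputError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return CorrelationResult(rho, n, _spearman_ci(rho, n), _t_pvalue(rho, n - 2))


def spearman_semipartial(
    x, y, covariates, residualize: str = "x", covariate_names: list[str] | None = None
) -> CorrelationResult:
    """Semi-partial Spearman: covariates regressed out of one side only.

    All columns are rank-transformed; the covariate ranks (plus an
    intercept) are removed from the ranks of ``x`` (the trait variable)
    by ordinary least squares, and the residuals are Pearson-correlated
    with the ranks of ``y``.  Complete cases only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] == len(x) and C.shape[1] != len(x):
        pass  # already (n, k)
    elif C.shape[1] == len(x):
        C = C.T
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(C).all(axis=1)
    x, y, C = x[ok], y[ok], C[ok]
    n, k = len(x), C.shape[1]
    if n < k + 4:
        raise DegenerateInputError(f"need at least {k + 4} complete cases, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance: correlation undefined")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    RC = np.column_stack([sps.rankdata(C[:, j]) for j in range(k)])
    design = np.column_stack([np.ones(n), RC])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateInputError("collinear covariates: rank-deficient design")
    target = rx if residualize == "x" else ry
    other = ry if residualize == "x" else rx
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ beta
    if np.allclose(resid, 0):
        raise DegenerateInputError("covariates explain the residualized variable exactly")
    rho = float(np.corrcoef(resid, other)[0, 1])
    names = covariate_names or [f"c{j}" for j in range(k)]
    return CorrelationResult(rho, n, _spearman_ci(rho, n), _t_pvalue(rho, n - 2 - k), names)
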