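"""Per-chromosome frequency smoothing and threshold QTL calling.

The raw pooled SNP variant frequency is smoothed per chromosome with a
penalized cubic B-spline written as a linear mixed model: the second-order
difference penalty on the spline coefficients acts as a random-effect
precision, and the smoothing parameter is the variance ratio estimated by
restricted maximum likelihood (REML).  Observations are weighted
proportionally to read depth.  A pointwise Wald confidence band comes
from the posterior covariance of the penalized fit.

QTLs are called where the smoothed curve leaves the [lower, upper]
frequency band (default 30%/70%, the significant-deviation thresholds on
either side of the Mendelian 50% expectation), over runs of at least
``min_markers`` markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.interpolate import BSpline

logger = logging.getLogger("poolseg")

__all__ = ["smooth_chromosome", "smooth_profile", "call_qtls", "report_linkage"]

_SPLINE_DEGREE = 3
_KNOT_EVERY = 25  # one interior knot per this many markers
_MIN_KNOTS = 8
_MAX_KNOTS = 40


@dataclass(frozen=True)
class ChromosomeFit:
    """Smoothed frequency with a pointwise confidence band at marker positions."""

    pos: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    lam: float  # REML smoothing parameter (inf for the weighted-mean fallback)
    edf: float  # effective degrees of freedom of the fit


def _basis(x: np.ndarray) -> np.ndarray:
    """Cubic B-spline design matrix with quantile-spaced interior knots."""
    n = len(x)
    n_interior = int(np.clip(n // _KNOT_EVERY, _MIN_KNOTS, _MAX_KNOTS))
    probs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
    interior = np.unique(np.quantile(x, probs))
    x0, x1 = float(x[0]), float(x[-1])
    interior = interior[(interior > x0) & (interior < x1)]
    t = np.r_[[x0] * (_SPLINE_DEGREE + 1), interior, [x1] * (_SPLINE_DEGREE + 1)]
    return BSpline.design_matrix(x, t, _SPLINE_DEGREE, extrapolate=False).toarray()


def smooth_chromosome(
    pos: np.ndarray,
    freq: np.ndarray,
    weights: np.ndarray | None = None,
    ci_level: float = 0.95,
) -> ChromosomeFit:
    """Fit the REML penalized spline to one chromosome's raw frequencies.

    Parameters
    ----------
    pos
        Sorted 1-based marker positions.
    freq
        Raw variant frequencies at those markers.
    weights
        Observation weights (read depths); normalized internally.
    ci_level
        Pointwise confidence level for the Wald band.
    """
    pos = np.asarray(pos, dtype=float)
    freq = np.asarray(freq, dtype=float)
    n = len(pos)
    if n != len(freq):
        raise ValueError("pos and freq lengths differ")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.mean()
    zc = stats.norm.ppf(0.5 + ci_level / 2.0)

    B = _basis(pos) if n >= 12 else None
    if B is None or n < B.shape[1]:
        logger.warning("chromosome with %d markers: falling back to weighted mean", n)
        mean = float(np.average(freq, weights=w))
        resid_var = float(np.average((freq - mean) ** 2, weights=w)) * n / max(n - 1, 1)
        se = np.sqrt(resid_var / w.sum())
        fitted = np.full(n, mean)
        return _clamped_fit(pos, fitted, fitted - zc * se, fitted + zc * se,
                            lam=np.inf, edf=1.0)

    K = B.shape[1]
    # second-order difference penalty on spline coefficients
    D = np.diff(np.eye(K), n=2, axis=0)
    P = D.T @ D
    A = (B * w[:, None]).T @ B
    b = B.T @ (w * freq)
    yWy = float(np.sum(w * freq**2))

    # Demmler-Reinsch diagonalization: A = R'R, C = R^-T P R^-1 = U s U'
    R = linalg.cholesky(A + 1e-10 * np.eye(K), lower=False)
    tmp = linalg.solve_triangular(R.T, P, lower=True)
    C = linalg.solve_triangular(R.T, tmp.T, lower=True)
    C = 0.5 * (C + C.T)
    s, U = linalg.eigh(C)
    s = np.clip(s, 0.0, None)
    null_dim = int(np.sum(s < 1e-9 * max(s.max(), 1.0)))  # = 2 for a D2 penalty
    z = U.T @ linalg.solve_triangular(R.T, b, lower=True)

    pos_s = s[s > 1e-9 * max(s.max(), 1.0)]

    def neg2_reml(loglam: float) -> float:
        lam = np.exp(loglam)
        denom = 1.0 + lam * s
        rss_pen = max(yWy - float(np.sum(z**2 / denom)), 1e-12)
        return (
            (n - null_dim) * np.log(rss_pen)
            + float(np.sum(np.log1p(lam * pos_s)))
            - (K - null_dim) * loglam
        )

    res = optimize.minimize_scalar(neg2_reml, bounds=(-15.0, 30.0), method="bounded")
    lam = float(np.exp(res.x))
    denom = 1.0 + lam * s
    alpha = z / denom
    theta = linalg.solve_triangular(R, U @ alpha, lower=False)
    fitted = B @ theta
    rss_pen = max(yWy - float(np.sum(z**2 / denom)), 1e-12)
    sigma2 = rss_pen / (n - null_dim)
    Btilde = B @ linalg.solve_triangular(R, U, lower=False)
    var_f = sigma2 * (Btilde**2 @ (1.0 / denom))
    se = np.sqrt(np.clip(var_f, 0.0, None))
    edf = float(np.sum(1.0 / denom))
    return _clamped_fit(pos, fitted, fitted - zc * se, fitted + zc * se, lam=lam, edf=edf)


def _clamped_fit(pos, fitted, lower, upper, lam, edf) -> ChromosomeFit:
    fitted = np.clip(fitted, 0.0, 1.0)
    lower = np.minimum(np.clip(lower, 0.0, 1.0), fitted)
    upper = np.maximum(np.clip(upper, 0.0, 1.0), fitted)
    return ChromosomeFit(pos=pos, fitted=fitted, lower=lower, upper=upper, lam=lam, edf=edf)


def smooth_profile(
    freq: pd.DataFrame, ci_level: float = 0.95, weight_col: str = "depth"
) -> pd.DataFrame:
    """Smooth a whole-genome frequency profile chromosome by chromosome.

    ``freq`` is a frequency table (chrom, pos, freq and optionally a depth
    column used as weights).  Returns one row per marker with columns
    ``chrom, pos, smoothed, lower, upper`` plus the per-chromosome
    smoothing parameter in ``df.attrs['lambda']``.
    """
    frames = []
    lambdas: dict[str, float] = {}
    for chrom, sub in freq.groupby("chrom", sort=False, observed=True):
        weights = sub[weight_col].to_numpy() if weight_col in sub.columns else None
        fit = smooth_chromosome(
            sub["pos"].to_numpy(), sub["freq"].to_numpy(), weights, ci_level
        )
        lambdas[str(chrom)] = fit.lam
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": sub["pos"].to_numpy(),
                 "smoothed": fit.fitted, "lower": fit.lower, "upper": fit.upper}
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["lambda"] = lambdas
    return out


def _runs(state: np.ndarray, merge_gap: int) -> list[tuple[int, int, int]]:
    """Maximal same-sign runs of a -1/0/+1 state vector, merging short gaps."""
    runs: list[tuple[int, int, int]] = []  # (start, end inclusive, sign)
    i = 0
    n = len(state)
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        sign = state[i]
        j = i
        while j + 1 < n and state[j + 1] == sign:
            j += 1
        runs.append((i, j, int(sign)))
        i = j + 1
    # merge runs of equal sign separated by fewer than merge_gap markers
    merged: list[tuple[int, int, int]] = []
    for run in runs:
        if merged and merged[-1][2] == run[2] and run[0] - merged[-1][1] - 1 < merge_gap:
            merged[-1] = (merged[-1][0], run[1], run[2])
        else:
            merged.append(run)
    return merged


def call_qtls(
    smoothed: pd.DataFrame,
    lower: float = 0.30,
    upper: float = 0.70,
    min_markers: int = 10,
    merge_gap: int = 5,
) -> pd.DataFrame:
    """Call QTL intervals where the smoothed frequency leaves [lower, upper].

    One call per maximal run of consecutive markers beyond a threshold
    spanning at least ``min_markers`` markers; runs of the same direction
    separated by fewer than ``merge_gap`` sub-threshold markers are
    merged.  Calls are sorted by deviation of the peak from 50%,
    descending.
    """
    if not 0.0 < lower < upper < 1.0:
        raise ValueError("thresholds must satisfy 0 < lower < upper < 1")
    rows = []
    for chrom, sub in smoothed.groupby("chrom", sort=False, observed=True):
        sm = sub["smoothed"].to_numpy()
        pos = sub["pos"].to_numpy()
        state = np.where(sm > upper, 1, np.where(sm < lower, -1, 0))
        for i, j, sign in _runs(state, merge_gap):
            n_markers = j - i + 1
            if n_markers < min_markers:
                continue
            seg = sm[i : j + 1]
            peak_rel = int(np.argmax(seg) if sign > 0 else np.argmin(seg))
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[i]),
                    "end": int(pos[j]),
                    "direction": "superior" if sign > 0 else "inferior",
                    "peak_freq": float(seg[peak_rel]),
                    "peak_pos": int(pos[i + peak_rel]),
                    "n_markers": n_markers,
                }
            )
    calls = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "direction", "peak_freq", "peak_pos", "n_markers"]
    )
    if len(calls):
        calls = calls.iloc[
            np.argsort(-(calls["peak_freq"] - 0.5).abs().to_numpy(), kind="stable")
        ].reset_index(drop=True)
    return calls


def report_linkage(
    calls: pd.DataFrame,
    selected: pd.DataFrame,
    random: pd.DataFrame,
    lower: float = 0.30,
    upper: float = 0.70,
) -> pd.DataFrame:
    """Tabulate QTL calls with the random-pool smoothed value as control.

    Both smoothed profiles must cover the identical marker set.  A call is
    flagged ``selection_independent`` when the random pool also deviates
    beyond the thresholds at the call's peak position.
    """
    same = (
        len(selected) == len(random)
        and (selected["chrom"].to_numpy() == random["chrom"].to_numpy()).all()
        and (selected["pos"].to_numpy() == random["pos"].to_numpy()).all()
    )
    if not same:
        raise ValueError("selected and random pools were smoothed on different marker sets")
    rand_at = random.set_index(["chrom", "pos"])["smoothed"]
    rows = []
    for call in calls.itertuples(index=False):
        r = float(rand_at.loc[(call.chrom, call.peak_pos)])
        rows.append(
            {
                "chrom": call.chrom,
                "start": call.start,
                "end": call.end,
                "direction": call.direction,
                "peak_pct": round(100.0 * call.peak_freq, 1),
                "peak_pos": call.peak_pos,
                "n_markers": call.n_markers,
                "random_pool_at_peak_pct": round(100.0 * r, 1),
                "selection_independent": bool(r > upper or r < lower),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "direction", "peak_pct", "peak_pos",
            "n_markers", "random_pool_at_peak_pct", "selection_independent",
        ],
    )
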