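"""Predation pressure from predator gut screens.

Each screened predator species i contributes a detection frequency f_ij
(fraction of its individuals positive for mimic j).  The community-wide
pressure on mimic j is the killing value

    K_j = sum_i -log(1 - f_ij),

an additive measure on the log-survival scale: independent mortality
sources combine by summation of their K contributions.  For the one
araneophagous, size-limited predator the raw frequencies are discounted by
a logistic capture probability in the mimic/predator body-size ratio,
because detections may reflect juvenile (non-mimetic) prey.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GUILDS = ("visual", "ant_eating", "non_visual")

#: logistic capture-probability coefficients fitted across spider guilds
CAPTURE_INTERCEPT = -1.99
CAPTURE_SLOPE = 2.11


@dataclass
class GutScreenTable:
    """Predator x mimic detection fractions with guild labels and sizes.

    ``frequencies``: DataFrame indexed by predator_id, one column per
    mimic, entries are fractions in [0, 1].  ``n_screened``: individuals
    screened per predator.  ``size_limited``: predators whose raw
    frequencies need the capture-probability adjustment.
    """

    frequencies: pd.DataFrame
    guild: pd.Series
    n_screened: pd.Series
    size_limited: pd.Series

    def __post_init__(self) -> None:
        f = self.frequencies.to_numpy(dtype=float)
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("detection fractions must lie in [0, 1]")
        if (self.n_screened < 1).any():
            raise ValueError("each predator needs N >= 1 screened individuals")
        bad = ~self.guild.isin(GUILDS)
        if bad.any():
            raise ValueError(f"unknown guild labels: {self.guild[bad].tolist()}")

    @property
    def predators(self) -> pd.Index:
        return self.frequencies.index

    @property
    def mimics(self) -> pd.Index:
        return self.frequencies.columns

    @classmethod
    def from_percent_table(cls, df: pd.DataFrame) -> "GutScreenTable":
        """Build from a table whose mimic columns are printed percentages."""
        meta = {"predator_id", "family", "guild", "size_limited", "N"}
        df = df.set_index("predator_id") if "predator_id" in df.columns else df
        mimic_cols = [c for c in df.columns if c not in meta]
        freq = df[mimic_cols].astype(float) / 100.0
        return cls(frequencies=freq, guild=df["guild"],
                   n_screened=df["N"].astype(int),
                   size_limited=df.get(
                       "size_limited",
                       pd.Series(0, index=df.index)).astype(bool))


@dataclass
class KResult:
    """Killing values per mimic with the per-predator contributions."""

    k: pd.Series
    contributions: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.k < 0).any():
            raise ValueError("killing values must be non-negative")


def capture_probability(ratio) -> np.ndarray | float:
    """Logistic capture probability as a function of prey/predator size ratio.

    p = 1 / (1 + exp(-1.99 + 2.11 * ratio)); strictly decreasing in the
    ratio, p(0) ~ 0.88, p = 0.5 exactly at ratio = 1.99/2.11.
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r < 0):
        raise ValueError("size ratio must be non-negative")
    p = 1.0 / (1.0 + np.exp(CAPTURE_INTERCEPT + CAPTURE_SLOPE * r))
    return float(p) if np.isscalar(ratio) else p


def adjust_screen_frequencies(gs: GutScreenTable,
                              predator_size: pd.Series,
                              mimic_size: pd.Series) -> GutScreenTable:
    """Discount size-limited predators' frequencies by capture probability.

    For each predator flagged size-limited, f_ij is replaced by
    f_ij * p(mimic_size_j / predator_size_i); other rows are unchanged.
    """
    freq = gs.frequencies.copy()
    flagged = gs.size_limited[gs.size_limited].index
    missing = [p for p in flagged if p not in predator_size.index
               or not np.isfinite(predator_size[p])]
    if missing:
        raise ValueError(f"missing body size for size-limited predators: {missing}")
    missing_m = [m for m in gs.mimics if m not in mimic_size.index]
    if flagged.size and missing_m:
        raise ValueError(f"missing body size for mimics: {missing_m}")
    for p in flagged:
        ratios = mimic_size[gs.mimics].to_numpy(float) / float(predator_size[p])
        freq.loc[p] = freq.loc[p].to_numpy(float) * capture_probability(ratios)
    return GutScreenTable(frequencies=freq, guild=gs.guild.copy(),
                          n_screened=gs.n_screened.copy(),
                          size_limited=gs.size_limited.copy())


def killing_value(frequencies, base: str = "natural") -> float:
    """K = sum_i -log(1 - f_i) over predators, for one prey species."""
    f = np.asarray(frequencies, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if np.any(f >= 1):
        idx = np.flatnonzero(f >= 1)
        raise ValueError(
            f"frequency of 1 at position(s) {idx.tolist()}: infinite killing value")
    k = float(-np.log1p(-f).sum())
    if base == "log10":
        k /= np.log(10.0)
    elif base != "natural":
        raise ValueError("base must be 'natural' or 'log10'")
    return k


def killing_values(gs: GutScreenTable, base: str = "natural") -> KResult:
    """Killing value per mimic across all predators of the table."""
    contrib = -np.log1p(-gs.frequencies.to_numpy(dtype=float))
    if not np.all(np.isfinite(contrib)):
        bad = gs.frequencies.index[np.any(~np.isfinite(contrib), axis=1)]
        raise ValueError(f"frequency of 1 for predator(s) {bad.tolist()}")
    if base == "log10":
        contrib = contrib / np.log(10.0)
    contrib = pd.DataFrame(contrib, index=gs.predators, columns=gs.mimics)
    return KResult(k=contrib.sum(axis=0), contributions=contrib)


def classify_guild(primer_positivity: float) -> str:
    """Diet class from the fraction positive for the ant-targeting primer.

    Strictly more than 10% positive -> specialised ant-eating; otherwise
    euryphagous.
    """
    if not 0.0 <= primer_positivity <= 1.0:
        raise ValueError("positivity fraction must lie in [0, 1]")
    return "ant_eating" if primer_positivity > 0.10 else "euryphagous"


def availability_chisq(captured_counts, available_counts):
    """Pearson chi-square of captures against availability proportions.

    Expected counts are the availability proportions scaled to the total
    number of captures; df = categories - 1.
    """
    obs = np.asarray(captured_counts, dtype=float)
    avail = np.asarray(available_counts, dtype=float)
    if avail.sum() <= 0:
        raise ValueError("availability counts must sum to a positive total")
    expected = avail / avail.sum() * obs.sum()
    if np.any((expected == 0) & (obs > 0)):
        raise ValueError("observed captures in a category with zero availability")
    keep = expected > 0
    stat, p = stats.chisquare(obs[keep], expected[keep])
    return float(stat), int(keep.sum() - 1), float(p)


def _cubic_spline_design(x: np.ndarray, knots: np.ndarray):
    """Cubic B-spline design matrix and exact curvature penalty.

    The penalty is S = integral of B''(t) B''(t)^T over the knot range
    (Gauss-Legendre, exact for the piecewise-linear second derivatives),
    so its null space is exactly the linear functions.
    """
    from scipy.interpolate import BSpline
    deg = 3
    t = np.concatenate([[knots[0]] * (deg + 1), knots[1:-1],
                        [knots[-1]] * (deg + 1)])
    B = BSpline.design_matrix(x, t, deg).toarray()
    nb = B.shape[1]
    # second-derivative Gram matrix, interval by interval
    nodes, weights = np.polynomial.legendre.leggauss(3)
    S = np.zeros((nb, nb))
    eye = np.eye(nb)
    d2 = [BSpline(t, eye[:, j], deg).derivative(2) for j in range(nb)]
    for a, b in zip(knots[:-1], knots[1:]):
        if b <= a:
            continue
        xs = 0.5 * (b - a) * nodes + 0.5 * (a + b)
        w = 0.5 * (b - a) * weights
        D2 = np.column_stack([f(xs) for f in d2])
        S += (D2 * w[:, None]).T @ D2
    return B, S


@dataclass
class SmoothFit:
    """Penalized-spline regression summary."""

    fitted: np.ndarray
    edf: float
    gcv: float
    penalty: float
    f_statistic: float
    df_num: float
    df_den: float
    p_value: float
    epsilon: float = 0.0


def smooth_regression(u, K, n_knots: int = 5, eps: float = None,
                      gcv_gamma: float = 2.0) -> SmoothFit:
    """Penalized cubic spline of log killing value on unpalatability.

    Zero K values are handled as log(K + eps) with eps equal to half the
    smallest positive K (a documented sensitivity choice).  The smoothing
    parameter minimises generalized cross-validation over a log-spaced
    grid, with an inflated model-complexity cost (``gcv_gamma``, default
    2.0) because plain GCV undersmooths badly at the sample sizes this
    analysis sees (n around 13), which would leave the approximate test
    anti-conservative; the smooth term is tested with an F comparing the
    selected fit to the intercept-only model on edf - 1 numerator degrees
    of freedom.
    """
    u = np.asarray(u, dtype=float)
    K = np.asarray(K, dtype=float)
    n = len(u)
    if n < 6:
        raise ValueError("smooth regression needs at least 6 species")
    if np.any(K < 0):
        raise ValueError("killing values must be non-negative")
    if eps is None:
        positive = K[K > 0]
        eps = 0.5 * positive.min() if (K == 0).any() and positive.size else 0.0
    y = np.log(K + eps)
    n_knots = min(n_knots, max(n - 2, 3))
    knots = np.unique(np.quantile(u, np.linspace(0, 1, n_knots)))
    if len(knots) < 2:
        raise ValueError("unpalatability values are constant")
    B, P = _cubic_spline_design(u, knots)
    BtB = B.T @ B
    Bty = B.T @ y
    scale = np.trace(BtB) / max(np.trace(P), 1e-12)
    best = None
    for lam in scale * np.logspace(-8, 8, 81):
        A = BtB + lam * P
        coef = np.linalg.solve(A, Bty)
        edf = float(np.trace(np.linalg.solve(A, BtB)))
        fitted = B @ coef
        rss = float(np.sum((y - fitted) ** 2))
        denom = n - gcv_gamma * edf
        gcv = n * rss / denom**2 if denom > 0 else np.inf
        if best is None or gcv < best[0]:
            best = (gcv, lam, fitted, edf)
    gcv, lam, fitted, edf = best
    rss1 = float(np.sum((y - fitted) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df_num = max(edf - 1.0, 1e-8)
    df_den = max(n - edf, 1e-8)
    f_stat = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    p = float(stats.f.sf(f_stat, df_num, df_den))
    return SmoothFit(fitted=fitted, edf=edf, gcv=gcv, penalty=lam,
                     f_statistic=float(f_stat), df_num=df_num, df_den=df_den,
                     p_value=p, epsilon=float(eps))
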