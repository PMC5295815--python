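"""Statistics for staged predator-prey trials.

Each trial presents one prey species to one predator individual and
records whether the prey was captured and, if attacked, an ordinal
post-attack reaction: eaten (rank 0), eaten but mouth cleaned (rank 1), or
spat out (rank 2), rescaled to a 0-1 aversion score.  Capture frequencies
across prey types within predator individuals are compared with Cochran's
Q; the aversion score is regressed on the unpalatability index with a
binomial (logit) GLM; and the combined mortality from several predators is
summarised by the same killing-value kernel as the field gut screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .predation import killing_value

TRIAL_COLUMNS = ("predator_id", "prey_species", "captured", "post_attack_rank")


@dataclass
class TrialTable:
    """One record per predator individual x prey presentation."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"predator_id", "prey_species", "captured"} - set(self.data.columns)
        if missing:
            raise ValueError(f"missing trial columns: {sorted(missing)}")
        if not self.data["captured"].isin([0, 1]).all():
            raise ValueError("captured must be 0/1")
        if "post_attack_rank" in self.data.columns:
            ranks = self.data["post_attack_rank"].dropna()
            if not ranks.isin([0, 1, 2]).all():
                raise ValueError("post-attack ranks must be 0, 1 or 2")
        dup = self.data.duplicated(["predator_id", "prey_species"])
        if dup.any():
            raise ValueError("one record per predator x prey presentation")

    def capture_matrix(self) -> pd.DataFrame:
        """Individuals x prey binary capture matrix (complete blocks)."""
        return self.data.pivot(index="predator_id", columns="prey_species",
                               values="captured")


def postattack_score(rank: int) -> float:
    """Rescale the ordinal post-attack rank to an aversion score in [0, 1].

    0 = eaten, 0.5 = eaten but mouth cleaned, 1 = spat out.
    """
    if rank not in (0, 1, 2):
        raise ValueError("post-attack rank must be 0, 1 or 2")
    return rank / 2.0


def cochran_q(binary_matrix):
    """Cochran's Q test for equal success rates across matched prey types.

    Rows are predator individuals (complete blocks), columns prey types.
    Returns (Q, df, p) with df = prey types - 1 and a chi-square p-value.
    """
    x = np.asarray(binary_matrix, dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError("Cochran's Q needs complete blocks (no missing cells)")
    if not np.isin(x, [0, 1]).all():
        raise ValueError("matrix must be binary")
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least two prey types")
    col = x.sum(axis=0)
    row = x.sum(axis=1)
    denom = k * row.sum() - np.sum(row**2)
    if denom == 0:
        raise ValueError("all rows constant (all-zero or all-one): Q undefined")
    q = k * (k - 1) * np.sum((col - col.mean()) ** 2) / denom
    df = k - 1
    return float(q), df, float(stats.chi2.sf(q, df))


def binomial_glm(x, y):
    """Binomial (logit) GLM of [0, 1] scores on a single predictor.

    Fit by iteratively reweighted least squares; the slope is tested with
    a deviance-based quasi-F on (1, n-2) degrees of freedom, which
    tolerates the non-integer 0/0.5/1 scores (quasi-likelihood scale).
    Perfect separation is flagged rather than raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("scores must lie in [0, 1]")
    n = len(y)
    X = sm.add_constant(x)
    separated = False
    if np.ptp(y) == 0:
        coefs = np.array([sm.families.links.Logit()(np.clip(y[0], 1e-8, 1 - 1e-8)),
                          0.0])
        return {"coefficients": coefs, "f_statistic": 0.0,
                "df": (1, n - 2), "p_value": 1.0, "separated": False}
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        full = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        null = sm.GLM(y, np.ones((n, 1)), family=sm.families.Binomial()).fit()
    if np.abs(full.params[1]) > 25 or not np.all(np.isfinite(full.bse)):
        separated = True
    pearson_phi = full.pearson_chi2 / max(n - 2, 1)
    f_stat = (null.deviance - full.deviance) / max(pearson_phi, 1e-12)
    df = (1, n - 2)
    p = float(stats.f.sf(f_stat, *df))
    return {"coefficients": np.asarray(full.params), "f_statistic": float(f_stat),
            "df": df, "p_value": p, "separated": separated}


def capture_frequencies(tt: TrialTable) -> pd.Series:
    """Per-prey capture frequency across predator individuals.

    These are the summaries handed to an off-the-shelf marginal model
    (e.g. GEE with exchangeable working correlation) when the repeated use
    of predator individuals must be accounted for.
    """
    return tt.data.groupby("prey_species")["captured"].mean()


def trial_killing_value(capture_probabilities, base: str = "natural") -> float:
    """Killing value from staged-trial capture probabilities.

    Same kernel as the field estimate: K = sum -log(1 - p) over the
    predators tested.
    """
    return killing_value(capture_probabilities, base=base)
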