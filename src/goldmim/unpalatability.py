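"""Defensive traits, proxy-based imputation, and the unpalatability index.

A species' unpalatability u_j is the sum of its defensive-trait values,
each trait first scaled by its across-species maximum so that traits of
very different ranges (a 0/1 communal-attack flag, spine lengths in mm,
gland areas in mm^2) contribute comparably:

    u_j = sum_i x_ij / max_j(x_ij)

Traits that could not be measured directly are interpolated from proxy
body measures (gaster or thorax length) via ordinary least squares, and
each species carries a weight equal to its proportion of directly
observed traits; downstream regressions use those weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: the core defensive traits of the 100-species analysis
CORE_TRAITS = (
    "sting_length_mm",
    "n_spines",
    "total_spine_length_mm",
    "mandible_size_mm",
    "cuticle_thickness_mm",
    "gland_area_mm2",
    "communal_attack",
)

#: extra behavioural traits of the five-species re-estimate, where body
#: size also enters the index
EXTENDED_TRAITS = CORE_TRAITS + (
    "biting_frequency",
    "sprays_chemicals",
    "body_size_mm",
)

PROXY_COLUMNS = ("gaster_length_mm", "thorax_length_mm", "body_size_mm")

#: trait -> proxy used to interpolate it when unmeasured
IMPUTATION_PROXIES = {
    "gland_area_mm2": "gaster_length_mm",
    "sting_length_mm": "gaster_length_mm",
    "cuticle_thickness_mm": "thorax_length_mm",
}


@dataclass
class TraitTable:
    """Per-species trait measurements plus an observed/imputed mask.

    ``data`` is indexed by species_id; ``observed`` is a boolean frame of
    the same shape restricted to trait columns (True = directly measured).
    Missing cells are NaN until imputed.
    """

    data: pd.DataFrame
    observed: pd.DataFrame = None
    traits: tuple = CORE_TRAITS

    def __post_init__(self) -> None:
        self.traits = tuple(t for t in self.traits if t in self.data.columns)
        if not self.traits:
            raise ValueError("trait table contains none of the configured traits")
        if self.observed is None:
            self.observed = self.data[list(self.traits)].notna()
        vals = self.data[list(self.traits)].to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("trait measurements must be non-negative")
        if "biting_frequency" in self.data.columns:
            bf = self.data["biting_frequency"].dropna()
            if ((bf < 0) | (bf > 1)).any():
                raise ValueError("biting_frequency must lie in [0, 1]")

    @property
    def species(self) -> pd.Index:
        return self.data.index

    @classmethod
    def from_csv(cls, path, traits: tuple = CORE_TRAITS) -> "TraitTable":
        df = pd.read_csv(path, index_col="species_id")
        return cls(df, traits=traits)


@dataclass
class UnpalatabilityResult:
    """Unpalatability index u_j and observed-fraction weights per species."""

    u: pd.Series
    weight: pd.Series
    trait_maxima: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if ((self.weight <= 0) | (self.weight > 1)).any():
            raise ValueError("weights must lie in (0, 1]")
        if (self.u < 0).any():
            raise ValueError("unpalatability index must be non-negative")


@dataclass
class LinearInterpolator:
    """OLS line trait ~ proxy used to fill unmeasured trait cells."""

    trait: str
    proxy: str
    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict(self, proxy_values) -> np.ndarray:
        pred = self.intercept + self.slope * np.asarray(proxy_values, dtype=float)
        return np.clip(pred, 0.0, None)


def ellipse_gland_area(d1: float, d2: float) -> float:
    """Area of a defensive gland from its two perpendicular diameters (mm).

    The gland is treated as a regular ellipse: pi * (d1/2) * (d2/2).
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("gland diameters must be non-negative")
    return float(np.pi * (d1 / 2.0) * (d2 / 2.0))


def fit_trait_interpolators(tt: TraitTable,
                            proxies: dict = None) -> dict[str, LinearInterpolator]:
    """Fit the trait-from-proxy OLS lines on species with both observed.

    Default models: gland area ~ gaster length, sting length ~ gaster
    length, cuticle thickness ~ thorax length.  Each fit needs at least
    three complete species and a non-constant proxy.
    """
    proxies = dict(IMPUTATION_PROXIES if proxies is None else proxies)
    models: dict[str, LinearInterpolator] = {}
    for trait, proxy in proxies.items():
        if trait not in tt.data.columns or proxy not in tt.data.columns:
            continue
        sub = tt.data[[trait, proxy]].dropna()
        sub = sub[tt.observed.loc[sub.index, trait]]
        if len(sub) < 3:
            raise ValueError(f"need >=3 complete species to fit {trait} ~ {proxy}")
        x = sub[proxy].to_numpy(dtype=float)
        y = sub[trait].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"constant proxy {proxy}: cannot fit {trait}")
        res = stats.linregress(x, y)
        models[trait] = LinearInterpolator(
            trait=trait, proxy=proxy, slope=float(res.slope),
            intercept=float(res.intercept), r_squared=float(res.rvalue**2),
            n=len(sub))
    return models


def impute_missing_traits(tt: TraitTable,
                          models: dict[str, LinearInterpolator]) -> TraitTable:
    """Fill unmeasured trait cells from the proxy regressions.

    Observed cells are never changed; negative predictions are floored at
    zero; the observed mask is updated so imputed cells count against the
    species weight.
    """
    data = tt.data.copy()
    observed = tt.observed.copy()
    for trait, model in models.items():
        if trait not in data.columns:
            continue
        missing = data[trait].isna()
        if not missing.any():
            continue
        proxy_vals = data.loc[missing, model.proxy]
        if proxy_vals.isna().any():
            bad = proxy_vals.index[proxy_vals.isna()].tolist()
            raise ValueError(
                f"species {bad} need imputation of {trait} but lack proxy "
                f"{model.proxy}")
        data.loc[missing, trait] = model.predict(proxy_vals)
        observed.loc[missing, trait] = False
    return TraitTable(data, observed=observed, traits=tt.traits)


def unpalatability_index(tt: TraitTable) -> UnpalatabilityResult:
    """Compute u_j = sum_i x_ij / max(x_i) over the configured traits.

    Maxima are taken across species after any imputation.  All-zero trait
    columns carry no information and are excluded from both the sum and
    the trait count; remaining missing cells are treated as zero
    contributions but still lower the species weight.
    """
    if len(tt.data) == 0:
        raise ValueError("empty trait table")
    x = tt.data[list(tt.traits)].astype(float)
    maxima = x.max(axis=0, skipna=True)
    active = maxima[maxima > 0].index
    scaled = x[active] / maxima[active]
    u = scaled.sum(axis=1, skipna=True)
    weight = tt.observed[list(tt.traits)].mean(axis=1)
    return UnpalatabilityResult(u=u, weight=weight, trait_maxima=maxima[active])


def bartlett_test(values, group_labels):
    """Bartlett's test of variance homogeneity across groups.

    Returns (K^2, df, p).  Requires at least two groups of size >= 2 and
    positive variance within every group.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need at least two groups with >=2 members")
    if any(np.var(g, ddof=1) == 0 for g in groups):
        raise ValueError("a group has zero variance; Bartlett statistic undefined")
    stat, p = stats.bartlett(*groups)
    return float(stat), len(groups) - 1, float(p)
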