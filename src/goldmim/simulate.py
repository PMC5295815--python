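"""Synthetic data with the statistical structure the analyses assume.

The generators emulate the study system at its native scale — about 100
golden mimic species, 13 predator species in three guilds, and staged
trials with five mimic prey — so that every stage of the pipeline can be
exercised and calibrated without the (undeposited) field measurements:

* a pure-birth phylogeny with Brownian trait evolution at a known Pagel
  lambda (for the comparative regressions),
* defensive traits positively coupled to body size, a golden patch area
  that is a quadratic function of the true unpalatability index, and
  colour features drawn from planted Gaussian clusters (for the ring
  ordination and signal-defence regressions),
* binomial gut-screen detections whose probabilities decline with
  unpalatability for visually hunting guilds, and
* Bernoulli staged-trial captures with an ordinal post-attack response
  increasing with unpalatability.

Every generator consumes a single seeded random stream derived from the
mandatory config seed, so outputs are bit-reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .colour import ColourMatrix, N_BODY_PARTS, RGB_CHANNELS
from .phylo import BrownianVCV, pagel_transform, vcv_from_tree
from .predation import GutScreenTable
from .trials import TrialTable
from .unpalatability import TraitTable, unpalatability_index

BODY_PARTS = ("head", "appendages", "pronotum", "mesonotum", "metanotum",
              "petiole", "gaster1", "gaster2")


@dataclass
class SimConfig:
    """Parameters of the synthetic study system (defaults = study scale)."""

    seed: int
    n_species: int = 100
    birth_rate: float = 1.0
    bm_sigma2: float = 1.0
    true_lambda: float = 1.0
    #: linear and quadratic coefficients of golden area on unpalatability
    area_slope: float = 1.0
    area_quadratic: float = 0.1
    area_noise_sd: float = 0.5
    trait_size_corr: float = 0.8
    #: planted colour clusters (the study inferred ten putative rings)
    n_clusters: int = 10
    cluster_separation: float = 60.0
    cluster_sd_fraction: float = 0.05
    #: predators per guild, matching the 13 screened predator species
    n_predators: dict = field(default_factory=lambda: {
        "visual": 5, "ant_eating": 5, "non_visual": 3})
    n_screened: int = 50
    detection_p0: float = 0.08
    detection_decay: float = 3.0
    #: staged trials: predator individuals per species, five mimic prey
    n_prey: int = 5
    n_individuals: int = 26
    capture_p_range: tuple = (0.05, 0.6)
    postattack_slope: float = 4.0
    mullerian_first: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.trait_size_corr <= 1:
            raise ValueError("trait-size correlation must lie in [0, 1]")
        if self.bm_sigma2 < 0 or self.birth_rate <= 0:
            raise ValueError("rates and variances must be positive")
        if not 0 <= self.detection_p0 <= 1:
            raise ValueError("detection probability must lie in [0, 1]")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_tree_bm(cfg: SimConfig):
    """Pure-birth tree plus one Brownian tip trait at the configured lambda.

    The trait vector is drawn from N(0, sigma^2 * V_lambda) where V is the
    Brownian covariance of the simulated tree, i.e. the lambda transform is
    applied at generation time.  Returns (tree, tip trait Series, V).
    """
    if cfg.n_species < 3:
        raise ValueError("need at least 3 species")
    rng = cfg.rng(1)
    pyrng = random.Random(int(rng.integers(2**31 - 1)))
    tree = treesim.birth_death_tree(
        birth_rate=cfg.birth_rate, death_rate=0.0,
        num_extant_tips=cfg.n_species, rng=pyrng)
    # the generator stops exactly at the n-th speciation, leaving the newest
    # pair of tips with zero pendant edges (singular covariance); sample the
    # process between events by running all lineages for the exponential
    # waiting time to the next birth
    extra = rng.exponential(1.0 / (cfg.birth_rate * cfg.n_species))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i:03d}"
    V = vcv_from_tree(tree)
    Vl = pagel_transform(V, cfg.true_lambda)
    traits = draw_brownian_tips(Vl, cfg.bm_sigma2, rng)
    return tree, pd.Series(traits, index=Vl.taxa, name="trait"), V


def draw_brownian_tips(V: BrownianVCV, sigma2: float,
                       rng: np.random.Generator) -> np.ndarray:
    """One multivariate-normal draw of tip values under sigma^2 * V."""
    n = len(V)
    if sigma2 == 0:
        return np.zeros(n)
    cov = sigma2 * V.matrix
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(cov + 1e-10 * np.trace(cov) / n * np.eye(n))
    return L @ rng.standard_normal(n)


def simulate_community(cfg: SimConfig):
    """Trait table and colour matrix for a synthetic mimic community.

    Continuous defensive traits share a latent body-size factor at the
    configured Pearson correlation; the proxies (gaster, thorax) are noisy
    fractions of body length; the golden patch area is a quadratic in the
    true unpalatability index plus Gaussian noise; colour features come
    from ``n_clusters`` planted Gaussian blobs.  Returns
    (TraitTable, ColourMatrix, true unpalatability Series).
    """
    rng = cfg.rng(2)
    n = cfg.n_species
    species = [f"sp{i:03d}" for i in range(n)]
    rho = cfg.trait_size_corr
    z_body = rng.standard_normal(n)
    body = 9.0 + 2.0 * z_body  # mm, spanning the 3-15 mm study range

    def correlated_trait(mean: float, sd: float) -> np.ndarray:
        z = rho * z_body + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        return np.clip(mean + sd * z, 0.0, None)

    data = pd.DataFrame({
        "sting_length_mm": correlated_trait(1.0, 0.2),
        "n_spines": np.round(correlated_trait(4.0, 0.8)),
        "total_spine_length_mm": correlated_trait(2.5, 0.5),
        "mandible_size_mm": correlated_trait(0.8, 0.16),
        "cuticle_thickness_mm": correlated_trait(0.03, 0.006),
        "gland_area_mm2": correlated_trait(2.0, 0.4),
        "communal_attack": rng.binomial(1, 0.5, n).astype(float),
        "gaster_length_mm": np.clip(0.4 * body + rng.normal(0, 0.15, n), 0.05, None),
        "thorax_length_mm": np.clip(0.3 * body + rng.normal(0, 0.15, n), 0.05, None),
        "body_size_mm": np.clip(body, 1.0, None),
    }, index=pd.Index(species, name="species_id"))
    tt = TraitTable(data)
    u = unpalatability_index(tt).u
    area = (1.0 + cfg.area_slope * u + cfg.area_quadratic * u**2
            + rng.normal(0, cfg.area_noise_sd, n))
    area = np.clip(area, 0.0, None)

    centers = _planted_centres(cfg, rng)
    labels = rng.permutation(np.resize(np.arange(cfg.n_clusters), n))
    sd = cfg.cluster_sd_fraction * cfg.cluster_separation
    feats = np.clip(centers[labels] + rng.normal(0, sd, (n, 24)), 0.0, 255.0)
    cols = pd.MultiIndex.from_product([BODY_PARTS, RGB_CHANNELS])
    part_rgb = pd.DataFrame(feats, index=data.index, columns=cols)
    lengths = pd.DataFrame(
        np.clip(rng.normal(body[:, None] / N_BODY_PARTS, 0.1,
                           size=(n, N_BODY_PARTS)), 0.05, None),
        index=data.index, columns=list(BODY_PARTS))
    cm = ColourMatrix(part_rgb=part_rgb, part_length=lengths,
                      body_size=pd.Series(np.clip(body, 1.0, None),
                                          index=data.index),
                      golden_area=pd.Series(area, index=data.index))
    cm.ring_truth = pd.Series(labels, index=data.index, name="ring_truth")
    return tt, cm, u


def _planted_centres(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Cluster centres in RGB feature space at the configured separation.

    Centres sit on a randomly rotated regular simplex, so *every* pair of
    planted rings differs by exactly ``cluster_separation`` in the
    24-dimensional feature space — the separation parameter means the same
    thing for all pairs.
    """
    k = cfg.n_clusters
    if k == 1:
        return rng.uniform(40.0, 215.0, (1, 24))
    simplex = np.eye(k) - 1.0 / k
    simplex /= np.sqrt(2.0)  # unit pairwise distances
    q, _ = np.linalg.qr(rng.standard_normal((24, 24)))
    centers = 128.0 + cfg.cluster_separation * simplex @ q[:, :k].T
    return np.clip(centers, 0.0, 255.0)


def simulate_gut_screen(cfg: SimConfig, u: pd.Series = None) -> GutScreenTable:
    """Binomial gut-screen detections for three predator guilds.

    Detection probability for mimic j by a visually hunting predator
    declines exponentially with the (max-scaled) unpalatability,
    pi = p0 * exp(-decay * u~); non-visual predators detect at the flat
    base rate.  Frequencies are binomial(N, pi)/N per predator.
    """
    rng = cfg.rng(3)
    if u is None:
        u = pd.Series(np.linspace(0, 7, cfg.n_prey if cfg.n_prey > 1 else 2),
                      index=[f"mimic{i}" for i in range(max(cfg.n_prey, 2))])
    u_scaled = u / u.max() if u.max() > 0 else u * 0.0
    rows, guilds, ns = [], [], []
    names = []
    for guild, count in cfg.n_predators.items():
        for i in range(count):
            if guild == "non_visual":
                pi = np.full(len(u), cfg.detection_p0)
            else:
                pi = cfg.detection_p0 * np.exp(
                    -cfg.detection_decay * u_scaled.to_numpy(float))
            f = rng.binomial(cfg.n_screened, pi) / cfg.n_screened
            rows.append(f)
            guilds.append(guild)
            ns.append(cfg.n_screened)
            names.append(f"{guild}_{i}")
    idx = pd.Index(names, name="predator_id")
    freq = pd.DataFrame(rows, index=idx, columns=u.index)
    return GutScreenTable(
        frequencies=freq, guild=pd.Series(guilds, index=idx),
        n_screened=pd.Series(ns, index=idx),
        size_limited=pd.Series(False, index=idx))


def simulate_trials(cfg: SimConfig, u: pd.Series = None,
                    capture_p: pd.Series = None) -> TrialTable:
    """Staged trials: Bernoulli captures and ordinal post-attack ranks.

    Capture probabilities default to an even spread over
    ``capture_p_range`` (decreasing in unpalatability); ranks come from a
    cumulative-logit model whose linear predictor increases with the
    max-scaled unpalatability, so better-defended prey are spat out more
    often.  ``mullerian_first`` reproduces the constrained prey order used
    with naive vertebrate predators (most defended prey presented first).
    """
    rng = cfg.rng(4)
    if u is None:
        u = pd.Series(np.linspace(7, 0.5, cfg.n_prey),
                      index=[f"prey{i}" for i in range(cfg.n_prey)])
    u_scaled = (u / u.max()).to_numpy(float) if u.max() > 0 else np.zeros(len(u))
    if capture_p is None:
        lo, hi = cfg.capture_p_range
        capture_p = pd.Series(hi - (hi - lo) * u_scaled, index=u.index)
    records = []
    prey_order = np.argsort(-u.to_numpy(float)) if cfg.mullerian_first else None
    for ind in range(cfg.n_individuals):
        order = (prey_order if prey_order is not None
                 else rng.permutation(len(u)))
        for j in order:
            prey = u.index[j]
            captured = int(rng.random() < capture_p[prey])
            eta = cfg.postattack_slope * (u_scaled[j] - 0.5)
            # cumulative logit: P(rank >= 1), P(rank = 2)
            p_ge1 = 1 / (1 + np.exp(-eta))
            p2 = 1 / (1 + np.exp(-(eta - 1.0)))
            r = rng.random()
            rank = 2 if r < p2 else (1 if r < p_ge1 else 0)
            records.append({"predator_id": f"ind{ind:02d}",
                            "prey_species": prey,
                            "captured": captured,
                            "post_attack_rank": rank if captured else np.nan})
    return TrialTable(pd.DataFrame.from_records(records))
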