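"""Colour-pattern quantification and mimicry-ring detection.

Each species is described by the mean RGB value of eight dorsal body parts
(head, appendages, three notal segments, petiole and two gastral/abdominal
regions), the length of each part, the total body length and the absolute
area of the dorsal golden patch.  Ring structure is sought by ordinating a
size-weighted colour matrix (Bray-Curtis dissimilarity, non-metric
multidimensional scaling) and scanning cluster counts with k-means, scoring
each partition with the simple structure index (ssi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.manifold import MDS

N_BODY_PARTS = 8
RGB_CHANNELS = ("R", "G", "B")

#: long-format colour table columns
COLOUR_COLUMNS = (
    "species_id", "part", "R", "G", "B",
    "part_length_mm", "body_size_mm", "golden_area_mm2",
)


@dataclass
class ColourMatrix:
    """Per-species colour-pattern measurements.

    ``part_rgb`` is a DataFrame indexed by species with a column MultiIndex
    (part, channel); ``part_length`` has one column per part (mm).
    """

    part_rgb: pd.DataFrame
    part_length: pd.DataFrame
    body_size: pd.Series
    golden_area: pd.Series

    def __post_init__(self) -> None:
        vals = self.part_rgb.to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 255):
            raise ValueError("RGB components must lie in [0, 255]")
        if np.any(self.part_length.to_numpy(dtype=float) < 0):
            raise ValueError("part lengths must be non-negative")
        if np.any(self.golden_area.to_numpy(dtype=float) < 0):
            raise ValueError("golden areas must be non-negative")

    @property
    def species(self) -> pd.Index:
        return self.part_rgb.index

    @property
    def parts(self) -> list[str]:
        return list(self.part_rgb.columns.get_level_values(0).unique())

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ColourMatrix":
        """Build from a long table with the ``COLOUR_COLUMNS`` schema."""
        missing = set(COLOUR_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing colour-table columns: {sorted(missing)}")
        rgb = df.pivot(index="species_id", columns="part",
                       values=list(RGB_CHANNELS))
        # pivot gives (channel, part); flip to (part, channel)
        rgb.columns = rgb.columns.swaplevel(0, 1)
        rgb = rgb.sort_index(axis=1)
        lengths = df.pivot(index="species_id", columns="part",
                           values="part_length_mm")
        per_sp = df.groupby("species_id")[["body_size_mm", "golden_area_mm2"]].first()
        per_sp = per_sp.loc[rgb.index]
        return cls(rgb, lengths.loc[rgb.index],
                   per_sp["body_size_mm"], per_sp["golden_area_mm2"])

    def to_long(self) -> pd.DataFrame:
        rows = []
        for sp in self.species:
            for part in self.parts:
                rows.append({
                    "species_id": sp, "part": part,
                    "R": self.part_rgb.loc[sp, (part, "R")],
                    "G": self.part_rgb.loc[sp, (part, "G")],
                    "B": self.part_rgb.loc[sp, (part, "B")],
                    "part_length_mm": self.part_length.loc[sp, part],
                    "body_size_mm": self.body_size.loc[sp],
                    "golden_area_mm2": self.golden_area.loc[sp],
                })
        return pd.DataFrame(rows, columns=list(COLOUR_COLUMNS))


@dataclass
class RingPartition:
    """A k-means ring assignment together with the ssi scan that chose k."""

    k: int
    labels: pd.Series
    ssi_by_k: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.nunique() != self.k:
            raise ValueError("k must equal the number of distinct labels")


def standardize_rgb(raw: ColourMatrix, white_ref, black_ref) -> ColourMatrix:
    """Linearly recalibrate RGB against white and black reference triples.

    Maps ``black_ref`` to 0 and ``white_ref`` to 255 per channel, clipping
    to [0, 255].  Mirrors an image-level white/black calibration, applied
    here at the level of the measured means.
    """
    white = np.asarray(white_ref, dtype=float)
    black = np.asarray(black_ref, dtype=float)
    span = white - black
    if np.any(span <= 0):
        raise ValueError("white reference must exceed black reference per channel")
    rgb = raw.part_rgb.copy()
    for i, ch in enumerate(RGB_CHANNELS):
        cols = [c for c in rgb.columns if c[1] == ch]
        rgb[cols] = np.clip((rgb[cols] - black[i]) / span[i] * 255.0, 0.0, 255.0)
    return ColourMatrix(rgb, raw.part_length.copy(),
                        raw.body_size.copy(), raw.golden_area.copy())


def rgb_contrast(golden, black) -> float:
    """Sum of absolute per-channel differences between two RGB triples.

    Used as the conspicuousness contrast between the golden patch and the
    black body colouration (maximum possible value 765).
    """
    g = np.asarray(golden, dtype=float)
    b = np.asarray(black, dtype=float)
    if g.shape != (3,) or b.shape != (3,):
        raise ValueError("RGB triples must have exactly three components")
    return float(np.abs(g - b).sum())


def weighted_colour_matrix(cm: ColourMatrix) -> pd.DataFrame:
    """Weight each part's RGB features by the part's relative length.

    Body parts of different size are differently conspicuous, so each
    part's three colour features are multiplied by that part's length
    divided by the species' total part length.  Returns the species x
    (8 parts x 3 channels) feature matrix used for ordination.
    """
    lengths = cm.part_length.to_numpy(dtype=float)
    totals = lengths.sum(axis=1)
    if np.any(totals <= 0):
        bad = cm.species[totals <= 0].tolist()
        raise ValueError(f"zero total part length for species: {bad}")
    weights = lengths / totals[:, None]
    out = cm.part_rgb.copy().astype(float)
    for j, part in enumerate(cm.part_length.columns):
        cols = [c for c in out.columns if c[0] == part]
        out[cols] = out[cols].to_numpy() * weights[:, [j]]
    return out


def bray_curtis(matrix) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix: d(x,y) = sum|x-y| / sum(x+y).

    Requires non-negative features.  A pair of all-zero rows is defined to
    have distance 0 (no evidence of difference).
    """
    x = np.asarray(matrix, dtype=float)
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires non-negative features")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    return np.nan_to_num(d, nan=0.0)


def _check_distance_matrix(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return d


def nmds(dist, dims: int = 2, n_starts: int = 20, seed: int = 0,
         max_iter: int = 500, tol: float = 1e-6):
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Kruskal stress-1 is minimised by iterative majorization (SMACOF) with
    monotone isotonic regression of the disparities; the best of
    ``n_starts`` random starts is returned as ``(coordinates, stress)``.
    """
    d = _check_distance_matrix(dist)
    if dims < 1:
        raise ValueError("dims must be >= 1")
    model = MDS(n_components=dims, metric_mds=False, metric="precomputed",
                n_init=n_starts, max_iter=max_iter, eps=tol, init="random",
                random_state=seed, normalized_stress=True)
    coords = model.fit_transform(d)
    return coords, float(model.stress_)


def _ssi(centers: np.ndarray, sizes: np.ndarray) -> float:
    """Simple structure index of a k-means partition.

    Combines, per feature, the contrast between the extreme cluster
    centres (span), the distinctiveness of the feature (how far its mean
    centre value sits from the grand centre mean) and the sizes of the two
    extreme clusters; normalised so the index is comparable across k.  The
    partition maximising ssi over k indicates the cluster number.
    """
    k, nvar = centers.shape
    cmax = centers.max(axis=0)
    cmin = centers.min(axis=0)
    span = cmax - cmin
    imax = centers.argmax(axis=0)
    imin = centers.argmin(axis=0)
    grand = centers.mean()
    absmdif = np.abs(centers.mean(axis=0) - grand)
    csizemax = sizes[imax]
    csizemin = sizes[imin]
    norm = nvar * max(csizemax.max(), csizemin.max()) * np.exp(-absmdif.min())
    val = (span * np.exp(-absmdif)) @ np.sqrt(csizemax * csizemin) / norm
    return float(val)


def kmeans_ssi_scan(matrix, k_range=range(2, 11), n_restarts: int = 10,
                    seed: int = 0) -> RingPartition:
    """Scan candidate ring numbers with k-means, scoring partitions by ssi.

    For each k the best-of-restarts k-means partition is scored; the k with
    maximal ssi is selected.  Empty clusters are avoided by k-means++
    re-seeding inside each restart.
    """
    if isinstance(matrix, pd.DataFrame):
        index = matrix.index
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    n = x.shape[0]
    if np.ptp(x, axis=0).max() == 0:
        raise ValueError("all points identical: no cluster structure to scan")
    k_range = [k for k in k_range]
    if not k_range or min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError("k_range must lie within [2, n_species - 1]")
    rng = np.random.default_rng(seed)
    ssi_by_k: dict[int, float] = {}
    fits = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts,
                    random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(x)
        sizes = np.bincount(labels, minlength=k).astype(float)
        ssi_by_k[k] = _ssi(km.cluster_centers_, sizes)
        fits[k] = labels
    best_k = max(ssi_by_k, key=lambda k: (ssi_by_k[k], -k))
    labels = pd.Series(fits[best_k], index=index, name="ring")
    return RingPartition(k=best_k, labels=labels, ssi_by_k=ssi_by_k)
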