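"""Gridded occurrences and the Mantel test of colour vs range overlap.

Occurrence records (decimal lon/lat) are projected with a spherical
Lambert azimuthal equal-area projection centred on Australia and binned
into square cells (default 400 km); a species is present (1) in a cell if
any record falls there.  Range overlap between species is the Bray-Curtis
distance between presence rows, colour distance is Euclidean on the
weighted colour features, and their association is assessed with a Mantel
permutation test on the Pearson correlation of the matrix upper triangles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .colour import ColourMatrix, bray_curtis, weighted_colour_matrix

EARTH_RADIUS_KM = 6371.0
#: projection centre (approximate centroid of Australia)
AUSTRALIA_CENTRE = (134.0, -27.0)


@dataclass
class PresenceMatrix:
    """Species x grid-cell 0/1 matrix at a given cell size."""

    matrix: pd.DataFrame
    cell_km: float

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("presence matrix must be binary")


def laea_project(lon, lat, centre=AUSTRALIA_CENTRE) -> tuple[np.ndarray, np.ndarray]:
    """Spherical Lambert azimuthal equal-area projection to km coordinates."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    lon0, lat0 = np.radians(centre[0]), np.radians(centre[1])
    cosc = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(lon - lon0)
    if np.any(cosc <= -1 + 1e-12):
        raise ValueError("record antipodal to projection centre")
    kprime = np.sqrt(2.0 / (1.0 + cosc))
    x = EARTH_RADIUS_KM * kprime * np.cos(lat) * np.sin(lon - lon0)
    y = EARTH_RADIUS_KM * kprime * (np.cos(lat0) * np.sin(lat)
                                    - np.sin(lat0) * np.cos(lat) * np.cos(lon - lon0))
    return x, y


def grid_occurrences(records: pd.DataFrame, cell_km: float = 400.0,
                     centre=AUSTRALIA_CENTRE) -> PresenceMatrix:
    """Bin occurrence records into equal-area grid cells.

    ``records`` needs columns species_id, lon, lat.  Cells are half-open
    squares (a record exactly on a boundary belongs to the lower-left
    cell); cells containing no record are dropped.
    """
    if cell_km <= 0:
        raise ValueError("cell size must be positive")
    if not {"species_id", "lon", "lat"} <= set(records.columns):
        raise ValueError("records need species_id, lon, lat columns")
    lon = records["lon"].to_numpy(float)
    lat = records["lat"].to_numpy(float)
    if np.any((lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)):
        raise ValueError("coordinates outside valid lon/lat ranges")
    x, y = laea_project(lon, lat, centre=centre)
    ix = np.floor(x / cell_km).astype(int)
    iy = np.floor(y / cell_km).astype(int)
    # cell ids as strings: tuples would be misread as multi-keys by crosstab
    cells = pd.Series([f"{a}|{b}" for a, b in zip(ix, iy)], name="cell")
    species = pd.Series(records["species_id"].to_numpy(), name="species_id")
    pm = pd.crosstab(species, cells).clip(upper=1)
    return PresenceMatrix(matrix=pm, cell_km=cell_km)


def distance_matrices(pm: PresenceMatrix, cm: ColourMatrix):
    """(D_geo, D_colour) on the shared species set.

    D_geo is Bray-Curtis on the presence rows; D_colour is Euclidean on
    the size-weighted colour features.  Both are returned as DataFrames
    aligned to the shared species ordering.
    """
    shared = pm.matrix.index.intersection(cm.species)
    if len(shared) == 0:
        raise ValueError("no species shared between presence and colour data")
    geo = bray_curtis(pm.matrix.loc[shared].to_numpy(float))
    feats = weighted_colour_matrix(cm).loc[shared].to_numpy(float)
    col = squareform(pdist(feats, metric="euclidean"))
    return (pd.DataFrame(geo, index=shared, columns=shared),
            pd.DataFrame(col, index=shared, columns=shared))


def mantel_test(d1, d2, n_perm: int = 999, seed: int = 0,
                alternative: str = "two-sided"):
    """Mantel permutation test of association between two distance matrices.

    r is the Pearson correlation of the upper off-diagonal triangles; the
    null distribution permutes the rows and columns of the second matrix
    jointly, and p = (1 + #{permuted r* at least as extreme}) / (n_perm + 1).
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("distance matrices must be square with equal shape")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    if va.std() == 0 or b[iu].std() == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    va = (va - va.mean()) / va.std()

    def corr(mat: np.ndarray) -> float:
        v = mat[iu]
        return float(va @ ((v - v.mean()) / v.std()) / len(va))

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_perm = corr(b[np.ix_(p, p)])
        if alternative == "two-sided":
            hit = abs(r_perm) >= abs(r_obs) - 1e-12
        elif alternative == "greater":
            hit = r_perm >= r_obs - 1e-12
        else:
            hit = r_perm <= r_obs + 1e-12
        count += hit
    return r_obs, (1 + count) / (n_perm + 1)


def mantel_exhaustive(d1, d2, alternative: str = "two-sided"):
    """Exact Mantel p-value by enumerating all permutations (tiny n only)."""
    from itertools import permutations

    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    n = a.shape[0]
    if n > 7:
        raise ValueError("exhaustive enumeration limited to n <= 7")
    iu = np.triu_indices(n, k=1)
    va = a[iu]
    va = (va - va.mean()) / va.std()

    def corr(mat):
        v = mat[iu]
        return float(va @ ((v - v.mean()) / v.std()) / len(va))

    r_obs = corr(b)
    rs = [corr(b[np.ix_(p, p)]) for p in permutations(range(n))]
    if alternative == "two-sided":
        count = sum(abs(r) >= abs(r_obs) - 1e-12 for r in rs)
    elif alternative == "greater":
        count = sum(r >= r_obs - 1e-12 for r in rs)
    else:
        count = sum(r <= r_obs + 1e-12 for r in rs)
    return r_obs, count / len(rs)
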