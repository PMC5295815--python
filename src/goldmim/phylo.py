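"""Phylogenetic covariance and generalised least squares with Pagel's lambda.

Under Brownian-motion trait evolution on a rooted tree, the covariance of
two tips equals the shared root-to-MRCA path length and a tip's variance
equals its root-to-tip depth.  Pagel's lambda rescales the off-diagonal
covariances, interpolating between a star phylogeny (lambda = 0, no
phylogenetic signal) and the full Brownian structure (lambda = 1); values
above 1 are admitted up to the largest value keeping the matrix positive
semidefinite, since empirical signal estimates can exceed 1.

GLS fits support per-species case weights w_j (here the proportion of
directly observed defensive traits), entering the effective covariance as
Sigma = W^-1 V W^-1 with W = diag(w), so better-observed species carry
more precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats


@dataclass
class BrownianVCV:
    """Species x species Brownian covariance with its lambda multiplier."""

    matrix: np.ndarray
    taxa: list[str]
    lam: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("covariance matrix must be square and symmetric")
        self.matrix = m

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GLSFit:
    """Generalised least-squares fit summary."""

    coefficients: np.ndarray
    std_errors: np.ndarray
    f_statistic: float
    df_num: int
    df_den: int
    f_pvalue: float
    log_likelihood: float
    sigma2: float
    names: list[str] = field(default_factory=list)
    lam: float = None
    lambda_warning: str = None


def load_tree(source: str, is_path: bool = True) -> dendropy.Tree:
    """Read a rooted newick tree (polytomies allowed)."""
    kwargs = {"path": source} if is_path else {"data": source}
    tree = dendropy.Tree.get(schema="newick", **kwargs)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def tree_from_genus_table(genus_of: dict[str, str],
                          backbone: dendropy.Tree = None,
                          species_branch: float = 0.0,
                          genus_branch: float = 1.0) -> dendropy.Tree:
    """Attach species as a hard polytomy under each genus of a backbone.

    If no genus-level backbone is given, a star tree of genera (unit
    branches) is used.  Species are splayed as zero-length polytomies by
    default, matching polytomic splitting at the species level.
    """
    genera = sorted(set(genus_of.values()))
    if backbone is None:
        newick = "(" + ",".join(f"{g}:{genus_branch}" for g in genera) + ");"
        backbone = dendropy.Tree.get(data=newick, schema="newick")
    by_genus: dict[str, list[str]] = {}
    for sp, g in genus_of.items():
        by_genus.setdefault(g, []).append(sp)
    for leaf in list(backbone.leaf_node_iter()):
        genus = leaf.taxon.label
        species = sorted(by_genus.get(genus, []))
        if not species:
            continue
        leaf.taxon = None
        for sp in species:
            child = dendropy.Node(edge_length=species_branch)
            child.taxon = backbone.taxon_namespace.new_taxon(label=sp)
            leaf.add_child(child)
    return backbone


def vcv_from_tree(tree: dendropy.Tree) -> BrownianVCV:
    """Brownian covariance: V[a,b] = shared root-to-MRCA path length."""
    tree = tree.clone(depth=1)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0 if edge.tail_node is None else 1.0
        elif edge.length < 0:
            raise ValueError("negative branch length in tree")
    leaves = list(tree.leaf_node_iter())
    taxa = [lf.taxon.label for lf in leaves]
    n = len(leaves)
    # depth of every node, then V[a,b] = depth(MRCA(a,b))
    depth = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth[node.parent_node] if node.parent_node else 0.0
        depth[node] = parent_depth + (node.edge.length or 0.0)
    v = np.zeros((n, n))
    # accumulate via postorder leaf-set merging: O(n^2) overall
    leaf_index = {lf: i for i, lf in enumerate(leaves)}
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [leaf_index[node]]
            v[leaf_index[node], leaf_index[node]] = depth[node]
            continue
        kids = [below.pop(c) for c in node.child_nodes()]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    for j in kids[b]:
                        v[i, j] = v[j, i] = depth[node]
        below[node] = [i for kid in kids for i in kid]
    return BrownianVCV(matrix=v, taxa=taxa, lam=1.0)


def max_feasible_lambda(V: BrownianVCV, upper: float = 5.0) -> float:
    """Largest lambda keeping the Pagel-transformed matrix PSD.

    V(lambda) = D + lambda (V - D) is linear in lambda, so its minimum
    eigenvalue is concave and the feasible set is an interval; locate the
    upper end by bisection.
    """
    v = V.matrix
    d = np.diag(np.diag(v))
    off = v - d

    def min_eig(lam: float) -> float:
        return float(np.linalg.eigvalsh(d + lam * off).min())

    if min_eig(upper) >= -1e-12:
        return upper
    lo, hi = 1.0, upper
    if min_eig(lo) < -1e-12:
        lo = 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_eig(mid) >= -1e-12:
            lo = mid
        else:
            hi = mid
    return lo


def pagel_transform(V: BrownianVCV, lam: float) -> BrownianVCV:
    """Multiply off-diagonal covariances by lambda, keeping the diagonal."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if lam > 1:
        lam_max = max_feasible_lambda(V)
        if lam > lam_max + 1e-9:
            raise ValueError(
                f"lambda={lam} exceeds feasible bound {lam_max:.4f} for this tree")
    v = V.matrix
    out = lam * v + (1.0 - lam) * np.diag(np.diag(v))
    return BrownianVCV(matrix=out, taxa=list(V.taxa), lam=lam)


def _whiten(V: np.ndarray, weights: np.ndarray):
    """Cholesky whitening of Sigma = W^-1 V W^-1 (W = diag(weights))."""
    w = np.asarray(weights, dtype=float)
    sigma = V / np.outer(w, w)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        # ridge for numerically semidefinite matrices (hard polytomies)
        jitter = 1e-10 * np.trace(sigma) / sigma.shape[0]
        L = np.linalg.cholesky(sigma + jitter * np.eye(sigma.shape[0]))
    return L, sigma


def gls_fit(X, y, V: BrownianVCV, case_weights=None,
            names: list[str] = None, lam: float = None) -> GLSFit:
    """Weighted GLS of y on X under covariance V.

    The F statistic tests all non-intercept columns of X by sequential
    reduction against the intercept-only model, in the whitened space.
    The reported log-likelihood is the ML Gaussian likelihood at the
    profiled sigma^2.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if case_weights is None:
        case_weights = np.ones(n)
    w = np.asarray(case_weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("case weights must be positive")
    L, _sigma = _whiten(V.matrix, w)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError("singular design matrix")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * rss / max(n - p, 1), 0, None))
    # sequential F for the non-intercept terms
    has_intercept = np.any(np.all(X == X[0, :], axis=0))
    if has_intercept and p > 1:
        icol = int(np.flatnonzero(np.all(X == X[0, :], axis=0))[0])
        X0w = Xw[:, [icol]]
        beta0, *_ = np.linalg.lstsq(X0w, yw, rcond=None)
        rss0 = float(np.sum((yw - X0w @ beta0) ** 2))
        df_num, df_den = p - 1, n - p
        f_stat = ((rss0 - rss) / df_num) / (rss / df_den)
        f_p = float(stats.f.sf(f_stat, df_num, df_den))
    else:
        df_num, df_den = p, n - p
        rss0 = float(yw @ yw)
        f_stat = ((rss0 - rss) / df_num) / (rss / max(df_den, 1))
        f_p = float(stats.f.sf(f_stat, df_num, max(df_den, 1)))
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return GLSFit(coefficients=beta, std_errors=se, f_statistic=float(f_stat),
                  df_num=df_num, df_den=df_den, f_pvalue=f_p,
                  log_likelihood=float(ll), sigma2=sigma2,
                  names=names or [f"b{i}" for i in range(p)], lam=lam)


def estimate_lambda_ml(X, y, V: BrownianVCV, case_weights=None,
                       bounds=None, grid_step: float = 0.01):
    """Profile-ML estimate of Pagel's lambda with the fit at the optimum.

    The profile log-likelihood is evaluated on a grid over the feasible
    range and refined locally (bounded scalar optimisation).  A flat
    profile (range < 1e-6) returns the boundary with a warning recorded on
    the fit.
    """
    if bounds is None:
        bounds = (0.0, max_feasible_lambda(V))
    lo, hi = bounds
    grid = np.arange(lo, hi, grid_step)
    grid = np.append(grid, hi) if grid.size == 0 or grid[-1] < hi else grid

    def nll(lam: float) -> float:
        fit = gls_fit(X, y, pagel_transform(V, lam), case_weights)
        return -fit.log_likelihood

    vals = np.array([nll(l) for l in grid])
    i = int(vals.argmin())
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    warning = None
    if float(vals.max() - vals.min()) < 1e-6:
        lam_hat = lo
        warning = "flat profile likelihood; lambda not identifiable"
        warnings.warn(warning)
    elif a == b:
        lam_hat = float(grid[i])
    else:
        res = optimize.minimize_scalar(nll, bounds=(a, b), method="bounded",
                                       options={"xatol": 1e-6})
        lam_hat = float(res.x)
        if nll(lam_hat) > vals[i]:
            lam_hat = float(grid[i])
    fit = gls_fit(X, y, pagel_transform(V, lam_hat), case_weights, lam=lam_hat)
    fit.lambda_warning = warning
    return lam_hat, fit


def golden_area_model(u, area, V: BrownianVCV, weights=None) -> GLSFit:
    """GLS of golden patch area on unpalatability with a quadratic term.

    The response is an area, so the linear predictor includes u and u^2;
    the Brownian correlation corrects for shared ancestry (which also
    absorbs body size, itself strongly phylogenetically structured), and
    the observed-fraction weights downweight heavily imputed species.
    The F statistic tests both u terms jointly.
    """
    u = np.asarray(u, dtype=float)
    area = np.asarray(area, dtype=float)
    X = np.column_stack([np.ones_like(u), u, u**2])
    return gls_fit(X, area, V, case_weights=weights,
                   names=["intercept", "u", "u^2"])
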