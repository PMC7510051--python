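"""Distance-based community analysis.

Bray-Curtis dissimilarity (typically on Hellinger-transformed counts),
sequential multivariate PERMANOVA, distance-based Moran eigenvector maps
(dbMEM/PCNM) for spatial, temporal and phylogenetic covariates, community
distances on a plant phylogeny (comdist, comdistnt, PhyloSor), non-metric
multidimensional scaling, and environment-vector fitting onto ordinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from .errors import FormatError, FungalscapeError


def _as_matrix(D: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list]:
    if isinstance(D, pd.DataFrame):
        return D.to_numpy(dtype=float), list(D.index)
    D = np.asarray(D, dtype=float)
    return D, list(range(D.shape[0]))


def bray_curtis(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between rows of a non-negative matrix."""
    X, ids = (matrix.to_numpy(dtype=float), list(matrix.index)) if isinstance(
        matrix, pd.DataFrame
    ) else (np.asarray(matrix, dtype=float), None)
    if np.any(X < 0):
        raise FungalscapeError("Bray-Curtis requires non-negative data")
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        raise FungalscapeError("Bray-Curtis undefined for zero-total rows")
    D = squareform(pdist(X, metric="braycurtis"))
    if ids is None:
        ids = list(range(X.shape[0]))
    return pd.DataFrame(D, index=ids, columns=ids)


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA decomposition of a distance matrix."""

    table: pd.DataFrame  # per-term df, SS, pseudo-F, R2 (%), p
    n_permutations: int
    seed: int

    def __repr__(self) -> str:
        return f"PermanovaResult(n_perm={self.n_permutations})\n{self.table}"


def _design_blocks(design: pd.DataFrame, terms: list[str]) -> list[np.ndarray]:
    blocks = []
    for term in terms:
        col = design[term]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = pd.unique(col)
            if len(levels) < 2:
                raise FungalscapeError(f"term {term!r} has a single level")
            dummies = pd.get_dummies(col, drop_first=True).to_numpy(dtype=float)
            blocks.append(dummies)
        else:
            v = col.to_numpy(dtype=float)
            if np.ptp(v) == 0:
                raise FungalscapeError(f"term {term!r} is constant")
            blocks.append(v[:, None])
    return blocks


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def permanova(
    D: pd.DataFrame | np.ndarray,
    design: pd.DataFrame,
    terms: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
    ss_type: str = "sequential",
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the Gower-centered inner-product matrix of the distance
    matrix; by default terms enter in the given order (sequential/type-I
    SS, matching stepwise model building); ``ss_type='marginal'`` tests
    each term against the model containing all others instead.  Each
    pseudo-F uses the full-model residual, and p-values come from
    ``n_perm`` free row permutations with
    ``p = (#{F* >= F} + 1) / (n_perm + 1)``.  With ``exhaustive`` all n!
    permutations are enumerated instead (small n only) and
    ``p = #{F* >= F} / n!`` (the identity permutation included).
    """
    if ss_type not in ("sequential", "marginal"):
        raise FungalscapeError(f"unknown ss_type: {ss_type!r}")
    Dm, ids = _as_matrix(D)
    n = Dm.shape[0]
    if terms is None:
        terms = list(design.columns)
    if exhaustive and n > 9:
        raise FungalscapeError("exhaustive enumeration limited to n <= 9")
    if not exhaustive and n_perm < 99:
        raise FungalscapeError("need at least 99 permutations")
    design = design.loc[ids] if isinstance(design, pd.DataFrame) and set(ids) <= set(design.index) else design
    if len(design) != n:
        raise FungalscapeError("design rows do not match the distance matrix")

    A = -0.5 * Dm**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    ss_total = float(np.trace(G))

    blocks = _design_blocks(design, terms)
    intercept = np.ones((n, 1))
    if ss_type == "sequential":
        hats, ranks = [], []
        X = intercept
        for block in blocks:
            X = np.hstack([X, block])
            hats.append(_hat(X))
            ranks.append(np.linalg.matrix_rank(X))
        base_hats = [None] * len(blocks)  # implicit: previous cumulative hat
        dfs = np.diff([1] + ranks).astype(int)
        full_rank = ranks[-1]
        full_hat = hats[-1]
    else:
        X_full = np.hstack([intercept] + blocks)
        full_hat = _hat(X_full)
        full_rank = np.linalg.matrix_rank(X_full)
        hats, base_hats, dfs = [], [], []
        for i in range(len(blocks)):
            X_wo = np.hstack([intercept] + [b for j, b in enumerate(blocks) if j != i])
            base_hats.append(_hat(X_wo))
            hats.append(full_hat)
            dfs.append(full_rank - np.linalg.matrix_rank(X_wo))
        dfs = np.asarray(dfs, dtype=int)
    df_res = n - full_rank
    if df_res <= 0:
        raise FungalscapeError("saturated design: no residual degrees of freedom")

    def term_stats(Gmat: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        traces = np.array([float(np.sum(H * Gmat)) for H in hats])
        if ss_type == "sequential":
            ss_terms = np.diff(np.concatenate([[0.0], traces]))
        else:
            lower = np.array([float(np.sum(H * Gmat)) for H in base_hats])
            ss_terms = traces - lower
        # ss_res is >= 0 up to rounding; clamp so a perfectly-fit design
        # yields F = +inf rather than a sign-flipped ratio
        ss_res = max(float(np.trace(Gmat)) - float(np.sum(full_hat * Gmat)), 0.0)
        with np.errstate(divide="ignore"):
            if ss_res == 0.0:
                F = np.where(ss_terms > 0, np.inf, 0.0)
            else:
                F = (ss_terms / dfs) / (ss_res / df_res)
        return ss_terms, ss_res, F

    ss_terms, ss_res, F_obs = term_stats(G)
    # tie tolerance: permutations reproducing the observed statistic must
    # count as >= despite floating-point noise
    with np.errstate(invalid="ignore"):
        F_cut = F_obs - 1e-9 * np.maximum(1.0, np.abs(F_obs))
    F_cut = np.where(np.isfinite(F_obs), F_cut, F_obs)

    exceed = np.zeros(len(terms))
    if exhaustive:
        from itertools import permutations as iter_permutations

        count = 0
        for p in iter_permutations(range(n)):
            p = np.asarray(p)
            _, _, F_perm = term_stats(G[np.ix_(p, p)])
            exceed += F_perm >= F_cut
            count += 1
        pvals = exceed / count
        n_perm = count
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            p = rng.permutation(n)
            _, _, F_perm = term_stats(G[np.ix_(p, p)])
            exceed += F_perm >= F_cut
        pvals = (exceed + 1.0) / (n_perm + 1.0)

    rows = []
    for i, term in enumerate(terms):
        rows.append(
            {
                "term": term,
                "df": int(dfs[i]),
                "ss": float(ss_terms[i]),
                "pseudo_F": float(F_obs[i]),
                "r2_pct": float(100.0 * ss_terms[i] / ss_total),
                "p": float(pvals[i]),
            }
        )
    rows.append(
        {
            "term": "residual",
            "df": int(df_res),
            "ss": float(ss_res),
            "pseudo_F": np.nan,
            "r2_pct": float(100.0 * ss_res / ss_total),
            "p": np.nan,
        }
    )
    return PermanovaResult(table=pd.DataFrame(rows).set_index("term"),
                           n_permutations=n_perm, seed=seed)


@dataclass
class MemBasis:
    """Moran eigenvector basis from a truncated distance matrix."""

    ids: list
    eigenvectors: pd.DataFrame  # columns MEM1, MEM2, ... (unit norm)
    eigenvalues: np.ndarray  # positive, descending
    truncation: float
    source: str = "gMEM"


def dbmem(
    D: pd.DataFrame | np.ndarray,
    truncation: float | None = None,
    source: str = "gMEM",
) -> MemBasis:
    """Distance-based Moran eigenvector maps (classical PCNM construction).

    Distances above the truncation threshold (default: the longest edge of
    the minimum spanning tree, guaranteeing connectivity) are replaced by
    4·t; the modified matrix is Gower-centered and eigen-decomposed, and
    eigenvectors with positive eigenvalues are retained in descending
    eigenvalue order (coarse to fine waves).
    """
    Dm, ids = _as_matrix(D)
    n = Dm.shape[0]
    if truncation is None:
        mst = minimum_spanning_tree(Dm).toarray()
        truncation = float(mst.max())
    if truncation <= 0:
        warnings.warn("all points identical; empty MEM basis")
        return MemBasis(ids=ids, eigenvectors=pd.DataFrame(index=ids),
                        eigenvalues=np.array([]), truncation=0.0, source=source)

    Dstar = np.where(Dm <= truncation, Dm, 4.0 * truncation)
    np.fill_diagonal(Dstar, 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ (-0.5 * Dstar**2) @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-8 * max(1.0, float(np.abs(eigval).max()))
    keep = eigval > tol
    if not keep.any():
        warnings.warn("no positive eigenvalues; empty MEM basis")
    vectors = pd.DataFrame(
        eigvec[:, keep],
        index=ids,
        columns=[f"MEM{i + 1}" for i in range(int(keep.sum()))],
    )
    return MemBasis(ids=ids, eigenvectors=vectors, eigenvalues=eigval[keep],
                    truncation=truncation, source=source)


def temporal_distances(dates: pd.Series, pool_winter: bool = True) -> pd.DataFrame:
    """Absolute day differences between sampling dates.

    With ``pool_winter`` (default), the slow seasons are pooled before
    differencing by mapping February-April to mid-March and
    November-January to mid-December (January joins the preceding year's
    pool), matching how sparse cold-season sampling is usually collapsed.
    """
    ts = pd.to_datetime(dates)

    def _pooled(t: pd.Timestamp) -> pd.Timestamp:
        if not pool_winter:
            return t
        if t.month in (2, 3, 4):
            return pd.Timestamp(year=t.year, month=3, day=15)
        if t.month in (11, 12):
            return pd.Timestamp(year=t.year, month=12, day=15)
        if t.month == 1:
            return pd.Timestamp(year=t.year - 1, month=12, day=15)
        return t

    pooled = ts.map(_pooled)
    days = pooled.map(pd.Timestamp.toordinal).to_numpy(dtype=float)
    D = np.abs(days[:, None] - days[None, :])
    return pd.DataFrame(D, index=dates.index, columns=dates.index)


def _tip_edge_sets(tree: dendropy.Tree) -> dict[str, set]:
    """For each tip label, the edges on its root-to-tip path (by id)."""
    paths: dict[str, set] = {}
    for leaf in tree.leaf_node_iter():
        edges = set()
        node = leaf
        while node is not tree.seed_node:
            if node.edge.length:
                edges.add(id(node.edge))
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    return paths


def phylo_community_distances(
    tree: dendropy.Tree, membership: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Phylogenetic distances between communities on a plant tree.

    ``membership`` is a samples × taxon-label table (nonzero = present).
    Returns ``comdist`` (mean pairwise patristic distance), ``comdistnt``
    (mean nearest-taxon distance, averaged both directions) and
    ``phylosor`` (1 − shared branch length / mean of total branch lengths).
    """
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    taxa = [str(c) for c in membership.columns]
    missing = sorted(set(taxa) - tip_labels)
    if missing:
        raise FormatError(f"community members not in tree: {missing}")

    pdm = tree.phylogenetic_distance_matrix()
    taxon_objs = {t.label: t for t in tree.taxon_namespace}
    k = len(taxa)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = pdm.patristic_distance(taxon_objs[taxa[i]], taxon_objs[taxa[j]])
            dist[i, j] = dist[j, i] = d

    edge_lengths = {
        id(e): e.length
        for e in tree.preorder_edge_iter()
        if e.length
    }
    tip_edges = _tip_edge_sets(tree)

    communities = []
    for _, row in membership.iterrows():
        present = [i for i, t in enumerate(taxa) if row.iloc[i] > 0]
        communities.append(present)
    n = len(communities)
    ids = list(membership.index)

    comdist = np.zeros((n, n))
    comdistnt = np.zeros((n, n))
    phylosor = np.zeros((n, n))
    edge_sets = []
    for present in communities:
        s: set = set()
        for i in present:
            s |= tip_edges[taxa[i]]
        edge_sets.append(s)
    bl_totals = [sum(edge_lengths[e] for e in s) for s in edge_sets]

    for a in range(n):
        for b in range(a + 1, n):
            A, B = communities[a], communities[b]
            if A and B:
                block = dist[np.ix_(A, B)]
                comdist[a, b] = comdist[b, a] = float(block.mean())
                nearest = 0.5 * (block.min(axis=1).mean() + block.min(axis=0).mean())
                comdistnt[a, b] = comdistnt[b, a] = float(nearest)
            else:
                comdist[a, b] = comdist[b, a] = np.nan
                comdistnt[a, b] = comdistnt[b, a] = np.nan
            shared = sum(edge_lengths[e] for e in edge_sets[a] & edge_sets[b])
            mean_bl = 0.5 * (bl_totals[a] + bl_totals[b])
            ps = 1.0 - shared / mean_bl if mean_bl > 0 else np.nan
            phylosor[a, b] = phylosor[b, a] = ps

    def frame(M):
        return pd.DataFrame(M, index=ids, columns=ids)

    return {"comdist": frame(comdist), "comdistnt": frame(comdistnt),
            "phylosor": frame(phylosor)}


def nmds(
    D: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
) -> tuple[pd.DataFrame, float, bool]:
    """Non-metric multidimensional scaling (Kruskal stress-1).

    Runs SMACOF with monotone (pool-adjacent-violators) regression from
    ``n_starts`` random starts and keeps the best.  Returns (coordinates,
    stress-1, converged flag).
    """
    Dm, ids = _as_matrix(D)
    n = Dm.shape[0]
    if n < k + 2:
        raise FungalscapeError(f"need at least {k + 2} points for {k}-D NMDS")
    if not np.all(np.isfinite(Dm)):
        raise FungalscapeError("non-finite distances")
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,
        eps=1e-9,
        n_jobs=1,
    )
    coords = model.fit_transform(Dm)
    converged = model.n_iter_ < max_iter
    frame = pd.DataFrame(coords, index=ids, columns=[f"NMDS{i + 1}" for i in range(k)])
    return frame, float(model.stress_), bool(converged)


def envfit_vectors(
    coordinates: pd.DataFrame,
    environment: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit environmental vectors onto an ordination.

    For each numeric variable, the least-squares direction in ordination
    space and its squared multiple correlation R²; significance by
    permuting the variable across samples.  Constant variables are skipped
    with a warning.
    """
    C = coordinates.to_numpy(dtype=float)
    C = C - C.mean(axis=0)
    rng = np.random.default_rng(seed)
    rows = []
    for name in environment.columns:
        v = environment[name].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"constant variable {name!r} skipped")
            continue
        vc = v - v.mean()

        def r2_of(vec: np.ndarray) -> tuple[float, np.ndarray]:
            beta, *_ = np.linalg.lstsq(C, vec, rcond=None)
            fitted = C @ beta
            denom = float(vec @ vec)
            return (float(fitted @ fitted) / denom if denom > 0 else 0.0), beta

        r2, beta = r2_of(vc)
        exceed = 0
        for _ in range(n_perm):
            r2p, _ = r2_of(rng.permutation(vc))
            exceed += r2p >= r2
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        row = {"variable": name, "r2": r2, "p": (exceed + 1) / (n_perm + 1)}
        for i, c in enumerate(coordinates.columns):
            row[f"dir_{c}"] = float(direction[i])
        rows.append(row)
    if not rows:
        cols = ["variable", "r2", "p"] + [f"dir_{c}" for c in coordinates.columns]
        return pd.DataFrame(columns=cols).set_index("variable")
    return pd.DataFrame(rows).set_index("variable")
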