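"""Niche modeling of richness and OTU abundance along environmental gradients.

The workflow mirrors how regional survey data are usually modeled when
hundreds of candidate predictors compete: an ensemble-of-trees regression
ranks predictors by permutation importance and filters them against
shuffled-decoy copies of themselves; the survivors are then fit with
quadratic least squares (response = b0 + b1·x + b2·x², predictor
standardized), each predictor's variance explained is reported, and the
fitted parabola is classified into a response shape (positive, negative,
unimodal, U, saturating, flat) from coefficient significance and the
location of the vertex relative to the observed predictor range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .diversity import logratio_pct
from .errors import FungalscapeError
from .io import OtuTable

SHAPE_GLYPHS = {
    "positive": "↗",
    "negative": "↘",
    "unimodal": "∩",
    "U": "U",
    "saturating": "Γ",
    "flat": "flat",
}


@dataclass
class PredictorFit:
    """Quadratic fit of the response against one standardized predictor."""

    name: str
    b0: float
    b1: float
    b2: float
    p_b1: float
    p_b2: float
    r2_pct: float
    shape: str
    mean: float
    sd: float
    vertex_std: float | None
    p5: float = float("nan")
    p95: float = float("nan")

    @property
    def vertex(self) -> float | None:
        """Vertex location in the predictor's original units."""
        if self.vertex_std is None:
            return None
        return self.mean + self.sd * self.vertex_std


@dataclass
class NicheModelResult:
    """Selected predictors, per-predictor quadratic fits, combined R²."""

    response: str
    candidates: list[str]
    importances: pd.Series
    selected: list[str]
    fits: dict[str, PredictorFit] = field(default_factory=dict)
    combined_r2_pct: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.selected:
            f = self.fits.get(name)
            if f is None:
                continue
            rows.append(
                {
                    "response": self.response,
                    "predictor": name,
                    "importance": float(self.importances.get(name, np.nan)),
                    "b0": f.b0,
                    "b1": f.b1,
                    "b2": f.b2,
                    "r2_pct": f.r2_pct,
                    "shape": f.shape,
                    "glyph": SHAPE_GLYPHS[f.shape],
                    "vertex": f.vertex,
                    "combined_r2_pct": self.combined_r2_pct,
                }
            )
        return pd.DataFrame(rows)


def select_predictors(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_trees: int = 999,
    seed: int = 0,
    n_iterations: int = 3,
    min_hits: int | None = None,
    importance_floor: float = 0.15,
    top_k: int | None = None,
) -> tuple[list[str], pd.Series]:
    """Rank and select predictors with a shuffled-decoy importance filter.

    Each iteration appends a label-shuffled decoy copy of every candidate,
    fits a random forest of ``n_trees`` trees (mtry = p/3 and a minimum
    leaf size of 5, the customary regression-forest settings), and scores
    candidates by permutation importance (mean MSE increase).  A candidate
    is selected when (a) its importance exceeds the largest decoy
    importance in ``min_hits`` of the iterations (default: all of them; a
    single iteration is not enough, because under a pure-noise response the
    largest real importance exceeds the largest decoy about half the time),
    and (b) its mean importance exceeds ``importance_floor`` × Var(y) (default 0.15) — an
    effect-size floor: permuting the predictor must inflate the MSE by a
    non-negligible share of the response variance, which screens out
    predictors whose apparent importance is only sampling noise.
    ``top_k`` switches to plain rank-by-importance selection.

    Returns (selected names ranked by mean importance, importance Series).
    """
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(y) & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    if not mask.all():
        warnings.warn(f"dropping {int((~mask).sum())} rows with missing values")
        X, y = X.loc[mask], y[mask]
    candidates = list(X.columns)
    if len(candidates) < 2:
        return candidates, pd.Series(np.nan, index=candidates)
    if min_hits is None:
        min_hits = n_iterations

    rng = np.random.default_rng(seed)
    imp_sum = np.zeros(len(candidates))
    hits = np.zeros(len(candidates), dtype=int)
    for it in range(n_iterations if top_k is None else 1):
        decoys = X.to_numpy(dtype=float).copy()
        for j in range(decoys.shape[1]):
            rng.shuffle(decoys[:, j])
        X_aug = np.hstack([X.to_numpy(dtype=float), decoys])
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=1.0 / 3.0,
            min_samples_leaf=5,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        rf.fit(X_aug, y)
        perm = permutation_importance(
            rf,
            X_aug,
            y,
            n_repeats=1,
            random_state=int(rng.integers(2**31)),
            scoring="neg_mean_squared_error",
            n_jobs=1,
        )
        real = perm.importances_mean[: len(candidates)]
        decoy_max = perm.importances_mean[len(candidates):].max()
        imp_sum += real
        hits += real > decoy_max

    n_done = n_iterations if top_k is None else 1
    importances = pd.Series(imp_sum / n_done, index=candidates)
    if top_k is not None:
        selected = list(importances.sort_values(ascending=False).index[:top_k])
    else:
        floor = importance_floor * float(np.var(y))
        selected = [
            c
            for c, h in zip(candidates, hits)
            if h >= min_hits and importances[c] > floor
        ]
        selected.sort(key=lambda c: -importances[c])
    return selected, importances


def _quadratic_ols(y: np.ndarray, x: np.ndarray):
    X = np.column_stack([np.ones_like(x), x, x**2])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient quadratic design; dropping the quadratic term")
        X = np.column_stack([np.ones_like(x), x])
        fit = sm.OLS(y, X).fit()
        b0, b1 = fit.params
        return fit, (b0, b1, 0.0), (fit.pvalues[1], 1.0)
    fit = sm.OLS(y, X).fit()
    b0, b1, b2 = fit.params
    return fit, (b0, b1, b2), (fit.pvalues[1], fit.pvalues[2])


def classify_shape(
    b1: float,
    b2: float,
    p_b1: float,
    p_b2: float,
    p5: float,
    p95: float,
    alpha: float = 0.05,
) -> str:
    """Response-shape class from a fitted quadratic over an observed range.

    Coordinates are on the standardized predictor scale; ``p5``/``p95`` are
    the observed 5th/95th percentiles on that same scale.
    """
    if p_b2 >= alpha or b2 == 0.0:
        if p_b1 < alpha:
            return "positive" if b1 > 0 else "negative"
        return "flat"
    vertex = -b1 / (2.0 * b2)
    slope_low = b1 + 2.0 * b2 * p5
    if b2 < 0:
        if p5 <= vertex <= p95:
            return "unimodal"
        if vertex < p5:
            return "negative"
        return "saturating" if slope_low > 0 else "flat"
    # convex mirror
    if p5 <= vertex <= p95:
        return "U"
    return "positive" if vertex < p5 else "negative"


def fit_quadratic_model(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    response_name: str = "response",
    importances: pd.Series | None = None,
    alpha: float = 0.05,
) -> NicheModelResult:
    """Quadratic fits for each (selected) predictor plus a combined model.

    Predictors are standardized to mean 0, SD 1 before fitting so
    coefficients are comparable and the vertex is numerically stable.
    Per-predictor R² is the squared correlation of fitted vs observed
    (×100); the combined model adds the quadratic terms of all predictors.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[1] == 0:
        raise FungalscapeError("no predictors to fit")
    if importances is None:
        importances = pd.Series(np.nan, index=X.columns)

    result = NicheModelResult(
        response=response_name,
        candidates=list(X.columns),
        importances=importances,
        selected=list(X.columns),
    )
    y_constant = np.ptp(y) == 0
    combined_cols = []
    for name in X.columns:
        raw = X[name].to_numpy(dtype=float)
        mu, sd = raw.mean(), raw.std(ddof=0)
        z = (raw - mu) / sd if sd > 0 else raw - mu
        if y_constant:
            # degenerate response: slope terms are exactly zero, nothing to test
            result.fits[name] = PredictorFit(
                name=name, b0=float(y.mean()), b1=0.0, b2=0.0,
                p_b1=1.0, p_b2=1.0, r2_pct=0.0, shape="flat",
                mean=float(mu), sd=float(sd if sd > 0 else 1.0), vertex_std=None,
            )
            combined_cols.extend([z, z**2])
            continue
        fit, (b0, b1, b2), (p1, p2) = _quadratic_ols(y, z)
        if np.var(fit.fittedvalues) > 0 and np.var(y) > 0:
            r2 = float(np.corrcoef(fit.fittedvalues, y)[0, 1] ** 2 * 100.0)
        else:
            r2 = 0.0
        p5, p95 = np.percentile(z, [5, 95])
        shape = classify_shape(b1, b2, p1, p2, p5, p95, alpha=alpha)
        vertex_std = -b1 / (2.0 * b2) if b2 != 0.0 else None
        result.fits[name] = PredictorFit(
            name=name, b0=float(b0), b1=float(b1), b2=float(b2),
            p_b1=float(p1), p_b2=float(p2), r2_pct=r2, shape=shape,
            mean=float(mu), sd=float(sd if sd > 0 else 1.0),
            vertex_std=vertex_std, p5=float(p5), p95=float(p95),
        )
        combined_cols.extend([z, z**2])

    design = sm.add_constant(np.column_stack(combined_cols))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("collinear combined design; coefficients determined by pseudo-inverse")
    combined = sm.OLS(y, design).fit()
    if np.var(combined.fittedvalues) > 0 and np.var(y) > 0:
        result.combined_r2_pct = float(
            np.corrcoef(combined.fittedvalues, y)[0, 1] ** 2 * 100.0
        )
    return result


def reclassify_shapes_fdr(
    results: list[NicheModelResult], alpha: float = 0.05
) -> list[NicheModelResult]:
    """Re-run shape classification with Benjamini-Hochberg adjusted p-values.

    Adjusts the pooled linear- and quadratic-coefficient p-values across all
    responses and predictors jointly, then reclassifies each fit's shape at
    ``alpha`` on the adjusted values.  Mutates and returns ``results``.
    """
    from statsmodels.stats.multitest import multipletests

    fits = [f for res in results for f in res.fits.values()]
    if not fits:
        return results
    pvals = np.array([p for f in fits for p in (f.p_b1, f.p_b2)])
    finite = np.isfinite(pvals)
    adjusted = pvals.copy()
    if finite.any():
        adjusted[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    for i, f in enumerate(fits):
        q1, q2 = adjusted[2 * i], adjusted[2 * i + 1]
        f.shape = classify_shape(f.b1, f.b2, q1, q2, f.p5, f.p95, alpha=alpha)
    return results


def niche_model(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    response_name: str = "response",
    n_trees: int = 999,
    seed: int = 0,
    **select_kwargs,
) -> NicheModelResult:
    """Full pipeline: decoy-filtered selection, then quadratic fits."""
    selected, importances = select_predictors(X, y, n_trees=n_trees, seed=seed, **select_kwargs)
    if not selected:
        return NicheModelResult(
            response=response_name,
            candidates=list(X.columns),
            importances=importances,
            selected=[],
        )
    result = fit_quadratic_model(
        np.asarray(y, dtype=float), X[selected], response_name=response_name,
        importances=importances,
    )
    result.candidates = list(X.columns)
    result.selected = selected
    return result


def otu_niche_model(
    table: OtuTable,
    otu_id: str,
    predictors: pd.DataFrame,
    min_prevalence: int = 20,
    n_trees: int = 999,
    seed: int = 0,
    **select_kwargs,
) -> NicheModelResult | None:
    """Realized-niche model for one OTU's relative abundance.

    The response is the anchored log-ratio of the OTU's percentage of the
    sample total.  OTUs present in fewer than ``min_prevalence`` samples are
    skipped (returns None with a notice).
    """
    if otu_id not in table.counts.columns:
        raise FungalscapeError(f"unknown OTU: {otu_id}")
    counts = table.counts[otu_id]
    prevalence = int((counts > 0).sum())
    if prevalence < min_prevalence:
        warnings.warn(
            f"{otu_id} present in {prevalence} < {min_prevalence} samples; skipped"
        )
        return None
    pct = 100.0 * counts / table.sample_totals()
    y = logratio_pct(pct)
    X = predictors.loc[table.counts.index]
    return niche_model(y, X, response_name=otu_id, n_trees=n_trees, seed=seed, **select_kwargs)
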