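"""Abundance transforms, diversity indices and depth normalization.

Includes the anchored percentage log-ratio transform (0% → −4, 50% → 0,
100% → +4), the Hellinger transform, Shannon diversity, sequencing-depth
residual richness (average of residuals from √depth and ln-depth
regressions), analytic rarefaction (hypergeometric expectation), and
per-group richness/abundance summaries.
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import FungalscapeError, QCError
from .io import OtuTable


def logratio_pct(p):
    """Anchored log-ratio transform of a percentage.

    ``log10((p + 0.01) / (100 - p + 0.01))``: maps 0% → −4, 50% → 0,
    100% → +4 (to <5e-5).  Accepts scalars or array-likes in [0, 100].
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise FungalscapeError("percentages must lie in [0, 100]")
    out = np.log10((arr + 0.01) / (100.0 - arr + 0.01))
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(out)
    if isinstance(p, pd.DataFrame):
        return pd.DataFrame(out, index=p.index, columns=p.columns)
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name=p.name)
    return out


def hellinger(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of within-sample relative abundance."""
    counts = table.counts if isinstance(table, OtuTable) else table
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        empty = totals.index[totals <= 0].tolist()
        raise QCError(f"zero-total samples: {empty}")
    return np.sqrt(counts.div(totals, axis=0))


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity −Σ pᵢ log pᵢ of one sample (natural log default)."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise QCError("Shannon index undefined for an all-zero sample")
    p = arr[arr > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def richness(table: OtuTable) -> pd.Series:
    """Observed OTU richness per sample."""
    return (table.counts > 0).sum(axis=1)


def depth_residual_richness(
    richness_values: pd.Series | np.ndarray,
    depths: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Depth-corrected richness residuals.

    Fits richness on √depth and, separately, on ln(depth) by ordinary least
    squares (with intercept) and averages the two raw residuals; both
    regressions tend to misestimate at one end of the depth range, and the
    average compensates.  With constant depths both fits collapse to the
    intercept and the residual degenerates to mean-centering.
    """
    r = np.asarray(richness_values, dtype=float)
    d = np.asarray(depths, dtype=float)
    if len(r) != len(d):
        raise FungalscapeError("richness and depth vectors differ in length")
    if len(r) < 3:
        raise FungalscapeError("need at least 3 samples")
    if np.any(d <= 0):
        raise FungalscapeError("depths must be positive")

    def _residuals(x: np.ndarray) -> np.ndarray:
        if np.ptp(x) == 0:
            return r - r.mean()
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, r, rcond=None)
        return r - X @ beta

    resid = 0.5 * (_residuals(np.sqrt(d)) + _residuals(np.log(d)))
    index = (
        richness_values.index
        if isinstance(richness_values, pd.Series)
        else pd.RangeIndex(len(r))
    )
    return pd.DataFrame({"raw_richness": r, "residual": resid}, index=index)


def _expected_richness(counts: np.ndarray, m: int) -> float:
    """Analytic E[S(m)] under draws without replacement (log-stable)."""
    counts = counts[counts > 0]
    total = int(counts.sum())
    if m < 0 or m > total:
        raise FungalscapeError(f"rarefaction depth {m} outside [0, {total}]")
    if m == 0:
        return 0.0
    s = len(counts)
    log_denom = gammaln(total + 1) - gammaln(m + 1) - gammaln(total - m + 1)
    keep = total - counts >= m
    a = total - counts[keep]
    log_num = gammaln(a + 1) - gammaln(m + 1) - gammaln(a - m + 1)
    return float(s - np.exp(log_num - log_denom).sum())


def _zero_sample_singletons(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.mask(counts == 1, 0)


def rarefaction_curve(
    table: OtuTable,
    depths: Iterable[int],
    singleton_mode: Literal["include", "exclude"] = "include",
    mode: Literal["pooled", "per_sample"] = "pooled",
) -> pd.DataFrame:
    """Expected OTU accumulation at standardized read depths.

    ``pooled`` (default) rarefies the summed count vector across samples;
    ``per_sample`` averages each sample's expectation (samples too shallow
    for a depth contribute NaN).  ``singleton_mode='exclude'`` zeroes counts
    equal to 1 *within each sample* before pooling, discarding locally rare
    OTUs that may be index-switching artifacts.
    """
    counts = table.counts
    if singleton_mode == "exclude":
        counts = _zero_sample_singletons(counts)
    elif singleton_mode != "include":
        raise FungalscapeError(f"unknown singleton_mode: {singleton_mode}")

    depths = [int(m) for m in depths]
    if mode == "pooled":
        pooled = counts.sum(axis=0).to_numpy()
        values = [_expected_richness(pooled, m) for m in depths]
    elif mode == "per_sample":
        values = []
        for m in depths:
            per = []
            for _, row in counts.iterrows():
                total = int(row.sum())
                per.append(_expected_richness(row.to_numpy(), m) if m <= total else np.nan)
            values.append(float(np.nanmean(per)))
    else:
        raise FungalscapeError(f"unknown mode: {mode}")
    return pd.DataFrame({"depth": depths, "expected_richness": values})


def group_richness(table: OtuTable, labels: pd.Series) -> pd.DataFrame:
    """Per-sample OTU richness for each level of a per-OTU label."""
    present = table.counts > 0
    out = {}
    aligned = labels.reindex(table.otu_ids).fillna("")
    for level in sorted(v for v in aligned.unique() if v != ""):
        members = aligned.index[aligned == level]
        out[level] = present[members].sum(axis=1)
    return pd.DataFrame(out, index=table.counts.index)


def group_proportions(table: OtuTable, labels: pd.Series) -> pd.DataFrame:
    """Per-sample sequence proportion for each level of a per-OTU label.

    Proportions use whole-sample totals, so levels sum to ≤ 1 with the
    remainder belonging to unlabeled OTUs.
    """
    totals = table.sample_totals()
    aligned = labels.reindex(table.otu_ids).fillna("")
    out = {}
    for level in sorted(v for v in aligned.unique() if v != ""):
        members = aligned.index[aligned == level]
        out[level] = table.counts[members].sum(axis=1) / totals
    return pd.DataFrame(out, index=table.counts.index)


def ecm_lineage_count(table: OtuTable, assignments: pd.DataFrame) -> pd.Series:
    """Number of distinct EcM lineages present per sample (phylogenetic
    richness proxy)."""
    lineages = assignments["ecm_lineage"].reindex(table.otu_ids).fillna("")
    present = table.counts > 0
    counts = pd.Series(0, index=table.counts.index)
    for lineage in sorted(v for v in lineages.unique() if v != ""):
        members = lineages.index[lineages == lineage]
        counts += present[members].any(axis=1).astype(int)
    counts.name = "ecm_lineage_count"
    return counts


def group_metrics(table: OtuTable, assignments: pd.DataFrame) -> dict[str, pd.DataFrame | pd.Series]:
    """Standard per-sample group summaries.

    Returns guild richness and sequence proportions, EcM lineage richness
    and count, and exploration-type proportions both raw and on the
    anchored log-ratio scale.
    """
    guilds = assignments["guild"].replace("unassigned", "")
    expl = assignments["exploration_type"]
    expl_prop = group_proportions(table, expl)
    return {
        "guild_richness": group_richness(table, guilds),
        "guild_proportion": group_proportions(table, guilds),
        "lineage_richness": group_richness(table, assignments["ecm_lineage"]),
        "ecm_lineage_count": ecm_lineage_count(table, assignments),
        "exploration_proportion": expl_prop,
        "exploration_logratio": logratio_pct(100.0 * expl_prop),
    }
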