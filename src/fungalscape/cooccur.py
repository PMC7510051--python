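"""Checkerboard C-score co-occurrence analysis with fixed-fixed nulls.

For an OTU pair with row totals Rᵢ, Rⱼ and S jointly occupied samples, the
C-score is (Rᵢ − S)(Rⱼ − S): the number of checkerboard sub-matrices the
pair forms.  Null matrices preserve both row (OTU incidence) and column
(sample richness) totals via a sequential 2×2 checkerboard swap chain.
Sign convention of the standardized effect size: SES > 0 means segregation
(avoidance), SES < 0 means aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import FungalscapeError
from .io import OtuTable


def presence_matrix(table: OtuTable, min_count: int = 1) -> pd.DataFrame:
    """OTU × sample presence/absence (presence = count ≥ ``min_count``)."""
    return (table.counts.T >= min_count).astype(np.int8)


def cscore_pair(presence: pd.DataFrame, i: str, j: str) -> int:
    """Checkerboard C-score (Rᵢ − S)(Rⱼ − S) for one OTU pair."""
    for otu in (i, j):
        if otu not in presence.index:
            raise FungalscapeError(f"unknown OTU: {otu}")
    a = presence.loc[i].to_numpy(dtype=np.int64)
    b = presence.loc[j].to_numpy(dtype=np.int64)
    ri, rj = int(a.sum()), int(b.sum())
    s = int((a & b).sum())
    return (ri - s) * (rj - s)


def _cscores(M: np.ndarray, pair_idx: list[tuple[int, int]]) -> np.ndarray:
    R = M.sum(axis=1)
    out = np.empty(len(pair_idx), dtype=np.int64)
    for k, (i, j) in enumerate(pair_idx):
        s = int(np.dot(M[i], M[j]))
        out[k] = (R[i] - s) * (R[j] - s)
    return out


def swap_chain(
    M: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
    debug: bool = False,
) -> np.ndarray:
    """Advance a fixed-fixed swap chain by ``n_steps`` attempted swaps.

    Each step picks a random 2×2 sub-matrix and swaps it when it is a
    checkerboard; this trial-swap kernel is symmetric, so the chain's
    stationary distribution is uniform over the margin-preserving set.
    Modifies ``M`` in place and returns it.
    """
    r, c = M.shape
    if debug:
        row0, col0 = M.sum(axis=1).copy(), M.sum(axis=0).copy()
    rows = rng.integers(0, r, size=(n_steps, 2))
    cols = rng.integers(0, c, size=(n_steps, 2))
    for (i1, i2), (j1, j2) in zip(rows, cols):
        if i1 == i2 or j1 == j2:
            continue
        a, b, cc, d = M[i1, j1], M[i1, j2], M[i2, j1], M[i2, j2]
        if a == d and b == cc and a != b:
            M[i1, j1], M[i2, j2] = b, b
            M[i1, j2], M[i2, j1] = a, a
            if debug:
                assert np.array_equal(M.sum(axis=1), row0)
                assert np.array_equal(M.sum(axis=0), col0)
    return M


@dataclass
class CScoreResult:
    """SES C-score results for a set of OTU pairs."""

    table: pd.DataFrame
    n_null: int
    seed: int


def ses_cscore(
    presence: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    n_null: int = 999,
    burn_in: int = 30_000,
    thin: int = 1_000,
    seed: int = 0,
    debug: bool = False,
) -> CScoreResult:
    """Standardized-effect-size C-scores against fixed-fixed swap nulls.

    ``burn_in`` attempted swaps precede the first null sample and ``thin``
    separate consecutive samples.  Two-tailed p per pair:
    ``(#{|C* − mean| >= |C − mean|} + 1) / (n_null + 1)``.  Pairs whose null
    distribution is degenerate (sd = 0, e.g. a swap-invariant matrix) are
    flagged with undefined SES and p = 1.
    """
    if presence.shape[0] < 2 or presence.shape[1] < 2:
        raise FungalscapeError("need at least a 2x2 presence matrix")
    otus = list(presence.index)
    if pairs is None:
        pairs = list(combinations(otus, 2))
    idx = {o: i for i, o in enumerate(otus)}
    pair_idx = [(idx[i], idx[j]) for i, j in pairs]

    M = presence.to_numpy(dtype=np.int8).copy()
    observed = _cscores(M, pair_idx)

    rng = np.random.default_rng(seed)
    work = M.copy()
    swap_chain(work, burn_in, rng, debug=debug)
    nulls = np.empty((n_null, len(pairs)), dtype=np.int64)
    for t in range(n_null):
        swap_chain(work, thin, rng, debug=debug)
        nulls[t] = _cscores(work, pair_idx)

    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=0)
    rows = []
    for k, (i, j) in enumerate(pairs):
        degenerate = sd[k] == 0
        if degenerate:
            ses, p = np.nan, 1.0
        else:
            ses = (observed[k] - mean[k]) / sd[k]
            p = (
                int(np.sum(np.abs(nulls[:, k] - mean[k]) >= abs(observed[k] - mean[k]))) + 1
            ) / (n_null + 1)
        rows.append(
            {
                "otu_i": i,
                "otu_j": j,
                "observed_c": int(observed[k]),
                "null_mean": float(mean[k]),
                "null_sd": float(sd[k]),
                "ses": float(ses) if not degenerate else np.nan,
                "p": float(p),
                "degenerate": bool(degenerate),
            }
        )
    return CScoreResult(table=pd.DataFrame(rows), n_null=n_null, seed=seed)
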