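"""Pre-statistics sample/OTU quality control with mold-spoilage screening.

The filter chain removes, in order: control samples, samples below a
minimum sequencing depth, blocklisted OTUs (suspected contamination or
non-target markers), samples left empty by the blocklist, and finally
samples heavily occupied by molds.  Mold spoilage is judged per sample on
the *maximum single-OTU relative abundance* within each of four mold
clades — Mortierellales, Umbelopsidales, Mucorales and mold-forming
Pezizomycotina — with strict thresholds on three of them (Mucorales is
profiled and exported but never a removal criterion).  Every stage is
recorded in a FilterReport so provenance mirrors the dataset-by-dataset
bookkeeping of a real survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, QCError
from .io import FilterReport, OtuTable


@dataclass
class QcThresholds:
    """Thresholds of the filter chain.

    Samples are dropped when the maximum single-OTU share (strict ``>``)
    exceeds 0.30 for Pezizomycotina molds or 0.15 for Umbelopsidales or
    Mortierellales; Mucorales has no removal threshold.  ``group_share``
    thresholding is available but off by default.
    """

    min_reads: int = 500
    pezizomycotina_max: float = 0.30
    umbelopsidales_max: float = 0.15
    mortierellales_max: float = 0.15
    otu_blocklist: frozenset[str] = field(default_factory=frozenset)
    use_group_share: bool = False

    def __post_init__(self):
        if self.min_reads < 1:
            raise ConfigurationError("min_reads must be >= 1")
        for name in ("pezizomycotina_max", "umbelopsidales_max", "mortierellales_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        self.otu_blocklist = frozenset(self.otu_blocklist)

    def per_group(self) -> dict[str, float]:
        return {
            "Pezizomycotina_mold": self.pezizomycotina_max,
            "Umbelopsidales": self.umbelopsidales_max,
            "Mortierellales": self.mortierellales_max,
        }


MOLD_GROUPS = ("Mortierellales", "Umbelopsidales", "Mucorales", "Pezizomycotina_mold")


def compute_mold_profiles(table: OtuTable, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mold shares for each mold group.

    Returns a frame indexed by sample with ``group_share_<g>`` (summed
    share of the group's OTUs) and ``max_otu_share_<g>`` (share of the
    group's single most abundant OTU in that sample).  Denominators are
    whole-sample totals, including non-mold OTUs.
    """
    totals = table.sample_totals()
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise QCError(f"zero-total samples (depth-filter first): {empty}")

    if "mold_group" in assignments.columns:
        groups = assignments["mold_group"].reindex(table.otu_ids).fillna("")
    else:
        groups = pd.Series("", index=table.otu_ids)

    out = pd.DataFrame(index=table.counts.index)
    for g in MOLD_GROUPS:
        members = groups.index[groups == g]
        if len(members):
            sub = table.counts[members]
            out[f"group_share_{g}"] = sub.sum(axis=1) / totals
            out[f"max_otu_share_{g}"] = sub.max(axis=1) / totals
        else:
            out[f"group_share_{g}"] = 0.0
            out[f"max_otu_share_{g}"] = 0.0
    return out


def global_top_mold_shares(table: OtuTable, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-sample share of each mold group's globally most abundant OTU.

    Exported as covariates (e.g. an "Umbelopsidales top OTU" predictor); not
    used by the removal rule, which works on the per-sample maximum.
    """
    totals = table.sample_totals()
    groups = assignments["mold_group"].reindex(table.otu_ids).fillna("")
    out = pd.DataFrame(index=table.counts.index)
    for g in MOLD_GROUPS:
        members = groups.index[groups == g]
        if len(members):
            top = table.counts[members].sum(axis=0).idxmax()
            out[f"top_otu_share_{g}"] = table.counts[top] / totals
        else:
            out[f"top_otu_share_{g}"] = 0.0
    return out


def flag_spoiled_samples(
    profiles: pd.DataFrame, thresholds: QcThresholds
) -> pd.Series:
    """Boolean flag per sample: does any thresholded group exceed its cap?"""
    kind = "group_share" if thresholds.use_group_share else "max_otu_share"
    flagged = pd.Series(False, index=profiles.index)
    for g, thr in thresholds.per_group().items():
        flagged |= profiles[f"{kind}_{g}"] > thr
    return flagged


def apply_qc_chain(
    table: OtuTable,
    metadata: pd.DataFrame,
    assignments: pd.DataFrame,
    thresholds: QcThresholds | None = None,
) -> tuple[OtuTable, FilterReport]:
    """Run the five-stage filter chain and return (table, provenance report).

    Stages: (1) drop control samples (metadata ``control_flag``); (2) drop
    samples under ``min_reads``; (3) drop blocklisted OTUs; (4) drop samples
    emptied by stage 3; (5) profile molds on the cleaned table and drop
    samples whose per-sample maximum mold-OTU share exceeds a group
    threshold.  Idempotent: re-running on its own output changes nothing.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    report = FilterReport(
        initial_samples=table.shape[0],
        initial_sequences=table.total_sequences(),
        initial_otus=table.shape[1],
    )

    controls = [
        s
        for s in table.sample_ids
        if s in metadata.index and bool(metadata.loc[s, "control_flag"])
    ]
    table = table.drop_samples(controls)
    report.add_stage(table, "remove_controls", controls)

    totals = table.sample_totals()
    shallow = totals.index[totals < thresholds.min_reads].tolist()
    table = table.drop_samples(shallow)
    report.add_stage(table, "remove_low_depth", shallow)

    blocked = [o for o in table.otu_ids if o in thresholds.otu_blocklist]
    table = table.drop_otus(blocked)
    report.add_stage(table, "remove_blocklisted_otus", blocked)

    totals = table.sample_totals()
    emptied = totals.index[totals == 0].tolist()
    table = table.drop_samples(emptied)
    report.add_stage(table, "remove_emptied_samples", emptied)

    profiles = compute_mold_profiles(table, assignments)
    spoiled = flag_spoiled_samples(profiles, thresholds)
    spoiled_ids = spoiled.index[spoiled].tolist()
    table = table.drop_samples(spoiled_ids)
    report.add_stage(table, "remove_mold_spoiled", spoiled_ids)

    if table.shape[0] == 0:
        raise QCError("no samples survive QC")
    return table, report


def guild_analysis_gate(
    table: OtuTable,
    assignments: pd.DataFrame,
    guild: str,
    min_otus: int = 20,
    min_sequences: int | None = None,
) -> list[str]:
    """Samples admissible for a per-guild analysis.

    Keeps samples with at least ``min_otus`` OTUs of the guild present and,
    when given, at least ``min_sequences`` reads of that guild (the stricter
    gate used for obligate-mutualist analyses).
    """
    members = assignments.index[assignments["guild"] == guild]
    members = [o for o in members if o in table.counts.columns]
    sub = table.counts[members]
    ok = (sub > 0).sum(axis=1) >= min_otus
    if min_sequences is not None:
        ok &= sub.sum(axis=1) >= min_sequences
    return ok.index[ok].tolist()
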