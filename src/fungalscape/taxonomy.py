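"""Rank-thresholded taxonomy assignment and functional annotation.

Each OTU carries up to ten best reference hits (similarity %, e-value,
taxonomy path).  A rank label is accepted only when the hits that pass that
rank's similarity/e-value thresholds agree unanimously; any conflict among
passing hits, or an empty passing set, leaves the rank UNASSIGNED, and once
a rank is unassigned all deeper ranks are forced UNASSIGNED.  Guilds, EcM
lineages, exploration types and mold groups are then looked up from a
genus-keyed traits table, with species-level overrides required for genera
flagged as having multiple lifestyles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]
UNASSIGNED = "UNASSIGNED"


@dataclass
class RankThresholds:
    """Per-rank (min similarity %, max e-value) acceptance criteria.

    Similarity must be strictly greater and e-value strictly smaller than
    the rank's bounds.  Order/family/genus inherit the class-level e-value
    criterion, since only their similarity bounds are stated separately.
    """

    thresholds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "kingdom": (70.0, 1e-20),
            "phylum": (75.0, 1e-50),
            "class": (75.0, 1e-50),
            "order": (80.0, 1e-50),
            "family": (85.0, 1e-50),
            "genus": (90.0, 1e-50),
        }
    )

    def passing(self, hits: pd.DataFrame, rank: str) -> pd.DataFrame:
        min_sim, max_e = self.thresholds[rank]
        ok = (hits["similarity_pct"] > min_sim) & (hits["evalue"] < max_e)
        return hits[ok]


def assign_rank(hits: pd.DataFrame, rank: str, thresholds: RankThresholds | None = None) -> str:
    """Label for one rank of one OTU, or UNASSIGNED.

    Hits passing the rank's thresholds and carrying a non-empty label at
    that rank must be unanimous; conflicting passing hits are conservatively
    left unidentified.
    """
    if thresholds is None:
        thresholds = RankThresholds()
    passing = thresholds.passing(hits, rank)
    if rank in passing.columns:
        labels = passing[rank].fillna("").astype(str)
        labels = labels[labels != ""].unique()
    else:
        labels = []
    if len(labels) != 1:
        return UNASSIGNED
    return str(labels[0])


def assign_taxonomy(
    hit_table: pd.DataFrame, thresholds: RankThresholds | None = None
) -> pd.DataFrame:
    """Assign kingdom..genus for every OTU in a hit table.

    Ranks are evaluated root-to-leaf and truncated at the first UNASSIGNED.
    OTUs whose hits fail even the kingdom thresholds come back fully
    UNASSIGNED (unknown eukaryotes); the caller decides whether to keep them
    in fungal tallies.
    """
    if thresholds is None:
        thresholds = RankThresholds()
    records = []
    for otu_id, hits in hit_table.groupby("otu_id", sort=True):
        hits = hits.sort_values("hit_order")
        rec = {"otu_id": otu_id}
        blocked = False
        for rank in RANKS:
            label = UNASSIGNED if blocked else assign_rank(hits, rank, thresholds)
            rec[rank] = label
            if label == UNASSIGNED:
                blocked = True
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    if out.empty:
        out = pd.DataFrame(columns=["otu_id", *RANKS])
    return out.set_index("otu_id")


def annotate_function(
    assignments: pd.DataFrame,
    traits: pd.DataFrame,
    species: pd.Series | None = None,
) -> pd.DataFrame:
    """Fill guild, EcM lineage, exploration type and mold group.

    ``traits`` is genus-keyed with optional species-level override rows (a
    non-empty ``species`` field).  For genera flagged multi-lifestyle, a
    species-level key (from ``species`` or an existing ``species`` column in
    ``assignments``) is required; without it the guild stays unassigned.
    Lineage and exploration type are carried only for EcM OTUs.
    """
    required = {"genus", "guild", "multi_lifestyle"}
    missing = required - set(traits.columns)
    if missing:
        raise FormatError(f"traits table missing columns: {sorted(missing)}")
    for col in ("species", "ecm_lineage", "exploration_type", "mold_group"):
        if col not in traits.columns:
            traits = traits.assign(**{col: ""})
    traits = traits.fillna({"species": "", "ecm_lineage": "", "exploration_type": "", "mold_group": ""})

    genus_rows = traits[traits["species"] == ""].drop_duplicates("genus").set_index("genus")
    species_rows = traits[traits["species"] != ""].set_index("species")

    if species is None and "species" in assignments.columns:
        species = assignments["species"]

    out = assignments.copy()
    out["guild"] = "unassigned"
    out["ecm_lineage"] = ""
    out["exploration_type"] = ""
    out["mold_group"] = ""

    for otu_id, rec in assignments.iterrows():
        genus = rec.get("genus", UNASSIGNED)
        if genus in (UNASSIGNED, "", None) or genus not in genus_rows.index:
            continue
        row = genus_rows.loc[genus]
        if bool(row["multi_lifestyle"]):
            sp = "" if species is None else str(species.get(otu_id, "") or "")
            if sp and sp in species_rows.index:
                row = species_rows.loc[sp]
            else:
                continue  # multi-lifestyle without species resolution
        guild = str(row["guild"]) or "unassigned"
        out.loc[otu_id, "guild"] = guild
        out.loc[otu_id, "mold_group"] = str(row["mold_group"])
        if guild == "EcM":
            out.loc[otu_id, "ecm_lineage"] = str(row["ecm_lineage"])
            out.loc[otu_id, "exploration_type"] = str(row["exploration_type"])
    return out
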