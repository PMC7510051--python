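"""Survey bundle input/output.

A *survey bundle* is a directory of flat, diffable text files:

``counts.tsv``
    sample x OTU integer count table; first column ``sample_id``, remaining
    header fields are OTU IDs.
``metadata.tsv``
    one row per sample, keyed by ``sample_id``; soil chemistry, tree
    basal-area percentages, coordinates, dates, collector, habitat fields.
``hits.tsv`` (optional)
    tabular best-hit records per OTU (similarity %, e-value, taxonomy path).
``traits.tsv`` (optional)
    genus-level functional traits lookup (guild, EcM lineage, exploration
    type, mold group), with optional species-level override rows.

All tables are UTF-8, tab-delimited, ``.`` decimal.  Rows and columns are
written in lexicographic order so that repeated saves are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import FormatError

HIT_COLUMNS = [
    "otu_id",
    "hit_order",
    "similarity_pct",
    "evalue",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
]

TRAIT_COLUMNS = [
    "genus",
    "species",
    "multi_lifestyle",
    "guild",
    "ecm_lineage",
    "exploration_type",
    "mold_group",
]


class OtuTable:
    """Sample x OTU non-negative integer count matrix.

    Thin wrapper around a pandas DataFrame (samples in rows, OTUs in
    columns) that enforces the invariants every downstream stage relies on:
    unique IDs, integer dtype, no negative entries.
    """

    def __init__(self, counts: pd.DataFrame, validate: bool = True):
        if validate:
            counts = self._validated(counts)
        self.counts = counts

    @staticmethod
    def _validated(counts: pd.DataFrame) -> pd.DataFrame:
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dup}")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU IDs: {dup}")
        values = counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise FormatError("counts must be numeric")
            if np.any(values < 0) or np.any(values != np.floor(values)):
                bad = np.argwhere((values < 0) | (values != np.floor(values)))[0]
                raise FormatError(
                    "counts must be non-negative integers; offending cell "
                    f"(sample={counts.index[bad[0]]!r}, otu={counts.columns[bad[1]]!r})"
                )
        return counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def total_sequences(self) -> int:
        return int(self.counts.to_numpy().sum())

    def drop_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        drop = set(sample_ids)
        keep = [s for s in self.sample_ids if s not in drop]
        return OtuTable(self.counts.loc[keep], validate=False)

    def drop_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        drop = set(otu_ids)
        keep = [o for o in self.otu_ids if o not in drop]
        return OtuTable(self.counts[keep], validate=False)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)

    def __eq__(self, other) -> bool:
        return isinstance(other, OtuTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"OtuTable({n} samples x {m} OTUs)"


@dataclass
class FilterStage:
    """One stage of the QC provenance chain."""

    stage_name: str
    n_samples: int
    n_sequences: int
    n_otus: int
    items_removed: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    """Ordered record of what each QC stage retained and removed."""

    initial_samples: int
    initial_sequences: int
    initial_otus: int
    stages: list[FilterStage] = field(default_factory=list)

    def add_stage(self, table: OtuTable, name: str, removed: Sequence[str]) -> None:
        self.stages.append(
            FilterStage(
                stage_name=name,
                n_samples=table.shape[0],
                n_sequences=table.total_sequences(),
                n_otus=table.shape[1],
                items_removed=sorted(removed),
            )
        )

    def sample_trajectory(self) -> list[int]:
        return [self.initial_samples] + [s.n_samples for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "initial": {
                "n_samples": self.initial_samples,
                "n_sequences": self.initial_sequences,
                "n_otus": self.initial_otus,
            },
            "stages": [
                {
                    "stage_name": s.stage_name,
                    "n_samples": s.n_samples,
                    "n_sequences": s.n_sequences,
                    "n_otus": s.n_otus,
                    "items_removed": s.items_removed,
                }
                for s in self.stages
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=False)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "FilterReport":
        rep = cls(
            initial_samples=d["initial"]["n_samples"],
            initial_sequences=d["initial"]["n_sequences"],
            initial_otus=d["initial"]["n_otus"],
        )
        for s in d["stages"]:
            rep.stages.append(FilterStage(**s))
        return rep


def _read_tsv(path: Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_counts(path: str | Path) -> OtuTable:
    df = _read_tsv(Path(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OtuTable(df)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(Path(path))
    if "sample_id" not in df.columns:
        raise FormatError("metadata must carry a 'sample_id' column")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample IDs in metadata: {dup}")
    return df.set_index("sample_id")


def read_hits(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(Path(path), dtype={"otu_id": str})
    missing = [c for c in ("otu_id", "hit_order", "similarity_pct", "evalue") if c not in df.columns]
    if missing:
        raise FormatError(f"hit table missing columns: {missing}")
    if ((df["similarity_pct"] < 0) | (df["similarity_pct"] > 100)).any():
        raise FormatError("similarity_pct must lie in [0, 100]")
    if (df["evalue"] < 0).any():
        raise FormatError("evalue must be non-negative")
    if df.duplicated(subset=["otu_id", "hit_order"]).any():
        raise FormatError("hit_order must be unique within each OTU")
    return df


def read_traits(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(Path(path))
    missing = [c for c in ("genus", "guild") if c not in df.columns]
    if missing:
        raise FormatError(f"traits table missing columns: {missing}")
    for col in TRAIT_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col != "multi_lifestyle" else False
    df["multi_lifestyle"] = df["multi_lifestyle"].astype(bool)
    return df


def load_survey(directory: str | Path):
    """Load a survey bundle; returns (OtuTable, metadata, hits, traits).

    ``hits`` and ``traits`` are None when the corresponding file is absent.
    Samples present in the count table but missing from metadata raise a
    FormatError naming them.
    """
    directory = Path(directory)
    table = read_counts(directory / "counts.tsv")
    metadata = read_metadata(directory / "metadata.tsv")
    missing = sorted(set(table.sample_ids) - set(metadata.index))
    if missing:
        raise FormatError(f"samples missing from metadata: {missing}")
    hits_path = directory / "hits.tsv"
    traits_path = directory / "traits.tsv"
    hits = read_hits(hits_path) if hits_path.exists() else None
    traits = read_traits(traits_path) if traits_path.exists() else None
    return table, metadata, hits, traits


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None) -> None:
    df.to_csv(path, sep="\t", index=index_label is not None, index_label=index_label)


def save_survey(
    directory: str | Path,
    table: OtuTable,
    metadata: pd.DataFrame,
    hits: pd.DataFrame | None = None,
    traits: pd.DataFrame | None = None,
    report: FilterReport | None = None,
) -> list[Path]:
    """Write a survey bundle with deterministic (lexicographic) ordering."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    counts = table.counts.sort_index(axis=0).sort_index(axis=1)
    path = directory / "counts.tsv"
    _write_tsv(counts, path, index_label="sample_id")
    written.append(path)

    meta = metadata.sort_index(axis=0)
    meta = meta[sorted(meta.columns)]
    path = directory / "metadata.tsv"
    _write_tsv(meta, path, index_label="sample_id")
    written.append(path)

    if hits is not None:
        path = directory / "hits.tsv"
        _write_tsv(hits.sort_values(["otu_id", "hit_order"]).reset_index(drop=True), path, None)
        written.append(path)
    if traits is not None:
        path = directory / "traits.tsv"
        _write_tsv(traits.sort_values(["genus", "species"]).reset_index(drop=True), path, None)
        written.append(path)
    if report is not None:
        path = directory / "filter_report.json"
        report.to_json(path)
        written.append(path)
    return written


def read_config(path: str | Path) -> dict:
    """Read a YAML configuration file into a plain mapping."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError("config file must contain a YAML mapping")
    return data


def read_tree(path_or_string: str | Path) -> dendropy.Tree:
    """Read a Newick phylogeny suitable for phylogenetic distances.

    Requires branch lengths on all non-root edges and unique tip labels;
    polytomies are fine.  Accepts either a file path or a literal Newick
    string (must end with ';').
    """
    text = None
    s = str(path_or_string)
    if s.strip().endswith(";") and "(" in s:
        text = s
    else:
        text = Path(path_or_string).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise FormatError(f"duplicate tip labels: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dup = sorted({l for l in labels if labels.count(l) > 1})
    if dup:
        raise FormatError(f"duplicate tip labels: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError(
                "tree has missing branch lengths; phylogenetic distances undefined"
            )
    return tree
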