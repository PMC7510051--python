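"""Synthetic regional soil-fungal survey generator.

Emulates the structure of a multi-year regional metabarcoding survey:
plots spread over a rectangle and several sampling years, soil chemistry
with realistic covariances (Ca rises and C/N falls with pH), per-habitat
tree basal-area compositions, and an OTU table in which every OTU has a
Gaussian realized niche along the soil-pH gradient:

    E[rel. abundance of OTU i in sample s]
        ∝ base_i · exp(−(pH_s − opt_i)² / (2 w_i²)) · host_i(s)

where ``host_i(s)`` is the basal-area proportion of the host tree genus for
host-linked ectomycorrhizal OTUs and 1 otherwise.  Counts are multinomial
draws at a lognormal sequencing depth clamped to a realistic floor/ceiling.
Artifact injection adds mold-spoiled samples (one inflated mold OTU whose
within-sample share exceeds its group's flagging threshold), sub-500-read
samples, and negative/positive control samples, recording everything in a
ground-truth object so downstream stages can be tested for exact recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import OtuTable
from .qc import QcThresholds
from .traits import TAXONOMY_PATHS, THRESHOLDED_MOLD_GROUPS, default_traits

TREE_GENERA = [
    "Pinus", "Picea", "Betula", "Populus", "Quercus", "Salix",
    "Corylus", "Alnus", "Tilia", "Acer", "Fraxinus",
]
ECM_TREE_GENERA = [
    "Pinus", "Picea", "Betula", "Populus", "Quercus", "Salix",
    "Corylus", "Alnus", "Tilia",
]
HABITATS = ["forest", "woodland", "park", "grassland", "cropland", "bog"]
COLLECTORS = ["AA", "BB", "CC", "DD", "EE"]

# Dirichlet concentration per habitat over TREE_GENERA, and total tree cover %
_HABITAT_TREE_PROFILE = {
    "forest": ([8, 8, 4, 1, 2, 1, 1, 1, 1, 1, 1], 95.0),
    "woodland": ([2, 2, 4, 2, 3, 2, 3, 2, 3, 2, 2], 70.0),
    "park": ([1, 2, 2, 2, 3, 1, 2, 1, 4, 4, 3], 55.0),
    "grassland": ([1, 1, 2, 1, 1, 2, 1, 1, 1, 1, 1], 6.0),
    "cropland": ([1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1], 3.0),
    "bog": ([8, 2, 3, 1, 1, 2, 1, 1, 1, 1, 1], 35.0),
}

#: genus pool for OTU truth: (genus, relative frequency weight)
_OTU_GENUS_WEIGHTS = [
    ("Russula", 5), ("Lactarius", 3), ("Inocybe", 6), ("Cortinarius", 5),
    ("Tomentella", 6), ("Amphinema", 2), ("Piloderma", 2), ("Suillus", 2),
    ("Cenococcum", 2), ("Hyaloscypha", 4), ("Tuber", 2), ("Ramaria", 1),
    ("Mortierella", 4), ("Umbelopsis", 2), ("Mucor", 2), ("Penicillium", 3),
    ("Aspergillus", 2), ("Mycena", 5), ("Phanerochaete", 3), ("Alternaria", 4),
    ("Fusarium", 3), ("Trichoderma", 3), ("Solicoccozyma", 4), ("Saitozyma", 2),
    ("Exophiala", 2), ("Oidiodendron", 3), ("Glomus", 4), ("Archaeorhizomyces", 3),
]


@dataclass
class SurveyConfig:
    """Study conditions for one synthetic survey.

    Depth parameters are on the natural-log scale and default to values
    whose lognormal mean/SD approximate ~2400 ± 1240 reads per sample with
    a 504-read floor and 12763-read ceiling.
    """

    n_plots: int = 300
    n_otus: int = 400
    n_control_samples: int = 6
    depth_log_mean: float = 7.675
    depth_log_sd: float = 0.483
    min_depth_truth: int = 504
    max_depth_truth: int = 12763
    frac_spoiled: float = 0.03
    frac_low_depth: float = 0.03
    pH_range: tuple[float, float] = (3.0, 8.0)
    niche_width_range: tuple[float, float] = (0.6, 2.0)
    frac_host_linked: float = 0.5
    multi_otu_spoilage: bool = False
    spatial_structure: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_plots < 2 or self.n_otus < 2:
            raise ConfigurationError("n_plots and n_otus must both be >= 2")
        for name in ("frac_spoiled", "frac_low_depth", "frac_host_linked"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.pH_range
        if not (2.0 <= lo < hi <= 9.0):
            raise ConfigurationError(f"pH_range must be increasing within [2, 9], got {self.pH_range}")
        wlo, whi = self.niche_width_range
        if not 0 < wlo <= whi:
            raise ConfigurationError("niche_width_range must be positive and increasing")
        if self.min_depth_truth < 1 or self.max_depth_truth < self.min_depth_truth:
            raise ConfigurationError("invalid depth truth bounds")
        if self.frac_spoiled + self.frac_low_depth > 1.0:
            raise ConfigurationError("frac_spoiled + frac_low_depth must not exceed 1")
        self.pH_range = tuple(self.pH_range)
        self.niche_width_range = tuple(self.niche_width_range)

    @classmethod
    def from_file(cls, path) -> "SurveyConfig":
        """Build a config from a YAML mapping of field names to values."""
        from .io import read_config

        return cls(**read_config(path))


@dataclass
class GroundTruth:
    """Truth labels attached to a synthetic survey.

    ``otus``: per-OTU niche optimum/width, host genus, base abundance,
    genus and mold group.  ``samples``: spoiled/control/low-depth flags,
    the spoiling mold group, and the drawn sequencing depth.
    """

    otus: pd.DataFrame
    samples: pd.DataFrame


class SurveyData(NamedTuple):
    table: OtuTable
    metadata: pd.DataFrame
    assignments: pd.DataFrame
    truth: GroundTruth


def _rng(config: SurveyConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def generate_environment(config: SurveyConfig) -> pd.DataFrame:
    """Generate per-plot environmental metadata.

    pH is uniform over the configured range; Ca (and Mg, more weakly) rise
    with pH while C/N falls, mimicking the calcareous-to-podzol gradient;
    tree basal-area percentages come from a per-habitat Dirichlet and EcM
    plant % is the sum over EcM tree genera.
    """
    rng = _rng(config, 1)
    n = config.n_plots
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    lo, hi = config.pH_range
    pH = rng.uniform(lo, hi, n)
    z = (pH - (lo + hi) / 2) / ((hi - lo) / 2)  # standardized pH in [-1, 1]

    # soil chemistry (mg/kg for cations/P/K, % for C and N)
    ca = np.exp(6.0 + 1.6 * z + rng.normal(0, 0.55, n))
    mg = np.exp(4.5 + 0.8 * z + rng.normal(0, 0.6, n))
    p = np.exp(3.4 + rng.normal(0, 0.7, n))
    k = np.exp(4.6 + rng.normal(0, 0.5, n))
    c_pct = np.exp(1.2 - 0.55 * z + rng.normal(0, 0.45, n))
    n_pct = np.exp(-1.3 - 0.15 * z + rng.normal(0, 0.35, n))
    d15n = rng.normal(3.0, 2.0, n)
    d13c = rng.normal(-27.0, 1.0, n)

    habitat = rng.choice(HABITATS, size=n, p=[0.45, 0.12, 0.10, 0.12, 0.11, 0.10])
    tree = np.zeros((n, len(TREE_GENERA)))
    for i, h in enumerate(habitat):
        alpha, cover = _HABITAT_TREE_PROFILE[h]
        tree[i] = rng.dirichlet(alpha) * cover
    tree_df = pd.DataFrame(tree, columns=[f"tree_{g}" for g in TREE_GENERA], index=sample_ids)
    ecm_pct = tree_df[[f"tree_{g}" for g in ECM_TREE_GENERA]].sum(axis=1)

    years = rng.choice([2015, 2016, 2017], size=n, p=[0.3, 0.4, 0.3])
    doy = rng.integers(120, 300, size=n)  # growing-season sampling
    dates = [
        (pd.Timestamp(f"{y}-01-01") + pd.Timedelta(days=int(d))).date().isoformat()
        for y, d in zip(years, doy)
    ]

    management = np.where(
        np.isin(habitat, ["woodland", "park"]),
        rng.choice(["managed", "unmanaged", "coppiced"], size=n),
        "",
    )

    meta = pd.DataFrame(
        {
            "x": rng.uniform(0, 200_000, n),
            "y": rng.uniform(0, 150_000, n),
            "date": dates,
            "collector": rng.choice(COLLECTORS, size=n),
            "habitat_type": habitat,
            "management": management,
            "vegetation_age": np.round(np.exp(rng.normal(3.8, 0.8, n))).astype(int),
            "plant_richness": rng.poisson(6, n) + 1,
            "pH_KCl": pH,
            "P": p,
            "K": k,
            "Mg": mg,
            "Ca": ca,
            "C_pct": c_pct,
            "N_pct": n_pct,
            "d15N": d15n,
            "d13C": d13c,
            "control_flag": False,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    meta = pd.concat([meta, tree_df], axis=1)
    meta["ecm_plant_pct"] = ecm_pct
    meta["ln_CN"] = np.log(c_pct / n_pct)
    meta["ln_CP"] = np.log((c_pct * 1e4) / p)  # % -> mg/kg for a unitless ratio
    meta["ln_NP"] = np.log((n_pct * 1e4) / p)
    return meta


def _draw_otu_truth(config: SurveyConfig, rng: np.random.Generator) -> pd.DataFrame:
    traits = default_traits()
    genus_rows = traits[traits["species"] == ""].set_index("genus")
    genera = [g for g, _ in _OTU_GENUS_WEIGHTS]
    weights = np.array([w for _, w in _OTU_GENUS_WEIGHTS], dtype=float)
    weights /= weights.sum()

    m = config.n_otus
    otu_ids = [f"OTU{i + 1:05d}" for i in range(m)]
    genus = rng.choice(genera, size=m, p=weights)
    lo, hi = config.pH_range
    # regional-pool optima extend well beyond the sampled gradient so the
    # summed expected abundance stays roughly flat across the window;
    # otherwise compositional closure shifts relative-abundance optima
    # outward relative to the truth optima
    optimum = rng.uniform(lo - 3.0, hi + 3.0, m)
    wlo, whi = config.niche_width_range
    width = rng.uniform(wlo, whi, m)
    base = np.exp(rng.normal(0.0, 1.0, m))

    guild = np.array([genus_rows.loc[g, "guild"] for g in genus], dtype=object)
    mold_group = np.array([genus_rows.loc[g, "mold_group"] for g in genus], dtype=object)
    # molds are ubiquitous background taxa: broad niches, damped abundance so
    # that un-spoiled samples stay well below the flagging thresholds
    is_mold = mold_group != ""
    base[is_mold] *= 0.25
    width[is_mold] = np.maximum(width[is_mold], 1.5)

    host = np.array([""] * m, dtype=object)
    is_ecm = guild == "EcM"
    linked = is_ecm & (rng.random(m) < config.frac_host_linked)
    host[linked] = rng.choice(ECM_TREE_GENERA, size=int(linked.sum()))

    species = np.array(
        [f"{g} sp{i + 1}" for i, g in enumerate(genus)], dtype=object
    )
    # multi-lifestyle genus gets resolvable species names
    fus = genus == "Fusarium"
    species[fus] = rng.choice(["Fusarium oxysporum", "Fusarium solani"], size=int(fus.sum()))

    return pd.DataFrame(
        {
            "genus": genus,
            "species": species,
            "guild": guild,
            "mold_group": mold_group,
            "niche_optimum": optimum,
            "niche_width": width,
            "base_abundance": base,
            "host_taxon": host,
        },
        index=pd.Index(otu_ids, name="otu_id"),
    )


def _truth_assignments(otu_truth: pd.DataFrame) -> pd.DataFrame:
    """Full truth taxonomy + function table for the generated OTUs."""
    traits = default_traits()
    genus_rows = traits[traits["species"] == ""].set_index("genus")
    rows = []
    for otu_id, rec in otu_truth.iterrows():
        g = rec["genus"]
        phylum, cls, order, family = TAXONOMY_PATHS[g]
        rows.append(
            {
                "otu_id": otu_id,
                "kingdom": "Fungi",
                "phylum": phylum,
                "class": cls,
                "order": order,
                "family": family,
                "genus": g,
                "species": rec["species"],
                "guild": rec["guild"],
                "ecm_lineage": genus_rows.loc[g, "ecm_lineage"],
                "exploration_type": genus_rows.loc[g, "exploration_type"],
                "mold_group": rec["mold_group"],
            }
        )
    return pd.DataFrame(rows).set_index("otu_id")


def expected_relative_abundance(
    metadata: pd.DataFrame, otu_truth: pd.DataFrame
) -> pd.DataFrame:
    """Expected relative-abundance matrix implied by the Gaussian niches."""
    pH = metadata["pH_KCl"].to_numpy()[:, None]
    opt = otu_truth["niche_optimum"].to_numpy()[None, :]
    wid = otu_truth["niche_width"].to_numpy()[None, :]
    expected = otu_truth["base_abundance"].to_numpy()[None, :] * np.exp(
        -((pH - opt) ** 2) / (2.0 * wid**2)
    )
    host = otu_truth["host_taxon"].to_numpy()
    for j, h in enumerate(host):
        if h:
            expected[:, j] *= metadata[f"tree_{h}"].to_numpy() / 100.0
    totals = expected.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ConfigurationError("a sample has all-zero expected abundance")
    return pd.DataFrame(
        expected / totals, index=metadata.index, columns=otu_truth.index
    )


def generate_otu_table(
    metadata: pd.DataFrame, config: SurveyConfig
) -> tuple[OtuTable, pd.DataFrame, GroundTruth]:
    """Draw the OTU count table and its ground truth from the niche model."""
    rng = _rng(config, 2)
    otu_truth = _draw_otu_truth(config, rng)
    probs = expected_relative_abundance(metadata, otu_truth)

    n = len(metadata)
    depth = np.exp(rng.normal(config.depth_log_mean, config.depth_log_sd, n))
    depth = np.clip(np.round(depth), config.min_depth_truth, config.max_depth_truth).astype(int)

    counts = np.empty((n, config.n_otus), dtype=np.int64)
    pvals = probs.to_numpy()
    for i in range(n):
        counts[i] = rng.multinomial(depth[i], pvals[i])
    table = OtuTable(
        pd.DataFrame(counts, index=metadata.index, columns=otu_truth.index),
        validate=False,
    )

    samples = pd.DataFrame(
        {
            "spoiled_flag": False,
            "spoiling_mold_group": "",
            "control_flag": False,
            "low_depth_flag": False,
            "depth": depth,
        },
        index=metadata.index,
    )
    truth = GroundTruth(otus=otu_truth, samples=samples)
    return table, _truth_assignments(otu_truth), truth


def inject_artifacts(
    table: OtuTable,
    metadata: pd.DataFrame,
    truth: GroundTruth,
    config: SurveyConfig,
    thresholds: QcThresholds | None = None,
) -> tuple[OtuTable, pd.DataFrame, GroundTruth]:
    """Inject spoiled samples, low-depth samples and control samples.

    Spoilage inflates one mold OTU of a randomly chosen thresholded group so
    that its within-sample share lands uniformly in (threshold, 0.9]; counts
    are rounded up so the achieved share strictly exceeds the draw.  Returns
    updated (table, metadata, truth); inputs are not modified.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    rng = _rng(config, 3)
    counts = table.counts.copy()
    meta = metadata.copy()
    samples = truth.samples.copy()

    n = len(counts)
    n_spoil = int(round(config.frac_spoiled * n))
    n_low = int(round(config.frac_low_depth * n))
    if n_spoil + n_low > n:
        raise ConfigurationError("frac_spoiled + frac_low_depth exceed the sample count")
    chosen = rng.choice(n, size=n_spoil + n_low, replace=False)
    spoil_idx, low_idx = chosen[:n_spoil], chosen[n_spoil:]

    group_thresholds = {
        "Pezizomycotina_mold": thresholds.pezizomycotina_max,
        "Umbelopsidales": thresholds.umbelopsidales_max,
        "Mortierellales": thresholds.mortierellales_max,
    }
    mold_otus = {
        g: truth.otus.index[truth.otus["mold_group"] == g].tolist()
        for g in THRESHOLDED_MOLD_GROUPS
    }
    available = [g for g in THRESHOLDED_MOLD_GROUPS if mold_otus[g]]
    if n_spoil and not available:
        raise ConfigurationError("no mold OTUs available to spoil samples with")

    for i in spoil_idx:
        sid = counts.index[i]
        group = available[rng.integers(len(available))]
        thr = group_thresholds[group]
        n_inflate = 1
        if config.multi_otu_spoilage and len(mold_otus[group]) > 1:
            n_inflate = int(rng.integers(2, min(4, len(mold_otus[group])) + 1))
        otus = list(rng.choice(mold_otus[group], size=n_inflate, replace=False))
        # the dominant OTU alone exceeds the group threshold (rounding up so
        # the achieved share strictly beats the draw); in multi-OTU mode the
        # remaining spoilers add smaller blooms on top
        target = thr + (0.9 - thr) * rng.uniform(np.nextafter(0.0, 1.0), 1.0)
        rest = int(counts.loc[sid].drop(otus).sum())
        lead = math.ceil(target / (1.0 - target) * rest)
        counts.loc[sid, otus[0]] = lead
        if n_inflate > 1:
            # secondary blooms are capped so the dominant OTU's diluted
            # share still strictly exceeds the group threshold
            extra_budget = 0.9 * (target / thr - 1.0) * (lead + rest)
            for o in otus[1:]:
                extra = int(min(lead * rng.uniform(0.1, 0.4),
                                extra_budget / (n_inflate - 1)))
                counts.loc[sid, o] = extra
        samples.loc[sid, ["spoiled_flag", "spoiling_mold_group"]] = True, group

    for i in low_idx:
        sid = counts.index[i]
        row = counts.loc[sid].to_numpy()
        total = int(row.sum())
        new_depth = int(rng.integers(50, thresholds.min_reads))
        if total > new_depth:
            counts.loc[sid] = rng.multivariate_hypergeometric(row, new_depth)
        samples.loc[sid, "low_depth_flag"] = True

    # control samples: alternating negative (sparse noise) / positive (8-OTU mock)
    mock_otus = list(counts.columns[:8])
    for j in range(config.n_control_samples):
        negative = j % 2 == 0
        cid = f"{'NEG' if negative else 'POS'}{j // 2 + 1:02d}"
        row = np.zeros(counts.shape[1], dtype=np.int64)
        if negative:
            n_reads = int(rng.integers(0, 51))
            if n_reads:
                hit = rng.integers(0, counts.shape[1], size=n_reads)
                row = np.bincount(hit, minlength=counts.shape[1]).astype(np.int64)
        else:
            for o in mock_otus:
                row[counts.columns.get_loc(o)] = int(rng.poisson(1000))
        counts.loc[cid] = row
        control_meta = meta.iloc[0].copy()
        control_meta["control_flag"] = True
        control_meta["habitat_type"] = "control"
        meta.loc[cid] = control_meta
        samples.loc[cid] = [False, "", True, False, int(row.sum())]

    new_truth = GroundTruth(otus=truth.otus.copy(), samples=samples)
    return OtuTable(counts, validate=False), meta, new_truth


def generate_survey(config: SurveyConfig) -> SurveyData:
    """End-to-end synthetic survey: environment, counts, artifacts."""
    metadata = generate_environment(config)
    table, assignments, truth = generate_otu_table(metadata, config)
    table, metadata, truth = inject_artifacts(table, metadata, truth, config)
    return SurveyData(table=table, metadata=metadata, assignments=assignments, truth=truth)


def truth_hit_table(
    assignments: pd.DataFrame,
    n_hits: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Noise-free reference-hit table consistent with truth taxonomy.

    Every OTU gets ``n_hits`` unanimous hits with genus-grade similarity and
    tiny e-values, so rank-threshold assignment must recover the truth path
    exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for otu_id, rec in assignments.iterrows():
        for h in range(1, n_hits + 1):
            rows.append(
                {
                    "otu_id": otu_id,
                    "hit_order": h,
                    "similarity_pct": float(rng.uniform(95.0, 99.9)),
                    "evalue": 1e-100,
                    "kingdom": rec["kingdom"],
                    "phylum": rec["phylum"],
                    "class": rec["class"],
                    "order": rec["order"],
                    "family": rec["family"],
                    "genus": rec["genus"],
                }
            )
    return pd.DataFrame(rows)
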