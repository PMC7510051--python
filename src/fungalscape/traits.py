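"""Synthetic functional-traits lookup used by the survey generator.

This is a small, hand-curated stand-in modeled on genus-level guild
databases for fungi: each row maps a genus to a guild and, for
ectomycorrhizal (EcM) genera, to an EcM lineage and exploration type; the
four mold clades carry a mold-group label.  Genera flagged multi-lifestyle
require a species-level override row before a guild is assigned.

The genus names and their lineage/exploration assignments follow common
usage in the fungal-ecology literature; the table itself is synthetic and
exists so the generator, taxonomy and QC modules can be exercised without
external downloads.
"""

from __future__ import annotations

import pandas as pd

MOLD_GROUPS = (
    "Mortierellales",
    "Umbelopsidales",
    "Mucorales",
    "Pezizomycotina_mold",
)

#: mold groups with a spoilage-removal threshold (Mucorales is profiled only)
THRESHOLDED_MOLD_GROUPS = ("Pezizomycotina_mold", "Umbelopsidales", "Mortierellales")

EXPLORATION_TYPES = (
    "contact",
    "short-distance-delicate",
    "short-distance-coarse",
    "medium-distance-smooth",
    "medium-distance-fringe",
    "long-distance",
    "mat",
)

# genus -> (phylum, class, order, family)
TAXONOMY_PATHS = {
    "Russula": ("Basidiomycota", "Agaricomycetes", "Russulales", "Russulaceae"),
    "Lactarius": ("Basidiomycota", "Agaricomycetes", "Russulales", "Russulaceae"),
    "Inocybe": ("Basidiomycota", "Agaricomycetes", "Agaricales", "Inocybaceae"),
    "Cortinarius": ("Basidiomycota", "Agaricomycetes", "Agaricales", "Cortinariaceae"),
    "Tomentella": ("Basidiomycota", "Agaricomycetes", "Thelephorales", "Thelephoraceae"),
    "Amphinema": ("Basidiomycota", "Agaricomycetes", "Atheliales", "Atheliaceae"),
    "Piloderma": ("Basidiomycota", "Agaricomycetes", "Atheliales", "Atheliaceae"),
    "Suillus": ("Basidiomycota", "Agaricomycetes", "Boletales", "Suillaceae"),
    "Cenococcum": ("Ascomycota", "Dothideomycetes", "Mytilinidiales", "Gloniaceae"),
    "Hyaloscypha": ("Ascomycota", "Leotiomycetes", "Helotiales", "Hyaloscyphaceae"),
    "Tuber": ("Ascomycota", "Pezizomycetes", "Pezizales", "Tuberaceae"),
    "Ramaria": ("Basidiomycota", "Agaricomycetes", "Gomphales", "Gomphaceae"),
    "Mortierella": ("Mortierellomycota", "Mortierellomycetes", "Mortierellales", "Mortierellaceae"),
    "Umbelopsis": ("Mucoromycota", "Umbelopsidomycetes", "Umbelopsidales", "Umbelopsidaceae"),
    "Mucor": ("Mucoromycota", "Mucoromycetes", "Mucorales", "Mucoraceae"),
    "Penicillium": ("Ascomycota", "Eurotiomycetes", "Eurotiales", "Aspergillaceae"),
    "Aspergillus": ("Ascomycota", "Eurotiomycetes", "Eurotiales", "Aspergillaceae"),
    "Mycena": ("Basidiomycota", "Agaricomycetes", "Agaricales", "Mycenaceae"),
    "Phanerochaete": ("Basidiomycota", "Agaricomycetes", "Polyporales", "Phanerochaetaceae"),
    "Alternaria": ("Ascomycota", "Dothideomycetes", "Pleosporales", "Pleosporaceae"),
    "Fusarium": ("Ascomycota", "Sordariomycetes", "Hypocreales", "Nectriaceae"),
    "Trichoderma": ("Ascomycota", "Sordariomycetes", "Hypocreales", "Hypocreaceae"),
    "Solicoccozyma": ("Basidiomycota", "Tremellomycetes", "Filobasidiales", "Piskurozymaceae"),
    "Saitozyma": ("Basidiomycota", "Tremellomycetes", "Tremellales", "Trimorphomycetaceae"),
    "Oidiodendron": ("Ascomycota", "Leotiomycetes", "Helotiales", "Myxotrichaceae"),
    "Glomus": ("Glomeromycota", "Glomeromycetes", "Glomerales", "Glomeraceae"),
    "Archaeorhizomyces": ("Ascomycota", "Archaeorhizomycetes", "Archaeorhizomycetales", "Archaeorhizomycetaceae"),
    "Exophiala": ("Ascomycota", "Eurotiomycetes", "Chaetothyriales", "Herpotrichiellaceae"),
}

# genus, species, multi_lifestyle, guild, ecm_lineage, exploration_type, mold_group
_ROWS = [
    ("Russula", "", False, "EcM", "/russula-lactarius", "contact", ""),
    ("Lactarius", "", False, "EcM", "/russula-lactarius", "contact", ""),
    ("Inocybe", "", False, "EcM", "/inocybe", "short-distance-delicate", ""),
    ("Cortinarius", "", False, "EcM", "/cortinarius", "medium-distance-fringe", ""),
    ("Tomentella", "", False, "EcM", "/tomentella-thelephora", "medium-distance-smooth", ""),
    ("Amphinema", "", False, "EcM", "/amphinema-tylospora", "medium-distance-fringe", ""),
    ("Piloderma", "", False, "EcM", "/piloderma", "medium-distance-fringe", ""),
    ("Suillus", "", False, "EcM", "/suillus-rhizopogon", "long-distance", ""),
    ("Cenococcum", "", False, "EcM", "/cenococcum", "short-distance-coarse", ""),
    ("Hyaloscypha", "", False, "EcM", "/meliniomyces", "short-distance-delicate", ""),
    ("Tuber", "", False, "EcM", "/tuber-helvella", "short-distance-coarse", ""),
    ("Ramaria", "", False, "EcM", "/ramaria-gautieria", "mat", ""),
    ("Mortierella", "", False, "soil saprotroph", "", "", "Mortierellales"),
    ("Umbelopsis", "", False, "soil saprotroph", "", "", "Umbelopsidales"),
    ("Mucor", "", False, "soil saprotroph", "", "", "Mucorales"),
    ("Penicillium", "", False, "soil saprotroph", "", "", "Pezizomycotina_mold"),
    ("Aspergillus", "", False, "soil saprotroph", "", "", "Pezizomycotina_mold"),
    ("Mycena", "", False, "litter saprotroph", "", "", ""),
    ("Phanerochaete", "", False, "white-rot", "", "", ""),
    ("Alternaria", "", False, "leaf pathogen", "", "", ""),
    # multi-lifestyle genus: guild requires the species-level override
    ("Fusarium", "", True, "", "", "", ""),
    ("Fusarium", "Fusarium oxysporum", True, "leaf pathogen", "", "", ""),
    ("Fusarium", "Fusarium solani", True, "soil saprotroph", "", "", ""),
    ("Trichoderma", "", False, "mycoparasite", "", "", ""),
    ("Solicoccozyma", "", False, "yeast", "", "", ""),
    ("Saitozyma", "", False, "yeast", "", "", ""),
    ("Exophiala", "", False, "dimorphic yeast", "", "", ""),
    ("Oidiodendron", "", False, "root endophyte", "", "", ""),
    ("Glomus", "", False, "AM", "", "", ""),
    ("Archaeorhizomyces", "", False, "soil saprotroph", "", "", ""),
]


def default_traits() -> pd.DataFrame:
    """Return the built-in synthetic traits table."""
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "genus",
            "species",
            "multi_lifestyle",
            "guild",
            "ecm_lineage",
            "exploration_type",
            "mold_group",
        ],
    )
    return df
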