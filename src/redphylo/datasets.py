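"""Built-in study design: the red-algal taxon panel and reference phylogeny.

The panel comprises 15 red algae (five seaweeds — Bangiophyceae plus
Florideophyceae —, eight non-seaweed mesophiles and two extremophilic
Cyanidiophytina) and 3 green algal outgroups.  The reference rooted
topology places the extremophiles sister to all mesophilic red algae,
the seaweeds at the base of the mesophiles, Stylonematophyceae basal
among the remaining mesophiles, and Compsopogonophyceae sister to
Porphyridiophyceae + Rhodellophyceae.
"""

from __future__ import annotations

import pandas as pd

from .orthologs import TaxonTable
from .trees import RootedTree, parse_newick

_TAXON_ROWS = [
    # taxon_id, name, group, class, data_type
    ("Hildenbrandia_rubra", "Hildenbrandia rubra", "red", "Seaweed", "transcriptome"),
    ("Palmaria_palmata", "Palmaria palmata", "red", "Seaweed", "transcriptome"),
    ("Calliarthron_tuberculosum", "Calliarthron tuberculosum", "red", "Seaweed", "partial genome"),
    ("Chondrus_crispus", "Chondrus crispus", "red", "Seaweed", "genome"),
    ("Porphyra_umbilicalis", "Porphyra umbilicalis", "red", "Seaweed", "transcriptome"),
    ("Purpureofilum_apyrenoidigerum", "Purpureofilum apyrenoidigerum", "red", "Mesophile", "transcriptome"),
    ("Rhodochaete_pulchella", "Rhodochaete pulchella", "red", "Mesophile", "transcriptome"),
    ("Rhodosorus_marinus", "Rhodosorus marinus", "red", "Mesophile", "transcriptome"),
    ("Rhodella_maculata", "Rhodella maculata", "red", "Mesophile", "transcriptome"),
    ("Compsopogon_coeruleus", "Compsopogon coeruleus", "red", "Mesophile", "transcriptome"),
    ("Erythrolobus_australicus", "Erythrolobus australicus", "red", "Mesophile", "transcriptome"),
    ("Timspurckia_oligopyrenoides", "Timspurckia oligopyrenoides", "red", "Mesophile", "transcriptome"),
    ("Porphyridium_purpureum", "Porphyridium purpureum", "red", "Mesophile", "transcriptome"),
    ("Galdieria_sulphuraria", "Galdieria sulphuraria", "red", "Extremophile", "transcriptome"),
    ("Cyanidioschyzon_merolae", "Cyanidioschyzon merolae", "red", "Extremophile", "genome"),
    ("Chlorella_variabilis", "Chlorella variabilis", "green", "Green", "genome"),
    ("Chlamydomonas_reinhardtii", "Chlamydomonas reinhardtii", "green", "Green", "genome"),
    ("Micromonas_pusilla", "Micromonas pusilla", "green", "Green", "genome"),
]


def red_algal_taxa() -> TaxonTable:
    """The 15 red + 3 green taxon panel."""
    return TaxonTable(
        pd.DataFrame(
            _TAXON_ROWS, columns=["taxon_id", "name", "group", "class", "data_type"]
        )
    )


# Rooted reference topology over the 15 red algae.  The resolution within
# Porphyridiophyceae is our construction; every class is monophyletic.
RED_ALGAL_TOPOLOGY = (
    "((Galdieria_sulphuraria,Cyanidioschyzon_merolae),"
    "((Porphyra_umbilicalis,(Hildenbrandia_rubra,(Palmaria_palmata,"
    "(Calliarthron_tuberculosum,Chondrus_crispus)))),"
    "((Rhodosorus_marinus,Purpureofilum_apyrenoidigerum),"
    "((Compsopogon_coeruleus,Rhodochaete_pulchella),"
    "(Rhodella_maculata,(Porphyridium_purpureum,"
    "(Erythrolobus_australicus,Timspurckia_oligopyrenoides)))))));"
)

FULL_TOPOLOGY = (
    "("
    + RED_ALGAL_TOPOLOGY[:-1]
    + ",((Chlamydomonas_reinhardtii,Chlorella_variabilis),Micromonas_pusilla));"
)


def make_ultrametric(
    tree: RootedTree, internal_length: float = 1.0, min_terminal: float = 1.0
) -> RootedTree:
    """Assign every internal branch ``internal_length`` coalescent units and
    pad terminal branches so all leaves are equidistant from the root."""
    out = tree.copy()
    depth = {id(out.root): 0.0}
    for node in out.preorder():
        if node.parent is not None and not node.is_leaf:
            node.length = internal_length
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + (
                internal_length if not node.is_leaf else 0.0
            )
    height = max(depth[id(l.parent)] for l in out.leaves()) + min_terminal
    for leaf in out.leaves():
        leaf.length = height - depth[id(leaf.parent)]
    out.root.length = None
    return out


def red_algal_species_tree(
    internal_length: float = 1.0,
    min_terminal: float = 1.0,
    with_outgroup: bool = False,
) -> RootedTree:
    """Reference species tree, ultrametric in coalescent units."""
    topo = parse_newick(FULL_TOPOLOGY if with_outgroup else RED_ALGAL_TOPOLOGY)
    return make_ultrametric(topo, internal_length, min_terminal)


# ---------------------------------------------------------------------------
# Isoprenoid (IPP) biosynthesis pathways
# ---------------------------------------------------------------------------

# Cytosolic mevalonate route (KEGG module M00095, metadata only)
MVA_ENZYMES = ("ACAT", "HMGS", "HMGR", "MVK", "PMK", "MVD", "IDI")
# Plastid methylerythritol-phosphate route (KEGG module M00096, metadata only)
MEP_ENZYMES = ("DXS", "DXR", "MCT", "CMK", "MDS", "HDS", "HDR", "IDI")
# The 3rd-6th MVA enzymes, the pathway's diagnostic core
MVA_CORE = ("HMGR", "MVK", "PMK", "MVD")

# Red algae retaining the MVA pathway: the two Stylonematophyceae and
# Galdieria sulphuraria.
MVA_PRESENT_TAXA = (
    "Galdieria_sulphuraria",
    "Rhodosorus_marinus",
    "Purpureofilum_apyrenoidigerum",
)


def mva_presence_character(taxa: TaxonTable | None = None) -> dict[str, str]:
    """MVA pathway presence/absence over the red panel (transcriptome
    absences treated as absent: the well-supported loss scenario)."""
    taxa = taxa or red_algal_taxa()
    return {
        t: ("present" if t in MVA_PRESENT_TAXA else "absent")
        for t in taxa.red_taxa()
    }
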