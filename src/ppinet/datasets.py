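"""Bundled worked-example data: the published heroin-use-disorder backbone.

A published topological study of the protein-protein interaction network
around 13 heroin-use-disorder susceptibility genes reported a giant
component of 111 proteins and 553 high-confidence interactions and a
16-protein hub/bottleneck backbone.  The printed backbone table (node,
degree, pair-normalised betweenness) is reproduced here so the selection
and summary machinery can be exercised on real numbers without any
database access.
"""

from __future__ import annotations

import pandas as pd

from .io import GeneSet

#: Giant-component size of the published network.
GIANT_COMPONENT_NODES = 111
GIANT_COMPONENT_EDGES = 553

#: The 13 susceptibility genes used as seed proteins.
SEED_PROTEINS = (
    "AUTS2", "CD74", "CEBPB", "CEBPG", "ENO2", "HAT1", "IMPDH2",
    "JUN", "MBD1", "PDK1", "PRKCB", "RASA1", "RGS3",
)

#: Published backbone: (node, degree k, betweenness centrality BC).
BACKBONE_TABLE = (
    ("JUN", 43, 0.138335165),
    ("MAPK14", 32, 0.083166142),
    ("FOS", 26, 0.059760577),
    ("LCK", 26, 0.058523406),
    ("RELA", 25, 0.069572515),
    ("MAPK1", 25, 0.046624799),
    ("CREBBP", 24, 0.163843625),
    ("ATF2", 24, 0.022118131),
    ("EP300", 23, 0.129821489),
    ("MAPK8", 22, 0.044774657),
    ("HRAS", 22, 0.027715087),
    ("CREB1", 17, 0.128192989),
    ("ITPA", 13, 0.181820962),
    ("PCK1", 7, 0.354489853),
    ("PKLR", 6, 0.135446205),
    ("PKM", 6, 0.135446205),
)

#: KEGG addiction-pathway memberships observed in the second extended network.
_ADDICTION_SETS = {
    "alcoholism": (
        "ARAF", "ATF2", "BRAF", "CREB1", "CREB5", "FOSB", "HDAC1", "HDAC2",
        "HDAC3", "HIST2H2BE", "HRAS", "MAP2K1", "MAPK1", "MAPK3", "RAF1", "SOS1",
    ),
    "amphetamine_addiction": (
        "ATF2", "CREB1", "CREB5", "FOS", "FOSB", "HDAC1", "JUN",
    ),
    "cocaine_addiction": (
        "ATF2", "CREB1", "CREB5", "FOSB", "JUN", "NFKB1", "RELA",
    ),
}


def backbone_table() -> pd.DataFrame:
    """The published 16-row backbone as a DataFrame (node, degree, betweenness)."""
    return pd.DataFrame(BACKBONE_TABLE, columns=["node", "degree", "betweenness"])


def seed_proteins() -> list[str]:
    """The 13 seed proteins of the published network query."""
    return list(SEED_PROTEINS)


def addiction_gene_sets() -> list[GeneSet]:
    """KEGG addiction-pathway gene sets as generic :class:`GeneSet` objects."""
    return [
        GeneSet(set_id=set_id, name=f"KEGG pathway: {set_id.replace('_', ' ')}",
                members=frozenset(members))
        for set_id, members in _ADDICTION_SETS.items()
    ]
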