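"""Dollo-parsimony counting of independent gene losses on a species tree.

Under Dollo parsimony a gene arises once and, once lost on a lineage, is
never regained.  With presence/loss states at the tips and the root fixed
to "present" (the gene is ancestral for the clade), the minimum number of
losses is found by labelling every internal node *present* iff any
descendant tip is present; each parent-present -> child-lost edge is one
independent loss event.  Polytomies need no special treatment.

The packaged fixtures encode the 35-family rodent phylogeny with the
species whose genomes have been screened for *SCNN1D*, and their
intact/pseudogene/absent status.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional

import dendropy
import pandas as pd

from .errors import FamilyUnknown, StateMissing

PRESENT = "present"
LOST = "lost"

#: rodent families recognized in the classification but without a sequenced
#: genome at the time of the screen (category ``no_data``)
NO_DATA_FAMILIES = (
    "Anomaluridae",
    "Zenkerellidae",
    "Geomyidae",
    "Sminthidae",
    "Platacanthomyidae",
    "Calomyscidae",
    "Diatomyidae",
    "Abrocomidae",
)

FAMILY_CATEGORIES = (
    "intact_with_fusion",
    "intact_without_fusion",
    "pseudogene",
    "absent",
    "mixed",
    "no_data",
)


@dataclass(frozen=True)
class LossEdge:
    """An edge on which the gene was lost, identified by the lost clade."""

    parent_tips: frozenset
    lost_tips: frozenset

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LossEdge({sorted(self.lost_tips)})"


def load_tree(source: str) -> dendropy.Tree:
    """Read a rooted Newick tree from a string or file path."""
    if "(" in source:
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def _tip_name(leaf) -> str:
    return leaf.taxon.label.replace("_", " ")


def dollo_min_losses(
    tree: dendropy.Tree,
    states: Mapping[str, str],
) -> tuple[int, set[LossEdge]]:
    """Minimum number of independent losses and the edges they map to.

    ``states`` maps tip names (spaces or underscores both accepted) to
    ``"present"``/``"lost"``.  The root is constrained to *present*; a
    tree whose tips are all lost therefore counts one loss on the edge
    below the root.
    """
    norm = {k.replace("_", " "): v for k, v in states.items()}
    presence: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            name = _tip_name(node)
            if name not in norm:
                raise StateMissing(f"no state for tip {name!r}")
            state = norm[name]
            if state not in (PRESENT, LOST):
                raise ValueError(f"bad state {state!r} for {name!r}")
            presence[node] = state == PRESENT
        else:
            presence[node] = any(presence[c] for c in node.child_nodes())

    losses: set[LossEdge] = set()
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        parent_present = True if parent is None else presence[parent]
        if not presence[node] and parent_present:
            lost_tips = frozenset(_tip_name(l) for l in node.leaf_iter())
            parent_tips = (
                frozenset(_tip_name(l) for l in tree.leaf_node_iter())
                if parent is None
                else frozenset(_tip_name(l) for l in parent.leaf_iter())
            )
            losses.add(LossEdge(parent_tips=parent_tips, lost_tips=lost_tips))
    return len(losses), losses


def summarize_family_states(
    statuses: Mapping[str, str],
    families: Mapping[str, str],
    fusion: Optional[Mapping[str, bool]] = None,
    all_families: Optional[Iterable[str]] = None,
) -> dict[str, str]:
    """Collapse species-level integrity statuses to one category per family.

    ``statuses`` maps species to ``intact``/``pseudogene``/``absent``.
    A family mixing intact and lost species is ``mixed``; a family whose
    species are all intact splits on whether any carries the exon fusion;
    families without screened species are ``no_data``.
    """
    fusion = fusion or {}
    per_family: dict[str, list[str]] = {}
    for species, status in statuses.items():
        if species not in families:
            raise FamilyUnknown(f"species {species!r} has no family assignment")
        if status not in ("intact", "pseudogene", "absent"):
            raise ValueError(f"bad status {status!r} for {species!r}")
        per_family.setdefault(families[species], []).append(species)

    out: dict[str, str] = {}
    universe = set(all_families or []) | set(per_family)
    for fam in universe:
        species = per_family.get(fam, [])
        if not species:
            out[fam] = "no_data"
            continue
        intact = [s for s in species if statuses[s] == "intact"]
        lost = [s for s in species if statuses[s] != "intact"]
        if intact and lost:
            out[fam] = "mixed"
        elif intact:
            out[fam] = (
                "intact_with_fusion"
                if any(fusion.get(s, False) for s in intact)
                else "intact_without_fusion"
            )
        else:
            out[fam] = (
                "absent"
                if all(statuses[s] == "absent" for s in species)
                else "pseudogene"
            )
    return out


# ---------------------------------------------------------------------------
# packaged fixtures: screened rodent species and the family phylogeny
# ---------------------------------------------------------------------------

def load_rodent_states() -> pd.DataFrame:
    """Species table of the rodent *SCNN1D* screen.

    Columns: species, family, clade, status (intact/pseudogene/absent),
    invasive (bool), fusion (bool).
    """
    ref = resources.files("enac_decay.data") / "rodent_scnn1d_states.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df["invasive"] = df["invasive"].astype(bool)
    df["fusion"] = df["fusion"].astype(bool)
    return df


def load_rodent_tree() -> dendropy.Tree:
    """Species-resolved rodent phylogeny matching the states table."""
    ref = resources.files("enac_decay.data") / "rodent_families.nwk"
    with resources.as_file(ref) as path:
        return load_tree(str(path))


def rodent_tip_states(df: Optional[pd.DataFrame] = None) -> dict[str, str]:
    """Presence/loss states for Dollo counting (pseudogene == absent == lost)."""
    if df is None:
        df = load_rodent_states()
    return {
        row.species: (PRESENT if row.status == "intact" else LOST)
        for row in df.itertuples()
    }
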