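"""Presence/absence profiles on species trees and Dollo gain/loss mapping.

Each component (gene family) is assumed to have been gained exactly once -
at the most recent common ancestor of the taxa that still carry it - and
lost any number of times afterwards (Dollo parsimony). The loss set is the
minimal set of edges below the gain whose removal explains every absent
leaf; uncertain leaves are resolved to whichever state avoids events.

Trees are handled with dendropy (Newick in/out, MRCA queries); clades are
reported as frozensets of leaf labels so results are independent of
internal-node naming.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd

PRESENT, ABSENT, UNCERTAIN = "1", "0", "?"
_STATES = {PRESENT, ABSENT, UNCERTAIN}


class NewickError(ValueError):
    pass


def read_newick(text: str) -> dendropy.Tree:
    """Parse a rooted Newick string; polytomies allowed, leaf labels unique."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:
        raise NewickError(f"invalid Newick: {exc}") from exc
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate leaf labels: {dupes}")
    if not labels:
        raise NewickError("tree has no labelled leaves")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon}


def _clade_leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(
        leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon
    )


@dataclass(frozen=True)
class PhyloProfile:
    """States matrix: components x taxa, cells in {'1', '0', '?'}."""

    frame: pd.DataFrame  # index = components, columns = taxa

    def __post_init__(self):
        bad = set(self.frame.to_numpy().ravel()) - _STATES
        if bad:
            raise ValueError(f"invalid profile states: {sorted(bad)}")
        if len(self.frame.index) and self.frame.shape[1] == 0:
            raise ValueError("profile has components but no taxa")

    @property
    def components(self) -> list[str]:
        return list(self.frame.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.columns)

    def taxa_in_state(self, component: str, state: str) -> set[str]:
        row = self.frame.loc[component]
        return set(row.index[row == state])

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping[str, str]]) -> "PhyloProfile":
        """``data[component][taxon] -> state``."""
        return cls(pd.DataFrame(data).T.fillna(UNCERTAIN).astype(str))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhyloProfile":
        return cls(pd.read_csv(path, sep="\t", index_col=0, dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t")


@dataclass(frozen=True)
class GainLossEntry:
    component: str
    gain_clade: frozenset[str] | None  # leaf set under the gain node
    loss_clades: tuple[frozenset[str], ...]  # leaf set under each loss edge

    @property
    def n_gains(self) -> int:
        return 0 if self.gain_clade is None else 1

    @property
    def n_losses(self) -> int:
        return len(self.loss_clades)


def dollo_map(
    tree: dendropy.Tree, profile: PhyloProfile, component: str
) -> GainLossEntry:
    """Single-gain / minimal-loss history for one component."""
    leaves = leaf_labels(tree)
    present = profile.taxa_in_state(component, PRESENT) & leaves
    absent = profile.taxa_in_state(component, ABSENT) & leaves
    if not present:
        return GainLossEntry(component, None, ())
    if len(present) == 1:
        only = next(iter(present))
        gain_node = next(
            leaf for leaf in tree.leaf_node_iter()
            if leaf.taxon and leaf.taxon.label == only
        )
    else:
        gain_node = tree.mrca(taxon_labels=sorted(present))

    losses: list[frozenset[str]] = []

    def walk(node: dendropy.Node) -> None:
        clade = _clade_leafset(node)
        if clade & present:
            for child in node.child_nodes():
                walk(child)
        elif clade & absent:
            losses.append(clade)
        # all-uncertain clades resolve present: no event

    for child in gain_node.child_nodes():
        walk(child)
    losses.sort(key=lambda c: (len(c), sorted(c)))
    return GainLossEntry(component, _clade_leafset(gain_node), tuple(losses))


def implied_leaf_states(
    tree: dendropy.Tree, entry: GainLossEntry
) -> dict[str, str]:
    """Leaf states implied by a gain/loss history (for consistency checks)."""
    states = {}
    lost = set().union(*entry.loss_clades) if entry.loss_clades else set()
    for leaf in leaf_labels(tree):
        if entry.gain_clade is None or leaf not in entry.gain_clade:
            states[leaf] = ABSENT
        elif leaf in lost:
            states[leaf] = ABSENT
        else:
            states[leaf] = PRESENT
    return states


def profile_report(
    tree: dendropy.Tree, profile: PhyloProfile
) -> tuple[dict[str, GainLossEntry], pd.DataFrame]:
    """Per-component gain/loss entries plus a tabular summary with totals."""
    entries = {c: dollo_map(tree, profile, c) for c in profile.components}
    rows = []
    for comp, entry in entries.items():
        uncertain_only = (
            not profile.taxa_in_state(comp, PRESENT)
            and not profile.taxa_in_state(comp, ABSENT)
        )
        rows.append(
            {
                "component": comp,
                "gains": entry.n_gains,
                "losses": entry.n_losses,
                "gain_clade": ",".join(sorted(entry.gain_clade))
                if entry.gain_clade
                else "",
                "loss_clades": ";".join(
                    ",".join(sorted(c)) for c in entry.loss_clades
                ),
                "uncertain_only": uncertain_only,
            }
        )
    table = pd.DataFrame(
        rows, columns=["component", "gains", "losses", "gain_clade",
                       "loss_clades", "uncertain_only"]
    )
    if len(table):
        totals = {
            "component": "TOTAL",
            "gains": int(table["gains"].sum()),
            "losses": int(table["losses"].sum()),
            "gain_clade": "",
            "loss_clades": "",
            "uncertain_only": False,
        }
        table = pd.concat([table, pd.DataFrame([totals])], ignore_index=True)
    return entries, table
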