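"""Packaged example/seed data.

Everything in ``tomseek/data`` is synthetic or hand-encoded: the domain
seed alignments are mutated synthetic consensus sequences (filenames say
so), the lineage tree is an encoding of a published consensus arrangement
of eukaryotic groups, and the presence/absence profile is an illustrative
example in that encoding - none of it is a copied data file.
"""

from __future__ import annotations

from importlib import resources

from .phyloprofile import PhyloProfile, read_newick
from .sequence_io import Alignment, read_alignment


def _data_path(name: str):
    return resources.files("tomseek").joinpath("data", name)


def hsp20_seed_alignment() -> Alignment:
    """Synthetic Hsp20/alpha-crystallin-domain seed alignment (8 rows)."""
    return read_alignment(str(_data_path("hsp20_seed_synthetic.fasta")))


def tpr_seed_alignment() -> Alignment:
    """Synthetic 34-aa TPR repeat seed alignment (8 rows)."""
    return read_alignment(str(_data_path("tpr_seed_synthetic.fasta")))


def lineage_consensus_tree():
    """Encoded consensus arrangement of major eukaryote lineages."""
    return read_newick(_data_path("lineage_consensus_tree.nwk").read_text())


def example_tom_profile() -> PhyloProfile:
    """Illustrative TOM-subunit presence/absence profile on that tree."""
    return PhyloProfile.from_tsv(str(_data_path("tom_profile_example.tsv")))
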