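"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Every generator is fully determined by (spec, seed) and emits a
machine-readable truth table alongside the data, so downstream recovery
tests compare against construction-time labels rather than re-derived ones.

Templates are synthetic consensus sequences composed for this package -
plausible caricatures of the real protein classes (beta-barrels with a
C-terminal beta-signal, Hsp20-TPR-TMD tail-anchored receptors, short
Tom22-like proteins), not copies of any database entry. Family members are
produced by per-site substitution of a template; positions that carry the
diagnostic feature are protected so construction-time truth stays true.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import motif_scan
from .lfq_enrichment import CTRL_COLS, TEST_COLS, LfqTable
from .phyloprofile import PhyloProfile, read_newick, _clade_leafset
from .sequence_io import AMINO_ACIDS, ProteinRecord, ResidueClassTable

# --------------------------------------------------------------------------
# templates (synthetic consensus sequences)

#: beta-barrel caricature; the last 8 residues are the beta-signal
#: (polar-x-G-x-x-hydrophobic-x-hydrophobic).
BARREL_TEMPLATE = (
    "MDLSKEYTGNKLSVQGELNPQGTLELSAGYQDRFFGLKGSVNLDTGEVAGYQLSNGYRLD"
    "PETNTLSGQLNFDGKVAYDLGNGLELGGGYRFSDGKLDAEVGYKQNLGNAGVVLAI"
)
#: same barrel, terminal hydrophobic residue replaced by serine
#: (beta-signal broken at its last position).
BARREL_SER_TEMPLATE = BARREL_TEMPLATE[:-1] + "S"

#: Hsp20-like alpha-crystallin caricature (~80 aa, beta-sandwich flavour).
HSP20_CONSENSUS = (
    "MSLIPFDDFFNEPFRSLDRMFDDALGRPAVRSYAPSVDIYEDDKEVVVKAELPGVKKEDV"
    "KVSVEDNVLTISGERKSEEE"
)
#: classic 34-aa TPR helical-repeat consensus caricature.
TPR_CONSENSUS = "AEAWYNLGNAYYKQGDYQKAIEYYQKALELDPNN"

_TMD_RECEPTOR = "LIVLIVLIVLIVLIVLIVLIV"  # 21-aa strongly hydrophobic anchor
#: Tom22-like TMD: W at position 2, hydroxylated run, S at W+4 (counting W
#: as +1), proline inside.
_TMD_TOM22 = "AWSTSIVLIVLPIVLIVLIV"

#: Hsp20-TPR(3)-TMD tail-anchored receptor caricature.
TOM36_TEMPLATE = (
    HSP20_CONSENSUS + "GSDEN" + TPR_CONSENSUS * 3 + "DKEDE" + _TMD_RECEPTOR + "KKNGS"
)
#: short Tom22-like protein: acidic cytosolic domain + C-terminal TMD.
TOM22_TEMPLATE = "MSDFEDDNLFGDEATDEQNSELDRLQDE" + _TMD_TOM22 + "KK"

_TEMPLATES = {
    "barrel": BARREL_TEMPLATE,
    "barrel_ser": BARREL_SER_TEMPLATE,
    "hsp20_tpr_tmd": TOM36_TEMPLATE,
    "tom22_like": TOM22_TEMPLATE,
}

# 0-based positions never mutated (diagnostic features)
_PROTECTED = {
    "barrel": set(range(len(BARREL_TEMPLATE) - 8, len(BARREL_TEMPLATE))),
    "barrel_ser": set(range(len(BARREL_SER_TEMPLATE) - 8, len(BARREL_SER_TEMPLATE))),
    "hsp20_tpr_tmd": set(
        range(len(TOM36_TEMPLATE) - 26, len(TOM36_TEMPLATE))
    ),  # TMD + tail
    "tom22_like": set(range(28, len(TOM22_TEMPLATE))),  # TMD + tail
}

#: Robinson-Robinson amino-acid frequencies (order = AMINO_ACIDS).
ROBINSON_FREQS = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
    0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
    0.05841, 0.06441, 0.01330, 0.03216,
])


def background_frequencies(kind: str = "uniform") -> np.ndarray:
    if kind == "uniform":
        return np.full(20, 1 / 20)
    if kind == "robinson":
        return ROBINSON_FREQS / ROBINSON_FREQS.sum()
    raise ValueError(f"unknown background {kind!r}")


# --------------------------------------------------------------------------
# proteome generation


@dataclass(frozen=True)
class FamilySpec:
    name: str
    template: str  # key in _TEMPLATES
    n_members: int
    mutation_rate: float = 0.05

    def __post_init__(self):
        if self.template not in _TEMPLATES:
            raise ValueError(f"unknown template {self.template!r}")
        if self.n_members < 1:
            raise ValueError("n_members must be positive")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass(frozen=True)
class ProteomeSpec:
    families: tuple[FamilySpec, ...] = ()
    n_decoys: int = 100
    decoy_length: int = 120
    background: str = "uniform"


def _mutate(
    template: str,
    rate: float,
    protected: set[int],
    bg: np.ndarray,
    rng: np.random.Generator,
) -> str:
    chars = list(template)
    for i in range(len(chars)):
        if i in protected:
            continue
        if rng.random() < rate:
            chars[i] = AMINO_ACIDS[rng.choice(20, p=bg)]
    return "".join(chars)


def _random_sequence(length: int, bg: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=length, p=bg))


def gen_proteome(
    spec: ProteomeSpec, seed: int
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Planted families + i.i.d. decoys, with a construction-truth table.

    Members of beta-signal-negative families are rejection-sampled so that
    mutation never plants an accidental motif match inside the C-terminal
    window; the truth table therefore states motif status exactly.
    """
    rng = np.random.default_rng(seed)
    bg = background_frequencies(spec.background)
    pattern = motif_scan.compile_pattern(
        motif_scan.DEFAULT_BETA_MOTIF, ResidueClassTable()
    )
    records: list[ProteinRecord] = []
    truth_rows = []
    for fam in spec.families:
        template = _TEMPLATES[fam.template]
        protected = _PROTECTED[fam.template]
        motif_expected = fam.template == "barrel"
        for i in range(fam.n_members):
            for _ in range(200):  # rejection loop, deterministic under rng
                seq = _mutate(template, fam.mutation_rate, protected, bg, rng)
                rec = ProteinRecord(f"{fam.name}_{i + 1:03d}", seq)
                hits = motif_scan.scan(rec, pattern)
                in_window = [h for h in hits if h.in_cterm_window]
                if motif_expected and in_window:
                    break
                if not motif_expected and fam.template == "barrel_ser" and not in_window:
                    break
                if fam.template not in ("barrel", "barrel_ser"):
                    break
            records.append(rec)
            truth_rows.append(
                {
                    "record_id": rec.id,
                    "family": fam.name,
                    "template": fam.template,
                    "is_decoy": False,
                    "motif_positive": motif_expected,
                    "tail_anchored": fam.template in ("hsp20_tpr_tmd", "tom22_like"),
                    "membrane": fam.template != "soluble",
                }
            )
    for i in range(spec.n_decoys):
        rec = ProteinRecord(
            f"DEC_{i + 1:04d}", _random_sequence(spec.decoy_length, bg, rng)
        )
        records.append(rec)
        truth_rows.append(
            {
                "record_id": rec.id,
                "family": "decoy",
                "template": "decoy",
                "is_decoy": True,
                "motif_positive": False,
                "tail_anchored": False,
                "membrane": False,
            }
        )
    return records, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# LFQ table generation


@dataclass(frozen=True)
class LfqSpec:
    n_proteins: int = 200
    n_members: int = 12
    delta_log2: float = 3.0
    noise_sd: float = 0.5
    control_missingness: float = 0.8
    background_missingness: float = 0.02
    mean_range: tuple[float, float] = (20.0, 30.0)


def gen_lfq(spec: LfqSpec, seed: int) -> tuple[LfqTable, pd.DataFrame]:
    """Log-normal replicate intensities with bait-specific enrichment.

    Background proteins share a protein-specific mean across both arms;
    bait-complex members are shifted by ``delta_log2`` in the test arm and
    their control cells are dropped with the stated missingness.
    """
    if spec.n_members > spec.n_proteins:
        raise ValueError("more members than proteins")
    rng = np.random.default_rng(seed)
    accs = [f"PROT_{i + 1:04d}" for i in range(spec.n_proteins)]
    members = set(accs[: spec.n_members])
    rows = []
    for acc in accs:
        mu = rng.uniform(*spec.mean_range)
        is_member = acc in members
        test = mu + (spec.delta_log2 if is_member else 0.0) + rng.normal(
            0, spec.noise_sd, 4
        )
        ctrl = mu + rng.normal(0, spec.noise_sd, 4)
        miss_p = spec.control_missingness if is_member else spec.background_missingness
        ctrl = np.where(rng.random(4) < miss_p, np.nan, ctrl)
        test = np.where(
            rng.random(4) < spec.background_missingness, np.nan, test
        )
        row = {"accession": acc, "name": f"protein {acc}"}
        row.update({c: v for c, v in zip(TEST_COLS, test)})
        row.update({c: v for c, v in zip(CTRL_COLS, ctrl)})
        rows.append(row)
    truth = pd.DataFrame(
        {"accession": accs, "is_member": [a in members for a in accs]}
    )
    return LfqTable(pd.DataFrame(rows)), truth


# --------------------------------------------------------------------------
# species tree + presence/absence profile generation


@dataclass(frozen=True)
class TreeProfileSpec:
    n_leaves: int = 12
    components: tuple[str, ...] = ("Tom40", "Tom22", "Tom7")
    p_loss: float = 0.2
    min_gain_clade: int = 4


@dataclass(frozen=True)
class TreeProfileTruth:
    gain_clades: dict[str, frozenset[str]]
    loss_clades: dict[str, tuple[frozenset[str], ...]]


def _random_newick(labels: list[str], rng: np.random.Generator) -> str:
    if len(labels) == 1:
        return labels[0]
    k = int(rng.integers(1, len(labels)))
    return (
        f"({_random_newick(labels[:k], rng)},{_random_newick(labels[k:], rng)})"
    )


def gen_tree_profile(
    spec: TreeProfileSpec, seed: int
) -> tuple[dendropy.Tree, PhyloProfile, TreeProfileTruth]:
    """Random rooted tree plus single-gain / multiple-loss histories.

    Losses are drawn edge-by-edge below the gain with probability
    ``p_loss``, under two constraints that keep the simulated history
    identifiable: the gain node keeps at least two surviving child edges
    and every surviving internal node keeps at least one, so the simulated
    events are exactly the minimal Dollo explanation of the leaf states.
    """
    rng = np.random.default_rng(seed)
    labels = [f"T{i + 1:02d}" for i in range(spec.n_leaves)]
    order = list(labels)
    rng.shuffle(order)
    tree = read_newick(_random_newick(order, rng) + ";")

    internal = [
        n
        for n in tree.preorder_node_iter()
        if not n.is_leaf() and len(_clade_leafset(n)) >= spec.min_gain_clade
    ]
    gains: dict[str, frozenset[str]] = {}
    losses: dict[str, tuple[frozenset[str], ...]] = {}
    states: dict[str, dict[str, str]] = {}
    for comp in spec.components:
        gain_node = internal[int(rng.integers(len(internal)))]
        comp_losses: list[frozenset[str]] = []
        present: set[str] = set()

        def descend(node, is_gain: bool) -> None:
            children = node.child_nodes()
            if not children:
                present.update(_clade_leafset(node))
                return
            min_survive = 2 if is_gain and len(children) >= 2 else 1
            while True:
                lost = [rng.random() < spec.p_loss for _ in children]
                if len(children) - sum(lost) >= min_survive:
                    break
            for child, is_lost in zip(children, lost):
                if is_lost:
                    comp_losses.append(_clade_leafset(child))
                else:
                    descend(child, False)

        descend(gain_node, True)
        gains[comp] = _clade_leafset(gain_node)
        losses[comp] = tuple(comp_losses)
        states[comp] = {t: ("1" if t in present else "0") for t in labels}
    profile = PhyloProfile.from_dict(states)
    return tree, profile, TreeProfileTruth(gains, losses)
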