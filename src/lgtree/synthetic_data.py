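"""Synthetic inputs with known ground truth for every pipeline stage.

Generates clade-labelled gene trees with planted transfer events and
controlled bootstrap-support regimes, alignments evolved under a
two-parameter (transition/transversion) substitution process, and tabular
BLAST hit sets with controlled per-genus e-value distributions.  Every
generator is a pure function of (parameters, seed).

Also re-emits the packaged CDS fixture table from an embedded literal, so
the shipped fixture and its loader can be tested against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    BlastHit,
    CdsRecord,
    GeneTree,
    TaxonGroupMap,
    TreeNode,
    write_cds_table,
)
from .lgt_classify import LgtCall

__all__ = [
    "SimScenario",
    "simulate_gene_tree",
    "evolve_alignment",
    "simulate_blast_hits",
    "table1_records",
    "write_table1_fixture",
    "random_tree",
]

QUERY_LABEL = "QUERY"


@dataclass(frozen=True)
class SimScenario:
    """Parameters for one synthetic gene-tree / alignment draw."""

    groups: tuple[str, ...] = ("cluster_IV", "cluster_XIVa", "other")
    clade_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"cluster_IV": 4, "cluster_XIVa": 4, "other": 3}
    )
    focal_group: str = "cluster_IV"
    event: str = "none"  # "none" | "transfer"
    donor: str | None = None
    support_regime: str = "pass"  # "pass": U(80,100); "fail": U(0,60)
    kappa: float = 2.0  # transition/transversion rate ratio
    seq_length: int = 1000
    branch_range: tuple[float, float] = (0.02, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event not in ("none", "transfer"):
            raise ValueError(f"unknown event {self.event!r}")
        if self.event == "transfer":
            if self.donor is None or self.donor not in self.groups:
                raise ValueError("transfer scenarios need a donor from the vocabulary")
            if self.donor == self.focal_group:
                raise ValueError("donor must differ from the focal group")
        if any(v < 1 for v in self.clade_sizes.values()):
            raise ValueError("clade sizes must be >= 1")
        if self.kappa <= 0 or self.seq_length < 1:
            raise ValueError("rates and sequence length must be positive")
        if self.support_regime not in ("pass", "fail"):
            raise ValueError(f"unknown support regime {self.support_regime!r}")


def _draw_support(rng: np.random.Generator, regime: str) -> float:
    lo, hi = (80.0, 100.0) if regime == "pass" else (0.0, 60.0)
    return float(rng.uniform(lo, hi))


def _random_clade(
    labels: Sequence[str], rng: np.random.Generator, br: tuple[float, float]
) -> TreeNode:
    """Random binary subtree over the given labels via sequential joins."""
    nodes = [TreeNode(label=l, length=float(rng.uniform(*br))) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(*br)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def random_tree(
    n_leaves: int, rng: np.random.Generator, br: tuple[float, float] = (0.02, 0.2)
) -> GeneTree:
    """Random rooted binary tree with branch lengths; leaves t1..tn."""
    root = _random_clade([f"t{i + 1}" for i in range(n_leaves)], rng, br)
    root.length = None
    return GeneTree(root, rooted=True)


def simulate_gene_tree(
    sc: SimScenario,
) -> tuple[GeneTree, LgtCall, TaxonGroupMap]:
    """Rooted, support-labelled gene tree with a planted (or absent) transfer.

    For ``transfer`` events the query leaf is grafted as sister to one leaf
    inside a pure donor-group clade (clade size >= 2 recommended so the
    direction is recoverable); the truth record is an lgt call naming the
    donor.  For ``none`` the query sits inside its focal-group clade and the
    truth is no_lgt.  Internal-node supports are drawn from the scenario's
    support regime; the root carries none.
    """
    rng = np.random.default_rng(sc.seed)
    br = sc.branch_range

    clades: dict[str, TreeNode] = {}
    entries: dict[str, tuple[str, str]] = {}
    for group in sc.groups:
        size = sc.clade_sizes.get(group, 0)
        if size < 1:
            continue
        labels = [f"{group}_{i + 1}" for i in range(size)]
        for l in labels:
            entries[l] = (l, group)  # each leaf its own species
        clades[group] = _random_clade(labels, rng, br)

    host_group = sc.donor if sc.event == "transfer" else sc.focal_group
    if host_group not in clades:
        raise ValueError(f"group {host_group!r} has no clade to graft into")
    host_clade = clades[host_group]
    host_leaves = host_clade.leaves()
    target = host_leaves[int(rng.integers(len(host_leaves)))]

    query = TreeNode(label=QUERY_LABEL, length=float(rng.uniform(*br)))
    graft = TreeNode(length=target.length)
    if target.parent is not None:
        parent = target.parent
        idx = parent.children.index(target)
        parent.children[idx] = graft
        graft.parent = parent
    else:
        clades[host_group] = graft
    target.length = float(rng.uniform(*br))
    graft.add_child(query)
    graft.add_child(target)
    entries[QUERY_LABEL] = (QUERY_LABEL, sc.focal_group)

    root = TreeNode()
    for group in sc.groups:
        if group in clades:
            node = clades[group]
            if node.length is None:
                node.length = float(rng.uniform(*br))
            root.add_child(node)
    for node in root.postorder():
        if not node.is_leaf and not node.is_root:
            node.support = _draw_support(rng, sc.support_regime)
    tree = GeneTree(root, rooted=True)
    tree.validate()

    gmap = TaxonGroupMap(
        entries=entries, vocabulary=tuple(sc.groups), focal_group=sc.focal_group
    )
    if sc.event == "transfer":
        if sc.support_regime == "pass":
            truth = LgtCall(
                gene_id=QUERY_LABEL,
                status="lgt",
                donor=sc.donor,
                direction=f"from {sc.donor} to {sc.focal_group}",
                method="truth",
            )
        else:
            truth = LgtCall(gene_id=QUERY_LABEL, status="unresolved", method="truth")
    else:
        status = "no_lgt" if sc.support_regime == "pass" else "unresolved"
        truth = LgtCall(gene_id=QUERY_LABEL, status=status, method="truth")
    return tree, truth, gmap


# ---------------------------------------------------------------------------
# Sequence evolution under the two-parameter process
# ---------------------------------------------------------------------------

_NUC = np.array(list("ACGT"))
# index of the transition partner (A<->G, C<->T) and the two transversions
_TS = np.array([2, 3, 0, 1])
_TV1 = np.array([1, 0, 1, 0])
_TV2 = np.array([3, 2, 3, 2])


def _k2p_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after branch length d."""
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e4b = math.exp(-4.0 * beta_t)
    e2ab = math.exp(-2.0 * (alpha_t + beta_t))
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.25 - 0.25 * e4b
    return p_ts, p_tv


def evolve_alignment(
    tree: GeneTree, sc: SimScenario
) -> list[tuple[str, str]]:
    """Evolve site-independent sequences down the tree (K2P process).

    Returns (leaf name, sequence) pairs in leaf order.  Every edge must have
    a branch length.  Deterministic for a fixed scenario seed.
    """
    rng = np.random.default_rng(sc.seed)
    L = sc.seq_length
    states: dict[TreeNode, np.ndarray] = {
        tree.root: rng.integers(0, 4, size=L)
    }
    out: list[tuple[str, str]] = []
    for node in tree.preorder():
        if node.is_root:
            continue
        if node.length is None:
            raise ValueError("evolve_alignment requires branch lengths on all edges")
        p_ts, p_tv = _k2p_probs(node.length, sc.kappa)
        parent_state = states[node.parent]
        u = rng.random(L)
        child = parent_state.copy()
        ts_mask = u < p_ts
        tv1_mask = (u >= p_ts) & (u < p_ts + p_tv)
        tv2_mask = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
        child[ts_mask] = _TS[parent_state[ts_mask]]
        child[tv1_mask] = _TV1[parent_state[tv1_mask]]
        child[tv2_mask] = _TV2[parent_state[tv2_mask]]
        states[node] = child
        if node.is_leaf:
            out.append((node.label, "".join(_NUC[child])))
    return out


# ---------------------------------------------------------------------------
# BLAST hit simulation
# ---------------------------------------------------------------------------


def simulate_blast_hits(
    genus_spec: Mapping[str, tuple[int, tuple[float, float]]],
    seed: int = 0,
    query_prefix: str = "gene",
) -> list[BlastHit]:
    """Hits with exact per-genus counts and controlled e-value magnitudes.

    ``genus_spec`` maps genus -> (hit count, (log10_lo, log10_hi)); each
    hit's e-value is 10**U(log10_lo, log10_hi).  Totals are exact and the
    draw is seeded.
    """
    rng = np.random.default_rng(seed)
    hits: list[BlastHit] = []
    for genus in sorted(genus_spec):
        count, (lo, hi) = genus_spec[genus]
        exponents = rng.uniform(lo, hi, size=count)
        for k, e in enumerate(exponents):
            hits.append(
                BlastHit(
                    query=f"{query_prefix}{k + 1}",
                    subject=f"{genus}_subj{k + 1}",
                    evalue=float(10.0 ** e),
                    identity=float(rng.uniform(30, 100)),
                    species=f"{genus} sp.",
                    genus=genus,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Embedded CDS fixture table
# ---------------------------------------------------------------------------

_D_XIVA = "from cluster_XIVa to cluster_IV"

# fosmid, cds, start, end, strand, gc, function, class, mobile,
# nj, ml, direction, species, accession, evalue, identity, focal
_TABLE1 = [
    ("7-14", 1, 18, 920, "+", 53.0, "Transposase for insertion sequence element ISRM5", "protein_coding", 1, "no", "no", "", "Pseudoflavonifractor capillosus", "ZP_02038860", 2e-136, 92, 1),
    ("7-14", 2, 1459, 1929, "-", 35.6, "Teicoplanin resistance protein vanZ", "protein_coding", 0, "novel", "novel", "", "Geobacillus thermodenitrificans", "YP_001124564", 7e-06, 31, 0),
    ("7-14", 3, 2346, 3584, "-", 50.8, "Putative transposase", "protein_coding", 1, "lgt", "lgt", _D_XIVA, "Coprococcus eutactus", "ZP_02205788", 2e-167, 69, 0),
    ("7-14", 4, 4214, 5032, "-", 43.8, "Hypothetical protein", "protein_coding", 0, "novel", "novel", "", "Anaerostipes caccae", "ZP_02418355", 1e-03, 39, 0),
    ("7-14", 5, 6252, 6962, "-", 51.9, "Outer membrane lipoprotein-sorting protein", "protein_coding", 0, "novel", "novel", "", "Caldicellulosiruptor saccharolyticus", "YP_001179297", 8e-06, 31, 0),
    ("7-14", 6, 6959, 7480, "-", 47.3, "RNA polymerase sigma-54 factor rpoN", "protein_coding", 0, "unresolved", "unresolved", "", "Alkaliphilus oremlandii", "YP_001512203", 1e-28, 40, 0),
    ("7-14", 7, 7745, 7820, "none", 63.2, "tRNA-Pro (TGG)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-14", 8, 8265, 10187, "-", 57.9, "Large exoproteins involved in heme utilization or adhesion", "protein_coding", 0, "unresolved", "unresolved", "", "Herpetosiphon aurantiacus", "YP_001545021", 2e-58, 35, 0),
    ("7-14", 9, 10188, 10862, "-", 55.4, "Hypothetical protein", "protein_coding", 0, "unresolved", "unresolved", "", "Anaerotruncus colihominis", "ZP_02440985", 3e-38, 56, 1),
    ("7-14", 10, 10855, 11580, "-", 54.4, "Hypothetical protein", "protein_coding", 0, "lgt", "lgt", "unresolved", "Desulfitobacterium hafniense", "YP_517449", 7e-67, 56, 0),
    ("7-14", 11, 11732, 12193, "-", 52.8, "Iron-sulfur cluster regulator IscR", "protein_coding", 0, "unresolved", "no", "", "Anaerotruncus colihominis", "ZP_02443971", 2e-44, 65, 1),
    ("7-14", 12, 12428, 13360, "+", 59.1, "Cysteine synthase", "protein_coding", 0, "unresolved", "unresolved", "", "Faecalibacterium prausnitzii", "ZP_02090920", 4e-123, 83, 1),
    ("7-14", 13, 13706, 13840, "-", 46.7, "Sodium/glutamate symporter", "protein_coding", 0, "unresolved", "unresolved", "", "Eubacterium siraeum", "ZP_02423775", 5e-12, 80, 1),
    ("7-14", 14, 13795, 14877, "-", 56.7, "Sodium/glutamate symporter", "protein_coding", 0, "unresolved", "unresolved", "", "Eubacterium siraeum", "ZP_02423775", 7e-134, 73, 1),
    ("7-14", 15, 14895, 15938, "-", 61.3, "Immunogenic protein", "protein_coding", 0, "unresolved", "unresolved", "", "Coprococcus eutactus", "ZP_02205701", 6e-61, 44, 0),
    ("7-14", 16, 16214, 17023, "-", 57.9, "8-oxoguanine-DNA-glycosylase", "protein_coding", 0, "lgt", "lgt", _D_XIVA, "Ruminococcus torques", "ZP_01966859", 9e-55, 43, 0),
    ("7-14", 17, 17025, 18026, "-", 57.6, "L-asparaginase", "protein_coding", 0, "unresolved", "unresolved", "", "Clostridium bolteae", "ZP_02087774", 7e-103, 54, 0),
    ("7-14", 18, 18036, 19133, "-", 62.6, "Exonuclease SbcD", "protein_coding", 0, "no", "no", "", "Pseudoflavonifractor capillosus", "ZP_02034908", 3e-98, 55, 1),
    ("7-14", 19, 19130, 19684, "-", 56.8, "EBSC protein", "protein_coding", 0, "unresolved", "unresolved", "", "Clostridium leptum", "ZP_02078782", 2e-54, 68, 1),
    ("7-14", 20, 19651, 20424, "-", 55.9, "Phosphoesterase family protein", "protein_coding", 0, "no", "no", "", "Pseudoflavonifractor capillosus", "ZP_02034909", 4e-87, 61, 1),
    ("7-14", 21, 21133, 21414, "-", 50.7, "Hypothetical protein", "protein_coding", 0, "unresolved", "unresolved", "", "Eubacterium siraeum", "ZP_02423392", 2e-08, 35, 1),
    ("7-14", 22, 22289, 23032, "+", 54.6, "Transposase for insertion sequence element ISRM5", "protein_coding", 1, "no", "no", "", "Pseudoflavonifractor capillosus", "ZP_02038860", 1e-110, 87, 1),
    ("7-14", 23, 23434, 23508, "none", 58.7, "tRNA-Glu (CTC)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-14", 24, 23684, 23759, "none", 52.6, "tRNA-Lys (CTT)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-14", 25, 23856, 26709, "none", 52.5, "23S rRNA gene", "rRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-14", 26, 27033, 27109, "none", 63.6, "tRNA-Ile (GAT)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-14", 27, 27121, 27196, "none", 53.9, "tRNA-Ala (TGC)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-14", 28, 27324, 28847, "none", 53.5, "16S rRNA gene", "rRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-14", 29, 29448, 30365, "-", 57.4, "Germination and sporulation", "protein_coding", 0, "lgt", "no", _D_XIVA, "Pseudoflavonifractor capillosus", "ZP_02038021", 1e-25, 38, 1),
    ("7-14", 30, 30362, 31768, "-", 60.5, "Osmosensitive K+ channel histidine kinase kdpD", "protein_coding", 0, "no", "no", "", "Pseudoflavonifractor capillosus", "ZP_02038022", 1e-120, 52, 1),
    ("7-14", 31, 31788, 32465, "-", 55.8, "Two-component response regulator SA14-24", "protein_coding", 0, "no", "no", "", "Pseudoflavonifractor capillosus", "ZP_02036840", 7e-86, 76, 1),
    ("7-14", 32, 32486, 32854, "-", 55.3, "Late competence protein comEA, DNA receptor", "protein_coding", 0, "unresolved", "unresolved", "", "Cand. Desulforudis audaxviator", "YP_001718193", 3e-15, 58, 0),
    ("7-14", 33, 33191, 34558, "+", 57.1, "D-alanyl-D-alanine carboxypeptidase", "protein_coding", 0, "no", "no", "", "Pseudoflavonifractor capillosus", "ZP_02036838", 3e-07, 47, 1),
    ("7-14", 34, 34607, 35155, "-", 59.7, "Nitroreductase family protein", "protein_coding", 0, "unresolved", "lgt", _D_XIVA, "Clostridium kluyveri", "YP_001393744", 9e-36, 50, 0),
    ("7-25", 1, 1, 794, "+", 51.5, "Integrase", "protein_coding", 1, "lgt", "lgt", _D_XIVA, "Clostridium bolteae", "ZP_02083674", 6e-90, 62, 0),
    ("7-25", 2, 910, 2469, "-", 57.8, "GMP synthase [glutamine-hydrolyzing]", "protein_coding", 0, "no", "no", "", "Pseudoflavonifractor capillosus", "ZP_02035344", 0.0, 82, 1),
    ("7-25", 3, 2447, 2962, "-", 56.2, "Xanthine phosphoribosyltransferase", "protein_coding", 0, "unresolved", "unresolved", "", "Coprococcus eutactus", "ZP_02207218", 3e-43, 54, 0),
    ("7-25", 4, 3418, 4239, "-", 60.5, "Nucleotide-binding protein", "protein_coding", 0, "no", "no", "", "Eubacterium siraeum", "ZP_02421312", 4e-91, 64, 1),
    ("7-25", 5, 4308, 6572, "-", 61.3, "Chromosome partition protein smc", "protein_coding", 0, "no", "no", "", "Pseudoflavonifractor capillosus", "ZP_02034907", 6e-103, 35, 1),
    ("7-25", 6, 7160, 8682, "none", 53.6, "16S rRNA gene", "rRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-25", 7, 8810, 8885, "none", 55.3, "tRNA-Ala (TGC)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-25", 8, 8897, 8973, "none", 64.9, "tRNA-Ile (GAT)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-25", 9, 9297, 12150, "none", 52.5, "23S rRNA gene", "rRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-25", 10, 12247, 12322, "none", 53.9, "tRNA-Lys (CTT)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-25", 11, 12498, 12572, "none", 58.7, "tRNA-Glu (CTC)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-25", 12, 12864, 12939, "none", 57.9, "tRNA-Asn (GTT)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-25", 13, 12994, 13070, "none", 61.0, "tRNA-Met (CAT)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-25", 14, 13108, 13183, "none", 59.2, "tRNA-Trp (CCA)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-25", 15, 13246, 13322, "none", 62.3, "tRNA-Asp (GTC)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-25", 16, 13328, 13403, "none", 59.2, "tRNA-Thr (GGT)", "tRNA", 0, "na", "na", "", "", "", None, None, 0),
    ("7-25", 17, 13613, 14674, "+", 54.3, "Transposase for insertion sequence element ISRM5", "protein_coding", 1, "no", "no", "", "Pseudoflavonifractor capillosus", "ZP_02038860", 4e-131, 89, 1),
    ("7-25", 18, 15027, 15791, "+", 40.4, "Unknown", "protein_coding", 0, "unresolved", "no", "", "Bacteroides thetaiotaomicron", "NP_810500", 1e-117, 78, 0),
    ("7-25", 19, 15913, 17193, "+", 55.2, "Hypothetical protein", "protein_coding", 0, "unresolved", "unresolved", "", "Eubacterium siraeum", "ZP_02421339", 4e-86, 44, 1),
    ("7-25", 20, 17144, 18088, "+", 56.9, "Hypothetical protein", "protein_coding", 0, "unresolved", "unresolved", "", "Eubacterium ventriosum", "ZP_02027484", 5e-66, 43, 0),
    ("7-25", 21, 18370, 19662, "+", 58.0, "Putative stomatin/prohibitin-family membrane protease subunit", "protein_coding", 0, "lgt", "lgt", "unresolved", "Clostridium acetobutylicum", "NP_349972", 2e-92, 48, 0),
    ("7-25", 22, 19560, 20867, "+", 57.0, "Protein RtcB", "protein_coding", 0, "no", "no", "", "Pseudoflavonifractor capillosus", "ZP_02038919", 2e-154, 69, 1),
    ("7-25", 23, 20864, 21208, "+", 55.1, "Predicted nucleotidyltransferase", "protein_coding", 0, "unresolved", "unresolved", "", "Escherichia coli", "ZP_03048733", 5e-16, 59, 0),
    ("7-25", 24, 22686, 23951, "+", 53.7, "Hypothetical lipoprotein", "protein_coding", 0, "lgt", "lgt", _D_XIVA, "Clostridium bolteae", "ZP_02087827", 0.0, 82, 0),
    ("7-25", 25, 24010, 25620, "+", 48.6, "ABC-type sugar transport system, ATP-binding protein", "protein_coding", 0, "lgt", "lgt", _D_XIVA, "Clostridium bolteae", "ZP_02087828", 0.0, 89, 0),
    ("7-25", 26, 25634, 26713, "+", 54.8, "ABC transporter integral membrane protein", "protein_coding", 0, "lgt", "lgt", _D_XIVA, "Clostridium bolteae", "ZP_02087829", 2e-164, 88, 0),
    ("7-25", 27, 26710, 27834, "+", 54.3, "ABC transporter integral membrane protein", "protein_coding", 0, "lgt", "lgt", _D_XIVA, "Clostridium bolteae", "ZP_02087830", 7e-167, 84, 0),
    ("7-25", 28, 27831, 28319, "+", 54.6, "Hypothetical protein", "protein_coding", 0, "lgt", "lgt", "unresolved", "Clostridium bolteae", "ZP_02087831", 6e-47, 70, 0),
]


def table1_records() -> list[CdsRecord]:
    """The embedded CDS fixture as validated records."""
    out = []
    for row in _TABLE1:
        (fosmid, cds, start, end, strand, gc, fn, fclass, mobile,
         nj, ml, direction, species, acc, evalue, ident, focal) = row
        out.append(
            CdsRecord(
                fosmid=fosmid, cds_index=cds, start=start, end=end,
                strand=strand, gc_percent=gc, function=fn,
                feature_class=fclass, mobile_element=bool(mobile),
                nj_lgt=nj, ml_lgt=ml, direction=direction,
                top_hit_species=species, top_hit_accession=acc,
                top_hit_evalue=evalue, top_hit_identity=ident,
                top_hit_in_focal_group=bool(focal),
            )
        )
    return out


def write_table1_fixture(path: str | Path) -> None:
    """Re-emit the fixture TSV from the embedded literal table."""
    write_cds_table(table1_records(), path)
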