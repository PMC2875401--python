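"""Bootstrap-gated tree-walk LGT classification and Fitch-parsimony
donor/direction inference.

A gene is "novel" when its best database hit is weaker than the e-value
threshold.  Otherwise, starting at the query leaf, the classifier steps back
toward the root until it reaches the first node whose support exceeds the
gate and whose descendants include a sequence from a species other than the
query's (the *decision node*).  The groups of the decision node's
descendants (query excluded) determine the call: only the focal group ->
no LGT; focal and non-focal -> unresolved; only non-focal -> LGT.  For LGT
calls, Fitch parsimony ancestral states determine the donor group and the
direction of transfer when unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import (
    CdsRecord,
    ClassifierConfig,
    GeneTree,
    TaxonGroupMap,
    TreeNode,
)
from .tree_build import root_tree

__all__ = [
    "LgtCall",
    "FitchResult",
    "classify_gene",
    "fitch_states",
    "infer_direction",
    "reconcile_methods",
    "summarize_calls",
    "CallSummary",
]

STATUSES = ("novel", "no_lgt", "unresolved", "lgt")


@dataclass
class LgtCall:
    """Per-gene classification record."""

    gene_id: str
    status: str
    support: float | None = None
    decision_groups: frozenset[str] = frozenset()
    donor: str | None = None
    direction: str = "not_applicable"
    method: str = "nj"
    notes: tuple[str, ...] = ()
    decision_node: TreeNode | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "novel" and (
            self.support is not None or self.decision_groups or self.donor
        ):
            raise ValueError("novel calls carry no tree-derived fields")
        if self.donor is not None and self.status != "lgt":
            raise ValueError("donor group only meaningful for lgt calls")


@dataclass(frozen=True)
class FitchResult:
    """Two-pass Fitch parsimony reconstruction over a finite group alphabet.

    ``state_sets`` holds the bottom-up (first-pass) set per node;
    ``final_states`` the top-down sets, retaining ambiguity rather than
    sampling a single state; ``changes`` is the parsimony minimum (exact on
    binary trees).
    """

    state_sets: dict[TreeNode, frozenset[str]]
    final_states: dict[TreeNode, frozenset[str]]
    changes: int


def fitch_states(
    tree: GeneTree, leaf_groups: Mapping[str, str | frozenset[str]]
) -> FitchResult:
    """Run the two-pass Fitch algorithm on a rooted tree.

    ``leaf_groups`` maps each leaf label to its group (or, exceptionally, a
    set of admissible groups for an uninformative leaf).  Unlabeled leaves
    are an error.
    """
    state: dict[TreeNode, frozenset[str]] = {}
    changes = 0
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in leaf_groups:
                raise ValueError(f"leaf {node.label!r} has no group label")
            g = leaf_groups[node.label]
            state[node] = frozenset([g]) if isinstance(g, str) else frozenset(g)
        else:
            inter = frozenset.intersection(*(state[c] for c in node.children))
            if inter:
                state[node] = inter
            else:
                state[node] = frozenset.union(*(state[c] for c in node.children))
                changes += 1

    final: dict[TreeNode, frozenset[str]] = {}
    for node in tree.preorder():
        if node.is_root:
            final[node] = state[node]
        else:
            narrowed = state[node] & final[node.parent]
            final[node] = narrowed if narrowed else state[node]
    return FitchResult(state_sets=state, final_states=final, changes=changes)


def _resolve_species(groups: TaxonGroupMap, label: str) -> str:
    return groups.species_of(label) if label in groups else label


def classify_gene(
    tree: GeneTree,
    query: str,
    groups: TaxonGroupMap,
    top_evalue: float,
    cfg: ClassifierConfig | None = None,
    method: str = "nj",
) -> LgtCall:
    """Classify one gene as novel / no_lgt / unresolved / lgt.

    ``top_evalue`` is the gene's best database-hit e-value; values strictly
    above ``cfg.evalue_threshold`` short-circuit to "novel".  Unrooted input
    trees are rooted per ``cfg.rooting`` before the walk.  If no node on the
    root path passes the gate the gene is recorded as unresolved with the
    decision-node fields absent.
    """
    cfg = cfg or ClassifierConfig()
    if top_evalue > cfg.evalue_threshold:
        return LgtCall(gene_id=query, status="novel", method=method)

    if not tree.rooted:
        tree = root_tree(tree, cfg.rooting)
    leaf = tree.find_leaf(query)

    query_species = _resolve_species(groups, query)
    for label in tree.leaf_labels():
        if label != query and label not in groups:
            raise ValueError(f"leaf {label!r} not resolvable through the group map")

    node = leaf.parent
    while node is not None:
        passes_gate = (
            node.support is not None
            and not node.is_root
            and node.support > cfg.support_threshold
        )
        if passes_gate:
            others = [l for l in node.leaves() if l is not leaf]
            if any(_resolve_species(groups, l.label) != query_species for l in others):
                g = frozenset(groups.group_of(l.label) for l in others)
                focal = cfg.focal_group
                if g <= {focal}:
                    status = "no_lgt"
                elif focal in g:
                    status = "unresolved"
                else:
                    status = "lgt"
                notes = ()
                if status == "lgt" and node.support < cfg.low_support_tier:
                    notes = ("low_support",)
                return LgtCall(
                    gene_id=query,
                    status=status,
                    support=float(node.support),
                    decision_groups=g,
                    direction="not_applicable",
                    method=method,
                    notes=notes,
                    decision_node=node,
                )
        node = node.parent
    return LgtCall(
        gene_id=query,
        status="unresolved",
        method=method,
        notes=("no_supported_node",),
    )


def infer_direction(
    call: LgtCall,
    tree: GeneTree,
    query: str,
    groups: TaxonGroupMap,
    cfg: ClassifierConfig | None = None,
) -> LgtCall:
    """Fill donor group and transfer direction on an lgt call.

    Fitch parsimony is run with the query labeled as a member of the focal
    group (its host lineage).  The donor is reported only when both the
    decision node's descendant groups and its final ancestral-state set are
    the same non-focal singleton; any ambiguity yields direction
    "unresolved".
    """
    cfg = cfg or ClassifierConfig()
    if call.status != "lgt":
        raise ValueError("infer_direction requires an lgt-status call")
    if call.decision_node is None:
        call.direction = "unresolved"
        return call

    leaf_groups: dict[str, str] = {}
    for label in tree.leaf_labels():
        if label == query:
            leaf_groups[label] = cfg.focal_group
        else:
            leaf_groups[label] = groups.group_of(label)
    fitch = fitch_states(tree, leaf_groups)

    donor: str | None = None
    if len(call.decision_groups) == 1:
        (candidate,) = call.decision_groups
        final = fitch.final_states.get(call.decision_node, frozenset())
        if candidate != cfg.focal_group and final == frozenset([candidate]):
            donor = candidate
    if donor is not None:
        call.donor = donor
        call.direction = f"from {donor} to {cfg.focal_group}"
    else:
        call.direction = "unresolved"
    return call


def classify_and_infer(
    tree: GeneTree,
    query: str,
    groups: TaxonGroupMap,
    top_evalue: float,
    cfg: ClassifierConfig | None = None,
    method: str = "nj",
) -> LgtCall:
    """Convenience: classify, then infer direction for lgt calls."""
    cfg = cfg or ClassifierConfig()
    if not tree.rooted:
        tree = root_tree(tree, cfg.rooting)
    call = classify_gene(tree, query, groups, top_evalue, cfg, method=method)
    if call.status == "lgt":
        call = infer_direction(call, tree, query, groups, cfg)
    return call


def reconcile_methods(
    nj_call: LgtCall, ml_call: LgtCall, policy: str = "conservative"
) -> LgtCall:
    """Combine NJ- and ML-based calls for the same gene.

    The conservative policy calls lgt only when both methods agree on lgt;
    a no_lgt from either method wins over lgt/unresolved; any other
    disagreement is unresolved.  Discordances are recorded in ``notes`` with
    both original statuses retained.
    """
    if nj_call.gene_id != ml_call.gene_id:
        raise ValueError(
            f"gene-id mismatch: {nj_call.gene_id!r} vs {ml_call.gene_id!r}"
        )
    if policy != "conservative":
        raise ValueError(f"unknown reconciliation policy {policy!r}")

    a, b = nj_call, ml_call
    statuses = {a.status, b.status}
    notes: list[str] = []
    if a.status != b.status:
        notes.append(f"discordant:{a.status}|{b.status}")
    for c in (a, b):
        if "low_support" in c.notes:
            notes.append(f"low_support:{c.method}")

    if a.status == b.status:
        status = a.status
    elif "no_lgt" in statuses:
        status = "no_lgt"
    else:
        # lgt vs unresolved/novel, or unresolved vs novel
        status = "unresolved"

    donor = None
    direction = "not_applicable"
    support = None
    groups_union: frozenset[str] = frozenset()
    if status == "lgt":
        donors = {c.donor for c in (a, b) if c.donor is not None}
        if len(donors) == 1:
            donor = donors.pop()
            direction = a.direction if a.donor else b.direction
        else:
            direction = "unresolved"
        supports = [c.support for c in (a, b) if c.support is not None]
        support = max(supports) if supports else None
        groups_union = a.decision_groups | b.decision_groups
    if status == "novel":
        return LgtCall(
            gene_id=a.gene_id, status="novel", method="reconciled",
            notes=tuple(notes),
        )
    return LgtCall(
        gene_id=a.gene_id,
        status=status,
        support=support,
        decision_groups=groups_union,
        donor=donor,
        direction=direction,
        method="reconciled",
        notes=tuple(notes),
    )


@dataclass(frozen=True)
class CallSummary:
    total: int = 0
    lgt: int = 0
    no_lgt: int = 0
    unresolved: int = 0
    novel: int = 0
    direction_resolved: int = 0
    per_donor: tuple[tuple[str, int], ...] = ()
    discordant: int = 0

    def donor_count(self, donor: str) -> int:
        return dict(self.per_donor).get(donor, 0)


def _status_from_record(rec: CdsRecord) -> tuple[str, str]:
    table = {"no": "no_lgt", "novel": "novel", "unresolved": "unresolved", "lgt": "lgt"}
    return table[rec.nj_lgt], table[rec.ml_lgt]


def calls_from_records(records: Iterable[CdsRecord]) -> list[LgtCall]:
    """Reconciled calls for the protein-coding rows of a CDS table."""
    out: list[LgtCall] = []
    for rec in records:
        if not rec.is_coding:
            continue
        nj_status, ml_status = _status_from_record(rec)
        gene = f"{rec.fosmid}:{rec.cds_index}"

        def one(status: str, tag: str) -> LgtCall:
            donor = None
            direction = "not_applicable"
            if status == "lgt":
                if rec.direction.startswith("from "):
                    donor = rec.direction.split()[1]
                    direction = rec.direction
                else:
                    direction = "unresolved"
            return LgtCall(gene_id=gene, status=status, donor=donor,
                           direction=direction, method=tag)

        out.append(reconcile_methods(one(nj_status, "nj"), one(ml_status, "ml")))
    return out


def summarize_calls(
    items: Sequence[LgtCall] | Sequence[CdsRecord],
) -> CallSummary:
    """Count statuses, resolved directions and per-donor totals.

    Accepts either reconciled :class:`LgtCall` objects or CDS fixture
    records (which are reconciled on the fly, coding rows only).
    """
    if not items:
        return CallSummary()
    if isinstance(items[0], CdsRecord):
        calls = calls_from_records(items)  # type: ignore[arg-type]
    else:
        calls = list(items)  # type: ignore[assignment]

    donors: dict[str, int] = {}
    counts = {"lgt": 0, "no_lgt": 0, "unresolved": 0, "novel": 0}
    resolved = 0
    discordant = 0
    for c in calls:
        counts[c.status] += 1
        if c.status == "lgt" and c.donor is not None:
            resolved += 1
            donors[c.donor] = donors.get(c.donor, 0) + 1
        if any(n.startswith("discordant:") for n in c.notes):
            discordant += 1
    return CallSummary(
        total=len(calls),
        lgt=counts["lgt"],
        no_lgt=counts["no_lgt"],
        unresolved=counts["unresolved"],
        novel=counts["novel"],
        direction_resolved=resolved,
        per_donor=tuple(sorted(donors.items())),
        discordant=discordant,
    )
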