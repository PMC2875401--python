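"""Domain types and readers/writers for every format the pipeline touches.

Covers the gene-tree container (with per-node bootstrap supports), the
taxon-to-group map, the classifier configuration, the packaged CDS fixture
table, and tabular BLAST hits.  All tabular writers emit UTF-8 TSV with a
single ``#``-prefixed header line.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "TreeNode",
    "GeneTree",
    "TaxonGroupMap",
    "ClassifierConfig",
    "CdsRecord",
    "BlastHit",
    "NewickParseError",
    "TreeValidationError",
    "FixtureIntegrityError",
    "read_newick",
    "write_newick",
    "read_group_map",
    "write_group_map",
    "load_table1_fixture",
    "read_cds_table",
    "write_cds_table",
    "read_blast_hits",
    "write_blast_hits",
    "read_fasta",
    "write_fasta",
    "to_zero_based_half_open",
    "from_zero_based_half_open",
]


class NewickParseError(ValueError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character offset {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    pass


class FixtureIntegrityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tree container
# ---------------------------------------------------------------------------


class TreeNode:
    """A node in a :class:`GeneTree`.

    ``label`` is the taxon name on leaves (and any non-numeric annotation on
    internal nodes); ``support`` is a bootstrap-style value in [0, 100] kept
    only on internal non-root nodes; ``length`` is the branch length to the
    parent in substitutions/site.
    """

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        support: float | None = None,
    ):
        self.label = label
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    # -- structure ----------------------------------------------------------

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "TreeNode") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def ancestors(self) -> Iterator["TreeNode"]:
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def copy(self) -> "TreeNode":
        clone = TreeNode(self.label, self.length, self.support)
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {kind} label={self.label!r} len={self.length} sup={self.support}>"


class GeneTree:
    """Phylogeny with optional per-node supports and a rooted/unrooted marker."""

    def __init__(self, root: TreeNode, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    # convenience delegations
    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return self.root.leaf_labels()

    def find_leaf(self, label: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(f"leaf {label!r} not found in tree")

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy(), rooted=self.rooted)

    def validate(self) -> None:
        labels = self.leaf_labels()
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise TreeValidationError(
                f"duplicate leaf labels: {', '.join(sorted(dupes))}"
            )
        for node in self.postorder():
            if not node.is_leaf and len(node.children) < 2:
                raise TreeValidationError("internal node with a single child")

    def bipartitions(self, nontrivial_only: bool = True) -> set[frozenset[frozenset[str]]]:
        """Unrooted bipartitions as unordered {side, complement} pairs."""
        all_leaves = frozenset(self.leaf_labels())
        out: set[frozenset[frozenset[str]]] = set()
        for node in self.postorder():
            if node.is_root:
                continue
            side = frozenset(node.leaf_labels())
            other = all_leaves - side
            if nontrivial_only and (len(side) < 2 or len(other) < 2):
                continue
            out.add(frozenset({side, other}))
        return out

    def __repr__(self) -> str:  # pragma: no cover
        state = "rooted" if self.rooted else "unrooted"
        return f"<GeneTree {state}, {len(self.leaves())} leaves>"


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_UNQUOTED_DISALLOWED = set("()[]{}:;,'\t\n\r ")


def _parse_label(text: str, pos: int) -> tuple[str, int]:
    if pos < len(text) and text[pos] == "'":
        end = pos + 1
        chunks: list[str] = []
        while True:
            if end >= len(text):
                raise NewickParseError("unterminated quoted label", pos)
            if text[end] == "'":
                if end + 1 < len(text) and text[end + 1] == "'":
                    chunks.append("'")
                    end += 2
                    continue
                break
            chunks.append(text[end])
            end += 1
        return "".join(chunks), end + 1
    end = pos
    while end < len(text) and text[end] not in _UNQUOTED_DISALLOWED:
        end += 1
    return text[pos:end], end


def read_newick(text: str, supports_in_comments: bool = False) -> GeneTree:
    """Parse a Newick string into a :class:`GeneTree`.

    Numeric internal-node labels are interpreted as bootstrap supports (the
    dominant dialect).  With ``supports_in_comments`` set, supports are read
    from ``[...]`` comments after the branch length instead, as some tools
    emit.

    Raises :class:`NewickParseError` (naming the character offset) on
    malformed input and :class:`TreeValidationError` on duplicate leaf
    labels.
    """
    s = text.strip()
    if not s:
        raise NewickParseError("empty Newick string", 0)
    pos = 0

    def parse_clade() -> tuple[TreeNode, None]:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            open_at = pos
            pos += 1
            while True:
                child, _ = parse_clade()
                node.add_child(child)
                if pos >= len(s):
                    raise NewickParseError("unbalanced parentheses", open_at)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickParseError(f"unexpected character {s[pos]!r}", pos)
        label, pos = _parse_label(s, pos)
        if label:
            node.label = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.match(r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?", s[pos:])
            if not m:
                raise NewickParseError("expected branch length after ':'", pos)
            node.length = float(m.group(0))
            pos += m.end()
        if pos < len(s) and s[pos] == "[":
            close = s.find("]", pos)
            if close == -1:
                raise NewickParseError("unterminated comment", pos)
            comment = s[pos + 1 : close]
            pos = close + 1
            if supports_in_comments:
                try:
                    node.support = float(comment)
                except ValueError:
                    pass
        return node, None

    root, _ = parse_clade()
    if pos >= len(s) or s[pos] != ";":
        raise NewickParseError("expected ';' terminating the tree", pos)
    if pos + 1 != len(s):
        raise NewickParseError("trailing characters after ';'", pos + 1)

    # Reinterpret numeric internal labels as supports (not on the root).
    if not supports_in_comments:
        for node in root.postorder():
            if node.is_leaf or node.is_root or node.label is None:
                continue
            try:
                node.support = float(node.label)
            except ValueError:
                continue
            node.label = None
    tree = GeneTree(root, rooted=len(root.children) == 2)
    tree.validate()
    return tree


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(x, ".12g")


def _quote_label(label: str) -> str:
    if any(c in _UNQUOTED_DISALLOWED for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: GeneTree) -> str:
    """Serialize; supports emitted as internal-node labels (round-trip safe)."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            out = _quote_label(node.label or "")
        else:
            out = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None and not node.is_root:
                out += _fmt_num(node.support)
            elif node.label:
                out += _quote_label(node.label)
        if node.length is not None:
            out += ":" + _fmt_num(node.length)
        return out

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Taxon group map
# ---------------------------------------------------------------------------

DEFAULT_FOCAL_GROUP = "cluster_IV"


@dataclass
class TaxonGroupMap:
    """Maps taxon identifiers to (species name, clade-group label)."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    vocabulary: tuple[str, ...] = ()
    focal_group: str = DEFAULT_FOCAL_GROUP

    def __post_init__(self) -> None:
        if not self.vocabulary:
            groups = {g for _, g in self.entries.values()}
            groups.add(self.focal_group)
            self.vocabulary = tuple(sorted(groups))
        if self.focal_group not in self.vocabulary:
            raise ValueError(
                f"focal group {self.focal_group!r} missing from vocabulary"
            )
        for taxon, (_, group) in self.entries.items():
            if group not in self.vocabulary:
                raise ValueError(
                    f"taxon {taxon!r} assigned to undeclared group {group!r}"
                )

    def group_of(self, taxon: str) -> str:
        return self.entries[taxon][1]

    def species_of(self, taxon: str) -> str:
        return self.entries[taxon][0]

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def read_group_map(
    path: str | Path, focal_group: str = DEFAULT_FOCAL_GROUP
) -> TaxonGroupMap:
    """Read a two-or-three-column TSV (taxon[, species], group).

    An optional ``# groups: a,b,c`` header line declares the allowed group
    vocabulary; otherwise the vocabulary is inferred from the file.
    Duplicate taxa are an error (the offending taxon is named).
    """
    entries: dict[str, tuple[str, str]] = {}
    declared: tuple[str, ...] = ()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*groups\s*:\s*(.+)", line)
            if m:
                declared = tuple(g.strip() for g in m.group(1).split(","))
            continue
        cols = line.split("\t")
        if len(cols) == 2:
            taxon, species, group = cols[0], cols[0], cols[1]
        elif len(cols) >= 3:
            taxon, species, group = cols[0], cols[1], cols[2]
        else:
            raise ValueError(f"group map line has {len(cols)} column(s): {line!r}")
        if taxon in entries:
            raise ValueError(f"duplicate taxon in group map: {taxon!r}")
        if declared and group not in declared:
            raise ValueError(
                f"group {group!r} for taxon {taxon!r} not in declared vocabulary"
            )
        entries[taxon] = (species, group)
    vocab = declared
    if vocab and focal_group not in vocab:
        vocab = vocab + (focal_group,)
    return TaxonGroupMap(entries=entries, vocabulary=vocab, focal_group=focal_group)


def write_group_map(gmap: TaxonGroupMap, path: str | Path) -> None:
    lines = ["# groups: " + ",".join(gmap.vocabulary)]
    for taxon, (species, group) in gmap.entries.items():
        lines.append(f"{taxon}\t{species}\t{group}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Classifier configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and policies for the tree-walk LGT classifier.

    ``evalue_threshold``: genes with best-hit e-value strictly above this are
    "novel".  ``support_threshold``: the walk stops at the first node with
    support strictly greater than this.  ``rooting`` is one of ``as-given``,
    ``midpoint`` or ``outgroup:<taxon>``.
    """

    evalue_threshold: float = 1e-6
    support_threshold: float = 60.0
    focal_group: str = DEFAULT_FOCAL_GROUP
    rooting: str = "midpoint"
    low_support_tier: float = 70.0  # report-only flag, not a gate

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if not (0 <= self.support_threshold <= 100):
            raise ValueError("support_threshold must be in [0, 100]")


# ---------------------------------------------------------------------------
# CDS fixture records
# ---------------------------------------------------------------------------

LGT_STATUSES = ("no", "novel", "unresolved", "lgt", "na")
FEATURE_CLASSES = ("protein_coding", "tRNA", "rRNA")
STRANDS = ("+", "-", "none")


@dataclass(frozen=True)
class CdsRecord:
    """One fixture row: a CDS/RNA feature with its LGT assessments."""

    fosmid: str
    cds_index: int
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    gc_percent: float
    function: str
    feature_class: str
    mobile_element: bool
    nj_lgt: str
    ml_lgt: str
    direction: str  # e.g. "from cluster_XIVa to cluster_IV", "unresolved", ""
    top_hit_species: str
    top_hit_accession: str
    top_hit_evalue: float | None
    top_hit_identity: float | None
    top_hit_in_focal_group: bool

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise FixtureIntegrityError(
                f"{self.fosmid} CDS {self.cds_index}: start must be < end"
            )
        if not (0 <= self.gc_percent <= 100):
            raise FixtureIntegrityError(
                f"{self.fosmid} CDS {self.cds_index}: GC percent out of range"
            )
        if self.strand not in STRANDS:
            raise FixtureIntegrityError(f"bad strand {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise FixtureIntegrityError(f"bad feature class {self.feature_class!r}")
        for val in (self.nj_lgt, self.ml_lgt):
            if val not in LGT_STATUSES:
                raise FixtureIntegrityError(f"bad LGT status {val!r}")
        if self.feature_class in ("tRNA", "rRNA"):
            if self.nj_lgt != "na" or self.ml_lgt != "na":
                raise FixtureIntegrityError(
                    f"{self.fosmid} CDS {self.cds_index}: RNA features must have"
                    " 'na' LGT assessments"
                )

    @property
    def is_coding(self) -> bool:
        return self.feature_class == "protein_coding"


def to_zero_based_half_open(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive coordinates -> 0-based half-open."""
    return start - 1, end


def from_zero_based_half_open(start: int, end: int) -> tuple[int, int]:
    return start + 1, end


_CDS_COLUMNS = [
    "fosmid",
    "cds_index",
    "start",
    "end",
    "strand",
    "gc_percent",
    "function",
    "feature_class",
    "mobile_element",
    "nj_lgt",
    "ml_lgt",
    "direction",
    "top_hit_species",
    "top_hit_accession",
    "top_hit_evalue",
    "top_hit_identity",
    "top_hit_in_focal_group",
]


def _parse_cds_row(cols: Mapping[str, str]) -> CdsRecord:
    def opt_float(x: str) -> float | None:
        return float(x) if x not in ("", "na") else None

    return CdsRecord(
        fosmid=cols["fosmid"],
        cds_index=int(cols["cds_index"]),
        start=int(cols["start"]),
        end=int(cols["end"]),
        strand=cols["strand"],
        gc_percent=float(cols["gc_percent"]),
        function=cols["function"],
        feature_class=cols["feature_class"],
        mobile_element=cols["mobile_element"] == "1",
        nj_lgt=cols["nj_lgt"],
        ml_lgt=cols["ml_lgt"],
        direction=cols["direction"],
        top_hit_species=cols["top_hit_species"],
        top_hit_accession=cols["top_hit_accession"],
        top_hit_evalue=opt_float(cols["top_hit_evalue"]),
        top_hit_identity=opt_float(cols["top_hit_identity"]),
        top_hit_in_focal_group=cols["top_hit_in_focal_group"] == "1",
    )


def read_cds_table(source: str | Path | io.TextIOBase) -> list[CdsRecord]:
    """Read a CDS table TSV (no integrity constraints beyond row validity)."""
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].lstrip("#").strip().split("\t")
    if header != _CDS_COLUMNS:
        raise FixtureIntegrityError(
            f"unexpected CDS table header: {header[:3]}..."
        )
    records = []
    for ln in lines[1:]:
        cols = ln.split("\t")
        if len(cols) != len(_CDS_COLUMNS):
            raise FixtureIntegrityError(
                f"CDS row has {len(cols)} columns, expected {len(_CDS_COLUMNS)}"
            )
        records.append(_parse_cds_row(dict(zip(_CDS_COLUMNS, cols))))
    return records


def write_cds_table(records: Sequence[CdsRecord], path: str | Path) -> None:
    def fmt(rec: CdsRecord) -> str:
        return "\t".join(
            [
                rec.fosmid,
                str(rec.cds_index),
                str(rec.start),
                str(rec.end),
                rec.strand,
                format(rec.gc_percent, ".1f"),
                rec.function,
                rec.feature_class,
                "1" if rec.mobile_element else "0",
                rec.nj_lgt,
                rec.ml_lgt,
                rec.direction,
                rec.top_hit_species,
                rec.top_hit_accession,
                "" if rec.top_hit_evalue is None else format(rec.top_hit_evalue, ".2e"),
                "" if rec.top_hit_identity is None else _fmt_num(rec.top_hit_identity),
                "1" if rec.top_hit_in_focal_group else "0",
            ]
        )

    lines = ["#" + "\t".join(_CDS_COLUMNS)] + [fmt(r) for r in records]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_EXPECTED_FIXTURE_SHAPE = {
    "total": 62,
    "protein_coding": 44,
    "rRNA": 4,
    "tRNA": 14,
    "per_fosmid": {"7-14": 34, "7-25": 28},
}


def load_table1_fixture(path: str | Path | None = None) -> list[CdsRecord]:
    """Load the packaged CDS fixture (or a user-supplied copy) and verify its
    frozen shape: 62 rows (34 + 28), 44 protein-coding, 2x16S + 2x23S + 14 tRNA.
    """
    if path is None:
        ref = resources.files("lgtree").joinpath("data/table1.tsv")
        records = read_cds_table(io.StringIO(ref.read_text(encoding="utf-8")))
    else:
        records = read_cds_table(path)

    shape = _EXPECTED_FIXTURE_SHAPE
    if len(records) != shape["total"]:
        raise FixtureIntegrityError(
            f"fixture has {len(records)} rows, expected {shape['total']}"
        )
    by_class: dict[str, int] = {}
    by_fosmid: dict[str, int] = {}
    for rec in records:
        by_class[rec.feature_class] = by_class.get(rec.feature_class, 0) + 1
        by_fosmid[rec.fosmid] = by_fosmid.get(rec.fosmid, 0) + 1
    if by_class.get("protein_coding") != shape["protein_coding"]:
        raise FixtureIntegrityError(
            f"fixture has {by_class.get('protein_coding')} coding rows,"
            f" expected {shape['protein_coding']}"
        )
    if by_class.get("rRNA") != shape["rRNA"] or by_class.get("tRNA") != shape["tRNA"]:
        raise FixtureIntegrityError("fixture RNA feature counts are wrong")
    if by_fosmid != shape["per_fosmid"]:
        raise FixtureIntegrityError(f"fixture per-fosmid counts wrong: {by_fosmid}")
    return records


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(name, sequence) pairs from a FASTA file (names cut at first space)."""
    from Bio import SeqIO

    return [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# BLAST hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlastHit:
    """One tabular BLAST hit with appended taxonomy."""

    query: str
    subject: str
    evalue: float
    identity: float = 0.0
    bitscore: float | None = None
    species: str = ""
    genus: str = ""

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


def read_blast_hits(path: str | Path) -> list[BlastHit]:
    """Read BLAST tabular hits: outfmt-6 column order with two appended
    taxonomy columns (species, genus).  Lines starting with '#' are skipped.
    """
    hits: list[BlastHit] = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) < 14:
            raise ValueError(
                f"BLAST hit line has {len(cols)} columns, expected >= 14"
            )
        hits.append(
            BlastHit(
                query=cols[0],
                subject=cols[1],
                identity=float(cols[2]),
                evalue=float(cols[10]),
                bitscore=float(cols[11]) if cols[11] else None,
                species=cols[12],
                genus=cols[13],
            )
        )
    return hits


def write_blast_hits(hits: Iterable[BlastHit], path: str | Path) -> None:
    header = (
        "#qseqid\tsseqid\tpident\tlength\tmismatch\tgapopen\tqstart\tqend"
        "\tsstart\tsend\tevalue\tbitscore\tspecies\tgenus"
    )
    lines = [header]
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.query,
                    h.subject,
                    _fmt_num(h.identity),
                    "0", "0", "0", "0", "0", "0", "0",
                    format(h.evalue, ".2e") if h.evalue else "0.0",
                    _fmt_num(h.bitscore) if h.bitscore is not None else "0",
                    h.species,
                    h.genus,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
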