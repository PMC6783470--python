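"""Readers/writers for the formats the pipeline touches, and the domain types
they populate.

Three kinds of input meet here and must be mutually consistent: a gapped
protein multiple alignment (FASTA), a phylogeny with branch lengths (Newick),
and a table of extant-taxon optimal growth temperatures (TSV).  Matching
between alignment ids, leaf labels and OGT taxa is exact string equality after
whitespace trimming — no fuzzy matching, because a silent mismatch corrupts
the downstream calibration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    IdentityError,
    RangeError,
    TreeError,
)

#: canonical amino acids in the conventional PAML ordering
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
#: ambiguity codes treated as missing data throughout
AMBIGUOUS = "XBZ"
GAP = "-"
_ALLOWED = set(AMINO_ACIDS) | set(AMBIGUOUS) | {GAP}

OGT_MIN, OGT_MAX = -5.0, 130.0


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A validated gapped amino-acid alignment.

    Rows are upper-case strings over the 20 canonical residues plus ``-``
    (gap) and ``X``/``B``/``Z`` (ambiguity, treated as missing data).
    Selenocysteine ``U`` and pyrrolysine ``O`` are rejected outright: they
    cannot be placed in the charged/polar/other partition the CvP statistic
    needs.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentShapeError("ids and rows differ in count")
        if not self.rows:
            raise AlignmentShapeError("alignment has no rows")
        seen: set[str] = set()
        for sid in self.ids:
            if not sid:
                raise IdentityError("empty sequence identifier")
            if sid in seen:
                raise IdentityError(f"duplicate sequence identifier {sid!r}")
            seen.add(sid)
        ncol = len(self.rows[0])
        if ncol < 1:
            raise AlignmentShapeError("alignment has zero columns")
        normalized = []
        for sid, row in zip(self.ids, self.rows):
            row = row.upper().replace(".", GAP)
            if len(row) != ncol:
                raise AlignmentShapeError(
                    f"row {sid!r} has length {len(row)}, expected {ncol}"
                )
            for col, ch in enumerate(row):
                if ch not in _ALLOWED:
                    raise AlphabetError(
                        f"illegal character {ch!r} in sequence {sid!r} "
                        f"at column {col + 1}"
                    )
            normalized.append(row)
        self.rows = normalized

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def row(self, sid: str) -> str:
        try:
            return self.rows[self.ids.index(sid)]
        except ValueError:
            raise IdentityError(f"no sequence with id {sid!r}") from None


def read_fasta_alignment(path) -> Alignment:
    """Read a gapped FASTA file into a validated :class:`Alignment`."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id.strip())
        rows.append(str(rec.seq))
    if len(ids) < 2:
        raise AlignmentShapeError(f"{path}: need at least 2 FASTA records, got {len(ids)}")
    return Alignment(ids, rows)


def write_fasta_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class Node:
    """A tree node. ``length`` is the branch to the parent (None at the top)."""

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.parent: Node | None = None
        self.children: list[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else "internal"
        return f"<Node {self.label!r} ({kind}, length={self.length})>"


class PhyloTree:
    """A phylogeny with branch lengths in substitutions/site.

    Rootedness follows the standard Newick convention: a bifurcating top-level
    node means rooted, a multifurcation means unrooted.  Branch lengths are
    mandatory on every non-root edge and must be nonnegative.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation ------------------------------------------

    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if any(not lab for lab in labels):
            raise TreeError("unlabeled leaf")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise IdentityError(f"duplicate leaf labels: {dup}")
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None:
                raise TreeError(
                    f"missing branch length on edge above {node.label or 'an internal node'}"
                )
            if node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} above "
                    f"{node.label or 'an internal node'}"
                )

    # -- traversal ----------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def rooted(self) -> bool:
        return len(self.root.children) == 2

    def total_length(self) -> float:
        return sum(n.length for n in self.preorder() if n is not self.root)

    # -- labeling and lookup ------------------------------------------------

    def assign_internal_labels(self, prefix: str = "N") -> None:
        """Give every unlabeled internal node a deterministic preorder label."""
        taken = {n.label for n in self.preorder() if n.label}
        counter = itertools.count(1)
        for node in self.preorder():
            if node.is_leaf or node.label:
                continue
            while True:
                cand = f"{prefix}{next(counter)}"
                if cand not in taken:
                    node.label = cand
                    taken.add(cand)
                    break

    def find(self, label: str) -> Node:
        for node in self.preorder():
            if node.label == label:
                return node
        raise IdentityError(f"no node labeled {label!r}")

    def mrca(self, labels) -> Node:
        """Most recent common ancestor of a set of leaf labels (rooted trees)."""
        want = set(labels)
        if not want:
            raise IdentityError("empty leaf selector")
        missing = want - set(self.leaf_labels())
        if missing:
            raise IdentityError(f"selector leaves absent from tree: {sorted(missing)}")
        node = self.find(next(iter(want)))
        covered = {node.label}
        while covered < want:
            node = node.parent
            covered = {l.label for l in _subtree_leaves(node)}
        return node

    # -- copying ------------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    # -- output -------------------------------------------------------------

    def newick(self, comments: dict[str, str] | None = None) -> str:
        """Serialize to Newick with 10-significant-digit branch lengths.

        ``comments`` maps node labels to bracketed ``key=value`` strings
        appended after the node label (e.g. ``{"N1": "ogt=93.2"}``).
        """
        comments = comments or {}

        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                body = f"({inner}){node.label or ''}"
            if node.label and node.label in comments:
                body += f"[&{comments[node.label]}]"
            if node.length is not None:
                body += f":{node.length:.10g}"
            return body

        return fmt(self.root) + ";"


def _subtree_leaves(node: Node) -> list[Node]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            label = dnode.label
        node = Node(label.strip() if label else None, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # root edge length carries no information here
    return PhyloTree(root)


def read_newick(path) -> PhyloTree:
    """Read a single Newick statement; rootedness inferred from root degree."""
    try:
        dtree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"cannot parse Newick file {path}: {exc}") from exc
    return _from_dendropy(dtree)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (convenience twin of :func:`read_newick`)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeError(f"cannot parse Newick: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree, path, comments: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick(comments) + "\n")


# ---------------------------------------------------------------------------
# OGT tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OGTRecord:
    """One extant taxon's optimal growth temperature.

    ``copy_id`` distinguishes multiple mcr-complex copies of one species;
    species with two copies enter the calibration twice with the same OGT.
    """

    taxon: str
    ogt: float
    copy_id: str = "1"
    psychrophile: bool = False

    def __post_init__(self) -> None:
        if not self.taxon:
            raise IdentityError("empty taxon id")
        if not (OGT_MIN <= self.ogt <= OGT_MAX):
            raise RangeError(
                f"OGT {self.ogt} for {self.taxon!r} outside [{OGT_MIN}, {OGT_MAX}] °C"
            )


_TRUE = {"true", "1", "yes", "t"}


def read_ogt_table(path) -> list[OGTRecord]:
    """Read a TSV with columns taxon, ogt_celsius[, copy_id][, psychrophile]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"taxon", "ogt_celsius"}
    if not required <= set(df.columns):
        raise IdentityError(
            f"OGT table needs columns {sorted(required)}, found {list(df.columns)}"
        )
    records: list[OGTRecord] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        taxon = str(row["taxon"]).strip()
        try:
            ogt = float(row["ogt_celsius"])
        except (TypeError, ValueError):
            raise RangeError(
                f"non-numeric OGT {row['ogt_celsius']!r} for taxon {taxon!r}"
            ) from None
        copy_id = str(row["copy_id"]).strip() if "copy_id" in df.columns and pd.notna(row.get("copy_id")) else "1"
        psy = (
            str(row["psychrophile"]).strip().lower() in _TRUE
            if "psychrophile" in df.columns and pd.notna(row.get("psychrophile"))
            else False
        )
        key = (taxon, copy_id)
        if key in seen:
            raise IdentityError(f"duplicate (taxon, copy_id) pair {key}")
        seen.add(key)
        records.append(OGTRecord(taxon, ogt, copy_id, psy))
    return records


def write_ogt_table(records: list[OGTRecord], path) -> None:
    df = pd.DataFrame(
        {
            "taxon": [r.taxon for r in records],
            "ogt_celsius": [repr(r.ogt) for r in records],
            "copy_id": [r.copy_id for r in records],
            "psychrophile": [str(r.psychrophile).lower() for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Node annotations
# ---------------------------------------------------------------------------

def write_node_annotations(
    tree: PhyloTree,
    table: dict[str, dict],
    tsv_path,
    newick_path=None,
) -> None:
    """Write per-node annotations as a TSV (preorder node order) and,
    optionally, a Newick file whose labels carry ``ogt=<value>`` comments.

    ``table`` maps node labels to flat records; every key must name a tree
    node.  An empty table yields a header-only TSV and an uncommented Newick.
    """
    known = {n.label for n in tree.preorder() if n.label}
    unknown = set(table) - known
    if unknown:
        raise IdentityError(f"annotations for unknown nodes: {sorted(unknown)}")

    columns: list[str] = []
    for rec in table.values():
        for key in rec:
            if key not in columns:
                columns.append(key)

    with open(tsv_path, "w") as fh:
        fh.write("\t".join(["node"] + columns) + "\n")
        for node in tree.preorder():
            if node.label not in table:
                continue
            rec = table[node.label]
            cells = [node.label] + [_fmt_cell(rec.get(c)) for c in columns]
            fh.write("\t".join(cells) + "\n")

    if newick_path is not None:
        comments = {
            label: f"ogt={rec['ogt_map']:.4f}"
            for label, rec in table.items()
            if isinstance(rec.get("ogt_map"), float)
        }
        write_newick(tree, newick_path, comments=comments)


def _fmt_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.6f}"
    if isinstance(value, bool):
        return str(value).lower()
    return str(value)
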