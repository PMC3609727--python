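"""Trees, alignments and clade definitions: reading, writing, masking, MRCA extraction.

Newick parsing is delegated to dendropy; FASTA to Biopython. The in-memory
tree is a minimal node structure tailored to the downstream dating optimizer
(stable postorder indexing, parent links, edge lengths on child nodes).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Unambiguous bases.
BASES = frozenset("ACGT")
#: IUPAC ambiguity codes (excluding the four bases).
AMBIGUITY = frozenset("RYSWKMBDHVN")
#: Full DNA alignment alphabet, gaps included.
ALPHABET = BASES | AMBIGUITY | {"-"}


class NewickParseError(ValueError):
    """Malformed Newick input."""


class MissingBranchLengthError(ValueError):
    """An edge of the input phylogram carries no branch length."""


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows or illegal symbols)."""


class TreeNode:
    """One node of a rooted tree.

    ``length`` is the length of the edge *above* the node (``None`` for the
    root). Extra numeric annotations (``age``, ``rate``) are attached by the
    chronology and simulation layers.
    """

    __slots__ = ("label", "length", "children", "parent", "age", "rate")

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.age: Optional[float] = None
        self.rate: Optional[float] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, length={self.length!r})"


class Phylogram:
    """Rooted tree with branch lengths in expected substitutions per site.

    Invariants (checked by :meth:`validate`): a unique root; branch lengths
    present and non-negative on every non-root edge; unique, non-empty tip
    labels.
    """

    def __init__(self, root: TreeNode, validate: bool = True):
        self.root = root
        if validate:
            self.validate()
        if len(self.tip_labels()) < 2:
            logger.warning("degenerate tree with fewer than 2 tips")
        if len(root.children) > 2:
            logger.warning(
                "root has %d children (unrooted basal multifurcation); "
                "treating the basal node as the root",
                len(root.children),
            )

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogram":
        """Read a phylogram from a Newick file path or literal string.

        Branch lengths are required on all non-root edges; internal node
        labels (e.g. bootstrap supports) are tolerated and preserved.
        """
        path = Path(source) if not str(source).lstrip().startswith("(") else None
        try:
            if path is not None:
                dtree = dendropy.Tree.get(
                    path=str(path), schema="newick",
                    suppress_internal_node_taxa=True, preserve_underscores=True,
                )
            else:
                dtree = dendropy.Tree.get(
                    data=str(source), schema="newick",
                    suppress_internal_node_taxa=True, preserve_underscores=True,
                )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        root = _convert_dendropy(dtree.seed_node)
        tree = cls(root)
        for node, parent in _edges(root):
            if node.length is None:
                child_desc = node.label or "internal node above tips {%s}" % (
                    ",".join(sorted(leaf.label for leaf in _leaves(node)))
                )
                raise MissingBranchLengthError(
                    f"edge leading to {child_desc} has no branch length"
                )
        return tree

    def to_newick(self) -> str:
        """Serialize to Newick with full float precision."""
        return _write_newick(self.root) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def copy(self) -> "Phylogram":
        return Phylogram(_copy_subtree(self.root), validate=False)

    # -- traversal ------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def find_tip(self, label: str) -> TreeNode:
        for tip in self.tips():
            if tip.label == label:
                return tip
        raise KeyError(f"unknown tip label: {label!r}")

    # -- queries --------------------------------------------------------

    def validate(self) -> None:
        labels = []
        for node, parent in _edges(self.root):
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on edge to {node.label!r}")
        for tip in self.tips():
            if not tip.label:
                raise ValueError("empty tip label")
            labels.append(tip.label)
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")

    def mrca(self, tip_labels: Sequence[str]) -> TreeNode:
        """Most recent common ancestor of the named tips.

        Computed as the deepest node on the intersection of root paths.
        """
        paths = []
        for label in tip_labels:
            tip = self.find_tip(label)
            path = []
            node: Optional[TreeNode] = tip
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        mrca = self.root
        for nodes in zip(*paths):
            if all(n is nodes[0] for n in nodes):
                mrca = nodes[0]
            else:
                break
        return mrca

    def extract_clade(self, clade: "CladeDefinition") -> tuple["Phylogram", bool]:
        """Subtree rooted at the MRCA of ``clade.tips``, plus a monophyly flag.

        The flag is true iff the MRCA subtree's tip set equals the clade's
        tip set exactly.
        """
        clade.validate_against(self)
        mrca = self.mrca(sorted(clade.tips))
        sub_root = _copy_subtree(mrca)
        sub_root.length = None
        sub_root.parent = None
        subtree = Phylogram(sub_root, validate=False)
        monophyletic = set(subtree.tip_labels()) == set(clade.tips)
        return subtree, monophyletic


# -- tree helpers -------------------------------------------------------


def _convert_dendropy(dnode: dendropy.Node) -> TreeNode:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = TreeNode(label=label, length=dnode.edge.length)
    for dchild in dnode.child_nodes():
        node.add_child(_convert_dendropy(dchild))
    return node


def _copy_subtree(node: TreeNode) -> TreeNode:
    clone = TreeNode(node.label, node.length)
    clone.age = node.age
    clone.rate = node.rate
    for child in node.children:
        clone.add_child(_copy_subtree(child))
    return clone


def _edges(root: TreeNode) -> Iterator[tuple[TreeNode, TreeNode]]:
    """Yield (child, parent) over all non-root edges."""
    stack = list(root.children)
    while stack:
        node = stack.pop()
        yield node, node.parent
        stack.extend(node.children)


def _leaves(node: TreeNode) -> Iterator[TreeNode]:
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        stack.extend(n.children)


def _fmt_length(x: float) -> str:
    return repr(float(x))


def _write_newick(node: TreeNode) -> str:
    if node.is_leaf:
        body = node.label or ""
    else:
        body = "(" + ",".join(_write_newick(c) for c in node.children) + ")"
        if node.label:
            body += node.label
    if node.length is not None:
        body += ":" + _fmt_length(node.length)
    return body


def read_newick(path: str | Path) -> Phylogram:
    """Module-level convenience wrapper around :meth:`Phylogram.from_newick`."""
    return Phylogram.from_newick(path)


def write_newick(tree: Phylogram, path: str | Path) -> None:
    tree.write_newick(path)


# -- alignments ---------------------------------------------------------


class Alignment:
    """A DNA multiple sequence alignment over A/C/G/T, IUPAC codes and ``-``."""

    def __init__(self, labels: Sequence[str], seqs: Sequence[str]):
        self.labels = list(labels)
        self.seqs = [s.upper() for s in seqs]
        if len(self.labels) != len(self.seqs):
            raise AlignmentError("labels and sequences differ in number")
        if not self.seqs:
            raise AlignmentError("empty alignment")
        self._validate()

    def _validate(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise AlignmentError(f"duplicate labels: {dupes}")
        ncol = len(self.seqs[0])
        ragged = [lab for lab, s in zip(self.labels, self.seqs) if len(s) != ncol]
        if ragged:
            raise AlignmentError(f"ragged sequence lengths for labels: {ragged}")
        for lab, s in zip(self.labels, self.seqs):
            for pos, ch in enumerate(s, start=1):
                if ch not in ALPHABET:
                    raise AlignmentError(
                        f"illegal symbol {ch!r} in {lab!r} at column {pos} "
                        "(DNA alphabet only)"
                    )

    @property
    def nseq(self) -> int:
        return len(self.seqs)

    @property
    def ncol(self) -> int:
        return len(self.seqs[0])

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no FASTA records in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path: str | Path, wrap: int = 70) -> None:
        records = [
            SeqRecord(Seq(s), id=lab, description="")
            for lab, s in zip(self.labels, self.seqs)
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
            writer.write_file(records)

    def subset(self, labels: Sequence[str]) -> "Alignment":
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"labels absent from alignment: {missing}")
        return Alignment(list(labels), [self.seqs[index[lab]] for lab in labels])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Alignment)
            and self.labels == other.labels
            and self.seqs == other.seqs
        )


def read_fasta(path: str | Path) -> Alignment:
    return Alignment.from_fasta(path)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    aln.to_fasta(path)


def mask_columns(
    aln: Alignment, ranges: Sequence[tuple[int, int]]
) -> Alignment:
    """Remove the union of 1-based inclusive column intervals.

    Intervals may overlap; the relative order of surviving columns is
    preserved. An interval outside ``[1, ncol]`` is an error.
    """
    masked: set[int] = set()
    for lo, hi in ranges:
        if lo < 1 or hi > aln.ncol or lo > hi:
            raise ValueError(
                f"interval {lo}-{hi} out of bounds for alignment of {aln.ncol} columns"
            )
        masked.update(range(lo, hi + 1))
    keep = [i for i in range(1, aln.ncol + 1) if i not in masked]
    seqs = ["".join(s[i - 1] for i in keep) for s in aln.seqs]
    return Alignment(aln.labels, seqs)


def parse_mask_ranges(text: str) -> list[tuple[int, int]]:
    """Parse ``"53-55,194-198,429-444"`` into 1-based inclusive intervals."""
    ranges: list[tuple[int, int]] = []
    if not text.strip():
        return ranges
    for chunk in text.split(","):
        m = re.fullmatch(r"\s*(\d+)\s*-\s*(\d+)\s*", chunk)
        if not m:
            raise ValueError(f"cannot parse mask interval {chunk!r} (expected start-end)")
        ranges.append((int(m.group(1)), int(m.group(2))))
    return ranges


# -- clade definitions --------------------------------------------------


@dataclass
class CladeDefinition:
    """A named clade: its tip labels and known/minimal species counts."""

    name: str
    tips: frozenset[str]
    n_min: int
    n_max_known: Optional[int] = None

    def __post_init__(self) -> None:
        self.tips = frozenset(self.tips)
        if not self.tips:
            raise ValueError(f"clade {self.name!r}: empty tip set")
        if self.n_min < 1:
            raise ValueError(f"clade {self.name!r}: n_min must be >= 1")
        if self.n_max_known is not None and self.n_max_known < self.n_min:
            raise ValueError(
                f"clade {self.name!r}: n_max_known ({self.n_max_known}) < n_min ({self.n_min})"
            )

    def validate_against(self, tree: Phylogram) -> None:
        tree_tips = set(tree.tip_labels())
        missing = sorted(self.tips - tree_tips)
        if missing:
            raise KeyError(f"clade {self.name!r}: tips not in tree: {missing}")


def read_clades_tsv(path: str | Path) -> list[CladeDefinition]:
    """Read clade definitions from TSV.

    Columns: ``name``, ``n_min``, ``n_max_known`` (may be empty), ``tips``
    (semicolon-separated tip labels).
    """
    clades: list[CladeDefinition] = []
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty clade file: {path}")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["name", "n_min", "n_max_known", "tips"]
    if header != expected:
        raise ValueError(f"clade file header {header} != {expected}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
        name, n_min, n_max_known, tips = parts
        clades.append(
            CladeDefinition(
                name=name,
                tips=frozenset(t.strip() for t in tips.split(";") if t.strip()),
                n_min=int(n_min),
                n_max_known=int(n_max_known) if n_max_known.strip() else None,
            )
        )
    return clades


def write_clades_tsv(clades: Sequence[CladeDefinition], path: str | Path) -> None:
    lines = ["name\tn_min\tn_max_known\ttips"]
    for c in clades:
        n_max = "" if c.n_max_known is None else str(c.n_max_known)
        lines.append(f"{c.name}\t{c.n_min}\t{n_max}\t" + ";".join(sorted(c.tips)))
    Path(path).write_text("\n".join(lines) + "\n")
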