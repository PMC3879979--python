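"""Alignment and tree I/O plus ortholog-quality filtering.

The pipeline works on per-gene protein alignments covering a small set of
focal strains (the closely related genomes on which substitutions are
mapped) and optional outgroup species (used only to decide which sites are
variable).  This module owns the two container types everything else
consumes — :class:`GeneAlignment` and :class:`Phylogeny` — together with
FASTA / TSV / newick round-tripping and the quality filters applied to
ortholog sets before analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from dendropy.utility.error import DataParseError
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MISSING = "X"
_ALPHABET = frozenset(AMINO_ACIDS) | {GAP, MISSING}

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "MISSING",
    "GeneAlignment",
    "Phylogeny",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "remove_gap_columns",
    "pairwise_identity_coverage",
    "ortholog_filter",
    "read_strand_table",
    "write_strand_table",
]


class RaggedAlignmentError(ValueError):
    """Raised when FASTA records in one alignment differ in length."""


@dataclass(frozen=True)
class GeneAlignment:
    """One gene's gap-handled protein alignment plus its strand label.

    Parameters
    ----------
    gene_id:
        Identifier of the gene.
    rows:
        Ordered mapping from sequence label to aligned amino acid string
        (uppercase one-letter codes, ``-`` for gap, ``X`` for unknown).
    focal_labels:
        The subset of row labels that are focal strains; substitutions are
        only mapped on these rows.  Outgroup rows (everything else) enter
        only the variable-site rule.
    strand:
        ``"leading"``, ``"lagging"`` or ``"unknown"``.
    source_columns:
        Original 0-based column index of each current column, kept through
        gap-column removal so reports can reference pre-filter coordinates.
    """

    gene_id: str
    rows: dict[str, str]
    focal_labels: tuple[str, ...]
    strand: str = "unknown"
    source_columns: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError(f"{self.gene_id}: alignment has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise RaggedAlignmentError(
                f"{self.gene_id}: rows have unequal lengths {sorted(lengths)}"
            )
        if not self.focal_labels:
            raise ValueError(f"{self.gene_id}: focal_labels is empty")
        missing = [l for l in self.focal_labels if l not in self.rows]
        if missing:
            raise KeyError(f"{self.gene_id}: focal labels absent from rows: {missing}")
        for label, seq in self.rows.items():
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"{self.gene_id}/{label}: illegal characters {sorted(bad)}"
                )
        if self.strand not in ("leading", "lagging", "unknown"):
            raise ValueError(f"{self.gene_id}: bad strand label {self.strand!r}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def outgroup_labels(self) -> tuple[str, ...]:
        focal = set(self.focal_labels)
        return tuple(l for l in self.rows if l not in focal)

    def focal_rows(self) -> dict[str, str]:
        return {l: self.rows[l] for l in self.focal_labels}

    def column(self, i: int) -> dict[str, str]:
        return {l: s[i] for l, s in self.rows.items()}


class Phylogeny:
    """A rooted tree over the focal strains.

    Thin wrapper around a flat node-array representation built from
    dendropy.  Every non-root node defines the branch (edge) above it; edges
    are named by their child node, with internal nodes auto-named ``N1``,
    ``N2``, ... in preorder when unnamed.  Branch independence — the
    "separate evolutionary lineages" requirement for parallel/convergent
    calls — is the absence of an ancestor–descendant relation between the
    two child nodes.
    """

    def __init__(
        self,
        parents: Sequence[int],
        names: Sequence[str],
        lengths: Sequence[float | None],
    ) -> None:
        self.parent = list(parents)  # parent index; -1 for root
        self.name = list(names)
        self.length = list(lengths)
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        root = None
        for i, p in enumerate(self.parent):
            if p == -1:
                if root is not None:
                    raise ValueError("tree has more than one root")
                root = i
            else:
                self.children[p].append(i)
        if root is None:
            raise ValueError("tree has no root")
        self.root = root
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("duplicate leaf labels")
        self._index = {nm: i for i, nm in enumerate(self.name)}
        if len(self._index) != n:
            raise ValueError("duplicate node names")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except DataParseError as exc:
            raise ValueError(f"invalid newick: {exc}") from exc
        return cls._from_dendropy(tree)

    @classmethod
    def from_file(cls, path: str | Path) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(path=str(path), schema="newick")
        except DataParseError as exc:
            raise ValueError(f"invalid newick in {path}: {exc}") from exc
        return cls._from_dendropy(tree)

    @classmethod
    def _from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        if not nodes:
            raise ValueError("empty tree")
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        parents, names, lengths = [], [], []
        auto = 0
        for nd in nodes:
            parents.append(idx[id(nd.parent_node)] if nd.parent_node else -1)
            label = nd.taxon.label if nd.taxon else nd.label
            if not label:
                auto += 1
                label = f"N{auto}"
            names.append(label.replace(" ", "_"))
            lengths.append(nd.edge.length)
        return cls(parents, names, lengths)

    @classmethod
    def ladder(cls, labels: Sequence[str], branch_length: float = 0.01) -> "Phylogeny":
        """Fully pectinate (caterpillar) rooted tree with equal branch lengths.

        ``ladder(["A","B","C"])`` is ``(A,(B,C));`` — each internal node
        splits off one leaf.
        """
        if len(labels) < 2:
            raise ValueError("need at least two leaves")
        parents: list[int] = [-1]
        names: list[str] = ["N1"]
        lengths: list[float | None] = [None]
        cur = 0
        for k, label in enumerate(labels[:-2]):
            parents.append(cur)
            names.append(label)
            lengths.append(branch_length)
            parents.append(cur)
            names.append(f"N{k + 2}")
            lengths.append(branch_length)
            cur = len(parents) - 1
        for label in labels[-2:]:
            parents.append(cur)
            names.append(label)
            lengths.append(branch_length)
        return cls(parents, names, lengths)

    # -- queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> list[str]:
        return [self.name[i] for i in self.leaves]

    @property
    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    @property
    def edges(self) -> list[str]:
        """Edge ids (child-node names) for every non-root node, preorder."""
        return [self.name[i] for i in range(self.n_nodes) if self.parent[i] != -1]

    def node_index(self, name: str) -> int:
        return self._index[name]

    def branch_length(self, edge: str) -> float | None:
        return self.length[self._index[edge]]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.children[i])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(reversed(self.children[i]))
        return order

    def is_ancestor_edge(self, edge_a: str, edge_b: str) -> bool:
        """True iff the child node of ``edge_a`` strictly contains ``edge_b``."""
        a = self._index[edge_a]
        b = self._index[edge_b]
        p = self.parent[b]
        while p != -1:
            if p == a:
                return True
            p = self.parent[p]
        return False

    def independent_edges(self, edge_a: str, edge_b: str) -> bool:
        """Neither branch ancestral to the other: separate lineages."""
        return (
            edge_a != edge_b
            and not self.is_ancestor_edge(edge_a, edge_b)
            and not self.is_ancestor_edge(edge_b, edge_a)
        )

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                s = self.name[i]
            else:
                s = "(" + ",".join(render(c) for c in self.children[i]) + ")"
                s += self.name[i] if self.name[i].startswith("N") is False else ""
            if self.parent[i] != -1 and self.length[i] is not None:
                s += f":{self.length[i]:g}"
            return s

        return render(self.root) + ";"

    def validate_focal(self, focal_labels: Iterable[str]) -> None:
        leaf = set(self.leaf_names)
        missing = [l for l in focal_labels if l not in leaf]
        if missing:
            raise KeyError(f"focal labels absent from tree: {missing}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta_alignment(
    path: str | Path,
    focal_labels: Sequence[str],
    gene_id: str | None = None,
    strand: str = "unknown",
) -> GeneAlignment:
    """Read one gene's multi-FASTA alignment.

    Sequences are uppercased; ragged records or missing focal labels are
    hard errors naming the offender.
    """
    path = Path(path)
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rows[rec.id] = str(rec.seq).upper()
    if not rows:
        raise ValueError(f"{path}: no FASTA records")
    length = len(next(iter(rows.values())))
    for label, seq in rows.items():
        if len(seq) != length:
            raise RaggedAlignmentError(
                f"{path}: record {label!r} has length {len(seq)}, expected {length}"
            )
    return GeneAlignment(
        gene_id=gene_id or path.stem,
        rows=rows,
        focal_labels=tuple(focal_labels),
        strand=strand,
    )


def write_fasta_alignment(aln: GeneAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=label, description="") for label, seq in aln.rows.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Gap handling
# ---------------------------------------------------------------------------


def remove_gap_columns(aln: GeneAlignment) -> GeneAlignment:
    """Drop every column holding a gap in any *focal* row.

    Columns whose only gaps sit in outgroup rows are kept: an outgroup gap
    counts as a variant under the variable-site rule, so those columns must
    stay visible downstream.  The returned alignment carries
    ``source_columns`` mapping new to original column indices.  Idempotent.
    """
    focal = [aln.rows[l] for l in aln.focal_labels]
    keep = [i for i in range(aln.length) if all(row[i] != GAP for row in focal)]
    if len(keep) == aln.length and aln.source_columns is not None:
        return aln
    prev = aln.source_columns or tuple(range(aln.length))
    rows = {l: "".join(s[i] for i in keep) for l, s in aln.rows.items()}
    return replace(
        aln, rows=rows, source_columns=tuple(prev[i] for i in keep)
    )


# ---------------------------------------------------------------------------
# Ortholog quality filters
# ---------------------------------------------------------------------------


def pairwise_identity_coverage(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Identity and mutual coverage of two rows of one alignment.

    Identity = matches / columns where both rows are non-gap.  Coverage =
    (columns where both are non-gap) / ungapped length of the shorter
    sequence, which applies the threshold symmetrically.  ``X`` never
    matches anything.  Returns ``(0.0, 0.0)`` when the rows never overlap.
    """
    both = [(a, b) for a, b in zip(seq_a, seq_b) if a != GAP and b != GAP]
    if not both:
        return 0.0, 0.0
    matches = sum(1 for a, b in both if a == b and a != MISSING)
    shorter = min(
        sum(1 for c in seq_a if c != GAP), sum(1 for c in seq_b if c != GAP)
    )
    return matches / len(both), len(both) / shorter


@dataclass
class FilterLog:
    """Per-gene record of filter outcomes."""

    gene_id: str
    kept: bool
    focal_ungapped_length: int
    dropped_outgroups: dict[str, dict[str, float]] = field(default_factory=dict)
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "kept": self.kept,
            "focal_ungapped_length": self.focal_ungapped_length,
            "dropped_outgroups": self.dropped_outgroups,
            "reason": self.reason,
        }


def ortholog_filter(
    alignments: Iterable[GeneAlignment],
    min_length: int = 200,
    min_identity: float = 0.70,
    min_coverage: float = 0.70,
) -> tuple[list[GeneAlignment], list[FilterLog]]:
    """Apply the core-gene length filter and outgroup similarity filters.

    A gene is kept iff its focal-region ungapped length is strictly greater
    than ``min_length`` (core genes ">200 amino acids").  Outgroup rows with
    identity or mutual coverage below threshold against the first focal row
    are dropped from the alignment without rejecting the gene.  Filtering
    the kept set again is a no-op (fixed point).
    """
    if min_length < 0 or not (0 <= min_identity <= 1) or not (0 <= min_coverage <= 1):
        raise ValueError("bad filter thresholds")
    kept: list[GeneAlignment] = []
    logs: list[FilterLog] = []
    for aln in alignments:
        ref = aln.rows[aln.focal_labels[0]]
        focal_len = sum(1 for c in ref if c != GAP)
        log = FilterLog(aln.gene_id, True, focal_len)
        if focal_len <= min_length:
            log.kept = False
            log.reason = f"focal length {focal_len} <= {min_length}"
            logs.append(log)
            continue
        rows = dict(aln.rows)
        for label in aln.outgroup_labels:
            ident, cov = pairwise_identity_coverage(ref, aln.rows[label])
            if ident < min_identity or cov < min_coverage:
                del rows[label]
                log.dropped_outgroups[label] = {
                    "identity": round(ident, 6),
                    "coverage": round(cov, 6),
                }
        kept.append(replace(aln, rows=rows) if len(rows) != len(aln.rows) else aln)
        logs.append(log)
    return kept, logs


def write_filter_log(logs: Sequence[FilterLog], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([l.to_dict() for l in logs], indent=2) + "\n"
    )


# ---------------------------------------------------------------------------
# Strand tables
# ---------------------------------------------------------------------------


def read_strand_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``gene_id<TAB>strand``; strand must be leading/lagging."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        gene_id, strand = parts
        if strand not in ("leading", "lagging"):
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        if gene_id in table:
            raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
        table[gene_id] = strand
    return table


def write_strand_table(table: Mapping[str, str], path: str | Path) -> None:
    lines = [f"{g}\t{s}" for g, s in table.items()]
    Path(path).write_text("\n".join(lines) + "\n")
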