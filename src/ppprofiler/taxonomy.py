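"""NCBI-taxdump-style taxonomy tree with lineage operations.

The tree is held fully in memory: one node per taxon id carrying its parent
pointer, rank string and scientific name. Two lineage operations are exposed:
:func:`ancestor_at_rank`, used to collapse strain-level hits to a higher rank
so each collapsed clade counts only once during scoring, and
:func:`descendants`, used to build presence profiles for whole lineages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator


class TaxdumpError(ValueError):
    """Malformed or structurally invalid taxdump input."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str = ""


@dataclass
class TaxonomyTree:
    """Rooted taxonomy: ``nodes`` maps taxid -> :class:`TaxonNode`.

    Exactly one node is its own parent (the root, taxid 1 by NCBI
    convention); every other parent pointer resolves within the tree.
    """

    nodes: dict[int, TaxonNode] = field(default_factory=dict)
    root: int = 1

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def parent(self, taxid: int) -> int:
        return self._get(taxid).parent

    def rank(self, taxid: int) -> str:
        return self._get(taxid).rank

    def name(self, taxid: int) -> str:
        return self._get(taxid).name

    def _get(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise KeyError(f"unknown taxid {taxid}") from None

    def lineage(self, taxid: int) -> Iterator[int]:
        """Yield taxid, its parent, ... up to and including the root."""
        node = self._get(taxid)
        while True:
            yield node.taxid
            if node.parent == node.taxid:
                return
            node = self.nodes[node.parent]

    def validate(self) -> None:
        """Check the structural invariants: single self-parented root,
        resolvable parents, no cycles."""
        roots = [t for t, n in self.nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise TaxdumpError(
                f"expected exactly one self-parented root, found {len(roots)}"
            )
        self.root = roots[0]
        for taxid, node in self.nodes.items():
            if node.parent not in self.nodes:
                raise TaxdumpError(
                    f"node {taxid} has dangling parent {node.parent}"
                )
        # cycle check via iterative walk with visited marking
        ok: set[int] = {self.root}
        for taxid in self.nodes:
            path = []
            t = taxid
            while t not in ok:
                if t in path:
                    raise TaxdumpError(f"cycle detected at taxid {t}")
                path.append(t)
                t = self.nodes[t].parent
            ok.update(path)


def _split_dmp(line: str) -> list[str]:
    # taxdump dialect: fields joined by "\t|\t", row terminated by "\t|"
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return line.split("\t|\t")


def load_taxdump(nodes_path: str | Path, names_path: str | Path | None = None) -> TaxonomyTree:
    """Parse ``nodes.dmp`` (and optionally ``names.dmp``) into a tree.

    Only the first three fields of nodes.dmp are used (taxid, parent taxid,
    rank); only "scientific name" rows of names.dmp are attached. Nodes with
    no name entry get an empty string.
    """
    tree = TaxonomyTree()
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) < 3:
                raise TaxdumpError(
                    f"{nodes_path}:{lineno}: expected >=3 '\\t|\\t' fields, got {len(fields)}"
                )
            try:
                taxid = int(fields[0])
                parent = int(fields[1])
            except ValueError:
                raise TaxdumpError(
                    f"{nodes_path}:{lineno}: non-integer taxid/parent"
                ) from None
            if taxid < 1:
                raise TaxdumpError(f"{nodes_path}:{lineno}: taxid must be >= 1")
            tree.nodes[taxid] = TaxonNode(taxid, parent, fields[2].strip())

    if names_path is not None:
        names: dict[int, str] = {}
        with open(names_path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                fields = _split_dmp(line)
                if len(fields) < 4:
                    raise TaxdumpError(
                        f"{names_path}:{lineno}: expected >=4 fields, got {len(fields)}"
                    )
                if fields[3].strip() == "scientific name":
                    names[int(fields[0])] = fields[1].strip()
        for taxid, name in names.items():
            if taxid in tree.nodes:
                n = tree.nodes[taxid]
                tree.nodes[taxid] = TaxonNode(n.taxid, n.parent, n.rank, name)

    tree.validate()
    return tree


def ancestor_at_rank(tree: TaxonomyTree, taxid: int, rank: str) -> int:
    """Nearest ancestor of ``taxid`` (including itself) with the given rank.

    When no node of that rank lies on the path to the root, the input taxid
    is returned unchanged so the hit remains countable during collapsing.
    """
    if not rank:
        raise ValueError("rank must be a non-empty string")
    for t in tree.lineage(taxid):
        if tree.rank(t) == rank:
            return t
    return taxid


def descendants(tree: TaxonomyTree, taxid: int) -> set[int]:
    """All nodes strictly below ``taxid`` (exclusive of the query node)."""
    tree._get(taxid)
    children: dict[int, list[int]] = {}
    for t, node in tree.nodes.items():
        if node.parent != t:
            children.setdefault(node.parent, []).append(t)
    out: set[int] = set()
    stack = list(children.get(taxid, []))
    while stack:
        t = stack.pop()
        out.add(t)
        stack.extend(children.get(t, []))
    return out
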