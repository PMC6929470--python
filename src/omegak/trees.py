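"""Phylogenies with {test}/{reference} branch labels.

Trees are stored in a flat indexed form (parent pointers + postorder)
that the pruning likelihood and the simulator share.  Newick parsing is
delegated to dendropy; branch labels use the HyPhy-style ``{test}``
suffix on node labels (``taxon{test}`` or ``){test}``).
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

TEST = "test"
REFERENCE = "reference"

_TEST_TAG = "__TEST__"


@dataclass
class LabelledTree:
    """Rooted representation of a (possibly unrooted) phylogeny.

    Node ``i`` has parent ``parent[i]`` (-1 for the root), branch length
    ``blen[i]`` on the edge above it, and ``is_test[i]`` marking that
    edge as a test (foreground) branch.  ``postorder`` lists all nodes
    children-before-parents with the root last.
    """

    parent: np.ndarray
    blen: np.ndarray
    is_test: np.ndarray
    children: list[list[int]]
    taxon_of: dict[int, str]  # leaf node -> taxon name
    postorder: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.postorder:
            self.postorder = self._compute_postorder()

    # -- construction ------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "LabelledTree":
        """Parse newick text or a path to a newick file.

        ``{test}`` suffixes on leaf or internal node labels mark the
        branch above that node as foreground; everything else is
        reference.
        """
        if isinstance(source, Path) or (
            "\n" not in str(source) and str(source).endswith((".nwk", ".tre", ".newick"))
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        text = text.strip()
        if not text:
            raise ValueError("empty newick input")
        if text.count("(") != text.count(")"):
            raise ValueError(
                f"unbalanced parentheses in newick (open={text.count('(')}, "
                f"close={text.count(')')})"
            )
        bad = re.search(r"\{(?!test\})[^}]*\}", text)
        if bad:
            raise ValueError(
                f"unknown branch label token {bad.group(0)!r} at position {bad.start()}"
            )
        text = text.replace("{test}", _TEST_TAG)
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except (ValueError, TypeError):
            raise
        except Exception as exc:  # dendropy reader errors
            raise ValueError(f"newick parse error: {exc}") from exc
        return cls._from_dendropy(tree)

    @classmethod
    def _from_dendropy(cls, tree: dendropy.Tree) -> "LabelledTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int32)
        blen = np.zeros(n, dtype=float)
        is_test = np.zeros(n, dtype=bool)
        children: list[list[int]] = [[] for _ in range(n)]
        taxon_of: dict[int, str] = {}
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                children[p].append(i)
                blen[i] = float(nd.edge.length) if nd.edge.length is not None else 0.0
                if blen[i] < 0:
                    raise ValueError(f"negative branch length {blen[i]} in input tree")
            label = nd.taxon.label if nd.taxon is not None else (nd.label or "")
            if label.endswith(_TEST_TAG):
                is_test[i] = True
                label = label[: -len(_TEST_TAG)]
            if nd.is_leaf():
                if not label:
                    raise ValueError("leaf without a taxon name in newick input")
                taxon_of[i] = label
        labels = list(taxon_of.values())
        if len(set(labels)) != len(labels):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise ValueError(f"duplicate taxa in tree: {dupes}")
        return cls(parent, blen, is_test, children, taxon_of)

    # -- properties --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.where(self.parent == -1)[0][0])

    @property
    def taxa(self) -> list[str]:
        return sorted(self.taxon_of.values())

    @property
    def leaves(self) -> list[int]:
        return sorted(self.taxon_of)

    def leaf_index(self) -> dict[str, int]:
        return {t: i for i, t in self.taxon_of.items()}

    def branch_nodes(self) -> list[int]:
        """Nodes that carry a branch (everything but the root)."""
        r = self.root
        return [i for i in range(self.n_nodes) if i != r]

    def total_length(self) -> float:
        return float(self.blen.sum())

    def _compute_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            order.append(nd)
            stack.extend(self.children[nd])
        order.reverse()
        return order

    # -- labelling ---------------------------------------------------

    def with_labels(self, foreground, mode: str = "clade") -> "LabelledTree":
        """Return a copy with test labels from foreground taxon groups.

        ``foreground`` is either a flat iterable of taxon names (one
        group) or an iterable of groups.  In ``clade`` mode every branch
        of the smallest subtree spanning each group is labelled,
        including the stem; in ``tips`` mode only terminal branches.
        """
        if mode not in ("clade", "tips"):
            raise ValueError(f"unknown labelling mode {mode!r}")
        groups = _as_groups(foreground)
        by_name = self.leaf_index()
        for g in groups:
            for t in g:
                if t not in by_name:
                    raise ValueError(f"foreground taxon {t!r} is not a leaf of the tree")
        is_test = np.zeros(self.n_nodes, dtype=bool)
        for g in groups:
            leaf_ids = [by_name[t] for t in g]
            if mode == "tips":
                for lf in leaf_ids:
                    is_test[lf] = True
                continue
            m = self.mrca(leaf_ids)
            for lf in leaf_ids:
                nd = lf
                while nd != m:
                    is_test[nd] = True
                    nd = int(self.parent[nd])
            if self.parent[m] != -1:
                is_test[m] = True  # stem of the spanning subtree
        return LabelledTree(
            self.parent.copy(), self.blen.copy(), is_test,
            [list(c) for c in self.children], dict(self.taxon_of),
            list(self.postorder),
        )

    def mrca(self, node_ids: list[int]) -> int:
        paths = []
        for nd in node_ids:
            path = []
            while nd != -1:
                path.append(nd)
                nd = int(self.parent[nd])
            paths.append(path[::-1])
        m = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            cand = paths[0][depth]
            if all(p[depth] == cand for p in paths):
                m = cand
            else:
                break
        return m

    # -- output ------------------------------------------------------

    def to_newick(self) -> str:
        def render(nd: int) -> str:
            tag = "{test}" if self.is_test[nd] and self.parent[nd] != -1 else ""
            if not self.children[nd]:
                label = self.taxon_of[nd]
                return f"{label}{tag}:{self.blen[nd]:.10g}"
            inner = ",".join(render(c) for c in self.children[nd])
            if self.parent[nd] == -1:
                return f"({inner})"
            return f"({inner}){tag}:{self.blen[nd]:.10g}"

        return render(self.root) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def scaled(self, factor: float) -> "LabelledTree":
        out = LabelledTree(
            self.parent.copy(), self.blen * factor, self.is_test.copy(),
            [list(c) for c in self.children], dict(self.taxon_of),
            list(self.postorder),
        )
        return out


def _as_groups(foreground) -> list[list[str]]:
    items = list(foreground)
    if not items:
        raise ValueError("foreground must contain at least one taxon")
    if all(isinstance(x, str) for x in items):
        return [items]
    return [list(g) for g in items]


def read_newick(path: str | Path) -> LabelledTree:
    return LabelledTree.from_newick(Path(path))


def write_newick(tree: LabelledTree, path: str | Path) -> None:
    tree.write(path)


def label_foreground(tree: LabelledTree, foreground, mode: str = "clade") -> LabelledTree:
    """Functional wrapper around :meth:`LabelledTree.with_labels`."""
    return tree.with_labels(foreground, mode=mode)


def nj_tree(aln) -> LabelledTree:
    """Neighbour-joining tree from codon-level p-distances.

    Distances use pairwise deletion of gapped/ambiguous codon sites; a
    pair with no overlapping resolved sites is an error.  Negative NJ
    branch lengths are clamped to zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as _skbio_nj

    taxa = aln.taxa
    if len(taxa) < 3:
        raise ValueError("neighbour joining needs at least 3 sequences")
    codes = aln.codes
    resolved = codes >= 0
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = resolved[i] & resolved[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no overlapping resolved codon sites between "
                    f"{taxa[i]!r} and {taxa[j]!r}"
                )
            diff = int((codes[i, both] != codes[j, both]).sum())
            d[i, j] = d[j, i] = diff / m
    if n == 3:
        # the unique unrooted topology has a closed-form solution
        a = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
        b = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
        c = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
        a, b, c = (max(x, 0.0) for x in (a, b, c))
        nwk = f"({taxa[0]}:{a:.10g},{taxa[1]}:{b:.10g},{taxa[2]}:{c:.10g});"
        return LabelledTree.from_newick(nwk)
    dm = DistanceMatrix(d, ids=list(taxa))
    tree = _skbio_nj(dm)
    out = LabelledTree.from_newick(str(tree).strip())
    np.clip(out.blen, 0.0, None, out=out.blen)
    return out
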