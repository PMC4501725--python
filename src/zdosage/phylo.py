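"""Distance-based phylogenetics: domain extraction, p-distances,
neighbor-joining, bootstrap supports, and newick serialization.

Trees are unrooted; they are stored rooted at an arbitrary internal
trifurcation (the usual convention for unrooted newick). Splits are
canonicalized against the lexicographically smallest leaf so that two
topologically identical trees produce identical split sets regardless of
their internal rooting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    IncomparablePairError,
    InsufficientDataError,
    InvalidInputError,
    OutOfRangeError,
    ParseError,
)

GAP = "-"

__all__ = [
    "Node",
    "Tree",
    "MsaBlock",
    "DistanceMatrix",
    "extract_domain",
    "p_distance",
    "neighbor_joining",
    "bootstrap",
    "write_newick",
    "read_newick",
    "tree_distance_matrix",
]


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """Tree node. ``length`` is the branch to the parent (ignored at the
    root); ``support`` is a bootstrap percentage on that branch (internal
    edges only)."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Tree:
    root: Node

    def leaves(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, canonicalized (the side not containing
        the smallest leaf name)."""
        all_leaves = frozenset(self.leaf_names())
        if len(all_leaves) != len(self.leaf_names()):
            raise InvalidInputError("duplicate leaf names in tree")
        ref = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node, clade in self._clades():
            if node is self.root or node.is_leaf:
                continue
            if 2 <= len(clade) <= len(all_leaves) - 2:
                side = clade if ref not in clade else all_leaves - clade
                out.add(frozenset(side))
        return out

    def _clades(self) -> list[tuple[Node, frozenset[str]]]:
        result: list[tuple[Node, frozenset[str]]] = []

        def rec(node: Node) -> frozenset[str]:
            if node.is_leaf:
                clade = frozenset([node.name])
            else:
                clade = frozenset().union(*(rec(c) for c in node.children))
            result.append((node, clade))
            return clade

        rec(self.root)
        return result


@dataclass
class MsaBlock:
    """Equal-length aligned amino-acid rows keyed by unique taxa labels."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise InvalidInputError("taxa and rows differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            raise InvalidInputError("duplicate taxa labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise InvalidInputError("aligned rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "MsaBlock":
        """Bootstrap replicate: columns drawn with replacement."""
        ncol = self.n_columns
        cols = rng.integers(0, ncol, size=ncol)
        arr = np.array([list(r) for r in self.rows])
        return MsaBlock(list(self.taxa), ["".join(r) for r in arr[:, cols]])


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InvalidInputError("distance matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("non-finite distances")
        if np.any(self.values < 0):
            raise InvalidInputError("negative distances")
        if not np.allclose(self.values, self.values.T):
            raise InvalidInputError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise InvalidInputError("nonzero diagonal")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_domain(protein: str, window_start: int = 51,
                   window_end: int = 122) -> str:
    """Residues ``window_start..window_end``, 1-based inclusive."""
    if window_start < 1 or window_end < window_start:
        raise OutOfRangeError(
            f"invalid window {window_start}..{window_end}")
    if len(protein) < window_end:
        raise OutOfRangeError(
            f"protein of length {len(protein)} shorter than window end "
            f"{window_end}")
    return protein[window_start - 1:window_end]


def p_distance(msa: MsaBlock) -> DistanceMatrix:
    """Uncorrected p-distance: mismatches / columns where both rows are
    non-gap. A pair with zero comparable columns is an error."""
    if len(msa.taxa) < 2:
        raise InsufficientDataError("need at least 2 taxa")
    n = len(msa.taxa)
    arr = np.array([list(r) for r in msa.rows])
    nongap = arr != GAP
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        comparable = nongap[i] & nongap[j]
        ncomp = int(comparable.sum())
        if ncomp == 0:
            raise IncomparablePairError(
                f"no comparable columns between {msa.taxa[i]!r} and "
                f"{msa.taxa[j]!r}")
        mism = int((arr[i][comparable] != arr[j][comparable]).sum())
        d[i, j] = d[j, i] = mism / ncomp
    return DistanceMatrix(list(msa.taxa), d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Standard NJ agglomeration on the Q-matrix criterion.

    Ties in Q are broken by the smallest (i, j) index pair. Negative limb
    estimates are clamped to zero with the deficit moved to the sister
    limb, so output branch lengths are non-negative. Exact on additive
    matrices.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise InsufficientDataError("neighbor joining needs >= 3 taxa")
    d = dm.values.copy()
    nodes: list[Node] = [Node(name=lbl) for lbl in dm.labels]
    active = list(range(n0))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = np.full((m, m), np.inf)
        flat[iu] = q[iu]
        # row-major argmin = lexicographically smallest tied (i, j)
        ii, jj = np.unravel_index(int(np.argmin(flat)), flat.shape)
        dij = sub[ii, jj]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = dij, 0.0
        elif lj < 0:
            li, lj = dij, 0.0
        gi, gj = active[ii], active[jj]
        new = Node(children=[
            _with_length(nodes[gi], li),
            _with_length(nodes[gj], lj),
        ])
        # distances from the new node to the remaining taxa
        rest = [a for k, a in enumerate(active) if k not in (ii, jj)]
        newdist = 0.5 * (d[gi, rest] + d[gj, rest] - dij)
        newdist = np.maximum(newdist, 0.0)
        gnew = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[gnew, rest] = newdist
        d[rest, gnew] = newdist
        nodes.append(new)
        active = rest + [gnew]

    # final three-point formulas
    x, y, z = active
    lx = max(0.0, (d[x, y] + d[x, z] - d[y, z]) / 2)
    ly = max(0.0, (d[x, y] + d[y, z] - d[x, z]) / 2)
    lz = max(0.0, (d[x, z] + d[y, z] - d[x, y]) / 2)
    root = Node(children=[
        _with_length(nodes[x], lx),
        _with_length(nodes[y], ly),
        _with_length(nodes[z], lz),
    ])
    return Tree(root)


def _with_length(node: Node, length: float) -> Node:
    node.length = float(length)
    return node


def tree_distance_matrix(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances implied by the tree."""
    labels = sorted(tree.leaf_names())
    idx = {lbl: k for k, lbl in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    def rec(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        below: list[dict[str, float]] = []
        for child in node.children:
            sub = rec(child)
            below.append({k: v + child.length for k, v in sub.items()})
        for a, b in itertools.combinations(below, 2):
            for la, da in a.items():
                for lb, db in b.items():
                    d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = da + db
        merged: dict[str, float] = {}
        for sub in below:
            merged.update(sub)
        return merged

    rec(tree.root)
    return DistanceMatrix(labels, d)


def bootstrap(msa: MsaBlock, n_replicates: int = 1000,
              seed: int | None = None) -> Tree:
    """NJ tree on the full alignment with per-internal-edge bootstrap
    supports (percentage of column-resampled replicate trees containing
    the split)."""
    if len(msa.taxa) < 4:
        raise InsufficientDataError("bootstrap needs >= 4 taxa")
    if msa.n_columns < 2:
        raise InsufficientDataError("alignment has < 2 columns")
    if n_replicates < 1:
        raise InvalidInputError("n_replicates must be >= 1")
    full = neighbor_joining(p_distance(msa))
    counts: dict[frozenset[str], int] = {s: 0 for s in full.splits()}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        rep = msa.resample_columns(rng)
        rep_splits = neighbor_joining(p_distance(rep)).splits()
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    # attach supports to internal nodes of the full tree
    all_leaves = frozenset(full.leaf_names())
    ref = min(all_leaves)
    for node, clade in full._clades():
        if node is full.root or node.is_leaf:
            continue
        if 2 <= len(clade) <= len(all_leaves) - 2:
            side = clade if ref not in clade else all_leaves - clade
            node.support = 100.0 * counts[frozenset(side)] / n_replicates
    return full


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def _fmt_float(x: float) -> str:
    return f"{x:.10g}"


def write_newick(tree: Tree) -> str:
    def fmt(node: Node, at_root: bool) -> str:
        if node.is_leaf:
            s = node.name or ""
        else:
            inner = ",".join(fmt(c, False) for c in node.children)
            label = "" if node.support is None else _fmt_float(node.support)
            s = f"({inner}){label}"
        if not at_root:
            s += f":{_fmt_float(node.length)}"
        return s

    return fmt(tree.root, True) + ";"


_LABEL_FORBIDDEN = set("(),:;")


def read_newick(text: str) -> Tree:
    """Parse a newick string. Internal-node labels that parse as numbers
    are taken as bootstrap supports; malformed input raises
    :class:`ParseError` with the offending position."""
    s = text.strip()
    pos = 0

    def peek() -> str:
        return s[pos] if pos < len(s) else ""

    def error(msg: str):
        raise ParseError(msg, position=pos)

    def read_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_FORBIDDEN:
            pos += 1
        return s[start:pos].strip()

    def read_length() -> float:
        nonlocal pos
        if peek() != ":":
            return 0.0
        pos += 1
        start = pos
        while pos < len(s) and (s[pos].isdigit() or s[pos] in ".eE+-"):
            pos += 1
        try:
            return float(s[start:pos])
        except ValueError:
            error(f"bad branch length {s[start:pos]!r}")

    def read_node() -> Node:
        nonlocal pos
        if peek() == "(":
            pos += 1
            children = [read_node()]
            while peek() == ",":
                pos += 1
                children.append(read_node())
            if peek() != ")":
                error("expected ')'")
            pos += 1
            label = read_label()
            node = Node(children=children)
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            label = read_label()
            if not label:
                error("expected a leaf label")
            node = Node(name=label)
        node.length = read_length()
        return node

    if not s:
        raise ParseError("empty newick string", position=0)
    root = read_node()
    if peek() != ";":
        error("expected ';' at end of tree")
    pos += 1
    if pos != len(s):
        error("trailing characters after ';'")
    return Tree(root)
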