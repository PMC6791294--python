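"""Phylogeny and character-data containers, Newick/CSV/NEXUS I/O, and terminal cropping.

Trees are rooted, strictly bifurcating, with branch lengths in relative-time
units (analyses downstream assume the root height is the time unit).  Parsing
and serialisation are delegated to :mod:`dendropy`; internally a flat
array-based representation is used so that likelihood pruning and simulation
can run over contiguous arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "CharacterData",
    "SamplingFractions",
    "read_newick",
    "write_newick",
    "read_states",
    "tree_height",
    "total_length",
    "crop_tree",
]

#: Relative tolerance on root-to-tip depth spread for a tree to count as ultrametric.
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Malformed tree or character input."""


@dataclass
class Phylogeny:
    """Rooted bifurcating tree over ``n_tips`` labelled tips.

    Node ids: tips are ``0 .. n_tips-1`` (in ``tip_labels`` order); internal
    nodes follow; the root is ``root``.  ``children[i]`` holds the two child
    ids of internal node ``i`` (``-1`` for tips); ``blen[root]`` may be 0.
    """

    parent: np.ndarray          # (n_nodes,) int, -1 at root
    children: np.ndarray        # (n_nodes, 2) int, -1 rows for tips
    blen: np.ndarray            # (n_nodes,) float branch length above each node
    tip_labels: list[str]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.children = np.asarray(self.children, dtype=np.int64)
        self.blen = np.asarray(self.blen, dtype=np.float64)
        n = self.n_nodes
        if self.children.shape != (n, 2) or self.blen.shape != (n,):
            raise TreeError("inconsistent array shapes")
        if len(self.tip_labels) != self.n_tips:
            raise TreeError("tip label count does not match tip count")
        if len(set(self.tip_labels)) != self.n_tips:
            raise TreeError("duplicate tip labels")
        if self.n_tips < 2:
            raise TreeError("tree must have at least 2 tips (not bifurcating)")
        if np.any(self.blen < 0):
            raise TreeError("negative branch length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError("tree must have exactly one root")
        self._root = int(roots[0])
        # strict bifurcation: internal nodes have exactly two valid children
        internal = self.children[self.n_tips:]
        if internal.size and np.any(internal < 0):
            raise TreeError("internal node without two children (not bifurcating)")

    # -- basic structure -------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def root(self) -> int:
        return self._root

    def postorder(self) -> np.ndarray:
        """Node ids, children always before parents."""
        order = np.empty(self.n_nodes, dtype=np.int64)
        stack = [self.root]
        k = self.n_nodes
        while stack:  # reverse preorder == postorder for our purposes
            v = stack.pop()
            k -= 1
            order[k] = v
            if v >= self.n_tips:
                stack.append(int(self.children[v, 0]))
                stack.append(int(self.children[v, 1]))
        return order

    def depths(self) -> np.ndarray:
        """Distance from the root to every node (root depth 0)."""
        d = np.zeros(self.n_nodes)
        for v in self.postorder()[::-1]:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.blen[v]
        return d

    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    def total_length(self) -> float:
        mask = self.parent >= 0
        return float(self.blen[mask].sum())

    def terminal_lengths(self) -> np.ndarray:
        return self.blen[: self.n_tips].copy()

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.depths()[: self.n_tips]
        h = d.max()
        return bool(h > 0 and (d.max() - d.min()) <= rtol * h)

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise TreeError(f"tip not found: {label!r}") from None

    def subtree_tips(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n_tips:
                out.append(v)
            else:
                stack.extend(int(c) for c in self.children[v])
        return out

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), self.children.copy(),
                         self.blen.copy(), list(self.tip_labels))

    # -- dendropy bridge -------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else (lf.label or "") for lf in leaves]
        if any(not lb for lb in labels):
            raise TreeError("unlabelled tip")
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")
        n_tips = len(labels)
        ids: dict[int, int] = {}
        for i, lf in enumerate(leaves):
            ids[id(lf)] = i
        k = n_tips
        internals = []
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                continue
            nch = len(nd.child_nodes())
            if nch != 2:
                raise TreeError(f"non-bifurcating node with {nch} children")
            ids[id(nd)] = k
            internals.append(nd)
            k += 1
        n = k
        parent = np.full(n, -1, dtype=np.int64)
        children = np.full((n, 2), -1, dtype=np.int64)
        blen = np.zeros(n)
        for nd in tree.preorder_node_iter():
            v = ids[id(nd)]
            blen[v] = nd.edge.length if nd.edge.length is not None else 0.0
            for j, ch in enumerate(nd.child_nodes()):
                children[v, j] = ids[id(ch)]
                parent[ids[id(ch)]] = v
        return cls(parent, children, blen, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for v in self.postorder():
            nd = dendropy.Node()
            nd.edge.length = float(self.blen[v])
            if v < self.n_tips:
                nd.taxon = taxa.get_taxon(self.tip_labels[v])
            else:
                nd.add_child(nodes[int(self.children[v, 0])])
                nd.add_child(nodes[int(self.children[v, 1])])
            nodes[v] = nd
        tree.seed_node = nodes[self.root]
        return tree


@dataclass
class CharacterData:
    """Binary character: tip label -> state, 0 (bee syndrome) or 1 (hummingbird)."""

    states: dict[str, int]

    def __post_init__(self) -> None:
        if not self.states:
            raise TreeError("empty character table")
        bad = {v for v in self.states.values() if v not in (0, 1)}
        if bad:
            raise TreeError(f"states must be 0 or 1, got {sorted(bad)}")

    def __getitem__(self, label: str) -> int:
        return self.states[label]

    def __len__(self) -> int:
        return len(self.states)

    def counts(self) -> tuple[int, int]:
        n1 = sum(self.states.values())
        return len(self.states) - n1, n1

    def proportion_state1(self) -> float:
        return sum(self.states.values()) / len(self.states)

    def as_array(self, tree: Phylogeny) -> np.ndarray:
        """Tip states in the tree's tip order; errors on missing tips."""
        missing = [lb for lb in tree.tip_labels if lb not in self.states]
        if missing:
            raise TreeError(f"tips missing from character table: {missing[:5]}")
        return np.array([self.states[lb] for lb in tree.tip_labels], dtype=np.int64)

    def validate_against(self, tree: Phylogeny) -> None:
        self.as_array(tree)


@dataclass(frozen=True)
class SamplingFractions:
    """Proportion of extant species of each state present in the tree."""

    f0: float = 0.83
    f1: float = 0.79

    def __post_init__(self) -> None:
        for f in (self.f0, self.f1):
            if not (0.0 < f <= 1.0):
                raise ValueError(f"sampling fractions must be in (0, 1], got {f}")


# ---------------------------------------------------------------------------
# I/O

def read_newick(text: str) -> Phylogeny:
    """Parse a rooted Newick string (quoted labels and E-notation lengths accepted)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse error: {exc}") from exc
    return Phylogeny.from_dendropy(tree)


def write_newick(tree: Phylogeny) -> str:
    """Serialise to Newick with 12-significant-digit branch lengths."""
    dt = tree.to_dendropy()
    # labels with spaces/periods come out quoted; plain labels stay unquoted
    s = dt.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
        preserve_spaces=True,
    )
    return s.strip()


def read_states(source: str) -> CharacterData:
    """Read a binary character table from CSV text/path or a NEXUS characters block.

    CSV: two columns (taxon, state), with or without a header row.
    NEXUS: a standard characters/data block with 0/1 symbols.
    """
    text = source
    if "\n" not in source and not source.lstrip().startswith("#"):
        # looks like a path
        with open(source) as fh:
            text = fh.read()
    if text.lstrip().upper().startswith("#NEXUS"):
        return _read_states_nexus(text)
    return _read_states_csv(text)


def _read_states_csv(text: str) -> CharacterData:
    import io

    df = pd.read_csv(io.StringIO(text), header=None, dtype=str,
                     skipinitialspace=True, comment="#")
    if df.empty:
        raise TreeError("empty character table")
    if df.shape[1] < 2:
        raise TreeError("character table needs two columns: taxon,state")
    # tolerate a header row like "taxon,state"
    if not df.iloc[0, 1].strip() in ("0", "1"):
        df = df.iloc[1:]
        if df.empty:
            raise TreeError("empty character table")
    states: dict[str, int] = {}
    for _, row in df.iterrows():
        label, raw = str(row.iloc[0]).strip(), str(row.iloc[1]).strip()
        if raw not in ("0", "1"):
            raise TreeError(f"unknown state symbol {raw!r} for taxon {label!r}")
        if label in states:
            raise TreeError(f"duplicate taxon in character table: {label!r}")
        states[label] = int(raw)
    return CharacterData(states)


def _read_states_nexus(text: str) -> CharacterData:
    try:
        mat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:
        raise TreeError(f"NEXUS parse error: {exc}") from exc
    states: dict[str, int] = {}
    for taxon in mat:
        symb = str(mat[taxon][0].symbol)
        if symb not in ("0", "1"):
            raise TreeError(f"unknown state symbol {symb!r} for taxon {taxon.label!r}")
        states[taxon.label] = int(symb)
    if not states:
        raise TreeError("empty character table")
    return CharacterData(states)


def tree_height(tree: Phylogeny) -> float:
    """Maximum root-to-tip path length."""
    return tree.height()


def total_length(tree: Phylogeny) -> float:
    """Sum of all branch lengths."""
    return tree.total_length()


# ---------------------------------------------------------------------------
# Terminal cropping

def crop_tree(
    tree: Phylogeny,
    reduction: float,
    states: CharacterData,
    rtol: float = 1e-9,
    max_iter: int = 200,
) -> tuple[Phylogeny, CharacterData]:
    """Truncate every lineage at a common slice depth so total length drops by ``reduction``.

    The slice depth ``s`` is found by bisection (truncated length is monotone
    in ``s``).  Clades whose crown age is more recent than ``s`` collapse to a
    single tip carrying the shared state of their members; a mixed-state
    collapse is an error.
    """
    if not (0.0 <= reduction < 1.0):
        raise TreeError(f"reduction must be in [0, 1), got {reduction}")
    if not tree.is_ultrametric():
        raise TreeError("crop_tree requires an ultrametric tree")
    states.validate_against(tree)
    if reduction == 0.0:
        return tree.copy(), CharacterData(dict(states.states))

    depths = tree.depths()
    height = float(depths[: tree.n_tips].max())
    L0 = tree.total_length()
    target = (1.0 - reduction) * L0

    pd_ = depths[tree.parent]          # parent depth per node (root: garbage, masked)
    has_parent = tree.parent >= 0

    def sliced_length(s: float) -> float:
        top = np.minimum(pd_, s)
        bot = np.minimum(depths, s)
        seg = np.where(has_parent, np.maximum(bot - top, 0.0), 0.0)
        return float(seg.sum())

    lo, hi = 0.0, height
    if sliced_length(hi) < target:  # pragma: no cover - cannot happen for reduction>0
        raise TreeError("reduction infeasible")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if sliced_length(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-15 * height:
            break
    s = 0.5 * (lo + hi)
    if abs(sliced_length(s) - target) > max(rtol * L0, 1e-12):
        raise TreeError("cropping bisection failed to reach the target length")

    # lineages crossing the slice: edges with parent above s and child at/below s
    crossing = [
        int(v) for v in range(tree.n_nodes)
        if has_parent[v] and depths[tree.parent[v]] < s <= depths[v]
    ]
    if len(crossing) < 2:
        raise TreeError("reduction infeasible: fewer than 2 lineages at slice depth")

    new_labels: list[str] = []
    new_states: dict[str, int] = {}
    cross_id: dict[int, int] = {}
    for i, v in enumerate(sorted(crossing)):
        members = tree.subtree_tips(v)
        member_states = {states[tree.tip_labels[t]] for t in members}
        if len(member_states) > 1:
            labels = [tree.tip_labels[t] for t in members]
            raise TreeError(f"collapsed group mixes states: {labels}")
        label = tree.tip_labels[min(members)]
        cross_id[v] = i
        new_labels.append(label)
        new_states[label] = member_states.pop()

    n_new_tips = len(new_labels)
    keep_internal = [
        int(v) for v in range(tree.n_tips, tree.n_nodes) if depths[v] < s
    ]
    node_id = dict(cross_id)
    for j, v in enumerate(keep_internal):
        node_id[v] = n_new_tips + j
    n_new = n_new_tips + len(keep_internal)
    parent = np.full(n_new, -1, dtype=np.int64)
    children = np.full((n_new, 2), -1, dtype=np.int64)
    blen = np.zeros(n_new)
    for v_old, v_new in node_id.items():
        p_old = int(tree.parent[v_old])
        if v_old in cross_id:
            blen[v_new] = s - depths[p_old]
        else:
            blen[v_new] = float(tree.blen[v_old])
        if p_old >= 0 and p_old in node_id:
            p_new = node_id[p_old]
            parent[v_new] = p_new
            slot = 0 if children[p_new, 0] < 0 else 1
            children[p_new, slot] = v_new
    cropped = Phylogeny(parent, children, blen, new_labels)
    return cropped, CharacterData(new_states)
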