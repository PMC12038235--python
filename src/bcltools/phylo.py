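"""MybA gene trees: Tamura-Nei distances, UPGMA, bootstrap support.

The tree protocol mirrors how the MybA cluster phylogenies are built in
practice: pairwise TN93 distances on the ungapped shared columns of a
nucleotide alignment, UPGMA clustering, bootstrap resampling of alignment
columns (default 1000 replicates), per-clade support on the point-estimate
tree, collapse of branches under 90% support, and rooting on an outgroup
(the Arabidopsis MYB75 anthocyanin regulator in the original analyses).

Trees are :class:`skbio.TreeNode` objects; integer support values are kept
both on ``node.support`` and, for Newick serialization, as internal node
names.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skbio import TreeNode

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINE = (0, 2)  # A, G


@dataclass
class DistanceMatrix:
    """Symmetric evolutionary distance matrix (substitutions/site).

    Saturated pairs are +inf (never silently clipped), which the stock
    containers refuse; hence this light wrapper.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        if not np.array_equal(v, v.T):
            raise ValueError("matrix must be symmetric")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")

    def __getitem__(self, pair):
        a, b = pair
        return self.values[self.labels.index(a), self.labels.index(b)]


def _encode(alignment: Mapping[str, str]):
    labels = list(alignment)
    length = len(next(iter(alignment.values())))
    if any(len(s) != length for s in alignment.values()):
        raise ValueError("ragged alignment")
    arr = np.full((len(labels), length), 4, dtype=np.int8)
    for i, name in enumerate(labels):
        for j, ch in enumerate(alignment[name].upper()):
            arr[i, j] = _CODE.get(ch, 4)
    return labels, arr


def _tn93_pair(x: np.ndarray, y: np.ndarray) -> float:
    """TN93 distance for one encoded sequence pair (complete deletion of
    gapped/ambiguous columns within the pair)."""
    ok = (x < 4) & (y < 4)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no shared ungapped columns")
    xs, ys = x[ok], y[ok]
    both = np.concatenate([xs, ys])
    freqs = np.bincount(both, minlength=4) / (2 * n)
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    diff = xs != ys
    x_pur = (xs == 0) | (xs == 2)
    y_pur = (ys == 0) | (ys == 2)
    p1 = float(np.sum(diff & x_pur & y_pur)) / n       # A<->G transitions
    p2 = float(np.sum(diff & ~x_pur & ~y_pur)) / n     # C<->T transitions
    q = float(np.sum(diff & (x_pur != y_pur))) / n     # transversions
    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0
    k1 = 2 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2 * gC * gT / gY if gY > 0 else 0.0
    k3 = 2 * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0.0)
              - (gC * gT * gR / gY if gY > 0 else 0.0))
    terms = []
    for k, num in ((k1, p1 / k1 + q / (2 * gR) if k1 > 0 else None),
                   (k2, p2 / k2 + q / (2 * gY) if k2 > 0 else None)):
        if num is None:
            if (k is k1 and p1 > 0) or (k is k2 and p2 > 0):
                return np.inf  # transitions observed but term undefined
            continue
        arg = 1.0 - num
        if arg <= 0:
            return np.inf
        terms.append(-k * np.log(arg))
    if k3 > 0:
        arg = 1.0 - q / (2 * gR * gY) if gR > 0 and gY > 0 else -1.0
        if arg <= 0:
            return np.inf
        terms.append(-k3 * np.log(arg))
    elif q > 0:
        return np.inf
    return float(sum(terms))


def tamura_nei_distance(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise TN93 distances; saturated pairs become +inf with a
    warning."""
    labels, arr = _encode(alignment)
    if len(labels) < 2:
        raise ValueError("need at least two sequences")
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _tn93_pair(arr[i], arr[j])
            if not np.isfinite(d):
                logger.warning("saturated TN93 distance for pair (%s, %s)",
                               labels[i], labels[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration; node heights are half the merge
    distance, so the output is ultrametric.  Ties are broken by the
    lexicographically smallest pair of cluster representatives (the
    sorted tuple of member labels), making the tree deterministic.
    """
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("UPGMA requires finite distances")
    clusters: dict[int, dict] = {}
    for i, label in enumerate(dm.labels):
        node = TreeNode(name=label)
        node.support = None
        clusters[i] = {"node": node, "height": 0.0, "size": 1,
                       "rep": (label,)}
    dist = {}
    for i in range(len(dm.labels)):
        for j in range(i + 1, len(dm.labels)):
            dist[(i, j)] = float(dm.values[i, j])
    next_id = len(dm.labels)
    while len(clusters) > 1:
        best = min(dist, key=lambda ij: (dist[ij],
                                         tuple(sorted((clusters[ij[0]]["rep"],
                                                       clusters[ij[1]]["rep"])))))
        i, j = best
        d = dist[best]
        height = d / 2.0
        ci, cj = clusters.pop(i), clusters.pop(j)
        for child in (ci, cj):
            child["node"].length = height - child["height"]
        parent = TreeNode(children=[ci["node"], cj["node"]])
        parent.support = None
        merged = {"node": parent, "height": height,
                  "size": ci["size"] + cj["size"],
                  "rep": tuple(sorted(ci["rep"] + cj["rep"]))}
        for k in list(clusters):
            dik = dist.pop(tuple(sorted((i, k))))
            djk = dist.pop(tuple(sorted((j, k))))
            dist[tuple(sorted((next_id, k)))] = (
                (ci["size"] * dik + cj["size"] * djk) / merged["size"])
        del dist[best]
        clusters[next_id] = merged
        next_id += 1
    root = next(iter(clusters.values()))["node"]
    root.length = None
    return root


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = [tip.accumulate_to_ancestor(tree) for tip in tree.tips()]
    return max(depths) - min(depths) <= tol


# ---------------------------------------------------------------------------
# Bootstrap support, collapse, rooting
# ---------------------------------------------------------------------------

def _clades(tree: TreeNode) -> set[frozenset]:
    out = set()
    for node in tree.non_tips(include_self=False):
        out.add(frozenset(t.name for t in node.tips()))
    return out


def bootstrap_consensus(alignment: Mapping[str, str], n_reps: int = 1000,
                        collapse_threshold: float = 90.0,
                        outgroup_label: str | None = None,
                        seed: int = 0) -> TreeNode:
    """UPGMA/TN93 tree with bootstrap supports, weak branches collapsed.

    Columns are resampled with replacement ``n_reps`` times; the support
    of each internal branch of the point-estimate tree is the percentage
    of replicate trees containing the same clade.  Branches under
    ``collapse_threshold`` are collapsed into polytomies (their length is
    absorbed into the children, preserving tip heights); the tree is then
    rooted on the outgroup edge.
    """
    labels, arr = _encode(alignment)
    if outgroup_label is not None and outgroup_label not in labels:
        raise ValueError(f"outgroup {outgroup_label!r} not in alignment")
    tree = upgma(tamura_nei_distance(alignment))
    target = {frozenset(t.name for t in node.tips()): node
              for node in tree.non_tips(include_self=False)}
    hits = {clade: 0 for clade in target}
    rng = np.random.default_rng(seed)
    n_cols = arr.shape[1]
    n = len(labels)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = arr[:, cols]
        values = np.zeros((n, n))
        try:
            for i in range(n):
                for j in range(i + 1, n):
                    values[i, j] = values[j, i] = _tn93_pair(rep[i], rep[j])
            rep_tree = upgma(DistanceMatrix(labels, values))
        except ValueError:
            continue  # saturated replicate: contributes no support
        rep_clades = _clades(rep_tree)
        for clade in hits:
            if clade in rep_clades:
                hits[clade] += 1
    for clade, node in target.items():
        node.support = round(100.0 * hits[clade] / n_reps, 1)
        node.name = str(int(round(node.support)))

    def weak(node):
        return (not node.is_tip() and not node.is_root()
                and node.support is not None
                and node.support < collapse_threshold)

    tree.unpack_by_func(weak)
    if outgroup_label is not None:
        out_tip = next(t for t in tree.tips() if t.name == outgroup_label)
        if out_tip.parent is not tree:
            tree = tree.root_by_outgroup([outgroup_label])
    return tree


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode) -> str:
    """Newick with branch lengths and integer support labels on internal
    nodes."""

    def emit(node: TreeNode) -> str:
        if node.is_tip():
            core = node.name or ""
        else:
            support = getattr(node, "support", None)
            label = (str(int(round(support))) if support is not None
                     else (node.name or ""))
            core = "(" + ",".join(emit(c) for c in node.children) + ")" + label
        if node.length is not None:
            core += f":{node.length:.10g}"
        return core

    return emit(tree) + ";"


def read_newick(text: str) -> TreeNode:
    tree = TreeNode.read(io.StringIO(text))
    for node in tree.traverse():
        support = None
        if not node.is_tip() and node.name is not None:
            try:
                support = float(node.name)
            except ValueError:
                support = None
        node.support = support
    return tree


def trees_equal(a: TreeNode, b: TreeNode, tol: float = 1e-9) -> bool:
    """Topology, branch lengths and supports equal (used for round-trip
    checks; polytomies compare exactly)."""
    if _clades(a) != _clades(b):
        return False
    if {t.name for t in a.tips()} != {t.name for t in b.tips()}:
        return False

    def node_map(tree):
        out = {}
        for node in tree.traverse(include_self=False):
            key = frozenset(t.name for t in node.tips())
            out[key] = node
        return out

    ma, mb = node_map(a), node_map(b)
    if set(ma) != set(mb):
        return False
    for key, na in ma.items():
        nb = mb[key]
        la = na.length if na.length is not None else 0.0
        lb = nb.length if nb.length is not None else 0.0
        if abs(la - lb) > tol:
            return False
        sa, sb = getattr(na, "support", None), getattr(nb, "support", None)
        if (sa is None) != (sb is None):
            return False
        if sa is not None and abs(round(sa) - round(sb)) > 0:
            return False
    return True
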