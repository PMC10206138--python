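"""Distance-based phylogenetics of receptor coding sequences.

Pairwise evolutionary distances on a supplied multiple alignment -
Tamura 3-parameter for nucleotides (corrects for transition/transversion
bias and G+C content), p-distance for proteins - with pairwise deletion
of gapped or ambiguous sites, neighbor-joining tree construction,
nonparametric bootstrap with per-branch support and a strict majority
consensus, outgroup rooting, and newick output.

The Tamura-3 distance for a sequence pair with transition proportion P,
transversion proportion Q and pooled G+C content theta is

    d = -h ln(1 - P/h - Q) - (1/2)(1 - h) ln(1 - 2Q),   h = 2 theta (1 - theta).

With theta = 1/2 this reduces to the Kimura two-parameter distance and,
when additionally transitions occur at twice the transversion rate per
site class, to Jukes-Cantor.  Saturated pairs (logarithm argument <= 0)
are flagged undefined; neighbor joining refuses such matrices rather
than imputing values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

NT_VALID = set("ACGT")
AA_VALID = set("ACDEFGHIKLMNPQRSTVWY")
PURINES = set("AG")
PYRIMIDINES = set("CT")


@dataclass
class Msa:
    labels: list
    rows: list
    alphabet: str = "nucleotide"   # nucleotide | amino_acid

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path, alphabet: str = "nucleotide") -> "Msa":
        from Bio import SeqIO

        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq))
        return cls(labels, rows, alphabet)

    def resample_sites(self, site_index: Sequence[int]) -> "Msa":
        rows = ["".join(r[i] for i in site_index) for r in self.rows]
        return Msa(self.labels, rows, self.alphabet)


@dataclass
class SitePairCounts:
    n_usable: int
    P: float = 0.0
    Q: float = 0.0
    theta: float = 0.0

    @property
    def h(self) -> float:
        return 2.0 * self.theta * (1.0 - self.theta)


def pairwise_deletion_mask(row_i: str, row_j: str,
                           alphabet: str = "nucleotide") -> list[int]:
    """Indices of sites usable for a pair: both symbols unambiguous and
    ungapped (A/C/G/T for nucleotides, the 20 standard residues for
    proteins)."""
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    valid = NT_VALID if alphabet == "nucleotide" else AA_VALID
    return [k for k, (a, b) in enumerate(zip(row_i.upper(), row_j.upper()))
            if a in valid and b in valid]


def tamura3_distance(row_i: str, row_j: str
                     ) -> tuple[float, SitePairCounts]:
    """Tamura 3-parameter distance for one pair (pairwise deletion).

    theta is the G+C fraction of the usable sites of both sequences
    pooled.  Returns (distance, counts); the distance is NaN when no
    sites are usable or a logarithm argument is non-positive.
    """
    mask = pairwise_deletion_mask(row_i, row_j, "nucleotide")
    n = len(mask)
    if n == 0:
        return float("nan"), SitePairCounts(0)
    ts = tv = gc = 0
    for k in mask:
        a, b = row_i[k].upper(), row_j[k].upper()
        gc += (a in "GC") + (b in "GC")
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    theta = gc / (2 * n)
    counts = SitePairCounts(n_usable=n, P=P, Q=Q, theta=theta)
    h = counts.h
    arg2 = 1.0 - 2.0 * Q
    if arg2 <= 0:
        return float("nan"), counts
    if h == 0.0:
        if P > 0:
            return float("nan"), counts
        return -0.5 * math.log(arg2), counts
    arg1 = 1.0 - P / h - Q
    if arg1 <= 0:
        return float("nan"), counts
    d = -h * math.log(arg1) - 0.5 * (1.0 - h) * math.log(arg2)
    return d, counts


def p_distance(row_i: str, row_j: str,
               alphabet: str = "amino_acid") -> float:
    """Proportion of differing sites among pairwise-usable sites."""
    mask = pairwise_deletion_mask(row_i, row_j, alphabet)
    if not mask:
        return float("nan")
    diffs = sum(row_i[k].upper() != row_j[k].upper() for k in mask)
    return diffs / len(mask)


@dataclass
class DistanceMatrix:
    labels: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    @property
    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.matrix[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(str(len(self.labels)) + "\n")
            for label, row in zip(self.labels, self.matrix):
                fh.write(label + "\t"
                         + "\t".join(f"{x:.6f}" for x in row) + "\n")


def distance_matrix(msa: Msa, kind: str = "tamura3") -> DistanceMatrix:
    n = len(msa.labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if kind == "tamura3":
                d, _ = tamura3_distance(msa.rows[i], msa.rows[j])
            elif kind == "p":
                d = p_distance(msa.rows[i], msa.rows[j], msa.alphabet)
            else:
                raise ValueError(f"unknown distance kind: {kind}")
            m[i, j] = m[j, i] = d
    return DistanceMatrix(msa.labels, m)


# --- trees ------------------------------------------------------------------

@dataclass
class Node:
    label: str = ""
    length: float = 0.0
    support: Optional[int] = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> frozenset:
        return frozenset(n.label for n in self.leaves())


@dataclass
class PhyloTree:
    root: Node

    @property
    def leaf_labels(self) -> frozenset:
        return self.root.leaf_labels()

    def bipartitions(self) -> dict:
        """Non-trivial splits of the (unrooted) tree, each normalized to
        the side not containing the alphabetically first leaf; maps
        split -> the Node whose subtree realizes it."""
        all_leaves = self.leaf_labels
        ref = min(all_leaves)
        out = {}
        def walk(node):
            for child in node.children:
                walk(child)
            if node is self.root:
                return
            side = node.leaf_labels()
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out[side] = node
        walk(self.root)
        return out

    def path_lengths(self) -> dict:
        """Leaf-to-leaf path-length metric implied by the branch lengths."""
        dists = {}
        def walk(node):
            if node.is_leaf:
                return {node.label: node.length}
            acc = {}
            for child in node.children:
                sub = walk(child)
                for la, da in acc.items():
                    for lb, db in sub.items():
                        key = (min(la, lb), max(la, lb))
                        dists[key] = da + db
                acc.update(sub)
            for label in acc:
                acc[label] += node.length
            return acc
        walk(self.root)
        return dists


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration with the Q criterion.

    Ties are broken by the lexicographically smallest pair of cluster
    representative labels (the alphabetically first leaf of each
    cluster), so the result is deterministic under taxon permutation.
    Negative branch lengths are clamped to zero.  Matrices with
    undefined entries are refused.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if dm.undefined_pairs:
        raise ValueError(
            "distance matrix has undefined entries; drop these taxa first: "
            f"{dm.undefined_pairs}")
    nodes = [Node(label=l) for l in dm.labels]
    reps = list(dm.labels)
    D = dm.matrix.astype(float).copy()

    def clamp(x):
        return x if x > 0 else 0.0

    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * D[i, j] - R[i] - R[j]
                pair = (min(reps[i], reps[j]), max(reps[i], reps[j]))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2 * (len(nodes) - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = clamp(li)
        child_j.length = clamp(lj)
        new = Node(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.zeros((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]
        D = D2

    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        nodes[0].length = clamp(0.5 * (d01 + d02 - d12))
        nodes[1].length = clamp(0.5 * (d01 + d12 - d02))
        nodes[2].length = clamp(0.5 * (d02 + d12 - d01))
        root = Node(children=list(nodes))
    else:
        nodes[0].length = nodes[1].length = clamp(D[0, 1] / 2)
        root = Node(children=list(nodes))
    return PhyloTree(root)


@dataclass
class BootstrapResult:
    tree: PhyloTree                    # full-data tree with supports
    consensus: Optional[PhyloTree]     # strict >50% majority-rule tree
    n_replicates: int
    n_dropped: int
    split_counts: dict


def bootstrap_support(msa: Msa, n_reps: int, seed: int,
                      distance_kind: str = "tamura3",
                      consensus: bool = False) -> BootstrapResult:
    """Nonparametric bootstrap over alignment sites.

    Replicate r resamples sites with the RNG stream ``seed + r``; each
    internal branch of the full-data tree is annotated with the
    percentage of accepted replicates containing the same bipartition.
    Replicates with undefined distances are dropped and counted.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = neighbor_joining(distance_matrix(msa, distance_kind))
    counts: dict = {}
    dropped = 0
    L = msa.n_sites
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        sites = rng.integers(0, L, size=L)
        rep = msa.resample_sites(sites)
        dm = distance_matrix(rep, distance_kind)
        if dm.undefined_pairs:
            dropped += 1
            continue
        tree = neighbor_joining(dm)
        for split in tree.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    accepted = n_reps - dropped
    for split, node in full.bipartitions().items():
        node.support = round(100.0 * counts.get(split, 0) / max(accepted, 1))
    cons = None
    if consensus:
        cons = majority_consensus(counts, accepted, full.leaf_labels)
    return BootstrapResult(tree=full, consensus=cons, n_replicates=n_reps,
                           n_dropped=dropped, split_counts=counts)


def majority_consensus(split_counts: dict, n_accepted: int,
                       leaf_labels: frozenset) -> PhyloTree:
    """Strict majority-rule consensus: splits in more than half of the
    replicates (mutually compatible by construction) assembled into a
    tree with supports and no branch lengths."""
    majority = [(s, c) for s, c in split_counts.items()
                if c / max(n_accepted, 1) > 0.5]
    majority.sort(key=lambda sc: (-len(sc[0]), sorted(sc[0])))
    leaf_nodes = {l: Node(label=l) for l in sorted(leaf_labels)}
    root = Node(children=list(leaf_nodes.values()))
    parents = {id(c): root for c in root.children}
    subtree_leafsets = {id(c): frozenset([c.label]) for c in root.children}

    def node_leafset(node):
        if node.is_leaf:
            return frozenset([node.label])
        return frozenset().union(*(node_leafset(c) for c in node.children))

    for split, count in majority:
        # the split may be stored as either side; use the side that is a
        # proper subtree candidate under the current root
        for side in (split, leaf_labels - split):
            host = root
            moved = [c for c in host.children
                     if node_leafset(c) <= side]
            while True:
                deeper = None
                for c in host.children:
                    ls = node_leafset(c)
                    if side < ls:
                        deeper = c
                        break
                if deeper is None:
                    break
                host = deeper
                moved = [c for c in host.children if node_leafset(c) <= side]
            covered = frozenset().union(
                *(node_leafset(c) for c in moved)) if moved else frozenset()
            if covered == side and len(moved) >= 2:
                new = Node(children=moved,
                           support=round(100.0 * count / max(n_accepted, 1)))
                host.children = [c for c in host.children
                                 if c not in moved] + [new]
                break
    return PhyloTree(root)


def root_tree(tree: PhyloTree, outgroup_labels: Iterable[str]) -> PhyloTree:
    """Root on the branch separating the outgroup from the ingroup.

    The outgroup must form a clade in the unrooted tree; otherwise a
    ValueError names the offending taxon set.  The separating branch is
    split evenly and its support is carried to both root children.
    """
    outgroup = frozenset(outgroup_labels)
    all_leaves = tree.leaf_labels
    if not outgroup or outgroup == all_leaves:
        raise ValueError("outgroup must be a proper non-empty subset of taxa")
    missing = outgroup - all_leaves
    if missing:
        raise ValueError(f"outgroup labels not in tree: {sorted(missing)}")

    if len(outgroup) == 1:
        label = next(iter(outgroup))
        target = next(n for n in tree.root.leaves() if n.label == label)
    else:
        ref = min(all_leaves)
        want = (all_leaves - outgroup if ref in outgroup else outgroup)
        target = tree.bipartitions().get(want)
        if target is not None and target.leaf_labels() != outgroup:
            # stored side is the ingroup; rerooting on that edge is the same
            pass
        if target is None:
            raise ValueError(
                "outgroup is not monophyletic in the unrooted tree; "
                f"no branch separates {sorted(outgroup)}")

    # re-root on the parent edge of `target` using an undirected view
    parent_of = {}
    def index(node):
        for c in node.children:
            parent_of[id(c)] = node
            index(c)
    index(tree.root)

    def rebuild_away(node, come_from):
        """Subtree of `node` looking away from `come_from`."""
        kids = [c for c in node.children if c is not come_from]
        parent = parent_of.get(id(node))
        new = Node(label=node.label, support=node.support)
        for c in kids:
            sub = rebuild_away(c, node)
            sub.length = c.length
            new.children.append(sub)
        if parent is not None and parent is not come_from:
            up = rebuild_away(parent, node)
            up.length = node.length
            up.support = node.support
            new.children.append(up)
        return new

    out_side = rebuild_away(target, parent_of[id(target)])
    in_side = rebuild_away(parent_of[id(target)], target)
    half = target.length / 2.0
    out_side.length = half
    in_side.length = half
    out_side.support = target.support
    in_side.support = target.support
    return PhyloTree(Node(children=[out_side, in_side]))


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, path=None,
                 include_lengths: bool = True) -> str:
    """Serialize with branch lengths and integer supports as internal
    node labels; labels containing newick metacharacters are quoted."""
    def fmt(node):
        if node.is_leaf:
            s = _quote_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.support is not None:
                s += str(int(node.support))
        if include_lengths:
            s += f":{node.length:g}"
        return s
    text = ("(" + ",".join(fmt(c) for c in tree.root.children) + ")"
            + (str(int(tree.root.support))
               if tree.root.support is not None else "") + ";")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
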