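"""Alignment-free phylogenetics and tree-comparison statistics.

Feature frequency profiles (FFP) summarise a sequence as counts of its
length-L words (L = 20 by default, suited to whole phage genomes); profile
divergence is Jensen-Shannon, the standard choice in the FFP literature.
Trees are inferred by neighbor joining (via dendropy) and can be
bootstrapped into a 50% majority-rule consensus.

Two statistics compare trees with cluster structure in mind:

* Matching Splits — minimum-cost perfect matching between the non-trivial
  bipartition sets of two trees, with the percent-of-star normalisation
  used to express "how different" two phylogenies are.
* gsi (genealogical sorting index) — degree of exclusive ancestry of a
  labelled group, 1 exactly when the group is monophyletic.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import linear_sum_assignment

from .seqcore import CONCRETE_BASES, LabelTable, SeqRecord


@dataclass
class FFProfile:
    """Word counts of one sequence at fixed feature length L.

    ``total`` is the number of counted windows; windows containing a
    non-ACGT character are skipped (ambiguity does not invent features).
    """

    sequence_id: str
    feature_length: int
    counts: dict[str, int]
    total: int


def ffp_profile(s: SeqRecord | str, feature_length: int = 20) -> FFProfile:
    """Sliding-window exact word counts of a nucleotide sequence."""
    sid = s.id if isinstance(s, SeqRecord) else "seq"
    seq = s.residues if isinstance(s, SeqRecord) else s
    L = feature_length
    if L < 1:
        raise ValueError("feature length must be >= 1")
    if len(seq) < L:
        raise ValueError(f"sequence {sid!r} shorter than feature length {L}")
    counts: dict[str, int] = {}
    total = 0
    # incremental validity scan: word is counted iff all L bases are concrete
    bad = [c not in CONCRETE_BASES for c in seq]
    bad_run = sum(bad[:L])
    for i in range(len(seq) - L + 1):
        if i > 0:
            bad_run += bad[i + L - 1] - bad[i - 1]
        if bad_run == 0:
            w = seq[i : i + L]
            counts[w] = counts.get(w, 0) + 1
            total += 1
    return FFProfile(sid, L, counts, total)


def ffp_distance(p: FFProfile, q: FFProfile) -> float:
    """Jensen-Shannon divergence (nats) between normalized profiles.

    0 iff the normalized profiles coincide; ln 2 for disjoint feature sets.
    Computed over shared features plus the disjoint mass, which keeps the
    cost proportional to the (typically small) intersection.
    """
    if p.feature_length != q.feature_length:
        raise ValueError("profiles have different feature lengths")
    if p.total == 0 or q.total == 0:
        raise ValueError("empty profile")
    ln2 = math.log(2.0)
    if p.counts.keys() == q.counts.keys() and all(
        p.counts[w] * q.total == q.counts[w] * p.total for w in p.counts
    ):
        return 0.0  # identical normalized profiles, exactly
    shared = p.counts.keys() & q.counts.keys()
    sp = sq = 0.0
    acc = 0.0
    for w in shared:
        pw = p.counts[w] / p.total
        qw = q.counts[w] / q.total
        m = 0.5 * (pw + qw)
        acc += 0.5 * (pw * math.log(pw / m) + qw * math.log(qw / m))
        sp += pw
        sq += qw
    acc += 0.5 * ((1.0 - sp) + (1.0 - sq)) * ln2
    return max(0.0, min(acc, ln2))


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.matrix < -1e-9).any():
            raise ValueError("distance matrix must be nonnegative")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )


def ffp_distance_matrix(profiles: list[FFProfile]) -> DistanceMatrix:
    n = len(profiles)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = ffp_distance(profiles[i], profiles[j])
    return DistanceMatrix([p.sequence_id for p in profiles], mat)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree; negative branch lengths are clamped to zero
    (with a warning), as usual for NJ on noisy distances."""
    if len(dm.labels) < 3:
        raise ValueError("need at least 3 labels for a tree")
    if len(set(dm.labels)) != len(dm.labels):
        raise ValueError("duplicate labels")
    buf = io.StringIO()
    buf.write("," + ",".join(dm.labels) + "\n")
    for lab, row in zip(dm.labels, dm.matrix):
        buf.write(lab + "," + ",".join(f"{v:.12g}" for v in row) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    clamped = False
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            clamped = True
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    return tree


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# Splits and Matching Splits
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def nontrivial_splits(tree: dendropy.Tree) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Bipartitions induced by internal edges, both sides with >= 2 leaves."""
    all_leaves = leaf_labels(tree)
    seen: set[frozenset[frozenset[str]]] = set()
    out: list[tuple[frozenset[str], frozenset[str]]] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = frozenset((side, other))
        if key in seen:
            continue
        seen.add(key)
        out.append((side, other))
    return out


def _split_cost(
    s: tuple[frozenset[str], frozenset[str]], t: tuple[frozenset[str], frozenset[str]]
) -> int:
    a1, _ = s
    a2, b2 = t
    return min(len(a1 ^ a2), len(a1 ^ b2))


def star_tree(labels: list[str]) -> dendropy.Tree:
    """Completely unresolved tree: one internal node, no internal splits."""
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    for t in tns:
        leaf = dendropy.Node(taxon=t)
        tree.seed_node.add_child(leaf)
    return tree


def matching_splits(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Matching Splits distance and its percent-of-star normalization.

    Minimum-cost perfect matching between the two non-trivial split sets;
    the cost of matching two splits is the smaller symmetric-difference
    size over the two side pairings. When the sets differ in cardinality
    the shorter one is padded with dummy splits; matching a real split to a
    dummy costs the size of its smaller side. The percentage is
    ``ms / matching_splits(t1, star) * 100``, i.e. 100 means "as different
    from t1 as a completely unresolved tree".
    """
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError("trees must share an identical leaf set")
    s1 = nontrivial_splits(t1)
    s2 = nontrivial_splits(t2)
    ms = _matching_cost(s1, s2)
    star_ms = _matching_cost(s1, [])
    pct = 100.0 * ms / star_ms if star_ms else 0.0
    return ms, pct


def _matching_cost(
    s1: list[tuple[frozenset[str], frozenset[str]]],
    s2: list[tuple[frozenset[str], frozenset[str]]],
) -> int:
    n = max(len(s1), len(s2))
    if n == 0:
        return 0
    cost = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(n):
            if i < len(s1) and j < len(s2):
                cost[i, j] = _split_cost(s1[i], s2[j])
            elif i < len(s1):
                cost[i, j] = min(len(s1[i][0]), len(s1[i][1]))
            elif j < len(s2):
                cost[i, j] = min(len(s2[j][0]), len(s2[j][1]))
    rows, cols = linear_sum_assignment(cost)
    return int(round(cost[rows, cols].sum()))


def ms_percent_of_star(ms: float, ms_star: float) -> float:
    """Normalize a Matching Splits value against the star-tree distance."""
    if ms_star <= 0:
        raise ValueError("star-tree MS must be positive")
    return 100.0 * ms / ms_star


# ---------------------------------------------------------------------------
# Genealogical sorting index
# ---------------------------------------------------------------------------

def gsi(tree: dendropy.Tree, group: set[str]) -> float:
    """Genealogical sorting index of a labelled group on a tree.

    gs = (n-1) / sum over uniting nodes of (children - 1), where the
    uniting nodes are the internal nodes on the paths from the group's
    leaves to their most recent common ancestor. The index rescales gs
    between its minimum on this tree (group dispersed over every internal
    node) and 1 (monophyly): gsi = (gs - gs_min) / (1 - gs_min).

    A group whose bipartition exists as an edge of the (possibly unrooted)
    tree scores exactly 1.
    """
    leaves = leaf_labels(tree)
    group = set(group)
    if not group.issubset(leaves):
        raise ValueError("group is not a subset of the tree's leaves")
    if len(group) < 2:
        raise ValueError("group must have at least 2 members")
    if group == leaves:
        raise ValueError("group must be a proper subset of the leaves")

    fg = frozenset(group)
    for side, other in nontrivial_splits(tree):
        if fg == side or fg == other:
            return 1.0
    # group of size n-1 (complement a single leaf) is trivially monophyletic
    if len(leaves - group) == 1:
        return 1.0

    node_map = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    with warnings.catch_warnings():
        # unrooted trees: the seed node deliberately serves as the root
        warnings.simplefilter("ignore", UserWarning)
        mrca = tree.mrca(taxa=[node_map[g].taxon for g in group])
    uniting_nodes: dict[int, dendropy.Node] = {}
    for g in group:
        node = node_map[g].parent_node
        while node is not None:
            uniting_nodes[id(node)] = node
            if node is mrca:
                break
            node = node.parent_node
    denom = sum(max(len(n.child_nodes()) - 1, 1) for n in uniting_nodes.values())
    n = len(group)
    gs = (n - 1) / denom

    all_internal = [
        nd for nd in tree.preorder_node_iter() if nd.child_nodes()
    ]
    denom_min = sum(max(len(nd.child_nodes()) - 1, 1) for nd in all_internal)
    gs_min = (n - 1) / denom_min
    if gs_min >= 1.0:
        return 1.0
    return max(0.0, min(1.0, (gs - gs_min) / (1.0 - gs_min)))


def clade_recovery(tree: dendropy.Tree, labels: LabelTable) -> dict[str, dict]:
    """Monophyly flag and gsi for every cluster and subcluster.

    Groups with a single leaf on the tree are reported as not applicable
    (``monophyletic`` and ``gsi`` set to None) rather than errors.
    """
    leaves = leaf_labels(tree)
    missing = [sid for sid in labels.ids() if sid not in leaves]
    if missing:
        raise ValueError(f"labelled ids missing from tree: {missing[:5]}")
    splits = {s for pair in nontrivial_splits(tree) for s in pair}
    report: dict[str, dict] = {}
    for level in ("cluster", "subcluster"):
        for name, members in sorted(labels.groups(level).items()):
            if name in report:  # cluster with a single identically-named subcluster
                continue
            entry: dict = {"level": level, "n": len(members)}
            if len(members) < 2:
                entry["monophyletic"] = None
                entry["gsi"] = None
            elif len(members) == len(leaves):
                entry["monophyletic"] = True
                entry["gsi"] = 1.0
            else:
                fg = frozenset(members)
                mono = fg in splits or len(leaves - fg) == 1
                entry["monophyletic"] = bool(mono)
                entry["gsi"] = gsi(tree, set(members))
            report[name] = entry
    return report


# ---------------------------------------------------------------------------
# Bootstrap majority-rule consensus
# ---------------------------------------------------------------------------

def _canonical_clades(
    tree: dendropy.Tree, ref: str
) -> set[frozenset[str]]:
    """Non-trivial splits, each stored as the side not containing ``ref``."""
    out = set()
    for side, other in nontrivial_splits(tree):
        out.add(other if ref in side else side)
    return out


def _tree_from_clades(
    labels: list[str], clades: list[tuple[frozenset[str], float]]
) -> dendropy.Tree:
    """Build a tree from mutually compatible clades (majority splits).

    The tree is rooted at an arbitrary reference leaf's side and returned
    unrooted-equivalent; supports become internal node labels.
    """
    full = frozenset(labels)
    items = sorted(clades, key=lambda cs: (-len(cs[0]), sorted(cs[0])[0]))

    def build(members: frozenset[str], inner: list[tuple[frozenset[str], float]], support) -> str:
        # maximal clades first (items are size-sorted); >50% clades never conflict
        maximal: list[tuple[frozenset[str], float]] = []
        used: set[str] = set()
        for c, s in inner:
            if not (c & used):
                maximal.append((c, s))
                used |= c
        parts = []
        for c, s in maximal:
            nested = [(c2, s2) for c2, s2 in inner if c2 < c]
            parts.append(build(c, nested, s))
        for leaf in sorted(members - used):
            parts.append(leaf)
        label = "" if support is None else f"{support:g}"
        return "(" + ",".join(parts) + ")" + label

    newick = build(full, items, None) + ";"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def bootstrap_consensus(
    data,
    replicates: int = 10000,
    mode: str = "ffp",
    min_freq: float = 0.5,
    seed: int | None = None,
) -> dendropy.Tree:
    """Bootstrap NJ trees and keep splits present in > ``min_freq`` of
    replicates (50% majority rule by default); supports are percentages.

    ``mode='ffp'``: ``data`` is a list of :class:`FFProfile`; the resampling
    unit is the feature (columns of the taxa-by-feature count table drawn
    with replacement). ``mode='msa'``: ``data`` is ``(ids, rows)`` of a
    multiple alignment and columns are resampled.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)

    if mode == "ffp":
        profiles: list[FFProfile] = data
        ids = [p.sequence_id for p in profiles]
        universe = sorted(set().union(*(p.counts.keys() for p in profiles)))
        U = len(universe)
        counts = np.zeros((len(profiles), U))
        for r, p in enumerate(profiles):
            for k, w in enumerate(universe):
                if w in p.counts:
                    counts[r, k] = p.counts[w]

        def replicate_matrix() -> np.ndarray:
            w = rng.multinomial(U, np.full(U, 1.0 / U))
            c = counts * w
            tot = c.sum(axis=1, keepdims=True)
            if (tot == 0).any():
                tot[tot == 0] = 1.0
            P = c / tot
            n = len(profiles)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = _jsd_vec(P[i], P[j])
            return d

    elif mode == "msa":
        ids, rows = data
        arr = np.array([list(r) for r in rows])
        ncol = arr.shape[1]

        def replicate_matrix() -> np.ndarray:
            idx = rng.integers(0, ncol, ncol)
            sub = arr[:, idx]
            n = len(ids)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = sub[i], sub[j]
                    mask = (a != "-") | (b != "-")
                    tot = mask.sum()
                    same = ((a == b) & (a != "-")).sum()
                    d[i, j] = d[j, i] = 1.0 - same / tot if tot else 1.0
            return d

    else:
        raise ValueError(f"unknown bootstrap mode {mode!r}")

    ref = sorted(ids)[0]
    freq: dict[frozenset[str], int] = {}
    for _ in range(replicates):
        t = nj_tree(DistanceMatrix(list(ids), replicate_matrix()))
        for clade in _canonical_clades(t, ref):
            freq[clade] = freq.get(clade, 0) + 1

    majority = [
        (clade, 100.0 * k / replicates)
        for clade, k in freq.items()
        if k / replicates > min_freq
    ]
    return _tree_from_clades(sorted(ids), majority)


def _jsd_vec(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kp = np.where(p > 0, p * np.log(p / m), 0.0)
        kq = np.where(q > 0, q * np.log(q / m), 0.0)
    return float(0.5 * (kp.sum() + kq.sum()))
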