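"""Interallelic distance matrices: cophenetic path sums and a NJ fallback.

The sorting criterion consumes pairwise distances between a locus's allele
sequences. The preferred source is a user-supplied tree with branch lengths
(e.g. a per-locus ML tree), from which distances are read off as cophenetic
(patristic) path sums. When no tree is available the module falls back to
an entirely self-contained route: uncorrected p-distances between alleles,
a neighbor-joining tree built from them, and cophenetic distances on that
tree. On additive input NJ is exact, so the fallback reproduces tree
distances wherever the data are tree-like.

Neighbor joining is implemented here (Saitou & Nei's algorithm with the
standard Q criterion). Negative branch-length estimates are clamped to
zero with the deficit moved to the adjacent branch (the usual remedy),
keeping cophenetic distances non-negative. Ties in the Q matrix are broken
by scan order over lexicographically sorted labels, so the tree — and
everything downstream — is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io import AlleleAlignment, check_tree_matches_alignment

__all__ = [
    "DistanceMatrix",
    "p_distance",
    "p_distance_matrix",
    "nj_tree",
    "cophenetic",
    "locus_distances",
]

DEFAULT_MIN_OVERLAP = 50


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances over ordered labels; NaN = missing.

    A pair is missing when the two sequences share fewer comparable sites
    than the caller's minimum overlap — downstream sorting treats any
    decision needing such a pair as equivocal (insufficient_overlap).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T)
        ):
            raise ValueError("distance matrix must be symmetric")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        """Distance between labels a and b (NaN if missing)."""
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self._index[lab] for lab in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def missing_labels(self) -> list[str]:
        """A small label set whose removal leaves the matrix complete.

        Greedy peeling: repeatedly drop the label involved in the most
        missing pairs. Dropping the returned labels (e.g. all-N alleles)
        makes the remainder usable for tree building.
        """
        mask = np.isnan(self.values)
        np.fill_diagonal(mask, False)
        active = list(range(len(self.labels)))
        dropped: list[int] = []
        while True:
            sub = mask[np.ix_(active, active)]
            counts = sub.sum(axis=1)
            if not counts.any():
                break
            worst = active[int(np.argmax(counts))]
            dropped.append(worst)
            active.remove(worst)
        return [self.labels[i] for i in sorted(dropped)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                cells = ["NA" if np.isnan(v) else format(v, ".6g") for v in row]
                fh.write(lab + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# p-distances

_COMPARABLE = np.frombuffer(b"ACGT", dtype="S1")


def _encode(sequences: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(sequences).encode("ascii"), dtype="S1")
    return arr.reshape(len(sequences), -1)


def p_distance(a: str, b: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Proportion of differing sites among comparable positions.

    Comparable positions are columns where both residues are in {A,C,G,T};
    N and gaps are excluded. Returns NaN when fewer than ``min_overlap``
    comparable sites remain.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    D = p_distance_matrix_from_sequences([a, b], min_overlap)
    return float(D[0, 1])


def p_distance_matrix_from_sequences(
    sequences: list[str], min_overlap: int = DEFAULT_MIN_OVERLAP
) -> np.ndarray:
    arr = _encode(sequences)
    valid = np.isin(arr, _COMPARABLE)
    n = len(sequences)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            n_comp = int(comp.sum())
            if n_comp < min_overlap:
                d = np.nan
            else:
                d = float(((arr[i] != arr[j]) & comp).sum()) / n_comp
            out[i, j] = out[j, i] = d
    return out


def p_distance_matrix(
    alignment: AlleleAlignment, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> DistanceMatrix:
    values = p_distance_matrix_from_sequences(
        [r.sequence for r in alignment.records], min_overlap
    )
    return DistanceMatrix(tuple(alignment.labels), values)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(D: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a complete distance matrix.

    Requires >= 3 labels and no missing entries (drop incomplete labels
    first). The returned tree is unrooted (trifurcating seed node).
    """
    if len(D) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    if not D.is_complete:
        raise ValueError(
            f"distance matrix has missing entries for {D.missing_labels()}"
        )

    order = sorted(range(len(D)), key=lambda i: D.labels[i])
    labels = [D.labels[i] for i in order]
    d = D.values[np.ix_(order, order)].astype(float).copy()

    tns = dendropy.TaxonNamespace(list(D.labels))
    nodes = [
        dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels
    ]
    active = list(range(len(labels)))

    def join(i: int, j: int, li: float, lj: float) -> dendropy.Node:
        # clamp a negative estimate to 0, moving the deficit to the sister
        # branch so the path length through the new node is preserved
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        return parent

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major scan over the sorted-label ordering: deterministic ties
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        parent = join(i, j, li, dij - li)
        # distances from the new node to the remaining actives
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        k = len(nodes) - 1
        active = [a for a in active if a not in (i, j)] + [k]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].edge.length = max(length, 0.0)
        root.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Cophenetic distances


def cophenetic(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length (patristic) distances between all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    labels = tuple(leaf.taxon.label for leaf in leaves)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            values[i, j] = values[j, i] = dist
    return DistanceMatrix(labels, values)


def locus_distances(
    alignment: AlleleAlignment,
    tree: dendropy.Tree | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """Distance matrix for one locus, ordered like the alignment labels.

    With a tree: cophenetic distances (the tree's leaves must equal the
    alignment's labels). Without: cophenetic distances on an NJ tree built
    from p-distances when every pair is defined; otherwise the raw
    p-distance matrix with its missing mask is returned and the sorting
    layer decides which samples are usable.
    """
    if tree is not None:
        check_tree_matches_alignment(tree, alignment)
        return cophenetic(tree).submatrix(alignment.labels)
    P = p_distance_matrix(alignment, min_overlap)
    if P.is_complete and len(P) >= 3:
        return cophenetic(nj_tree(P)).submatrix(alignment.labels)
    return P
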