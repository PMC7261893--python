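"""Simple-matching dissimilarity and neighbor-joining trees for gamete
populations.

The dissimilarity between two haploid units is d = 1 - (1/L) * sum(m_l),
with L the number of jointly non-missing loci and m_l = 1 when the calls
match (simple matching at ploidy 1).  Missing data are handled by pairwise
deletion: L is specific to each pair.  Trees are built by the Saitou-Nei
neighbor-joining agglomeration; the "weighted" variant requested by some
workflows falls back to classic NJ with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marker_io import GenotypeMatrix


@dataclass
class DissimilarityMatrix:
    unit_ids: list[str]
    d: np.ndarray  # symmetric, zero diagonal, values in [0, 1]
    loci_used: np.ndarray  # pairwise counts of jointly non-missing loci

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.unit_ids, columns=self.unit_ids)


def simple_matching(
    gm: GenotypeMatrix, on_no_overlap: str = "error"
) -> DissimilarityMatrix:
    """Pairwise simple-matching dissimilarity of a haploid matrix.

    A pair with no jointly scored locus has no defined distance: this
    raises unless ``on_no_overlap="nan"``.
    """
    if gm.ploidy != 1:
        raise ValueError("simple_matching expects a haploid matrix")
    if gm.n_units < 2:
        raise ValueError("need at least two units")
    if on_no_overlap not in ("error", "nan"):
        raise ValueError(f"unknown on_no_overlap policy {on_no_overlap!r}")
    codes = np.column_stack(
        [pd.factorize(gm.calls[c], use_na_sentinel=True)[0] for c in gm.loci]
    )
    n = codes.shape[0]
    d = np.zeros((n, n))
    used = np.zeros((n, n), dtype=int)
    valid = codes >= 0
    # row-chunked to keep the broadcast bounded for large populations
    chunk = max(1, 2_000_000 // max(1, n * codes.shape[1]))
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        both = valid[start:stop, None, :] & valid[None, :, :]
        eq = (codes[start:stop, None, :] == codes[None, :, :]) & both
        L = both.sum(axis=2)
        m = eq.sum(axis=2)
        with np.errstate(invalid="ignore"):
            block = 1.0 - m / L
        used[start:stop] = L
        d[start:stop] = block
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        if on_no_overlap == "error":
            bad = np.argwhere(np.isnan(np.triu(d, 1)))
            i, j = bad[0]
            raise ValueError(
                f"units {gm.unit_ids[i]!r} and {gm.unit_ids[j]!r} share no "
                "scored locus; pass on_no_overlap='nan' to keep NaN"
            )
    return DissimilarityMatrix(unit_ids=list(gm.unit_ids), d=d, loci_used=used)


@dataclass
class PhyloTree:
    """Unrooted binary tree over unit ids, arbitrarily rooted at the last
    neighbor-joining join (a degree-3 node) for serialization."""

    root: int
    children: dict[int, list[tuple[int, float]]]
    leaf_names: dict[int, str]

    @property
    def leaf_ids(self) -> list[str]:
        return [self.leaf_names[k] for k in sorted(self.leaf_names)]

    def newick(self, decimals: int = 6) -> str:
        def render(node: int) -> str:
            if node in self.leaf_names:
                return _quote(self.leaf_names[node])
            parts = [
                f"{render(c)}:{length:.{decimals}f}"
                for c, length in self.children[node]
            ]
            return "(" + ",".join(parts) + ")"

        return render(self.root) + ";"

    def canonical_newick(self, decimals: int = 6) -> str:
        """Newick with children recursively sorted by their smallest leaf
        name: identical topologies serialize identically regardless of the
        input row order."""

        def minleaf(node: int) -> str:
            if node in self.leaf_names:
                return self.leaf_names[node]
            return min(minleaf(c) for c, _ in self.children[node])

        def render(node: int) -> str:
            if node in self.leaf_names:
                return _quote(self.leaf_names[node])
            kids = sorted(self.children[node], key=lambda cl: minleaf(cl[0]))
            parts = [f"{render(c)}:{length:.{decimals}f}" for c, length in kids]
            return "(" + ",".join(parts) + ")"

        return render(self.root) + ";"

    def leaf_path_lengths(self) -> pd.DataFrame:
        """Patristic (sum of branch length) distances between all leaves."""
        adjacency: dict[int, list[tuple[int, float]]] = {}
        for parent, kids in self.children.items():
            for child, length in kids:
                adjacency.setdefault(parent, []).append((child, length))
                adjacency.setdefault(child, []).append((parent, length))
        leaves = sorted(self.leaf_names)
        names = [self.leaf_names[k] for k in leaves]
        out = np.zeros((len(leaves), len(leaves)))
        for a, src in enumerate(leaves):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nbr, length in adjacency.get(node, []):
                    if nbr not in dist:
                        dist[nbr] = dist[node] + length
                        stack.append(nbr)
            for b, dst in enumerate(leaves):
                out[a, b] = dist[dst]
        return pd.DataFrame(out, index=names, columns=names)


def _quote(name: str) -> str:
    if any(c in name for c in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def nj_tree(dm: DissimilarityMatrix, variant: str = "classic") -> PhyloTree:
    """Neighbor-joining tree from a dissimilarity matrix.

    Classic Saitou-Nei agglomeration with the standard Q criterion and
    branch-length formulas; a negative branch length is clamped to zero and
    its magnitude transferred to the sister branch, preserving the joined
    pair's distance.  On an additive matrix the tree's leaf-to-leaf path
    lengths reproduce the input exactly.
    """
    if variant == "weighted":
        warnings.warn(
            "weighted neighbor-joining is approximated by the classic "
            "Saitou-Nei algorithm",
            stacklevel=2,
        )
    elif variant != "classic":
        raise ValueError(f"unknown NJ variant {variant!r}")
    n = len(dm.unit_ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least three units")
    if np.isnan(dm.d).any():
        raise ValueError("dissimilarity matrix contains undefined distances")

    ids = list(range(n))
    dist = {(i, j): float(dm.d[i, j]) for i in range(n) for j in range(n) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    children: dict[int, list[tuple[int, float]]] = {}
    leaf_names = dict(enumerate(dm.unit_ids))
    # smallest leaf name under each node: canonical tie-break so the tree
    # is invariant to input row order even with duplicate genotypes
    minleaf = {i: name for i, name in leaf_names.items()}
    next_id = n
    active = ids[:]
    while len(active) > 3:
        k = len(active)
        r = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best, best_key = None, None
        for ai in range(k):
            for aj in range(ai + 1, k):
                i, j = active[ai], active[aj]
                q = (k - 2) * get(i, j) - r[i] - r[j]
                key = (q, *sorted((minleaf[i], minleaf[j])))
                if best_key is None or key < best_key:
                    best_key, best = key, (i, j)
        i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (k - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        u = next_id
        next_id += 1
        children[u] = [(i, li), (j, lj)]
        minleaf[u] = min(minleaf[i], minleaf[j])
        for m in active:
            if m in (i, j):
                continue
            dist[(min(m, u), max(m, u))] = 0.5 * (get(i, m) + get(j, m) - dij)
        active = [m for m in active if m not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    root = next_id
    children[root] = [
        (a, max(la, 0.0)),
        (b, max(lb, 0.0)),
        (c, max(lc, 0.0)),
    ]
    return PhyloTree(root=root, children=children, leaf_names=leaf_names)


@dataclass
class TreeReport:
    """Joint tree over two populations with per-leaf source labels."""

    tree: PhyloTree
    labels: dict[str, str]  # leaf name -> population label
    min_clade_size: int

    @property
    def exclusive_clades(self) -> list[tuple[str, int]]:
        """Maximal single-population subtrees (under the serialization
        rooting) with at least ``min_clade_size`` leaves."""
        found: list[tuple[str, int]] = []

        def labels_of(node: int) -> set[str]:
            if node in self.tree.leaf_names:
                return {self.labels[self.tree.leaf_names[node]]}
            out: set[str] = set()
            for child, _ in self.tree.children[node]:
                out |= labels_of(child)
            return out

        def size_of(node: int) -> int:
            if node in self.tree.leaf_names:
                return 1
            return sum(size_of(c) for c, _ in self.tree.children[node])

        def walk(node: int) -> None:
            labs = labels_of(node)
            if len(labs) == 1 and size_of(node) >= self.min_clade_size:
                found.append((labs.pop(), size_of(node)))
                return
            if node in self.tree.leaf_names:
                return
            for child, _ in self.tree.children[node]:
                walk(child)

        walk(self.tree.root)
        return found

    def exclusivity_count(self, label: str | None = None) -> int:
        clades = self.exclusive_clades
        if label is None:
            return len(clades)
        return sum(1 for lab, _ in clades if lab == label)

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"unit_id": list(self.labels), "population": list(self.labels.values())}
        )


def population_tree_report(
    gm_a: GenotypeMatrix,
    gm_b: GenotypeMatrix,
    label_a: str = "A",
    label_b: str = "B",
    variant: str = "classic",
    min_clade_size: int = 2,
) -> TreeReport:
    """Joint neighbor-joining tree of two haploid populations sharing one
    marker panel, with leaves annotated by source population."""
    if list(gm_a.loci) != list(gm_b.loci):
        raise ValueError("populations are genotyped on different marker panels")
    calls_a, calls_b = gm_a.calls.copy(), gm_b.calls.copy()
    overlap = set(calls_a.index) & set(calls_b.index)
    if overlap:
        calls_a.index = [f"{label_a}:{u}" for u in calls_a.index]
        calls_b.index = [f"{label_b}:{u}" for u in calls_b.index]
    merged = GenotypeMatrix(calls=pd.concat([calls_a, calls_b]), ploidy=1)
    labels = {u: label_a for u in calls_a.index}
    labels.update({u: label_b for u in calls_b.index})
    dm = simple_matching(merged)
    tree = nj_tree(dm, variant=variant)
    return TreeReport(tree=tree, labels=labels, min_clade_size=min_clade_size)
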