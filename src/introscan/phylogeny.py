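"""Pairwise p-distances from SNP genotypes and neighbor-joining trees.

The donor lineage of an introgressed segment is assigned by building an
unrooted neighbor-joining tree over the panel from genotype mismatch
fractions (p-distances) computed on the SNPs inside the segment: the query
line should attach inside the clade of the true donor species.

Distances are computed directly from the genotype matrix rather than from
realigned sequences: the input is a SNP table, so the mismatch fraction over
jointly called sites is the natural distance. A HET vs HOM comparison
contributes 0.5 by default (the two lines share one allele), configurable
to a full mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .panel_io import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair shared-site counts."""

    taxa: list[str]
    d: np.ndarray  # (n, n) float
    n_shared: np.ndarray  # (n, n) int

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if np.isnan(self.d).any():
            raise ValueError("distance matrix contains NaN")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.d < 0).any() or (self.d > 1).any():
            raise ValueError("p-distances must lie in [0, 1]")


def p_distance_matrix(
    G: GenotypeMatrix, min_overlap: int = 50, het_weight: float = 0.5
) -> DistanceMatrix:
    """Mismatch-fraction distances over sites called in both accessions.

    d(i,j) = sum of per-site mismatch weights / n_shared(i,j), where a
    HOM_REF vs HOM_ALT comparison weighs 1 and HET vs HOM weighs
    ``het_weight``. Any pair sharing fewer than ``min_overlap`` sites is an
    error (sparse overlaps give unstable distances).
    """
    if G.n_accessions < 2:
        raise ValueError("need at least two accessions")
    calls = G.calls.astype(float)
    calls[G.calls == MISSING] = np.nan

    n = G.n_accessions
    d = np.zeros((n, n))
    n_shared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        n_shared[i, i] = int((~np.isnan(calls[:, i])).sum())
        for j in range(i + 1, n):
            both = ~np.isnan(calls[:, i]) & ~np.isnan(calls[:, j])
            m = int(both.sum())
            n_shared[i, j] = n_shared[j, i] = m
            if m == 0:
                raise ValueError(
                    f"accessions {G.accessions[i]!r} and {G.accessions[j]!r} "
                    f"share no called sites"
                )
            if m < min_overlap:
                raise ValueError(
                    f"pair ({G.accessions[i]!r}, {G.accessions[j]!r}) shares only "
                    f"{m} sites (< min_overlap={min_overlap})"
                )
            diff = np.abs(calls[both, i] - calls[both, j])
            # |codes| differ by 1 for HET-vs-HOM, by 2 for opposite homozygotes
            mismatch = np.where(diff == 1, het_weight, 0.0) + np.where(diff == 2, 1.0, 0.0)
            d[i, j] = d[j, i] = float(mismatch.sum()) / m
    return DistanceMatrix(taxa=list(G.accessions), d=d, n_shared=n_shared)


def neighbor_joining(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined (ties: lowest index pair in current taxon order). Negative branch
    lengths are clamped to zero with the deficit transferred to the sister
    branch, so path lengths through the join are preserved. Returns an
    unrooted tree as a trifurcating-rooted skbio TreeNode.
    """
    n = len(D.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = D.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima: scan in row-major order
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or q[i, j] < q[best[0], best[1]] - 1e-12:
                    best = (i, j)
        i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = float(li)
        nodes[j].length = float(lj)

        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [x for x in range(m) if x != i and x != j]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = dk[keep]
        d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[x] for x in keep] + [new]

    # final three branches around the central node (closed form)
    a, b, c = nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    a.length = float(max(la, 0.0))
    b.length = float(max(lb, 0.0))
    c.length = float(max(lc, 0.0))
    return TreeNode(children=[a, b, c])


def _needs_quoting(name: str) -> bool:
    return any(ch in name for ch in " \t()[]':;,")


def _newick_label(name: str | None) -> str:
    if not name:
        return ""
    if _needs_quoting(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        s = _newick_label(node.name)
    else:
        s = "(" + ",".join(_newick_node(c) for c in node.children) + ")"
        s += _newick_label(node.name)
    if node.length is not None:
        s += f":{node.length:.6g}"
    return s


def write_newick(tree: TreeNode, path) -> None:
    """Write standard Newick with branch lengths to 6 significant digits.

    Leaf names containing spaces or Newick metacharacters are quoted.
    """
    with open(path, "w") as fh:
        fh.write(newick_string(tree))


def newick_string(tree: TreeNode) -> str:
    return _newick_node(tree) + ";\n"


def write_distance_tsv(D: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(D.taxa) + "\n")
        for i, t in enumerate(D.taxa):
            fh.write(t + "\t" + "\t".join(f"{x:.6g}" for x in D.d[i]) + "\n")


def query_neighbor_clade(tree: TreeNode, query: str, donor_taxa: set[str]) -> bool:
    """Does the query attach inside the donor clade?

    True iff some internal edge separates {query} + a nonempty subset of
    donors (and nothing else) from the rest of the tree, i.e. the query's
    smallest non-trivial surrounding clade is all-donor.
    """
    all_tips = {t.name for t in tree.tips()}
    if query not in all_tips:
        raise ValueError(f"query {query!r} not in tree")
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = {t.name for t in node.tips()}
        for s in (side, all_tips - side):
            rest = s - {query}
            if query in s and rest and rest <= donor_taxa:
                return True
    return False
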