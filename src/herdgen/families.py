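"""Family structure: neighbor-joining tree, lineage cutting, family assignment.

Boars anchor the familial lineages of a closed conservation herd: an NJ
tree (Saitou–Nei) is built from the boars' IBS distance matrix, the tree is
cut into ``k`` lineages at its longest edges, and every sow joins the
lineage whose boars she is most related to in the G matrix.  A sow whose
relationship to *every* boar falls below a threshold (0.1 by default, the
usual "unrelated for mating purposes" cut-off) is placed in a separate
unrelated family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relatedness import RelationshipMatrix


@dataclass
class Edge:
    u: int
    v: int
    length: float
    order: int  # insertion order during agglomeration (tie-break key)


@dataclass
class PhyloTree:
    """Unrooted tree: nodes 0..n_leaves-1 are leaves, the rest internal."""

    leaf_names: list[str]
    edges: list[Edge]
    n_nodes: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {
            i: [] for i in range(self.n_nodes)
        }
        for e in self.edges:
            adj[e.u].append((e.v, e.length))
            adj[e.v].append((e.u, e.length))
        return adj

    def leaf_path_lengths(self) -> np.ndarray:
        """Matrix of summed branch lengths between every leaf pair."""
        adj = self.adjacency()
        n = self.n_leaves
        out = np.zeros((n, n))
        for src in range(n):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for dst in range(n):
                out[src, dst] = dist[dst]
        return out

    def newick(self, precision: int = 10) -> str:
        """Serialize rooted at the last internal node (or a leaf for n=2)."""
        adj = self.adjacency()
        root = self.n_nodes - 1

        def fmt(x: float) -> str:
            return f"{x:.{precision}g}"

        def render(node: int, parent: int) -> str:
            children = [(v, w) for v, w in adj[node] if v != parent]
            if not children:
                return self.leaf_names[node]
            inner = ",".join(f"{render(v, node)}:{fmt(w)}" for v, w in children)
            label = self.leaf_names[node] if node < self.n_leaves else ""
            return f"({inner}){label}"

        return render(root, -1) + ";"


def neighbor_joining(
    d: np.ndarray, leaf_names: list[str] | None = None
) -> PhyloTree:
    """Classic Saitou–Nei neighbor joining.

    At each step the pair minimizing ``Q_ij = (r−2) D_ij − Σ_k D_ik −
    Σ_k D_jk`` is joined, with ties broken by the smallest (i, j) node-index
    pair.  Negative branch lengths are clamped to zero with the deficit
    moved to the sibling edge so the pair's summed length is preserved.
    """
    d = np.asarray(d, dtype=np.float64)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least two taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    names = leaf_names if leaf_names is not None else [f"L{i}" for i in range(n)]
    if len(names) != n:
        raise ValueError("leaf_names length must match matrix order")

    edges: list[Edge] = []
    order = 0

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        total = li + lj
        if li < 0:
            return 0.0, total
        if lj < 0:
            return total, 0.0
        return li, lj

    if n == 2:
        return PhyloTree(names, [Edge(0, 1, float(d[0, 1]), 0)], 2)

    # active: node id -> index into the working distance matrix
    active = list(range(n))
    work = d.copy()
    next_node = n

    while len(active) > 3:
        r = len(active)
        sums = work.sum(axis=1)
        q = (r - 2) * work - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        # tie-break: smallest (node_i, node_j) pair among minimal Q
        qmin = q.min()
        cand = np.argwhere(q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        best = min(
            (tuple(sorted((active[a], active[b]))), (a, b))
            for a, b in cand
            if a < b
        )[1]
        a, b = best
        dij = work[a, b]
        li = 0.5 * dij + (sums[a] - sums[b]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        edges.append(Edge(active[a], next_node, float(li), order))
        order += 1
        edges.append(Edge(active[b], next_node, float(lj), order))
        order += 1
        # distances from the new node to the remaining taxa
        rest = [k for k in range(r) if k not in (a, b)]
        new_d = 0.5 * (work[a, rest] + work[b, rest] - dij)
        new_d = np.maximum(new_d, 0.0)
        keep = work[np.ix_(rest, rest)]
        work = np.zeros((len(rest) + 1, len(rest) + 1))
        work[:-1, :-1] = keep
        work[-1, :-1] = new_d
        work[:-1, -1] = new_d
        active = [active[k] for k in rest] + [next_node]
        next_node += 1

    # final three taxa join a single central node (three-point formulas)
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (work[a, b] + work[a, c] - work[b, c])
    lb = 0.5 * (work[a, b] + work[b, c] - work[a, c])
    lc = 0.5 * (work[a, c] + work[b, c] - work[a, b])
    clamped = [max(0.0, x) for x in (la, lb, lc)]
    center = next_node
    for node, length in zip((active[a], active[b], active[c]), clamped):
        edges.append(Edge(node, center, float(length), order))
        order += 1
    next_node += 1

    tree = PhyloTree(names, edges, next_node)
    if any(x < 0 for x in (la, lb, lc)) or any(
        e.length < 0 for e in edges
    ):
        tree.metadata["negative_branches_clamped"] = True
    return tree


def cut_lineages(tree: PhyloTree, k: int) -> dict[str, int]:
    """Cut the tree into ``k`` lineages by removing its longest edges.

    Edges are ranked internal-internal first, then leaf edges, by
    decreasing branch length with ties broken by insertion order; edges are
    removed greedily, skipping any removal that does not split a
    leaf-bearing component, until ``k`` leaf-bearing components exist.
    Lineages are numbered 1..k by their smallest contained leaf index.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")

    def is_internal(e: Edge) -> bool:
        return e.u >= n and e.v >= n

    ranked = sorted(
        tree.edges, key=lambda e: (not is_internal(e), -e.length, e.order)
    )
    removed: set[int] = set()

    def leaf_components() -> list[set[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(tree.n_nodes)}
        for idx, e in enumerate(tree.edges):
            if idx in removed:
                continue
            adj[e.u].append(e.v)
            adj[e.v].append(e.u)
        seen: set[int] = set()
        comps = []
        for start in range(tree.n_nodes):
            if start in seen:
                continue
            comp = set()
            stack = [start]
            seen.add(start)
            while stack:
                u = stack.pop()
                comp.add(u)
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            leaves = {x for x in comp if x < n}
            if leaves:
                comps.append(leaves)
        return comps

    edge_index = {id(e): i for i, e in enumerate(tree.edges)}
    comps = leaf_components()
    for e in ranked:
        if len(comps) >= k:
            break
        idx = edge_index[id(e)]
        removed.add(idx)
        new_comps = leaf_components()
        if len(new_comps) > len(comps):
            comps = new_comps
        else:
            removed.discard(idx)

    comps.sort(key=min)
    assignment: dict[str, int] = {}
    for lineage, comp in enumerate(comps, start=1):
        for leaf in comp:
            assignment[tree.leaf_names[leaf]] = lineage
    return assignment


def suggest_k(tree: PhyloTree) -> int:
    """Largest-gap heuristic over internal branch lengths (never auto-applied).

    Finds the largest gap in the sorted internal-edge lengths, removes every
    internal edge above the gap, and returns the number of leaf-bearing
    components that result.
    """
    n = tree.n_leaves
    lengths = sorted(
        (e.length for e in tree.edges if e.u >= n and e.v >= n), reverse=True
    )
    if len(lengths) < 2:
        return 1
    gaps = [lengths[i] - lengths[i + 1] for i in range(len(lengths) - 1)]
    cutoff = lengths[int(np.argmax(gaps))]
    long_edges = {
        id(e)
        for e in tree.edges
        if e.u >= n and e.v >= n and e.length >= cutoff - 1e-15
    }
    adj: dict[int, list[int]] = {i: [] for i in range(tree.n_nodes)}
    for e in tree.edges:
        if id(e) in long_edges:
            continue
        adj[e.u].append(e.v)
        adj[e.v].append(e.u)
    seen: set[int] = set()
    k = 0
    for start in range(tree.n_nodes):
        if start in seen:
            continue
        stack = [start]
        seen.add(start)
        has_leaf = False
        while stack:
            u = stack.pop()
            has_leaf = has_leaf or u < n
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        k += int(has_leaf)
    return max(1, k)


@dataclass
class FamilyAssignment:
    lineage_of_boar: dict[str, int]
    family_of_sample: dict[str, int]
    threshold: float
    unrelated_family: int  # index used for below-threshold samples

    def to_tsv(self, group_labels: dict[str, str] | None = None) -> str:
        lines = ["sample_id\tgroup\tlineage\tfamily"]
        for sid, fam in self.family_of_sample.items():
            lineage = self.lineage_of_boar.get(sid, "")
            group = (group_labels or {}).get(
                sid, "boar" if sid in self.lineage_of_boar else "sow"
            )
            lines.append(f"{sid}\t{group}\t{lineage}\t{fam}")
        return "\n".join(lines) + "\n"


def assign_families(
    g: RelationshipMatrix,
    lineage_of_boar: dict[str, int],
    threshold: float = 0.1,
    sow_rule: str = "mean",
) -> FamilyAssignment:
    """Extend boar lineages to the whole herd via the G matrix.

    Each boar inherits its lineage as its family.  Each remaining sample
    (sow) joins the family of the lineage with the largest mean (or, with
    ``sow_rule='max'``, largest maximum) relationship to its boars — unless
    her maximum relationship over *all* boars is below ``threshold``, in
    which case she forms part of the separate unrelated family (index
    ``max lineage + 1``).  Lineage ties go to the lowest lineage index.
    """
    if sow_rule not in ("mean", "max"):
        raise ValueError("sow_rule must be 'mean' or 'max'")
    if not lineage_of_boar:
        raise ValueError("lineage_of_boar must be non-empty")
    index = {sid: i for i, sid in enumerate(g.sample_ids)}
    missing = [b for b in lineage_of_boar if b not in index]
    if missing:
        raise ValueError(f"boars absent from the relationship matrix: {missing}")

    lineages = sorted(set(lineage_of_boar.values()))
    boars_in: dict[int, list[int]] = {
        lin: [index[b] for b, l in lineage_of_boar.items() if l == lin]
        for lin in lineages
    }
    unrelated = max(lineages) + 1

    family: dict[str, int] = {}
    for boar, lin in lineage_of_boar.items():
        family[boar] = lin
    all_boar_idx = [index[b] for b in lineage_of_boar]
    for sid in g.sample_ids:
        if sid in lineage_of_boar:
            continue
        i = index[sid]
        rel_to_boars = g.values[i, all_boar_idx]
        if float(rel_to_boars.max()) < threshold:
            family[sid] = unrelated
            continue
        best_lin, best_score = None, -np.inf
        for lin in lineages:  # ascending → ties keep the lowest index
            vals = g.values[i, boars_in[lin]]
            score = float(vals.mean() if sow_rule == "mean" else vals.max())
            if score > best_score + 1e-15:
                best_lin, best_score = lin, score
        family[sid] = best_lin
    return FamilyAssignment(
        lineage_of_boar=dict(lineage_of_boar),
        family_of_sample=family,
        threshold=threshold,
        unrelated_family=unrelated,
    )
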