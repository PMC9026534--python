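"""Independent reference implementations used only to check the package.

Each oracle is written naively (enumeration, literal rule application,
path counting) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test by full enumeration
# ---------------------------------------------------------------------------

def hwe_enum_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact HWE p-value via direct log-probability enumeration.

    P(h het | n individuals, nA/nB allele counts) =
        n! / (hom1! h! hom2!) * 2^h * nA! nB! / (2n)!
    """
    n = n_hom1 + n_het + n_hom2
    na = 2 * n_hom1 + n_het
    nb = 2 * n_hom2 + n_het

    def logp(h: int) -> float:
        hom1 = (na - h) // 2
        hom2 = (nb - h) // 2
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom1 + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom2 + 1)
            + h * math.log(2)
            + math.lgamma(na + 1)
            + math.lgamma(nb + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = [h for h in range(min(na, nb) + 1) if (na - h) % 2 == 0]
    probs = {h: math.exp(logp(h)) for h in hets}
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    return min(
        1.0,
        sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total,
    )


# ---------------------------------------------------------------------------
# ROH detection by literal rule application
# ---------------------------------------------------------------------------

def roh_oracle(
    genotypes: np.ndarray,
    positions: np.ndarray,
    *,
    min_snps: int = 30,
    window: int = 50,
    density_bp_per_snp: int = 1_000_000,
    max_het: int = 1,
    max_missing: int = 1,
    threshold: float = 0.05,
    min_length: int = 1_000_000,
    max_gap: int = 1_000_000,
) -> list[tuple[int, int, int]]:
    """Single-sample single-chromosome ROH by explicit window enumeration.

    Returns (start_bp, end_bp, n_snps) tuples.
    """
    g = np.asarray(genotypes)
    pos = np.asarray(positions)
    m = len(g)
    w = min(window, m)

    # (a) enumerate all windows explicitly
    windows = []
    for s in range(m - w + 1):
        chunk = g[s : s + w]
        good = (
            int((chunk == 1).sum()) <= max_het
            and int((chunk == MISSING).sum()) <= max_missing
        )
        windows.append((s, s + w, good))

    # (b) per-SNP eligibility
    eligible = []
    for i in range(m):
        covering = [good for (s, e, good) in windows if s <= i < e]
        frac = sum(covering) / len(covering)
        eligible.append(frac >= threshold)

    # maximal runs of eligible SNPs
    runs, cur = [], []
    for i in range(m):
        if eligible[i]:
            cur.append(i)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)

    # (c) split at large gaps
    split = []
    for run in runs:
        piece = [run[0]]
        for i in run[1:]:
            if pos[i] - pos[piece[-1]] > max_gap:
                split.append(piece)
                piece = [i]
            else:
                piece.append(i)
        split.append(piece)

    # (d) greedy split at cap-busting calls, then trim to homozygous ends
    capped = []
    for run in split:
        piece, h, mi = [], 0, 0
        for i in run:
            if g[i] == 1 and h + 1 > max_het:
                if piece:
                    capped.append(piece)
                piece, h, mi = [], 0, 0
                continue
            if g[i] == MISSING and mi + 1 > max_missing:
                if piece:
                    capped.append(piece)
                piece, h, mi = [], 0, 0
                continue
            h += int(g[i] == 1)
            mi += int(g[i] == MISSING)
            piece.append(i)
        if piece:
            capped.append(piece)

    out = []
    for run in capped:
        while run and g[run[0]] not in (0, 2):
            run = run[1:]
        while run and g[run[-1]] not in (0, 2):
            run = run[:-1]
        # (e) final filters
        if len(run) < min_snps:
            continue
        length = int(pos[run[-1]] - pos[run[0]])
        if length < min_length:
            continue
        if length / len(run) > density_bp_per_snp:
            continue
        out.append((int(pos[run[0]]), int(pos[run[-1]]), len(run)))
    return out


# ---------------------------------------------------------------------------
# random additive trees (NJ oracle)
# ---------------------------------------------------------------------------

def random_additive_matrix(
    n_leaves: int, rng: np.random.Generator
) -> np.ndarray:
    """Leaf-pair path-length matrix of a random binary tree.

    The tree is built by random sequential joins with branch lengths drawn
    from Uniform(0.1, 1.0); distances are additive by construction.
    """
    # nodes: adjacency with branch lengths
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_leaves)}

    def link(a: int, b: int, w: float) -> None:
        adj[a].append((b, w))
        adj[b].append((a, w))

    active = list(range(n_leaves))
    nxt = n_leaves
    while len(active) > 2:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        adj[nxt] = []
        link(a, nxt, float(rng.uniform(0.1, 1.0)))
        link(b, nxt, float(rng.uniform(0.1, 1.0)))
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    link(active[0], active[1], float(rng.uniform(0.1, 1.0)))

    d = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for dst in range(n_leaves):
            d[src, dst] = dist[dst]
    return d
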