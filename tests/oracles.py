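"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: the
aligner oracle is a plain-python dict-based DP, and the tRF oracle is a
pairwise union-find clusterer.
"""

from __future__ import annotations


def affine_fit_optimum(read: str, ref: str, scheme) -> float | None:
    """Exhaustive affine-gap fit-alignment optimum (score only).

    Same contract as fit_align: full read consumed except clips (5' clip
    free up to clip5_max_free then penalized per base; 3' clip free only
    past the reference terminus), affine gaps, at least min_ref_cols
    reference columns consumed.  Returns None when no alignment qualifies.
    """
    n, m, K = len(read), len(ref), scheme.min_ref_cols
    NEG = float("-inf")
    go, ge = scheme.gap_open, scheme.gap_extend
    M: dict = {}
    Ix: dict = {}
    Iy: dict = {}

    def g(d, k, i, j):
        return d.get((k, i, j), NEG)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = scheme.match if read[i - 1] == ref[j - 1] else scheme.mismatch
            for k in range(1, K + 1):
                cands = []
                if k == 1:
                    cands.append(scheme.clip_penalty * max(0, (i - 1) - scheme.clip5_max_free))
                for kp in ([k - 1] if k < K else [K - 1, K]):
                    if kp >= 1:
                        cands += [g(M, kp, i - 1, j - 1), g(Ix, kp, i - 1, j - 1),
                                  g(Iy, kp, i - 1, j - 1)]
                if cands:
                    v = s + max(cands)
                    if v > NEG:
                        M[(k, i, j)] = v
                vx = max(g(M, k, i - 1, j) + go + ge, g(Ix, k, i - 1, j) + ge)
                if vx > NEG:
                    Ix[(k, i, j)] = vx
                if k >= 2:
                    if k < K:
                        vy = max(g(M, k - 1, i, j - 1) + go + ge,
                                 g(Iy, k - 1, i, j - 1) + ge)
                    else:
                        vy = max(g(M, K, i, j - 1) + go + ge,
                                 g(M, K - 1, i, j - 1) + go + ge,
                                 g(Iy, K, i, j - 1) + ge,
                                 g(Iy, K - 1, i, j - 1) + ge)
                    if vy > NEG:
                        Iy[(k, i, j)] = vy
    best = NEG
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if i == n:
                end = 0
            elif j == m:
                end = scheme.clip_penalty * max(0, (n - i) - scheme.clip3_max_free)
            else:
                end = scheme.clip_penalty * (n - i)
            v = g(M, K, i, j)
            if v > NEG:
                best = max(best, v + end)
    return None if best == NEG else best


def random_alignment_pair(rng, max_read=80, max_ref=90):
    """One seeded (read, ref) pair: half derived-with-errors, half random."""
    rl = int(rng.integers(12, max_read + 1))
    ml = int(rng.integers(15, max_ref + 1))
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, ml))
    if rng.random() < 0.6 and ml > 20:
        s = int(rng.integers(0, max(1, ml - rl + 1))) if ml > rl else 0
        core = list(ref[s:s + min(rl, ml)])
        for _ in range(int(rng.integers(0, 4))):
            p = int(rng.integers(0, len(core)))
            r = rng.random()
            if r < 0.4:
                core[p] = "ACGT"[int(rng.integers(0, 4))]
            elif r < 0.7:
                core.pop(p)
            else:
                core.insert(p, "ACGT"[int(rng.integers(0, 4))])
        read = "".join(core)
        if len(read) < 12:
            read = "".join("ACGT"[i] for i in rng.integers(0, 4, rl))
    else:
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, rl))
    return read, ref


def trf_calls_bruteforce(counts: dict[int, int], n_reads: int,
                         min_dist=7, min_frac=0.05, merge_gap=3):
    """Independent tRF caller: threshold, then cluster candidates by
    repeated pairwise merging (union-find), report each cluster at its
    smallest distance (3'-most site) with the summed member fraction.

    Returns a sorted list of (reported_distance, cluster_fraction)."""
    cand = [d for d, c in counts.items() if d > min_dist and c / n_reads > min_frac]
    parent = {d: d for d in cand}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    changed = True
    while changed:
        changed = False
        for a in cand:
            for b in cand:
                if a < b and b - a <= merge_gap and find(a) != find(b):
                    parent[find(b)] = find(a)
                    changed = True
    clusters: dict[int, list[int]] = {}
    for d in cand:
        clusters.setdefault(find(d), []).append(d)
    out = []
    for members in clusters.values():
        rep = min(members)
        frac = sum(counts[d] for d in members) / n_reads
        out.append((rep, frac))
    return sorted(out)
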