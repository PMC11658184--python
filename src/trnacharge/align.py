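"""Read processing and fit-alignment against the tRNA reference set.

The mapper is a single explicit component replacing the usual two-stage
small-RNA workflow (a local-alignment pre-pass to strip reverse-transcriptase
5' additions, followed by a global mapper).  A *fit alignment* consumes the
whole read except permitted soft clips and may land anywhere on the
reference:

* up to ``clip5_max_free`` read bases may be clipped at the 5' end at zero
  cost (tolerating RT terminal-transferase additions); further 5' clipping
  costs ``clip_penalty`` per base;
* 3' clipping is free only for read bases extending past the reference 3'
  terminus (non-templated tails on CCA-less references); clipping before the
  terminus costs ``clip_penalty`` per base;
* gaps are affine (a gap of length L costs gap_open + L * gap_extend);
* matches score 0, so a perfect alignment scores 0 and every penalty is
  negative — the mapping threshold is the mapper-style linear function
  ``min_score(len) = -0.7 - 0.7 * len``.

Alignments consuming fewer than ``min_ref_cols`` reference columns are
declared unalignable rather than returned (prevents degenerate clip-everything
solutions).  Ambiguity is defined at the level of distinct reference
sequences: equal best scores for two or more genes flag the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .reference import ReferenceSet, TRNAGene

_NEG = -1e18
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 0
    mismatch: int = -5
    gap_open: int = -5
    gap_extend: int = -3
    clip5_max_free: int = 5
    clip3_max_free: int = 5  # free overhang past the reference 3' terminus
    clip_penalty: int = -5
    min_ref_cols: int = 10

    def clip5_cost(self, n_clipped: int) -> int:
        extra = max(0, n_clipped - self.clip5_max_free)
        return self.clip_penalty * extra

    def clip3_cost(self, n_clipped: int, at_terminus: bool) -> int:
        """3' clip cost: free past the reference terminus up to
        clip3_max_free bases (non-templated tails), penalized otherwise."""
        if at_terminus:
            return self.clip_penalty * max(0, n_clipped - self.clip3_max_free)
        return self.clip_penalty * n_clipped


# Alignment ops, 5'->3' on the read:
#   ("S", seq)  5' soft clip
#   ("M", n)    run of n exact matches
#   ("X", base) one mismatch column (payload = read base)
#   ("I", seq)  insertion (read bases absent from the reference)
#   ("D", n)    deletion of n reference bases
#   ("E", seq)  3' soft clip
Op = tuple[str, object]


@dataclass
class AlignmentRecord:
    """A read fit-aligned into one reference gene."""

    read_id: str
    gene_id: str
    ref_start: int
    ref_end: int
    ops: tuple[Op, ...]
    score: float
    n_sub: int = 0
    n_del: int = 0
    n_ins: int = 0
    ambiguous: bool = False
    tied_gene_ids: tuple[str, ...] = ()
    seq: str = ""  # full read sequence including clips

    @property
    def clip5(self) -> str:
        return self.ops[0][1] if self.ops and self.ops[0][0] == "S" else ""

    @property
    def clip3(self) -> str:
        return self.ops[-1][1] if self.ops and self.ops[-1][0] == "E" else ""

    def read_consumed(self) -> int:
        n = 0
        for kind, payload in self.ops:
            if kind in ("S", "I", "E"):
                n += len(payload)
            elif kind == "M":
                n += payload
            elif kind == "X":
                n += 1
        return n

    def ref_consumed(self) -> int:
        n = 0
        for kind, payload in self.ops:
            if kind in ("M", "D"):
                n += payload
            elif kind == "X":
                n += 1
        return n

    def iter_columns(self) -> Iterator[tuple[int, str]]:
        """Yield (reference position, kind) per reference-consuming column;
        kind is "M" (match), "X" (substitution) or "D" (deletion)."""
        pos = self.ref_start
        for kind, payload in self.ops:
            if kind == "M":
                for p in range(pos, pos + payload):
                    yield p, "M"
                pos += payload
            elif kind == "X":
                yield pos, "X"
                pos += 1
            elif kind == "D":
                for p in range(pos, pos + payload):
                    yield p, "D"
                pos += payload

    def insertions(self) -> Iterator[tuple[int, str]]:
        """Yield (reference position of the 5' flanking column, inserted seq)."""
        pos = self.ref_start
        for kind, payload in self.ops:
            if kind == "M":
                pos += payload
            elif kind in ("X", ):
                pos += 1
            elif kind == "D":
                pos += payload
            elif kind == "I":
                yield pos - 1, payload


def score_of(ops: Iterable[Op], scheme: ScoringScheme, ref_len: int, ref_end: int) -> float:
    """Recompute the score of an ops list under the scheme (invariant check)."""
    total = 0.0
    ops = tuple(ops)
    for idx, (kind, payload) in enumerate(ops):
        if kind == "M":
            total += scheme.match * payload
        elif kind == "X":
            total += scheme.mismatch
        elif kind in ("I", "D"):
            ln = len(payload) if kind == "I" else payload
            total += scheme.gap_open + scheme.gap_extend * ln
        elif kind == "S":
            total += scheme.clip5_cost(len(payload))
        elif kind == "E":
            total += scheme.clip3_cost(len(payload), at_terminus=(ref_end == ref_len))
    return total


def min_score(read_len: int) -> float:
    """Mapping threshold as a linear function of read length (the mapper's
    ``L,b,m`` convention: f(x) = b + m*x with b = m = -0.7)."""
    if read_len < 0:
        raise ValueError("read_len must be >= 0")
    return -0.7 - 0.7 * read_len


# ---------------------------------------------------------------------------
# Pair merging and adapter trimming
# ---------------------------------------------------------------------------

def merge_pairs(
    r1: tuple[str, str],
    r2: tuple[str, str],
    min_overlap: int = 30,
    max_mismatch: int = 4,
) -> tuple[tuple[str, str] | None, str]:
    """Merge a read pair into one sequence via the best ungapped overlap.

    ``r2`` is given 5'->3' on the opposite strand and is reverse-complemented
    internally.  Overlaps of at least ``min_overlap`` are scanned; the one
    with fewest mismatches wins (ties -> longest overlap).  More than
    ``max_mismatch`` mismatches in the best overlap rejects the pair.
    Disagreeing overlap bases are resolved by higher quality, ties -> r1.

    Returns (merged (seq, qual) or None, code) with code one of
    "merged", "empty_read", "no_overlap", "too_many_mismatches".
    """
    seq1, qual1 = r1
    seq2, qual2 = r2
    if not seq1 or not seq2:
        return None, "empty_read"
    seq2 = revcomp(seq2)
    qual2 = qual2[::-1]
    a1 = np.frombuffer(seq1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(seq2.encode(), dtype=np.uint8)
    best: tuple[int, int] | None = None  # (mismatches, overlap)
    max_o = min(len(seq1), len(seq2))
    for o in range(min_overlap, max_o + 1):
        mm = int(np.count_nonzero(a1[len(seq1) - o:] != a2[:o]))
        if best is None or mm < best[0] or (mm == best[0] and o > best[1]):
            best = (mm, o)
    if best is None:
        return None, "no_overlap"
    mm, o = best
    if mm > max_mismatch:
        return None, "too_many_mismatches"
    start = len(seq1) - o
    mid_seq = []
    mid_qual = []
    for k in range(o):
        b1, q1 = seq1[start + k], qual1[start + k]
        b2, q2 = seq2[k], qual2[k]
        if b1 == b2 or q1 >= q2:
            mid_seq.append(b1)
            mid_qual.append(max(q1, q2) if b1 == b2 else q1)
        else:
            mid_seq.append(b2)
            mid_qual.append(q2)
    merged_seq = seq1[:start] + "".join(mid_seq) + seq2[o:]
    merged_qual = qual1[:start] + "".join(mid_qual) + qual2[o:]
    return (merged_seq, merged_qual), "merged"


def trim_adapter(seq: str, adapter: str) -> tuple[str | None, str]:
    """Locate the adapter toward the read 3' end (<= 1 mismatch per 10
    adapter bases) and remove it together with everything 3' of it.

    Returns (trimmed insert or None, code) with code one of "trimmed",
    "too_short", "no_adapter".
    """
    if not adapter:
        raise ValueError("adapter_seq must be non-empty")
    la = len(adapter)
    if len(seq) < la:
        return None, "too_short"
    allowed = la // 10
    aa = np.frombuffer(adapter.encode(), dtype=np.uint8)
    aseq = np.frombuffer(seq.encode(), dtype=np.uint8)
    for p in range(0, len(seq) - la + 1):
        mm = int(np.count_nonzero(aseq[p:p + la] != aa))
        if mm <= allowed:
            return seq[:p], "trimmed"
    return None, "no_adapter"


# ---------------------------------------------------------------------------
# Fit alignment (affine-gap dynamic programming)
# ---------------------------------------------------------------------------

def fit_align(
    read: str, gene: TRNAGene, scheme: ScoringScheme = ScoringScheme(), read_id: str = ""
) -> AlignmentRecord | None:
    """Maximum-score fit alignment of ``read`` into ``gene``.

    The read is fully consumed except permitted clips; the aligned span may
    start and end anywhere on the reference.  The optimum is taken over
    alignments consuming at least ``scheme.min_ref_cols`` reference columns
    — the constraint is part of the optimization (a layered DP tracking the
    capped column count), because free end clips would otherwise allow
    degenerate one-column "alignments" to outscore any genuine alignment
    containing an error.  Deterministic tie-break: co-optimal endpoints are
    resolved preferring fewer clipped bases, then smaller ref_start, then
    the lexicographically smallest ops tuple.  Returns None ("unalignable")
    when no qualifying alignment exists.
    """
    n, m = len(read), len(gene.seq)
    K = scheme.min_ref_cols
    if n == 0 or m < K:
        return None
    go, ge = scheme.gap_open, scheme.gap_extend
    sub = np.where(
        np.frombuffer(read.encode(), dtype=np.uint8)[:, None]
        == np.frombuffer(gene.seq.encode(), dtype=np.uint8)[None, :],
        float(scheme.match),
        float(scheme.mismatch),
    )  # (n, m)
    clip5 = np.array([scheme.clip5_cost(i) for i in range(n)], dtype=float)

    # layer k = min(reference columns consumed so far, K); only layer K
    # alignments are eligible at the end
    M = np.full((K + 1, n + 1, m + 1), _NEG)
    Ix = np.full((K + 1, n + 1, m + 1), _NEG)  # gap in reference (insertion in read)
    Iy = np.full((K + 1, n + 1, m + 1), _NEG)  # gap in read (deletion of reference)
    js = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        s_row = sub[i - 1]
        # best predecessor per layer from the previous row, all layers at once
        P = np.maximum(np.maximum(M[:, i - 1], Ix[:, i - 1]), Iy[:, i - 1])
        M[1, i, 1:] = s_row + clip5[i - 1]
        if K >= 2:
            M[2:K, i, 1:] = s_row + P[1:K - 1, :-1]
            M[K, i, 1:] = s_row + np.maximum(P[K - 1, :-1], P[K, :-1])
        # Ix layers: consume read only, layer unchanged
        Ix[1:, i, 1:] = np.maximum(M[1:, i - 1, 1:] + (go + ge), Ix[1:, i - 1, 1:] + ge)
        # Iy layers: consume reference, layer increments (capped at K)
        for k in range(2, K):
            Iy[k, i, 1:] = np.maximum(M[k - 1, i, :-1] + go + ge,
                                      Iy[k - 1, i, :-1] + ge)
        # capped layer: same-layer extension along j in closed form
        src = np.maximum(np.maximum(M[K, i] + go, M[K - 1, i] + go),
                         Iy[K - 1, i])
        a = src - ge * js
        runmax = np.maximum.accumulate(a)[:-1]
        Iy[K, i, 1:] = ge * js[1:] + runmax

    # end bonus: free 3' clip only past the reference terminus (capped)
    end_cost = np.full((n + 1, m + 1), _NEG)
    for i in range(1, n + 1):
        if i == n:
            end_cost[i, 1:] = 0.0
        else:
            end_cost[i, 1:] = scheme.clip3_cost(n - i, at_terminus=False)
            end_cost[i, m] = scheme.clip3_cost(n - i, at_terminus=True)
    total = M[K] + end_cost
    best = float(total[1:, 1:].max(initial=_NEG))
    if best <= _NEG / 2:
        return None
    ends = np.argwhere(total == best)
    candidates = []
    for i, j in ends:
        rec = _traceback(read, gene, scheme, M, Ix, Iy, int(i), int(j), best, read_id)
        if rec is not None:
            candidates.append(rec)
    if not candidates:
        return None
    candidates.sort(key=lambda r: (len(r.clip5) + len(r.clip3), r.ref_start, r.ops))
    return candidates[0]


def _traceback(read, gene, scheme, M, Ix, Iy, i, j, best, read_id) -> AlignmentRecord | None:
    go, ge = scheme.gap_open, scheme.gap_extend
    n = len(read)
    K = scheme.min_ref_cols
    ref_end = j
    cols: list[tuple[str, object]] = []  # reversed op columns
    state, k = "M", K
    tol = 1e-6
    while True:
        if state == "M":
            ri, gj = read[i - 1], gene.seq[j - 1]
            s = scheme.match if ri == gj else scheme.mismatch
            cols.append(("M", None) if ri == gj else ("X", ri))
            target = M[k, i, j] - s
            i, j = i - 1, j - 1
            # predecessors live in layer k-1 (and also k when capped);
            # continuing is preferred over starting (fewer clipped bases)
            found = False
            layers = [k - 1] if k < K else [K, K - 1]
            if k > 1 or k == K:
                for kp in layers:
                    if kp < 1:
                        continue
                    if abs(M[kp, i, j] - target) < tol:
                        state, k, found = "M", kp, True
                        break
                    if abs(Ix[kp, i, j] - target) < tol:
                        state, k, found = "Ix", kp, True
                        break
                    if abs(Iy[kp, i, j] - target) < tol:
                        state, k, found = "Iy", kp, True
                        break
            if not found:
                if abs(scheme.clip5_cost(i) - target) < tol:
                    break  # alignment start
                return None  # numerically impossible path
        elif state == "Ix":  # insertion: consumes read, layer unchanged
            cols.append(("I", read[i - 1]))
            target = Ix[k, i, j]
            if abs(M[k, i - 1, j] + go + ge - target) < tol:
                state = "M"
            else:
                state = "Ix"
            i -= 1
        else:  # Iy deletion: consumes reference, layer decrements (capped)
            cols.append(("D", None))
            target = Iy[k, i, j]
            layers = [(k - 1, True)] if k < K else [(K, False), (K - 1, False), (K - 1, True)]
            nxt = None
            if k < K:
                if abs(M[k - 1, i, j - 1] + go + ge - target) < tol:
                    nxt = ("M", k - 1)
                elif abs(Iy[k - 1, i, j - 1] + ge - target) < tol:
                    nxt = ("Iy", k - 1)
            else:
                if abs(M[K, i, j - 1] + go + ge - target) < tol:
                    nxt = ("M", K)
                elif abs(M[K - 1, i, j - 1] + go + ge - target) < tol:
                    nxt = ("M", K - 1)
                elif abs(Iy[K, i, j - 1] + ge - target) < tol:
                    nxt = ("Iy", K)
                elif abs(Iy[K - 1, i, j - 1] + ge - target) < tol:
                    nxt = ("Iy", K - 1)
            if nxt is None:
                return None
            state, k = nxt
            j -= 1
    ref_start = j
    clip5_seq = read[:i]
    # ops were collected 3'->5'; reverse and run-length merge
    cols.reverse()
    ops: list[Op] = []
    if clip5_seq:
        ops.append(("S", clip5_seq))
    n_sub = n_del = n_ins = 0
    for kind, payload in cols:
        if kind == "M":
            if ops and ops[-1][0] == "M":
                ops[-1] = ("M", ops[-1][1] + 1)
            else:
                ops.append(("M", 1))
        elif kind == "X":
            n_sub += 1
            ops.append(("X", payload))
        elif kind == "I":
            n_ins += 1
            if ops and ops[-1][0] == "I":
                ops[-1] = ("I", ops[-1][1] + payload)
            else:
                ops.append(("I", payload))
        elif kind == "D":
            n_del += 1
            if ops and ops[-1][0] == "D":
                ops[-1] = ("D", ops[-1][1] + 1)
            else:
                ops.append(("D", 1))
    # read positions consumed so far
    consumed = len(clip5_seq) + sum(
        (p if k == "M" else len(p) if k == "I" else 1 if k == "X" else 0)
        for k, p in ops if k != "S"
    )
    clip3_seq = read[consumed:]
    if clip3_seq:
        ops.append(("E", clip3_seq))
    return AlignmentRecord(
        read_id=read_id,
        gene_id=gene.gene_id,
        ref_start=ref_start,
        ref_end=ref_end,
        ops=tuple(ops),
        score=best,
        n_sub=n_sub,
        n_del=n_del,
        n_ins=n_ins,
        seq=read,
    )


def _exact_fit(read: str, gene: TRNAGene, scheme: ScoringScheme, read_id: str) -> AlignmentRecord | None:
    """Fast path: a zero-score (perfect) fit alignment, if one exists.

    Score 0 is the global maximum under the scheme, so an exact hit makes
    full dynamic programming unnecessary.  Covers (a) read (minus a free 5'
    clip) contained in the gene and (b) read running past the gene 3'
    terminus with a free overhang clip.
    """
    n, m = len(read), len(gene.seq)
    if n < scheme.min_ref_cols:
        return None
    # candidates keyed by (total clipped bases, ref_start) for the tie-break
    cands: list[tuple[int, int, int, int, int]] = []  # (clipped, ref_start, k, p, alen)
    for k in range(0, min(scheme.clip5_max_free, n - scheme.min_ref_cols) + 1):
        core = read[k:]
        p = gene.seq.find(core)
        if p >= 0:
            cands.append((k, p, k, p, len(core)))
            continue
        # overhang: read[k:k+mm] matches the gene suffix, the rest runs past
        # the reference 3' terminus and is clipped at zero cost.  Probe with
        # the first min_ref_cols bases so the scan is O(1) for typical reads.
        probe = core[:scheme.min_ref_cols]
        q = 0
        while True:
            q = gene.seq.find(probe, q)
            if q < 0:
                break
            mm = m - q
            if (scheme.min_ref_cols <= mm < len(core)
                    and len(core) - mm <= scheme.clip3_max_free
                    and gene.seq[q:] == core[:mm]):
                cands.append((k + len(core) - mm, q, k, q, mm))
                break
            q += 1
    if not cands:
        return None
    _, _, k, p, alen = min(cands)
    ops: list[Op] = []
    if k:
        ops.append(("S", read[:k]))
    ops.append(("M", alen))
    tail = read[k + alen:]
    if tail:
        ops.append(("E", tail))
    return AlignmentRecord(
        read_id=read_id, gene_id=gene.gene_id, ref_start=p, ref_end=p + alen,
        ops=tuple(ops), score=0.0, seq=read,
    )


def _single_mismatch_fit(read: str, gene: TRNAGene, scheme: ScoringScheme,
                         read_id: str) -> AlignmentRecord | None:
    """Fast path: an ungapped fit alignment with exactly one mismatch and no
    penalized clip (score == scheme.mismatch).

    Only sound when no perfect (score 0) alignment exists: every alternative
    then carries a gap (gap_open + gap_extend < mismatch), a second
    mismatch, or a penalized clip, so a single-mismatch ungapped alignment
    attains the optimum."""
    n, m = len(read), len(gene.seq)
    aread = np.frombuffer(read.encode(), dtype=np.uint8)
    aref = np.frombuffer(gene.seq.encode(), dtype=np.uint8)
    best: tuple[int, int, int] | None = None  # (ref_start, k, core_len)
    for k in range(0, min(scheme.clip5_max_free, n - scheme.min_ref_cols) + 1):
        core = aread[k:]
        for p in range(0, m - len(core) + 1):
            neq = core != aref[p:p + len(core)]
            if int(neq.sum()) == 1:
                cand = (p, k, len(core))
                if best is None or (k, p) < (best[1], best[0]):
                    best = cand
        # overhang past the 3' terminus (free clip, capped), still one mismatch
        for mm in range(min(len(core) - 1, m),
                        max(scheme.min_ref_cols, len(core) - scheme.clip3_max_free) - 1, -1):
            neq = core[:mm] != aref[m - mm:]
            if int(neq.sum()) == 1:
                cand = (m - mm, k, mm)
                if best is None or (k, m - mm) < (best[1], best[0]):
                    best = cand
                break
    if best is None:
        return None
    p, k, core_len = best
    ops: list[Op] = []
    if k:
        ops.append(("S", read[:k]))
    core = aread[k:k + core_len]
    mis = int(np.nonzero(core != aref[p:p + core_len])[0][0])
    if mis:
        ops.append(("M", mis))
    ops.append(("X", read[k + mis]))
    if core_len - mis - 1:
        ops.append(("M", core_len - mis - 1))
    tail = read[k + core_len:]
    if tail:
        ops.append(("E", tail))
    return AlignmentRecord(
        read_id=read_id, gene_id=gene.gene_id, ref_start=p, ref_end=p + core_len,
        ops=tuple(ops), score=float(scheme.mismatch), n_sub=1, seq=read,
    )


def map_read(
    read: str,
    refset: ReferenceSet,
    scheme: ScoringScheme = ScoringScheme(),
    read_id: str = "",
) -> AlignmentRecord | None:
    """Fit-align a read against every gene; best score wins if it clears
    ``min_score(len(read))``.

    Equal best scores for two or more (distinct-sequence) genes set
    ``ambiguous`` and record the tied ids; the returned record belongs to
    the lexicographically smallest tied gene id so the outcome never depends
    on reference order.  Returns None when unmapped.
    """
    if len(refset) == 0:
        raise ValueError("empty reference set")
    # tier 1: perfect (score 0) hits — nothing can beat them, ties only
    exact: dict[str, AlignmentRecord] = {}
    for gene in refset:
        rec = _exact_fit(read, gene, scheme, read_id)
        if rec is not None:
            exact[gene.gene_id] = rec
    if exact:
        tied = sorted(exact)
        rec = exact[tied[0]]
        if len(tied) > 1:
            rec.ambiguous = True
            rec.tied_gene_ids = tuple(tied)
        return rec
    # tier 2: single-mismatch ungapped hits (score == mismatch).  Any
    # alignment scoring better than a gap (gap_open + gap_extend) must be
    # ungapped with <= 1 substitution and no penalized clip, so these two
    # tiers find every gene whose optimum exceeds the best gapped score —
    # full DP is only needed when neither tier fires anywhere.
    near: dict[str, AlignmentRecord] = {}
    shortcut_sound = (scheme.mismatch > scheme.gap_open + scheme.gap_extend
                      and scheme.clip_penalty <= scheme.mismatch)
    if shortcut_sound:
        for gene in refset:
            rec = _single_mismatch_fit(read, gene, scheme, read_id)
            if rec is not None:
                near[gene.gene_id] = rec
    if near:
        tied = sorted(near)
        rec = near[tied[0]]
        if len(tied) > 1:
            rec.ambiguous = True
            rec.tied_gene_ids = tuple(tied)
        return rec
    records: list[AlignmentRecord] = []
    for gene in refset:
        rec = fit_align(read, gene, scheme, read_id=read_id)
        if rec is not None:
            records.append(rec)
    if not records:
        return None
    best = max(r.score for r in records)
    if best < min_score(len(read)):
        return None
    tied = sorted((r for r in records if r.score == best), key=lambda r: r.gene_id)
    rec = tied[0]
    if len(tied) > 1:
        rec.ambiguous = True
        rec.tied_gene_ids = tuple(r.gene_id for r in tied)
    return rec


# ---------------------------------------------------------------------------
# SAM I/O and mapping summaries
# ---------------------------------------------------------------------------

def _cigar_of(rec: AlignmentRecord) -> str:
    parts: list[tuple[int, str]] = []

    def push(n: int, op: str):
        if parts and parts[-1][1] == op:
            parts[-1] = (parts[-1][0] + n, op)
        else:
            parts.append((n, op))

    for kind, payload in rec.ops:
        if kind == "S":
            push(len(payload), "S")
        elif kind == "M":
            push(payload, "M")
        elif kind == "X":
            push(1, "M")
        elif kind == "I":
            push(len(payload), "I")
        elif kind == "D":
            push(payload, "D")
        elif kind == "E":
            push(len(payload), "S")
    return "".join(f"{n}{op}" for n, op in parts)


def write_sam(records: Iterable[AlignmentRecord], refset: ReferenceSet, path: str | Path) -> None:
    """Serialize alignment records as SAM (1-based POS, soft clips, NM tag =
    substitutions + inserted + deleted bases, XA ambiguity flag, XT tied ids)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for g in refset:
            fh.write(f"@SQ\tSN:{g.gene_id}\tLN:{len(g.seq)}\n")
        for rec in records:
            if rec.gene_id not in refset.by_id:
                raise KeyError(f"unknown gene_id {rec.gene_id!r} in alignment record")
            nm = rec.n_sub + rec.n_del + sum(
                len(p) for k, p in rec.ops if k == "I"
            )
            fields = [
                rec.read_id or "read",
                "0",
                rec.gene_id,
                str(rec.ref_start + 1),
                "255",
                _cigar_of(rec),
                "*",
                "0",
                "0",
                rec.seq or "*",
                "*",
                f"NM:i:{nm}",
                f"AS:i:{int(rec.score)}",
                f"XA:i:{1 if rec.ambiguous else 0}",
            ]
            if rec.tied_gene_ids:
                fields.append("XT:Z:" + ",".join(rec.tied_gene_ids))
            fh.write("\t".join(fields) + "\n")


def parse_sam(path: str | Path, refset: ReferenceSet) -> list[AlignmentRecord]:
    """Re-parse a SAM file written by write_sam back into AlignmentRecords.

    Ops are reconstructed by walking the CIGAR against the known reference
    sequence (M columns are re-split into matches and mismatches)."""
    import pysam

    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                continue
            gene = refset.by_id[a.reference_name]
            seq = a.query_sequence or ""
            ops: list[Op] = []
            qpos, rpos = 0, a.reference_start
            first = True
            n_sub = n_del = n_ins = 0
            for op, ln in a.cigartuples:
                if op == 4:  # S
                    clipped = seq[qpos:qpos + ln]
                    ops.append(("S", clipped) if first else ("E", clipped))
                    qpos += ln
                elif op in (0, 7, 8):  # M/=/X
                    for k in range(ln):
                        rb, qb = gene.seq[rpos + k], seq[qpos + k]
                        if rb == qb:
                            if ops and ops[-1][0] == "M":
                                ops[-1] = ("M", ops[-1][1] + 1)
                            else:
                                ops.append(("M", 1))
                        else:
                            n_sub += 1
                            ops.append(("X", qb))
                    qpos += ln
                    rpos += ln
                elif op == 1:  # I
                    n_ins += ln
                    ops.append(("I", seq[qpos:qpos + ln]))
                    qpos += ln
                elif op == 2:  # D
                    n_del += ln
                    ops.append(("D", ln))
                    rpos += ln
                first = False
            rec = AlignmentRecord(
                read_id=a.query_name,
                gene_id=a.reference_name,
                ref_start=a.reference_start,
                ref_end=rpos,
                ops=tuple(ops),
                score=float(a.get_tag("AS")) if a.has_tag("AS") else 0.0,
                n_sub=n_sub,
                n_del=n_del,
                n_ins=n_ins,
                ambiguous=bool(a.get_tag("XA")) if a.has_tag("XA") else False,
                tied_gene_ids=tuple(a.get_tag("XT").split(",")) if a.has_tag("XT") else (),
                seq=seq,
            )
            out.append(rec)
    return out


@dataclass
class MappingSummary:
    processed: int = 0
    merged: int = 0
    trimmed: int = 0
    mapped: int = 0
    ambiguous: int = 0
    unmapped: int = 0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k in ("processed", "merged", "trimmed", "mapped", "ambiguous", "unmapped"):
                fh.write(f"{k}\t{getattr(self, k)}\n")


def map_reads(
    reads: Iterable[tuple[str, str, str]],
    refset: ReferenceSet,
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[list[AlignmentRecord], MappingSummary]:
    """Map a list of (name, seq, qual) reads; returns records + summary."""
    summary = MappingSummary()
    records = []
    for name, seq, _qual in reads:
        summary.processed += 1
        rec = map_read(seq, refset, scheme, read_id=name)
        if rec is None:
            summary.unmapped += 1
            continue
        summary.mapped += 1
        if rec.ambiguous:
            summary.ambiguous += 1
        records.append(rec)
    return records, summary


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out
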