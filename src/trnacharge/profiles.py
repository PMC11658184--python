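"""Sprinzl-anchored positional analytics.

All positional outputs are keyed by Sprinzl labels so that genes of
different lengths are comparable: 5'/3' read-end histograms (hard-stop
modification and fragment breakpoints), misincorporation matrices
(substitution + deletion signatures of base modifications), the paired
CCA-vs-CC modification comparison, the truncation-charging association,
and the 5'-tRF caller.

Conventions adopted throughout:

* a read's 5' position is its first reference-consuming column — 5' soft
  clips (RT terminal-transferase additions) do not shift it;
* a deleted reference position counts as covered *and* misincorporated;
  insertions are attributed to the 5' flanking position and tallied
  separately, excluded from headline rates;
* cells with coverage <= min_cov carry NaN (an explicit mask), never 0;
* 5'-tRF distances are measured from the annotated mature 3' terminus
  including the CCA; ">7 nt" is strict.  Because of the ~35 nt library
  size floor, fragments shorter than that are unobservable: each gene's
  maximum detectable distance is reported alongside the calls rather than
  treating missing short fragments as absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .reference import LABEL_RANK, ReferenceSet, TRNAGene
from .tails import (CATEGORY_CC, CATEGORY_CCA, TailCall, cca_percentage)

DEFAULT_MIN_COV = 50


def _records_by_gene(records: Iterable[AlignmentRecord], exclude_ambiguous: bool = True):
    by_gene: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        if exclude_ambiguous and r.ambiguous:
            continue
        by_gene.setdefault(r.gene_id, []).append(r)
    return by_gene


def gene_position_counts(records: Sequence[AlignmentRecord], gene: TRNAGene) -> pd.DataFrame:
    """Per-reference-position coverage / substitution / deletion / insertion
    counts for one gene (columns: position, sprinzl, coverage, sub, del, ins)."""
    L = len(gene.seq)
    cov = np.zeros(L, dtype=np.int64)
    sub = np.zeros(L, dtype=np.int64)
    dele = np.zeros(L, dtype=np.int64)
    ins = np.zeros(L, dtype=np.int64)
    for rec in records:
        if rec.n_sub == 0 and rec.n_del == 0:
            cov[rec.ref_start:rec.ref_end] += 1
        else:
            for pos, kind in rec.iter_columns():
                cov[pos] += 1
                if kind == "X":
                    sub[pos] += 1
                elif kind == "D":
                    dele[pos] += 1
        for pos, _seq in rec.insertions():
            if 0 <= pos < L:
                ins[pos] += 1
    labels = list(gene.sprinzl) if gene.sprinzl else [""] * L
    return pd.DataFrame({
        "position": np.arange(L), "sprinzl": labels,
        "coverage": cov, "sub": sub, "del": dele, "ins": ins,
    })


@dataclass
class PositionProfile:
    """Per-gene positional values on the gene's Sprinzl axis.

    values are counts per thousand reads mapped to the normalization basis
    (the genome's gene set by default, the gene itself when per-gene
    normalization is requested)."""

    gene_id: str
    labels: tuple[str, ...]
    values: np.ndarray
    basis: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.labels), name=self.gene_id)


def end_histogram(
    records: Iterable[AlignmentRecord],
    refset: ReferenceSet,
    genome: str,
    which_end: str = "five_prime",
    per_gene_basis: bool = False,
    exclude_ambiguous: bool = True,
) -> dict[str, PositionProfile]:
    """Histogram of read 5' start (or 3' end) Sprinzl positions per gene,
    per thousand reads mapped to the genome's gene set.

    Returns an empty dict (undefined profiles) when the genome has no
    mapped reads.  Genes without Sprinzl labels (t-elements, stem-loops)
    are skipped."""
    if which_end not in ("five_prime", "three_prime"):
        raise ValueError(f"which_end={which_end!r}")
    by_gene = _records_by_gene(records, exclude_ambiguous)
    genome_genes = [g for g in refset if g.genome == genome]
    basis = sum(len(by_gene.get(g.gene_id, ())) for g in genome_genes)
    if basis == 0:
        return {}
    out: dict[str, PositionProfile] = {}
    for gene in genome_genes:
        if not gene.sprinzl:
            continue
        recs = by_gene.get(gene.gene_id, [])
        counts = np.zeros(len(gene.seq), dtype=np.int64)
        for r in recs:
            pos = r.ref_start if which_end == "five_prime" else r.ref_end - 1
            counts[pos] += 1
        b = len(recs) if per_gene_basis else basis
        if b == 0:
            continue
        out[gene.gene_id] = PositionProfile(
            gene.gene_id, tuple(gene.sprinzl), 1000.0 * counts / b, b
        )
    return out


def profiles_to_frame(profiles: dict[str, PositionProfile]) -> pd.DataFrame:
    """Genes x Sprinzl-label matrix (union of labels in canonical order)."""
    labels = sorted({l for p in profiles.values() for l in p.labels},
                    key=lambda l: LABEL_RANK[l])
    df = pd.DataFrame(index=sorted(profiles), columns=labels, dtype=float)
    for gid, p in profiles.items():
        for lab, v in zip(p.labels, p.values):
            df.at[gid, lab] = v
    return df


def misincorporation_matrix(
    records: Iterable[AlignmentRecord],
    refset: ReferenceSet,
    min_cov: int = DEFAULT_MIN_COV,
    level: str = "isodecoder",
    exclude_ambiguous: bool = True,
) -> pd.DataFrame:
    """(substitution + deletion) fraction of covering reads per Sprinzl
    position, rows = isodecoder families (or single genes with
    level="gene"), NaN where coverage <= min_cov."""
    by_gene = _records_by_gene(records, exclude_ambiguous)
    # accumulate per (row, label): coverage and sub+del
    acc: dict[str, dict[str, np.ndarray]] = {}
    if level == "gene":
        groups = {g.gene_id: [g.gene_id] for g in refset if g.sprinzl}
    else:
        groups = {
            f"{genome}-{aa}-{ac}" if ac else f"{genome}-{aa}": ids
            for (genome, aa, ac), ids in sorted(refset.isodecoder_map.items())
            if any(refset.by_id[i].sprinzl for i in ids)
        }
    cells: dict[str, dict[str, list[int]]] = {}
    for row_name, gene_ids in groups.items():
        agg: dict[str, list[int]] = {}
        for gid in gene_ids:
            gene = refset.by_id[gid]
            if not gene.sprinzl:
                continue
            pc = gene_position_counts(by_gene.get(gid, []), gene)
            for lab, cov, s, d in zip(pc.sprinzl, pc.coverage, pc["sub"], pc["del"]):
                a = agg.setdefault(lab, [0, 0])
                a[0] += int(cov)
                a[1] += int(s) + int(d)
        cells[row_name] = agg
    labels = sorted({l for agg in cells.values() for l in agg}, key=lambda l: LABEL_RANK[l])
    mat = pd.DataFrame(index=list(cells), columns=labels, dtype=float)
    for row_name, agg in cells.items():
        for lab, (cov, mis) in agg.items():
            mat.at[row_name, lab] = (mis / cov) if cov > min_cov else np.nan
    return mat


@dataclass
class PairedRateComparison:
    """Paired per-site misincorporation rates for CCA vs CC reads."""

    sites: pd.DataFrame  # columns: row, sprinzl, rate_cca, rate_cc
    pearson_r: float
    pearson_p: float
    t_stat: float
    t_p: float
    n_sites: int
    diagnostic: str = ""


def compare_cca_cc(
    records: Sequence[AlignmentRecord],
    calls: Sequence[TailCall],
    refset: ReferenceSet,
    min_cov: int = DEFAULT_MIN_COV,
) -> PairedRateComparison:
    """Misincorporation rates computed separately on CCA-tail reads
    (aminoacylated) and CC-tail reads (uncharged), paired per site.

    Sites are (isodecoder family, Sprinzl label) cells passing min_cov in
    both read classes.  Fewer than 3 shared sites leaves the test undefined
    with a diagnostic."""
    cat_by_read = {c.read_id: c.category for c in calls}
    recs_cca = [r for r in records if cat_by_read.get(r.read_id) == CATEGORY_CCA]
    recs_cc = [r for r in records if cat_by_read.get(r.read_id) == CATEGORY_CC]
    m_cca = misincorporation_matrix(recs_cca, refset, min_cov)
    m_cc = misincorporation_matrix(recs_cc, refset, min_cov)
    rows = []
    common_rows = m_cca.index.intersection(m_cc.index)
    common_cols = m_cca.columns.intersection(m_cc.columns)
    for row in common_rows:
        for col in common_cols:
            a, b = m_cca.at[row, col], m_cc.at[row, col]
            if not (np.isnan(a) or np.isnan(b)):
                rows.append({"row": row, "sprinzl": col, "rate_cca": a, "rate_cc": b})
    sites = pd.DataFrame(rows, columns=["row", "sprinzl", "rate_cca", "rate_cc"])
    if len(sites) < 3:
        return PairedRateComparison(sites, np.nan, np.nan, np.nan, np.nan, len(sites),
                                    diagnostic=f"only {len(sites)} shared sites pass min_cov")
    from scipy import stats as sps

    a = sites.rate_cca.to_numpy()
    b = sites.rate_cc.to_numpy()
    if np.allclose(a.std(), 0) or np.allclose(b.std(), 0):
        r, rp = np.nan, np.nan
        diag = "zero variance in one read class"
    else:
        r, rp = sps.pearsonr(a, b)
        diag = ""
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        t, tp = (0.0, 1.0) if np.allclose(d.mean(), 0) else (np.nan, np.nan)
    else:
        t, tp = sps.ttest_rel(a, b)
    return PairedRateComparison(sites, float(r), float(rp), float(t), float(tp),
                                len(sites), diag)


@dataclass
class TruncationAssociation:
    per_gene: pd.DataFrame  # gene_id, genome, cca_pct_full_length, cca_pct_truncated
    per_genome_tests: pd.DataFrame  # genome, n_genes, mean_diff, t, p
    n_dropped: int


def truncation_association(
    records: Sequence[AlignmentRecord],
    calls: Sequence[TailCall],
    refset: ReferenceSet,
    min_reads: int = 100,
) -> TruncationAssociation:
    """CCA% of full-length-start reads vs 5'-truncated reads per gene, with
    a paired t-test across genes within each genome.

    A read is 5'-truncated when its start label is strictly 3' of Sprinzl
    "1" (first reference-consuming column > 0).  Genes failing min_reads in
    either read class are dropped and counted."""
    cat_by_read = {c.read_id: c.category for c in calls}
    per_gene_counts: dict[str, np.ndarray] = {}
    for r in records:
        cat = cat_by_read.get(r.read_id)
        if cat not in (CATEGORY_CCA, CATEGORY_CC):
            continue
        truncated = r.ref_start > 0
        arr = per_gene_counts.setdefault(r.gene_id, np.zeros(4, dtype=np.int64))
        # [full_cca, full_cc, trunc_cca, trunc_cc]
        arr[2 * truncated + (cat == CATEGORY_CC)] += 1
    rows = []
    n_dropped = 0
    for gid, (fc, fn, tc, tn) in sorted(per_gene_counts.items()):
        full_total, trunc_total = fc + fn, tc + tn
        if full_total < min_reads or trunc_total < min_reads:
            n_dropped += 1
            continue
        rows.append({
            "gene_id": gid,
            "genome": refset.by_id[gid].genome,
            "cca_pct_full_length": cca_percentage(int(fc), int(fn), None),
            "cca_pct_truncated": cca_percentage(int(tc), int(tn), None),
        })
    per_gene = pd.DataFrame(rows, columns=["gene_id", "genome", "cca_pct_full_length",
                                           "cca_pct_truncated"])
    from scipy import stats as sps

    test_rows = []
    for genome, sub in per_gene.groupby("genome"):
        diff = (sub.cca_pct_truncated - sub.cca_pct_full_length).to_numpy()
        if len(diff) < 2 or np.allclose(np.std(diff, ddof=1), 0):
            t, p = np.nan, np.nan
        else:
            t, p = sps.ttest_rel(sub.cca_pct_truncated, sub.cca_pct_full_length)
        test_rows.append({"genome": genome, "n_genes": len(sub),
                          "mean_diff": float(np.mean(diff)) if len(diff) else np.nan,
                          "t": float(t), "p": float(p)})
    per_genome = pd.DataFrame(test_rows, columns=["genome", "n_genes", "mean_diff", "t", "p"])
    return TruncationAssociation(per_gene, per_genome, n_dropped)


# ---------------------------------------------------------------------------
# 5' tRF calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TRFCall:
    """One called 5'-tRF breakpoint.

    distance: nucleotides between the read 3' end and the annotated mature
    3' terminus (strictly greater than min_dist).  The reported position is
    the 3'-most above-threshold member of its cluster; cluster_fraction sums
    only above-threshold members."""

    gene_id: str
    distance: int
    end_position: int  # 0-based reference index of the last aligned base
    fraction: float
    cluster_distances: tuple[int, ...]
    cluster_fraction: float


def call_5prime_trfs(
    records: Sequence[AlignmentRecord],
    gene: TRNAGene,
    min_dist: int = 7,
    min_frac: float = 0.05,
    merge_gap: int = 3,
) -> list[TRFCall]:
    """Call 5'-tRF breakpoints for one gene from read 3'-end positions.

    Candidate positions lie more than ``min_dist`` nt from the annotated 3'
    end and hold more than ``min_frac`` of all reads mapping to the gene.
    Candidates separated by ``merge_gap`` or fewer nucleotides are a single
    tRF reported at the 3'-most (smallest-distance) member."""
    n = len(records)
    if n == 0:
        return []
    counts: dict[int, int] = {}
    for r in records:
        d = len(gene.seq) - r.ref_end
        counts[d] = counts.get(d, 0) + 1
    cands = sorted(
        d for d, c in counts.items() if d > min_dist and c / n > min_frac
    )
    calls: list[TRFCall] = []
    i = 0
    while i < len(cands):
        j = i
        while j + 1 < len(cands) and cands[j + 1] - cands[j] <= merge_gap:
            j += 1
        cluster = tuple(cands[i:j + 1])
        rep = cluster[0]  # smallest distance = 3'-most site
        calls.append(TRFCall(
            gene_id=gene.gene_id,
            distance=rep,
            end_position=len(gene.seq) - rep - 1,
            fraction=counts[rep] / n,
            cluster_distances=cluster,
            cluster_fraction=sum(counts[d] for d in cluster) / n,
        ))
        i = j + 1
    return calls


def trf_table(
    records: Iterable[AlignmentRecord],
    refset: ReferenceSet,
    min_dist: int = 7,
    min_frac: float = 0.05,
    merge_gap: int = 3,
    size_min: int = 35,
    exclude_ambiguous: bool = True,
) -> pd.DataFrame:
    """tRF calls for every gene, with each gene's maximum detectable
    distance under the library size floor (fragments shorter than size_min
    are unobservable, not absent)."""
    by_gene = _records_by_gene(records, exclude_ambiguous)
    rows = []
    for gene in refset:
        recs = by_gene.get(gene.gene_id, [])
        max_detect = len(gene.seq) - size_min
        for call in call_5prime_trfs(recs, gene, min_dist, min_frac, merge_gap):
            rows.append({
                "gene_id": gene.gene_id,
                "distance": call.distance,
                "end_position": call.end_position,
                "sprinzl": gene.sprinzl_of(call.end_position) or "",
                "fraction": call.fraction,
                "cluster_distances": ",".join(map(str, call.cluster_distances)),
                "cluster_fraction": call.cluster_fraction,
                "max_detectable_distance": max_detect,
            })
    return pd.DataFrame(rows, columns=[
        "gene_id", "distance", "end_position", "sprinzl", "fraction",
        "cluster_distances", "cluster_fraction", "max_detectable_distance",
    ])
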