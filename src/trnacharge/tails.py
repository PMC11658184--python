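"""3'-end classification and CCA-tail / charging statistics.

Tail calls are coordinate-based: the category follows from where the
alignment ends on the reference (``end_offset`` = distance of the read's
last reference-consuming column from the reference 3' terminus), never from
base identity.  A mismatched base inside Sprinzl 74-76 is flagged
(``tail_mismatch``) but does not change the category — modification-induced
misincorporations would otherwise corrupt tail calls.

The headline "CCA percentage" follows the convention of reporting intact
CCA tails among reads that lack at most one 3' nucleotide:
``100 * n_CCA / (n_CCA + n_CC)``, while the "non-CC/CCA percentage" is the
fraction of *all* reads missing two or more 3' nucleotides.  The two do not
sum to 100 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .align import AlignmentRecord
from .reference import ReferenceSet, TRNAGene

CATEGORY_CCA = "CCA"
CATEGORY_CC = "CC"
CATEGORY_MISSING = "MISSING2PLUS"
CATEGORY_NONTEMPLATED = "NONTEMPLATED"

#: default per-gene read-count floor below which percentages are undefined
DEFAULT_MIN_READS = 100


@dataclass(frozen=True)
class TailCall:
    read_id: str
    gene_id: str
    end_offset: int
    category: str
    addition: str = ""  # non-templated 3' tail (CCA-less genes only)
    tail_mismatch: bool = False


def classify_tail(aln: AlignmentRecord, gene: TRNAGene) -> TailCall:
    """Classify one aligned read's 3' state.

    Canonical (CCA-bearing) genes: end_offset 0 -> CCA, 1 -> CC, >=2 ->
    MISSING2PLUS; a 3' clip beyond a complete CCA keeps the CCA category
    with the clip recorded as the addition.  CCA-less genes (t-elements,
    stem-loops): NONTEMPLATED, with the 3' clip as the addition string.
    """
    if aln.gene_id != gene.gene_id:
        raise ValueError(f"alignment {aln.read_id} is for {aln.gene_id}, not {gene.gene_id}")
    end_offset = len(gene.seq) - aln.ref_end
    if not gene.has_cca:
        return TailCall(aln.read_id, gene.gene_id, end_offset, CATEGORY_NONTEMPLATED,
                        addition=aln.clip3)
    tail_mismatch = False
    if aln.n_sub or aln.n_del:
        tail_mismatch = any(
            kind in ("X", "D") and pos >= len(gene.seq) - 3
            for pos, kind in aln.iter_columns()
        )
    if end_offset == 0:
        cat = CATEGORY_CCA
    elif end_offset == 1:
        cat = CATEGORY_CC
    else:
        cat = CATEGORY_MISSING
    return TailCall(aln.read_id, gene.gene_id, end_offset, cat,
                    addition=aln.clip3 if end_offset == 0 else "",
                    tail_mismatch=tail_mismatch)


def classify_tails(
    records: Iterable[AlignmentRecord],
    refset: ReferenceSet,
    exclude_ambiguous: bool = True,
) -> list[TailCall]:
    calls = []
    for rec in records:
        if exclude_ambiguous and rec.ambiguous:
            continue
        calls.append(classify_tail(rec, refset.by_id[rec.gene_id]))
    return calls


@dataclass
class LibraryTable:
    """Per-(gene, library) tail-category counts with derived percentages.

    ``table`` columns: gene_id, library, treatment, n_total, n_CCA, n_CC,
    n_missing2plus, cca_pct, noncca_pct (NaN where undefined)."""

    table: pd.DataFrame
    min_reads: int = DEFAULT_MIN_READS

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def row(self, gene_id: str) -> pd.Series:
        sub = self.table[self.table.gene_id == gene_id]
        if sub.empty:
            raise KeyError(gene_id)
        return sub.iloc[0]


def tabulate_library(
    calls: Sequence[TailCall],
    refset: ReferenceSet,
    library: str,
    treatment: str,
    min_reads: int = DEFAULT_MIN_READS,
) -> LibraryTable:
    """Aggregate tail calls into a per-gene LibraryTable (canonical genes;
    NONTEMPLATED calls from CCA-less genes are excluded — see tail_spectrum)."""
    counts: dict[str, dict[str, int]] = {}
    for c in calls:
        d = counts.setdefault(c.gene_id, {CATEGORY_CCA: 0, CATEGORY_CC: 0, CATEGORY_MISSING: 0,
                                          CATEGORY_NONTEMPLATED: 0})
        d[c.category] += 1
    rows = []
    for gene in refset:
        d = counts.get(gene.gene_id)
        if d is None or not gene.has_cca:
            continue
        n_cca, n_cc, n_miss = d[CATEGORY_CCA], d[CATEGORY_CC], d[CATEGORY_MISSING]
        n_total = n_cca + n_cc + n_miss
        rows.append({
            "gene_id": gene.gene_id,
            "genome": gene.genome,
            "library": library,
            "treatment": treatment,
            "n_total": n_total,
            "n_CCA": n_cca,
            "n_CC": n_cc,
            "n_missing2plus": n_miss,
            "cca_pct": cca_percentage(n_cca, n_cc, n_total, min_reads),
            "noncca_pct": noncca_percentage(n_miss, n_total),
        })
    return LibraryTable(pd.DataFrame(rows), min_reads=min_reads)


def cca_percentage(
    n_cca: int, n_cc: int, n_total: int | None = None, min_reads: int = DEFAULT_MIN_READS
) -> float:
    """Intact-CCA percentage after excluding reads missing more than one 3'
    nucleotide: 100 * n_CCA / (n_CCA + n_CC).

    Undefined (NaN, never zero) when the grouping unit has fewer than
    ``min_reads`` total reads or no CCA/CC reads at all.  Pass
    ``n_total=None`` to skip the read floor (pure arithmetic form).
    """
    if n_total is not None and n_total < min_reads:
        return float("nan")
    denom = n_cca + n_cc
    if denom == 0:
        return float("nan")
    return 100.0 * n_cca / denom


def noncca_percentage(n_missing2plus: int, n_total: int) -> float:
    """Fraction of *all* reads lacking two or more 3' nucleotides (percent)."""
    if n_total == 0:
        return float("nan")
    return 100.0 * n_missing2plus / n_total


def charging_index(gene_id: str, periodate: LibraryTable, control: LibraryTable) -> tuple[float, bool]:
    """Periodate CCA% divided by no-periodate control CCA% for one gene.

    Returns (ratio, capped_flag); the flag marks ratios above 1 (possible
    with sampling noise since the control is an imperfect baseline).  NaN
    when either percentage is undefined."""
    try:
        p = periodate.row(gene_id)["cca_pct"]
        c = control.row(gene_id)["cca_pct"]
    except KeyError:
        return float("nan"), False
    if math.isnan(p) or math.isnan(c) or c == 0:
        return float("nan"), False
    ratio = p / c
    return ratio, ratio > 1.0


def retention_ratio(gene_id: str, deacyl_periodate: LibraryTable, periodate: LibraryTable) -> tuple[float, bool]:
    """Pre-deacylated CCA% divided by standard-periodate CCA% for one gene:
    1 means pre-deacylation removed nothing (deacylation-resistant); 0 means
    it eliminated all CCA tails."""
    return charging_index(gene_id, deacyl_periodate, periodate)


def index_table(
    gene_ids: Iterable[str], numerator: LibraryTable, denominator: LibraryTable,
    colname: str = "charging_index",
) -> pd.DataFrame:
    rows = []
    for gid in gene_ids:
        ratio, capped = charging_index(gid, numerator, denominator)
        rows.append({"gene_id": gid, colname: ratio, "capped": capped})
    return pd.DataFrame(rows)


def family_cca_percentages(
    table: LibraryTable,
    refset: ReferenceSet,
    level: str = "isoacceptor",
    weighting: str = "unweighted",
) -> pd.DataFrame:
    """CCA% summarized per isodecoder/isoacceptor family.

    ``weighting="pooled"`` pools raw counts across member genes;
    ``"unweighted"`` (default) averages member-gene percentages, matching
    figure-style family averages.  Both are legitimate; pooled equals the
    count-weighted combination of member values.
    """
    fam_map = refset.isoacceptor_map if level == "isoacceptor" else refset.isodecoder_map
    t = table.table.set_index("gene_id")
    rows = []
    for key, gene_ids in sorted(fam_map.items()):
        members = [g for g in gene_ids if g in t.index]
        if not members:
            continue
        sub = t.loc[members]
        if weighting == "pooled":
            pct = cca_percentage(int(sub.n_CCA.sum()), int(sub.n_CC.sum()),
                                 int(sub.n_total.sum()), table.min_reads)
        else:
            vals = sub.cca_pct.dropna()
            pct = float(vals.mean()) if len(vals) else float("nan")
        row = {"genome": key[0], "amino_acid": key[1], "cca_pct": pct,
               "n_genes": len(members), "n_total": int(sub.n_total.sum())}
        if level == "isodecoder":
            row["anticodon"] = key[2]
        rows.append(row)
    return pd.DataFrame(rows)


def genome_cca_percentages(table: LibraryTable) -> pd.DataFrame:
    """Pooled CCA% and non-CC/CCA% per genome of origin."""
    rows = []
    for genome, sub in table.table.groupby("genome"):
        rows.append({
            "genome": genome,
            "n_total": int(sub.n_total.sum()),
            "cca_pct": cca_percentage(int(sub.n_CCA.sum()), int(sub.n_CC.sum()),
                                      int(sub.n_total.sum()), table.min_reads),
            "noncca_pct": noncca_percentage(int(sub.n_missing2plus.sum()),
                                            int(sub.n_total.sum())),
        })
    return pd.DataFrame(rows)


def tail_spectrum(calls: Sequence[TailCall], gene: TRNAGene) -> pd.DataFrame:
    """Histogram of non-templated 3' additions on a CCA-less gene, sorted by
    count descending (additions reported verbatim; the empty addition is the
    "None" row)."""
    if gene.has_cca:
        raise ValueError(f"{gene.gene_id}: tail_spectrum applies only to CCA-less genes")
    counts: dict[str, int] = {}
    for c in calls:
        if c.gene_id != gene.gene_id:
            continue
        key = c.addition if c.addition else "None"
        counts[key] = counts.get(key, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["addition", "count"])
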