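"""tRNA reference handling: gene model, Sprinzl coordinates, families.

The reference set is a FASTA of mature tRNA / tRNA-like sequences plus a
tab-separated annotation sidecar describing, for every FASTA id, its genome
of origin, structural category, amino acid, anticodon, and the spans of the
canonical structural segments.  Everything downstream (tail classification,
positional profiles) is anchored to these annotations, so loading is strict:
missing or inconsistent annotation is a hard error, never a silent skip.

Coordinates are 0-based half-open internally.  Sequences are stored in DNA
space (U is converted to T on load) and uppercase.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

GENOMES = ("nuclear", "plastid", "mitochondrial", "spike_in")
CATEGORIES = ("canonical", "t_element", "trna_like", "stem_loop")
CCA_STATUSES = ("encoded", "appended", "absent")

_DNA = set("ACGT")

# Canonical structural segments and their supported length ranges.
# D-loop 7-11 nt and variable region 4-23 nt are the supported envelopes;
# anything outside is rejected loudly rather than mislabeled.
SEGMENT_LENGTHS: dict[str, tuple[int, int]] = {
    "acceptor_stem_5": (7, 7),
    "connector_1": (2, 2),
    "d_stem_5": (4, 4),
    "d_loop": (7, 11),
    "d_stem_3": (4, 4),
    "connector_2": (1, 1),
    "anticodon_stem_5": (5, 5),
    "anticodon_loop": (7, 7),
    "anticodon_stem_3": (5, 5),
    "variable": (4, 23),
    "t_stem_5": (5, 5),
    "t_loop": (7, 7),
    "t_stem_3": (5, 5),
    "acceptor_stem_3": (7, 7),
    "discriminator": (1, 1),
    "cca": (3, 3),
}

SEGMENT_ORDER = tuple(SEGMENT_LENGTHS)

# Fixed Sprinzl labels for the constant-length segments.
_FIXED_LABELS: dict[str, tuple[str, ...]] = {
    "acceptor_stem_5": tuple(str(i) for i in range(1, 8)),
    "connector_1": ("8", "9"),
    "d_stem_5": ("10", "11", "12", "13"),
    "d_stem_3": ("22", "23", "24", "25"),
    "connector_2": ("26",),
    "anticodon_stem_5": tuple(str(i) for i in range(27, 32)),
    "anticodon_loop": tuple(str(i) for i in range(32, 39)),
    "anticodon_stem_3": tuple(str(i) for i in range(39, 44)),
    "t_stem_5": tuple(str(i) for i in range(49, 54)),
    "t_loop": tuple(str(i) for i in range(54, 61)),
    "t_stem_3": tuple(str(i) for i in range(61, 66)),
    "acceptor_stem_3": tuple(str(i) for i in range(66, 73)),
    "discriminator": ("73",),
    "cca": ("74", "75", "76"),
}

# D-loop labels by length.  Canonical 8-nt loop is 14..21; a 7-nt loop skips
# position 17; longer loops gain the standard insertion labels 17a/20a/20b.
_D_LOOP_LABELS: dict[int, tuple[str, ...]] = {
    7: ("14", "15", "16", "18", "19", "20", "21"),
    8: ("14", "15", "16", "17", "18", "19", "20", "21"),
    9: ("14", "15", "16", "17", "17a", "18", "19", "20", "21"),
    10: ("14", "15", "16", "17", "17a", "18", "19", "20", "20a", "21"),
    11: ("14", "15", "16", "17", "17a", "18", "19", "20", "20a", "20b", "21"),
}

_MAX_E_LABELS = SEGMENT_LENGTHS["variable"][1] - 3  # middle positions of the longest arm


def _variable_labels(length: int) -> tuple[str, ...]:
    """Sprinzl labels for a variable region of the given length.

    Short regions (4-5 nt) use the canonical 44-48 positions (a 4-nt region
    skips 47).  Long variable arms keep 44/45 and the terminal 48 and label
    the expanded middle with "e"-prefixed insertion labels.
    """
    if length == 4:
        return ("44", "45", "46", "48")
    if length == 5:
        return ("44", "45", "46", "47", "48")
    mid = tuple(f"e{i}" for i in range(1, length - 2))
    return ("44", "45") + mid + ("48",)


def _canonical_label_order() -> tuple[str, ...]:
    order: list[str] = []
    for i in range(1, 17):
        order.append(str(i))
    order += ["17", "17a", "18", "19", "20", "20a", "20b", "21"]
    for i in range(22, 46):
        order.append(str(i))
    order += [f"e{i}" for i in range(1, _MAX_E_LABELS + 1)]
    order += ["46", "47", "48"]
    for i in range(49, 77):
        order.append(str(i))
    return tuple(order)


#: Every Sprinzl label this package can emit, in canonical 5'->3' order.
CANONICAL_LABEL_ORDER: tuple[str, ...] = _canonical_label_order()
LABEL_RANK: dict[str, int] = {lab: i for i, lab in enumerate(CANONICAL_LABEL_ORDER)}


class ReferenceError(ValueError):
    """Raised for any invalid reference input (FASTA/annotation mismatch,
    bad alphabet, segment spans that do not tile the sequence, ...)."""


@dataclass(frozen=True)
class TRNAGene:
    """One reference sequence with its structural annotation.

    ``segments`` is an ordered tuple of ``(label, start, end)`` with 0-based
    half-open spans that must tile ``[0, len(seq))``.  ``sprinzl`` holds one
    canonical label per nucleotide for canonical/tRNA-like genes (empty for
    structures without a cloverleaf annotation).  ``source_ids`` carries all
    FASTA ids collapsed into this gene when byte-identical sequences were
    deduplicated.
    """

    gene_id: str
    genome: str
    category: str
    amino_acid: str
    anticodon: str
    seq: str
    cca_status: str
    segments: tuple[tuple[str, int, int], ...]
    sprinzl: tuple[str, ...] = ()
    source_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.source_ids:
            object.__setattr__(self, "source_ids", (self.gene_id,))

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def has_cca(self) -> bool:
        return self.cca_status in ("encoded", "appended")

    def sprinzl_of(self, pos: int) -> str | None:
        """Sprinzl label of a 0-based reference position (None if unlabeled)."""
        if self.sprinzl and 0 <= pos < len(self.sprinzl):
            return self.sprinzl[pos]
        return None


def validate_gene(gene: TRNAGene) -> None:
    """Check every TRNAGene invariant; raise ReferenceError on violation."""
    if not gene.seq:
        raise ReferenceError(f"{gene.gene_id}: empty sequence")
    bad = set(gene.seq) - _DNA
    if bad:
        raise ReferenceError(f"{gene.gene_id}: non-ACGT characters {sorted(bad)}")
    if gene.genome not in GENOMES:
        raise ReferenceError(f"{gene.gene_id}: unknown genome {gene.genome!r}")
    if gene.category not in CATEGORIES:
        raise ReferenceError(f"{gene.gene_id}: unknown category {gene.category!r}")
    if gene.cca_status not in CCA_STATUSES:
        raise ReferenceError(f"{gene.gene_id}: unknown cca_status {gene.cca_status!r}")
    pos = 0
    for label, start, end in gene.segments:
        if start != pos or end <= start:
            raise ReferenceError(
                f"{gene.gene_id}: segments do not tile the sequence "
                f"(segment {label!r} spans [{start},{end}) but expected start {pos})"
            )
        pos = end
    if pos != len(gene.seq):
        raise ReferenceError(
            f"{gene.gene_id}: segments cover [0,{pos}) but sequence length is {len(gene.seq)}"
        )
    if gene.sprinzl:
        if len(gene.sprinzl) != len(gene.seq):
            raise ReferenceError(f"{gene.gene_id}: sprinzl length != sequence length")
        ranks = []
        for lab in gene.sprinzl:
            if lab not in LABEL_RANK:
                raise ReferenceError(f"{gene.gene_id}: unknown Sprinzl label {lab!r}")
            ranks.append(LABEL_RANK[lab])
        if len(set(gene.sprinzl)) != len(gene.sprinzl):
            raise ReferenceError(f"{gene.gene_id}: duplicate Sprinzl labels")
        if ranks != sorted(ranks):
            raise ReferenceError(f"{gene.gene_id}: Sprinzl labels not monotone")
        if gene.has_cca and tuple(gene.sprinzl[-3:]) != ("74", "75", "76"):
            raise ReferenceError(f"{gene.gene_id}: CCA gene must end with labels 74,75,76")
        if not gene.has_cca and {"74", "75", "76"} & set(gene.sprinzl):
            raise ReferenceError(f"{gene.gene_id}: CCA-less gene carries 74/75/76 labels")
    if gene.has_cca and not gene.seq.endswith("CCA"):
        raise ReferenceError(f"{gene.gene_id}: cca_status={gene.cca_status} but sequence does not end CCA")


def assign_sprinzl(gene: TRNAGene) -> tuple[str, ...]:
    """Assign one canonical Sprinzl label per nucleotide from the segment
    annotation.

    Constant-length segments carry their fixed labels.  The D-loop and
    variable region are labeled by length: short D-loops skip position 17,
    long ones gain 17a/20a/20b; variable regions longer than 5 nt keep
    44/45/48 and fill the middle with e-labels.  Segment lengths outside the
    supported envelope are a hard error naming the segment.
    """
    labels: list[str] = []
    for seg_label, start, end in gene.segments:
        length = end - start
        if seg_label not in SEGMENT_LENGTHS:
            raise ReferenceError(f"{gene.gene_id}: unknown segment label {seg_label!r}")
        lo, hi = SEGMENT_LENGTHS[seg_label]
        if not lo <= length <= hi:
            raise ReferenceError(
                f"{gene.gene_id}: segment {seg_label!r} length {length} outside "
                f"supported range [{lo},{hi}]"
            )
        if seg_label == "d_loop":
            labels.extend(_D_LOOP_LABELS[length])
        elif seg_label == "variable":
            labels.extend(_variable_labels(length))
        else:
            labels.extend(_FIXED_LABELS[seg_label])
    return tuple(labels)


def ensure_cca(gene: TRNAGene) -> TRNAGene:
    """Normalize the 3' end of a canonical gene so tail classification is
    uniform: canonical genes without a genomic CCA get one appended
    (cca_status="appended"); canonical genes already ending in an annotated
    CCA are marked "encoded"; non-canonical genes (t-elements, stem-loops,
    tRNA-like) are returned unchanged with cca_status="absent"."""
    if gene.category != "canonical":
        if gene.cca_status != "absent":
            gene = dataclasses.replace(gene, cca_status="absent")
        return gene
    if gene.seq.endswith("CCA") and gene.segments and gene.segments[-1][0] == "cca":
        if gene.cca_status != "encoded":
            gene = dataclasses.replace(gene, cca_status="encoded")
        return gene
    n = len(gene.seq)
    new = dataclasses.replace(
        gene,
        seq=gene.seq + "CCA",
        segments=gene.segments + (("cca", n, n + 3),),
        cca_status="appended",
    )
    if gene.sprinzl or _uses_canonical_segments(gene):
        new = dataclasses.replace(new, sprinzl=assign_sprinzl(new))
    validate_gene(new)
    return new


def _uses_canonical_segments(gene: TRNAGene) -> bool:
    return all(label in SEGMENT_LENGTHS for label, _, _ in gene.segments)


@dataclass
class ReferenceSet:
    """A validated collection of TRNAGene with family lookups.

    Isodecoder families share (genome, amino acid, anticodon); isoacceptor
    families share (genome, amino acid).  Elongator and initiator Met stay
    distinct through their amino-acid labels "Met(e)" / "Met(i)"."""

    genes: list[TRNAGene]
    by_id: dict[str, TRNAGene] = field(default_factory=dict, repr=False)
    isodecoder_map: dict[tuple[str, str, str], list[str]] = field(default_factory=dict, repr=False)
    isoacceptor_map: dict[tuple[str, str], list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ReferenceError("duplicate gene ids in reference set")
        seqs = [g.seq for g in self.genes]
        if len(set(seqs)) != len(seqs):
            raise ReferenceError("duplicate sequences in reference set (dedup first)")
        self.by_id = {g.gene_id: g for g in self.genes}
        self.isodecoder_map, self.isoacceptor_map = group_families_from_genes(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def canonicalize(self) -> "ReferenceSet":
        """Apply ensure_cca to every gene (idempotent)."""
        return ReferenceSet([ensure_cca(g) for g in self.genes])

    def genome_of(self, gene_id: str) -> str:
        return self.by_id[gene_id].genome


def group_families_from_genes(
    genes: Iterable[TRNAGene],
) -> tuple[dict[tuple[str, str, str], list[str]], dict[tuple[str, str], list[str]]]:
    isodecoder: dict[tuple[str, str, str], list[str]] = {}
    isoacceptor: dict[tuple[str, str], list[str]] = {}
    for g in genes:
        isodecoder.setdefault((g.genome, g.amino_acid, g.anticodon), []).append(g.gene_id)
        isoacceptor.setdefault((g.genome, g.amino_acid), []).append(g.gene_id)
    return isodecoder, isoacceptor


def group_families(refset: ReferenceSet):
    """(isodecoder_map, isoacceptor_map) keyed by (genome, aa, anticodon)
    and (genome, aa) respectively."""
    return refset.isodecoder_map, refset.isoacceptor_map


# ---------------------------------------------------------------------------
# Annotation sidecar I/O
#
# Tab-separated columns:
#   id  genome  category  aa  anticodon  cca_encoded  segments
# where segments is a semicolon list of "label:start-end" with 0-based
# half-open spans, e.g. "acceptor_stem_5:0-7;connector_1:7-9;...".
# Non-cloverleaf structures (t-elements, stem-loops) may use a single
# "body:0-N" segment and receive no Sprinzl labels.
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("id", "genome", "category", "aa", "anticodon", "cca_encoded", "segments")


def _parse_segments(text: str) -> tuple[tuple[str, int, int], ...]:
    out = []
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        label, _, span = chunk.partition(":")
        start_s, _, end_s = span.partition("-")
        out.append((label.strip(), int(start_s), int(end_s)))
    return tuple(out)


def _format_segments(segments) -> str:
    return ";".join(f"{label}:{start}-{end}" for label, start, end in segments)


def read_annotation(path: str | Path) -> dict[str, dict]:
    rows: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ANNOTATION_COLUMNS:
            raise ReferenceError(
                f"annotation header {header} != expected {list(ANNOTATION_COLUMNS)}"
            )
        for line in fh:
            if not line.strip():
                continue
            vals = line.rstrip("\n").split("\t")
            row = dict(zip(ANNOTATION_COLUMNS, vals))
            rows[row["id"]] = row
    return rows


def load_reference(fasta_path: str | Path, annotation_path: str | Path) -> ReferenceSet:
    """Load and validate a reference set from FASTA + annotation TSV.

    Sequences are uppercased and U->T converted.  Entries with byte-identical
    sequences are collapsed into one gene carrying all source ids (the first
    id in file order names the merged gene).  Every FASTA id must have an
    annotation row; any alphabet or segment-tiling problem is a hard error.
    """
    ann = read_annotation(annotation_path)
    genes: list[TRNAGene] = []
    seen_seq: dict[str, int] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        fid = rec.id
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _DNA
        if bad:
            raise ReferenceError(f"{fid}: non-ACGTU characters {sorted(bad)}")
        if fid not in ann:
            raise ReferenceError(f"{fid}: no annotation row")
        if seq in seen_seq:
            # byte-identical sequence: merge ids into the existing gene
            i = seen_seq[seq]
            g = genes[i]
            genes[i] = dataclasses.replace(g, source_ids=g.source_ids + (fid,))
            continue
        row = ann[fid]
        segments = _parse_segments(row["segments"])
        cca_encoded = row["cca_encoded"].strip().lower() in ("1", "true", "yes")
        cca_status = "encoded" if cca_encoded else "absent"
        gene = TRNAGene(
            gene_id=fid,
            genome=row["genome"].strip(),
            category=row["category"].strip(),
            amino_acid=row["aa"].strip(),
            anticodon=row["anticodon"].strip().upper().replace("U", "T"),
            seq=seq,
            cca_status=cca_status,
            segments=segments,
        )
        if _uses_canonical_segments(gene):
            gene = dataclasses.replace(gene, sprinzl=assign_sprinzl(gene))
        validate_gene(gene)
        seen_seq[seq] = len(genes)
        genes.append(gene)
    return ReferenceSet(genes)


def write_annotation(refset: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for g in refset:
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.genome,
                        g.category,
                        g.amino_acid,
                        g.anticodon,
                        # an appended CCA is part of the serialized sequence,
                        # so it reloads as encoded
                        "yes" if g.has_cca else "no",
                        _format_segments(g.segments),
                    ]
                )
                + "\n"
            )


def write_fasta(refset: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in refset:
            fh.write(f">{g.gene_id}\n{g.seq}\n")


def write_sprinzl_tsv(refset: ReferenceSet, path: str | Path) -> None:
    """Export per-gene position -> Sprinzl label maps (gene, 0-based pos,
    base, label)."""
    with open(path, "w") as fh:
        fh.write("gene_id\tposition\tbase\tsprinzl\n")
        for g in refset:
            for i, lab in enumerate(g.sprinzl):
                fh.write(f"{g.gene_id}\t{i}\t{g.seq[i]}\t{lab}\n")


def convert_plantrna_table(path: str | Path) -> None:  # pragma: no cover - stub
    """Placeholder for converting a plantRNA structural-annotation export into
    the TSV sidecar schema above.  Not implemented: the sidecar format is the
    supported input; see README for the column definitions."""
    raise NotImplementedError(
        "write an annotation TSV with columns "
        + ", ".join(ANNOTATION_COLUMNS)
        + " (segments as 'label:start-end' semicolon list, 0-based half-open)"
    )
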