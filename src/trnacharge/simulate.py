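"""Seeded synthetic MSR-seq libraries with ground truth.

The generator emulates the physical chain the analysis assumes:

1. each tRNA molecule is aminoacylated with gene-specific probability theta;
   a charged molecule necessarily carries an intact CCA (the amino acid is
   esterified to the terminal A);
2. uncharged molecules carry an intact CCA with probability
   ``cca_intact_uncharged`` and otherwise end in CC (the in-vivo CC pool and
   extraction damage are indistinguishable to the assay, so one knob models
   both);
3. periodate treatment removes the terminal nucleotide of any molecule with
   a free 3' end with efficiency ``periodate_eff``; charged molecules are
   protected.  A pre-deacylation treatment first strips amino acids with
   efficiency ``deacyl_eff`` (scaled down by a gene-specific
   ``deacyl_resistance``);
4. independent off-target 3' degradation removes 1 + Geometric(p) extra
   nucleotides with treatment-dependent probability (handling damage in
   controls, harsher chemistry damage under periodate);
5. reverse transcription scans 3'->5': hard-stop modification sites truncate
   the cDNA immediately 3' of the site, surviving sites may emit a deletion
   or a misincorporated base, and terminal-transferase activity appends a
   few random bases past the template 5' end;
6. a ~35 nt size-selection floor drops short products.

Identical config + seed produces byte-identical FASTQ and manifest.  The
truth manifest records per-gene molecule fates and 3'-state counts before
size selection so downstream recovery can be tested quantitatively.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import ReferenceSet, TRNAGene, ensure_cca, assign_sprinzl

TREATMENTS = ("control", "periodate", "deacyl_periodate")

#: default off-target 3'-degradation probability per treatment
DEFAULT_EXTRA_DEGRADATION = {"control": 0.10, "periodate": 0.35, "deacyl_periodate": 0.35}

_BASES = "ACGT"

FATES = (
    "charged_protected",
    "terminal_removed",
    "extra_degraded",
    "trf",
    "rt_truncated",
    "intact_uncharged",
)


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ModSite:
    """A modified template position (named by Sprinzl label).

    When reverse transcription reaches the site it stops with ``stop_prob``
    (truncating the read immediately 3' of the site).  If it reads through,
    the site emits a deletion with ``del_prob`` or a substituted base with
    ``sub_prob`` (drawn from ``sub_base_probs`` over ACGT; default uniform
    over the three non-template bases).  Otherwise the template base is
    copied faithfully.
    """

    label: str
    stop_prob: float = 0.0
    del_prob: float = 0.0
    sub_prob: float = 0.0
    sub_base_probs: tuple[float, float, float, float] | None = None  # order ACGT

    def validate(self) -> None:
        for p in (self.stop_prob, self.del_prob, self.sub_prob):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"mod site {self.label}: probability {p} outside [0,1]")
        if self.del_prob + self.sub_prob > 1.0 + 1e-12:
            raise SimulationError(f"mod site {self.label}: del_prob + sub_prob > 1")
        if self.sub_base_probs is not None:
            if len(self.sub_base_probs) != 4 or abs(sum(self.sub_base_probs) - 1.0) > 1e-9:
                raise SimulationError(f"mod site {self.label}: sub_base_probs must sum to 1")


@dataclass(frozen=True)
class GeneParams:
    """Per-gene simulation parameters.

    theta is the aminoacylation (charging) fraction.  tRF molecules are
    generated as independent species: a 5' fragment spans [0, breakpoint)
    and a 3' fragment spans [breakpoint, len); both are uncharged and
    ligatable.
    """

    theta: float = 0.55
    cca_intact_uncharged: float = 0.8
    deacyl_resistance: float = 0.0
    mod_sites: tuple[ModSite, ...] = ()
    trf_5prime_prob: float = 0.0
    trf_5prime_breakpoint: int | None = None
    trf_3prime_prob: float = 0.0
    trf_3prime_breakpoint: int | None = None

    def validate(self, gene: TRNAGene) -> None:
        for name in ("theta", "cca_intact_uncharged", "deacyl_resistance",
                     "trf_5prime_prob", "trf_3prime_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{gene.gene_id}: {name}={v} outside [0,1]")
        if self.trf_5prime_prob + self.trf_3prime_prob > 1.0 + 1e-12:
            raise SimulationError(f"{gene.gene_id}: tRF probabilities sum above 1")
        for prob, bp, name in (
            (self.trf_5prime_prob, self.trf_5prime_breakpoint, "trf_5prime_breakpoint"),
            (self.trf_3prime_prob, self.trf_3prime_breakpoint, "trf_3prime_breakpoint"),
        ):
            if prob > 0:
                if bp is None or not 0 < bp < len(gene.seq):
                    raise SimulationError(f"{gene.gene_id}: {name}={bp} not inside the gene")
        for site in self.mod_sites:
            site.validate()
            if gene.sprinzl and site.label not in gene.sprinzl:
                raise SimulationError(
                    f"{gene.gene_id}: mod site label {site.label!r} not in gene's Sprinzl map"
                )


@dataclass
class SimulationConfig:
    """Everything needed to generate one library deterministically."""

    seed: int
    n_reads_per_gene: int
    treatment: str
    gene_params: dict[str, GeneParams] = field(default_factory=dict)
    default_params: GeneParams = field(default_factory=GeneParams)
    # chemistry
    periodate_eff: float = 0.98
    deacyl_eff: float = 0.9
    extra_degradation: float | None = None  # None -> treatment default
    extra_degradation_geom: float = 0.5
    # reverse transcription
    terminal_transferase_prob: float = 0.3
    max_5prime_ext: int = 3
    # library construction
    size_min: int = 35
    anonymize_names: bool = False
    library_index: int = 0

    def params_for(self, gene_id: str) -> GeneParams:
        return self.gene_params.get(gene_id, self.default_params)

    @property
    def extra_degradation_rate(self) -> float:
        if self.extra_degradation is not None:
            return self.extra_degradation
        return DEFAULT_EXTRA_DEGRADATION[self.treatment]

    def validate(self, refset: ReferenceSet) -> None:
        if self.treatment not in TREATMENTS:
            raise SimulationError(f"unknown treatment {self.treatment!r}")
        if self.n_reads_per_gene <= 0:
            raise SimulationError("n_reads_per_gene must be positive")
        for name in ("periodate_eff", "deacyl_eff", "extra_degradation_geom",
                     "terminal_transferase_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0,1]")
        if self.extra_degradation is not None and not 0.0 <= self.extra_degradation <= 1.0:
            raise SimulationError("extra_degradation outside [0,1]")
        if self.extra_degradation_geom <= 0.0:
            raise SimulationError("extra_degradation_geom must be > 0")
        if self.max_5prime_ext < 1:
            raise SimulationError("max_5prime_ext must be >= 1")
        for gid in self.gene_params:
            if gid not in refset.by_id:
                raise SimulationError(f"gene_params references unknown gene {gid!r}")
        for gene in refset:
            self.params_for(gene.gene_id).validate(gene)

    def rng(self) -> np.random.Generator:
        # one stream per library, seeded from (seed, library index)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(self.library_index,))
        )


@dataclass
class Molecule:
    """One RNA molecule between extraction and reverse transcription;
    spans [ref_start, ref_end) of its gene."""

    gene: TRNAGene
    ref_start: int
    ref_end: int
    charged: bool
    is_trf: bool = False
    terminal_removed: bool = False
    extra_removed: int = 0

    @property
    def end_offset(self) -> int:
        return len(self.gene.seq) - self.ref_end


def apply_treatment(mol: Molecule, config: SimulationConfig, rng: np.random.Generator) -> Molecule:
    """Apply deacylation / periodate / off-target degradation to a molecule.

    Pre-deacylation strips the amino acid with probability
    deacyl_eff * (1 - deacyl_resistance).  Periodate then removes the
    terminal nucleotide of every molecule with a free 3' end with
    probability periodate_eff (charged molecules are protected).
    Independently, any molecule (charged or not) suffers extra 3' loss of
    1 + Geometric(extra_degradation_geom) nucleotides with the treatment's
    extra-degradation probability.
    """
    if config.treatment == "deacyl_periodate" and mol.charged:
        p_deacyl = config.deacyl_eff * (1.0 - config.params_for(mol.gene.gene_id).deacyl_resistance)
        if rng.random() < p_deacyl:
            mol.charged = False
    if config.treatment in ("periodate", "deacyl_periodate"):
        if not mol.charged and rng.random() < config.periodate_eff:
            if mol.ref_end > mol.ref_start:
                mol.ref_end -= 1
                mol.terminal_removed = True
    if rng.random() < config.extra_degradation_rate:
        # rng.geometric has support {1,2,...}: exactly the 1 + Geometric(p)
        # loss model (one guaranteed nucleotide plus a geometric tail)
        k = int(rng.geometric(config.extra_degradation_geom))
        k = min(k, mol.ref_end - mol.ref_start)
        mol.ref_end -= k
        mol.extra_removed = k
    return mol


def _resolve_mod_sites(gene: TRNAGene, params: GeneParams) -> list[tuple[int, ModSite]]:
    """Map Sprinzl-labeled mod sites to 0-based reference positions, sorted
    3'->5' (descending position), the order RT encounters them."""
    if not params.mod_sites or not gene.sprinzl:
        return []
    index = {lab: i for i, lab in enumerate(gene.sprinzl)}
    out = [(index[s.label], s) for s in params.mod_sites if s.label in index]
    out.sort(key=lambda t: -t[0])
    return out


def _draw_sub_base(site: ModSite, template: str, rng: np.random.Generator) -> str:
    if site.sub_base_probs is None:
        choices = [b for b in _BASES if b != template]
        return choices[int(rng.integers(0, len(choices)))]
    r = rng.random()
    acc = 0.0
    for base, p in zip(_BASES, site.sub_base_probs):
        acc += p
        if r < acc:
            return base
    return _BASES[-1]


def reverse_transcribe(
    mol: Molecule,
    mod_positions: list[tuple[int, ModSite]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, int, bool, int]:
    """Produce the read sequence for one molecule.

    Returns (read_seq, read_ref_start, rt_stopped, n_deletions).  RT scans
    3'->5'; a hard stop at reference position p leaves a read whose 5' end
    is p+1.  Surviving sites emit deletions or substitutions.  With
    probability terminal_transferase_prob, 1..max_5prime_ext random bases
    are appended past the template 5' end (they become 5' soft clips when
    mapped).
    """
    start, end = mol.ref_start, mol.ref_end
    events: dict[int, str] = {}  # ref position -> "-" (deletion) or substituted base
    stopped = False
    for pos, site in mod_positions:  # descending position = RT encounter order
        if pos < start or pos >= end:
            continue
        if site.stop_prob > 0 and rng.random() < site.stop_prob:
            start = pos + 1
            stopped = True
            break
        if site.del_prob > 0 or site.sub_prob > 0:
            r = rng.random()
            if r < site.del_prob:
                events[pos] = "-"
            elif r < site.del_prob + site.sub_prob:
                events[pos] = _draw_sub_base(site, mol.gene.seq[pos], rng)
    n_del = 0
    if events:
        chars = []
        for p in range(start, end):
            ev = events.get(p)
            if ev is None:
                chars.append(mol.gene.seq[p])
            elif ev == "-":
                n_del += 1
            else:
                chars.append(ev)
        seq = "".join(chars)
    else:
        seq = mol.gene.seq[start:end]
    if config.terminal_transferase_prob > 0 and rng.random() < config.terminal_transferase_prob:
        k = int(rng.integers(1, config.max_5prime_ext + 1))
        ext = "".join(_BASES[i] for i in rng.integers(0, 4, size=k))
        seq = ext + seq
    return seq, start, stopped, n_del


@dataclass
class TruthManifest:
    """Simulator ground truth: one row per gene with the theta used, molecule
    counts by fate, and 3'-state counts (before size selection)."""

    table: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthManifest":
        return cls(pd.read_csv(path, sep="\t"))


def _classify_fate(mol: Molecule, charged_at_start: bool, stopped: bool) -> str:
    if mol.is_trf:
        return "trf"
    if mol.extra_removed > 0:
        return "extra_degraded"
    if mol.terminal_removed:
        return "terminal_removed"
    if stopped:
        return "rt_truncated"
    if mol.charged:
        return "charged_protected"
    return "intact_uncharged"


def simulate_library(
    config: SimulationConfig, refset: ReferenceSet
) -> tuple[list[tuple[str, str, str]], TruthManifest]:
    """Generate one library: a list of (name, sequence, quality) reads plus
    the ground-truth manifest.

    The reference set must be canonicalized (``ReferenceSet.canonicalize``)
    so every canonical gene ends in CCA.  Read names encode gene id, fate
    and 3' end offset for white-box tests unless ``anonymize_names`` is set.
    """
    config.validate(refset)
    for g in refset:
        if g.category == "canonical" and not g.has_cca:
            raise SimulationError(f"{g.gene_id}: canonicalize the reference set first (ensure_cca)")
    rng = config.rng()
    reads: list[tuple[str, str, str]] = []
    rows = []
    read_counter = 0
    for gene in refset:
        params = config.params_for(gene.gene_id)
        mod_positions = _resolve_mod_sites(gene, params)
        L = len(gene.seq)
        fate_counts = dict.fromkeys(FATES, 0)
        tail_counts = {"n_cca": 0, "n_cc": 0, "n_missing2plus": 0}
        n_emitted = 0
        for i in range(config.n_reads_per_gene):
            u = rng.random()
            if u < params.trf_5prime_prob:
                mol = Molecule(gene, 0, params.trf_5prime_breakpoint, charged=False, is_trf=True)
            elif u < params.trf_5prime_prob + params.trf_3prime_prob:
                mol = Molecule(gene, params.trf_3prime_breakpoint, L, charged=False, is_trf=True)
            else:
                charged = rng.random() < params.theta
                if charged:
                    mol = Molecule(gene, 0, L, charged=True)
                else:
                    intact = rng.random() < params.cca_intact_uncharged
                    mol = Molecule(gene, 0, L if intact else L - 1, charged=False)
            charged_at_start = mol.charged
            mol = apply_treatment(mol, config, rng)
            seq, read_start, stopped, _n_del = reverse_transcribe(mol, mod_positions, config, rng)
            fate = _classify_fate(mol, charged_at_start, stopped)
            fate_counts[fate] += 1
            off = mol.end_offset
            if off == 0:
                tail_counts["n_cca"] += 1
            elif off == 1:
                tail_counts["n_cc"] += 1
            else:
                tail_counts["n_missing2plus"] += 1
            if len(seq) < config.size_min:
                continue
            if config.anonymize_names:
                name = f"r{read_counter:08d}"
            else:
                name = f"{gene.gene_id}|m{i:06d}|{fate}|off{off}"
            reads.append((name, seq, "I" * len(seq)))
            n_emitted += 1
            read_counter += 1
        row = {
            "gene_id": gene.gene_id,
            "genome": gene.genome,
            "treatment": config.treatment,
            "theta": params.theta,
            "n_molecules": config.n_reads_per_gene,
            "n_emitted": n_emitted,
        }
        row.update({f"n_{f}": fate_counts[f] for f in FATES})
        row.update(tail_counts)
        rows.append(row)
    truth = TruthManifest(pd.DataFrame(rows))
    return reads, truth


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def split_paired(
    reads: list[tuple[str, str, str]], read_len: int = 150, min_overlap: int = 30
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Optional paired-end mode: split each merged read into overlapping
    R1 (5' forward) and R2 (3' reverse-complement) with overlap >= min_overlap."""
    comp = str.maketrans("ACGT", "TGCA")
    r1s, r2s = [], []
    for name, seq, _ in reads:
        r1 = seq[:read_len]
        r2 = seq[max(0, len(seq) - read_len):].translate(comp)[::-1]
        if len(seq) > 2 * read_len - min_overlap:
            # enforce the overlap guarantee by lengthening both mates
            half = (len(seq) + min_overlap + 1) // 2
            r1 = seq[:half]
            r2 = seq[len(seq) - half:].translate(comp)[::-1]
        r1s.append((name, r1, "I" * len(r1)))
        r2s.append((name, r2, "I" * len(r2)))
    return r1s, r2s


# ---------------------------------------------------------------------------
# Synthetic reference construction (for tests, examples, and the no-download
# acceptance pipeline).  Structurally valid cloverleaves with randomized
# sequence; anticodons are written into positions 34-36.
# ---------------------------------------------------------------------------

_AA_CYCLE = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met(e)", "Met(i)", "Phe", "Pro", "Ser", "Thr", "Trp",
    "Tyr", "Val",
)


def make_canonical_gene(
    gene_id: str,
    rng: np.random.Generator,
    *,
    genome: str = "nuclear",
    amino_acid: str = "Ala",
    anticodon: str | None = None,
    d_loop_len: int = 8,
    variable_len: int = 5,
    with_cca: bool = True,
) -> TRNAGene:
    """A structurally valid random canonical tRNA gene.

    With the default d_loop_len=8 and variable_len=5 the mature sequence is
    76 nt and carries consecutive Sprinzl labels 1..76.
    """
    lengths = [
        ("acceptor_stem_5", 7), ("connector_1", 2), ("d_stem_5", 4),
        ("d_loop", d_loop_len), ("d_stem_3", 4), ("connector_2", 1),
        ("anticodon_stem_5", 5), ("anticodon_loop", 7), ("anticodon_stem_3", 5),
        ("variable", variable_len), ("t_stem_5", 5), ("t_loop", 7),
        ("t_stem_3", 5), ("acceptor_stem_3", 7), ("discriminator", 1),
    ]
    segments = []
    pos = 0
    for label, ln in lengths:
        segments.append((label, pos, pos + ln))
        pos += ln
    body_len = pos
    seq = list(_BASES[i] for i in rng.integers(0, 4, size=body_len))
    if anticodon is None:
        anticodon = "".join(_BASES[i] for i in rng.integers(0, 4, size=3))
    ac_start = dict((lab, (s, e)) for lab, s, e in segments)["anticodon_loop"][0] + 2
    seq[ac_start:ac_start + 3] = list(anticodon)
    gene = TRNAGene(
        gene_id=gene_id,
        genome=genome,
        category="canonical",
        amino_acid=amino_acid,
        anticodon=anticodon,
        seq="".join(seq),
        cca_status="absent",
        segments=tuple(segments),
    )
    gene = dataclasses.replace(gene, sprinzl=assign_sprinzl(gene))
    if with_cca:
        gene = ensure_cca(gene)
    return gene


def make_t_element(gene_id: str, rng: np.random.Generator, length: int = 60) -> TRNAGene:
    """A mitochondrial t-element: tRNA-like, no genomic (or appended) CCA."""
    seq = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
    return TRNAGene(
        gene_id=gene_id,
        genome="mitochondrial",
        category="t_element",
        amino_acid="---",
        anticodon="",
        seq=seq,
        cca_status="absent",
        segments=(("body", 0, length),),
    )


def make_spike_in(gene_id: str, rng: np.random.Generator) -> TRNAGene:
    """A synthetic uncharged spike-in tRNA (canonical structure, genome
    spike_in) that flows through tail classification unchanged."""
    return make_canonical_gene(gene_id, rng, genome="spike_in", amino_acid="Ile",
                               anticodon="GAT")


def random_reference_set(
    n_genes: int,
    seed: int,
    *,
    include_t_element: bool = False,
    include_spike_in: bool = False,
    genome_cycle: tuple[str, ...] = ("nuclear", "nuclear", "nuclear", "plastid", "mitochondrial"),
) -> ReferenceSet:
    """A deterministic synthetic reference set of canonical genes (plus
    optional t-element and spike-in) suitable for end-to-end runs."""
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        aa = _AA_CYCLE[i % len(_AA_CYCLE)]
        genome = genome_cycle[i % len(genome_cycle)]
        d_loop = int(rng.integers(7, 10))
        var = int(rng.integers(4, 6))
        genes.append(
            make_canonical_gene(
                f"{genome[:3]}-tRNA-{aa}-{i + 1:03d}", rng, genome=genome, amino_acid=aa,
                d_loop_len=d_loop, variable_len=var,
            )
        )
    if include_t_element:
        genes.append(make_t_element("mit-tE-ccmC", rng))
    if include_spike_in:
        genes.append(make_spike_in("spike-tRNA-Ile", rng))
    return ReferenceSet(genes)
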