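"""Canned synthetic experiments exercising the whole pipeline.

Each function builds a seeded synthetic study (reference + libraries),
runs simulation -> mapping -> tail classification -> quantification end to
end, and returns the headline quantities.  They serve three audiences: the
examples, the test suite, and anyone wanting a quick calibration check of
the chemistry model.  Problem sizes are chosen so each scenario's sampling
error is small relative to the effect it measures (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import align, profiles, simulate, tails
from .reference import ReferenceSet
from .simulate import GeneParams, ModSite, SimulationConfig, random_reference_set


def _pipeline_tables(refset, configs: dict[str, SimulationConfig], min_reads=100):
    tables = {}
    for name, cfg in configs.items():
        reads, _truth = simulate.simulate_library(cfg, refset)
        records, _ = align.map_reads(reads, refset)
        calls = tails.classify_tails(records, refset)
        tables[name] = tails.tabulate_library(calls, refset, name, cfg.treatment, min_reads)
    return tables


def charging_recovery(
    seed: int, n_genes: int = 50, n_reads: int = 2000, ideal: bool = True
) -> dict:
    """Recover per-gene charging fractions from simulated libraries.

    theta ~ Uniform(0.2, 0.9) per gene.  Ideal chemistry (periodate fully
    efficient, no off-target degradation, uncharged molecules all CCA-intact)
    makes the charging index an unbiased estimator of theta; realistic
    chemistry (periodate 98% efficient, 35% off-target degradation) degrades
    absolute accuracy but preserves the ranking of the periodate-library
    CCA%.  Returns mean absolute error and Spearman correlation vs truth.
    """
    refset = random_reference_set(n_genes, seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(101,)))
    thetas = {g.gene_id: float(rng.uniform(0.2, 0.9)) for g in refset}
    gene_params = {
        gid: GeneParams(theta=th, cca_intact_uncharged=1.0)
        for gid, th in thetas.items()
    }
    if ideal:
        chem = dict(periodate_eff=1.0, extra_degradation=0.0)
    else:
        chem = dict(periodate_eff=0.98, extra_degradation=0.35)
    configs = {
        "periodate": SimulationConfig(seed=seed, n_reads_per_gene=n_reads,
                                      treatment="periodate", gene_params=gene_params,
                                      library_index=0, **chem),
        "control": SimulationConfig(seed=seed, n_reads_per_gene=n_reads,
                                    treatment="control", gene_params=gene_params,
                                    library_index=1, extra_degradation=0.0),
    }
    tables = _pipeline_tables(refset, configs)
    gene_ids = sorted(thetas)
    idx = tails.index_table(gene_ids, tables["periodate"], tables["control"])
    idx["theta"] = [thetas[g] for g in idx.gene_id]
    errors = (idx.charging_index - idx.theta).abs()
    pct = tables["periodate"].table.set_index("gene_id").cca_pct
    rho, _ = sps.spearmanr([thetas[g] for g in pct.index], pct.to_numpy())
    return {
        "mae": float(errors.mean()),
        "spearman_cca_vs_theta": float(rho),
        "n_genes": len(gene_ids),
        "index_table": idx,
    }


def spikein_experiment(
    seed: int, n_periodate: int = 300_000, n_control: int = 100_000
) -> dict:
    """A synthetic uncharged spike-in under periodate and control treatments.

    The spike-in is never aminoacylated (theta = 0) and enters the sample
    with a fully intact CCA, so its periodate CCA% measures the periodate
    failure rate (1 - efficiency, slightly shrunk by off-target degradation
    feeding the CC class), while its control CCA% measures handling
    degradation alone.  The analytic expectations under the generative model
    are returned alongside the measured values.
    """
    rng = np.random.default_rng(seed)
    spike = simulate.make_spike_in("spike-tRNA-Ile", rng)
    refset = ReferenceSet([spike])
    params = {"spike-tRNA-Ile": GeneParams(theta=0.0, cca_intact_uncharged=1.0)}
    cfg_p = SimulationConfig(seed=seed, n_reads_per_gene=n_periodate,
                             treatment="periodate", gene_params=params, library_index=0)
    cfg_c = SimulationConfig(seed=seed, n_reads_per_gene=n_control,
                             treatment="control", gene_params=params, library_index=1)
    tables = _pipeline_tables(refset, {"periodate": cfg_p, "control": cfg_c})
    out = {}
    for lib, cfg in (("periodate", cfg_p), ("control", cfg_c)):
        row = tables[lib].row("spike-tRNA-Ile")
        out[f"{lib}_cca_pct"] = float(row.cca_pct)
        out[f"{lib}_n"] = int(row.n_total)
        out[f"{lib}_denominator"] = int(row.n_CCA + row.n_CC)
        out[f"{lib}_expected_cca_pct"] = _expected_spikein_cca_pct(cfg)
    return out


def _expected_spikein_cca_pct(cfg: SimulationConfig) -> float:
    """Closed-form CCA% for an uncharged, CCA-intact spike-in."""
    d = cfg.extra_degradation_rate
    g = cfg.extra_degradation_geom  # P(extra loss == 1)
    e = cfg.periodate_eff if cfg.treatment in ("periodate", "deacyl_periodate") else 0.0
    # terminal removal (uncharged, prob e), then extra loss of 1+Geom
    p_cca = (1 - e) * (1 - d)
    p_cc = e * (1 - d) + (1 - e) * d * g
    return 100.0 * p_cca / (p_cca + p_cc)


def hardstop_experiment(seed: int, n_reads: int = 4000, stop_label: str = "58") -> dict:
    """A fully penetrant hard-stop modification: every read's 5' end lands
    immediately 3' of the modified position.

    The library size floor is lowered so the short truncation products stay
    observable (a stop at position 58 of a 76-nt tRNA leaves an 18-nt cDNA).
    Returns the 5' histogram mass (per thousand) at the label one position
    3' of the stop site."""
    refset = random_reference_set(1, seed)
    gene = refset.genes[0]
    params = {gene.gene_id: GeneParams(
        theta=0.6, mod_sites=(ModSite(stop_label, stop_prob=1.0),))}
    # terminal-transferase additions are disabled: a random 5' extension can
    # coincidentally match the base 5' of the stop and shift the inferred
    # start, which is a property of any mapper, not of the stop caller
    cfg = SimulationConfig(seed=seed, n_reads_per_gene=n_reads, treatment="control",
                           gene_params=params, extra_degradation=0.0, size_min=15,
                           terminal_transferase_prob=0.0)
    reads, _ = simulate.simulate_library(cfg, refset)
    records, _ = align.map_reads(reads, refset)
    hist = profiles.end_histogram(records, refset, gene.genome, "five_prime")
    series = hist[gene.gene_id].as_series()
    stop_idx = gene.sprinzl.index(stop_label)
    next_label = gene.sprinzl[stop_idx + 1]
    return {
        "next_label": next_label,
        "mass_at_next_label": float(series[next_label]),
        "total_mass": float(series.sum()),
        "n_reads": len(reads),
    }


def misincorporation_calibration(
    seed: int, n_reads: int = 10_000, label: str = "26",
    del_prob: float = 0.25, sub_prob: float = 0.50, min_cov: int = 50,
) -> dict:
    """A single modified site with known deletion and substitution rates.

    The recovered matrix cell should equal del_prob + sub_prob within
    binomial sampling error; a second tiny library checks that rows with
    coverage below the floor are masked rather than reported as zero.

    The synthetic gene is built with distinct bases around the modified
    site: a single-base deletion inside a repeated-base run has several
    co-optimal alignments and would be attributed to a neighboring column
    (a property of any aligner, not of this calibration)."""
    refset = random_reference_set(1, seed)
    gene = refset.genes[0]
    pos = gene.sprinzl.index(label)
    seq = list(gene.seq)
    seq[pos - 1:pos + 2] = ["A", "G", "T"]
    import dataclasses

    gene = dataclasses.replace(gene, seq="".join(seq))
    refset = ReferenceSet([gene])
    params = {gene.gene_id: GeneParams(
        theta=0.6, mod_sites=(ModSite(label, del_prob=del_prob, sub_prob=sub_prob),))}
    cfg = SimulationConfig(seed=seed, n_reads_per_gene=n_reads, treatment="control",
                           gene_params=params, extra_degradation=0.0)
    reads, _ = simulate.simulate_library(cfg, refset)
    records, _ = align.map_reads(reads, refset)
    mat = profiles.misincorporation_matrix(records, refset, min_cov=min_cov, level="gene")
    cell = float(mat.at[gene.gene_id, label])
    cov = len(records)
    # low-coverage masking check on a 40-read library
    cfg_small = SimulationConfig(seed=seed, n_reads_per_gene=40, treatment="control",
                                 gene_params=params, extra_degradation=0.0,
                                 library_index=1)
    reads_s, _ = simulate.simulate_library(cfg_small, refset)
    records_s, _ = align.map_reads(reads_s, refset)
    mat_s = profiles.misincorporation_matrix(records_s, refset, min_cov=min_cov, level="gene")
    return {
        "rate": cell,
        "expected": del_prob + sub_prob,
        "coverage": cov,
        "binomial_se": float(np.sqrt((del_prob + sub_prob) * (1 - del_prob - sub_prob) / cov)),
        "low_coverage_row_all_masked": bool(mat_s.loc[gene.gene_id].isna().all()),
    }
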