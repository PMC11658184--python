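"""Statistical comparisons and report assembly.

Thin, strict wrappers around classical tests (fixed-effects one-way ANOVA,
t-tests with Welch as the unpaired default, Pearson correlation) plus the
report bundle writer.  No multiple-testing correction is applied anywhere —
raw P values are reported, so readers comparing many families should adjust
externally.  Degenerate inputs raise rather than returning NaN silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """Raised when a test's input leaves the statistic undefined (zero
    variance, too few values or groups)."""


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA.

    Requires >= 2 groups with >= 2 values each.  Zero within-group variance
    is an error (F undefined); equal group means with spread give F = 0,
    P = 1."""
    if len(groups) < 2:
        raise DegenerateDataError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise DegenerateDataError("every ANOVA group needs at least two values")
    n_total = sum(len(g) for g in arrays)
    grand = np.concatenate(arrays).mean()
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if ss_within == 0:
        raise DegenerateDataError("zero within-group variance: F undefined")
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


def two_sample_t(
    a: Sequence[float], b: Sequence[float], paired: bool = False
) -> tuple[float, float]:
    """Two-sided t-test: Welch for unpaired samples, paired otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("t-test needs at least two values per sample")
    if paired:
        if len(a) != len(b):
            raise DegenerateDataError("paired t-test needs equal sizes")
        d = a - b
        if np.std(d, ddof=1) == 0:
            if np.allclose(d, 0):
                return 0.0, 1.0
            raise DegenerateDataError("zero variance of paired differences")
        t, p = sps.ttest_rel(a, b)
    else:
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            if np.isclose(a.mean(), b.mean()):
                return 0.0, 1.0
            raise DegenerateDataError("zero variance in both samples")
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def pearson_corr(
    x: Sequence[float], y: Sequence[float], log_transform: bool = False
) -> tuple[float, float]:
    """Sample Pearson r with a two-sided P from the t transform.

    ``log_transform`` applies natural log to both variables first (used for
    half-life style comparisons spanning orders of magnitude)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateDataError("Pearson correlation needs n >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DegenerateDataError("non-finite values")
    if log_transform:
        if (x <= 0).any() or (y <= 0).any():
            raise DegenerateDataError("log transform needs positive values")
        x, y = np.log(x), np.log(y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in x or y")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GroupedValues:
    """Labeled value groups for a test (treatments, genomes, ...)."""

    labels: tuple[str, ...]
    values: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values differ in length")

    def anova(self) -> tuple[float, float]:
        return one_way_anova(self.values)

    def sizes(self) -> dict[str, int]:
        return {l: len(v) for l, v in zip(self.labels, self.values)}


def read_comparison_table(path: str | Path) -> pd.DataFrame:
    """Read a user-supplied two-column TSV (key, value) for external
    comparisons, e.g. correlating retention ratios against published
    aminoacyl-tRNA half-lives.  Never bundled with the package."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns, got {df.shape[1]}")
    return df


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

REQUIRED_ARTIFACTS = (
    "library_tables",      # dict library -> tails.LibraryTable
    "genome_summaries",    # dict library -> DataFrame
    "family_summaries",    # dict library -> DataFrame
)


def build_report(
    tables: dict,
    profiles_out: dict,
    config: dict,
    out_dir: str | Path,
) -> Path:
    """Assemble the report bundle into one directory.

    ``tables`` must contain per-library LibraryTables plus genome/family
    summaries; ``profiles_out`` may contain profile matrices, the charging
    and retention index tables, the tRF table and tail spectra.  A
    machine-readable run manifest (inputs, parameters, seed) and a log are
    always written.  Missing required artifacts are a hard error naming the
    artifact.  Output is byte-stable for fixed inputs; timestamps are
    isolated to the log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key in REQUIRED_ARTIFACTS:
        if key not in tables:
            raise KeyError(f"missing required report artifact {key!r}")
    written = []
    for lib, table in sorted(tables["library_tables"].items()):
        p = out / f"per_gene.{lib}.tsv"
        table.to_tsv(p)
        written.append(p.name)
    for name in ("genome_summaries", "family_summaries"):
        for lib, df in sorted(tables[name].items()):
            p = out / f"{name.removesuffix('_summaries')}_summary.{lib}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format="%.6g")
            written.append(p.name)
    for key in ("charging_index", "retention_ratio", "trf_calls"):
        if key in profiles_out:
            p = out / f"{key}.tsv"
            profiles_out[key].to_csv(p, sep="\t", index=False, float_format="%.6g")
            written.append(p.name)
    for key in ("histogram_5p", "histogram_3p", "misincorporation"):
        if key in profiles_out:
            for lib, df in sorted(profiles_out[key].items()):
                p = out / f"{key}.{lib}.tsv"
                df.to_csv(p, sep="\t", float_format="%.6g")
                written.append(p.name)
    # tail spectrum always present, empty-with-header when no CCA-less genes
    spectra = profiles_out.get("tail_spectra", {})
    p = out / "tail_spectrum.tsv"
    with open(p, "w") as fh:
        fh.write("gene_id\taddition\tcount\n")
        for gid, df in sorted(spectra.items()):
            for _, row in df.iterrows():
                fh.write(f"{gid}\t{row['addition']}\t{row['count']}\n")
    written.append(p.name)
    if "stats" in profiles_out:
        p = out / "stats.tsv"
        profiles_out["stats"].to_csv(p, sep="\t", index=False, float_format="%.6g")
        written.append(p.name)
    manifest = {
        "config": config,
        "artifacts": sorted(written),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    import time

    with open(out / "run.log", "w") as fh:
        fh.write(f"report built at {time.strftime('%Y-%m-%dT%H:%M:%S')}\n")
        for name in sorted(written):
            fh.write(f"wrote {name}\n")
    return out
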