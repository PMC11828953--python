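"""Protein-to-mRNA ratio (PTR) statistics.

PTR = protein abundance (iBAQ) / transcript abundance (TPM), computed on
species-level means because proteomics and RNA-seq replicates are unpaired.
Genes are classified low / moderate / high by mean +/- m*SD thresholds on
log10(PTR) (ratio distributions span decades; linear-scale thresholds would
be dominated by the right tail — a config flag restores linear mode).
Gene-set contrasts use one-way ANOVA gating followed by pairwise two-tailed
Wilcoxon rank-sum tests with Benjamini-Hochberg adjustment, with a
fixed-size gene resampling null as control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, RunConfig, aggregate_replicates

logger = logging.getLogger("c4omics")

CLASSES = ("low", "moderate", "high")


def classify_by_sd(values: np.ndarray, m: float = 1.0) -> np.ndarray:
    """Classify each value as low/moderate/high by mean +/- m*SD thresholds.

    Thresholds are computed on the supplied vector itself.  ``low`` iff
    v < mean - m*SD; ``high`` iff v > mean + m*SD; values exactly at a
    threshold are moderate.  An all-identical vector (SD 0) is entirely
    moderate.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values to set SD thresholds")
    if m <= 0:
        raise ValueError("SD multiplier must be positive")
    mu = finite.mean()
    sd = finite.std(ddof=1)
    out = np.full(values.shape, "moderate", dtype=object)
    out[values < mu - m * sd] = "low"
    out[values > mu + m * sd] = "high"
    out[~np.isfinite(values)] = "moderate"
    return out


@dataclass
class PTRTable:
    """Per-(gene, species) PTR values with per-species class thresholds."""

    data: pd.DataFrame            # columns: gene_id, species, rna_mean, protein_mean, ptr, log10_ptr, ptr_class
    thresholds: dict              # species -> (mean, sd) on the classification scale
    n_excluded: dict              # species -> genes dropped by the detection floor
    log_scale: bool = True

    def species_values(self, species: str, gene_subset=None) -> pd.Series:
        sub = self.data[self.data["species"] == species]
        if gene_subset is not None:
            sub = sub[sub["gene_id"].isin(set(gene_subset))]
        return sub.set_index("gene_id")["log10_ptr"]


def compute_ptr(
    rna: AbundanceTable, protein: AbundanceTable, cfg: RunConfig | None = None
) -> PTRTable:
    """Species-mean PTR per gene, with mean +/- SD classification per species.

    A (gene, species) row exists only when the RNA species-mean passes the
    detection floor (``cfg.min_tpm``) *and* protein was detected (finite,
    positive mean).  Undetected pairs are excluded and counted; a zero RNA
    mean with detected protein is excluded with a warning.
    """
    cfg = cfg or RunConfig()
    rna_mean, _, rna_det = aggregate_replicates(rna, min_detect=cfg.min_tpm)
    prot_mean, _, _ = aggregate_replicates(protein, min_detect=np.nextafter(0, 1))
    prot_det = prot_mean.notna() & prot_mean.gt(0)

    rows = []
    thresholds = {}
    n_excluded = {}
    species = [sp for sp in rna_mean.columns if sp in prot_mean.columns]
    for sp in species:
        ok = rna_det[sp] & prot_det[sp]
        zero_rna = prot_det[sp] & rna_mean[sp].eq(0)
        if zero_rna.any():
            logger.warning("%s: %d genes with detected protein but zero RNA "
                           "mean excluded", sp, int(zero_rna.sum()))
        n_excluded[sp] = int((~ok).sum())
        genes = rna_mean.index[ok]
        r = rna_mean.loc[genes, sp].to_numpy()
        p = prot_mean.loc[genes, sp].to_numpy()
        ptr = p / r
        log10_ptr = np.log10(ptr)
        scale_vals = log10_ptr if cfg.ptr_log_scale else ptr
        finite = scale_vals[np.isfinite(scale_vals)]
        if finite.size >= 2:
            classes = classify_by_sd(scale_vals, cfg.ptr_sd_multiplier)
            thresholds[sp] = (float(finite.mean()), float(finite.std(ddof=1)))
        else:
            # too few genes to set SD thresholds: everything moderate
            classes = np.full(scale_vals.shape, "moderate", dtype=object)
            thresholds[sp] = (float("nan"), float("nan"))
        rows.append(pd.DataFrame({
            "gene_id": genes, "species": sp, "rna_mean": r, "protein_mean": p,
            "ptr": ptr, "log10_ptr": log10_ptr, "ptr_class": classes,
        }))
    data = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["gene_id", "species", "rna_mean", "protein_mean", "ptr",
                 "log10_ptr", "ptr_class"])
    return PTRTable(data=data, thresholds=thresholds, n_excluded=n_excluded,
                    log_scale=cfg.ptr_log_scale)


# ---------------------------------------------------------------------------
# Group comparison: ANOVA gate + pairwise rank-sum + BH
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """One-way ANOVA across groups plus BH-adjusted pairwise rank-sum tests."""

    anova_p: float
    pairwise: pd.DataFrame   # columns: group_a, group_b, statistic, p_raw, p_adj, stars, gated
    gated: bool = False

    def pair(self, a: str, b: str) -> pd.Series:
        key = tuple(sorted((a, b)))
        sel = self.pairwise[
            (self.pairwise["group_a"] == key[0]) & (self.pairwise["group_b"] == key[1])
        ]
        if sel.empty:
            raise KeyError(f"no comparison for pair {key}")
        return sel.iloc[0]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]], cfg: RunConfig | None = None
) -> GroupComparison:
    """One-way ANOVA gate, then pairwise two-tailed Wilcoxon rank-sum tests
    with BH adjustment over the pairwise family.

    Pairwise rows are flagged ``gated`` when the ANOVA p is at or above the
    gate alpha; they are still reported.
    """
    cfg = cfg or RunConfig()
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, v in groups.items():
        if np.isfinite(v).sum() < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        groups[name] = v[np.isfinite(v)]
    anova_p = float(stats.f_oneway(*groups.values()).pvalue)
    gated = not (anova_p < cfg.anova_alpha)

    names = sorted(groups)
    rows = []
    for a, b in combinations(names, 2):
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b,
                     "statistic": float(res.statistic), "p_raw": float(res.pvalue)})
    pw = pd.DataFrame(rows)
    pw["p_adj"] = adjust_bh(pw["p_raw"].to_numpy())
    pw["stars"] = [_stars(p) if not gated else "ns(gated)" for p in pw["p_adj"]]
    pw["gated"] = gated
    return GroupComparison(anova_p=anova_p, pairwise=pw, gated=gated)


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Resampling null, Z-scores, log-scale correlation
# ---------------------------------------------------------------------------

def resample_null(
    ptr: PTRTable,
    n_genes: int = 14,
    n_resamples: int = 100,
    seed: int = 0,
    cfg: RunConfig | None = None,
) -> tuple[pd.DataFrame, GroupComparison]:
    """Fixed-size gene resampling control for gene-set PTR contrasts.

    For each species, draw ``n_genes`` classified genes without replacement
    ``n_resamples`` times and record the mean log10 PTR of each draw; the
    resampled distributions are then compared across species the same way as
    a real gene set.  A species-level effect restricted to a small gene set
    leaves this genome-wide null flat.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for sp in sorted(ptr.data["species"].unique()):
        vals = ptr.species_values(sp).to_numpy()
        vals = vals[np.isfinite(vals)]
        if n_genes > vals.size:
            raise ValueError(f"{sp}: cannot draw {n_genes} genes from {vals.size}")
        means = np.empty(n_resamples)
        for i in range(n_resamples):
            means[i] = rng.choice(vals, size=n_genes, replace=False).mean()
        out[sp] = means
    df = pd.DataFrame(out)
    comparison = compare_groups(out, cfg)
    return df, comparison


def zscore_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Row-wise Z-score normalization (gene rows to mean 0, SD 1).

    Rows with zero SD are emitted as zeros and their labels returned as
    flagged.  Uses the population SD (ddof=0), the usual heatmap convention.
    """
    vals = matrix.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flagged = [matrix.index[i] for i in range(len(matrix)) if sd[i, 0] == 0]
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mu) / safe_sd
    z[(sd == 0).repeat(vals.shape[1], axis=1)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged


def correlate_log(x: Sequence[float], y: Sequence[float]) -> tuple[float, int]:
    """Pearson correlation of paired abundances on the log10 scale.

    Pairs where either value is absent or non-positive are dropped; requires
    at least 3 usable pairs.  Returns (r, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 detected pairs, got {n}")
    r = float(stats.pearsonr(np.log10(x[ok]), np.log10(y[ok])).statistic)
    return r, n
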