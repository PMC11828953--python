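"""Translation efficiency (TE) and protein-to-RPF analysis.

TE for a gene is the ratio of ribosome-protected-fragment (RPF) abundance to
RNA abundance, a proxy for ribosome loading per transcript.  To compare TE
distributions across species, raw TE is divided by the mean TE of a
photosynthesis reference set (excluding C4 genes), making the species-level
normalizer explicit and te-norm scale-invariant under global RPF rescaling.
Extreme classes are the top and bottom ``frac`` of the ranked gene list
(floor arithmetic, identifier tie-break), not SD-based thresholds: TE spans
a wide range with heavy tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, GeneSet, RunConfig, aggregate_replicates
from .ptr import adjust_bh

logger = logging.getLogger("c4omics")


def classify_extremes(values: pd.Series, frac: float = 0.05) -> pd.Series:
    """Mark exactly floor(frac*n) genes per tail as low / high, rest moderate.

    ``values`` must be indexed by gene identifier; ties at the rank cutoff
    are broken by ascending gene identifier, so the classification is
    deterministic across runs.
    """
    if not 0.0 < frac < 0.5:
        raise ValueError("frac must lie in (0, 0.5)")
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values")
    n_tail = floor(frac * n)
    order = values.reset_index()
    order.columns = ["gene_id", "value"]
    order = order.sort_values(["value", "gene_id"], kind="mergesort")
    classes = pd.Series("moderate", index=values.index, dtype=object)
    if n_tail > 0:
        classes.loc[order["gene_id"].iloc[:n_tail]] = "low"
        classes.loc[order["gene_id"].iloc[-n_tail:]] = "high"
    return classes


@dataclass
class TranslationTable:
    """Per-(gene, species) TE values; ``normalizers`` maps species to the
    photosynthesis-set mean raw TE used for te_norm."""

    data: pd.DataFrame   # gene_id, species, rna_mean, rpf_mean, te_raw, te_norm, te_class [, protein_mean, protein_rpf_ratio, ratio_class]
    normalizers: dict

    def species_frame(self, species: str) -> pd.DataFrame:
        return self.data[self.data["species"] == species].set_index("gene_id")


def compute_te_normalized(
    rna: AbundanceTable,
    rpf: AbundanceTable,
    photo_set: GeneSet,
    c4_set: GeneSet,
    cfg: RunConfig | None = None,
) -> TranslationTable:
    """Raw and photosynthesis-normalized TE per (gene, species).

    Genes enter only when detected (species-mean TPM >= floor) in both RNA
    and RPF.  The normalizer is the arithmetic mean (median by config) of
    raw TE over the photosynthesis set minus the C4 set; by construction the
    mean te_norm over that set is 1 in every species.
    """
    cfg = cfg or RunConfig()
    rna_mean, _, rna_det = aggregate_replicates(rna, min_detect=cfg.min_tpm)
    rpf_mean, _, rpf_det = aggregate_replicates(rpf, min_detect=cfg.min_tpm)
    norm_genes = photo_set.members - c4_set.members

    rows = []
    normalizers = {}
    species = [sp for sp in rna_mean.columns if sp in rpf_mean.columns]
    for sp in species:
        ok = rna_det[sp] & rpf_det[sp]
        genes = rna_mean.index[ok]
        r = rna_mean.loc[genes, sp].to_numpy()
        f = rpf_mean.loc[genes, sp].to_numpy()
        te_raw = f / r
        te_series = pd.Series(te_raw, index=genes)
        ref = te_series[te_series.index.isin(norm_genes)]
        if ref.empty:
            raise ValueError(
                f"{sp}: normalization set (photosynthesis minus C4) is empty "
                "after detection filtering"
            )
        normalizer = float(ref.median() if cfg.te_normalizer == "median" else ref.mean())
        normalizers[sp] = normalizer
        te_norm = te_series / normalizer
        classes = classify_extremes(te_norm, cfg.extreme_fraction)
        rows.append(pd.DataFrame({
            "gene_id": genes, "species": sp, "rna_mean": r, "rpf_mean": f,
            "te_raw": te_raw, "te_norm": te_norm.to_numpy(),
            "te_class": classes.to_numpy(),
        }))
    data = pd.concat(rows, ignore_index=True)
    return TranslationTable(data=data, normalizers=normalizers)


def compute_protein_rpf(
    protein: AbundanceTable,
    rpf: AbundanceTable,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Protein/RPF abundance ratio per (gene, species) with extreme classes.

    Same censoring rule as TE: a row requires protein detection (finite,
    positive mean) and RPF passing the TPM floor; classes use the same
    extreme fraction as TE.
    """
    cfg = cfg or RunConfig()
    prot_mean, _, _ = aggregate_replicates(protein, min_detect=np.nextafter(0, 1))
    prot_det = prot_mean.notna() & prot_mean.gt(0)
    rpf_mean, _, rpf_det = aggregate_replicates(rpf, min_detect=cfg.min_tpm)

    rows = []
    species = [sp for sp in prot_mean.columns if sp in rpf_mean.columns]
    for sp in species:
        ok = prot_det[sp] & rpf_det[sp]
        genes = prot_mean.index[ok]
        p = prot_mean.loc[genes, sp].to_numpy()
        f = rpf_mean.loc[genes, sp].to_numpy()
        ratio = pd.Series(p / f, index=genes)
        classes = classify_extremes(ratio, cfg.extreme_fraction)
        rows.append(pd.DataFrame({
            "gene_id": genes, "species": sp, "protein_mean": p, "rpf_mean": f,
            "protein_rpf_ratio": ratio.to_numpy(), "ratio_class": classes.to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def compare_between_species(
    table: pd.DataFrame,
    gene_sets: list[GeneSet],
    species_a: str,
    species_b: str,
    value_col: str,
) -> pd.DataFrame:
    """Two-tailed rank-sum tests of a per-gene metric between two species,
    one row per gene set, BH-adjusted across the sets tested.

    ``table`` must have gene_id/species/``value_col`` columns (a
    :class:`TranslationTable`'s data, or the protein-RPF frame).  A set with
    fewer than 3 genes shared between the two species raises.
    """
    rows = []
    for gs in gene_sets:
        a = table[(table["species"] == species_a) & table["gene_id"].isin(gs.members)]
        b = table[(table["species"] == species_b) & table["gene_id"].isin(gs.members)]
        shared = set(a["gene_id"]) & set(b["gene_id"])
        if len(shared) < 3:
            raise ValueError(
                f"gene set {gs.name!r}: only {len(shared)} genes shared between "
                f"{species_a} and {species_b}"
            )
        va = a[a["gene_id"].isin(shared)][value_col].to_numpy()
        vb = b[b["gene_id"].isin(shared)][value_col].to_numpy()
        res = stats.mannwhitneyu(va, vb, alternative="two-sided")
        rows.append({
            "gene_set": gs.name, "species_a": species_a, "species_b": species_b,
            "metric": value_col, "n_genes": len(shared),
            "median_a": float(np.median(va)), "median_b": float(np.median(vb)),
            "statistic": float(res.statistic), "p_raw": float(res.pvalue),
        })
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_bh(out["p_raw"].to_numpy())
    return out
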