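"""Gene-regulatory-network refinement and TF-family summaries.

Network inference is upstream input; this module only (1) filters TF->gene
edges by cognate promoter-CRE support — an edge survives when the target
gene carries, within its promoter window, a CRE family cognate to the TF's
family — (2) extracts the sub-network over a target gene set (the "C4GRN"
when the set is the C4 genes), and (3) summarizes TF families, including the
ERF-per-target-gene rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger("c4omics")

# family-level cognate map covering the five families the synthetic networks
# use; supply your own table for real annotations
DEFAULT_COGNATE_MAP: dict[str, set] = {
    f: {f} for f in ("ERF", "bHLH", "MYB", "NAC", "C2H2")
}


@dataclass
class GRN:
    """Edges plus TF-family and promoter-CRE-family annotations."""

    edges: pd.DataFrame                 # columns: tf_id, target_id
    tf_family: dict                     # tf_id -> family
    gene_cre_families: dict             # gene_id -> set of CRE families in promoter
    cognate_map: dict = field(default_factory=lambda: dict(DEFAULT_COGNATE_MAP))
    removed_edges: int = 0

    def __post_init__(self) -> None:
        need = {"tf_id", "target_id"}
        if not need.issubset(self.edges.columns):
            raise ValueError(f"edge table needs columns {need}")

    @property
    def tfs(self) -> set:
        return set(self.edges["tf_id"])

    @property
    def targets(self) -> set:
        return set(self.edges["target_id"])


def grn_from_tables(
    edges: pd.DataFrame,
    tf_family: pd.DataFrame,
    promoter_cres: pd.DataFrame,
    cognate_map: dict | None = None,
) -> GRN:
    """Assemble a :class:`GRN` from the three input tables
    (edge list; tf_id/family; gene_id/comma-separated cre_families)."""
    fam = dict(zip(tf_family["tf_id"], tf_family["family"]))
    cre = {
        g: set(str(s).split(",")) if str(s) else set()
        for g, s in zip(promoter_cres["gene_id"], promoter_cres["cre_families"])
    }
    return GRN(edges=edges.copy(), tf_family=fam, gene_cre_families=cre,
               cognate_map=cognate_map or dict(DEFAULT_COGNATE_MAP))


def filter_tfs_by_cognate_cre(grn: GRN) -> GRN:
    """Drop edges whose target gene lacks a promoter CRE family cognate to
    the TF's family; TFs with unknown family are dropped with a warning."""
    keep = []
    unknown = set()
    for tf, target in zip(grn.edges["tf_id"], grn.edges["target_id"]):
        fam = grn.tf_family.get(tf)
        if fam is None:
            unknown.add(tf)
            keep.append(False)
            continue
        cognate = grn.cognate_map.get(fam, set())
        keep.append(bool(grn.gene_cre_families.get(target, set()) & cognate))
    if unknown:
        logger.warning("dropped edges of %d TFs with unknown family", len(unknown))
    filtered = grn.edges[pd.Series(keep, index=grn.edges.index)]
    return GRN(edges=filtered.reset_index(drop=True), tf_family=grn.tf_family,
               gene_cre_families=grn.gene_cre_families, cognate_map=grn.cognate_map,
               removed_edges=int(len(grn.edges) - len(filtered)))


def extract_target_grn(grn: GRN, target_members: set) -> GRN:
    """Sub-network of edges onto the target gene set."""
    sub = grn.edges[grn.edges["target_id"].isin(set(target_members))]
    return GRN(edges=sub.reset_index(drop=True), tf_family=grn.tf_family,
               gene_cre_families=grn.gene_cre_families, cognate_map=grn.cognate_map)


def tf_family_summary(
    grn: GRN, target_members: set
) -> tuple[pd.DataFrame, dict]:
    """Family counts of distinct TFs in the sub-network over the target set,
    sorted descending with the top five flagged, plus summary metrics.

    ``erf_per_target_gene`` = (#distinct ERF TFs in sub-network) /
    (#target genes with at least one regulator).
    """
    sub = extract_target_grn(grn, target_members)
    tf_fams = {tf: grn.tf_family.get(tf, "unknown") for tf in sub.tfs}
    counts = pd.Series(list(tf_fams.values())).value_counts()
    table = counts.rename_axis("family").reset_index(name="n_tfs")
    table["top5"] = False
    table.loc[table.index[:5], "top5"] = True
    regulated = sub.targets & set(target_members)
    erf_tfs = {tf for tf, f in tf_fams.items() if f == "ERF"}
    metrics = {
        "n_tfs": len(sub.tfs),
        "n_regulated_targets": len(regulated),
        "n_erf_tfs": len(erf_tfs),
        "erf_per_target_gene": (len(erf_tfs) / len(regulated)) if regulated else 0.0,
    }
    return table, metrics
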