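"""CRE enrichment among ACR motif occurrences associated with a gene set.

The null model follows the occurrence-count design: from the background pool
of N motif occurrences over all accessible chromatin regions, draw k (the
number of target-associated occurrences) without replacement B times, and
compare each CRE's observed target-associated count against its permuted
counts.  A one-sided Fisher's exact test on the same 2x2 margins is the
analytic cross-check.  Note the permutation shuffles occurrence labels, not
genomic positions: ACR spatial structure is not part of this null.
"""

from __future__ import annotations

import logging
from collections import Counter
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import CREOccurrence, GeneModel, GeneSet, OccurrencePool, RunConfig
from .ptr import adjust_bh

logger = logging.getLogger("c4omics")

CONTEXTS = ("gACR", "upACR", "downACR")


# ---------------------------------------------------------------------------
# Context assignment
# ---------------------------------------------------------------------------

def gene_windows(gene: GeneModel, window: int = 3000) -> dict[str, tuple[int, int]]:
    """Genic / upstream / downstream intervals for one gene, strand-aware.

    Upstream runs ``window`` bp from the start codon away from the gene;
    downstream runs ``window`` bp past the last coding base.  All intervals
    are 0-based half-open on the genome.
    """
    if gene.strand == "+":
        up = (gene.start_codon - window, gene.start_codon)
        down = (gene.stop_codon + 1, gene.stop_codon + 1 + window)
    else:
        up = (gene.start_codon + 1, gene.start_codon + 1 + window)
        down = (gene.stop_codon - window, gene.stop_codon)
    return {
        "gACR": (gene.start, gene.end),
        "upACR": (max(0, up[0]), up[1]),
        "downACR": (max(0, down[0]), down[1]),
    }


def assign_context(
    occurrences: Iterable[CREOccurrence],
    genes: Sequence[GeneModel],
    window: int = 3000,
) -> list[CREOccurrence]:
    """Label each occurrence with (context, gene) pairs by interval overlap.

    An occurrence may label several genes (e.g. between two gene starts);
    unassigned occurrences are kept with empty labels.  Overlap means a
    non-empty intersection between the occurrence interval and the gene's
    genic/upstream/downstream window.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        for ctx, (a, b) in gene_windows(g, window).items():
            if a < b:
                trees.setdefault((g.chrom, ctx), IntervalTree()).addi(a, b, g.gene_id)
    out = []
    for occ in occurrences:
        occ.contexts = set()
        occ.gene_ids = set()
        for ctx in CONTEXTS:
            tree = trees.get((occ.chrom, ctx))
            if tree is None:
                continue
            for hit in tree.overlap(occ.start, occ.end):
                occ.contexts.add(ctx)
                occ.gene_ids.add(hit.data)
        out.append(occ)
    return out


def build_pool(
    occurrences: Sequence[CREOccurrence], target: GeneSet
) -> OccurrencePool:
    """Count background (all) and target-associated occurrences per CRE.

    An occurrence counts toward k once if any of its labeled genes is in the
    target set, regardless of how many labels it carries.
    """
    n_counter: Counter = Counter()
    k_counter: Counter = Counter()
    for occ in occurrences:
        n_counter[occ.cre_id] += 1
        if occ.gene_ids & target.members:
            k_counter[occ.cre_id] += 1
    cre_ids = sorted(n_counter)
    n_c = np.array([n_counter[c] for c in cre_ids], dtype=np.int64)
    k_c = np.array([k_counter.get(c, 0) for c in cre_ids], dtype=np.int64)
    if k_c.sum() == 0:
        raise ValueError(
            f"no occurrences associated with target set {target.name!r}: "
            "nothing to test"
        )
    return OccurrencePool(cre_ids=cre_ids, n_c=n_c, k_c=k_c)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def permutation_enrichment(
    pool: OccurrencePool,
    B: int = 1000,
    seed: int = 0,
    p_mode: str = "ge_plus_one",
    sampling: str = "hypergeometric",
) -> pd.DataFrame:
    """Monte Carlo permutation enrichment p-value per CRE.

    Each permutation draws k occurrences from the N-occurrence background
    pool without replacement (``sampling='multinomial'`` switches to
    with-replacement draws for very large pools) and records per-CRE counts.
    The default estimator is ``p = (1 + #{b: count_b >= k_c}) / (B + 1)``,
    which is never exactly zero and handles degenerate pools;
    ``p_mode='strict_paper'`` gives the literal exceedance proportion
    ``#{b: count_b > k_c} / B``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    N, k = pool.N, pool.k
    if k > N:
        raise ValueError("k exceeds pool size N")
    rng = np.random.default_rng(seed)
    if sampling == "hypergeometric":
        counts = rng.multivariate_hypergeometric(pool.n_c, k, size=B)
    elif sampling == "multinomial":
        counts = rng.multinomial(k, pool.n_c / N, size=B)
    else:
        raise ValueError(f"unknown sampling mode {sampling!r}")
    obs = pool.k_c
    if p_mode == "ge_plus_one":
        p = (1 + (counts >= obs).sum(axis=0)) / (B + 1)
    elif p_mode == "strict_paper":
        p = (counts > obs).sum(axis=0) / B
    else:
        raise ValueError(f"unknown p_mode {p_mode!r}")
    return pd.DataFrame({
        "cre_id": pool.cre_ids,
        "observed": obs,
        "expected": k * pool.n_c / N,
        "perm_mean": counts.mean(axis=0),
        "perm_p": p,
    })


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def fisher_enrichment(pool: OccurrencePool) -> pd.DataFrame:
    """One-sided (greater) Fisher's exact p and odds ratio per CRE.

    2x2 per CRE: ``[[k_c, k-k_c], [n_c-k_c, (N-n_c)-(k-k_c)]]``.  The odds
    ratio is the sample odds ratio with Haldane 0.5 continuity correction
    when any cell is zero (flagged in ``or_corrected``).
    """
    N, k = pool.N, pool.k
    rows = []
    for cre, n_c, k_c in zip(pool.cre_ids, pool.n_c, pool.k_c):
        a = int(k_c)
        b = int(k - k_c)
        c = int(n_c - k_c)
        d = int((N - n_c) - (k - k_c))
        if min(a, b, c, d) < 0:
            raise ValueError(f"{cre}: negative contingency cell — pool invariant breach")
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
        corrected = 0 in (a, b, c, d)
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
        rows.append({"cre_id": cre, "fisher_p": p,
                     "odds_ratio": (aa * dd) / (bb * cc),
                     "or_corrected": corrected})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Combined result + summary
# ---------------------------------------------------------------------------

def run_enrichment(
    pool: OccurrencePool, cfg: RunConfig | None = None
) -> pd.DataFrame:
    """Permutation + Fisher enrichment with BH-adjusted q per method."""
    cfg = cfg or RunConfig()
    perm = permutation_enrichment(
        pool, B=cfg.b_permutations, seed=cfg.seed,
        p_mode=cfg.p_mode, sampling=cfg.permutation_sampling,
    )
    fish = fisher_enrichment(pool)
    out = perm.merge(fish, on="cre_id")
    out["perm_q"] = adjust_bh(out["perm_p"].to_numpy())
    out["fisher_q"] = adjust_bh(out["fisher_p"].to_numpy())
    out["enriched"] = out["perm_q"] < 0.05
    return out


def cre_family(cre_id: str) -> str:
    """Family label from a ``FAMILY_n`` style identifier."""
    return cre_id.rsplit("_", 1)[0]


def summarize_enriched(
    results: pd.DataFrame,
    pool: OccurrencePool,
    family_map: dict[str, str] | None = None,
    q_col: str = "perm_q",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """log2 target-associated frequency of enriched CREs (q < alpha),
    with per-family shares when a family map is available."""
    hit = results[results[q_col] < alpha].copy()
    cols = ["cre_id", "family", "observed", "log2_frequency"]
    if hit.empty:
        return pd.DataFrame(columns=cols)
    fam = family_map or {c: cre_family(c) for c in hit["cre_id"]}
    hit["family"] = hit["cre_id"].map(fam)
    hit["log2_frequency"] = np.log2(hit["observed"].astype(float))
    return hit[cols].sort_values("log2_frequency", ascending=False).reset_index(drop=True)
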