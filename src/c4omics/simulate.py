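"""Synthetic multi-species multi-omics generator with exact ground truth.

Every generator is a pure function of :class:`SimConfig` (seed included) and
emulates one class of study inputs:

* ``gen_multiomics`` — RNA (TPM), protein (iBAQ) and ribosome-protected
  fragment (TPM) tables for five species spanning the C3 -> C3-C4 -> C4
  photosynthetic types, with a configurable RNA fold ``F`` and protein fold
  ``G`` applied to the C4 gene set in C4-type species.  The realized
  protein-to-mRNA ratio of those genes is then ``G/F`` times baseline while
  translation efficiency is untouched, which is the regulatory scenario the
  downstream statistics are meant to detect.
* ``gen_cre_dataset`` — a pool of motif occurrences over accessible chromatin
  regions tied to genes, with selected CREs spiked among target-gene
  occurrences.
* ``gen_sequences`` — CDS with controlled GC3 and genomic fragments with
  planted TSD-IR-spacer-IRrc-TSD retroduplication blocks.
* ``gen_grn`` — a TF -> target edge list with family annotations, cognate
  promoter-CRE support for a known TF subset, and ERF edges onto C4 genes
  over-represented.

Abundances are log10-normal: TPM and iBAQ span orders of magnitude and the
usual display scale for these data is logarithmic.  Protein couples to the
species-level RNA mean rather than to individual RNA replicates because
proteomics and RNA-seq replicates are unpaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .io import AbundanceTable, CREOccurrence, GeneModel, GeneSet, OccurrencePool
from .seqfeat import revcomp

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_SPECIES = (
    ("Frob", "C3"),
    ("Fson", "C3C4"),
    ("Fram", "C3C4"),
    ("Flin", "C3C4"),
    ("Ftri", "C4"),
)

CRE_FAMILIES = ("ERF", "bHLH", "MYB", "NAC", "C2H2")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with defaults set to the study design
    (five species, six RNA/protein replicates, two ribosome-profiling
    replicates, ~10-fold C4 RNA induction)."""

    seed: int = 0
    species: tuple = DEFAULT_SPECIES
    n_genes: int = 2000
    n_replicates_rna: int = 6
    n_replicates_protein: int = 6
    n_replicates_rpf: int = 2

    # abundance model (log10 scale)
    rna_log10_mu: float = 1.0
    rna_log10_sigma: float = 0.5
    ptr_log10_mu: float = 1.0
    ptr_log10_sd: float = 0.25
    te_log10_mu: float = 0.0
    te_log10_sd: float = 0.2
    noise_sd_rna: float = 0.1
    noise_sd_protein: float = 0.2
    noise_sd_rpf: float = 0.15

    # effect sizes on the C4 gene set in C4-type species
    c4_rna_fold: float = 10.0       # F
    c4_protein_fold: float = 3.0    # G
    c4_te_fold: float = 1.0         # kept 1: translation efficiency unchanged

    # gene sets (disjoint blocks of the gene list)
    n_c4_genes: int = 14
    n_photo_genes: int = 100
    n_photoresp_genes: int = 50

    # CRE occurrence pool
    m_cres: int = 50
    n_occurrences: int = 100_000
    k_target_occurrences: int = 2000
    dirichlet_conc: float = 50.0
    spiked_cre_ids: tuple = ("ERF_1", "ERF_2", "ERF_3", "bHLH_1", "MYB_1")
    spike_multiplier: float = 3.0
    n_cre_genes: int = 100
    n_cre_target_genes: int = 14
    motif_length: int = 8

    # sequences
    n_cds: int = 50
    cds_length: int = 300
    target_gc3: float = 0.5
    n_signatures: int = 5
    fragment_length: int = 1000
    ir_length: int = 9
    tsd_length: int = 4
    spacer_range: tuple = (100, 200)

    # GRN
    n_tfs: int = 50
    n_grn_genes: int = 200
    n_grn_edges: int = 1000
    cognate_fraction: float = 0.7
    erf_c4_bias: float = 5.0

    def __post_init__(self) -> None:
        if self.c4_rna_fold <= 0 or self.c4_protein_fold <= 0:
            raise ValueError("C4 fold changes F and G must be positive")
        if self.spike_multiplier <= 0:
            raise ValueError("spike multiplier must be positive")
        if self.rna_log10_sigma <= 0:
            raise ValueError("rna_log10_sigma must be positive")
        if self.cds_length % 3 != 0:
            raise ValueError("cds_length must be a multiple of 3")
        if not 0.0 <= self.target_gc3 <= 1.0:
            raise ValueError("target_gc3 must lie in [0, 1]")
        if self.k_target_occurrences > self.n_occurrences:
            raise ValueError("k_target_occurrences cannot exceed n_occurrences")
        if self.n_tfs < 1:
            raise ValueError("need at least one TF")
        if self.n_c4_genes + self.n_photo_genes + self.n_photoresp_genes > self.n_genes:
            raise ValueError("gene-set blocks exceed n_genes")
        min_block = 2 * self.tsd_length + 2 * self.ir_length + self.spacer_range[0]
        if self.fragment_length < min_block:
            raise ValueError("fragment shorter than the planted signature block")


@dataclass
class GroundTruth:
    """Exact per-entity truths recorded by the generators; sufficient to
    predict every downstream result without re-deriving randomness."""

    tables: dict = field(default_factory=dict)   # name -> DataFrame
    scalars: dict = field(default_factory=dict)  # JSON-serializable extras

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"ground_truth_{name}.tsv", sep="\t")
        (outdir / "ground_truth.json").write_text(
            json.dumps(self.scalars, indent=2, default=str)
        )


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def default_gene_sets(cfg: SimConfig) -> dict[str, GeneSet]:
    """Disjoint C4 / photosynthesis / photorespiratory blocks of the gene list."""
    genes = _gene_ids(cfg.n_genes)
    a, b, c = cfg.n_c4_genes, cfg.n_photo_genes, cfg.n_photoresp_genes
    return {
        "c4": GeneSet("c4", frozenset(genes[:a])),
        "photosynthesis": GeneSet("photosynthesis", frozenset(genes[a:a + b])),
        "photorespiratory": GeneSet("photorespiratory", frozenset(genes[a + b:a + b + c])),
    }


# ---------------------------------------------------------------------------
# Multi-omics tables
# ---------------------------------------------------------------------------

def gen_multiomics(cfg: SimConfig) -> tuple[dict[str, AbundanceTable], dict[str, GeneSet], GroundTruth]:
    """Generate RNA/protein/RPF tables, gene sets, and exact truths.

    Model (all means on the linear scale, noise log10-normal):

    * base RNA mean per gene: ``10**Normal(mu, sigma)``, shared across species
    * RNA mean(g, s) = base * F for C4-set genes in C4-type species, else base
    * protein mean(g, s) = base * PTR(g) * (G for boosted genes, else 1)
      so the realized PTR of boosted genes is PTR(g) * G/F
    * RPF mean(g, s) = RNA mean(g, s) * TE(g): translation efficiency is
      deliberately species-invariant
    * each replicate = mean * 10**Normal(0, role noise SD)
    """
    rng = _rng(cfg, 1)
    genes = _gene_ids(cfg.n_genes)
    gene_sets = default_gene_sets(cfg)
    c4_genes = gene_sets["c4"].members

    base_log10 = rng.normal(cfg.rna_log10_mu, cfg.rna_log10_sigma, cfg.n_genes)
    ptr = 10 ** rng.normal(cfg.ptr_log10_mu, cfg.ptr_log10_sd, cfg.n_genes)
    te = 10 ** rng.normal(cfg.te_log10_mu, cfg.te_log10_sd, cfg.n_genes)
    base_rna = 10 ** base_log10
    is_c4_gene = np.array([g in c4_genes for g in genes])

    rna_mean, prot_mean, rpf_mean = {}, {}, {}
    for sp, ptype in cfg.species:
        boosted = is_c4_gene & (ptype == "C4")
        rna = np.where(boosted, base_rna * cfg.c4_rna_fold, base_rna)
        prot = np.where(boosted, base_rna * ptr * cfg.c4_protein_fold, base_rna * ptr)
        rpf = rna * te * np.where(boosted, cfg.c4_te_fold, 1.0)
        rna_mean[sp], prot_mean[sp], rpf_mean[sp] = rna, prot, rpf

    def replicate_table(means: dict, n_rep: int, noise_sd: float) -> pd.DataFrame:
        cols = {}
        for sp, _ in cfg.species:
            for r in range(1, n_rep + 1):
                noise = 10 ** rng.normal(0.0, noise_sd, cfg.n_genes) if noise_sd > 0 \
                    else np.ones(cfg.n_genes)
                cols[f"{sp}_R{r}"] = means[sp] * noise
        return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))

    tables = {
        "rna": AbundanceTable("rna", replicate_table(rna_mean, cfg.n_replicates_rna, cfg.noise_sd_rna)),
        "protein": AbundanceTable("protein", replicate_table(prot_mean, cfg.n_replicates_protein, cfg.noise_sd_protein)),
        "rpf": AbundanceTable("rpf", replicate_table(rpf_mean, cfg.n_replicates_rpf, cfg.noise_sd_rpf)),
    }

    idx = pd.Index(genes, name="gene_id")
    truth = GroundTruth(
        tables={
            "rna_mean": pd.DataFrame(rna_mean, index=idx),
            "protein_mean": pd.DataFrame(prot_mean, index=idx),
            "rpf_mean": pd.DataFrame(rpf_mean, index=idx),
            "ptr": pd.DataFrame({sp: prot_mean[sp] / rna_mean[sp] for sp, _ in cfg.species}, index=idx),
            "te": pd.DataFrame({sp: rpf_mean[sp] / rna_mean[sp] for sp, _ in cfg.species}, index=idx),
        },
        scalars={
            "species_types": dict(cfg.species),
            "c4_ptr_ratio": cfg.c4_protein_fold / cfg.c4_rna_fold,
        },
    )
    return tables, gene_sets, truth


# ---------------------------------------------------------------------------
# CRE occurrence pool over ACRs
# ---------------------------------------------------------------------------

def cre_ids_for(cfg: SimConfig) -> list[str]:
    """CRE identifiers named by TF family, round-robin over families."""
    per = {}
    ids = []
    for i in range(cfg.m_cres):
        fam = CRE_FAMILIES[i % len(CRE_FAMILIES)]
        per[fam] = per.get(fam, 0) + 1
        ids.append(f"{fam}_{per[fam]}")
    return ids


def _cre_gene_layout(cfg: SimConfig) -> tuple[list[GeneModel], pd.DataFrame, dict]:
    """Genes spaced 10 kb apart on one chromosome, each with three ACRs
    planted in its genic, upstream and downstream contexts."""
    models = []
    acr_rows = []
    acr_lookup = {}
    for i in range(cfg.n_cre_genes):
        gid = f"g{i:04d}"
        start = 5000 + i * 10_000
        end = start + 2000
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            sc, tc = start, end - 1
            up = (sc - 2000, sc - 1500)
            down = (tc + 500, tc + 1000)
        else:
            sc, tc = end - 1, start
            up = (sc + 1500, sc + 2000)
            down = (tc - 1000, tc - 500)
        body = (start + 500, start + 1000)
        models.append(GeneModel(gid, "chr1", start, end, strand, sc, tc))
        for ctx, (a, b) in (("gACR", body), ("upACR", up), ("downACR", down)):
            name = f"acr_{gid}_{ctx}"
            acr_rows.append({"chrom": "chr1", "start": a, "end": b, "name": name})
            acr_lookup[(gid, ctx)] = (a, b, name)
    acrs = pd.DataFrame(acr_rows)
    return models, acrs, acr_lookup


def _draw_cre_identities(cfg: SimConfig, rng: np.random.Generator):
    """Background frequencies and CRE identity draws for the occurrence pool."""
    ids = cre_ids_for(cfg)
    spiked = [c for c in cfg.spiked_cre_ids if c in ids]
    p = rng.dirichlet(np.full(cfg.m_cres, cfg.dirichlet_conc))
    spike_w = np.ones(cfg.m_cres)
    for c in spiked:
        spike_w[ids.index(c)] = cfg.spike_multiplier
    p_spiked = p * spike_w
    if not np.all(p_spiked > 0):
        raise ValueError("spike multiplier produced a zero-probability CRE")
    p_spiked = p_spiked / p_spiked.sum()
    N, k = cfg.n_occurrences, cfg.k_target_occurrences
    cre_bg = rng.choice(cfg.m_cres, size=N - k, p=p)
    cre_tg = rng.choice(cfg.m_cres, size=k, p=p_spiked)
    return ids, spiked, p, cre_bg, cre_tg


def gen_cre_pool(cfg: SimConfig) -> tuple[OccurrencePool, GroundTruth]:
    """Counts-only variant of :func:`gen_cre_dataset`.

    Draws the same background/target CRE identities but skips genomic
    placement — the enrichment statistics depend only on the counts, so this
    is the cheap route for large-N calibration pools.
    """
    rng = _rng(cfg, 2)
    ids, spiked, p, cre_bg, cre_tg = _draw_cre_identities(cfg, rng)
    n_c = np.bincount(np.concatenate([cre_bg, cre_tg]), minlength=cfg.m_cres)
    k_c = np.bincount(cre_tg, minlength=cfg.m_cres)
    pool = OccurrencePool(cre_ids=ids, n_c=n_c, k_c=k_c)
    truth = GroundTruth(
        tables={"cre_counts": pd.DataFrame(
            {"n_c": n_c, "k_c": k_c, "background_p": p},
            index=pd.Index(ids, name="cre_id"))},
        scalars={"N": int(cfg.n_occurrences), "k": int(cfg.k_target_occurrences),
                 "spiked_cres": spiked, "spike_multiplier": cfg.spike_multiplier},
    )
    return pool, truth


def gen_cre_dataset(cfg: SimConfig) -> tuple[list[CREOccurrence], list[GeneModel], pd.DataFrame, GeneSet, GroundTruth]:
    """Place N motif occurrences in gene-tied ACRs with spiked enrichment.

    Exactly ``k_target_occurrences`` occurrences land in ACRs of target-set
    genes; their CRE identities are drawn with spiked CREs re-weighted by the
    spike multiplier ``s`` (s=1 makes the target subset an unbiased draw from
    the background composition).  Exact per-CRE counts go into GroundTruth.
    """
    rng = _rng(cfg, 2)
    ids, spiked, p, cre_bg, cre_tg = _draw_cre_identities(cfg, rng)
    models, acrs, acr_lookup = _cre_gene_layout(cfg)
    gene_ids = [m.gene_id for m in models]
    target = GeneSet("c4", frozenset(gene_ids[:cfg.n_cre_target_genes]))
    N, k = cfg.n_occurrences, cfg.k_target_occurrences

    target_genes = gene_ids[:cfg.n_cre_target_genes]
    other_genes = gene_ids[cfg.n_cre_target_genes:]
    contexts = ("gACR", "upACR", "downACR")

    def place(cre_idx: np.ndarray, host_pool: list[str]) -> list[CREOccurrence]:
        hosts = rng.choice(len(host_pool), size=len(cre_idx))
        ctxs = rng.choice(3, size=len(cre_idx))
        offs = rng.random(len(cre_idx))
        occs = []
        for ci, hi, xi, u in zip(cre_idx, hosts, ctxs, offs):
            gid = host_pool[hi]
            a, b, name = acr_lookup[(gid, contexts[xi])]
            s = a + int(u * (b - a - cfg.motif_length))
            occs.append(CREOccurrence(
                cre_id=ids[ci], acr_id=name, chrom="chr1",
                start=s, end=s + cfg.motif_length, q_value=0.01,
            ))
        return occs

    occurrences = place(cre_tg, target_genes) + place(cre_bg, other_genes)

    n_c = np.bincount(np.concatenate([cre_bg, cre_tg]), minlength=cfg.m_cres)
    k_c = np.bincount(cre_tg, minlength=cfg.m_cres)
    truth = GroundTruth(
        tables={"cre_counts": pd.DataFrame(
            {"n_c": n_c, "k_c": k_c, "background_p": p},
            index=pd.Index(ids, name="cre_id"))},
        scalars={"N": int(N), "k": int(k), "spiked_cres": spiked,
                 "spike_multiplier": cfg.spike_multiplier,
                 "target_genes": target_genes},
    )
    return occurrences, models, acrs, target, truth


# ---------------------------------------------------------------------------
# Sequences: GC3-controlled CDS and planted retro signatures
# ---------------------------------------------------------------------------

def random_cds(rng: np.random.Generator, length: int, gc3_target: float) -> str:
    """Random codons with third-position G/C probability = gc3_target."""
    n_codons = length // 3
    pos12 = rng.choice(list("ACGT"), size=(n_codons, 2))
    third_gc = rng.random(n_codons) < gc3_target
    gc_pick = rng.choice(list("GC"), size=n_codons)
    at_pick = rng.choice(list("AT"), size=n_codons)
    third = np.where(third_gc, gc_pick, at_pick)
    codons = np.column_stack([pos12, third])
    return "".join(codons.ravel())


def plant_retro_block(
    rng: np.random.Generator,
    length: int,
    ir_seq: str | None = None,
    tsd_seq: str | None = None,
    ir_length: int = 9,
    tsd_length: int = 4,
    spacer_length: int | None = None,
    spacer_range: tuple[int, int] = (100, 200),
    position: int | None = None,
) -> tuple[str, dict]:
    """Embed one TSD-IR-spacer-IRrc-TSD block in a uniform-random background.

    Single-base guards keep the planted geometry exact for any background:
    the block's neighbours cannot extend the inverted repeat inward/outward
    or lengthen the direct repeat by chance, so a scanner recovers exactly
    the planted IR and TSD lengths.  Returns (sequence, info) where info
    records the planted coordinates.
    """
    bases = "ACGT"
    if tsd_seq is None:
        while True:
            tsd_seq = "".join(rng.choice(list(bases), size=tsd_length))
            if tsd_seq[-1] != _COMP[tsd_seq[0]]:
                break  # outward IR extension must be blocked by the TSD
    if tsd_seq[-1] == _COMP[tsd_seq[0]]:
        raise ValueError("TSD would allow outward extension of the inverted repeat")
    if ir_seq is None:
        ir_seq = "".join(rng.choice(list(bases), size=ir_length))
    if spacer_length is None:
        spacer_length = int(rng.integers(spacer_range[0], spacer_range[1] + 1))
    spacer = list("".join(rng.choice(list(bases), size=spacer_length)))
    # inward extension guard: spacer[0] must not pair with spacer[-1]
    while spacer[0] == _COMP[spacer[-1]]:
        spacer[-1] = str(rng.choice(list(bases)))
    spacer = "".join(spacer)

    block = tsd_seq + ir_seq + spacer + revcomp(ir_seq) + tsd_seq
    if length < len(block):
        raise ValueError(f"fragment length {length} < planted block {len(block)}")
    if position is None:
        position = int(rng.integers(0, length - len(block) + 1))
    seq = list("".join(rng.choice(list(bases), size=length)))
    seq[position:position + len(block)] = list(block)
    # TSD lengthening guard: base before the left TSD must differ from the
    # base after the right TSD
    lo, hi = position - 1, position + len(block)
    if lo >= 0 and hi < length and seq[lo] == seq[hi]:
        choices = [b for b in bases if b != seq[lo]]
        seq[hi] = str(rng.choice(choices))
    seq = "".join(seq)

    left_ir = position + len(tsd_seq)
    right_ir = left_ir + len(ir_seq) + spacer_length
    info = {
        "position": position, "ir_seq": ir_seq, "tsd_seq": tsd_seq,
        "ir_length": len(ir_seq), "tsd_length": len(tsd_seq),
        "spacer_length": spacer_length,
        "left_ir_start": left_ir, "left_ir_end": left_ir + len(ir_seq),
        "right_ir_start": right_ir, "right_ir_end": right_ir + len(ir_seq),
    }
    return seq, info


def gen_sequences(cfg: SimConfig) -> tuple[dict[str, str], dict[str, str], GroundTruth]:
    """CDS FASTA with controlled GC3 plus genomic fragments with planted
    retroduplication blocks."""
    rng = _rng(cfg, 3)
    cds = {f"cds_{i:03d}": random_cds(rng, cfg.cds_length, cfg.target_gc3)
           for i in range(cfg.n_cds)}
    genomic = {}
    planted = []
    for i in range(cfg.n_signatures):
        seq, info = plant_retro_block(
            rng, cfg.fragment_length, ir_length=cfg.ir_length,
            tsd_length=cfg.tsd_length, spacer_range=cfg.spacer_range,
        )
        name = f"frag_{i:03d}"
        genomic[name] = seq
        info["seq_id"] = name
        planted.append(info)
    truth = GroundTruth(
        tables={"planted_signatures": pd.DataFrame(planted).set_index("seq_id")},
        scalars={"target_gc3": cfg.target_gc3},
    )
    return cds, genomic, truth


# ---------------------------------------------------------------------------
# GRN
# ---------------------------------------------------------------------------

def gen_grn(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """TF -> target edges with family labels and cognate promoter support.

    A fraction of TFs (``cognate_fraction``) is given cognate promoter-CRE
    families at its targets, so cognate filtering retains (approximately)
    that fraction of edges.  ERF TFs choose C4-set targets with probability
    boosted ``erf_c4_bias``-fold.
    """
    if cfg.n_tfs == 0:
        raise ValueError("zero TFs")
    rng = _rng(cfg, 4)
    tfs = [f"tf_{i:03d}" for i in range(cfg.n_tfs)]
    families = [CRE_FAMILIES[i % len(CRE_FAMILIES)] for i in range(cfg.n_tfs)]
    tf_family = pd.DataFrame({"tf_id": tfs, "family": families})
    genes = _gene_ids(cfg.n_grn_genes)
    c4 = genes[:cfg.n_c4_genes]
    is_c4 = np.array([g in set(c4) for g in genes])

    n_cognate = int(round(cfg.cognate_fraction * cfg.n_tfs))
    cognate_tfs = set(rng.choice(tfs, size=n_cognate, replace=False)) if n_cognate else set()

    base_w = np.ones(cfg.n_grn_genes)
    erf_w = np.where(is_c4, cfg.erf_c4_bias, 1.0)
    edges = []
    promoter: dict[str, set] = {g: set() for g in genes}
    for _ in range(cfg.n_grn_edges):
        ti = int(rng.integers(cfg.n_tfs))
        w = erf_w if families[ti] == "ERF" else base_w
        gi = int(rng.choice(cfg.n_grn_genes, p=w / w.sum()))
        edges.append({"tf_id": tfs[ti], "target_id": genes[gi]})
        if tfs[ti] in cognate_tfs:
            promoter[genes[gi]].add(families[ti])
    edges_df = pd.DataFrame(edges).drop_duplicates().reset_index(drop=True)
    promoter_df = pd.DataFrame(
        [{"gene_id": g, "cre_families": ",".join(sorted(fams))}
         for g, fams in promoter.items() if fams]
    )
    if promoter_df.empty:
        promoter_df = pd.DataFrame(columns=["gene_id", "cre_families"])

    # bookkeeping: which edges survive cognate filtering, and the ERF metric
    surviving = edges_df[[
        fam in promoter[t] for fam, t in zip(
            edges_df["tf_id"].map(dict(zip(tfs, families))), edges_df["target_id"])
    ]]
    c4_edges = surviving[surviving["target_id"].isin(c4)]
    fam_of = dict(zip(tfs, families))
    erf_tfs = {t for t in c4_edges["tf_id"] if fam_of[t] == "ERF"}
    regulated_c4 = set(c4_edges["target_id"])
    truth = GroundTruth(
        tables={"edges": edges_df.set_index("tf_id")},
        scalars={
            "cognate_tfs": sorted(cognate_tfs),
            "c4_genes": c4,
            "expected_retained_fraction": cfg.cognate_fraction,
            "n_edges_surviving": int(len(surviving)),
            "erf_tfs_in_c4grn": sorted(erf_tfs),
            "erf_per_c4_gene": (len(erf_tfs) / len(regulated_c4)) if regulated_c4 else 0.0,
        },
    )
    return edges_df, tf_family, promoter_df, truth


def simconfig_to_json(cfg: SimConfig) -> str:
    return json.dumps(asdict(cfg), indent=2, default=list)
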