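"""Domain types and file I/O shared by every analysis stage.

Conventions
-----------
* All internal coordinates are 0-based half-open ``[start, end)``.  GFF3 and
  FIMO files (1-based inclusive) are converted at the boundary, BED is native.
* Abundance tables are gene x sample matrices.  Sample headers follow the
  ``SPECIES_R<k>`` dialect (e.g. ``Ftri_R1``).  Missing protein/RPF values are
  *absent* (NaN), never zero: non-detection in iBAQ is censoring.
* "Upstream" and "downstream" are always relative to the gene's strand.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("c4omics")

ROLES = ("rna", "protein", "rpf")
ROLE_UNITS = {"rna": "TPM", "protein": "iBAQ", "rpf": "TPM"}

_SAMPLE_RE = re.compile(r"^(?P<species>.+)_R(?P<rep>\d+)$")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Gene x sample quantification matrix for one omics role.

    Parameters
    ----------
    role : {'rna', 'protein', 'rpf'}
    data : pandas.DataFrame
        Index = gene identifiers, columns = ``SPECIES_R<k>`` sample names.
        NaN marks an absent (undetected) measurement.
    units : str
        'TPM' for rna/rpf, 'iBAQ' for protein.
    """

    role: str
    data: pd.DataFrame
    units: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not self.units:
            self.units = ROLE_UNITS[self.role]
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups[:5]}")
        vals = self.data.to_numpy(dtype=float)
        finite = np.isfinite(vals) | np.isnan(vals)
        if not finite.all():
            raise FormatError("abundance values must be finite or absent (NaN)")
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError("abundance values must be non-negative")
        for name in self.data.columns:
            parse_sample_name(name)  # raises on malformed header

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[tuple[str, int]]:
        return [parse_sample_name(c) for c in self.data.columns]

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp, _ in self.samples:
            seen.setdefault(sp, None)
        return list(seen)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene identifiers (e.g. c4, photosynthesis)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GeneModel:
    """Stranded gene interval with start/stop-codon anchors.

    ``start_codon`` / ``stop_codon`` are the genomic positions (0-based) of
    the transcript-orientation *first* base of the start codon and *last*
    base of the coding region.  On the minus strand the start-codon anchor is
    therefore the highest CDS coordinate.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    start_codon: int
    stop_codon: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: empty interval [{self.start},{self.end})")
        for anchor in (self.start_codon, self.stop_codon):
            if not (self.start <= anchor < self.end):
                raise ValueError(f"{self.gene_id}: codon anchor {anchor} outside gene")


@dataclass
class CREOccurrence:
    """One motif occurrence inside an accessible chromatin region."""

    cre_id: str
    acr_id: str
    chrom: str
    start: int
    end: int
    q_value: float = 0.0
    contexts: set = field(default_factory=set)   # subset of {gACR, upACR, downACR}
    gene_ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"invalid occurrence interval [{self.start},{self.end})")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q-value {self.q_value} outside [0,1]")


@dataclass
class OccurrencePool:
    """Per-CRE occurrence counts: background (n_c, total N) and
    target-gene-associated subset (k_c, total k)."""

    cre_ids: list
    n_c: np.ndarray
    k_c: np.ndarray

    def __post_init__(self) -> None:
        self.n_c = np.asarray(self.n_c, dtype=np.int64)
        self.k_c = np.asarray(self.k_c, dtype=np.int64)
        if len(self.cre_ids) != len(self.n_c) or len(self.n_c) != len(self.k_c):
            raise ValueError("cre_ids, n_c, k_c must have equal length")
        if (self.k_c < 0).any() or (self.n_c < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.k_c > self.n_c).any():
            raise ValueError("k_c exceeds n_c for some CRE")

    @property
    def N(self) -> int:
        return int(self.n_c.sum())

    @property
    def k(self) -> int:
        return int(self.k_c.sum())


@dataclass
class RunConfig:
    """Thresholds, estimator modes and seeds shared across stages.

    Defaults follow the study design: B=1000 permutation draws, 3 kb
    promoter/downstream windows, FIMO q <= 0.05, mean +/- 1 SD abundance-ratio
    classes and top/bottom-5% extreme classes.
    """

    seed: int = 0
    b_permutations: int = 1000
    ptr_sd_multiplier: float = 1.0
    extreme_fraction: float = 0.05
    min_tpm: float = 1.0
    fimo_q_max: float = 0.05
    window_bp: int = 3000
    anova_alpha: float = 0.05
    ptr_log_scale: bool = True           # mean+/-SD thresholds on log10(PTR)
    te_normalizer: str = "mean"          # or "median"
    p_mode: str = "ge_plus_one"          # or "strict_paper"
    permutation_sampling: str = "hypergeometric"  # or "multinomial"
    tsd_inside: bool = False             # TSD geometry: direct repeats outside IR pair
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.b_permutations < 1:
            raise ValueError("b_permutations must be >= 1")
        if not 0.0 < self.extreme_fraction < 0.5:
            raise ValueError("extreme_fraction must lie in (0, 0.5)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.ptr_sd_multiplier <= 0:
            raise ValueError("ptr_sd_multiplier must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Sample-name dialect
# ---------------------------------------------------------------------------

def parse_sample_name(name: str) -> tuple[str, int]:
    """Split a ``SPECIES_R<k>`` header token into (species, replicate)."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise FormatError(
            f"malformed sample header {name!r}: expected SPECIES_R<k> (e.g. Ftri_R1)"
        )
    rep = int(m.group("rep"))
    if rep < 1:
        raise FormatError(f"replicate index must be >= 1 in {name!r}")
    return m.group("species"), rep


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

def read_abundance_table(path: str | Path, role: str) -> AbundanceTable:
    """Read one gene x sample TSV (first column gene id, header = samples).

    Empty cells are absent measurements; negative values are rejected with
    the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path.name}: duplicate gene id {dup!r}")
    data = df.apply(pd.to_numeric, errors="coerce")
    # absent = genuinely empty cell; anything else unparseable is an error
    raw_str = df.fillna("").astype(str).apply(lambda s: s.str.strip())
    unparseable = data.isna() & ~raw_str.isin(["", "NA", "NaN", "nan"])
    if unparseable.to_numpy().any():
        i, j = np.argwhere(unparseable.to_numpy())[0]
        raise FormatError(
            f"{path.name}, line {i + 2}: cannot parse value {df.iloc[i, j]!r}"
        )
    negative = data.lt(0)
    if negative.to_numpy().any():
        i, j = np.argwhere(negative.to_numpy())[0]
        raise FormatError(
            f"{path.name}, line {i + 2}: negative abundance {data.iloc[i, j]}"
        )
    return AbundanceTable(role=role, data=data.astype(float))


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="")


def load_omics_bundle(
    paths: Mapping[str, str | Path], config: RunConfig | None = None
) -> dict[str, AbundanceTable]:
    """Load RNA/protein/RPF tables and align them on the union of gene ids.

    Genes missing from a role's file become absent (NaN) rows, never zeros.
    """
    tables = {}
    for role, path in paths.items():
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        tables[role] = read_abundance_table(path, role)
    all_genes = sorted(set().union(*(t.data.index for t in tables.values())))
    for role, t in tables.items():
        tables[role] = AbundanceTable(
            role=role, data=t.data.reindex(all_genes), units=t.units
        )
    return tables


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-gene-per-line list (comments with '#' allowed)."""
    path = Path(path)
    members = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            members.append(line.split("\t")[0])
    return GeneSet(name=name or path.stem, members=frozenset(members))


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(gene_set.members)) + "\n")


# ---------------------------------------------------------------------------
# Replicate aggregation
# ---------------------------------------------------------------------------

def aggregate_replicates(
    table: AbundanceTable, min_detect: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-species gene means, SDs and detection flags.

    Returns ``(means, sds, detected)`` each gene x species.  Detection means
    the per-species mean is >= ``min_detect`` (absent replicates propagate:
    a gene with no finite replicate in a species has NaN mean and is not
    detected).  Single-replicate species get SD 0.
    """
    cols_by_species: dict[str, list[str]] = {}
    for col in table.data.columns:
        sp, _ = parse_sample_name(col)
        cols_by_species.setdefault(sp, []).append(col)
    for sp, cols in cols_by_species.items():
        if not cols:
            raise ValueError(f"species {sp!r} has zero samples")
    means = {}
    sds = {}
    for sp, cols in cols_by_species.items():
        block = table.data[cols]
        means[sp] = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        # single replicate -> SD reported as 0, not NaN
        sd = sd.where(block.notna().sum(axis=1) != 1, 0.0)
        sds[sp] = sd
    means_df = pd.DataFrame(means)
    sds_df = pd.DataFrame(sds)
    detected = means_df.ge(min_detect) & means_df.notna()
    return means_df, sds_df, detected


# ---------------------------------------------------------------------------
# Genome annotations: GFF3 + BED + FASTA
# ---------------------------------------------------------------------------

def read_gff3_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene + CDS features from a GFF3 file into :class:`GeneModel`.

    GFF3 1-based inclusive coordinates become 0-based half-open.  A gene
    without CDS features is excluded with a warning (no codon anchors).
    """
    path = Path(path)
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols,
                     dtype={"seqid": str, "type": str, "attributes": str})
    genes = df[df["type"] == "gene"].copy()
    cds = df[df["type"] == "CDS"].copy()
    genes["gene_id"] = genes["attributes"].str.extract(r"ID=([^;]+)")
    cds["parent"] = cds["attributes"].str.extract(r"Parent=([^;]+)")
    models = []
    cds_by_parent = dict(tuple(cds.groupby("parent")))
    for _, g in genes.iterrows():
        gid = g["gene_id"]
        sub = cds_by_parent.get(gid)
        if sub is None or sub.empty:
            logger.warning("gene %s has no CDS features; excluded", gid)
            continue
        start0 = int(g["start"]) - 1
        end0 = int(g["end"])
        cds_lo = int(sub["start"].min()) - 1
        cds_hi = int(sub["end"].max())
        if g["strand"] == "+":
            sc, tc = cds_lo, cds_hi - 1
        else:
            sc, tc = cds_hi - 1, cds_lo
        models.append(GeneModel(gene_id=gid, chrom=str(g["seqid"]), start=start0,
                                end=end0, strand=str(g["strand"]),
                                start_codon=sc, stop_codon=tc))
    return models


def write_gff3_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene + single-CDS records covering the codon anchors."""
    lines = ["##gff-version 3"]
    for m in models:
        lines.append("\t".join([
            m.chrom, "c4omics", "gene", str(m.start + 1), str(m.end), ".",
            m.strand, ".", f"ID={m.gene_id}",
        ]))
        lo = min(m.start_codon, m.stop_codon)
        hi = max(m.start_codon, m.stop_codon)
        lines.append("\t".join([
            m.chrom, "c4omics", "CDS", str(lo + 1), str(hi + 1), ".",
            m.strand, "0", f"ID={m.gene_id}.cds;Parent={m.gene_id}",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read BED3+ into a frame with chrom/start/end (+name when present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise FormatError(f"{Path(path).name}: BED needs >= 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["chrom"] = out["chrom"].astype(str)
    if df.shape[1] >= 4:
        out["name"] = df.iloc[:, 3].astype(str)
    else:
        out["name"] = [f"acr_{i}" for i in range(len(out))]
    if (out["start"] >= out["end"]).any():
        raise FormatError(f"{Path(path).name}: empty BED interval")
    return out


def write_bed_intervals(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def load_genome_annotations(
    gff3: str | Path, acr_bed: str | Path, fasta: str | Path | None = None
) -> tuple[list[GeneModel], pd.DataFrame, dict[str, str]]:
    """Load gene models, ACR intervals and (optionally) genome sequences.

    Raises on a sequence-id namespace mismatch between the GFF3 and BED.
    """
    models = read_gff3_gene_models(gff3)
    acrs = read_bed_intervals(acr_bed)
    seqs = read_fasta(fasta) if fasta is not None else {}
    gff_chroms = {m.chrom for m in models}
    bed_chroms = set(acrs["chrom"])
    if gff_chroms and bed_chroms and not (gff_chroms & bed_chroms):
        raise FormatError(
            f"no shared sequence ids between annotation ({sorted(gff_chroms)[:3]}...) "
            f"and ACR BED ({sorted(bed_chroms)[:3]}...)"
        )
    return models, acrs, seqs


# ---------------------------------------------------------------------------
# FIMO-dialect motif occurrences
# ---------------------------------------------------------------------------

FIMO_COLUMNS = ["motif_id", "sequence_name", "start", "stop", "strand",
                "score", "p-value", "q-value"]


def load_motif_occurrences(
    tsv: str | Path, q_max: float = 0.05
) -> list[CREOccurrence]:
    """Load a FIMO-dialect occurrence table, dropping rows with q > q_max.

    FIMO coordinates (1-based inclusive) become 0-based half-open.  The
    ``sequence_name`` column is interpreted as ``<acr_id>`` and, when it
    matches ``chrom:start-end``, the coordinates are genome-anchored.
    """
    path = Path(tsv)
    df = pd.read_csv(path, sep="\t", comment="#")
    if "q-value" not in df.columns:
        raise FormatError(
            f"{path.name}: no 'q-value' column; pass q_max=1.0 and a table with "
            "an explicit q-value column to disable filtering"
        )
    n0 = len(df)
    df = df[df["q-value"] <= q_max]
    logger.info("dropped %d/%d occurrences with q > %g", n0 - len(df), n0, q_max)
    occs = []
    for motif, seqname, start, stop, q in zip(
        df["motif_id"], df["sequence_name"], df["start"], df["stop"], df["q-value"]
    ):
        seqname = str(seqname)
        m = re.match(r"^(.+):(\d+)-(\d+)$", seqname)
        if m:
            chrom, offset = m.group(1), int(m.group(2))
        else:
            chrom, offset = seqname, 0
        occs.append(CREOccurrence(
            cre_id=str(motif), acr_id=seqname, chrom=chrom,
            start=offset + int(start) - 1, end=offset + int(stop),
            q_value=float(q),
        ))
    return occs


def write_motif_occurrences(occs: Iterable[CREOccurrence], path: str | Path) -> None:
    """Write occurrences in the FIMO TSV dialect (1-based inclusive)."""
    rows = []
    for o in occs:
        rows.append({
            "motif_id": o.cre_id, "sequence_name": o.chrom,
            "start": o.start + 1, "stop": o.end, "strand": "+",
            "score": 0.0, "p-value": 0.0, "q-value": o.q_value,
        })
    pd.DataFrame(rows, columns=FIMO_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result writing
# ---------------------------------------------------------------------------

def write_results(
    results: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    config: RunConfig | None = None,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write each result frame as TSV under ``outdir`` and return a manifest.

    The manifest lists file name, row count, config hash and seed; it is also
    written to ``manifest.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or RunConfig()
    rows = []
    for name, df in results.items():
        target = outdir / f"{name}.tsv"
        if target.exists() and not overwrite:
            raise FileExistsError(f"{target} exists; pass overwrite=True")
        df.to_csv(target, sep="\t", index=False)
        rows.append({"file": target.name, "rows": len(df),
                     "config_hash": cfg.config_hash(), "seed": cfg.seed})
    manifest = pd.DataFrame(rows, columns=["file", "rows", "config_hash", "seed"])
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
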