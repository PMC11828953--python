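"""Sequence-level classifiers: GC3, retroduplication signatures, functional copies.

The retroduplication scanner looks for the footprint a retrotransposon-mediated
gene duplication leaves in genomic DNA: an inverted-repeat pair (a sequence
followed downstream by its reverse complement) whose outer boundaries are
flanked by a short identical direct repeat, the target site duplication (TSD)
created on insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet."""
    return "".join(_COMP[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# GC3
# ---------------------------------------------------------------------------

def gc3(cds: str) -> float:
    """Fraction of codons with G or C at the third position.

    Codons whose third base is N are excluded from both numerator and
    denominator.  Raises on empty input or length not divisible by 3.
    """
    cds = cds.upper()
    if not cds:
        raise ValueError("empty CDS")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if set(cds) - set("ACGTN"):
        raise ValueError(f"unexpected characters: {sorted(set(cds) - set('ACGTN'))}")
    third = cds[2::3]
    informative = [b for b in third if b != "N"]
    if not informative:
        raise ValueError("no informative third positions (all N)")
    gc = sum(1 for b in informative if b in "GC")
    return gc / len(informative)


# ---------------------------------------------------------------------------
# Inverted repeat + TSD scanner
# ---------------------------------------------------------------------------

@dataclass
class RetroSignature:
    """A detected inverted-repeat pair with flanking direct-repeat TSD."""

    seq_id: str
    left_start: int
    left_end: int          # half-open
    right_start: int
    right_end: int
    ir_seq: str            # sequence of the left unit
    tsd_seq: str
    spacer_length: int
    mismatches: int = 0

    @property
    def ir_length(self) -> int:
        return self.left_end - self.left_start

    @property
    def tsd_length(self) -> int:
        return len(self.tsd_seq)

    @property
    def score(self) -> int:
        # no scoring is standard for this signature; length-additive with a
        # mismatch penalty gives a deterministic ranking
        return self.ir_length + self.tsd_length - 2 * self.mismatches

    def sort_key(self):
        return (-self.score, self.left_start, self.right_start)


def _match_vector(seq: str, d: int, n: int) -> tuple[int, int, np.ndarray]:
    """Complement-match indicator along diagonal d (pair p <-> d-p), for
    p in [p_lo, p_hi] with p < d - p."""
    p_lo = max(0, d - (n - 1))
    p_hi = (d - 1) // 2
    if p_hi < p_lo:
        return p_lo, p_hi, np.zeros(0, dtype=bool)
    ps = np.arange(p_lo, p_hi + 1)
    left = np.frombuffer(seq.encode(), dtype=np.uint8)[ps]
    right = np.frombuffer(seq.encode(), dtype=np.uint8)[d - ps]
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
        comp[ord(a)] = ord(b)
    c = comp[left] == right
    c &= comp[left] != 0  # N or unknown never matches
    return p_lo, p_hi, c


def _tsd_at(seq: str, i: int, j: int, L: int, tsd_range: tuple[int, int],
            tsd_inside: bool) -> str | None:
    """Longest exact direct repeat of length within tsd_range flanking the
    IR pair; None if no length in range matches."""
    n = len(seq)
    t_lo, t_hi = tsd_range
    for t in range(t_hi, t_lo - 1, -1):
        if tsd_inside:
            if i + L + t <= j - t and seq[i + L:i + L + t] == seq[j - t:j]:
                return seq[i + L:i + L + t]
        else:
            if i - t >= 0 and j + L + t <= n and seq[i - t:i] == seq[j + L:j + L + t]:
                return seq[i - t:i]
    return None


def find_inverted_repeat_tsd(
    seq: str,
    seq_id: str = "seq",
    min_ir: int = 6,
    tsd_range: tuple[int, int] = (3, 6),
    max_spacer: int = 5000,
    max_mismatch: int = 0,
    tsd_inside: bool = False,
) -> list[RetroSignature]:
    """Scan one sequence for maximal inverted-repeat pairs with flanking TSDs.

    A hit is a pair of disjoint intervals ``[i, i+L)`` and ``[j, j+L)`` with
    ``seq[i:i+L]`` equal to the reverse complement of ``seq[j:j+L]`` up to
    ``max_mismatch`` mismatches, ``L >= min_ir``, spacer ``j-(i+L)`` in
    ``[0, max_spacer]``, that cannot be extended by one base (inward or
    outward) within the mismatch budget, together with an identical direct
    repeat of the longest length in ``tsd_range`` immediately outside the
    pair (or inside, with ``tsd_inside``).

    Results are sorted by score ``L + t - 2*mismatches`` (descending), ties
    broken by leftmost position.  Sequences too short to host a signature
    yield an empty list.
    """
    seq = seq.upper()
    n = len(seq)
    t_lo, _ = tsd_range
    if n < 2 * min_ir + 2 * t_lo:
        return []
    out: list[RetroSignature] = []
    for d in range(2 * min_ir - 1, 2 * n - 2):
        p_lo, p_hi, c = _match_vector(seq, d, n)
        if c.size == 0 or not c.any():
            continue
        # maximal true-runs; with a mismatch budget, spans of consecutive
        # runs whose internal gaps stay within budget (one-base extension
        # across a mismatching base is never allowed: ends must match)
        idx = np.flatnonzero(c)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate([[idx[0]], idx[breaks + 1]]) + p_lo
        run_ends = np.concatenate([idx[breaks], [idx[-1]]]) + p_lo  # inclusive
        n_runs = len(run_starts)
        for r0 in range(n_runs):
            mm = 0
            for r1 in range(r0, n_runs):
                if r1 > r0:
                    mm += run_starts[r1] - run_ends[r1 - 1] - 1
                    if mm > max_mismatch:
                        break
                a, b = int(run_starts[r0]), int(run_ends[r1])
                L = b - a + 1
                if L < min_ir:
                    continue
                i, j = a, d - b
                spacer = j - (a + L)
                if spacer < 0 or spacer > max_spacer:
                    continue
                tsd = _tsd_at(seq, i, j, L, tsd_range, tsd_inside)
                if tsd is None:
                    continue
                out.append(RetroSignature(
                    seq_id=seq_id, left_start=i, left_end=i + L,
                    right_start=j, right_end=j + L,
                    ir_seq=seq[i:i + L], tsd_seq=tsd,
                    spacer_length=spacer, mismatches=mm,
                ))
    out.sort(key=RetroSignature.sort_key)
    return out


def signatures_to_frame(signatures: list[RetroSignature]) -> pd.DataFrame:
    cols = ["seq_id", "left_start", "left_end", "right_start", "right_end",
            "ir_length", "ir_seq", "spacer_length", "tsd_length", "tsd_seq",
            "mismatches", "score"]
    rows = [{
        "seq_id": s.seq_id, "left_start": s.left_start, "left_end": s.left_end,
        "right_start": s.right_start, "right_end": s.right_end,
        "ir_length": s.ir_length, "ir_seq": s.ir_seq,
        "spacer_length": s.spacer_length, "tsd_length": s.tsd_length,
        "tsd_seq": s.tsd_seq, "mismatches": s.mismatches, "score": s.score,
    } for s in signatures]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Functional-copy rule
# ---------------------------------------------------------------------------

@dataclass
class ParalogGroup:
    """A paralogous group with per-species mean transcript abundance (TPM).

    ``expression``: members x species frame of species-mean TPM; NaN marks a
    member absent from a species' annotation.
    """

    group_id: str
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expression.empty:
            raise ValueError(f"paralog group {self.group_id} has no members")


@dataclass
class FunctionalCopyCall:
    group_id: str
    gene_id: str | None
    tie: bool
    trace: dict = field(default_factory=dict)


def identify_functional_copy(
    group: ParalogGroup, c4_species: set[str], c3_species: set[str]
) -> FunctionalCopyCall:
    """Designate the functional copy of a gene family in C4-type species.

    Two criteria, both on transcript abundance: (1) the candidate has the
    highest mean TPM across C4-type species within its paralogous group;
    (2) that abundance exceeds the C3-species abundance of its counterpart
    (the same gene where annotated, otherwise the group's most expressed
    C3 member).  A tie on criterion 1 returns no call with a tie flag.
    """
    expr = group.expression
    c4_cols = [c for c in expr.columns if c in c4_species]
    c3_cols = [c for c in expr.columns if c in c3_species]
    if not c4_cols or not c3_cols:
        raise ValueError(f"group {group.group_id}: need expression in both "
                         "C4-type and C3-type species")
    c4_mean = expr[c4_cols].mean(axis=1)
    if c4_mean.isna().all():
        raise ValueError(f"group {group.group_id}: no C4-species expression data")
    top = c4_mean.max()
    winners = c4_mean.index[c4_mean == top]
    trace = {"c4_mean": c4_mean.to_dict(), "criterion1_max": float(top)}
    if len(winners) > 1:
        return FunctionalCopyCall(group.group_id, None, tie=True, trace=trace)
    cand = winners[0]
    c3_val = expr.loc[cand, c3_cols].mean()
    if pd.isna(c3_val):
        # counterpart absent from C3 annotations: fall back to the group's
        # most expressed C3 member
        c3_val = expr[c3_cols].mean(axis=1).max()
    trace["criterion2_c3_counterpart"] = float(c3_val) if pd.notna(c3_val) else None
    if pd.notna(c3_val) and top > c3_val:
        return FunctionalCopyCall(group.group_id, str(cand), tie=False, trace=trace)
    return FunctionalCopyCall(group.group_id, None, tie=False, trace=trace)
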