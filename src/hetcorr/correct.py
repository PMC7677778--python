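"""Zygosity-aware correction of long reads.

Correction is a vote constrained by the zygosity decision at each anchor
site: a homozygous site is rewritten to the most frequent allele of the
voting pool; at a heterozygous site a read base already matching one of
the two top alleles is left untouched, anything else is replaced by a
seeded-uniform choice between the two.  The null allele N represents a
deletion: an N winner deletes the read base, and a deleted read base at a
site whose winners are real bases is re-inserted.

For mapped long reads (Lm) the voting pool at an anchor merges the long-
and short-read pileup counts (configurable to short-only); unmapped long
reads (Lu) are corrected one by one purely from the short reads mapped
onto them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from hetcorr.align import (
    ALLELES,
    Alignment,
    N_CODE,
    Pileup,
    PileupColumn,
    RankedCounts,
    rank_alleles,
)
from hetcorr.simulate import Read, ReadSet, codes_to_seq, revcomp, seq_to_codes
from hetcorr.zygosity import HET_CODE, HETEROZYGOUS, HOMO_CODE, HOMOZYGOUS

# an edit is (position in the target-forward-oriented read, old, new);
# '-' denotes absence (old '-' = inserted base, new '-' = deleted base)
Edit = tuple[int, str, str]


@dataclass
class CorrectedRead:
    id: str
    sequence: str  # stored in the read's original orientation
    edits: list[Edit] = field(default_factory=list)
    strand: str = "+"

    @property
    def n_edits(self) -> int:
        return len(self.edits)


def apply_edits(oriented_original: str, edits: list[Edit]) -> str:
    """Replay edits on the oriented original sequence (test/audit helper)."""
    out: list[str] = []
    by_pos: dict[int, list[Edit]] = {}
    for e in edits:
        by_pos.setdefault(e[0], []).append(e)
    for pos in range(len(oriented_original) + 1):
        subs = [e for e in by_pos.get(pos, []) if e[1] != "-"]
        inss = [e for e in by_pos.get(pos, []) if e[1] == "-"]
        for _, _, new in inss:
            out.append(new)
        if pos < len(oriented_original):
            if subs:
                _, old, new = subs[0]
                if new != "-":
                    out.append(new)
            else:
                out.append(oriented_original[pos])
    return "".join(out)


def voting_pool(
    long_col: Optional[PileupColumn],
    short_col: Optional[PileupColumn],
    mode: str = "merged",
) -> RankedCounts:
    """Ranked replacement alleles at an anchor site.

    ``merged`` sums long- and short-read counts; ``short`` uses short-read
    counts only.  Ties rank in fixed A<C<G<T<N order.
    """
    counts: dict[str, int] = {}
    cols = []
    if mode == "merged":
        cols = [c for c in (long_col, short_col) if c is not None]
    elif mode == "short":
        cols = [short_col] if short_col is not None else []
    else:
        raise ValueError(f"unknown pool mode {mode!r}")
    for col in cols:
        for a, c in col.counts.items():
            counts[a] = counts.get(a, 0) + c
    site = next((c.site for c in cols), -1)
    return rank_alleles(PileupColumn(site=site, counts=counts))


def correct_base(
    read_base: str, H: str, pool: RankedCounts, rng: np.random.Generator
) -> str:
    """Correct a single base ('N' in or out denotes a deleted base)."""
    if pool.d == 0:
        return read_base
    top = [a for a, _ in pool.alleles[:2]]
    if H == HOMOZYGOUS:
        return top[0]
    if H != HETEROZYGOUS:
        raise ValueError(f"unknown hypothesis {H!r}")
    if read_base in top:
        return read_base
    if len(top) == 1:
        return top[0]
    return top[int(rng.integers(0, 2))]


def ranked_top_two(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column top-two allele codes of a (5, L) count matrix.

    Ties break in A<C<G<T<N order; -1 marks an absent rank (count zero).
    """
    # count dominates; among equal counts the smaller allele index wins
    key = counts.astype(np.int64) * 8 + (4 - np.arange(5))[:, None]
    order = np.argsort(-key, axis=0, kind="stable")
    top1 = order[0].astype(np.int8)
    top2 = order[1].astype(np.int8)
    c1 = np.take_along_axis(counts, order[:1], axis=0)[0]
    c2 = np.take_along_axis(counts, order[1:2], axis=0)[0]
    top1[c1 == 0] = -1
    top2[c2 == 0] = -1
    return top1, top2


def _correct_read_against_target(
    read: Read,
    aln: Alignment,
    decision: np.ndarray,
    top1: np.ndarray,
    top2: np.ndarray,
    rng: np.random.Generator,
) -> CorrectedRead:
    """Apply the correction rules along one alignment."""
    oriented = read.sequence if aln.strand == "+" else revcomp(read.sequence)
    q = seq_to_codes(oriented)
    pieces: list[np.ndarray] = []
    edits: list[Edit] = []
    qpos, tpos = 0, aln.target_start
    for op, n in aln.ops:
        if op in "=XM":
            sites = np.arange(tpos, tpos + n)
            bases = q[qpos : qpos + n].astype(np.int8)
            dec = decision[sites]
            t1 = top1[sites]
            t2 = top2[sites]
            new = bases.copy()
            homo = (dec == HOMO_CODE) & (t1 >= 0)
            new[homo] = t1[homo]
            het = (dec == HET_CODE) & (t1 >= 0)
            keep = (bases == t1) | ((t2 >= 0) & (bases == t2))
            repl = het & ~keep
            if repl.any():
                pick = rng.integers(0, 2, size=int(repl.sum()))
                alt = np.where(pick == 0, t1[repl], np.where(t2[repl] >= 0, t2[repl], t1[repl]))
                new[repl] = alt
            changed = np.nonzero(new != bases)[0]
            for i in changed:
                old_b = ALLELES[bases[i]]
                new_b = ALLELES[new[i]] if new[i] != N_CODE else "-"
                edits.append((qpos + int(i), old_b, new_b))
            pieces.append(new[new != N_CODE].astype(np.uint8))
            qpos += n
            tpos += n
        elif op == "I":
            pieces.append(q[qpos : qpos + n])
            qpos += n
        elif op == "D":
            # the read deletes these target sites; re-insert where the
            # winning alleles are real bases
            for site in range(tpos, tpos + n):
                dec = int(decision[site])
                t1, t2 = int(top1[site]), int(top2[site])
                if dec == 0 or t1 < 0:
                    continue
                if dec == HOMO_CODE:
                    ins = t1
                else:  # heterozygous: N in the top two keeps the deletion
                    if t1 == N_CODE or t2 == N_CODE:
                        continue
                    if t2 < 0:
                        ins = t1
                    else:
                        ins = t1 if int(rng.integers(0, 2)) == 0 else t2
                if ins == N_CODE:
                    continue
                pieces.append(np.array([ins], dtype=np.uint8))
                edits.append((qpos, "-", ALLELES[ins]))
            tpos += n
    corrected_oriented = codes_to_seq(
        np.concatenate(pieces) if pieces else np.empty(0, dtype=np.uint8)
    )
    seq = corrected_oriented if aln.strand == "+" else revcomp(corrected_oriented)
    return CorrectedRead(id=read.id, sequence=seq, edits=edits, strand=aln.strand)


def correct_Lm(
    Lm: ReadSet,
    alignments: Iterable[Alignment],
    decision: np.ndarray,
    top1: np.ndarray,
    top2: np.ndarray,
    rng: np.random.Generator,
) -> list[CorrectedRead]:
    """Correct every mapped long read against the pseudo-reference anchors.

    ``decision``/``top1``/``top2`` are per-anchor arrays (fused zygosity
    decision and the voting pool's two top allele codes).  Reads without an
    alignment pass through unchanged.
    """
    aln_by_id = {a.read_id: a for a in alignments}
    out = []
    for read in Lm:
        aln = aln_by_id.get(read.id)
        if aln is None:
            out.append(CorrectedRead(id=read.id, sequence=read.sequence))
        else:
            out.append(
                _correct_read_against_target(read, aln, decision, top1, top2, rng)
            )
    return out


def correct_Lu(
    Lu: ReadSet,
    lu_maps: dict[str, tuple[list[Alignment], Pileup]],
    e_short: float,
    prior,
    rng: np.random.Generator,
) -> list[CorrectedRead]:
    """Correct each unmapped long read from the short reads mapped onto it.

    Zygosity (H_u) and voting pool both come from the short-read pileup on
    the Lu read itself; uncovered positions stay untouched.
    """
    from hetcorr.zygosity import classify_columns

    out = []
    for read in Lu:
        entry = lu_maps.get(read.id)
        if entry is None or entry[1].depth().sum() == 0:
            out.append(CorrectedRead(id=read.id, sequence=read.sequence))
            continue
        pileup = entry[1]
        decision, _, _ = classify_columns(pileup.counts, e_short, prior)
        top1, top2 = ranked_top_two(pileup.counts)
        identity = Alignment(
            read_id=read.id,
            target_id=read.id,
            target_start=0,
            ops=[("=", len(read.sequence))],
            read_length=len(read.sequence),
        )
        out.append(
            _correct_read_against_target(read, identity, decision, top1, top2, rng)
        )
    return out
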