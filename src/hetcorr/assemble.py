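"""Pseudo-reference assembly by overlap-layout-consensus.

Four steps: (1) treat every long read as a node; (2) score overlaps
between read pairs with Smith-Waterman, keeping those whose aligned
length lies in [min_length, max_length] and whose score exceeds the
threshold; (3) greedily merge reads into contigs in descending overlap
score, taking a per-column majority-vote consensus; (4) repeat overlap
detection on the contigs themselves and merge until a fixpoint.  The
final contigs are linked, longest first, with runs of 50 N as spacers
into a single pseudo reference whose spacer positions are masked from
downstream anchoring.

The pseudo reference is only a shared coordinate system for pileups, not
a biological truth; any externally assembled FASTA can be substituted for
it at the pipeline seam.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from hetcorr import dp
from hetcorr.simulate import Read, ReadSet, codes_to_seq, seq_to_codes

SPACER_LEN = 50


@dataclass
class AssemblyParams:
    min_length: int = 100
    max_length: Optional[int] = None  # None: no upper bound on overlap length
    theta_score: float = 100.0
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    k: int = 15  # k-mer prefilter for candidate pairs

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if self.max_length is not None and self.max_length < self.min_length:
            raise ValueError("need min_length <= max_length")
        if self.theta_score <= 0:
            raise ValueError("theta_score must be positive")


@dataclass
class Overlap:
    read_i: str
    read_j: str
    span_i: tuple[int, int]  # half-open on read_i
    span_j: tuple[int, int]  # half-open on read_j
    score: float
    length: int  # alignment columns


@dataclass
class Contig:
    sequence: str
    members: list[tuple[str, int]]  # (read_id, offset of read start in contig)


@dataclass
class PseudoReference:
    sequence: str
    contig_spans: list[tuple[int, int]]
    spacer_mask: np.ndarray  # boolean, True at spacer positions

    def __len__(self) -> int:
        return len(self.sequence)


def _share_kmer(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return a in b or b in a
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def _pair_overlap(
    a: Read, b: Read, p: AssemblyParams
) -> Optional[Overlap]:
    res = dp.smith_waterman(a.sequence, b.sequence, p.match, p.mismatch, p.gap)
    if res.score <= p.theta_score:
        return None
    length = res.length
    if length < p.min_length:
        return None
    if p.max_length is not None and length > p.max_length:
        return None
    return Overlap(
        read_i=a.id,
        read_j=b.id,
        span_i=res.query_span,
        span_j=res.target_span,
        score=res.score,
        length=length,
    )


def compute_overlaps(L: ReadSet, p: AssemblyParams) -> list[Overlap]:
    """All-pairs overlap detection (k-mer prefiltered, Smith-Waterman scored).

    One overlap per unordered read pair whose local alignment clears both
    the score threshold and the length window; pairs sharing no k-mer are
    skipped — a pair overlapping by at least min_length >= k necessarily
    shares a k-mer only when the overlap is exact, so the filter is a
    heuristic for noisy reads but lossless on exact overlaps.
    """
    if len(L) == 0:
        raise ValueError("cannot assemble an empty read set")
    overlaps = []
    for a, b in itertools.combinations(L, 2):
        if not _share_kmer(a.sequence, b.sequence, min(p.k, p.min_length)):
            continue
        ov = _pair_overlap(a, b, p)
        if ov is not None:
            overlaps.append(ov)
    return overlaps


class _OffsetForest:
    """Union-find over reads carrying each read's offset within its contig."""

    def __init__(self, ids: list[str]):
        self.parent = {i: i for i in ids}
        self.offset = {i: 0 for i in ids}  # offset relative to component root

    def find(self, x: str) -> tuple[str, int]:
        path = []
        while self.parent[x] != x:
            path.append(x)
            x = self.parent[x]
        # path compression with offset accumulation
        total = 0
        for node in reversed(path):
            total += self.offset[node]
            self.parent[node] = x
            self.offset[node] = total
        return x, 0

    def offset_to_root(self, x: str) -> int:
        self.find(x)
        return self.offset[x] if self.parent[x] != x else 0

    def union(self, a: str, b: str, rel: int) -> bool:
        """Attach so that offset(b) - offset(a) == rel; False if already joined."""
        ra, _ = self.find(a)
        rb, _ = self.find(b)
        off_a = self.offset[a] if self.parent[a] != a else 0
        off_b = self.offset[b] if self.parent[b] != b else 0
        if ra == rb:
            return False
        self.parent[rb] = ra
        self.offset[rb] = off_a + rel - off_b
        return True


def _consensus(
    reads_by_id: dict[str, Read], members: list[tuple[str, int]]
) -> tuple[str, list[tuple[str, int]]]:
    start = min(off for _, off in members)
    members = sorted(
        [(rid, off - start) for rid, off in members], key=lambda m: (m[1], m[0])
    )
    end = max(off + len(reads_by_id[rid].sequence) for rid, off in members)
    counts = np.zeros((4, end), dtype=np.int32)
    for rid, off in members:
        codes = seq_to_codes(reads_by_id[rid].sequence)
        np.add.at(counts, (codes, np.arange(off, off + codes.size)), 1)
    # majority vote, ties to the smaller allele index (argmax is first max)
    best = counts.argmax(axis=0).astype(np.uint8)
    return codes_to_seq(best), members


def layout_contigs(L: ReadSet, overlaps: list[Overlap]) -> list[Contig]:
    """Greedy layout in descending overlap score (ties by id pair).

    Offsets come from the ungapped interpretation of each overlap's spans;
    the consensus at overlapping columns is a per-column majority vote.
    """
    reads_by_id = L.by_id()
    forest = _OffsetForest(list(reads_by_id))
    ordered = sorted(overlaps, key=lambda o: (-o.score, o.read_i, o.read_j))
    for ov in ordered:
        rel = ov.span_i[0] - ov.span_j[0]  # read_j start relative to read_i start
        forest.union(ov.read_i, ov.read_j, rel)
    groups: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for rid in reads_by_id:
        root, _ = forest.find(rid)
        off = forest.offset[rid] if forest.parent[rid] != rid else 0
        groups[root].append((rid, off))
    contigs = []
    for root in sorted(groups):
        seq, members = _consensus(reads_by_id, groups[root])
        contigs.append(Contig(sequence=seq, members=members))
    return contigs


def merge_contigs(contigs: list[Contig], p: AssemblyParams) -> list[Contig]:
    """Re-run overlap detection on contig sequences and merge to a fixpoint."""
    current = contigs
    for _ in range(len(contigs) + 1):
        if len(current) <= 1:
            break
        as_reads = ReadSet(
            [Read(id=f"c{idx}", sequence=c.sequence) for idx, c in enumerate(current)]
        )
        overlaps = compute_overlaps(as_reads, p)
        if not overlaps:
            break
        merged = layout_contigs(as_reads, overlaps)
        # carry original read members through the contig-level layout
        out = []
        for mc in merged:
            members: list[tuple[str, int]] = []
            for cid, off in mc.members:
                src = current[int(cid[1:])]
                members.extend((rid, off + roff) for rid, roff in src.members)
            out.append(Contig(sequence=mc.sequence, members=sorted(members, key=lambda m: (m[1], m[0]))))
        if len(out) == len(current):
            current = out
            break
        current = out
    return current


def link_contigs(contigs: list[Contig]) -> PseudoReference:
    """Concatenate contigs (longest first, ties by first member id) with N spacers."""
    if not contigs:
        raise ValueError("no contigs to link")
    ordered = sorted(
        contigs,
        key=lambda c: (-len(c.sequence), c.members[0][0] if c.members else ""),
    )
    parts: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    for idx, c in enumerate(ordered):
        if idx > 0:
            parts.append("N" * SPACER_LEN)
            pos += SPACER_LEN
        spans.append((pos, pos + len(c.sequence)))
        parts.append(c.sequence)
        pos += len(c.sequence)
    sequence = "".join(parts)
    mask = np.ones(len(sequence), dtype=bool)
    for a, b in spans:
        mask[a:b] = False
    return PseudoReference(sequence=sequence, contig_spans=spans, spacer_mask=mask)


def assemble_pseudo_reference(L: ReadSet, p: Optional[AssemblyParams] = None) -> PseudoReference:
    """Full four-step assembly: overlaps, layout, contig merge, linking."""
    p = p or AssemblyParams()
    overlaps = compute_overlaps(L, p)
    contigs = layout_contigs(L, overlaps)
    contigs = merge_contigs(contigs, p)
    return link_contigs(contigs)
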