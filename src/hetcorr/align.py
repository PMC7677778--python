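"""Read mapping, the mapped/unmapped split, and pileup construction.

Long reads are mapped to the pseudo reference and split at the 90%
mapped-base threshold: reads with strictly more than 90% of their bases
aligned (match or substitution) join ``Lm``; the rest form ``Lu`` and are
later corrected against short reads mapped to each of them individually.

Three mapping modes are provided:

``seeded``
    k-mer anchoring on the target followed by banded edit-distance
    alignment (edlib) of the read against the anchored window.
``exhaustive``
    full semi-global dynamic programming (the oracle; desk-scale only).
``truth_anchored``
    for simulated reads: place each read at its recorded truth
    coordinates and re-align locally inside a padded window.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

import edlib
import numpy as np

from hetcorr import dp
from hetcorr.simulate import Read, ReadSet, revcomp, seq_to_codes

ALLELES = "ACGTN"
N_CODE = 4

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _parse_cigar(cigar: str) -> dp.Ops:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


@dataclass
class Alignment:
    """Best placement of one read on one target.

    ``ops`` describe the read *in target-forward orientation*: for a '-'
    strand alignment they apply to the reverse complement of the stored
    read sequence.  Coordinates are 0-based, half-open.
    """

    read_id: str
    target_id: str
    target_start: int
    ops: dp.Ops
    read_length: int
    strand: str = "+"
    score: float = 0.0

    @property
    def aligned_bases(self) -> int:
        return sum(n for op, n in self.ops if op in "=X")

    @property
    def pct_mapped(self) -> float:
        if self.read_length == 0:
            return 0.0
        return self.aligned_bases / self.read_length

    @property
    def target_end(self) -> int:
        return self.target_start + sum(n for op, n in self.ops if op in "=XD")


def _edlib_alignment(
    read: Read,
    oriented_seq: str,
    window_start: int,
    window: str,
    target_id: str,
    strand: str,
    max_edit_frac: float,
    refine: bool = False,
) -> Optional[Alignment]:
    if not oriented_seq or not window:
        return None
    res = edlib.align(oriented_seq, window, mode="HW", task="path")
    ed = res["editDistance"]
    if ed < 0 or ed > max_edit_frac * len(oriented_seq):
        return None
    if refine:
        # edlib located the window; exact score-maximising DP supplies the ops
        exact = dp.semiglobal(oriented_seq, window)
        start = exact.target_span[0]
        ops = exact.ops
        score = exact.score
    else:
        start = res["locations"][0][0]
        ops = _refine_ops(_parse_cigar(res["cigar"]))
        score = -float(ed)
    return Alignment(
        read_id=read.id,
        target_id=target_id,
        target_start=window_start + start,
        ops=ops,
        read_length=len(read.sequence),
        strand=strand,
        score=score,
    )


def _refine_ops(ops: dp.Ops) -> dp.Ops:
    """Merge adjacent ops of equal kind (edlib output is already =/X/I/D)."""
    out: dp.Ops = []
    for op, n in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _kmer_index(seq: str, k: int, max_hits: int = 64) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(0, len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return {kmer: pos for kmer, pos in index.items() if len(pos) <= max_hits}


def _seed_window(
    seq: str, index: dict[str, list[int]], k: int, target_len: int
) -> Optional[tuple[int, int]]:
    """Vote on an (approximate) target diagonal from shared k-mers."""
    stride = max(1, k // 2)
    diags: list[int] = []
    for q in range(0, len(seq) - k + 1, stride):
        for t in index.get(seq[q : q + k], ()):
            diags.append(t - q)
    if not diags:
        return None
    arr = np.asarray(diags)
    bin_w = max(32, int(0.2 * len(seq)))
    bins = arr // bin_w
    vals, counts = np.unique(bins, return_counts=True)
    best = vals[int(np.argmax(counts))]
    sel = arr[(bins == best) | (bins == best - 1) | (bins == best + 1)]
    pad = max(50, int(0.15 * len(seq)))
    w0 = max(0, int(sel.min()) - pad)
    w1 = min(target_len, int(sel.max()) + len(seq) + pad)
    return w0, w1


def map_reads(
    reads: Iterable[Read],
    target_id: str,
    target_seq: str,
    mode: str = "seeded",
    k: int = 15,
    max_edit_frac: float = 0.35,
    both_strands: bool = True,
) -> list[Alignment]:
    """Map reads to one target, keeping at most the best alignment per read."""
    if not target_seq:
        raise ValueError("empty target")
    alignments: list[Alignment] = []
    if mode == "seeded":
        index = _kmer_index(target_seq, k)
        for read in reads:
            best: Optional[Alignment] = None
            strands = ("+", "-") if both_strands else ("+",)
            for strand in strands:
                oriented = read.sequence if strand == "+" else revcomp(read.sequence)
                win = _seed_window(oriented, index, k, len(target_seq))
                if win is None:
                    continue
                aln = _edlib_alignment(
                    read, oriented, win[0], target_seq[win[0] : win[1]],
                    target_id, strand, max_edit_frac, refine=True,
                )
                if aln is not None and (best is None or aln.score > best.score):
                    best = aln
            if best is not None:
                alignments.append(best)
    elif mode == "exhaustive":
        for read in reads:
            best = None
            strands = ("+", "-") if both_strands else ("+",)
            for strand in strands:
                oriented = read.sequence if strand == "+" else revcomp(read.sequence)
                res = dp.semiglobal(oriented, target_seq)
                aln = Alignment(
                    read_id=read.id,
                    target_id=target_id,
                    target_start=res.target_span[0],
                    ops=res.ops,
                    read_length=len(read.sequence),
                    strand=strand,
                    score=res.score,
                )
                if best is None or aln.score > best.score:
                    best = aln
            alignments.append(best)
    elif mode == "truth_anchored":
        for read in reads:
            if read.truth_span is None:
                raise ValueError(f"read {read.id} has no truth_span")
            start, end, strand, _hap = read.truth_span
            pad = max(30, int(0.2 * (end - start)))
            w0 = max(0, start - pad)
            w1 = min(len(target_seq), end + pad)
            oriented = read.sequence if strand == "+" else revcomp(read.sequence)
            aln = _edlib_alignment(
                read, oriented, w0, target_seq[w0:w1], target_id, strand, max_edit_frac
            )
            if aln is not None:
                alignments.append(aln)
    else:
        raise ValueError(f"unknown mapping mode: {mode!r}")
    return alignments


def split_long_reads(
    L: ReadSet, alignments: Iterable[Alignment], threshold: float = 0.90
) -> tuple[ReadSet, ReadSet]:
    """Partition L at the mapped-base threshold (strictly greater -> Lm)."""
    pct = {a.read_id: a.pct_mapped for a in alignments}
    Lm, Lu = [], []
    for read in L:
        (Lm if pct.get(read.id, 0.0) > threshold else Lu).append(read)
    return ReadSet(Lm), ReadSet(Lu)


@dataclass
class PileupColumn:
    """Allele counts over {A,C,G,T,N} at one anchor site; N counts deletions."""

    site: int
    counts: dict[str, int]
    source: str = "long"

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class RankedCounts:
    """Alleles sorted by count (descending, ties in A<C<G<T<N order)."""

    alleles: list[tuple[str, int]]
    depth: int

    @property
    def d(self) -> int:
        """Number of distinct observed alleles (the bases-distribution count)."""
        return len(self.alleles)

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.alleles]

    def suffix_totals(self) -> list[int]:
        """D_q = sum of counts at rank q and below, q = 1..d."""
        out, total = [], 0
        for c in reversed(self.counts):
            total += c
            out.append(total)
        return out[::-1]


def rank_alleles(col: PileupColumn) -> RankedCounts:
    items = [(a, int(col.counts.get(a, 0))) for a in ALLELES]
    items = [it for it in items if it[1] > 0]
    items.sort(key=lambda it: (-it[1], ALLELES.index(it[0])))
    return RankedCounts(items, depth=sum(c for _, c in items))


class Pileup:
    """Dense per-site allele counts against one target.

    ``counts`` is a (5, target_length) int32 matrix in A,C,G,T,N row order;
    behaves as a mapping from covered site to :class:`PileupColumn`.
    """

    def __init__(self, counts: np.ndarray, source: str = "long", n_insertions: int = 0):
        self.counts = counts
        self.source = source
        self.n_insertions = n_insertions

    @property
    def target_length(self) -> int:
        return self.counts.shape[1]

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def covered_sites(self) -> np.ndarray:
        return np.nonzero(self.depth() > 0)[0]

    def column(self, site: int) -> PileupColumn:
        col = self.counts[:, site]
        return PileupColumn(
            site=site,
            counts={a: int(col[i]) for i, a in enumerate(ALLELES) if col[i] > 0},
            source=self.source,
        )

    def __getitem__(self, site: int) -> PileupColumn:
        return self.column(site)

    def __contains__(self, site: int) -> bool:
        return 0 <= site < self.target_length and self.depth()[site] > 0

    def items(self):
        for site in self.covered_sites():
            yield int(site), self.column(int(site))

    def merged_with(self, other: "Pileup") -> "Pileup":
        return Pileup(self.counts + other.counts, source="merged")


def build_pileup(
    alignments: Iterable[Alignment],
    reads_by_id: dict[str, Read],
    target_length: int,
    spacer_mask: Optional[np.ndarray] = None,
    source: str = "long",
) -> Pileup:
    """Tally aligned read bases per anchor site.

    Match/substitution columns contribute the read base; a deletion op
    contributes one N per spanned site; insertions relative to the target
    have no anchor and are only counted in ``n_insertions``.
    """
    flat_chunks: list[np.ndarray] = []
    n_ins = 0
    for aln in alignments:
        read = reads_by_id[aln.read_id]
        seq = read.sequence if aln.strand == "+" else revcomp(read.sequence)
        qcodes = seq_to_codes(seq)
        qpos, tpos = 0, aln.target_start
        for op, n in aln.ops:
            if op in "=X" or op == "M":
                sites = np.arange(tpos, tpos + n, dtype=np.int64)
                flat_chunks.append(sites * 5 + qcodes[qpos : qpos + n])
                qpos += n
                tpos += n
            elif op == "I":
                qpos += n
                n_ins += n
            elif op == "D":
                sites = np.arange(tpos, tpos + n, dtype=np.int64)
                flat_chunks.append(sites * 5 + N_CODE)
                tpos += n
    if flat_chunks:
        flat = np.concatenate(flat_chunks)
        counts = np.bincount(flat, minlength=5 * target_length).reshape(
            target_length, 5
        ).T.astype(np.int32)
    else:
        counts = np.zeros((5, target_length), dtype=np.int32)
    if spacer_mask is not None:
        counts[:, spacer_mask] = 0
    return Pileup(counts, source=source, n_insertions=n_ins)


def map_short_to_lu(
    S: ReadSet,
    Lu: ReadSet,
    k: int = 13,
    max_edit_frac: float = 0.3,
) -> dict[str, tuple[list[Alignment], Pileup]]:
    """Map short reads to each unmapped long read separately.

    Returns, per Lu read, the accepted short-read alignments onto it and
    the resulting pileup over its own coordinates.  A Lu read with no
    mapped short reads gets an empty pileup (and passes through correction
    untouched).
    """
    result: dict[str, tuple[list[Alignment], Pileup]] = {}
    if len(Lu) == 0:
        return result
    # one joint k-mer index over all Lu reads
    joint: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for li, lu in enumerate(Lu):
        seq = lu.sequence
        for i in range(0, len(seq) - k + 1):
            joint[seq[i : i + k]].append((li, i))
    per_lu: dict[int, list[Alignment]] = defaultdict(list)
    s_by_id = S.by_id()
    for read in S:
        candidates: set[int] = set()
        for strand in ("+", "-"):
            seq = read.sequence if strand == "+" else revcomp(read.sequence)
            for i in range(0, len(seq) - k + 1, max(1, k // 2)):
                for li, _pos in joint.get(seq[i : i + k], ()):
                    candidates.add(li)
        for li in candidates:
            lu = Lu[li]
            best: Optional[Alignment] = None
            for strand in ("+", "-"):
                oriented = read.sequence if strand == "+" else revcomp(read.sequence)
                aln = _edlib_alignment(
                    read, oriented, 0, lu.sequence, lu.id, strand, max_edit_frac,
                    refine=True,
                )
                if aln is not None and (best is None or aln.score > best.score):
                    best = aln
            if best is not None:
                per_lu[li].append(best)
    for li, lu in enumerate(Lu):
        alns = per_lu.get(li, [])
        pileup = build_pileup(alns, s_by_id, len(lu.sequence), source="short")
        result[lu.id] = (alns, pileup)
    return result


# ---------------------------------------------------------------------------
# SAM interchange (pysam)

_OP_TO_SAM = {"=": 7, "X": 8, "I": 1, "D": 2}
_SAM_TO_OP = {7: "=", 8: "X", 1: "I", 2: "D", 0: "M"}


def write_sam(
    path: str,
    alignments: Iterable[Alignment],
    reads_by_id: dict[str, Read],
    target_id: str,
    target_length: int,
) -> None:
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": target_id, "LN": target_length}]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for aln in alignments:
            read = reads_by_id[aln.read_id]
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seq = read.sequence if aln.strand == "+" else revcomp(read.sequence)
            seg.query_sequence = seq
            seg.flag = 16 if aln.strand == "-" else 0
            seg.reference_id = 0
            seg.reference_start = aln.target_start
            seg.mapping_quality = 60
            seg.cigartuples = [(_OP_TO_SAM[op], n) for op, n in aln.ops]
            out.write(seg)


def read_sam(path: str, target_seq: str) -> tuple[list[Alignment], ReadSet]:
    """Load alignments from SAM; M ops are split into =/X against the target."""
    import pysam

    alignments: list[Alignment] = []
    reads: list[Read] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            strand = "-" if seg.is_reverse else "+"
            oriented = seg.query_sequence.upper()
            stored = revcomp(oriented) if strand == "-" else oriented
            reads.append(Read(id=seg.query_name, sequence=stored))
            ops: dp.Ops = []
            qpos, tpos = 0, seg.reference_start
            for code, n in seg.cigartuples:
                op = _SAM_TO_OP.get(code)
                if op is None:  # soft/hard clips and friends are ignored
                    if code == 4:  # soft clip consumes query
                        qpos += n
                    continue
                if op == "M":
                    for j in range(n):
                        same = (
                            tpos + j < len(target_seq)
                            and oriented[qpos + j] == target_seq[tpos + j]
                        )
                        sub_op = "=" if same else "X"
                        if ops and ops[-1][0] == sub_op:
                            ops[-1] = (sub_op, ops[-1][1] + 1)
                        else:
                            ops.append((sub_op, 1))
                    qpos += n
                    tpos += n
                else:
                    ops.append((op, n))
                    if op == "I":
                        qpos += n
                    elif op == "D":
                        tpos += n
            alignments.append(
                Alignment(
                    read_id=seg.query_name,
                    target_id=seg.reference_name or "ref",
                    target_start=seg.reference_start,
                    ops=_refine_ops(ops),
                    read_length=len(oriented),
                    strand=strand,
                )
            )
    return alignments, ReadSet(reads)
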