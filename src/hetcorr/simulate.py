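"""Diploid genome and read simulation.

Emulates the study design used throughout the package: a reference region
with a known number of planted heterozygous SNPs, long reads at
third-generation error rates (default 15%, substitutions/insertions/
deletions in equal parts) and short reads at next-generation error rates
(default 5%, substitution only).

``coverage`` is the sequencing depth **per haplotype**: each of the two
haplotypes is sequenced at the requested depth, so the diploid pile at a
site has about twice that many reads.  This mirrors running a read
simulator once per haplotype, the natural way to obtain heterozygous
variants from a haploid simulator.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

BASES = "ACGT"
_BASE2CODE = {b: i for i, b in enumerate("ACGTN")}
_CODE2BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes 0..4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.empty(raw.size, dtype=np.uint8)
    for base, code in _BASE2CODE.items():
        codes[raw == ord(base)] = code
    return codes


def codes_to_seq(codes: np.ndarray) -> str:
    return _CODE2BASE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class HetSiteTruth:
    """A planted heterozygous SNP: ``allele_a`` on hap1, ``allele_b`` on hap2."""

    position: int  # 0-based index on the reference backbone
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("heterozygous site needs two distinct alleles")


@dataclass
class Haplome:
    """A diploid genome: two haplotypes differing exactly at ``het_sites``.

    ``ref`` (the hap1 backbone) plays the role of the truth reference that
    corrected reads are evaluated against.
    """

    hap1: str
    hap2: str
    het_sites: list[HetSiteTruth]

    @property
    def ref(self) -> str:
        return self.hap1

    def __post_init__(self) -> None:
        if len(self.hap1) != len(self.hap2):
            raise ValueError("haplotypes must have equal length")

    def haplotype(self, which: int) -> str:
        return self.hap1 if which == 1 else self.hap2


@dataclass(frozen=True)
class ErrorModelParams:
    """Per-base error rates; all events independent per emitted base."""

    sub_rate: float = 0.05
    ins_rate: float = 0.05
    del_rate: float = 0.05

    @property
    def total_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("error rates must lie in [0, 1)")
        if self.total_rate >= 0.6:
            raise ValueError(
                "total error rate must stay below 0.6 so that a true allele "
                "remains more likely than an error allele"
            )

    @classmethod
    def long_read(cls, total: float = 0.15) -> "ErrorModelParams":
        """Equal substitution/insertion/deletion split of a total rate."""
        return cls(total / 3.0, total / 3.0, total / 3.0)

    @classmethod
    def short_read(cls, total: float = 0.05) -> "ErrorModelParams":
        """Substitution-only model for short reads."""
        return cls(total, 0.0, 0.0)


# truth_span: (ref_start, ref_end, strand, haplotype)
TruthSpan = Tuple[int, int, str, int]


@dataclass
class Read:
    id: str
    sequence: str
    quality: Optional[str] = None
    truth_span: Optional[TruthSpan] = None


@dataclass
class ReadSet:
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def __getitem__(self, i: int) -> Read:
        return self.reads[i]

    def by_id(self) -> dict[str, Read]:
        return {r.id: r for r in self.reads}

    def total_bases(self) -> int:
        return sum(len(r.sequence) for r in self.reads)


def make_diploid_genome(
    length: int, n_het: int, seed: int, margin: int = 0
) -> Haplome:
    """Uniform-random diploid genome with ``n_het`` planted heterozygous SNPs.

    Positions are sampled uniformly without replacement from
    ``[margin, length - margin)``; the alternate allele is uniform over the
    three non-reference bases.  A nonzero margin keeps sites inside the
    fully covered interior of the simulated region, emulating variants
    planted well inside a much larger reference, away from the coverage
    ramp at the region's ends.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if margin < 0 or length - 2 * margin < n_het:
        raise ValueError("margin leaves too little interior for n_het sites")
    if not 0 <= n_het <= length:
        raise ValueError("n_het must lie in [0, length]")
    rng = np.random.default_rng(seed)
    ref_codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    positions = np.sort(
        margin + rng.choice(length - 2 * margin, size=n_het, replace=False)
    )
    # alternate allele: shift by 1..3 mod 4 guarantees a different base
    shifts = rng.integers(1, 4, size=n_het, dtype=np.uint8)
    hap2_codes = ref_codes.copy()
    hap2_codes[positions] = (ref_codes[positions] + shifts) % 4
    hap1 = codes_to_seq(ref_codes)
    hap2 = codes_to_seq(hap2_codes)
    sites = [
        HetSiteTruth(int(p), hap1[p], hap2[p]) for p in positions
    ]
    return Haplome(hap1, hap2, sites)


def _mutate(codes: np.ndarray, err: ErrorModelParams, rng: np.random.Generator) -> np.ndarray:
    """Apply independent per-base substitution/deletion/insertion errors."""
    n = codes.size
    if err.total_rate == 0.0:
        return codes
    keep = rng.random(n) >= err.del_rate
    sub = rng.random(n) < err.sub_rate
    mutated = codes.copy()
    if sub.any():
        shifts = rng.integers(1, 4, size=int(sub.sum()), dtype=np.uint8)
        mutated[sub] = (mutated[sub] + shifts) % 4
    if err.ins_rate > 0.0:
        ins = rng.random(n) < err.ins_rate
        ins_base = rng.integers(0, 4, size=n, dtype=np.uint8)
        k = keep.astype(np.int64)
        counts = k + ins.astype(np.int64)
        out = np.empty(int(counts.sum()), dtype=np.uint8)
        starts = np.cumsum(counts) - counts
        out[starts[keep]] = mutated[keep]
        out[starts[ins] + k[ins]] = ins_base[ins]
        return out
    return mutated[keep]


def simulate_reads(
    h: Haplome,
    coverage: float,
    mean_len: int,
    min_len: int,
    err: ErrorModelParams,
    seed: int,
    rc_fraction: float = 0.0,
    id_prefix: str = "r",
) -> ReadSet:
    """Simulate reads from both haplotypes at ``coverage`` depth per haplotype.

    Each read picks a haplotype uniformly, a start position uniform over the
    genome, and a length from a lognormal (sigma=0.3) around ``mean_len``
    truncated to [min_len, genome length].  Reads are emitted until the total
    base count reaches 2 x coverage x genome length.  With ``rc_fraction`` > 0
    that fraction of reads is stored reverse-complemented (strand '-').
    """
    glen = len(h.ref)
    if glen == 0:
        raise ValueError("empty genome")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 1 <= min_len <= mean_len:
        raise ValueError("need mean_len >= min_len >= 1")
    rng = np.random.default_rng(seed)
    hap_codes = {1: seq_to_codes(h.hap1), 2: seq_to_codes(h.hap2)}
    target = 2.0 * coverage * glen
    reads: list[Read] = []
    emitted = 0
    idx = 0
    sigma = 0.3
    mu = np.log(mean_len) - sigma * sigma / 2.0  # lognormal mean == mean_len
    while emitted < target:
        hap = int(rng.integers(1, 3))
        length = int(round(rng.lognormal(mu, sigma)))
        length = max(min_len, min(length, glen))
        start = int(rng.integers(0, glen - length + 1))
        src = hap_codes[hap][start : start + length]
        out = _mutate(src, err, rng)
        seq = codes_to_seq(out)
        strand = "+"
        if rc_fraction > 0.0 and rng.random() < rc_fraction:
            seq = revcomp(seq)
            strand = "-"
        reads.append(
            Read(
                id=f"{id_prefix}{idx}",
                sequence=seq,
                truth_span=(start, start + length, strand, hap),
            )
        )
        emitted += len(seq)
        idx += 1
    return ReadSet(reads)


def _write_fasta(path: str, records: list[tuple[str, str]], header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _write_fastq(path: str, rs: ReadSet) -> None:
    with open(path, "w") as fh:
        for r in rs:
            q = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{q}\n")


def write_dataset(h: Haplome, L: ReadSet, S: ReadSet, outdir: str) -> dict[str, str]:
    """Write the simulated dataset as plain-text files; returns path map.

    All coordinates in the TSVs are 0-based, half-open.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "ref": os.path.join(outdir, "ref.fasta"),
        "hap1": os.path.join(outdir, "hap1.fasta"),
        "hap2": os.path.join(outdir, "hap2.fasta"),
        "long": os.path.join(outdir, "long.fastq"),
        "short": os.path.join(outdir, "short.fastq"),
        "het_truth": os.path.join(outdir, "het_truth.tsv"),
        "truth_spans": os.path.join(outdir, "truth_spans.tsv"),
    }
    _write_fasta(paths["ref"], [("ref", h.ref)])
    _write_fasta(paths["hap1"], [("hap1", h.hap1)])
    _write_fasta(paths["hap2"], [("hap2", h.hap2)])
    _write_fastq(paths["long"], L)
    _write_fastq(paths["short"], S)
    with open(paths["het_truth"], "w") as fh:
        fh.write("# position (0-based)\tallele_a\tallele_b\n")
        for s in h.het_sites:
            fh.write(f"{s.position}\t{s.allele_a}\t{s.allele_b}\n")
    with open(paths["truth_spans"], "w") as fh:
        fh.write("# read_id\tref_start\tref_end\tstrand\thaplotype (0-based, half-open)\n")
        for rs, tag in ((L, "L"), (S, "S")):
            for r in rs:
                if r.truth_span is not None:
                    a, b, strand, hap = r.truth_span
                    fh.write(f"{r.id}\t{a}\t{b}\t{strand}\t{hap}\n")
    return paths


def read_fastx(path: str) -> ReadSet:
    """Read FASTA or FASTQ (detected from the first byte) into a ReadSet."""
    from Bio import SeqIO

    fmt = "fastq"
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        fmt = "fasta"
    reads = []
    for rec in SeqIO.parse(path, fmt):
        qual = None
        if fmt == "fastq":
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(id=rec.id, sequence=str(rec.seq).upper(), quality=qual))
    return ReadSet(reads)


def read_het_truth(path: str) -> list[HetSiteTruth]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            pos, a, b = line.split()
            sites.append(HetSiteTruth(int(pos), a, b))
    return sites


def read_truth_spans(path: str) -> dict[str, TruthSpan]:
    spans: dict[str, TruthSpan] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rid, a, b, strand, hap = line.split()
            spans[rid] = (int(a), int(b), strand, int(hap))
    return spans
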