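"""Heterozygosity-retention evaluation of corrected reads.

Corrected long reads are mapped back to the truth reference and each
planted heterozygous site is inspected: the site *retains* heterozygosity
when the balance between its two most frequent alleles falls inside a
heterozygous interval (the conventional interval is [0.2, 0.8]).  Accuracy
is the retained fraction, TP/(TP+FN), i.e. one minus the error rate.
Allele identity is audited separately by the *difference value*: the
proportion of the two true alleles minus the proportion of the other two
bases, graded negative / draw / good (0 < v <= 0.3) / excellent (v > 0.3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from hetcorr.align import ALLELES, Pileup, PileupColumn, rank_alleles
from hetcorr.simulate import HetSiteTruth

PRESET_INTERVALS: tuple[tuple[float, float], ...] = (
    (0.20, 0.80),
    (0.25, 0.75),
    (0.30, 0.70),
    (0.35, 0.65),
)


@dataclass(frozen=True)
class EvalParams:
    """A heterozygous interval [lo, hi]; inclusive on both ends."""

    lo: float = 0.20
    hi: float = 0.80

    def __post_init__(self) -> None:
        if not (0.0 < self.lo <= 0.5 <= self.hi < 1.0):
            raise ValueError("need 0 < lo <= 0.5 <= hi < 1")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lo, self.hi)


def retention(col: PileupColumn, params: EvalParams) -> tuple[bool, float]:
    """Top-two allele balance and whether it lies inside the interval.

    The balance is count(top1)/(count(top1)+count(top2)); a site with fewer
    than two covering reads cannot exhibit heterozygosity and is lost by
    convention (balance reported as 1.0, or 0.0 when uncovered).
    """
    rc = rank_alleles(col)
    if rc.depth < 2:
        return False, 0.0 if rc.depth == 0 else 1.0
    if rc.d < 2:
        return False, 1.0
    c1, c2 = rc.counts[0], rc.counts[1]
    balance = c1 / (c1 + c2)
    return bool(params.lo <= balance <= params.hi), float(balance)


def difference_value(col: PileupColumn, site: HetSiteTruth) -> tuple[float, str]:
    """Proportion of the true allele pair minus proportion of the other bases.

    Proportions run over A/C/G/T counts only (deletions excluded).  Grades:
    negative (< 0), draw (== 0), good ((0, 0.3]), excellent ((0.3, 1]).
    """
    acgt = {a: col.counts.get(a, 0) for a in "ACGT"}
    total = sum(acgt.values())
    if total == 0:
        raise ValueError("difference value undefined at zero A/C/G/T depth")
    true_pair = {site.allele_a, site.allele_b}
    p_true = sum(c for a, c in acgt.items() if a in true_pair) / total
    p_other = 1.0 - p_true
    value = p_true - p_other
    if value < 0:
        quality = "negative"
    elif value == 0:
        quality = "draw"
    elif value <= 0.3:
        quality = "good"
    else:
        quality = "excellent"
    return float(value), quality


@dataclass
class SiteEvaluation:
    site: HetSiteTruth
    depth: int
    balance: float
    retained: dict[tuple[float, float], bool]
    difference: Optional[float]
    quality: str  # negative/draw/good/excellent, or not_retained/uncovered


def evaluate_sites(
    pileup: Pileup,
    het_sites: Iterable[HetSiteTruth],
    intervals: Iterable[tuple[float, float]] = PRESET_INTERVALS,
    reference_interval: tuple[float, float] = (0.20, 0.80),
) -> list[SiteEvaluation]:
    """Evaluate every planted heterozygous site against the post-correction pileup.

    The quality grade is computed for sites retained under the
    ``reference_interval``; sites lost there are graded ``not_retained``.
    """
    intervals = [tuple(iv) for iv in intervals]
    evals = []
    for site in het_sites:
        col = pileup.column(site.position)
        retained = {}
        balance = 0.0
        for iv in intervals:
            ok, balance = retention(col, EvalParams(*iv))
            retained[iv] = ok
        depth = col.depth
        acgt_depth = sum(col.counts.get(a, 0) for a in "ACGT")
        diff: Optional[float] = None
        if acgt_depth > 0:
            diff, grade = difference_value(col, site)
        else:
            grade = "uncovered"
        if not retained.get(reference_interval, False):
            grade = "not_retained"
        evals.append(
            SiteEvaluation(
                site=site,
                depth=depth,
                balance=balance,
                retained=retained,
                difference=diff,
                quality=grade,
            )
        )
    return evals


def accuracy(evals: list[SiteEvaluation], interval: tuple[float, float]) -> float:
    """Fraction of planted heterozygous sites retained: TP/(TP+FN)."""
    if not evals:
        raise ValueError("no sites to evaluate")
    tp = sum(1 for ev in evals if ev.retained.get(tuple(interval), False))
    return tp / len(evals)


def report(
    evals: list[SiteEvaluation],
    intervals: Iterable[tuple[float, float]] = PRESET_INTERVALS,
) -> tuple[pd.DataFrame, dict]:
    """Per-interval accuracy table plus a quality histogram (TSV/JSON ready)."""
    intervals = [tuple(iv) for iv in intervals]
    rows = []
    for iv in intervals:
        acc = accuracy(evals, iv)
        rows.append({"interval_lo": iv[0], "interval_hi": iv[1], "accuracy": acc})
    table = pd.DataFrame(rows)
    buckets = ["negative", "draw", "good", "excellent"]
    hist = {b: sum(1 for ev in evals if ev.quality == b) for b in buckets}
    hist["not_retained"] = sum(1 for ev in evals if ev.quality == "not_retained")
    summary = {
        "n_sites": len(evals),
        "accuracy": {
            f"[{iv[0]:.2f},{iv[1]:.2f}]": row["accuracy"]
            for iv, row in zip(intervals, rows)
        },
        "quality_histogram": hist,
    }
    return table, summary


def write_report(
    evals: list[SiteEvaluation],
    tsv_path: str,
    json_path: str,
    intervals: Iterable[tuple[float, float]] = PRESET_INTERVALS,
    header: str = "",
) -> dict:
    intervals = [tuple(iv) for iv in intervals]
    with open(tsv_path, "w") as fh:
        if header:
            fh.write(header)
        cols = "\t".join(f"retained[{lo:.2f},{hi:.2f}]" for lo, hi in intervals)
        fh.write(f"# site\tdepth\tbalance\t{cols}\tdifference_value\tquality\n")
        for ev in evals:
            flags = "\t".join(str(int(ev.retained[iv])) for iv in intervals)
            diff = "" if ev.difference is None else f"{ev.difference:.4f}"
            fh.write(
                f"{ev.site.position}\t{ev.depth}\t{ev.balance:.4f}\t{flags}\t"
                f"{diff}\t{ev.quality}\n"
            )
    _, summary = report(evals, intervals)
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
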