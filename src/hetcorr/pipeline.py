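"""End-to-end orchestration of the correction pipeline.

The ten-step flow: obtain a pseudo reference (assembled from the long
reads, or substituted), map the long reads and split them into Lm/Lu at
the 90% mapped-base threshold, map the short reads to the reference and
to each Lu read, build pileups, judge zygosity per anchor from each read
source, fuse the judgments, correct Lm against the anchors and each Lu
read from its own short-read pileup, merge into L', and — when truth is
available — evaluate heterozygosity retention.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from hetcorr import align as al
from hetcorr import assemble as asm
from hetcorr import correct as co
from hetcorr import evaluate as ev
from hetcorr import simulate as sim
from hetcorr import zygosity as zy

log = logging.getLogger("hetcorr")


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    Coverages are per haplotype; error rates are total per-base rates
    (long reads split equally into substitution/insertion/deletion, short
    reads substitution-only).  ``e_long``/``e_short`` are the classifier's
    assumed error rates and default to the simulated ones.
    """

    # simulation
    genome_length: int = 100_000
    n_het: int = 500
    long_cov: float = 5.0
    short_cov: float = 10.0
    long_err_total: float = 0.15
    short_err_total: float = 0.05
    long_mean_len: int = 2000
    long_min_len: int = 200
    short_mean_len: int = 100
    short_min_len: int = 50
    rc_fraction: float = 0.0
    het_margin: Optional[int] = None  # default: one mean long-read length
    # alignment
    mapping_mode: str = "truth_anchored"  # seeded | exhaustive | truth_anchored
    map_threshold: float = 0.90
    use_truth_ref: bool = True  # anchor on the simulator's reference
    # classification
    e_long: Optional[float] = None
    e_short: Optional[float] = None
    prior_kind: str = "point"
    prior_p_homo: float = 0.5
    prior_a: float = 300.0
    prior_b: float = 300.0
    prior_beta_mode: str = "mean"
    # correction
    pool: str = "merged"  # merged | short
    # evaluation
    intervals: tuple = ev.PRESET_INTERVALS
    # plumbing
    seed: int = 0
    outdir: Optional[str] = None
    # optional external inputs (file seams); simulation is skipped when set
    long_path: Optional[str] = None
    short_path: Optional[str] = None
    ref_path: Optional[str] = None
    het_truth_path: Optional[str] = None
    truth_spans_path: Optional[str] = None

    def prior(self) -> zy.PriorSpec:
        return zy.PriorSpec(
            kind=self.prior_kind,
            p_homo=self.prior_p_homo,
            a=self.prior_a,
            b=self.prior_b,
            beta_mode=self.prior_beta_mode,
            seed=self.seed,
        )

    def effective_e_long(self) -> float:
        return self.e_long if self.e_long is not None else self.long_err_total

    def effective_e_short(self) -> float:
        return self.e_short if self.e_short is not None else self.short_err_total

    def to_dict(self) -> dict:
        d = asdict(self)
        d["intervals"] = [list(iv) for iv in self.intervals]
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class StageData:
    """Everything up to the pileups; classification-independent."""

    haplome: Optional[sim.Haplome]
    L: sim.ReadSet
    S: sim.ReadSet
    ref_seq: str
    spacer_mask: Optional[np.ndarray]
    aln_L: list[al.Alignment]
    Lm: sim.ReadSet
    Lu: sim.ReadSet
    aln_S: list[al.Alignment]
    pileup_long: al.Pileup
    pileup_short: al.Pileup
    lu_maps: dict
    het_sites: list[sim.HetSiteTruth]


@dataclass
class PipelineResult:
    config: RunConfig
    corrected: list[co.CorrectedRead]
    counts: dict
    evals: Optional[list[ev.SiteEvaluation]] = None
    accuracy_table: Optional[pd.DataFrame] = None
    summary: Optional[dict] = None

    def accuracy(self, interval=(0.20, 0.80)) -> float:
        if self.evals is None:
            raise ValueError("no truth available; accuracy undefined")
        return ev.accuracy(self.evals, interval)

    @property
    def n_edits(self) -> int:
        return sum(r.n_edits for r in self.corrected)


def prepare_stages(config: RunConfig) -> StageData:
    """Simulate or load inputs, obtain Ref, map reads, build pileups."""
    het_sites: list[sim.HetSiteTruth] = []
    haplome = None
    if config.long_path is None:
        margin = config.het_margin
        if margin is None:
            margin = config.long_mean_len
        margin = min(margin, max(0, (config.genome_length - config.n_het) // 2))
        haplome = sim.make_diploid_genome(
            config.genome_length, config.n_het, seed=config.seed, margin=margin
        )
        het_sites = haplome.het_sites
        L = sim.simulate_reads(
            haplome,
            config.long_cov,
            config.long_mean_len,
            config.long_min_len,
            sim.ErrorModelParams.long_read(config.long_err_total),
            seed=config.seed + 1,
            rc_fraction=config.rc_fraction,
            id_prefix="L",
        )
        S = sim.simulate_reads(
            haplome,
            config.short_cov,
            config.short_mean_len,
            config.short_min_len,
            sim.ErrorModelParams.short_read(config.short_err_total),
            seed=config.seed + 2,
            id_prefix="S",
        )
    else:
        L = sim.read_fastx(config.long_path)
        S = sim.read_fastx(config.short_path) if config.short_path else sim.ReadSet([])
        if config.het_truth_path:
            het_sites = sim.read_het_truth(config.het_truth_path)
        if config.truth_spans_path:
            spans = sim.read_truth_spans(config.truth_spans_path)
            for rs in (L, S):
                for r in rs:
                    r.truth_span = spans.get(r.id)
    spacer_mask = None
    if config.ref_path:
        ref_seq = sim.read_fastx(config.ref_path)[0].sequence
    elif config.use_truth_ref and haplome is not None:
        ref_seq = haplome.ref
    else:
        pseudo = asm.assemble_pseudo_reference(L)
        ref_seq = pseudo.sequence
        spacer_mask = pseudo.spacer_mask
    mode = config.mapping_mode
    aln_L = al.map_reads(L, "ref", ref_seq, mode=mode)
    Lm, Lu = al.split_long_reads(L, aln_L, config.map_threshold)
    log.info("|L|=%d -> |Lm|=%d, |Lu|=%d", len(L), len(Lm), len(Lu))
    lm_ids = {r.id for r in Lm}
    aln_Lm = [a for a in aln_L if a.read_id in lm_ids]
    aln_S = al.map_reads(S, "ref", ref_seq, mode=mode)
    pileup_long = al.build_pileup(
        aln_Lm, L.by_id(), len(ref_seq), spacer_mask, source="long"
    )
    pileup_short = al.build_pileup(
        aln_S, S.by_id(), len(ref_seq), spacer_mask, source="short"
    )
    lu_maps = al.map_short_to_lu(S, Lu) if len(Lu) else {}
    return StageData(
        haplome=haplome,
        L=L,
        S=S,
        ref_seq=ref_seq,
        spacer_mask=spacer_mask,
        aln_L=aln_Lm,
        Lm=Lm,
        Lu=Lu,
        aln_S=aln_S,
        pileup_long=pileup_long,
        pileup_short=pileup_short,
        lu_maps=lu_maps,
        het_sites=het_sites,
    )


def classify_and_correct(stage: StageData, config: RunConfig) -> tuple[list[co.CorrectedRead], dict]:
    """Steps 4-10: zygosity per source, fusion, correction, merge to L'."""
    prior = config.prior()
    dec_long, lpH_long, lpX_long = zy.classify_columns(
        stage.pileup_long.counts, config.effective_e_long(), prior
    )
    dec_short, lpH_short, lpX_short = zy.classify_columns(
        stage.pileup_short.counts, config.effective_e_short(), prior
    )
    fused = zy.combine_decisions(dec_long, dec_short)
    if config.pool == "merged":
        pool_counts = stage.pileup_long.counts + stage.pileup_short.counts
    elif config.pool == "short":
        pool_counts = stage.pileup_short.counts
    else:
        raise ValueError(f"unknown pool mode {config.pool!r}")
    top1, top2 = co.ranked_top_two(pool_counts)
    rng = np.random.default_rng(config.seed + 3)
    Lm_prime = co.correct_Lm(stage.Lm, stage.aln_L, fused, top1, top2, rng)
    Lu_prime = co.correct_Lu(
        stage.Lu, stage.lu_maps, config.effective_e_short(), prior, rng
    )
    corrected = Lm_prime + Lu_prime
    counts = {
        "n_L": len(stage.L),
        "n_Lm": len(stage.Lm),
        "n_Lu": len(stage.Lu),
        "n_S": len(stage.S),
        "n_sites_called_long": int((dec_long != zy.NO_CALL).sum()),
        "n_sites_called_short": int((dec_short != zy.NO_CALL).sum()),
        "n_sites_het_fused": int((fused == zy.HET_CODE).sum()),
        "n_edits": sum(r.n_edits for r in corrected),
    }
    log.info(
        "decided %d long / %d short sites; %d fused heterozygous; %d edits",
        counts["n_sites_called_long"],
        counts["n_sites_called_short"],
        counts["n_sites_het_fused"],
        counts["n_edits"],
    )
    return corrected, counts


def evaluate_corrected(
    stage: StageData, config: RunConfig, corrected: list[co.CorrectedRead]
) -> Optional[list[ev.SiteEvaluation]]:
    """Map L' back to the truth reference and score retention per het site."""
    if not stage.het_sites:
        return None
    if stage.haplome is not None:
        truth_ref = stage.haplome.ref
    elif config.ref_path:
        truth_ref = stage.ref_seq
    else:
        return None
    spans = {r.id: r.truth_span for r in stage.L}
    reads = []
    for cr in corrected:
        span = spans.get(cr.id)
        reads.append(sim.Read(id=cr.id, sequence=cr.sequence, truth_span=span))
    mode = "truth_anchored" if all(r.truth_span for r in reads) else "seeded"
    alns = al.map_reads(reads, "truth", truth_ref, mode=mode)
    pileup = al.build_pileup(
        alns, {r.id: r for r in reads}, len(truth_ref), source="long"
    )
    return ev.evaluate_sites(pileup, stage.het_sites, config.intervals)


def _write_outputs(
    config: RunConfig,
    stage: StageData,
    corrected: list[co.CorrectedRead],
    evals,
    summary,
) -> None:
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    tag = f"# config_hash={config.config_hash()}\n"
    with open(os.path.join(outdir, "corrected.fasta"), "w") as fh:
        fh.write(f";{tag[1:]}")
        for r in corrected:
            fh.write(f">{r.id}\n{r.sequence}\n")
    with open(os.path.join(outdir, "edits.tsv"), "w") as fh:
        fh.write(tag)
        fh.write("# read_id\tread_pos\told\tnew ('-' = absent)\n")
        for r in corrected:
            for pos, old, new in r.edits:
                fh.write(f"{r.id}\t{pos}\t{old}\t{new}\n")
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    if evals is not None:
        ev.write_report(
            evals,
            os.path.join(outdir, "evaluation.tsv"),
            os.path.join(outdir, "summary.json"),
            config.intervals,
            header=tag,
        )


def run_pipeline(config: RunConfig, stage: Optional[StageData] = None) -> PipelineResult:
    """Execute the full pipeline; pass a prepared ``stage`` to reuse alignments.

    Reusing a stage re-runs only classification, correction and
    evaluation, which is how prior- or error-rate sweeps over identical
    read data are performed.
    """
    if stage is None:
        stage = prepare_stages(config)
    corrected, counts = classify_and_correct(stage, config)
    evals = evaluate_corrected(stage, config, corrected)
    table = summary = None
    if evals is not None:
        table, summary = ev.report(evals, config.intervals)
    if config.outdir:
        _write_outputs(config, stage, corrected, evals, summary)
    return PipelineResult(
        config=config,
        corrected=corrected,
        counts=counts,
        evals=evals,
        accuracy_table=table,
        summary=summary,
    )
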