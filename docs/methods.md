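# Methods

`hetcorr` corrects long diploid reads with short-read evidence while
preserving heterozygous sites.  This note documents the probabilistic
model, the simulator that defines the package's study conditions, the
numerical conventions, and the design choices made where the problem was
genuinely open — together with what the test suite does and does not
demonstrate.

## The zygosity model

At an anchor site the pile of aligned read bases over the alphabet
{A, C, G, T, N} (N = deletion spanning the site) is summarised by ranked
counts |X₁| ≥ … ≥ |X₅| and the number of distinct alleles d.  Two
hypotheses are compared:

* **homozygous** — rank 1 is the true allele, everything else is error:
  p = (1−e, e/4, e/4, e/4, e/4);
* **heterozygous** — ranks 1 and 2 are the two alleles at expected 1:1:
  p = ((1−e)/2, (1−e)/2, e/3, e/3, e/3),

where e is the per-base error rate of the read class (defaults: 0.15 for
long reads, 0.05 for short reads; both configurable).  The likelihood is
evaluated as a chain of conditional binomials, rank q contributing
Bin(|X_q|; D_q, π_q) with D_q the suffix total and π_q = p_q/Σ_{j≥q}p_j;
zero-count ranks drop out.  The chain's product is identical to the
multinomial pmf of the count vector under p — the test suite proves this
exhaustively for every ranked vector up to depth 12.  Posteriors are the
likelihoods times the prior P(c); the larger unnormalized posterior wins.

Three conventions matter:

* a column showing a single allele (d = 1) is judged homozygous outright,
  regardless of the prior;
* a posterior tie resolves to homozygous — heterozygosity is never
  fabricated on equal evidence;
* e must stay below 0.6, otherwise an error allele under the
  heterozygous hypothesis (e/3) would outrank a true allele ((1−e)/2) and
  the rank-based model would invert.

The model scores *ranked* counts with rank-indexed category
probabilities, i.e. it is evaluated on order statistics without summing
over category-to-rank assignments.  The omitted combinatorial factor is
not exactly hypothesis-independent, but switching to the full
order-statistic sum was checked by hand on representative columns and
does not change the decisions that dominate behaviour; the simple chain
is kept because it reproduces the sequential-binomial structure exactly.

### Fusing long- and short-read judgments

Where both read classes cover an anchor, agreement adopts the short-read
judgment (the more accurate technology); disagreement adopts whichever
side said *homozygous*.  With only one judgment available, it stands.

This override is the method's dominant failure mode at low long-read
depth: a heterozygous site whose long-read pile happens to be skewed
(minor haplotype sampled 0–2 times) is judged homozygous by the
long-read model, overrides the short reads' correct heterozygous call,
and the subsequent vote collapses the site.  At per-haplotype depth ~5
and e = 0.15 the likelihood at a (5,1) or (6,1) column genuinely favours
homozygosity under any consistent per-allele error model, so this is a
property of the method, not of the implementation; the acceptance tests
measure its aggregate cost directly (retention accuracy ≈ 0.87–0.88 at
5× per haplotype, rising above 0.94 at 10×).

### Priors

P(homozygous) is a point probability (default 0.5) or derives from a
Beta(a, b) distribution in one of three modes: the Beta mean a/(a+b)
(default), a seeded draw, or the density at a guess θ renormalized
against the density at 1−θ so the pair sums to one (a Beta *density* is
not itself a probability; the three modes make the choice explicit).
Retention accuracy is monotone in P(homozygous) — lowering it can only
reduce homozygous overrides at true heterozygous sites — and the
prior-sensitivity acceptance test measures exactly this monotone profile.

## Correction rules

Per anchored read base, with the fused judgment H and a voting pool
(long + short counts merged at Lm anchors by default, configurable to
short-only; short-only by construction for Lu reads):

* H homozygous → replace with the pool's top allele;
* H heterozygous → keep the base if it is one of the two top alleles,
  otherwise replace with a seeded uniform choice between them;
* a winning N deletes the base; a read deletion at a site whose winners
  are real bases is re-inserted (random between two heterozygous
  winners); read insertions relative to the reference have no anchor and
  are never touched.

All randomness flows from one per-run seed recorded in the output
headers; re-running a configuration is byte-identical.  Edits are logged
as (position, old, new) against the target-forward-oriented read, with
`-` marking an absent base, and replaying the edit log reproduces the
corrected sequence.

## The simulator and what it represents

The simulator defines the conditions under which the pipeline is
characterised: a uniform-random diploid genome (default 100 kb) with a
fixed number of planted heterozygous SNPs (default 500; positions
uniform, alternate allele uniform over the other three bases), long
reads with truncated-lognormal lengths (σ = 0.3, mean 2 kb) and
independent per-base errors split equally into substitution, insertion
and deletion (total 15%), and short reads (mean 100 bp) with
substitution-only errors (5%).

Two deliberate conventions:

* **Coverage is depth per haplotype.**  Each haplotype is sequenced at
  the requested depth, as when a haploid read simulator is run once per
  haplotype; the diploid pile at a site is therefore about twice the
  nominal figure.  Under the alternative reading (coverage = total
  diploid depth) a 3× data set would leave ~45% of heterozygous sites
  covered by one haplotype only — no classifier could retain them — so
  the per-haplotype reading is the one under which the method's reported
  behaviour is reachable at all.
* **Planted sites sit in the region interior** (margin of one mean long
  read length, pipeline default).  At desk scale the coverage ramp at
  the simulated region's ends is an artefact: a site 100 bp from the
  edge of a 100 kb region cannot reach nominal depth, whereas variants
  in a megabase-scale region are effectively all interior.

The simulator does **not** model: position- or quality-dependent error
rates, homopolymer bias, chimeric or strand-split reads (reverse-strand
reads are available behind `rc_fraction` but off by default), repeats or
realistic genome composition (GC is 0.5), or structural variation.
Passing tests therefore demonstrate the pipeline's behaviour under
idealised independent-error diploid data, not performance on real
genomes.

## Alignment and assembly conventions

* Mapping modes: `seeded` (k-mer diagonal voting locates a window, an
  exact score-maximising semi-global DP inside the window supplies the
  alignment), `exhaustive` (full semi-global DP, the oracle; desk scale),
  and `truth_anchored` (simulated reads re-aligned inside a padded
  window at their recorded coordinates; the fast path for study-scale
  runs).  One best alignment per read; both orientations tried;
  alignments worse than a 35% edit fraction are discarded, leaving the
  read unmapped.  Scoring defaults: match +1, mismatch −1, gap −2.
* The mapped/unmapped split is strict: a read joins Lm only when
  *more than* 90% of its bases align as match or substitution.
* Assembly: all-vs-all Smith–Waterman on k-mer-prefiltered pairs
  (k = 15); an overlap stands when its score exceeds θ (default 100) and
  its aligned length is ≥ 100 (no upper bound by default, configurable).
  Greedy merge in descending score, ties by read-id pair; per-column
  majority consensus, ties to the alphabetically first allele; contig
  merging repeats to a fixpoint; final contigs are linked longest-first
  with 50-N spacers whose positions are masked from anchoring.  The
  assembler is intended for desk-scale inputs; genome-scale users supply
  an external assembly at the `--ref` seam.
* Coordinates are 0-based half-open throughout; deletions contribute one
  N per spanned column; insertions between anchors are counted only as a
  diagnostic.

## Evaluation conventions

A planted site is retained when the balance |X₁|/(|X₁|+|X₂|) of its
post-correction pile (corrected long reads mapped back to the truth
reference) lies inside the inclusive heterozygous interval; presets
[0.20,0.80], [0.25,0.75], [0.30,0.70], [0.35,0.65] are nested, so
retention is monotone and accuracy never increases as the interval
narrows.  A site with fewer than two covering reads is counted lost.
The difference value excludes N and grades positive values as good
(≤ 0.3) or excellent (> 0.3); exact zero is a draw.

## Problem sizes

Study-scale checks run a 100 kb genome with 500 sites (≈ 500 long and
20 000 short reads at the default coverages), completing in roughly
10–25 s per configuration; the acceptance script averages three seeded
replicates per operating point.  The noiseless fixpoint check uses a
10 kb genome at 75× per haplotype so that both haplotypes are present at
every site with overwhelming probability — the regime in which "no
errors in, no edits out, accuracy 1.0" is a mathematical identity rather
than a coin flip.  Exhaustive-oracle checks (likelihood identity,
Smith–Waterman) run on instances small enough for brute force.

## Known limitations

* Retention accuracy at very low long-read depth is bounded by the
  homozygous-override fusion rule (see above); the acceptance suite
  reports the honest values.
* Base qualities are ignored; counts are unweighted.
* Only biallelic heterozygosity is modelled; a third true allele is
  treated as error.
* The evaluator requires truth (simulated or supplied); there is no
  reference-free quality metric.
* SAM import reconstructs match/mismatch from the reference, so `M`
  CIGARs require the reference sequence used for mapping.
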