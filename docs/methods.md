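# Methods

This note documents the models, estimators and design choices behind
`thtargets`, in the order the pipeline runs them.

## Experimental design and the direct/late distinction

The pipeline assumes a four-condition induction experiment: control, TH
(thyroid hormone), CHX (cycloheximide, a translation inhibitor) and TH_CHX
(CHX added shortly before TH), with replicate units per condition (default
4). Because CHX blocks synthesis of new protein, a gene whose TH response
survives CHX is regulated by pre-existing TR/RXR and is a *direct* target;
a gene responding to TH only when translation is permitted is a *late*
target, downstream of the direct ones. CHX itself perturbs transcription
broadly (among other things it rapidly up-regulates ribosome-biogenesis
genes), which is why the focal contrast for direct targets is TH_CHX
**vs CHX** — the CHX effect cancels — and why a separate `chx_response`
class is tracked from CHX vs control.

## Synthetic data generator

`synth.simulate` emulates that design with planted ground truth. Counts
are negative binomial with `var = μ + αμ²` (the DESeq-family
parameterization); α is shared across genes (default 0.1, a typical
replicate-level overdispersion for bulk RNA-seq of pooled animals).
Baseline means are log10-uniform on [1, 3] (10–1000 counts), spanning
weakly to strongly expressed genes; gene lengths are uniform on
500–5,000 bp. Class effects multiply condition means by `2^±effect_lfc`:

| class          | TH        | CHX       | TH_CHX    |
|----------------|-----------|-----------|-----------|
| `direct_up`    | ×2^L      | —         | ×2^L      |
| `direct_down`  | ×2^−L     | —         | ×2^−L     |
| `late`         | ×2^L      | —         | —         |
| `chx_response` | —         | ×2^L      | ×2^L      |
| `null`         | —         | —         | —         |

with L = 3 by default (8-fold), the magnitude of a strong, unambiguous
hormone response; class fractions default to 2% / 1% / 5% / 10% with the
remainder null. Late genes are modelled as up-regulated only; the
classifier is direction-symmetric, so a signed late class would add
nothing to what the tests can detect.

Promoters are uniform-random over {A,C,G,T} (default 5,000 bp — the
window used for TRE prediction). Uniform background makes the expected
number of chance DR4 hits analytically computable, which the scanner tests
exploit. Each direct-target promoter carries exactly one planted DR4
element at a random position and strand: the spacer bases are drawn freely
and a configurable number of mismatches (default 2, half the scan budget)
is introduced at positions chosen uniformly among the 12 half-site
positions. Counts and promoters come from separate RNG streams spawned
from the master seed, so either output can be regenerated independently.

What the generator does *not* emulate: library-size variation between
samples (size factors are therefore exercised by construction only mildly),
per-gene dispersion variation, correlated genes, GC/length biases,
isoforms, and promoter base composition or repeat structure. Passing the
planted-recovery tests therefore demonstrates the correctness and
calibration of the inference chain under its own model assumptions, not
performance on real libraries.

## Differential expression

`detest.fit_contrast` is a small, fully specified member of the NB-Wald
family:

- **Size factors**: median-of-ratios across the samples of the two
  conditions (geometric-mean reference over genes positive in all
  samples). The "library size" used by FPKM, by contrast, is the raw
  column sum, since mapped-read totals are unavailable without alignments.
- **Dispersion**: per gene, method of moments on normalized counts —
  `α̂_c = (s²_c − m_c)/m_c²` within each condition, pooled with weights
  `n_c − 1` — then shrunk toward a mean-dispersion trend
  `α(μ) = a₀ + a₁/μ` fitted by least squares (coefficients clipped at 0)
  over all genes with a positive estimate:
  `α_shrunk = (d·α̂ + d₀·α_trend)/(d + d₀)` with data df `d = n_a+n_b−2`
  and prior df `d₀ = 12`. A 6-df moment estimate is far too noisy to
  plug into a Wald statistic — it both inflates the type-I error and,
  when it randomly overshoots, destroys power — and sharing information
  across genes is precisely how the established NB tools make
  few-replicate designs workable. With fewer than 10 usable genes no
  trend can be fit and the per-gene estimate is used as is. Final
  estimates are floored at 1e-8.
- **Effect size**: `log2fc = log₂((m_b + ½)/(m_a + ½))`; the 0.5
  pseudo-count keeps fold changes finite at zero means.
- **Test**: Wald statistic `log2fc / SE` with the delta-method SE
  `SE² = [(m_a+αm_a²)/(n_a(m_a+½)²) + (m_b+αm_b²)/(n_b(m_b+½)²)]/ln²2`,
  referred to Student-t with `d + d₀` df (or `d` when no trend was fit).
  The t reference accounts for the residual uncertainty of the dispersion
  estimate; calibration was verified by null simulation across true
  dispersions 0.02–0.4 (empirical p<0.05 rates 0.035–0.063, against
  0.07–0.09 for a normal reference at high dispersion).
- Genes with zero counts in every sample get `log2fc = 0` and missing
  p-values, and are excluded from the BH denominator.
- **DET filter**: `|log2fc| ≥ 1` (inclusive) and `padj < 0.05` (strict),
  exactly these boundary semantics.

This is deliberately not a line-for-line reimplementation of any specific
DE package; it is pinned here so that every number it produces is
reproducible from this description.

## Target classification

From the DET sets of TH vs control (A), TH_CHX vs CHX (B) and CHX vs
control (C): `direct_up` = up in A and B; `direct_down` = down in A and B;
genes in A and B with *opposite* directions are flagged `discordant` and
are not direct (the defining biology is a concordant CHX-resistant
response); `late` = in A only; `chx_response` = in C but not A; `null`
otherwise. Labels partition the universe; all sets must share it. Venn
tallies (`overlap_counts`) require direction agreement for "shared" and
count discordant genes on both "only" sides, reported separately. The
TH_CHX vs control contrast is computed and persisted for inspection but
takes no part in labelling.

## TRE scanning and the consensus motif

The DR4 element is scanned as the degenerate pattern `AGGTCANNNNAGGTCA`
with a mismatch budget (default 4) counted **only at the 12 half-site
positions**; the spacer is unconstrained by definition of the element, and
an `N` in the *sequence* counts as a mismatch wherever the pattern is
informative. Both strands are scanned by default (TR/RXR sites function
in either orientation); `forward_only` mimics a literal text search.
Coordinates are 0-based, half-open, on the forward strand (a minus-strand
hit reports the forward coordinate of its leftmost base and the
reverse-complement 16-mer); ties in `best_per_gene` mode resolve to fewest
mismatches, then leftmost start, then `+` strand, making outputs fully
deterministic. Promoters longer than the window are scanned only over
their trailing `window_bp` bases (the TSS-proximal window); shorter ones
are scanned in full, mirroring genes near contig edges.

`build_motif` computes counts, frequencies, information content
`IC_i = 2 + Σ_b f_ib log₂ f_ib` (0·log 0 = 0) and a consensus with
thresholds 0.75 (uppercase) and 0.5 (lowercase), `n` below; frequency
ties resolve to the first base in A<C<G<T order. The thresholds are
exposed because logo-style consensus calling has no single convention;
these defaults reproduce the mixed-case-with-n style in which DR4
consensus sequences (e.g. `AGGTCAnnTnAGGTCA`) are conventionally printed.

## Enrichment, qPCR, length statistics

- Over-representation is a plain upper-tail hypergeometric test
  `P(X ≥ k | N, K, n)` with BH adjustment over tested terms. No
  length-bias (Wallenius) correction is applied: the weights such a
  correction needs are data we do not model; the `weights` hook reserves
  the interface. The universe is the caller's choice; the pipeline uses
  all genes with a defined adjusted p-value in the focal contrast.
- qPCR fold changes follow 2^−ΔΔCt with a reference gene per sample and
  the calibrator ΔCt aggregated by arithmetic mean, so the calibrator
  group's geometric-mean fold is exactly 1. Group significance is a
  standard one-way ANOVA call, reported only.
- N50/N90 use the descending cumulative rule: the first length at which
  sequences that long or longer reach 50% (90%) of total bases — the
  assembly-stats convention. Length bins are half-open `[lo, hi)` with an
  open-ended final bin.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic data at
sizes chosen so each property is measured with adequate resolution: 1,000
genes × 16 samples for recovery (30 planted direct targets), 2,000 genes
for null calibration, 100 × 1 kb sequences × budgets 0–4 × both strand
modes for the scanner oracle. Every stochastic step draws from
`numpy.random.default_rng` seeded explicitly; the pipeline spawns
per-output streams from one master seed and records it in `summary.json`,
so identical configs produce byte-identical summaries.

## Known limitations

- The DE stand-in shares one trend across genes; strongly heteroskedastic
  dispersion (common in real data) is only partly captured.
- The classifier is threshold-based; near-threshold genes flip classes
  under resampling, which is inherent to the published filter semantics
  rather than to this implementation.
- The scanner reports Hamming-style matches only; it does not score
  binding affinity (no PWM log-odds against a background model) and has
  no notion of chromosomal context.
- FPKM uses raw transcript lengths and column-sum library sizes; without
  alignments, effective lengths and mapped-read totals are not available.
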