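# Methods

## Chemistry and coordinate conventions

NaBH₄ reduction followed by aniline β-elimination excises the methylated
guanosine: a molecule methylated at 1-based mature position *p* yields a 5′
piece covering positions 1..*p*−1 and a 3′ piece covering *p*+1..*L*. Site
calling inverts this map: a tested fragment whose 0-based start is *s*
nominates position *s* (the base immediately 5′ of the fragment,
"start-anchored" evidence), and a fragment whose 0-based exclusive end is
*e* nominates *e*+1 ("end-anchored"). Both kinds of evidence are merged at
the same candidate position by default; a starts-only mode is available.
Candidates are only accepted where the reference base is G, and positions
adjacent to a rejected candidate that are G are surfaced in a diagnostics
column but never called — an intentional tripwire for off-by-one
regressions in the boundary conventions.

All reported positions are 1-based on the mature sequence; internal
arithmetic is 0-based half-open. The canonical variable-loop m⁷G position
is 46. tRNAs whose long variable loop or intron shifts that position take
explicit per-id overrides; full structural (Sprinzl) renumbering is out of
scope.

## Pipeline parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| preprocess | 3′ adapter | NEXTFLEX v3 `TGGAATTCTCGGGTGCCAAGG` | protocol standard |
| preprocess | min length | 23 nt | applied to the adapter-trimmed length, before end-trimming; the alternative order is a config switch |
| preprocess | fixed end trim | 4 nt each end | the random nucleotides NEXTFLEX ligates to both insert ends |
| preprocess | adapter matching | min overlap 3, error rate 0.1 | common cutadapt-style defaults; N counts as a mismatch |
| align | max mismatches | 2 | ungapped end-to-end, bowtie `-v 2` semantics |
| align | max placements | 500 | reads exceeding this are suppressed entirely (`-m 500` semantics); all valid placements count toward the cap |
| align | multi-map weight | 1/n per placement | conserves read mass; count-all and drop-multi alternatives exist |
| count | fragment filter | total < 10 over all samples, strict, pre-pseudocount fractional totals | |
| count | pseudocount | +1 to every retained cell | |
| count | tRF threshold | length fraction < 0.7 of the mature tRNA | only tRFs are tested |
| test | significance | BH-adjusted p ≤ 0.05 | configurable |
| test | effect size | interaction log2FC ≥ 1 | WT-specific gain; the sign gate excludes KO-enriched fragments |

Fragment classification (5′ halves for ends in the anticodon window 32–38,
short 5′ fragments for ends in the D-loop window 14–21, 3′ fragments,
internal, full-length-like at fraction ≥ 0.7) is reporting-only and never
gates the statistics; the windows are canonical-cloverleaf defaults and
configurable.

## Statistical model

Per fragment, counts follow NB2 (variance μ + αμ²) with log link, offsets
log *s<sub>j</sub>*, and design `intercept + condition + treated +
condition:treated` with KO and untreated as reference levels. Fitting is
IRLS at fixed dispersion (convergence max |Δβ| < 1e−8 or 100 iterations);
standard errors come from the observed Fisher information
X′ diag(μ(1+αy)/(1+αμ)²) X. Counts are rounded to integers after the
pseudocount because the NB likelihood is defined on integers; at the count
depths involved this perturbs estimates negligibly (the interaction
contrast is invariant to common scaling, and tests cover the rounding
path). Fits that diverge or separate are flagged unconverged and excluded
from the BH family.

Size factors are median-of-ratios over rows with all-positive counts
(guaranteed after the pseudocount), rescaled so their geometric mean is 1.
They are computed on the tRF matrix that enters testing. A practical
consequence, visible in the simulator: normalization is anchored by the
null (background) fragment species, so libraries must be deep enough that
background species clear the 10-count filter; in signal-only matrices the
median absorbs the treatment effect. The test suite deliberately operates
in the deep regime.

Dispersion is estimated per fragment by method of moments on normalized
counts — residual variance pooled across the four design cells,
α̂ = max(0, (s²−μ̄)/μ̄²) — then shrunk halfway on the log scale toward a
mean–dispersion trend α(μ) = a₀/μ + a₁ fitted by least squares with
non-negativity. Fragments whose truncated moment estimate is exactly zero
carry no usable dispersion information at 3 replicates per cell and take
the trend value directly: shrinking a log-zero estimate would assign them
near-Poisson dispersions and measurably inflate the null Wald statistics.
With this rule the null type-I error at p < 0.05 sits inside the 99%
binomial interval around 0.05 in the calibration tests. Floor 1e−8. This
is a deliberately simple, self-contained stand-in for Cox–Reid/empirical-
Bayes dispersion machinery; exact DESeq2 numerics are not a goal.

## The simulator

`m7gmap.simulate` generates the 12-library design from a reference set and
an explicit truth object. Per molecule: reference drawn by relative
abundance with NB-dispersed per-reference totals (dispersion 0.05 by
default — typical replicate-level overdispersion for abundant small-RNA
species); if treated AND WT AND methylated, cleavage at the m⁷G with
probability `cleavage_efficiency` (default 0.3), the base excised and one
side sequenced with equal odds; otherwise a background break at a uniform
internal position with probability `background_cleavage_rate` (default
0.02); otherwise full length. Reads get 4 random nucleotides on both ends,
the 3′ adapter, truncation to 75 cycles, constant quality, and a uniform
0.001 substitution rate. Read names carry provenance (reference, piece,
cleavage position) for truth-based assertions only; no pipeline stage
parses them.

What the simulator does not emulate: PCR duplication, ligation sequence
bias, position-dependent error profiles, non-tRNA contaminating reads,
partial CCA/processing intermediates, and real multi-mapping structure
between near-identical isodecoders (synthetic panels are random sequences,
so multi-mapping is exercised by dedicated identical-sequence fixtures
rather than arising organically). Passing recovery tests therefore
demonstrate the inferential machinery under the stated generative
assumptions, not robustness to every artefact of real libraries.

## Aligner

Ungapped end-to-end alignment with a completeness contract: no placement
with ≤ max_mismatches may be missed. Reads of length ≥ 3k (k = index k-mer
size, default 12) are searched seed-and-verify with one k-mer per third of
the read — with ≤2 mismatches at least one third is mismatch-free by
pigeonhole, and its leading k-mer is queried exactly. Shorter reads are
verified brute-force against every offset of every reference with a
vectorised Hamming scan (cached sliding-window views make this cheap).
Identical read sequences share one lookup, which is what makes deeply
sequenced small-RNA libraries fast to align. The test suite checks the hit
sets against an independent all-offsets scan over fuzzed reads. Forward
strand only by default (stranded protocol, sense references); reverse-
complement search is a flag.

## Problem sizes

Desk-scale defaults keep everything runnable on one CPU: 50k molecules per
library for single-reference recovery runs (≈1 minute end to end), 75k per
library for 8-reference panel runs, and 2000 fragments for count-level
calibration. These sizes were chosen so that background fragment species
clear the count filter (see the normalization note above) while runs stay
interactive.

## Known limitations

- Direct alignment to mature tRNA references replaces genome-wide
  alignment followed by tRNA-interval intersection; reads that would also
  match non-tRNA loci are handled differently by construction.
- Isodecoders are collapsed only when mature sequences are byte-identical;
  near-identical isodecoders share reads fractionally and can dilute
  per-gene evidence.
- The per-tRNA verdict is "methylated if ≥1 candidate site passes both the
  significance and fold-change gates"; no stoichiometry is estimated.
- Positions are mature-sequence coordinates; comparisons across tRNAs with
  different variable-loop lengths require the per-id overrides.
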