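# Methods

This note documents the model behind `famvar`, the parameters that matter,
the numerical conventions, what the synthetic generator does and does not
emulate, and the design choices that were genuinely open.

## Model and assumptions

The pipeline treats causal-variant discovery in a densely affected family as
a conjunction of independent filters, under a **monogenic dominant** model:
one rare, highly penetrant germline allele is assumed to be carried
heterozygously (or homozygously) by every affected member and absent from
unaffected members. Penetrance is assumed complete in cases and controls;
the "possible carrier" role exists precisely because that assumption is
unsafe for relatives with intermediate phenotypes (e.g. early polyps), whose
genotypes are therefore never constrained. The filters are deliberately
deterministic — there is no likelihood model or prior; the output is an
auditable funnel, not a posterior.

Annotation scores are consumed, never computed: the package assumes an
upstream annotator has supplied CADD PHRED, conservation scores, gene
intolerance metrics and per-tool predictions. Misannotation upstream
propagates; the cascade only enforces the decision rules.

## Parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| `min_qual` | 20 | PHRED | standard call-confidence floor |
| `min_depth` | 5 | reads | minimal coverage for a germline genotype |
| `max_af` | 0.001 | frequency | "rare" for a high-penetrance dominant allele |
| `cadd_min` | 10 | PHRED-like | top ~10% most deleterious substitutions |
| `gerp_min` | 2.0 | RS score, inclusive | constrained-element convention |
| `phastcons_min_exclusive` | 0.3 | probability, strict | conservation probability floor |
| `phylop_min` | 3.0 | −log p, inclusive | per-site conservation significance |
| `conservation_votes_needed` | 2 of 3 | votes | robustness to one missing/disagreeing tool |
| `intolerance_fraction` | 0.6 | fraction of 4 → ≥3 | majority of gene-level criteria |
| `deleteriousness_fraction` | 0.6 | fraction of 10 → ≥6 | majority of ensemble tools |
| `pwm_threshold` | 0.8 | relative score | the common "80% of profile maximum" site-calling default |
| `pwm_pseudocount` | 0.8 | counts | JASPAR-style smoothing, distributed by background |
| `scan_flank` | 60 | bp each side | ~130 bp window; motif hits near a promoter SNV fall well inside |

Boundary semantics are asserted in tests: GERP 2.0 and PhyloP 3.0 pass
(inclusive), PhastCons 0.3 fails (strict), VEST3 0.5 and Reliability Index 5
pass (inclusive), allele frequency exactly 0.001 passes (inclusive).

## Votes and missing data

Vote fractions use **fixed denominators** by default (4 intolerance criteria,
10 tools); a missing or undefined criterion counts as a failed vote. This
keeps reported percentages comparable across variants and makes the printed
75/80/100/90% figures of the worked example directly interpretable. The
alternative `denominator="available"` shrinks the denominator to the
criteria actually defined (e.g. 3 for a stop-loss variant, which has neither
a missense Z nor a pLI criterion); it is provided but non-default, because it
silently changes what "60%" means per variant. MetaSVM/MetaLR predictions are
parsed when present but excluded from the default vote so the ten-tool
denominator holds.

The class-specific fourth intolerance criterion is ExAC missense Z > 0 for
missense variants and pLI ≥ 0.9 for stop-gain, frameshift and splicing
variants; other classes have no defined fourth criterion (fail in fixed
mode, dropped from the denominator in available mode).

Splicing-region variants are kept through synonymous exclusion by default
(`keep_splicing`), flagged by their region class; they carry no exonic
effect, so excluding them is a one-flag change.

## Segregation details

Heterozygous and homozygous-alternate genotypes both count as "present"
(dominant model). A missing genotype in a case drops the variant in the
default strict mode — reproducibility over sensitivity — with a permissive
mode behind a flag. Relatedness screening is the Jaccard similarity of
rare-variant carrier sets per sample pair; it is a sample-swap sanity check,
not a kinship estimator.

## PWM scanning

Counts are converted to probabilities with a total pseudocount of 0.8
distributed by the background (uniform 0.25 per base by default), then to
log2 odds against that background. The relative score of a window min-max
normalizes its raw log-odds sum over the matrix's own attainable range, so
1.0 is reached exactly by per-column-maximal sequences and the 0.8 hit
threshold is scale-free across motifs. Both strands are scanned; minus-strand
hits are scored on the reverse complement, reported at plus-strand window
coordinates with the strand-matched site sequence. Windows containing N are
skipped rather than imputed. Differential calls group hits by TF name, so a
factor with several matrix versions counts once, and a TF counts as affected
if *any* of its hits is exclusive to one allele — hits are not required to
overlap the variant position (an `overlap`-restricted view can be derived
from the reported hit coordinates).

The scanner is validated two ways: exhaustive per-window enumeration for
short motifs, and an independent log-odds/score-range computation via
Biopython's motif machinery (whose flat per-cell pseudocount equals this
package's background-distributed one when the background is uniform).

## Coordinates

Internally all intervals are 0-based half-open (BED-native); every
user-facing position, including TFBS hit coordinates, is 1-based inclusive.
The conversion identities (`start_1based = start + 1`,
`length = end − start`) are property-tested.

## Synthetic data

The generator emulates the *structure* the pipeline assumes, at the scale of
the motivating study: a 6-sample pedigree (4 affected siblings, 1 possible
carrier, 1 control) and 11,076 rare variants by default. Background
distributions are chosen for testability, documented here, and are **not**
cohort statistics:

- per-sample heterozygous-carrier probability 0.3, i.i.d. across samples and
  variants;
- allele frequencies log-uniform over 10⁻⁶–10⁻²;
- CADD PHRED: 90% U(0, 10), 10% U(10, 40), so ~10% clear the CADD stage;
- GERP ~ N(0, 2.5), PhyloP ~ N(0, 2), PhastCons ~ Beta(0.4, 0.6),
  intolerance scores ~ N(0, 1), Z ~ N(0, 1.5), pLI ~ Beta(0.2, 0.8);
- each categorical tool damaging with probability 0.3; Reliability Index
  uniform on 0–10; VEST3 uniform on [0, 1].

Planted variants realize a prescribed fate (`fail_stage=None` or one named
stage) with scores set just inside or outside each threshold; realization is
verified at generation time against the very predicates the pipeline uses,
so an unrealizable profile fails loudly. Because genotypes are i.i.d., the
expected number of background variants surviving segregation has the closed
form n·p^c·(1−p)^k (c cases, k controls), which the test suite checks within
3 binomial standard deviations over 100 seeds.

The promoter generator concentrates a synthetic motif's information content
in one column (a uniformly sharp motif loses only 1/L of its score range to
any single substitution, which an 0.8 relative threshold cannot detect) and
plants the disrupting SNV there; wild-type detection and mutant loss are
verified at generation, with automatic sharpening and a hard error if the
plant cannot cross the threshold.

What the generator does **not** emulate: linkage disequilibrium, realistic
site-frequency spectra, mutation-rate heterogeneity, Mendelian transmission
within the pedigree (genotypes are i.i.d., not inherited), correlated
annotation scores, or sequence composition biases. Passing tests therefore
demonstrate the correctness of the decision logic and its arithmetic, not
the pipeline's sensitivity/specificity on real exomes.

The test suite and worked examples run the cohort generator at reduced sizes
(a few hundred to a few thousand variants); the stage logic is size-free,
and the distributional checks are scaled accordingly.

## Worked-example fixtures

The two curated coding candidates carry their reported CADD, GERP, PhyloP,
PhastCons and allele-frequency values. Their per-tool calls and raw
intolerance scores were published only as vote percentages, so the fixture
reconstructs panels that realize exactly those percentages (3/4 and 8/10 for
*PTGES*; 4/4 and 9/10 for *SLC15A4*); the acceptance tests assert the
reconstruction reproduces the printed fractions before asserting survival.
The promoter fixture stores the published differential hit lists
(TF, matrix, score, span, strand, site) in window-local coordinates; the
window's genomic anchor and strand convention were not published, so those
coordinates are treated as window-relative and the package's own scans
report both window-relative and genomic positions.

## Known limitations

- No compound-heterozygous or recessive mode; the segregation rule is
  dominant-only (configurable genotype floor, but one rule per run).
- The rarity filter trusts the declared filtering populations; a variant
  common in an unrepresented population will pass.
- Gene-level intolerance scores penalize short or poorly covered genes in
  well-known ways; the cascade inherits those biases.
- PWM hit gain/loss is a binding *prediction*; no expression or occupancy
  data enter the call.
- MSA percent identity depends on the ortholog set supplied; the package
  computes the reference-vs-ortholog mean (all-pairs available as an option)
  and makes no claim about which scheme produced any published figure.
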