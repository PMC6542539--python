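# Methods

This note records the models, parameter choices and numerical
conventions behind `ripscan`, and what the synthetic-data tests do and
do not establish about real data.

## Enrichment statistic

Per library, counts are normalized to reads per million (RPM); every
normalized column sums to 1e6 by construction.  The per-gene RIP
efficiency is `e = RPM(Bound)/RPM(Input)` and the background-corrected
value `c = e_tagged − e_untagged`, protocol-matched.  Conventions that
the outputs depend on:

- **Coverage filter.** "Below 15 Input RPM" is exclusive: RPM = 15.0 is
  retained.  "Coverage" is interpreted on the RPM scale, not raw reads.
  Noncoding transcripts are dropped by default.
- **Correction domain.** A gene must pass the filter in both the tagged
  and the untagged experiment (set intersection); the subtraction is
  undefined otherwise.  A `fill_zero` mode (missing untagged efficiency
  treated as 0) is provided for sensitivity analysis.
- **Negative `c`** is kept, not floored; such genes simply rank low.
- **Ranking tie-break.** Descending `c`, then larger Bound RPM, then
  lexicographic gene id — a deterministic total order, so two runs (or
  two implementations) produce identical rank columns.

## Target calling

The default rule is the boxplot whisker convention: member iff
`c > Q3 + k·IQR`, `k = 1.5`, `IQR = Q3 − Q1`, quartiles by linear
interpolation between order statistics (`numpy.quantile`,
`method="linear"`).  Because called-set sizes are sensitive to the
quartile estimator and to whether the threshold anchors at Q3 or at the
mean, the anchor is configurable (`center_rule = quartile | mean`) and
the threshold actually used is recorded in every `TargetSet`.
Exclusion of bead-sticky transcripts removes genes that are themselves
IQR outliers of the *untagged* (uncorrected) efficiency distribution.
Venn regions assign every gene of the union to exactly one membership
pattern; region sizes therefore sum to the union size (property-tested
against brute-force enumeration over all 2^n patterns).

## fRIP peak calling

Per fragment, `r = bound/input` at a common PCR cycle; the cycle is the
largest recorded one at which no fragment's Input intensity reaches the
saturation level.  Fragments with Input intensity below a floor —
default 10% of the median Input — amplify too poorly for a trustworthy
ratio; they are flagged, excluded from peak calling, and can never win
the peak.  The peak is the argmax of `r` over unflagged fragments (ties
to the smaller index).  The smear report walks upstream from the peak
while the ratio exceeds the median of non-peak unflagged ratios,
stopping at the first fragment at or below it (or at a flagged
fragment); it formalizes the partial-cleavage signature in which
RNase-underdigested molecules still carry the binding site and extend
one–two amplicons upstream.  The floor and the median-based smear
cutoff are this package's quantitative renderings of what bench
analyses judge by eye on a gel.

## Window folding and mimic calls

Folding is Nussinov base-pair maximization over {AU, UA, GC, CG, GU,
UG} with a minimum hairpin loop of 3 nt.  A thermodynamic model is
deliberately out of scope: for 15-nt windows the downstream calls
depend only on the pairing pattern, and pair maximization admits an
exact, exhaustive enumeration oracle (every test of the folder checks
optimality against it; sequences ≤ 22 nt).  The traceback is canonical
— prefer "last base unpaired" when optimal, otherwise pair it with the
smallest admissible partner — so dot-bracket output is reproducible
across implementations.

Coordinates are 1-based on the coding strand with position 1 the A of
the start codon; DNA input is transcribed automatically (U ≡ T
throughout, including mutation specs such as `T1101A`).

A mimic hit requires all three triplet bases inside one hairpin loop
whose closing stack has ≥ `min_stem` (default 2) pairs.  Hits from
overlapping windows that present the same triplet occurrence are merged,
keeping the longest stem (ties to the smallest window start).

**Variant classification.** `anticodon_lost` is decided from sequence
alone (any mutated base inside the triplet).  Otherwise the mutant
window is refolded: `stem_disrupted` when the stack closing the
triplet's loop in the mutant retains < 50% of the wild-type closing
pairs, or the triplet is no longer in a hairpin loop; else
`stem_preserved`.  Retention is measured on the loop-closing stack
rather than on global pair overlap — pairs that survive elsewhere in
the window do not rescue a mimic whose own stem has come apart.  The
50% threshold is configurable; the three canonical designs (loop
mutation, two-base stem break, compensatory swap) classify identically
over a wide range of it.

## Synthetic data

The generators define the conditions under which the pipeline is
validated; they emulate the study's published scale, not any particular
dataset.

**RIP-seq counts.** ~5,000 genes (tests and the acceptance runs use
2,000 with proportionally scaled 2 M-read libraries to keep runtimes in
seconds; per-gene mean coverage matches the 10–18 M-read, ~5,000-gene
originals).  Latent abundances are log-normal (σ = 1.5), matching the
heavy-tailed transcriptome.  Each gene carries a bead affinity
(log-normal, σ = 0.5, mean `background_capture` = 0.02) drawn once and
shared by the tagged and untagged strains — exactly the assumption that
justifies the untagged subtraction.  Planted targets add a specific
capture term: bound weight `p·(bead + background_capture·(fold−1))`;
specific binding is protein-mediated and does not inherit the gene's
bead luck.  Planted genes' abundances are clamped to at least the
median: true targets — the synthetase "self" transcripts in particular
— are well-expressed mRNAs that pass the coverage filter.  Counts are
negative binomial (`var = mu + dispersion·mu²`, default dispersion 0.1,
the Poisson limit as dispersion → 0) realized as a gamma–Poisson
mixture whose gamma factor is drawn once per strain and shared by that
strain's Input and Bound libraries, because both are prepared from one
extract; the Bound/Input ratio of a strain therefore carries counting
noise only, mirroring the single-experiment design.

**fRIP panels.** The Bound signal is `background` (0.05) everywhere,
plus 1 at the site fragment, plus `carryover^d` at distance `d ≤
carryover_span` upstream.  The span defaults to 2: cleavage products
average ~200 nt, about two amplicon spacings, so more distal fragments
see only background.  PCR efficiency multiplies Bound and Input alike
and cancels in the ratio; multiplicative log-normal noise (σ = 0.1)
models band-quantification error.  Setting `noise_sigma = 0` gives the
exact expected panel, used for the deterministic fragment-10 fixture.

**Mimic CDSs.** The planted element is `stem_len` G–C pairs closing a
3-nt loop holding the triplet.  Flanks are random A/C — a pairing-poor
alphabet (no A–A, C–C or A–C pairs) — with an A-only buffer of one scan
window around the element, which makes the designed hairpin the unique
maximum-pairing structure in every window containing it; scanner
recovery of the truth position is then a theorem, not a probability.

**What passing these tests does not show.** Real RIP-seq has GC and
length biases, multimapping artifacts, untagged backgrounds that are
not perfectly shared, and replicate structure; real gels have
background subtraction and saturation artifacts; real mRNAs fold under
thermodynamics with tertiary context.  The synthetic results validate
the statistical logic and the code, not the biology of any particular
transcript.

## Problem sizes and determinism

Stochastic validations use 100 simulations (planted recovery), 12
(null calibration; the null check uses a replicate-based standard
error, since per-gene corrected efficiencies within one simulation are
correlated through the shared library-size normalization), 200 (fRIP
recovery), 1,000 sequences (folding oracle) and all 576 single-base
codon substitutions (synonymy oracle).  All randomness flows through
explicit `numpy` `Generator` seeds; there is no global random state,
and identical seeds give byte-identical output files (tested through
the CLI manifest hashes).

## Known limitations

- The folder ignores stacking energetics and dangles; stems reported
  are maximal pair stacks, not thermodynamic helices.
- The IQR rule has no error control; its false-positive rate on the
  simulated null (~5%) is a property of the heavy-tailed corrected
  distribution, reported rather than controlled.
- The spreadsheet reader expects a wide raw-count sheet and maps
  columns heuristically (or via an explicit `sample_map`); published
  workbooks with unusual headers need the explicit map.
- Reproduction of published ranks and set sizes requires the original
  raw-count workbook, which is not redistributable inside this
  repository; without it the corresponding acceptance test reports the
  missing input.
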