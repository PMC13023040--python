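# Methods

This note documents the models and procedures implemented in `repairmap`,
the defaults they use, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates and the cut site

All coordinates are 0-based; intervals are half-open; the cut site is an
inter-base coordinate. SpCas9 is modeled as cutting bluntly 3 nt 5′ of the
NGG PAM on the protospacer strand; on a minus-strand annotation the rule
mirrors (verified by a reverse-complement identity test). Cas9 also
produces a sequence-dependent minority of 1-nt 5′ overhangs; these are not
modeled as distinct cut geometries, but their fill-in product is exactly
the flank-templated 1-bp insertion the classifier flags via `templated`.

## Alignment and event extraction

Reads are aligned globally to the reference amplicon with affine gap
penalties (Biopython `PairwiseAligner`; defaults match +2 / mismatch −3 /
gap open −8 / gap extend −1, all configurable). These values favor one
contiguous indel over scattered gaps on short amplicons. Reads whose
aligned identity falls below 60% are excluded as unalignable and counted.
The aligned walk emits insertion/deletion/substitution events in reference
coordinates; adjacent mismatches merge into one substitution event. A
round-trip invariant (applying the events to the reference reconstructs
the read exactly) is enforced in tests for every generated read.

### Left-normalization

Indels in repeats are placement-ambiguous. Every indel is shifted to its
leftmost equivalent placement (the canonical VCF convention): deletions
slide while the base entering the window equals the base leaving it,
insertions rotate their inserted sequence. The operation is idempotent and
allele-preserving, and tests compare it against exhaustive enumeration of
all placements producing the identical edited string.

### Microhomology

For a left-normalized deletion of length L at s, the junction
microhomology is the largest k ≤ L with
`ref[s:s+k] == ref[s+L:s+L+k]` — the repeat copy retained at an MMEJ
junction, equal to the placement-ambiguity span of the deletion (capped at
L). Computing it on the left-normalized prefix form is equivalent to the
suffix form at the rightmost placement; the equivalence is covered by the
brute-force oracle test (10,000 random 30-mers).

## Classification

Events are first restricted to a ±5 bp window around the cut
(interval-overlap semantics; configurable). The window default follows the
observation that substitutions cluster within 5 bp of the cleavage site.
Labels:

- no events → `Unedited`; substitutions only → `Mut`;
- otherwise the dominant indel (longest; ties prefer the deletion, since
  deletion identity is the mechanistically informative feature) decides:
  insertions split at 1 bp (`1bp Ins` vs `Large Ins`), deletions split at
  5 bp (small vs large) and at 2 bp of junction MH (MH vs NonMH).

Decisions that were genuinely open and how they were fixed:

- **mh_min = 2.** Reported MMEJ signatures involve 2–4 bp of
  microhomology; a single shared base is treated as chance identity, not
  MH. Configurable.
- **Complex alleles** (insertion + deletion) classify by the dominant
  indel; co-occurring substitutions never demote an indel allele to
  `Mut`.
- **Reads containing N** inside the cut window are excluded and counted
  rather than guessed.

The spectrum reports proportions over the seven edited patterns (summing
to 1) and the editing fraction edited/(edited+unedited) separately.
Breakpoint profiles histogram deleted positions relative to the cut and
report the PAM-distal : PAM-proximal deleted-base ratio (infinite ratios
are flagged, not silently clipped).

## Kinetic model

Within the editable fraction, a three-state linear ODE describes intact
(u) → cut (b) → indel (e) flow with perfect repair returning b → u:

    u' = −k_cut u + k_perf b;  b' = k_cut u − (k_perf + k_err) b;  e' = k_err b

Rates are first-order, in h⁻¹, on the default harvest grid
0, 3, 6, 12, 18, 24, 36, 48, 60, 72 h. Because the system is linear with
constant coefficients it is solved with the matrix exponential of the
generator — exact to machine precision, so mass conservation (u+b+e = 1)
holds trivially and e(t) is non-decreasing.

Fitting proceeds in two stages:

1. **Logistic stage.** A 3-parameter logistic least-squares fit of the
   observed edited fraction estimates f_max (clipped to (0,1]); flat
   near-zero signals are flagged unreliable rather than fit.
2. **ODE stage.** With f_max fixed, (k_cut, k_err, k_perf) minimize the
   unweighted sum of squares of F_obs − f_max·e(t) (optional weights,
   e.g. inverse binomial SDs). The fit runs in log-parameter space from a
   multi-start grid (k_cut, k_err ∈ {10⁻³,…,1}, k_perf ∈ {10⁻⁹, 10⁻³})
   to escape local minima, reports R² against the mean model, per-time
   residuals, and an identifiability flag for k_perf.

**Observation model.** By default only the resolved indel pool is
observed: F(t) = f_max·e(t), treating cut-but-unrepaired molecules as
unamplifiable. `observe_broken=True` counts them as edited instead.

**Rate-exchange symmetry.** With only e(t) observed, the model is exactly
invariant under exchanging k_cut and k_err — e(t) depends on the rates
only through their sum (plus k_perf) and product. The pair is therefore
identifiable only up to order, for any k_perf. The fit resolves the label
by convention: the larger rate is reported as k_cut, matching the regime
time-course experiments consistently show (cleavage faster than
error-prone repair, which sits near 0.1–0.2 h⁻¹). Under
`observe_broken=True` the intact fraction enters the signal and the
ordering becomes identifiable from data.

**k_perf identifiability.** When k_perf ≪ k_err the objective is nearly
flat in k_perf; the fit flags `k_perf_unidentified` from the local
curvature (relative SE of log k_perf > 1, or a vanishing Jacobian column)
instead of reporting a spuriously precise value.

## Screen statistics

- **Assignment**: exact, position-anchored guide matching, zero
  mismatches; unmatched reads are counted, duplicated manifest sequences
  are a hard error.
- **Filtering**: guides with ≤10 edited reads (boundary inclusive) or no
  edited alleles are excluded, with a reason log. "No detectable
  mutations" is interpreted as overall-edited = 0, not per-pattern.
- **Per-guide test**: 2×2 Fisher exact test of the guide's pattern
  frequency against the *pooled* non-targeting controls (pooling
  maximizes control precision). Tail p-values are exact hypergeometric;
  the log₂FC uses a Haldane +0.5 pseudo-count only when a cell is zero,
  keeping the test itself exact.
- **Directional ranking**: a gene *promotes* an outcome when its knockout
  depletes it, so the promoting analysis ranks guides with negative log₂FC
  by ascending left-tail p; direction-inconsistent guides are appended in
  descending tail-p order (the most significant inconsistency is penalized
  hardest). Ties break by |log₂FC| descending, then guide id; the scheme
  is deterministic and order-invariant. The inhibiting analysis mirrors
  with the right tail.
- **RRA**: for a gene with k guides at normalized ranks r₍₁₎ ≤ … ≤ r₍ₖ₎,
  ρ = minⱼ BetaCDF(r₍ⱼ₎; j, k−j+1). Empirical p-values draw k i.i.d.
  uniform ranks per permutation (the null that matches ρ's definition;
  permuting realized ranks is available as an option) and use the
  (1+x)/(1+n) estimator, so p ≥ 1/(n_perm+1). All genes with the same k
  share one simulated null, which is what makes 20,000-permutation
  defaults cheap.
- **Integration**: shared genes only; combined log₂FC is the weighted
  mean and combined p the weighted Stouffer z-combination
  z = (w_A z_A + w_B z_B)/√(w_A²+w_B²) of the one-tailed p-values.
  Default weights are each library's overall frequency of the pattern
  (the library-level reading of outcome-frequency weighting; guide-level
  weights are a config option). p = 0 is clamped to the smallest positive
  float before the z-transform.
- **Hits**: |log₂FC| > 0.5 and combined P < .05, both strict. No FDR
  correction is applied by default, mirroring the permutation-plus-effect
  thresholding design; Benjamini–Hochberg is available as a flag.

## Clustering

Per pattern and direction the top-n (default 50) genes by gene-level
p-value are selected — 7 × 2 × 50 = 700 selection slots, deduplicated
into matrix rows. Effect profiles (combined log₂FC across the seven
patterns) are standardized per gene (patterns sit on very different
frequency scales), clustered with average linkage on Euclidean distances
(correlation distance available), and summarized as a gene×gene Pearson
matrix. Constant rows standardize to zero and are flagged; NaNs abort
with the offending gene names.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions for every test:

- **Loci**: random 120-bp amplicons with an NGG PAM and planted deletion
  sites whose post-normalization microhomology is verified to equal the
  requested length (defaults: a 4-bp deletion with 2-bp MH and an 8-bp
  deletion with 3-bp MH, both spanning the cut).
- **Reads**: drawn from a specified pattern spectrum, error-free by
  default (an optional uniform substitution error rate exists for
  robustness checks); 70% of insertions are flank-templated; every read
  name carries its true pattern. Insertions are constructed so their
  left-normalized anchor stays inside the ±5 bp calling window; large
  insertions are 2–5 bp.
- **Time courses**: binomial sampling of F(t) at a configurable depth
  with a time-varying pattern mixture in which 1-bp insertions peak early
  (~h timescale) and MH deletions accumulate late (~24 h timescale),
  echoing the observed order of pathway engagement.
- **Screens**: negative-binomial read depths (mean 200, matching the
  reported 100–300 read-count mode), a shared baseline outcome
  distribution with deletions dominant (~64%), multiplicative planted
  effects with renormalization, and the GeCKOv2 composition at full scale
  (19,050 genes × 6 + 1,864 miRNAs × 4 + 1,000 non-targeting = 122,756
  guides); tests and calibration studies run scaled-down compositions
  (100–200 genes) with the same structure.

Passing tests on these data demonstrate algorithmic correctness —
round-trip consistency, oracle agreement, calibrated error rates, power
against planted effects — under idealized reads. They do not demonstrate
robustness to sequencing error, PCR chimeras/duplicates, guide cross-talk,
or locus-specific outcome idiosyncrasies, none of which the generators
model.

## Numerical choices and problem sizes

- ODE solution via `scipy.linalg.expm`; logistic and ODE fits via
  `least_squares` (LM in log-space, tolerances 10⁻¹²–10⁻¹⁴, log-clipped
  to avoid overflow during line-search excursions).
- Fisher tails via `scipy.stats.hypergeom`, validated against exact
  integer enumeration: exhaustively for all 2×2 tables with margins ≤ 30
  (≈245,000 tables in the test suite) plus thousands of random tables
  with margins up to 200. Exhaustive enumeration at margins ≤ 200
  (~4×10⁸ tables) is not attempted; random coverage stands in above the
  exhaustive bound.
- Calibration studies use 2,000 permutations, 200-gene null screens and
  50-replicate power studies; simulation studies for rate recovery use
  30–40 replicates at 5,000 reads per timepoint. These sizes give
  Monte-Carlo error well below the tolerances asserted.
- Determinism: every stochastic routine takes an explicit seed or
  `numpy` Generator; identical spec + seed reproduces byte-identical
  outputs (asserted for the pipeline's score tables).

## Known limitations

- The seven-pattern taxonomy is specific to blunt-ish Cas9 DSBs; other
  nucleases (Cas12a staggered cuts) or editors (base/prime) would need
  different outcome classes and kinetic structure.
- The kinetic model treats the editable fraction as homogeneous; cell
  subpopulations with different rates are absorbed into effective
  constants.
- k_cut/k_err are reported under the exchange-symmetry convention above;
  if error-prone repair genuinely outpaced cleavage at a locus, the labels
  would be swapped by construction.
- The Fisher test treats reads as independent draws; PCR duplicates in
  real data violate this and inflate significance.
- Complex alleles carrying several same-length indels classify by a
  deterministic tie-break (deletion over insertion), a convention, not a
  mechanistic claim.
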