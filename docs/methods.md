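# Methods

## The substitution model

Sequences evolve under a general time-reversible model with discrete-gamma
rate variation and invariant sites (GTR+Γ+I). The rate matrix is built
from six exchangeabilities s (order AC, AG, AT, CG, CT, GT; GT ≡ 1 as the
reference) and stationary frequencies π as Q_ij = s_ij π_j, diagonal set
so rows sum to zero, and rescaled so −Σ_i π_i Q_ii = 1. Among-site rate
variation uses n equiprobable gamma classes whose rates are the
conditional bin means of Gamma(α, α) (the mean-of-bins discretization;
a median variant is not offered — means preserve the unit-mean property
exactly after rescaling). Invariant sites enter as an extra class with
rate 0 and weight p_inv; the variable-class rates are then divided by
(1 − p_inv) so that the weighted mean over *all* classes is exactly 1 and
branch lengths remain expected substitutions per site. Under these
conventions total log-likelihoods agree with phangorn's `pml` to the
printed precision (checked in the test suite), so fitted branch lengths
and site likelihoods are directly comparable to mainstream ML software.

Transition probabilities use the symmetric eigendecomposition of
diag(√π) Q diag(1/√π), exact for reversible Q. Parameters are validated
(frequencies positive and summing to 1 within 1e−12, α > 0,
0 ≤ p_inv < 1).

## Likelihood computation

Per-site log-likelihoods come from Felsenstein pruning over the unique
site patterns of the alignment (a ~130 kb, 8-taxon simulated plastome
compresses to a few thousand patterns), vectorized over patterns and rate
classes, with per-node max-rescaling and log-scale accumulators so even
adversarial inputs cannot underflow. Gaps and `?` contribute a partial
likelihood of 1 for every state (an all-gap column has lnL exactly 0);
IUPAC ambiguity codes restrict to their compatible states, which is why an
`R` is informative where a gap is not. Trees have unrooted semantics; the
likelihood is invariant to the traversal root (pulley principle), asserted
in tests, and rooting requested at a leaf is normalized to its neighbor so
the leaf's state is never dropped.

## Fitting on a fixed topology

`fit_on_topology` alternates (a) coordinate-wise Brent optimization of
each branch length on the log scale, bracketed around the current value
(a fixed global bracket can strand Brent in the flat saturated tail of the
likelihood curve — the bracket expands if the optimum hits an edge), with
a floor of 1e−8, and (b) a Nelder–Mead simplex over the free model
parameters in log/logit space, augmented with one log tree-scale
coordinate because α, p_inv and the overall branch scale are strongly
coupled. The first cycle seeds the simplex from a coarse (α, p_inv) grid.
Frequencies default to empirical counts unless freed; p_inv is bounded by
0.99 × the observed constant-column fraction to damp the Γ+I
identifiability ridge. Convergence is declared when a full cycle improves
lnL by less than `tol` (default 1e−4); non-convergence returns the best
state with a warning and a flag.

**The Γ+I ridge.** At the short branch lengths typical of low-level
plastome phylogenetics the joint (α, p_inv) profile likelihood is nearly
flat: on 50 kb simulated data the profile changes by well under one lnL
unit from (α = 0.5, p_inv = 0.3) to (α ≈ 1.8, p_inv ≈ 0.56). No optimizer
can recover α to within 10% from such data with p_inv jointly free — the
information is simply absent. The parameter-recovery study therefore
measures *conditional* recovery: p_inv is fixed at its known simulation
value and branch lengths, α and the exchangeabilities are fit. Under that
standard validation design the median relative error of α is ~3% and of
total tree length ~1% at 50 kb. Analyses of real data should treat a
jointly fitted α as a nuisance summary of rate variation, not an estimand.

## The conflict scan

Given per-site profiles for two candidate topologies fitted separately on
the same alignment (a flag allows sharing one model fit), the per-site
difference Δℓ_i is summed in sliding windows (defaults: window 5,000
columns, step 100; trailing partial windows are dropped so all sums are
comparable). Region calling centers the window sums at their median —
without centering, a genome-wide preference for one topology would flag
everything — and marks windows whose centered value exceeds k·MAD
(default k = 3). Maximal same-sign runs of at least `min_run` windows
(default 10) qualify as regions **only if** the run's window starts span
at least one window size (default `min_span = window_size`). The span
condition is structural: with a 98%-overlap between consecutive windows,
a single anomalous stretch shorter than one window inflates up to
window/step consecutive windows purely by arithmetic, and without the
guard most chimeric replicates grew extra short false regions from
chance clusters of strongly informative sites. Region boundaries are
reported at the first and last qualifying window *centers* (within half a
window of the underlying signal edge by construction); the raw union of
window spans is also reported, as are un-trimmed source coordinates when
the alignment carries a coordinate map. Calling is deterministic,
idempotent, and equivariant under a global sign flip.

## Topology tests

All tests resample stored site log-likelihoods (RELL; no refitting).
Replicates are drawn as multinomial counts over the unique joint site
patterns, so 10,000 replicates on 130 kb are a few matrix products. The
SH test centers each topology's replicate totals, uses the centered
maximum difference as the null statistic, and is run against the observed
δ = lnL(best) − lnL(t); it is conservative by construction, which the
test-suite verifies as a type-I error ≤ nominal on 500 star-tree null
datasets. The AU test draws replicates at ten scales r ∈ {0.5, …, 1.4}
(⌈rL⌉ columns), converts per-scale never-best frequencies to normal
quantiles, fits z(r) = d√r + c/√r by weighted least squares
(delta-method binomial weights), and reports p = 1 − Φ(d − c); degenerate
frequency vectors (all 0 or all 1) clamp p to {1, 0} with a flag. Seeds
are explicit everywhere and recorded in the outputs.

## Alignment trimming

The trimmer implements the five published Gblocks selection steps:
classify columns by the count of the majority residue (nonconserved < b1,
conserved ≥ b1, highly conserved ≥ b2; gaps never count toward the
majority), reject runs of more than b3 contiguous nonconserved positions,
trim block flanks inward to highly conserved anchors, remove gap columns
(b5 = none: any gap; half: > 50% gapped; all: none) together with
adjacent nonconserved stretches, and drop blocks shorter than b4. It is a
re-implementation from the published description, not a byte-match of the
0.91b binary, whose tie-breaking on pathological inputs is undocumented;
a hand-worked fixture pins the intended semantics. In codon mode a
triplet's status is that of its weakest column and the steps run over
triplets (b3/b4 still counted in nucleotide positions), so output lengths
are multiples of 3. Trimming is deterministic and idempotent, and the
relaxed preset can never retain fewer columns than the strict one. The
named presets carry the 21-taxon thresholds (strict b1=13, b2=21, b3=8,
b4=10, b5=none; relaxed b1=13, b2=13, b3=8, b4=5, b5=half);
`strict_for`/`relaxed_for` scale them to other taxon counts using the
Gblocks default proportions (50%+1 and 85%).

## IR-isomer read classification

An `ArrangementSpec` holds a reference genome with two inverted-repeat
copies; arrangement "B" is the reference with the span from the start of
the first copy to the end of the second reverse-complemented (an
involution; because the copies are inverted duplicates this flips only the
intervening segment). A read pair is *spanning* when its mates sit on
opposite sides of one IR copy with at least `min_flank` (default 50 bp)
mapped bases beyond the repeat; it supports the arrangement whose
reference yields a concordant (inward-facing, insert within mean ± 4 SD
of the observed insert distribution) spanning placement, and is ambiguous
if both or neither do while still straddling an IR within a plausible
fragment extent. Mates confined to the repeat are uninformative and
excluded. For error-free synthetic libraries an internal exact-match
mapper (all forward and reverse-complement placements) avoids any external
aligner; real libraries enter as SAM files mapped against the A and B
references.

## The synthetic-data generator

The generator operationalizes an introgression scenario — two plastid
haplotype lineages, transient heteroplasmy, recombination — as a
*two-tree chimera*: all columns evolve under one GTR+Γ+I model, but the
columns of one contiguous segment follow an alternative topology. The
default conditions are a 130,000-column, 8-taxon alignment (two
*Juniperus*, two *Cupressus*, one each of *Callitropsis*,
*Hesperocyparis*, *Xanthocyparis*, one outgroup; a 21-taxon preset
mirrors denser sampling) with the segment at columns 31,000–46,000,
branch lengths of order 0.01–0.05 (shallow divergence), moderately
AT-rich frequencies (0.30, 0.20, 0.20, 0.30), α = 0.5, p_inv = 0.3 —
fixture values chosen as typical for plastome data, not estimates from
any particular data set. Rate classes are drawn once per site and shared
across the tree. Indels are overlaid post hoc (geometric lengths, mean 4;
hotspot intervals multiply the start rate) because only their effect on
trimming and gap statistics is needed — there is no evolutionary indel
model, so indel placement carries no phylogenetic signal. IR-isomer
libraries draw each error-free pair from arrangement B with probability
`fraction_B` (insert ~ Normal(400, 50), reads 150 bp); a `span_only` mode
conditions fragments to span an IR copy, giving classifier studies ~834
spanning pairs without simulating genome-scale coverage.

What passing tests on these data do **not** show: robustness to
alignment error, sequencing error, rate heterotachy, within-segment
recombination breakpoints, or model misspecification — the generator
matches the fitted model family by design, so the studies isolate the
statistical machinery rather than stress realism.

## Study sizes and determinism

The simulation studies run at: 20 chimeric + 20 null 130 kb replicates
for scan power/specificity (partition SH tests with 2,000 RELL
replicates, whole-alignment fits capped at 3 optimization cycles — ample
for scan behavior); 10 × 50 kb for parameter recovery; 500 × 2 kb
star-tree nulls for SH size; 200 libraries × 834 pairs for the
classifier. All simulators are bit-reproducible under a fixed seed;
every stochastic routine takes an explicit seed and CLI outputs embed the
seed and a configuration hash.

## Known limitations

* Topology search is out of scope: candidate topologies are supplied.
* The AU implementation follows the standard multiscale-bootstrap
  description; scale grid and weighting are config, and exact p-values
  will differ slightly from other implementations.
* Codon-mode trimming decides per triplet, which is coarser than
  column-level decisions near block edges.
* The internal read mapper is exact-match only; real (error-containing)
  libraries must be mapped externally and supplied as SAM.
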