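# Methods

This note documents the models behind `cloneval`, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
conventions. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The validation model

A sequencing cluster is a clonal population of identical molecules; a
systematic base-calling error changes the emitted read but not the molecule.
Re-sequencing the physically retrieved clone therefore replicates only true
template bases. Classification of a flagged variant against the clone's
validation pileup uses a consensus threshold `c ∈ [0.80, 0.95]` (default
0.80, the permissive end of the documented range; configurable and echoed in
all outputs):

- alternate-allele fraction ≥ c → `true_variant`;
- reference fraction ≥ c → `artifact` (the original call was a miscall);
- any third allele ≥ c → `validation_artifact` — the clone was damaged,
  degraded, or PCR-mutated *during* validation, a category reported
  separately so it can neither inflate true variants nor hide in artifacts;
- otherwise, or when the position's depth is ≤ 2% of the clone's mean depth
  (the low-coverage exclusion for validation sequencing), `indeterminate`.

`indeterminate` is deliberately added even though a minimal implementation
could force every call into artifact/true: a mixed or shallow pileup carries
no evidence either way, and silently counting it would bias both the
artifact fraction and the recovered VF. Raising `c` can only move verdicts
into `indeterminate`, never flip artifact↔true directly — a property the
test suite checks.

Insertion alleles are keyed by `(position, inserted sequence)` because
homopolymer over-calls are the dominant pyrosequencing artifact class and
must not be conflated with substitutions at the neighboring base.

## Edit representation and alignment

All discrepancies are reference-anchored edits (0-based half-open;
insertions precede their reference base), with indels stored left-shifted to
canonical form, so simulator truth, aligner output and pileup consensus all
name the same physical change identically. Reports and VCF output convert to
1-based coordinates.

Reads are full-length amplicon reads, so variant calling uses banded
*global* alignment with affine gaps (match +1, mismatch −2, gap open −4, gap
extend −1; a length-k gap costs `open + k·extend`). The scoring scheme is a
package default, stated in config and overridable — the original analysis
used a local aligner with unpublished parameters, and external SAM or BLAST
tabular alignments can be ingested instead. Tie-breaks are deterministic:
substitution preferred over gap, deletion over insertion, indels
left-normalized after traceback. Alignments scoring below half the
perfect-match score are excluded as unalignable (with the read id and reason
logged) rather than contributing spurious calls. The banded kernel is
verified against an independent full-DP oracle on every instance ≤ 60 bp.

One consequence of alignment-based calling, preserved deliberately: an
insertion and a deletion a few bases apart in repetitive sequence can be
co-optimally represented as a handful of substitutions. The edit *path*
always reproduces the read; only the representation is ambiguous. Ground
truth for classification therefore lives at the molecule level (does the
clone carry this allele?), which is also how the tests score verdicts.

## The simulator

**Reference.** A deterministic synthetic 261-base amplicon with 20-base
primer intervals at both ends (221 assayable bases) and planted `GGG`
homopolymers near the 173rd and 191st base, mirroring the study geometry.
Primer intervals are excluded from error-rate denominators because
oligo-synthesis errors would otherwise masquerade as polymerase errors.

**Spike-in mixtures.** Templates carry designed variants at distinct
positions (overlaps are rejected — otherwise reads cannot be attributed to a
template) with fractions normalized to 1. Two composition modes: `multinomial`
(molecule counts scatter binomially around the design — the generator's
default) and `expected` (largest-remainder rounding: the mixture contains
exactly the expected number of molecules of each template, as in a pipetted
spike-in). The benchmark experiments use `expected` so the designed fraction
is the known input being recovered; the realized-fraction drift seen in real
quantification data (e.g. 0.01%→0.002%) arises only under `multinomial`
scatter plus quantification noise, which is not modelled further.

**PCR.** Default `poisson_approx`: each sampled molecule carries
`K ~ Poisson(L_eff · (sub_rate + indel_rate) · d)` mutations at uniform
non-primer positions — each of `d` doublings is an independent error
opportunity; enumerating 2⁴³ molecules is impossible and unnecessary at
desk scale. `lineage_tree` mode (for integer `d ≤ ~15`) grows the
replication tree explicitly, every daughter adding `Binomial(L_eff, rate)`
fresh errors on its newly synthesized strand, which reproduces the same mean
while capturing jackpot clustering; the two modes agree within Monte-Carlo
error for small `d` (tested).

**Sequencer errors.** Aggregate per-base substitution and indel rates
(defaults 0.148% and 0.147%, a pyrosequencing-scale signature) with two
structural factors: a non-decreasing positional gain along the read (errors
concentrate toward the read end) and a homopolymer multiplier on indels
(default 10× at run length 3, rising for longer runs; over-call insertions
duplicate the run base). Both factors are normalized so the configured
aggregates stay exact — the functional forms are package choices,
exposed as free parameters. Phred scores are emitted from the realized
per-base error probability, `Q = −10·log₁₀P` rounded and clipped to
[2, 41], with optional jitter; a lognormal per-read error multiplier
(`read_rate_sigma`) makes mean read quality informative about read accuracy,
which is what the quality-filter loss analysis exercises. No flowgram-level
signal simulation: base-caller internals are represented only through this
aggregate signature, so conclusions about real instruments transfer only at
that level.

**Single-origin bookkeeping.** Every emitted discrepancy carries exactly one
origin label. To keep that exact, error processes never stack within ±4
bases of an existing edit on the same read and indels are canonicalized at
draw time. At the simulated rates a multi-hit site is a ~10⁻⁴-per-read
event, far below the resolution of any statistic computed here. Reads sample
the molecule pool without replacement when the pool allows (each chip
cluster is a distinct physical molecule).

**Chip and frames.** Clusters sit on a jittered grid (guaranteeing a minimum
separation) in a global stitched pixel space; frames overlap by a configured
margin with float-valued true offsets; the truth pixel→stage similarity
transform generates stage coordinates exactly. Rendered frames place a
Gaussian spot (σ = 1.4 px by default) at each cluster, plus optional
Gaussian noise.

**Validation reads.** Re-reads of the *molecule* (template + PCR edits —
sequencer miscalls do not replicate) with independent substitution-style
noise at `val_error_rate`; indel noise in the validation platform is not
modelled separately. An optional `damage_rate` (default 0 — the effect is
reported only qualitatively upstream, so it is opt-in) injects one mutation
into the molecule before re-reading, producing the `validation_artifact`
signature.

## Registration

- **Spot centers** come from three-point log-quadratic interpolation through
  each peak — exact for a sampled Gaussian — with an intensity-weighted
  centroid fallback; peaks on the frame border are discarded as unreliable,
  and peak pairs closer than the laser's safe separation are both dropped
  (documented degenerate case). Coordinates are float throughout.
- **Stitching** estimates each adjacent-pair offset from mutual
  nearest-neighbor spot pairs in the overlap and reconciles all offsets by
  least squares over the whole adjacency graph rather than chaining
  sequentially; offsets are never rounded, which is precisely why error does
  not accumulate along long chains. An `integer_offsets` baseline is kept
  only so that claim is a measurable comparison (terminal error over a
  200-frame chain, tested). Frames with no shared spots fall back to
  dead-reckoning on the nominal offset, with a warning.
- **Pattern matching** uses triangle descriptors (sorted side ratios —
  invariant to translation, rotation and scale; reflections excluded since a
  chip cannot mirror) to propose vertex correspondences, each verified by
  consensus: the candidate similarity transform mapping the most observed
  spots onto distinct expected clusters within tolerance wins and is refined
  on its inliers. Below a minimum inlier fraction a no-match error signals
  the wrong chip region. The original description names the idea
  ("diffusion-like mapping", analytic least-squares, invariance) without
  equations; this construction is the package's interpretation satisfying
  every stated property. Nothing quantitative is published about decoy
  tolerance, so the defaults are property-tested, not literature-anchored.
- **Similarity fit** is the closed-form least-squares solution from the
  centered cross-covariance (`θ = atan2(Σp×q, Σp·q)`, scale from the
  variance ratio); no iterations. Only coincident (zero-variance) source
  points are rejected: unlike an affine fit, a 2-D similarity is well-posed
  on collinear points, and two distinct points are always collinear.
- **Retrieval plans** order targets boustrophedon over stage bands —
  deterministic and near-minimal travel without a TSP dependency — assign
  wells A1…H12 (or A1…P24) in plan order so every well maps back to its
  read, spill to further plates beyond capacity, and flag collision-risk
  clusters with a neighbor inside the laser radius.

## Estimators

- `pcr_error_rate = true_variant_bases / assayed_bases / doublings`, with
  assayed bases counted per aligned read over non-primer reference positions
  (per-interval masking, not a fixed constant, since read lengths can vary).
  The 95% CI is exact Poisson (Garwood) on the validated count — the
  upstream work reports no uncertainty, so the interval is this package's
  addition. In spike-in runs, designed template alleles are excluded from
  the count (they are known inputs, not polymerase errors).
- `doublings_from_copies = log₂(final/initial)`.
- `quality_filter` implements the two common conventions (mean-Q; fraction
  of bases ≥ Q, the `-q N -p P` rule) with inclusive comparisons.
- `sample_size` is the standard normal-approximation size with
  finite-population correction (`n₀ = z²p₀(1−p₀)/m²`,
  `n = n₀/(1+(n₀−1)/N)`, rounded up). The original study's derivation is
  unavailable; this op reports the standard formula and makes no claim to
  match the study's chosen 1048/817.
- `budget_crossover` makes the verbal cost argument explicit with two linear
  equations, echoed verbatim in every output so alternates can be swapped
  in: one run of at least `run_reads` covers the panel; barcoding multiplies
  the *entire* run (including non-target reads — the expensive part) by the
  barcode depth; validation adds `validation_reads_per_call` per flagged
  call, with flagged calls proportional to the error rate. Defaults
  (`run_reads = 10⁵`, depth 100, 1000 validation reads per call, error rate
  0.1%, barcode depth 10) put the crossover at 9×10³ sites; it scales as
  `(barcode_depth − 1)` and inversely with the error rate, exactly.

## Problem sizes and numerical choices

The benchmark experiments run at the study's conditions where those are
desk-scale: 50 replicates of 10,000 reads (~2.2×10⁶ assayed bases each) for
the fidelity recovery; 164,332 reads for the sensitivity floor; fifty
20,000-read ladders for the VF-agreement comparison (a deliberate
scale-down of the original read count, which is why only the *improvement*
is asserted, not the printed R² values); 200-frame chains for stitching.
Quantities tied to the archived instrument runs (absolute indel counts,
positional error distributions, retrieval throughput) are not reproducible
from simulation and are not claimed.

Tolerances: similarity-transform recovery is exact to 1e-6; stitching
sub-pixel recovery to 0.02 px noiseless; stochastic checks use 3×
Monte-Carlo-SE bands or exact binomial/Poisson intervals. Ties in consensus
calling break to the lexicographically first allele (`ACGT-`); ties in
alignment break as documented above; all RNG is `numpy.random.default_rng`
seeded explicitly, and identical config + seed reproduces every output byte
for byte (tested).

## Known limitations

- No paired-end logic, quality-aware alignment, multi-contig references,
  diploid genotyping or structural variants.
- The polymerase mutational spectrum is uniform over positions and alt
  bases; real spectra (transition bias, context effects) are out of scope.
- Validation-phase indel noise and real micrograph segmentation (beyond
  Gaussian spots) are not modelled.
- The cost model is an explicit simplification of a verbal argument; its
  parameters, not its form, carry the uncertainty.
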