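# Methods

## Channel model

All vectors are indexed by the 96 canonical SBS channels: substitution
blocks C>A, C>G, C>T, T>A, T>C, T>G, contexts lexicographic by 5' then 3'
base within each block, every variant folded to the pyrimidine strand.
Coordinates follow the VCF convention (1-based, reference allele on the
forward strand); the reference trinucleotide is fetched as pos−1..pos+1 and
purine-centred variants are reverse-complemented before channel assignment.
Mutational opportunities are 32 pyrimidine-centred trinucleotide
frequencies (purine contexts folded before lookup, matching the signature
convention). Mutation identity for all concordance/filtering operations is
(chrom, pos, ref, alt); multiplicity within a sample is collapsed with a
warning.

The 80-channel ("non-T>C") representation drops the 16 T>C channels and
keeps the remaining order, so the C>T block occupies indices 32–47 in both
representations. It is used when batch-related T>C artefacts of unknown
origin cannot be excluded: T>C counts are treated as missing data, zeroed
and (for probability vectors) renormalized.

## Artefact-correction model

An observed catalogue **V** is decomposed as V ≈ W₁H₁ + W₂H₂ with W₁ a
fixed artefact signature and (W₂, H) inferred by minimising the generalized
KL divergence Σᵢ [vᵢ log(vᵢ/v̂ᵢ) − vᵢ + v̂ᵢ] under Lee–Seung multiplicative
updates. Each iteration updates both activities, then the free column
against the refreshed reconstruction; W₂ is renormalized to sum 1 each
iteration with the scale absorbed into H₂, which keeps (W₂, H₂)
identifiable. Divisions are guarded by ε = 1e−12; the guard never enters
reported outputs.

**Initialization.** H starts at an equal split of the observed total with
uniform jitter in [0.8, 1.2]; W₂ is drawn from a flat Dirichlet so every
channel has support — multiplicative updates cannot escape zero entries, so
a dense start is required for the updates to be able to reach any solution.

**Stopping.** Every 20 iterations the mean divergence of the latest
20-iteration batch is divided by that of the previous batch; since the
divergence is non-increasing this ratio rises toward 1 as progress stalls,
and iteration stops once it reaches 0.95, subject to a minimum of 200 and a
maximum of 3000 iterations. The stopping rule is load-bearing, not merely a
cost saving: the free column has enough parameters to absorb sampling noise
given unlimited iterations (on a catalogue drawn purely from W₁, the
biological share H₂/(H₁+H₂) grows from ≈0.06 after 20 iterations to ≈0.19
at 200 and to ≈1 at 3000), so bounded iteration acts as the model's
regularizer. All defaults are exposed in `CorrectionConfig`.

**Restarts and outputs.** 100 restarts with consecutive seeds are averaged
(element-wise over W₂, H₁, H₂; W₂ renormalized after averaging). Restarts
are iterated as one vectorized batch with per-restart freezing at each
restart's own stopping point, so results are bitwise-reproducible from
(V, W₁, config, base seed) and independent of batching. Two corrected
catalogues are emitted: `corrected_subtract = max(V − H₁W₁, 0)` (primary —
preserves the observed channel detail) and the smooth model reconstruction
`corrected_model = H₂W₂`.

**Known behaviour at the identifiability limit.** When the biological C>T
spectrum closely resembles W₁ (signal-to-noise similarity, SNS → 1) the
split between artefact and biology on C>T channels is not identifiable.
Empirically the restarts then agree with each other but are collectively
biased — H₁ absorbs biological C>T mutations and its relative error grows
by an order of magnitude along the similarity gradient — so uncertainty
across restarts must not be read as a reliability measure. A related
degeneracy affects even disjoint supports: because W₂ is free, it retains
part of its initial mass on the artefact block (the multiplier V/V̂ reaches
1 before that mass decays), and the inferred H₁ settles ~4% below the
injected artefact total in the disjoint-block construction used by the
acceptance script. Consumers needing exact artefact totals in such corner
cases should treat H₁ as a lower bound.

## Signature derivation

Per-sample profiles are zeroed on T>C, renormalized, and embedded in 2-D by
t-SNE on the pairwise cosine-distance matrix of the 80 informative
channels. t-SNE hyperparameters are not dictated by the procedure itself;
the package uses 2 components, precomputed-distance mode, random
initialization and perplexity min(30, ⌊(N−1)/3⌋) so that small cohorts stay
embeddable, and records them in `Embedding.params`. Within each protocol
group (grouping by known label, not by unsupervised cluster assignment) a
Gaussian KDE with Scott's bandwidth is evaluated at each embedded point;
points strictly above the group's median density are kept, ties at the
median filling the ⌈N/2⌉ quota in ascending index order so selection is
reproducible. An exactly coincident group (singular 2-D covariance) is kept
whole with a warning. The mean of the selected profiles, renormalized, is
one candidate; the final signature averages candidates over t-SNE seeds
0..99.

The two bundled signatures are synthetic stand-ins (see
`data/synthetic_ffpe_signatures.tsv`): C>T-dominated probability vectors
with zero T>C mass, the repaired one concentrated (>80%) at N[C>T]G
channels as expected from 5-methylcytosine deamination surviving UDG
repair, the unrepaired one spread across all 16 C>T contexts with moderate
CpG elevation. They satisfy every `NoiseSignature` invariant and are
suitable for simulation, testing and demonstration; they are not measured
artefact spectra, and real-data analyses should derive cohort-specific
signatures or supply measured ones.

## Refitting

With every basis column fixed, the KL objective is convex in the
activities, so refitting runs activity-only multiplicative updates from a
deterministic equal split (no restarts) under the same stopping machinery.
Tests cross-check the optimum against an exhaustive grid search over the
mixing proportion and a non-negative least-squares fit; the methods agree
within 0.01 relative activity on identifiable mixtures (pairwise signature
cosine < 0.95). Two identical signatures recover the correct total with an
arbitrary split. Presence calls are strict: a signature is "present" iff
its relative activity exceeds 0.1. The active signature set is always an
explicit input, never auto-selected.

For 80c fits, activities are rescaled to the 96c scale by dividing by the
non-T>C mass of the corresponding 96c signature. The 80c/96c inconsistency
rate is log₁₀(activity₈₀c/activity₉₆c), with the well-refitted band
[−0.30, 0.18] applied exactly as printed (an activity ratio of exactly 0.5
gives −0.30103 and so falls marginally outside). Zero activity on either
side yields a NaN sentinel that is counted, never averaged or coerced to
±∞.

## Simulator

Biological catalogues are multinomial draws of a requested total from a
signature-mixture distribution. Artefacts are injected as independent
per-channel Poisson counts with mean noise_total·W₁ᵢ — distributionally
identical to drawing a Poisson total and distributing it multinomially, an
identity the tests verify. By default T>C channels of the observed
catalogue are zeroed after injection (the analysis convention when batch
T>C artefacts cannot be ruled out); `drop_TC=False` retains all 96
channels. One master seed derives per-sample child seeds through a
generator seeded with it, so cohorts are reproducible from a single
integer.

Diagnostics: SNR = biological C>T count / injected artefact count (linear
in the signal); SNS = cosine between biology and W₁ on C>T channels
(scale-invariant). Correction accuracy is the cosine between true and
corrected catalogues on C>T channels; accuracy > 0.90 (strict) counts as
well-corrected. Samples whose biology carries no C>T mutations get NaN
sentinels and are excluded from summaries.

What the simulator does *not* emulate: read-level error processes,
allele-frequency or orientation-bias structure of real FFPE artefacts,
germline leakage, inter-channel correlation of signature activities within
cancer types, and fixation-time kinetics. Passing the synthetic benchmarks
therefore demonstrates correctness of the decomposition machinery under
the stated generative model, not end-to-end performance on sequencing data.

## Problem sizes and numerical choices

The shipped evaluations run at desk scale, chosen so the whole suite and
the acceptance script each complete in minutes on one CPU: the recovery
benchmark uses 50 samples (mixture biology of 10⁴–10⁵ mutations from a
Dirichlet(2,2,2) activity draw, 10⁴ unrepaired artefacts, 100 restarts),
the SNR ladder 5 levels × 20 samples at a fixed artefact load of 10⁴, and
optimizer monotonicity 1000 random instances × 5 update steps. Cohort
summaries report 95% t-intervals of bin means over quantile bins (0–10 /
10–50 / 50–90 / 90–100%) of the biological C>T load. Monotonicity of noisy
bin means is asserted within the sampling error of the means, since
saturated accuracy levels (>0.99) tie to within sampling noise.

Degenerate inputs are rejected rather than coerced: empty catalogues in
analytic operations, zero masked sub-vectors in cosine similarity, zero
panel opportunity under observed counts, all-T>C mass in 80c
renormalization. Zero-count catalogues remain representable so filtering
pipelines stay total.
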