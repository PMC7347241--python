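# Methods

## Scope and data model

`spectclone` infers B cell clonal families from annotated heavy-chain
rearrangements (AIRR or legacy Change-O TSV). V(D)J annotation is assumed
upstream; each record needs an IMGT-gapped `sequence_alignment`, the
matching `germline_alignment`, `v_call`/`j_call` (possibly comma-separated
multiple assignments), and the `junction`. Processing is: productive filter
→ collapse to unique sequences → VJ(ℓ)-grouping → per-group spectral
clustering → propagation of clone labels back to all input rows.

The productive filter applies three conjunctive criteria: the annotated
functionality flag, a stop-codon scan over complete codons of the
gap-stripped alignment in frame 1 (IMGT alignments are codon-aligned from
position 1), and junction length divisible by 3. Collapsing keys on the
full sequence alignment, not the junction alone, so the integrated model
sees every distinct V/J mutation pattern.

## VJ(ℓ)-grouping

Clones cannot change germline gene or junction length (point-mutation
assumption), so clustering is confined to groups sharing IGHV gene, IGHJ
gene (allele-stripped) and junction length. Because annotation tools emit
multiple gene assignments for ambiguous reads, the default "chain" grouping
connects two sequences whenever their V-gene sets intersect and their
J-gene sets intersect, and takes connected components; "exact" grouping
(literal gene-set keys) is kept for diagnostics. Junction length is a hard
key in both modes. Each group's mutations are called against an *effective
germline*: the per-position minimal IUPAC code covering every base observed
across the group's distinct germline alleles, so allele differences are
never mistaken for mutations. Groups of size 1 bypass clustering and become
singleton clones; size-2 groups merge only when their weighted distance is
exactly 0 (the eigen-gap is meaningless at m = 2; the rule is conservative).

## Pairwise SHM model

For a pair (i, j) each informative position n (effective germline not N or
gap, position outside the masked junction/CDR3 span, both bases A/C/G/T) is
flagged α (one sequence mutated), β (both mutated to different bases) or γ
(both mutated to the same base). γ requires the *same* substituted base:
two different substitutions at one position are independent events, not a
shared inheritance. The normaliser ν_ij is the mean of the two per-sequence
informative-position counts (the alternative — counting positions
informative in both — differs only when non-ACGT characters are asymmetric
between the pair; the mean was chosen as it penalises low-quality sequences
symmetrically).

T = (Σα + 2Σβ + 2Σγ)/ν and H = 2Σγ/ν give total and shared mutation loads;
H ≤ T always. Shared mutations at SHM hot spots are discounted by
M = Π(1 − μ(n)) over shared positions, with μ(n) the 5-mer targeting-model
mutability of the germline context, averaged over the group's distinct
germline alleles (ambiguous IUPAC motifs average over compatible ACGT
5-mers; windows off the sequence end or containing N contribute 0). The
final similarity

S = M · exp(−(T−H)²/2σ_T²) · (1 − exp(−H²/2σ_H²))

uses σ_T, σ_H = population standard deviations of the upper-triangular
off-diagonal entries of T and H within the group, so the meaning of "many
shared mutations" adapts to each group's local mutation frequency. When a
σ is 0 (all pairs identical) the Gaussian is defined as 1 at 0 and 0
elsewhere, which degenerates the formula gracefully. S is forced to 0
wherever H = 0: without shared mutations the junction signal alone decides.

Targeting models are two-column TSVs (motif, mutability ∈ [0, 1]);
`TargetingModel.uniform(v)` builds flat models (v = 0 disables damping).
The simulator's built-in model puts weight 0.30 on classic AID hot-spot
5-mer contexts (WRC read toward the mutated C, and the reverse-complement
GYW), 0.02 on SYC-type cold spots, 0.10 elsewhere.

## Graph construction and model selection

The weighted distance is W = X (recombination-based) or W = (1−S)·X
(integrated). X is the Hamming distance over junctions or CDR3s, ignoring
positions with non-ACGT characters in either sequence (N matches anything);
CDR3 mode requires junction length ≥ 7 and falls back to the junction
otherwise. In the integrated model the mask excluded from the SHM analysis
matches the targeted region, so in CDR3 mode the conserved junction flanks
are analysed for SHM.

**Local scales.** For each row of W the off-diagonal distances are examined
for a "relatively large gap". A Gaussian kernel density estimate (Silverman
bandwidth, 512-point grid over the data range) is scanned for local minima
(first finite difference changing sign negative → positive). A minimum
qualifies only if its density is below half of the lower flanking maximum:
junction Hamming distances are integers, and the shallow dips between
adjacent-integer peaks of a sparsely sampled single clone are quantization
artifacts, not neighbourhood boundaries. Among qualifying minima the one
with the lowest density wins (ties: the smallest location), and w_i is the
largest distance strictly below it. Without a qualifying minimum, w_i falls
back to the lower edge of the largest gap in the rank-ordered *positive*
distances — a gap starting at 0 would make exact-duplicate sequences their
own neighbourhood — with exact ties broken toward the larger distance,
keeping neighbourhoods maximal for unimodal rows. A zero scale is replaced
by the smallest positive distance in the row (or 1 for an all-zero row).

**Spectral step.** K_ij = exp(−W_ij²/(w_i w_j)) (fully connected, K_ii = 1),
L = D − K unnormalised, eigenvectors used raw. The number of clones k is
chosen by the eigen-gap: clone components appear as eigenvalues numerically
close to zero (between-clone kernels vanish at typical between-clone
distances), so candidate gaps are those whose left edge lies within 5% of
the spectral maximum, and the largest such gap wins (ties toward smaller
k). Gaps higher in the spectrum are produced by blocks of identical
sequences (degree degeneracies) and weakly attached clone members, not by
clone structure; an unrestricted argmax over all gaps shatters single-clone
groups into k ≈ m pieces. k-means (k-means++, 10 restarts) on the k bottom
eigenvectors assigns members; the per-group k-means seed derives from the
run seed and the group id (CRC32), so results are independent of group
order and thread count. Eigen-decomposition failures retry once with 1e-12
symmetric jitter, then fall back to the recombination-based model for that
group with a warning.

## Synthetic repertoires

The simulator emulates single-lineage bulk BCR simulation directly in
annotated coordinates. A built-in pool of 12 synthetic V templates (300 nt)
and 4 J templates (51 nt), built from stop-free codons, ships with the
package; the first two V genes carry a second allele one substitution away
to exercise the effective-germline path. A clone's founder is
V + random insert + J with the insert drawn from stop-free codons (the D
segment is folded into the insert; grouping never uses D calls); the
junction spans the last V codon, the insert and the first J codon, so
junction lengths are multiples of 3 in 21–60 nt. Clones expand along a
random lineage: starting from the root branch (germline → MRCA, mutated
like any other branch, which creates clone-wide shared mutations), a random
leaf either bifurcates (probability 0.5) or accumulates further mutations
in place until the clone size is reached. Each branch carries
Poisson(rate × length) substitutions at positions drawn proportionally to
the 5-mer targeting model.

Study conditions (desk scale): repertoire size ~ Normal(2000, 200); clone
sizes round(amplitude · Gamma(0.75, 0.75)) + 1 with amplitude ~
Normal(20, 2); branch mutation rate 0.0027 substitutions/site (≈1
substitution per branch on a ~370 nt read, leaf mutation frequencies
1–3%). The rate was chosen analytically: the fraction of non-singleton
clones without any shared mutation is dominated by two-member clones whose
root branch is unmutated (probability e^(−λ) with λ ≈ 1 expected root
substitutions), which together with the clone-size distribution puts the
shared-SHM prevalence near 95%. Simulated SHM can create stop codons;
such reads are removed by the productive filter exactly as annotated
non-productive reads would be (typically 30–40% at this mutation load), so
a 2000-read repertoire yields roughly 1000–1400 unique sequences.

What the simulator does *not* model: insertions/deletions, sequencing
error, PCR amplification bias, selection, isotypes, light chains, and
realistic germline similarity between distinct V genes. The last point
matters for interpretation: with fully random junction inserts, unrelated
clones essentially never collide in junction space, so specificity is near
1 for every configuration and passing tests demonstrate correct recovery of
well-separated clones plus internal consistency of the SHM machinery — not
the full difficulty of real repertoires, where distinct clones can share
similar junctions. Relatedly, at this scale the integrated model's
advantage over the recombination-based model (bridging sub-lineages via
shared root-branch mutations, isolating low-sharing outliers) has little
signal to act on, and the two models differ only on a handful of borderline
groups; the dedicated ordering check in the test suite documents this
honestly rather than asserting an advantage the desk-scale conditions
cannot produce.

## Evaluation protocols

Accuracy is measured over unordered sequence pairs (TP: same clone in truth
and prediction; TN: different in both; FP/FN accordingly), with sensitivity
TP/(TP+FN), specificity TN/(TN+FP) and precision TP/(TP+FP); 0/0 ratios are
reported as undefined and excluded from averages. Pairs are evaluated over
unique sequences by default (the clustering substrate); duplicate-expanded
evaluation is available and is used for the zero-mutation recovery check,
where every clone collapses to a single unique sequence. Metrics are
macro-averaged per repertoire.

The negative-control experiment compares each true clone's mean pairwise H
(V/J segments, junction masked) against size-matched random samples drawn
without replacement from the same VJ(ℓ)-group (excluding the clone's exact
member set); the empirical p-value is the fraction of control means at
least as large. Clones equal to their whole group have no distinct controls
and are skipped — meaningful controls require multi-clone groups, which at
desk scale are produced with a reduced gene pool and narrowed
junction-length range. The cross-individual protocol estimates specificity
without ground truth: single sequences spiked from other repertoires into a
base repertoire must come out as singletons; any larger grouping is a false
positive by construction.

## Numerical and reproducibility notes

- All randomness (simulation, control sampling, spike cycles, k-means)
  derives from explicit integer seeds; identical inputs and seeds give
  byte-identical outputs at any thread count.
- Oracle tests check the vectorised T/H/M/S pipeline against a pure-python
  position-enumeration implementation to 1e-12 on hundreds of random
  groups, including IUPAC germlines, N bases, masks and allele averaging.
- The acceptance study (5 repertoires × 3 configurations) runs in ~25 s on
  one CPU; problem sizes were chosen so the whole test suite stays
  interactive while clone and group sizes remain large enough for the
  spectral machinery to be exercised (groups up to ~50 unique sequences).
- Degenerate inputs: empty groups cannot occur (grouping partitions the
  input); all-zero distance rows get unit scales; σ = 0 and μ = 1 are
  handled without division by zero or log of zero (mutability 1 forces
  M = 0 via clipping at 1e-300).
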