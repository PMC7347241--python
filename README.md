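# spectclone

Spectral clustering inference of B cell clonal families from AIRR-seq
heavy-chain data, integrating junction/CDR3 sequence similarity with shared
somatic hypermutation (SHM) patterns in the V and J segments.

## The problem

Members of a B cell clone descend from a single V(D)J rearrangement and
differ only by somatic hypermutation. Most clonal-inference tools group
sequences by IGHV gene, IGHJ gene, and junction length, then cluster on
junction-sequence similarity alone. That discards a second signal: clonally
related cells inherit SHMs from common ancestors, so truly related pairs
share substitutions at identical V/J-segment positions far more often than
unrelated pairs from the same germline background. `spectclone` combines
both signals in a self-tuning spectral clustering framework.

## The model

Within each VJ(ℓ)-group (sequences sharing V gene, J gene and junction
length ℓ), for every sequence pair (i, j) compared against the group's
effective (IUPAC-union) germline:

- **X** — Hamming distance between junctions, or CDR3s (junction minus the
  3 nt conserved flank at each end).
- **T, H** — normalised total and shared mutation counts. Per position a
  pair contributes α (mutated in one sequence), β (both mutated,
  differently) or γ (both mutated to the same base — a shared SHM):

  T_ij = (1/ν_ij) Σ_n [α + 2(β + γ)],  H_ij = (2/ν_ij) Σ_n γ,

  with ν_ij the mean number of informative (A/C/G/T) positions.
- **M** — hot-spot damping, M_ij = Π_n (1 − μ_ij(n)) over shared positions,
  where μ is the 5-mer targeting-model mutability of the germline context
  (shared mutations at SHM hot spots are weak evidence of clonality).
- **S** — SHM similarity,

  S_ij = M_ij · exp(−(T_ij−H_ij)²/2σ_T²) · (1 − exp(−H_ij²/2σ_H²)) ∈ [0, 1),

  which is zero whenever no mutation is shared.
- **W** — weighted distance: W = X (recombination-based model) or
  W = (1 − S)·X (integrated model; shared SHMs act as a spring pulling
  clonal pairs together).
- **Clustering** — a fully connected Gaussian kernel
  K_ij = exp(−W_ij²/(w_i w_j)) with per-sequence local scales w_i chosen at
  a density gap in each row's distance profile; the number of clones k is
  the eigen-gap of the unnormalised Laplacian L = D − K, and k-means on the
  k bottom eigenvectors yields the partition.

The four configurations are named `ham-junc`, `ham-cdr3`, `ham-shm-junc`
and `ham-shm-cdr3`.

The package also ships a ground-truth repertoire simulator (random V(D)J
recombination from a germline pool, gamma-distributed clone sizes,
stochastic branching lineage trees, 5-mer context-dependent point
substitutions) and pairwise evaluation protocols (sensitivity / specificity
/ precision over sequence pairs, negative-control shared-SHM enrichment,
cross-individual spike-in specificity).

## Worked example

Simulate a labelled repertoire, assign clones with the integrated
CDR3-targeted model, and score the result against the truth:

```bash
spectclone simulate --output sim.tsv --seed 7 --n-sequences 300 --n-sequences-sd 10
# simulated 300 sequences in 21 clones

spectclone define-clones --input sim.tsv --output clones.tsv \
    --method integrated --target cdr3 --seed 1 --report report.json
# ham-shm-cdr3: 169 unique sequences, 19 VJ(l)-groups, 19 clones

spectclone evaluate --predicted clones.tsv --truth sim.tsv
# {
#   "TP": 1740, "FP": 0, "TN": 13485, "FN": 0,
#   "sensitivity": 1.0, "specificity": 1.0, "precision": 1.0
# }
```

The first step writes an AIRR TSV with a ground-truth `clone_id` column.
`define-clones` filters non-productive reads (here 125 sequences acquired
stop codons through simulated SHM), collapses identical reads into unique
sequences, partitions them into VJ(ℓ)-groups and clusters each group; the
output TSV carries the inferred `clone_id` for every retained input row.
`evaluate` counts unordered sequence pairs: all 1740 truly clonal pairs were
recovered (sensitivity 1.0) with no false links (specificity and precision
1.0). The same operations are available as library functions
(`spectclone.simulate_repertoire`, `spectclone.assign_clones`,
`spectclone.pairwise_confusion`, ...).

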