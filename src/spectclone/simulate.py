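"""Ground-truth-labelled synthetic BCR heavy-chain repertoires.

Each clone starts from a random V(D)J recombination event drawn from a
germline pool (the D segment is folded into a random junction insert) and
expands along a stochastic branching lineage tree.  Every branch carries a
Poisson number of point substitutions placed by a 5-mer context-dependent
targeting model; leaves inherit all ancestral mutations, which creates the
shared somatic-hypermutation signal that clonal inference exploits.  Clone
sizes follow a scaled gamma distribution and the repertoire size is drawn
from a normal distribution.

Sequences are emitted directly in annotated coordinates (the germline
alignment, gene calls and junction are known by construction), so the
output feeds the clonal inference pipeline without an annotation step.
No indels, sequencing error, or selection are modelled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .airr_io import Rearrangement, RearrangementSet, STOP_CODONS, to_dataframe
from .shm_model import TargetingModel

_BASES = "ACGT"
_NON_STOP_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3) if "".join(c) not in STOP_CODONS
]


@dataclass(frozen=True)
class GermlinePool:
    """Named V and J germline templates; keys include allele suffixes (*01)."""

    v: dict
    j: dict

    def __post_init__(self):
        if not self.v or not self.j:
            raise ValueError("germline pool must contain at least one V and one J template")


@dataclass
class SimulationParams:
    """Study conditions for the synthetic repertoires.

    Desk-scale defaults: ~2000 sequences per repertoire with clone sizes
    round(amplitude * Gamma(0.75, 0.75)) + 1 and amplitude ~ N(20, 2);
    the full-scale study conditions use 600k/100k sequences and amplitude
    N(1000, 100).  ``mutation_rate_per_branch`` is the per-site substitution
    probability on each lineage branch (default ~1 substitution per branch
    on a ~370 nt read, giving leaf mutation frequencies of 1-3%).
    """

    n_sequences_mean: float = 2000.0
    n_sequences_sd: float = 200.0
    clone_size_gamma_shape: float = 0.75
    clone_size_gamma_scale: float = 0.75
    clone_size_amplitude_mean: float = 20.0
    clone_size_amplitude_sd: float = 2.0
    mutation_rate_per_branch: float = 0.0027
    branching_prob: float = 0.5
    junction_length_range: tuple[int, int] = (21, 60)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.junction_length_range
        if lo % 3 or hi % 3 or lo < 9 or hi < lo:
            raise ValueError("junction_length_range must be multiples of 3, >= 9")
        if not (0 < self.branching_prob < 1):
            raise ValueError("branching_prob must lie in (0, 1)")
        if self.mutation_rate_per_branch < 0:
            raise ValueError("mutation rate must be non-negative")


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame sequence with no stop codons."""
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def toy_germline_pool(
    n_v: int = 12,
    n_j: int = 4,
    v_length: int = 300,
    j_length: int = 51,
    n_dual_allele_v: int = 2,
    seed: int = 20210,
) -> GermlinePool:
    """Built-in synthetic germline pool (no download required).

    ``n_v`` V genes of ``v_length`` nt and ``n_j`` J genes of ``j_length``
    nt, all built from stop-free codons so founders are productive.  The
    first ``n_dual_allele_v`` V genes get a second allele differing by one
    synonymous-position substitution, exercising the allele-grouping path.
    """
    if v_length % 3 or j_length % 3:
        raise ValueError("template lengths must be multiples of 3")
    rng = np.random.default_rng(seed)
    v = {}
    for i in range(1, n_v + 1):
        seq = _random_coding(rng, v_length // 3)
        v[f"SVH{i}-1*01"] = seq
        if i <= n_dual_allele_v:
            pos = int(rng.integers(30, v_length - 60))
            old = seq[pos]
            new = rng.choice([b for b in _BASES if b != old])
            allele2 = seq[:pos] + str(new) + seq[pos + 1 :]
            codon_start = 3 * (pos // 3)
            if allele2[codon_start : codon_start + 3] not in STOP_CODONS:
                v[f"SVH{i}-1*02"] = allele2
    j = {f"SJH{i}*01": _random_coding(rng, j_length // 3) for i in range(1, n_j + 1)}
    return GermlinePool(v=v, j=j)


def default_shm_targeting() -> TargetingModel:
    """Simple hot/cold-spot 5-mer targeting model used by the simulator.

    Classic AID hot-spot motifs (WRC at the centre read 5'->3', and the
    reverse-complement GYW context) get elevated mutability, SYC-type
    cold-spots get reduced mutability, everything else a flat baseline.
    """
    W, R, Y, S = set("AT"), set("AG"), set("CT"), set("GC")
    table = {}
    for p in itertools.product(_BASES, repeat=5):
        m = "".join(p)
        hot = (m[2] == "C" and m[0] in W and m[1] in R) or (
            m[2] == "G" and m[3] in Y and m[4] in W
        )
        cold = (m[2] == "C" and m[0] in S and m[1] in Y) or (
            m[2] == "G" and m[3] in R and m[4] in S
        )
        table[m] = 0.30 if hot else (0.02 if cold else 0.10)
    return TargetingModel(table, name="toy-hotspot")


@dataclass
class SimulatedClone:
    clone_id: str
    v_call: str
    j_call: str
    germline: str
    junction_length: int
    root_branch_mutations: int
    leaves: list[str] = field(default_factory=list)


def sample_recombination(
    params: SimulationParams, pool: GermlinePool, rng: np.random.Generator
) -> tuple[str, str, str, int]:
    """One V(D)J recombination event: (germline, v_call, j_call, junction_length).

    The founder is V + random insert + J with the insert drawn from
    stop-free codons (productive rearrangement); the junction spans the last
    V codon, the insert, and the first J codon.
    """
    v_call = str(rng.choice(sorted(pool.v)))
    j_call = str(rng.choice(sorted(pool.j)))
    lo, hi = params.junction_length_range
    ell = int(rng.choice(np.arange(lo, hi + 1, 3)))
    insert = _random_coding(rng, (ell - 6) // 3)
    germline = pool.v[v_call] + insert + pool.j[j_call]
    return germline, v_call, j_call, ell


def _mutation_weights(seq: str, tm: TargetingModel) -> np.ndarray:
    w = np.zeros(len(seq))
    for n in range(2, len(seq) - 2):
        w[n] = tm[seq[n - 2 : n + 3]]
    return w


def _mutate_branch(
    seq: str, params: SimulationParams, tm: TargetingModel, rng: np.random.Generator
) -> tuple[str, int]:
    """Apply Poisson(rate * length) targeted substitutions along one branch."""
    n_mut = int(rng.poisson(params.mutation_rate_per_branch * len(seq)))
    if n_mut == 0:
        return seq, 0
    chars = list(seq)
    weights = _mutation_weights(seq, tm)
    total = weights.sum()
    for _ in range(n_mut):
        if total > 0:
            pos = int(rng.choice(len(chars), p=weights / total))
        else:
            pos = int(rng.integers(0, len(chars)))
        old = chars[pos]
        chars[pos] = str(rng.choice([b for b in _BASES if b != old]))
    return "".join(chars), n_mut


def evolve_clone(
    germline: str,
    size: int,
    params: SimulationParams,
    tm: TargetingModel,
    rng: np.random.Generator,
) -> tuple[list[str], int]:
    """Evolve ``size`` leaves along a stochastic branching lineage tree.

    The root branch (germline -> most recent common ancestor) is mutated
    like any other branch, so its substitutions are shared by every leaf.
    At each step a random leaf either bifurcates (probability
    ``branching_prob``) or accumulates further mutations in place.  Returns
    the leaf sequences and the root-branch mutation count.
    """
    if size < 1:
        raise ValueError("clone size must be >= 1")
    mrca, n_root = _mutate_branch(germline, params, tm, rng)
    leaves = [mrca]
    while len(leaves) < size:
        i = int(rng.integers(0, len(leaves)))
        if rng.random() < params.branching_prob:
            parent = leaves.pop(i)
            child_a, _ = _mutate_branch(parent, params, tm, rng)
            child_b, _ = _mutate_branch(parent, params, tm, rng)
            leaves.extend([child_a, child_b])
        else:
            leaves[i], _ = _mutate_branch(leaves[i], params, tm, rng)
    return leaves, n_root


def _draw_clone_sizes(
    total: int, params: SimulationParams, rng: np.random.Generator
) -> list[int]:
    amplitude = max(1.0, rng.normal(params.clone_size_amplitude_mean, params.clone_size_amplitude_sd))
    sizes: list[int] = []
    acc = 0
    while acc < total:
        g = rng.gamma(params.clone_size_gamma_shape, params.clone_size_gamma_scale)
        size = int(round(amplitude * g)) + 1
        size = min(size, total - acc)
        if size < 1:
            size = 1
        sizes.append(size)
        acc += size
    return sizes


def simulate_repertoire(
    params: SimulationParams,
    pool: GermlinePool | None = None,
    tm: TargetingModel | None = None,
) -> tuple[RearrangementSet, pd.DataFrame, pd.DataFrame]:
    """Simulate one repertoire; returns (records, truth table, clone metadata).

    The truth table maps sequence_id -> true clone_id; the metadata table
    carries per-clone provenance (gene calls, root-branch mutation count,
    clone size).  Deterministic given ``params.seed``.
    """
    pool = pool or toy_germline_pool()
    tm = tm or default_shm_targeting()
    rng = np.random.default_rng(params.seed)
    total = max(1, int(round(rng.normal(params.n_sequences_mean, params.n_sequences_sd))))
    sizes = _draw_clone_sizes(total, params, rng)

    records: list[Rearrangement] = []
    truth_rows = []
    meta_rows = []
    seq_counter = 0
    v_length = len(next(iter(pool.v.values())))
    for c_idx, size in enumerate(sizes, start=1):
        clone_id = f"C{c_idx}"
        germline, v_call, j_call, ell = sample_recombination(params, pool, rng)
        leaves, n_root = evolve_clone(germline, size, params, tm, rng)
        meta_rows.append(
            {
                "clone_id": clone_id,
                "v_call": v_call,
                "j_call": j_call,
                "junction_length": ell,
                "size": size,
                "root_branch_mutations": n_root,
            }
        )
        start = v_length - 3
        for leaf in leaves:
            seq_counter += 1
            sid = f"S{seq_counter}"
            records.append(
                Rearrangement(
                    sequence_id=sid,
                    sequence_alignment=leaf,
                    germline_alignment=germline,
                    v_call=v_call,
                    j_call=j_call,
                    junction=leaf[start : start + ell],
                    junction_length=ell,
                    functional_flag=True,
                    duplicate_count=1,
                )
            )
            truth_rows.append({"sequence_id": sid, "clone_id": clone_id})
    rs = RearrangementSet(records=records, provenance=f"simulate:seed={params.seed}")
    return rs, pd.DataFrame(truth_rows), pd.DataFrame(meta_rows)


def write_simulation(rs: RearrangementSet, truth: pd.DataFrame, path, meta=None, meta_path=None):
    """Write a simulated repertoire as AIRR TSV with a truth clone_id column."""
    df = to_dataframe(rs).merge(truth, on="sequence_id")
    df.to_csv(path, sep="\t", index=False)
    if meta is not None and meta_path is not None:
        meta.to_csv(meta_path, sep="\t", index=False)
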