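"""Shared somatic-hypermutation (SHM) similarity between sequence pairs.

Members of a B cell clone inherit mutations from common ancestors, so pairs
of clonally related sequences share substitutions at identical positions in
the V and J segments.  This module quantifies that signal.  For a pair
(i, j) compared against the group's effective germline, every informative
position n is flagged as

* alpha(n): mutated in exactly one of the two sequences,
* beta(n):  mutated in both, to different bases,
* gamma(n): mutated in both, to the same base (a shared mutation).

The per-pair totals are normalised by nu_ij, the average number of
informative (A/C/G/T) positions of the two sequences, giving the total- and
shared-mutation matrices

    T_ij = (1/nu_ij) * sum_n [alpha + 2(beta + gamma)]
    H_ij = (2/nu_ij) * sum_n gamma

Shared mutations at SHM hot-spots are expected even between unrelated
sequences, so a damping matrix built from a 5-mer targeting model discounts
them:

    M_ij = prod_{n: gamma(n)=1} (1 - mu_ij(n))

where mu_ij(n) is the germline motif mutability averaged over the group's
distinct germline alleles.  The final SHM similarity is

    S_ij = M_ij * exp(-(T_ij - H_ij)^2 / 2 sigma_T^2)
                * (1 - exp(-H_ij^2 / 2 sigma_H^2))

with sigma_T, sigma_H the standard deviations of T and H within the group,
so that the similarity scale adapts to the local mutation load.  S is zero
whenever no mutation is shared (H = 0).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .airr_io import GAP_CHARS, strip_gaps
from .grouping import IUPAC_TO_SET, VJLGroup

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


class TargetingModelError(ValueError):
    pass


@dataclass(frozen=True)
class TargetingModel:
    """5-mer motif -> mutability map in [0, 1] (S5F-style hot/cold spots)."""

    mutability: dict
    name: str = "custom"

    def __post_init__(self):
        for motif, value in self.mutability.items():
            if len(motif) != 5 or any(c not in _BASE_CODE for c in motif):
                raise TargetingModelError(f"invalid motif: {motif!r}")
            if not (0.0 <= value <= 1.0):
                raise TargetingModelError(f"mutability outside [0,1] for {motif}: {value}")

    def __getitem__(self, motif: str) -> float:
        return self.mutability.get(motif, 0.0)

    @classmethod
    def uniform(cls, value: float) -> "TargetingModel":
        if not (0.0 <= value <= 1.0):
            raise TargetingModelError(f"uniform mutability outside [0,1]: {value}")
        motifs = ("".join(p) for p in itertools.product(_BASES, repeat=5))
        return cls({m: value for m in motifs}, name=f"uniform:{value}")


def load_targeting_model(source) -> TargetingModel:
    """Load a targeting model from a two-column TSV (motif, mutability).

    ``{"uniform": v}`` builds the flat model with mutability ``v`` for every
    motif.  Motifs absent from a file get mutability 0 (no damping).
    """
    if isinstance(source, TargetingModel):
        return source
    if isinstance(source, dict) and "uniform" in source:
        return TargetingModel.uniform(float(source["uniform"]))
    df = pd.read_csv(source, sep="\t")
    if "motif" not in df.columns or "mutability" not in df.columns:
        raise TargetingModelError("targeting model file needs columns: motif, mutability")
    table = {str(m).upper(): float(v) for m, v in zip(df["motif"], df["mutability"])}
    return TargetingModel(table, name=str(source))


def motif_mutability(tm: TargetingModel, germline: str, pos: int) -> float:
    """Mutability of the 5-mer centred at ``pos`` of the gap-stripped germline.

    IUPAC-ambiguous motifs average over all compatible ACGT 5-mers; windows
    running off an end or containing N return 0.
    """
    stripped = strip_gaps(germline)
    if not (0 <= pos < len(stripped)):
        return 0.0
    if pos < 2 or pos > len(stripped) - 3:
        return 0.0
    window = stripped[pos - 2 : pos + 3]
    if "N" in window:
        return 0.0
    sets = []
    for c in window:
        s = IUPAC_TO_SET.get(c)
        if s is None:
            return 0.0
        sets.append(sorted(s))
    motifs = ["".join(p) for p in itertools.product(*sets)]
    return float(np.mean([tm[m] for m in motifs]))


@dataclass
class MutationProfile:
    """Per-position mutation flags for one sequence pair."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    shared_positions: list[int]
    nu: float

    @property
    def n_alpha(self) -> int:
        return int(self.alpha.sum())

    @property
    def n_beta(self) -> int:
        return int(self.beta.sum())

    @property
    def n_gamma(self) -> int:
        return int(self.gamma.sum())


def _encode(seqs: list[str]) -> np.ndarray:
    """(m, L) uint8 codes: A,C,G,T -> 0..3, everything else (gaps, N, IUPAC) -> 4."""
    arr = np.full((len(seqs), len(seqs[0])), 4, dtype=np.uint8)
    for s, seq in enumerate(seqs):
        for n, c in enumerate(seq):
            arr[s, n] = _BASE_CODE.get(c, 4)
    return arr


def _germline_tables(egl: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position (informative, allowed-base) tables for an IUPAC germline.

    ``informative[n]`` is False at gaps and N; ``allowed[b, n]`` says base b
    belongs to the germline's IUPAC set at n (i.e. is NOT a mutation).
    """
    L = len(egl)
    informative = np.zeros(L, dtype=bool)
    allowed = np.zeros((4, L), dtype=bool)
    for n, c in enumerate(egl):
        if c in GAP_CHARS or c == "N":
            continue
        s = IUPAC_TO_SET.get(c)
        if s is None or s == IUPAC_TO_SET["N"]:
            continue
        informative[n] = True
        for b in s:
            allowed[_BASE_CODE[b], n] = True
    return informative, allowed


def classify_pair_mutations(
    seq_i: str, seq_j: str, egl: str, mask: set[int] | frozenset[int] = frozenset()
) -> MutationProfile:
    """Flag alpha/beta/gamma mutations for one pair against the effective germline.

    ``mask`` is the set of alignment positions excluded from the analysis
    (the junction or CDR3 span, depending on the targeted region).  A
    sequence is mutated at n iff its base is A/C/G/T and lies outside the
    germline's IUPAC set; positions where either base is non-ACGT carry no
    flags.  nu is the mean of the two per-sequence informative-position
    counts.
    """
    if not (len(seq_i) == len(seq_j) == len(egl)):
        raise ValueError("sequence/germline length mismatch")
    arr = _encode([seq_i, seq_j])
    informative, allowed = _germline_tables(egl)
    unmasked = np.ones(len(egl), dtype=bool)
    if mask:
        unmasked[list(mask)] = False
    valid = informative & unmasked
    is_base = arr < 4
    ok = is_base & valid
    safe = np.where(is_base, arr, 0)
    mut = ok & ~allowed[safe, np.arange(len(egl))[None, :]]
    both_ok = ok[0] & ok[1]
    gamma = mut[0] & mut[1] & (arr[0] == arr[1])
    beta = mut[0] & mut[1] & (arr[0] != arr[1])
    alpha = both_ok & (mut[0] ^ mut[1])
    nu = float((ok[0].sum() + ok[1].sum()) / 2.0)
    return MutationProfile(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        shared_positions=list(np.flatnonzero(gamma)),
        nu=nu,
    )


def _group_arrays(group: VJLGroup, sequences: dict[str, str], mask) -> dict:
    """Vectorised per-group flag matrices shared by T/H and damping."""
    seqs = [sequences[i] for i in group.member_ids]
    L = len(group.effective_germline)
    if any(len(s) != L for s in seqs):
        raise ValueError("group member alignment length mismatch")
    arr = _encode(seqs)
    informative, allowed = _germline_tables(group.effective_germline)
    unmasked = np.ones(L, dtype=bool)
    if mask:
        unmasked[list(mask)] = False
    valid = informative & unmasked
    is_base = arr < 4
    ok = is_base & valid
    safe = np.where(is_base, arr, 0)
    mut = ok & ~allowed[safe, np.arange(L)[None, :]]
    per_base = [(mut & (arr == b)).astype(np.float64) for b in range(4)]
    return {"ok": ok.astype(np.float64), "mut": mut.astype(np.float64), "per_base": per_base}


def mutation_matrices(
    group: VJLGroup, sequences: dict[str, str], mask=frozenset()
) -> tuple[np.ndarray, np.ndarray]:
    """Total- and shared-mutation matrices (T, H) for a VJ(l)-group.

    Fully uninformative pairs (nu = 0) get T = H = 0.
    """
    g = _group_arrays(group, sequences, mask)
    ok, mut, per_base = g["ok"], g["mut"], g["per_base"]
    gamma = sum(pb @ pb.T for pb in per_base)
    both_mut = mut @ mut.T
    beta = both_mut - gamma
    a_half = mut @ (ok - mut).T
    alpha = a_half + a_half.T
    cnt = ok.sum(axis=1)
    nu = (cnt[:, None] + cnt[None, :]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(nu > 0, (alpha + 2.0 * (beta + gamma)) / nu, 0.0)
        H = np.where(nu > 0, 2.0 * gamma / nu, 0.0)
    np.fill_diagonal(T, 0.0)
    np.fill_diagonal(H, 0.0)
    return T, H


def position_mutabilities(group: VJLGroup, tm: TargetingModel) -> np.ndarray:
    """Per alignment position, motif mutability averaged over the group's alleles.

    Positions are alignment coordinates; each allele contributes the
    mutability of its own gap-stripped 5-mer at that position.
    """
    L = len(group.effective_germline)
    mu = np.zeros(L)
    per_allele = []
    for allele in group.germline_alleles:
        vals = np.zeros(L)
        stripped_pos = -1
        for n, c in enumerate(allele):
            if c in GAP_CHARS:
                continue
            stripped_pos += 1
            vals[n] = motif_mutability(tm, allele, stripped_pos)
        per_allele.append(vals)
    mu = np.mean(per_allele, axis=0)
    return mu


def damping_matrix(
    group: VJLGroup,
    tm: TargetingModel,
    sequences: dict[str, str],
    mask=frozenset(),
) -> np.ndarray:
    """Hot-spot damping M_ij = prod over shared positions of (1 - mu(n))."""
    g = _group_arrays(group, sequences, mask)
    mu = position_mutabilities(group, tm)
    log_keep = np.log(np.clip(1.0 - mu, 1e-300, 1.0))
    logM = sum((pb * log_keep[None, :]) @ pb.T for pb in g["per_base"])
    M = np.exp(logM)
    np.fill_diagonal(M, 1.0)
    return M


def _gaussian(x: np.ndarray, sigma: float) -> np.ndarray:
    """exp(-x^2 / 2 sigma^2) with the sigma=0 limit: 1 at x=0, 0 elsewhere."""
    if sigma > 0:
        return np.exp(-(x**2) / (2.0 * sigma**2))
    return np.where(x == 0, 1.0, 0.0)


def _offdiag_std(A: np.ndarray) -> float:
    iu = np.triu_indices_from(A, k=1)
    if iu[0].size == 0:
        return 0.0
    return float(np.std(A[iu]))


def shm_similarity(
    T: np.ndarray,
    H: np.ndarray,
    M: np.ndarray,
    sigma_T: float | None = None,
    sigma_H: float | None = None,
) -> np.ndarray:
    """SHM similarity S in [0, 1); zero wherever H is zero.

    sigma_T / sigma_H default to the population standard deviation of the
    upper-triangular off-diagonal entries of T and H for the group.
    """
    if sigma_T is None:
        sigma_T = _offdiag_std(T)
    if sigma_H is None:
        sigma_H = _offdiag_std(H)
    S = M * _gaussian(T - H, sigma_T) * (1.0 - _gaussian(H, sigma_H))
    S[H == 0] = 0.0
    np.fill_diagonal(S, 0.0)
    return S


def shm_similarity_matrix(
    group: VJLGroup,
    sequences: dict[str, str],
    tm: TargetingModel,
    mask=frozenset(),
) -> np.ndarray:
    """Convenience: T, H, M and S for a group in one call."""
    T, H = mutation_matrices(group, sequences, mask)
    M = damping_matrix(group, tm, sequences, mask)
    return shm_similarity(T, H, M)
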