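"""Self-tuning spectral clustering of VJ(l)-groups into clones.

Within each VJ(l)-group a weighted distance matrix is built from the
junction (or CDR3) Hamming distance X, optionally contracted by the SHM
similarity S:

    W = X                 (recombination-based model)
    W = (1 - S) * X       (integrated model)

The integrated form acts like a spring (Hooke's law, W = kappa*X with
kappa = 1 - S): sequence pairs that share many somatic mutations are pulled
together.  A fully connected graph kernel with per-sequence local scales

    K_ij = exp(-W_ij^2 / (w_i w_j))

is then formed; the scale w_i is found at a density gap in sequence i's
distance profile (self-tuning local scaling).  The number of clones k is
chosen by the largest gap in the spectrum of the unnormalised Laplacian
L = D - K, and k-means on the k bottom eigenvectors yields the partition.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from joblib import Parallel, delayed
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans

from .airr_io import GAP_CHARS, RearrangementSet
from .grouping import VJLGroup, build_vjl_groups
from .shm_model import TargetingModel, _BASE_CODE, shm_similarity_matrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterConfig:
    """Configuration for clonal assignment.

    method: "recomb" uses junction/CDR3 Hamming distance only; "integrated"
    additionally contracts distances by the shared-SHM similarity.
    target: "junction" or "cdr3" (junction minus the 3 nt conserved flank at
    each end).
    """

    method: str = "integrated"
    target: str = "cdr3"
    targeting_model: TargetingModel | None = None
    seed: int = 0
    threads: int = 1
    grouping_mode: str = "chain"

    def __post_init__(self):
        if self.method not in ("recomb", "integrated"):
            raise ValueError(f"unknown method: {self.method!r}")
        if self.target not in ("junction", "cdr3"):
            raise ValueError(f"unknown target: {self.target!r}")
        if self.method == "integrated" and self.targeting_model is None:
            self.targeting_model = TargetingModel.uniform(0.0)

    @property
    def name(self) -> str:
        """Configuration name: ham-junc, ham-cdr3, ham-shm-junc, ham-shm-cdr3."""
        shm = "shm-" if self.method == "integrated" else ""
        region = "junc" if self.target == "junction" else "cdr3"
        return f"ham-{shm}{region}"


@dataclass
class ClonePartition:
    """Clone assignments for unique sequences plus per-group provenance."""

    assignments: dict[str, str]
    per_group: dict[str, dict] = field(default_factory=dict)
    method: str = "integrated"
    target_region: str = "cdr3"
    seed: int = 0

    def expand(self, collapse_map: dict[str, str]) -> dict[str, str]:
        """Propagate clone ids to all original (pre-collapse) sequence ids."""
        return {orig: self.assignments[rep] for orig, rep in collapse_map.items()}


def junction_distance_matrix(junctions: list[str], target: str = "junction") -> np.ndarray:
    """Pairwise Hamming distance over junctions (or CDR3s, dropping 3 nt flanks).

    Positions where either base is not A/C/G/T are not counted (N matches
    anything).  All junctions must share one length; CDR3 mode needs length
    >= 7 and falls back to the full junction otherwise.
    """
    lengths = {len(j) for j in junctions}
    if len(lengths) != 1:
        raise ValueError("junction length mismatch within group")
    ell = lengths.pop()
    if target == "cdr3":
        if ell < 7:
            logger.warning("junction length %d < 7: falling back to junction target", ell)
        else:
            junctions = [j[3 : ell - 3] for j in junctions]
    arr = np.full((len(junctions), len(junctions[0]) or 1), 4, dtype=np.uint8)
    for s, j in enumerate(junctions):
        for n, c in enumerate(j):
            arr[s, n] = _BASE_CODE.get(c, 4)
    ok = (arr < 4).astype(np.float64)
    eq = sum(((arr == b) & (arr < 4)).astype(np.float64) @ ((arr == b).astype(np.float64)).T
             for b in range(4))
    both = ok @ ok.T
    X = both - eq
    np.fill_diagonal(X, 0.0)
    return X


def weighted_distance(X: np.ndarray, S: np.ndarray | None, method: str) -> np.ndarray:
    """W = X (recomb) or W = (1 - S) * X (integrated)."""
    if method == "recomb" or S is None:
        return X.copy()
    return (1.0 - S) * X


def _row_scale(d: np.ndarray) -> float:
    """Distance-gap scale for one row of W (see local_scales)."""
    if d.max() == d.min():
        return float(d[0])
    try:
        kde = gaussian_kde(d, bw_method="silverman")
        grid = np.linspace(d.min(), d.max(), 512)
        dens = kde(grid)
        sign = np.sign(np.diff(dens))
        # extrema from sign changes of the first finite difference; a local
        # minimum follows a local maximum when the sign flips neg -> pos
        minima, maxima = [], [0]
        prev = 0.0
        for i in range(len(sign)):
            if sign[i] == 0:
                continue
            if prev < 0 and sign[i] > 0:
                minima.append(i)
            elif prev > 0 and sign[i] < 0:
                maxima.append(i)
            prev = sign[i]
        maxima.append(len(dens) - 1)
        # a qualifying minimum must be a genuine valley, not a shallow dip
        # between quantization peaks of integer Hamming rows: its density
        # must fall below half of the lower flanking peak
        qualifying = []
        for m_idx in minima:
            left = max((x for x in maxima if x < m_idx), default=0)
            right = min((x for x in maxima if x > m_idx), default=len(dens) - 1)
            if dens[m_idx] < 0.5 * min(dens[left], dens[right]):
                qualifying.append(m_idx)
        if qualifying:
            best = qualifying[int(np.argmin(dens[qualifying]))]
            loc = grid[best]
            below = d[d < loc]
            if below.size:
                return float(below.max())
    except np.linalg.LinAlgError:
        pass
    # fallback: lower edge of the largest gap in the rank-ordered positive
    # distances (a gap starting at 0 would make exact duplicates their own
    # neighborhood); exact ties break toward the larger distance, keeping
    # the neighborhood maximal rather than splitting a uniform cloud
    s = np.sort(d[d > 0])
    if s.size == 0:
        return 0.0
    gaps = np.diff(s)
    if gaps.size == 0:
        return float(s[0])
    idx = int(len(gaps) - 1 - np.argmax(gaps[::-1]))
    return float(s[idx])


def local_scales(W: np.ndarray) -> np.ndarray:
    """Per-sequence local scaling parameters w_i from the distance-gap procedure.

    For each row the off-diagonal weighted distances are examined: a Gaussian
    kernel density estimate (Silverman bandwidth, 512-point grid over the
    data range) is scanned for local minima, and w_i is the largest distance
    strictly below the lowest-density minimum.  Without a qualifying minimum,
    w_i falls back to the lower edge of the largest gap in the rank-ordered
    distances.  Zero scales are replaced by the smallest positive distance in
    the row (or 1 when the row is all zero).
    """
    m = W.shape[0]
    if m < 2:
        return np.ones(m)
    w = np.empty(m)
    for i in range(m):
        d = np.delete(W[i], i)
        w[i] = _row_scale(d)
        if w[i] == 0:
            positive = d[d > 0]
            w[i] = float(positive.min()) if positive.size else 1.0
    return w


def kernel_matrix(W: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gaussian graph kernel K_ij = exp(-W_ij^2 / (w_i w_j))."""
    if np.any(w <= 0):
        raise ValueError("local scales must be strictly positive")
    K = np.exp(-(W**2) / np.outer(w, w))
    np.fill_diagonal(K, 1.0)
    return K


def laplacian(K: np.ndarray) -> np.ndarray:
    """Unnormalised graph Laplacian L = D - K."""
    return np.diag(K.sum(axis=1)) - K


def estimate_k(eigenvalues: np.ndarray) -> int:
    """Number of clones by the eigen-gap: largest jump out of the small eigenvalues.

    Clone components show up as eigenvalues numerically close to zero
    (between-clone kernels vanish), followed by a jump into the bulk of the
    spectrum, so only gaps whose left edge lies within 5% of the spectral
    maximum are candidates.  Gaps higher in the spectrum reflect duplicate
    blocks and weakly attached members, not separate clones.  Ties break
    toward smaller k; a single eigenvalue gives k = 1.
    """
    vals = np.asarray(eigenvalues, dtype=float)
    if vals.size <= 1:
        return 1
    gaps = np.diff(vals)
    cap = 0.05 * vals[-1]
    candidates = np.flatnonzero(vals[:-1] <= cap)
    if candidates.size == 0:
        candidates = np.array([0])
    best = candidates[int(np.argmax(gaps[candidates]))]
    return int(best) + 1


def _group_seed(seed: int, group_id: str) -> int:
    """Deterministic per-group k-means seed, independent of group order."""
    return (int(seed) + zlib.crc32(group_id.encode())) % (2**31 - 1)


def _alignment_mask(group: VJLGroup, sequence: str, target: str) -> frozenset[int]:
    """Alignment-coordinate positions excluded from the SHM analysis.

    The group's junction span is in gap-stripped coordinates; it is mapped
    onto the alignment through one member's gap structure.  Junction target
    masks the full junction; CDR3 target keeps the 3 nt conserved flanks in
    the analysis.
    """
    start, end = group.junction_span
    if target == "cdr3" and end - start >= 7:
        start, end = start + 3, end - 3
    mask = []
    stripped = -1
    for n, c in enumerate(sequence):
        if c in GAP_CHARS:
            continue
        stripped += 1
        if start <= stripped < end:
            mask.append(n)
    return frozenset(mask)


def cluster_group(
    group: VJLGroup,
    sequences: dict[str, str],
    junctions: dict[str, str],
    config: ClusterConfig,
) -> np.ndarray:
    """Integer clone labels for the members of one VJ(l)-group."""
    m = len(group)
    if m == 1:
        return np.zeros(1, dtype=int)
    junc = [junctions[i] for i in group.member_ids]
    X = junction_distance_matrix(junc, config.target)
    S = None
    if config.method == "integrated":
        mask = _alignment_mask(group, sequences[group.member_ids[0]], config.target)
        S = shm_similarity_matrix(group, sequences, config.targeting_model, mask)
    W = weighted_distance(X, S, config.method)
    if m == 2:
        # eigen-gap is meaningless at m=2: merge iff the weighted distance vanishes
        return np.zeros(2, dtype=int) if W[0, 1] == 0 else np.arange(2)
    if not W.any():
        return np.zeros(m, dtype=int)
    w = local_scales(W)
    K = kernel_matrix(W, w)
    L = laplacian(K)
    try:
        vals, vecs = scipy.linalg.eigh(L)
    except scipy.linalg.LinAlgError:
        L = L + np.eye(m) * 1e-12
        vals, vecs = scipy.linalg.eigh(L)
    k = estimate_k(vals)
    if k <= 1:
        return np.zeros(m, dtype=int)
    if k >= m:
        return np.arange(m)
    features = vecs[:, :k]
    km = KMeans(
        n_clusters=k,
        n_init=10,
        random_state=_group_seed(config.seed, group.group_id),
    )
    return km.fit_predict(features)


def _cluster_one(group, sequences, junctions, config):
    try:
        labels = cluster_group(group, sequences, junctions, config)
        return group.group_id, labels, None
    except Exception as exc:  # pragma: no cover - defensive fallback
        if config.method == "integrated":
            logger.warning(
                "group %s failed under integrated model (%s); falling back to recomb",
                group.group_id,
                exc,
            )
            fallback = ClusterConfig(
                method="recomb",
                target=config.target,
                seed=config.seed,
                grouping_mode=config.grouping_mode,
            )
            labels = cluster_group(group, sequences, junctions, fallback)
            return group.group_id, labels, "recomb-fallback"
        raise


def assign_clones(rs: RearrangementSet, config: ClusterConfig) -> ClonePartition:
    """Cluster every VJ(l)-group independently and return the clone partition.

    Groups are embarrassingly parallel; per-group k-means seeds derive from
    (seed, group_id) so thread count and group order never change results.
    Clone ids are globally unique and never span VJ(l)-groups.
    """
    groups = build_vjl_groups(rs, mode=config.grouping_mode)
    sequences = {r.sequence_id: r.sequence_alignment for r in rs}
    junctions = {r.sequence_id: r.junction for r in rs}
    if config.threads > 1:
        results = Parallel(n_jobs=config.threads, backend="loky")(
            delayed(_cluster_one)(g, sequences, junctions, config) for g in groups
        )
    else:
        results = [_cluster_one(g, sequences, junctions, config) for g in groups]
    by_gid = {gid: (labels, note) for gid, labels, note in results}

    assignments: dict[str, str] = {}
    per_group: dict[str, dict] = {}
    clone_counter = 0
    for group in sorted(groups, key=lambda g: g.group_id):
        labels, note = by_gid[group.group_id]
        label_to_clone: dict[int, str] = {}
        for lab in sorted(set(int(x) for x in labels)):
            clone_counter += 1
            label_to_clone[lab] = str(clone_counter)
        for seq_id, lab in zip(group.member_ids, labels):
            assignments[seq_id] = label_to_clone[int(lab)]
        per_group[group.group_id] = {
            "size": len(group),
            "k": len(label_to_clone),
            "method": note or config.method,
        }
    return ClonePartition(
        assignments=assignments,
        per_group=per_group,
        method=config.method,
        target_region=config.target,
        seed=config.seed,
    )
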