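"""Independent brute-force reference implementations used only by tests.

Pure-python position-by-position enumeration of pairwise mutation profiles,
damping and SHM similarity.  Deliberately shares no code with the package's
vectorised implementation.
"""

import itertools
import math

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
GAPS = "-."


def brute_motif_mutability(table, germline, pos):
    stripped = "".join(c for c in germline if c not in GAPS)
    if pos < 2 or pos > len(stripped) - 3:
        return 0.0
    window = stripped[pos - 2 : pos + 3]
    if "N" in window:
        return 0.0
    choices = []
    for c in window:
        if c not in IUPAC:
            return 0.0
        choices.append(sorted(IUPAC[c]))
    vals = [table.get("".join(m), 0.0) for m in itertools.product(*choices)]
    return sum(vals) / len(vals)


def brute_pair_profile(seq_i, seq_j, egl, mask):
    """(n_alpha, n_beta, n_gamma, shared_positions, nu) for one pair."""
    a = b = g = 0
    shared = []
    cnt_i = cnt_j = 0
    for n, (ci, cj, ce) in enumerate(zip(seq_i, seq_j, egl)):
        if n in mask or ce in GAPS or ce == "N" or ce not in IUPAC:
            continue
        allowed = IUPAC[ce]
        ok_i = ci in "ACGT"
        ok_j = cj in "ACGT"
        cnt_i += ok_i
        cnt_j += ok_j
        if not (ok_i and ok_j):
            continue
        mut_i = ci not in allowed
        mut_j = cj not in allowed
        if mut_i and mut_j:
            if ci == cj:
                g += 1
                shared.append(n)
            else:
                b += 1
        elif mut_i or mut_j:
            a += 1
    return a, b, g, shared, (cnt_i + cnt_j) / 2.0


def brute_group_matrices(seqs, egl, alleles, mutability_table, mask):
    """T, H, M as plain nested lists for a list of aligned sequences."""
    m = len(seqs)
    T = [[0.0] * m for _ in range(m)]
    H = [[0.0] * m for _ in range(m)]
    M = [[1.0] * m for _ in range(m)]
    # per-position mutability averaged over alleles, in alignment coordinates
    mu = []
    for n in range(len(egl)):
        vals = []
        for al in alleles:
            stripped_pos = sum(1 for c in al[:n] if c not in GAPS)
            if al[n] in GAPS:
                vals.append(0.0)
            else:
                vals.append(brute_motif_mutability(mutability_table, al, stripped_pos))
        mu.append(sum(vals) / len(vals))
    for i in range(m):
        for j in range(i + 1, m):
            a, b, g, shared, nu = brute_pair_profile(seqs[i], seqs[j], egl, mask)
            if nu > 0:
                T[i][j] = T[j][i] = (a + 2 * (b + g)) / nu
                H[i][j] = H[j][i] = 2 * g / nu
            prod = 1.0
            for n in shared:
                prod *= 1.0 - mu[n]
            M[i][j] = M[j][i] = prod
    return T, H, M


def brute_shm_similarity(T, H, M):
    m = len(T)
    upper_t = [T[i][j] for i in range(m) for j in range(i + 1, m)]
    upper_h = [H[i][j] for i in range(m) for j in range(i + 1, m)]

    def pstd(xs):
        if not xs:
            return 0.0
        mean = sum(xs) / len(xs)
        return math.sqrt(sum((x - mean) ** 2 for x in xs) / len(xs))

    st, sh = pstd(upper_t), pstd(upper_h)

    def gauss(x, s):
        if s > 0:
            return math.exp(-(x**2) / (2 * s**2))
        return 1.0 if x == 0 else 0.0

    S = [[0.0] * m for _ in range(m)]
    for i in range(m):
        for j in range(m):
            if i == j or H[i][j] == 0:
                continue
            S[i][j] = M[i][j] * gauss(T[i][j] - H[i][j], st) * (1 - gauss(H[i][j], sh))
    return S
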