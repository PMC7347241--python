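"""Partitioning of unique sequences into VJ(l)-groups.

Clonally related heavy chains share the germline IGHV gene, IGHJ gene and
junction length (point-mutation assumption), so clustering is performed
independently inside each VJ(l)-group.  Annotation tools may emit several
comma-separated gene assignments for one read; "chain" grouping therefore
merges sequences transitively whenever both their V-gene sets and their
J-gene sets overlap, while "exact" grouping keys on the literal gene sets.

Each group carries an *effective germline*: the per-position IUPAC union of
the distinct germline alleles observed among its members, against which
somatic mutations are called.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .airr_io import GAP_CHARS, Rearrangement, RearrangementSet

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes as base sets.
IUPAC_TO_SET = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
SET_TO_IUPAC = {v: k for k, v in IUPAC_TO_SET.items()}

_ALLELE_RE = re.compile(r"\*[0-9]+$")


@dataclass
class VJLGroup:
    """A set of unique sequences sharing gene calls and junction length."""

    group_id: str
    member_ids: list[str]
    v_genes: frozenset[str]
    j_genes: frozenset[str]
    junction_length: int
    effective_germline: str
    germline_alleles: list[str]
    #: [start, end) of the junction in gap-stripped coordinates
    junction_span: tuple[int, int]

    def __len__(self) -> int:
        return len(self.member_ids)


def parse_gene_calls(call: str) -> frozenset[str]:
    """Split a (possibly multiple) gene call into allele-stripped gene names.

    ``"IGHV1-2*02,IGHV1-2*04"`` -> ``{"IGHV1-2"}``.
    """
    if not call or not call.strip():
        raise ValueError("empty gene call")
    genes = {_ALLELE_RE.sub("", part.strip()) for part in call.split(",") if part.strip()}
    if not genes:
        raise ValueError(f"unparseable gene call: {call!r}")
    return frozenset(genes)


def effective_germline(germlines: list[str]) -> str:
    """Per-position IUPAC union of aligned germline sequences.

    At each position the output is the minimal IUPAC code covering every
    A/C/G/T observed across the inputs; all-gap columns stay gaps, N in any
    input forces N.
    """
    if not germlines:
        raise ValueError("need at least one germline")
    length = len(germlines[0])
    if any(len(g) != length for g in germlines):
        raise ValueError("germline length mismatch")
    out = []
    for n in range(length):
        bases: set[str] = set()
        gap_char = None
        for g in germlines:
            c = g[n]
            if c in GAP_CHARS:
                gap_char = gap_char or c
            else:
                bases |= IUPAC_TO_SET.get(c, IUPAC_TO_SET["N"])
        if not bases:
            out.append(gap_char or ".")
        else:
            out.append(SET_TO_IUPAC[frozenset(bases)])
    return "".join(out)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def build_vjl_groups(rs: RearrangementSet, mode: str = "chain") -> list[VJLGroup]:
    """Partition unique sequences into VJ(l)-groups.

    exact mode keys on (sorted V-gene set, sorted J-gene set, junction
    length); chain mode connects two sequences within a junction-length
    stratum whenever their V-gene sets intersect AND their J-gene sets
    intersect, and takes connected components (transitive closure), so a
    read with an ambiguous multi-gene assignment bridges its alternatives.
    """
    if mode not in ("exact", "chain"):
        raise ValueError(f"unknown grouping mode: {mode!r}")
    usable: list[tuple[Rearrangement, frozenset, frozenset, tuple[int, int]]] = []
    for r in rs:
        span = r.junction_span()
        if span is None:
            logger.warning(
                "dropping %s: junction not found in gap-stripped sequence", r.sequence_id
            )
            continue
        usable.append((r, parse_gene_calls(r.v_call), parse_gene_calls(r.j_call), span))

    buckets: dict[object, list[int]] = {}
    if mode == "exact":
        for idx, (r, v, j, _span) in enumerate(usable):
            key = (tuple(sorted(v)), tuple(sorted(j)), r.junction_length)
            buckets.setdefault(key, []).append(idx)
        components = list(buckets.values())
    else:
        by_length: dict[int, list[int]] = {}
        for idx, (r, _v, _j, _span) in enumerate(usable):
            by_length.setdefault(r.junction_length, []).append(idx)
        uf = _UnionFind(len(usable))
        for members in by_length.values():
            for a_pos, i in enumerate(members):
                vi, ji = usable[i][1], usable[i][2]
                for jdx in members[a_pos + 1 :]:
                    vj, jj = usable[jdx][1], usable[jdx][2]
                    if vi & vj and ji & jj:
                        uf.union(i, jdx)
        comp: dict[int, list[int]] = {}
        for idx in range(len(usable)):
            comp.setdefault(uf.find(idx), []).append(idx)
        components = list(comp.values())

    # deterministic ordering: by first member's input position
    components.sort(key=lambda ix: ix[0])
    groups = []
    for ordinal, idxs in enumerate(components):
        members = [usable[i] for i in idxs]
        v_genes = frozenset().union(*(m[1] for m in members))
        j_genes = frozenset().union(*(m[2] for m in members))
        germlines = list(dict.fromkeys(m[0].germline_alignment for m in members))
        spans = {m[3] for m in members}
        if len(spans) > 1:
            logger.warning("inconsistent junction spans in group %d: %s", ordinal, spans)
        group_id = "{}_{}_{}_{:04d}".format(
            "+".join(sorted(v_genes)),
            "+".join(sorted(j_genes)),
            members[0][0].junction_length,
            ordinal,
        )
        groups.append(
            VJLGroup(
                group_id=group_id,
                member_ids=[m[0].sequence_id for m in members],
                v_genes=v_genes,
                j_genes=j_genes,
                junction_length=members[0][0].junction_length,
                effective_germline=effective_germline(germlines),
                germline_alleles=germlines,
                junction_span=members[0][3],
            )
        )
    return groups
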