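"""Reading, filtering, deduplication and writing of AIRR / Change-O rearrangement tables.

The clonal inference pipeline consumes annotated heavy-chain rearrangements:
every record carries an IMGT-gapped sequence alignment, the matching germline
alignment, V/J gene calls and the junction.  Two tab-separated dialects are
supported: the AIRR Rearrangement standard (lower-case column names) and the
legacy Change-O convention (upper-case names, ``SEQUENCE_IMGT`` etc.).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: AIRR column -> Change-O legacy column
CHANGEO_COLUMNS = {
    "sequence_id": "SEQUENCE_ID",
    "sequence_alignment": "SEQUENCE_IMGT",
    "germline_alignment": "GERMLINE_IMGT",
    "v_call": "V_CALL",
    "j_call": "J_CALL",
    "junction": "JUNCTION",
    "junction_length": "JUNCTION_LENGTH",
    "productive": "FUNCTIONAL",
    "duplicate_count": "DUPCOUNT",
}

MANDATORY_COLUMNS = (
    "sequence_id",
    "sequence_alignment",
    "germline_alignment",
    "v_call",
    "j_call",
    "junction",
)

_TRUTHY = {"t", "true", "1", "yes", "y"}


class FormatError(ValueError):
    """Input table does not conform to the AIRR/Change-O contract."""


class IntegrityError(ValueError):
    """Internal consistency violation (e.g. unassigned sequence on write)."""


@dataclass(frozen=True)
class Rearrangement:
    """One annotated BCR heavy-chain sequence.

    ``sequence_alignment`` and ``germline_alignment`` are IMGT-gapped
    nucleotide strings of equal length; ``duplicate_count`` is the
    multiplicity after collapsing identical reads.
    """

    sequence_id: str
    sequence_alignment: str
    germline_alignment: str
    v_call: str
    j_call: str
    junction: str
    junction_length: int
    functional_flag: bool = True
    duplicate_count: int = 1

    def ungapped(self) -> str:
        """Gap-stripped sequence alignment."""
        return strip_gaps(self.sequence_alignment)

    def junction_span(self) -> tuple[int, int] | None:
        """[start, end) of the junction in gap-stripped coordinates.

        Located by exact substring search; ``None`` when the annotation is
        inconsistent (junction absent from the read).
        """
        if not self.junction:
            return None
        start = self.ungapped().find(self.junction)
        if start < 0:
            return None
        return start, start + len(self.junction)


@dataclass
class RearrangementSet:
    """Ordered collection of rearrangements with provenance.

    ``collapse_map`` maps every original sequence_id to its unique-sequence
    representative after :func:`collapse_identical` (identity map before).
    """

    records: list[Rearrangement]
    provenance: str = ""
    collapse_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.sequence_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise IntegrityError("duplicate sequence_id in rearrangement set")
        if not self.collapse_map:
            self.collapse_map = {i: i for i in ids}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.sequence_id for r in self.records]


def strip_gaps(seq: str) -> str:
    return seq.replace("-", "").replace(".", "")


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return True
    return str(value).strip().lower() in _TRUTHY


def read_rearrangements(path, dialect: str = "airr") -> RearrangementSet:
    """Read an AIRR (``dialect='airr'``) or Change-O (``'changeo'``) TSV.

    Missing ``junction_length`` is recomputed from the junction; the optional
    productive/functional and duplicate-count columns default to True / 1.
    Row order is preserved.
    """
    if dialect not in ("airr", "changeo"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    if df.empty:
        raise FormatError(f"empty rearrangement table: {path}")
    if dialect == "changeo":
        rename = {v: k for k, v in CHANGEO_COLUMNS.items()}
        df = df.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col}")
    records = []
    for row in df.itertuples(index=False):
        junction = "" if pd.isna(getattr(row, "junction")) else str(getattr(row, "junction"))
        jl = getattr(row, "junction_length", None)
        junction_length = len(junction) if jl is None or pd.isna(jl) else int(float(jl))
        dup = getattr(row, "duplicate_count", None)
        seq = str(getattr(row, "sequence_alignment")).upper()
        germ = str(getattr(row, "germline_alignment")).upper()
        if len(seq) != len(germ):
            raise FormatError(
                f"sequence/germline alignment length mismatch for {getattr(row, 'sequence_id')}"
            )
        records.append(
            Rearrangement(
                sequence_id=str(getattr(row, "sequence_id")),
                sequence_alignment=seq,
                germline_alignment=germ,
                v_call=str(getattr(row, "v_call")),
                j_call=str(getattr(row, "j_call")),
                junction=junction.upper(),
                junction_length=junction_length,
                functional_flag=_as_bool(getattr(row, "productive", True)),
                duplicate_count=1 if dup is None or pd.isna(dup) else int(float(dup)),
            )
        )
    return RearrangementSet(records=records, provenance=f"read:{path}")


def has_stop_codon(seq: str) -> bool:
    """Scan complete codons of a gap-stripped sequence in frame 1."""
    s = strip_gaps(seq)
    return any(s[i : i + 3] in STOP_CODONS for i in range(0, len(s) - 2, 3))


def filter_productive(rs: RearrangementSet) -> RearrangementSet:
    """Keep records that are functional, stop-free, and have in-frame junctions.

    The three criteria are applied conjunctively: the annotated functionality
    flag must be set, the gap-stripped alignment must contain no stop codon in
    frame 1, and the junction length must be divisible by 3.
    """
    removed = {"functional": 0, "stop_codon": 0, "junction_frame": 0}
    kept = []
    for r in rs:
        if not r.functional_flag:
            removed["functional"] += 1
        elif has_stop_codon(r.sequence_alignment):
            removed["stop_codon"] += 1
        elif r.junction_length % 3 != 0:
            removed["junction_frame"] += 1
        else:
            kept.append(r)
    if any(removed.values()):
        logger.info("filter_productive removed %s", removed)
    return RearrangementSet(
        records=kept,
        provenance=rs.provenance + "|filter_productive",
        collapse_map={r.sequence_id: rs.collapse_map[r.sequence_id] for r in kept},
    )


def collapse_identical(rs: RearrangementSet) -> RearrangementSet:
    """Merge records with identical sequence_alignment into unique sequences.

    The first record of each identity class is the representative; its
    duplicate_count becomes the sum of merged multiplicities.  The mapping
    from every original id to its representative is kept on the returned set
    so clone assignments can later be propagated back to all input rows.
    """
    by_seq: dict[str, list[Rearrangement]] = {}
    order: list[str] = []
    for r in rs:
        if r.sequence_alignment not in by_seq:
            order.append(r.sequence_alignment)
        by_seq.setdefault(r.sequence_alignment, []).append(r)
    records = []
    collapse_map = {}
    for seq in order:
        group = by_seq[seq]
        rep = group[0]
        total = sum(g.duplicate_count for g in group)
        records.append(replace(rep, duplicate_count=total))
        for g in group:
            collapse_map[g.sequence_id] = rep.sequence_id
    return RearrangementSet(
        records=records,
        provenance=rs.provenance + "|collapse_identical",
        collapse_map=collapse_map,
    )


def to_dataframe(rs: RearrangementSet) -> pd.DataFrame:
    """AIRR-schema DataFrame view of a rearrangement set."""
    return pd.DataFrame(
        {
            "sequence_id": [r.sequence_id for r in rs],
            "sequence_alignment": [r.sequence_alignment for r in rs],
            "germline_alignment": [r.germline_alignment for r in rs],
            "v_call": [r.v_call for r in rs],
            "j_call": [r.j_call for r in rs],
            "junction": [r.junction for r in rs],
            "junction_length": [r.junction_length for r in rs],
            "productive": ["T" if r.functional_flag else "F" for r in rs],
            "duplicate_count": [r.duplicate_count for r in rs],
        }
    )


def write_clones(rs: RearrangementSet, assignments: dict[str, str], path) -> None:
    """Write the set as AIRR TSV with an added ``clone_id`` column.

    ``assignments`` must cover every sequence_id in ``rs`` (after expansion
    of collapsed duplicates by the caller).
    """
    missing = [r.sequence_id for r in rs if r.sequence_id not in assignments]
    if missing:
        raise IntegrityError(f"no clone assignment for: {missing[:5]}")
    df = to_dataframe(rs)
    df["clone_id"] = [assignments[r.sequence_id] for r in rs]
    df.to_csv(path, sep="\t", index=False)
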