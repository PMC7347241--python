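import pandas as pd
import pytest

from spectclone.airr_io import RearrangementSet, Rearrangement


AIRR_COLUMNS = [
    "sequence_id",
    "sequence_alignment",
    "germline_alignment",
    "v_call",
    "j_call",
    "junction",
    "junction_length",
    "productive",
    "duplicate_count",
]


def make_record(
    sequence_id="s1",
    sequence_alignment="ATGGCCAAATGTGCAAGGTGGGGTCAAGGG",
    germline_alignment=None,
    v_call="IGHV1-2*02",
    j_call="IGHJ4*01",
    junction="TGTGCAAGGTGG",
    functional_flag=True,
    duplicate_count=1,
):
    if germline_alignment is None:
        germline_alignment = sequence_alignment
    return Rearrangement(
        sequence_id=sequence_id,
        sequence_alignment=sequence_alignment,
        germline_alignment=germline_alignment,
        v_call=v_call,
        j_call=j_call,
        junction=junction,
        junction_length=len(junction),
        functional_flag=functional_flag,
        duplicate_count=duplicate_count,
    )


@pytest.fixture
def airr_tsv(tmp_path):
    """Write a 3-row AIRR TSV and return its path."""

    def _write(rows, path_name="input.tsv"):
        df = pd.DataFrame(rows)
        path = tmp_path / path_name
        df.to_csv(path, sep="\t", index=False)
        return path

    return _write


@pytest.fixture
def three_row_table():
    base = "ATGGCCAAATGTGCAAGGTGGGGTCAAGGG"
    variant = base[:4] + "T" + base[5:]
    return [
        {
            "sequence_id": "a",
            "sequence_alignment": base,
            "germline_alignment": base,
            "v_call": "IGHV1-2*02",
            "j_call": "IGHJ4*01",
            "junction": "TGTGCAAGGTGG",
            "junction_length": 12,
            "productive": "T",
            "duplicate_count": 1,
        },
        {
            "sequence_id": "b",
            "sequence_alignment": base,
            "germline_alignment": base,
            "v_call": "IGHV1-2*02",
            "j_call": "IGHJ4*01",
            "junction": "TGTGCAAGGTGG",
            "junction_length": 12,
            "productive": "T",
            "duplicate_count": 2,
        },
        {
            "sequence_id": "c",
            "sequence_alignment": variant,
            "germline_alignment": base,
            "v_call": "IGHV1-2*04",
            "j_call": "IGHJ4*01",
            "junction": "TGTGCAAGGTGG",
            "junction_length": 12,
            "productive": "T",
            "duplicate_count": 1,
        },
    ]


def as_set(records):
    return RearrangementSet(records=list(records))
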