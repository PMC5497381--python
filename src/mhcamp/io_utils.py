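"""Small FASTA/TSV helpers shared by the CLI and pipeline."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_tag_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {
        "amplicon_id",
        "individual_id",
        "template",
        "replicate",
        "fwd_tag",
        "rev_tag",
        "is_negative_control",
    }
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"tag sheet missing columns: {sorted(missing)}")
    return sheet
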