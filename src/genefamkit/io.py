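"""FASTA and TSV input/output.

Sequences are read with Biopython, uppercased, validated against the
nucleotide alphabet (A/C/G/T/N plus the gap character), and returned in file
order.  Report TSVs carry a comment header with the tool version and a
configuration hash so runs are traceable and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .errors import InvalidSequenceError

ALPHABET = frozenset("ACGTN-")


def read_sequences(path) -> dict[str, str]:
    """Read a (possibly gapped) nucleotide FASTA, preserving record order."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise InvalidSequenceError(f"duplicate sequence label {record.id!r}")
        seq = str(record.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in ALPHABET:
                raise InvalidSequenceError(
                    f"record {record.id!r}: invalid character {ch!r} at position {pos}"
                )
        out[record.id] = seq
    return out


def write_sequences(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=label, description="")
        for label, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def config_hash(config: Mapping) -> str:
    """Short stable hash of a JSON-serialisable configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:10]


def tsv_header(config: Mapping | None = None, notes: str = "") -> str:
    parts = [f"genefamkit {__version__}"]
    if config is not None:
        parts.append(f"config={config_hash(config)}")
    parts.append("coordinates are 1-based inclusive; missing values are '.'")
    if notes:
        parts.append(notes)
    return "# " + "; ".join(parts)


def write_tsv(path, frame: pd.DataFrame, config: Mapping | None = None,
              notes: str = "") -> None:
    path = Path(path)
    with path.open("w") as handle:
        handle.write(tsv_header(config, notes) + "\n")
        frame.to_csv(handle, sep="\t", index=False, na_rep=".",
                     lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
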