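"""Promoter characterisation: global alignment, indel calling, motif scanning.

The motif scanner matches IUPAC degenerate patterns on both strands and
reports every (overlapping) occurrence in forward-strand coordinates, in the
style of plant cis-element database scans.  The aligner is a standard affine
gap (Gotoh) global aligner with deterministic trace-back, tuned by default to
favour single long indels so contiguous insertions are recovered as one event.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidSequenceError

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",  # N in a pattern matches anything; N in sequence matches only N
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    pattern: str
    both_strands: bool = True

    def __post_init__(self):
        pattern = self.pattern.upper()
        object.__setattr__(self, "pattern", pattern)
        if len(pattern) < 4:
            raise ConfigurationError(
                f"motif {self.name!r}: pattern shorter than 4 bases"
            )
        bad = [c for c in pattern if c not in IUPAC_CODES]
        if bad:
            raise ConfigurationError(
                f"motif {self.name!r}: invalid IUPAC code(s) {bad}"
            )


#: stand-in library for plant cis-element scans (E-box, Myb cores, light
#: response elements); real analyses should supply their own TSV
DEFAULT_MOTIFS = (
    MotifDefinition("MYC_EBOX", "CANNTG"),
    MotifDefinition("MYB_CORE", "CNGTTR"),
    MotifDefinition("MYBPLANT", "MACCWAMC"),
    MotifDefinition("GBOX", "CACGTG"),
    MotifDefinition("GT1_MOTIF", "GRWAAW"),
)


@dataclass(frozen=True)
class MotifHit:
    motif: str
    seq_id: str
    start: int  # 1-based inclusive, forward strand
    end: int    # 1-based inclusive
    strand: str  # "+" or "-"
    match: str   # reverse-complemented for "-" hits


@dataclass(frozen=True)
class IndelCall:
    reference_id: str
    query_id: str
    position: int  # 1-based reference coordinate of the base preceding the event
    kind: str      # "insertion" | "deletion"
    length: int
    sequence: str


def _pattern_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC_CODES[c]}]" for c in pattern))


def scan_motifs(
    seq: str,
    library: Iterable[MotifDefinition] = DEFAULT_MOTIFS,
    seq_id: str = "seq",
) -> list[MotifHit]:
    """All occurrences of each library pattern in ``seq``, both strands.

    Minus-strand hits are found by matching the reverse complement of the
    pattern against the forward sequence; coordinates are always 1-based on
    the forward strand and palindromic motifs are reported on both strands.
    """
    seq = seq.upper()
    bad = [c for c in set(seq) if c not in "ACGTN"]
    if bad:
        raise InvalidSequenceError(f"sequence contains invalid characters {bad}")
    hits: list[MotifHit] = []
    for motif in library:
        strands = [("+", motif.pattern)]
        if motif.both_strands:
            strands.append(("-", reverse_complement(motif.pattern)))
        for strand, pattern in strands:
            regex = re.compile(f"(?=({_pattern_regex(pattern).pattern}))")
            for m in regex.finditer(seq):
                sub = m.group(1)
                hits.append(MotifHit(
                    motif=motif.name,
                    seq_id=seq_id,
                    start=m.start() + 1,
                    end=m.start() + len(motif.pattern),
                    strand=strand,
                    match=sub if strand == "+" else reverse_complement(sub),
                ))
    hits.sort(key=lambda h: (h.start, h.motif, h.strand))
    return hits


def load_motif_library(path) -> list[MotifDefinition]:
    """Read a TSV motif library: name <tab> IUPAC pattern [<tab> + | both]."""
    library = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ConfigurationError(f"malformed motif line: {line!r}")
            both = len(parts) < 3 or parts[2].strip().lower() in ("both", "+-", "-")
            library.append(MotifDefinition(parts[0], parts[1], both_strands=both))
    return library


_NEG = -1e30


def global_align(
    seq_a: str,
    seq_b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> tuple[str, str, float]:
    """Optimal affine-gap global alignment of two nucleotide sequences.

    A gap of length L scores ``gap_open + L * gap_extend``.  Trace-back ties
    are broken deterministically: diagonal, then up (gap in ``seq_b``), then
    left (gap in ``seq_a``).  Returns ``(aligned_a, aligned_b, score)``.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        raise InvalidSequenceError("global alignment requires non-empty sequences")
    n, m = len(seq_a), len(seq_b)
    a_arr = np.frombuffer(seq_a.encode(), dtype="S1")
    b_arr = np.frombuffer(seq_b.encode(), dtype="S1")
    js = np.arange(m + 1, dtype=float)

    M = np.full((n + 1, m + 1), _NEG)
    IX = np.full((n + 1, m + 1), _NEG)  # gap in seq_b (consume a; "up")
    IY = np.full((n + 1, m + 1), _NEG)  # gap in seq_a (consume b; "left")
    M[0, 0] = 0.0
    IY[0, 1:] = gap_open + gap_extend * js[1:]
    for i in range(1, n + 1):
        IX[i, :] = np.maximum(M[i - 1, :] + gap_open + gap_extend,
                              IX[i - 1, :] + gap_extend)
        sub = np.where(b_arr == a_arr[i - 1], match, mismatch)
        prev = np.maximum(np.maximum(M[i - 1, :m], IX[i - 1, :m]), IY[i - 1, :m])
        M[i, 1:] = prev + sub
        # horizontal gaps within the row: running max over gap-start cells
        start = np.maximum.accumulate(M[i, :m] - gap_extend * js[:m])
        IY[i, 1:] = np.maximum(gap_open + gap_extend * js[1:] + start, _NEG)

    # trace-back, preferring diagonal, then up, then left
    i, j = n, m
    state = max(
        (("M", M[n, m]), ("X", IX[n, m]), ("Y", IY[n, m])),
        key=lambda t: t[1],
    )
    score = state[1]
    if M[n, m] == score:
        state = "M"
    elif IX[n, m] == score:
        state = "X"
    else:
        state = "Y"
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = match if seq_a[i - 1] == seq_b[j - 1] else mismatch
            target = M[i, j] - s
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if M[i, j] == target:
                state = "M"
            elif IX[i, j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            came_open = M[i - 1, j] + gap_open + gap_extend
            i -= 1
            state = "M" if came_open == IX[i + 1, j] else "X"
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            came_open = M[i, j - 1] + gap_open + gap_extend
            j -= 1
            state = "M" if came_open == IY[i, j + 1] else "Y"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score)


def call_indels(
    aligned_a: str,
    aligned_b: str,
    reference: str = "a",
    reference_id: str = "reference",
    query_id: str = "query",
) -> list[IndelCall]:
    """Merge maximal gap runs of an aligned pair into indel calls.

    Gap runs in the reference are insertions (sequence taken from the query),
    runs in the query are deletions.  Positions are 1-based reference
    coordinates of the base preceding the event (0 for leading events).
    Columns gapped in both sequences are ignored.
    """
    if len(aligned_a) != len(aligned_b):
        raise InvalidSequenceError("aligned sequences differ in length")
    if reference == "a":
        ref, qry = aligned_a.upper(), aligned_b.upper()
    elif reference == "b":
        ref, qry = aligned_b.upper(), aligned_a.upper()
    else:
        raise ConfigurationError("reference must be 'a' or 'b'")
    calls: list[IndelCall] = []
    ref_pos = 0
    run_kind = None
    run_seq: list[str] = []
    run_pos = 0

    def flush():
        nonlocal run_kind, run_seq
        if run_kind is not None:
            calls.append(IndelCall(
                reference_id=reference_id,
                query_id=query_id,
                position=run_pos,
                kind=run_kind,
                length=len(run_seq),
                sequence="".join(run_seq),
            ))
        run_kind = None
        run_seq = []

    for r, q in zip(ref, qry):
        if r == "-" and q == "-":
            continue
        if r == "-":
            if run_kind != "insertion":
                flush()
                run_kind = "insertion"
                run_pos = ref_pos
            run_seq.append(q)
        elif q == "-":
            if run_kind != "deletion":
                flush()
                run_kind = "deletion"
                run_pos = ref_pos
            run_seq.append(r)
            ref_pos += 1
        else:
            flush()
            ref_pos += 1
    flush()
    return calls


def apply_indels(reference: str, calls: Sequence[IndelCall]) -> str:
    """Reconstruct the query by applying indel calls to the ungapped reference."""
    events = sorted(calls, key=lambda c: (c.position, 0 if c.kind == "deletion" else 1))
    out: list[str] = []
    cursor = 0
    for call in events:
        out.append(reference[cursor:call.position])
        cursor = call.position
        if call.kind == "insertion":
            out.append(call.sequence)
        else:
            cursor += call.length
    out.append(reference[cursor:])
    return "".join(out)
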