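"""Counting-based estimation of synonymous and nonsynonymous substitution rates.

Implements the classic pathway-counting estimator for pairs of in-frame
aligned coding sequences: fractional synonymous/nonsynonymous site counts per
codon (optionally weighted by a transition/transversion rate ratio ``kappa``),
pathway-averaged difference counts between codons, and Jukes–Cantor correction
of the resulting proportions.  With ``kappa = 1`` the site counting reduces to
the original unweighted method.

Only the standard nuclear genetic code is supported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .errors import (
    AllPathsThroughStopError,
    EmptyAlignmentError,
    InvalidCodonError,
    SaturationError,
)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, standard code, stop codons excluded
AMINO_ACID: Mapping[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(AMINO_ACID))
BASES = "ACGT"

_PURINES = frozenset("AG")


def is_transition(a: str, b: str) -> bool:
    """True if ``a -> b`` is a transition (purine<->purine or pyr<->pyr)."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _require_sense_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise InvalidCodonError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise InvalidCodonError(f"stop codon not allowed: {codon!r}")
    return codon


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous (``s``) and nonsynonymous (``n``) site counts."""

    s: float
    n: float
    kappa: float = 1.0


@lru_cache(maxsize=None)
def syn_nonsyn_sites(codon: str, kappa: float = 1.0) -> SiteCounts:
    """Count fractional synonymous/nonsynonymous sites of a sense codon.

    Each codon position contributes the weighted fraction of its three
    possible single-base substitutions that are synonymous; weights are
    ``kappa`` for transitions and 1 for transversions.  Substitutions that
    would create a stop codon are excluded from both numerator and
    denominator.  ``s + n == 3`` exactly.
    """
    codon = _require_sense_codon(codon)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    aa = AMINO_ACID[codon]
    s = 0.0
    for pos in range(3):
        num = 0.0
        den = 0.0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            w = kappa if is_transition(codon[pos], alt) else 1.0
            den += w
            if AMINO_ACID[mutant] == aa:
                num += w
        if den > 0:
            s += num / den
    return SiteCounts(s=s, n=3.0 - s, kappa=kappa)


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    All orders of the differing positions are enumerated as single-step
    mutational pathways; pathways passing through a stop codon are excluded
    and the remaining ones weighted equally.  Raises
    :class:`AllPathsThroughStopError` when every pathway is blocked.
    """
    codon_a = _require_sense_codon(codon_a)
    codon_b = _require_sense_codon(codon_b)
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)
    paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = codon_a
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AMINO_ACID[cur] == AMINO_ACID[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        raise AllPathsThroughStopError(
            f"all pathways {codon_a}->{codon_b} pass through a stop codon"
        )
    sd_mean = sum(p[0] for p in paths) / len(paths)
    nd_mean = sum(p[1] for p in paths) / len(paths)
    return (sd_mean, nd_mean)


def jukes_cantor_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction ``-(3/4) ln(1 - 4p/3)``."""
    if p < 0:
        raise ValueError("difference proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"proportion {p} >= 3/4: distance undefined")
    if p == 0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of in-frame aligned coding sequences (gap character ``-``)."""

    seq_a: str
    seq_b: str
    labels: tuple[str, str] = ("a", "b")

    def __post_init__(self):
        object.__setattr__(self, "seq_a", self.seq_a.upper())
        object.__setattr__(self, "seq_b", self.seq_b.upper())
        if len(self.seq_a) != len(self.seq_b):
            raise InvalidCodonError("aligned sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise InvalidCodonError("alignment length not divisible by 3")
        if not any(True for _ in self.iter_clean_columns()):
            raise EmptyAlignmentError(
                "no ungapped, unambiguous, stop-free codon column in alignment"
            )

    def iter_codon_columns(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i:i + 3], self.seq_b[i:i + 3]

    def iter_clean_columns(self):
        """Codon columns free of gaps, ambiguity and stops in both sequences."""
        for ca, cb in self.iter_codon_columns():
            if any(b not in BASES for b in ca + cb):
                continue
            if ca in STOP_CODONS or cb in STOP_CODONS:
                continue
            yield ca, cb


@dataclass(frozen=True)
class KsKaResult:
    """Summary of a pairwise synonymous/nonsynonymous rate estimate."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float
    ka: float
    codons_used: int
    dropped_gap_ambiguous: int = 0
    dropped_stop: int = 0
    dropped_blocked: int = 0
    labels: tuple[str, str] = ("a", "b")
    flags: tuple[str, ...] = ()


def estimate_ks_ka(aln: CodonAlignment, kappa: float = 1.0) -> KsKaResult:
    """Estimate Ks and Ka for one aligned pair.

    Codon columns with a gap, ambiguous base or stop codon in either sequence
    are dropped entirely (complete deletion per column), as are the rare
    columns whose every mutational pathway crosses a stop; dropped counts are
    recorded on the result.  Site totals ``S``/``N`` are the mean of the two
    per-sequence totals; ``pS >= 3/4`` (or ``pN``) raises
    :class:`SaturationError` carrying the partial result.
    """
    s_a = s_b = 0.0
    sd = nd = 0.0
    used = 0
    dropped_gap = dropped_stop = dropped_blocked = 0
    flags: list[str] = []
    for ca, cb in aln.iter_codon_columns():
        if any(b not in BASES for b in ca + cb):
            dropped_gap += 1
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            dropped_stop += 1
            continue
        try:
            d_s, d_n = pathway_differences(ca, cb)
        except AllPathsThroughStopError:
            dropped_blocked += 1
            continue
        s_a += syn_nonsyn_sites(ca, kappa).s
        s_b += syn_nonsyn_sites(cb, kappa).s
        sd += d_s
        nd += d_n
        used += 1
    if used == 0:
        raise EmptyAlignmentError("no retained codon columns")
    S = (s_a + s_b) / 2.0
    N = 3.0 * used - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    if dropped_blocked:
        flags.append(f"blocked_pathway_columns={dropped_blocked}")

    def _finish(ks, ka, extra_flags=()):
        return KsKaResult(
            S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, ks=ks, ka=ka,
            codons_used=used,
            dropped_gap_ambiguous=dropped_gap,
            dropped_stop=dropped_stop,
            dropped_blocked=dropped_blocked,
            labels=aln.labels,
            flags=tuple(flags) + tuple(extra_flags),
        )

    if pS >= 0.75 or pN >= 0.75:
        which = "pS" if pS >= 0.75 else "pN"
        partial = _finish(float("nan"), float("nan"), (f"saturated:{which}",))
        raise SaturationError(
            f"{which} >= 3/4 for pair {aln.labels}: distance saturated",
            partial=partial,
        )
    return _finish(jukes_cantor_correct(pS), jukes_cantor_correct(pN))


def pairwise_ks_matrix(
    sequences: Mapping[str, str], kappa: float = 1.0
) -> pd.DataFrame:
    """Symmetric Ks matrix over a multiple alignment of coding sequences.

    ``sequences`` maps taxon label to its (gapped) aligned CDS; every pair is
    estimated with :func:`estimate_ks_ka`.  Saturated or empty pairs are
    reported as NaN rather than raising.
    """
    labels = list(sequences)
    if len(labels) != len(set(labels)):
        raise InvalidCodonError("duplicate taxon labels in input")
    mat = pd.DataFrame(
        np.zeros((len(labels), len(labels))), index=labels, columns=labels
    )
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            try:
                aln = CodonAlignment(sequences[la], sequences[lb], (la, lb))
                value = estimate_ks_ka(aln, kappa=kappa).ks
            except (SaturationError, EmptyAlignmentError):
                value = float("nan")
            mat.loc[la, lb] = value
            mat.loc[lb, la] = value
    return mat
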