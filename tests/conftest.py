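import itertools

import pytest

from genefamkit.substitution_rates import (
    AMINO_ACID,
    BASES,
    SENSE_CODONS,
    STOP_CODONS,
)


def brute_force_sites(codon: str, kappa: float = 1.0) -> float:
    """Independent enumeration of the 9 single-base neighbours of a codon."""
    s = 0.0
    for pos in range(3):
        num = den = 0.0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            purines = set("AG")
            transition = (codon[pos] in purines) == (alt in purines)
            w = kappa if transition else 1.0
            den += w
            if AMINO_ACID[mutant] == AMINO_ACID[codon]:
                num += w
        if den:
            s += num / den
    return s


def brute_force_pathways(codon_a: str, codon_b: str):
    """Enumerate every pathway permutation; returns (sd, nd) or None if blocked."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return (0.0, 0.0)
    results = []
    for order in itertools.permutations(diff):
        cur = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if AMINO_ACID[cur] == AMINO_ACID[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


@pytest.fixture(scope="session")
def sense_codons():
    return SENSE_CODONS
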