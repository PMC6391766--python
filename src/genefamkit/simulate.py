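"""Synthetic data with known ground truth for every pipeline stage.

Generators cover clock-evolved CDS pairs and families (synonymous-only by
default), promoters with planted motifs and indels, and replicated qPCR Ct
tables with planted fold changes.  All randomness flows from a single
``numpy`` generator seeded once per call, so outputs are byte-identical for a
fixed configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .promoters import IUPAC_CODES, IndelCall, MotifHit
from .substitution_rates import (
    AMINO_ACID,
    BASES,
    CodonAlignment,
    SENSE_CODONS,
    STOP_CODONS,
    syn_nonsyn_sites,
)

YEARS_PER_MY = 1e6

#: the 17-bp promoter insertion used as the default planted indel
DEFAULT_INSERTION = "CAGCAGAGCACTAGCTC"


def _neighbors(codon: str, synonymous: bool) -> tuple[tuple[int, str], ...]:
    out = []
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            same = AMINO_ACID[mutant] == AMINO_ACID[codon]
            if same == synonymous:
                out.append((pos, alt))
    return tuple(out)


SYN_NEIGHBORS = {c: _neighbors(c, True) for c in SENSE_CODONS}
NONSYN_NEIGHBORS = {c: _neighbors(c, False) for c in SENSE_CODONS}


def _p_from_distance(d: float) -> float:
    """Invert the Jukes-Cantor correction: expected difference proportion."""
    return 0.75 * -math.expm1(-4.0 * d / 3.0)


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n)]


def _site_total(codons: Sequence[str], synonymous: bool) -> float:
    if synonymous:
        return sum(syn_nonsyn_sites(c).s for c in codons)
    return sum(syn_nonsyn_sites(c).n for c in codons)


@dataclass(frozen=True)
class CdsPairTruth:
    """Bookkeeping of the substitutions planted between a simulated pair."""

    n_codons: int
    planted_syn: int
    planted_nonsyn: int
    s_mean: float
    n_mean: float
    realized_ks: float
    realized_ka: float


def _plant_differences(
    codons: list[str],
    rng: np.random.Generator,
    target_distance: float,
    synonymous: bool,
    s_other: float,
    blocked: set[int],
) -> int:
    """Plant single-base differences until the realised proportion matches.

    Each planted change turns one untouched codon into a single-base
    (non)synonymous neighbour, so the pathway difference count equals the
    number of planted changes exactly.  The loop tracks the running mean site
    total of both sequences and stops — with a stochastically rounded final
    step — once ``count / mean_sites`` reaches the proportion that
    Jukes-Cantor-inverts to ``target_distance``.
    """
    if target_distance == 0:
        return 0
    p_target = _p_from_distance(target_distance)
    table = SYN_NEIGHBORS if synonymous else NONSYN_NEIGHBORS
    eligible = [i for i in range(len(codons))
                if i not in blocked and table[codons[i]]]
    sites = _site_total(codons, synonymous)
    count = 0
    while True:
        mean_sites = 0.5 * (sites + s_other)
        deficit = p_target * mean_sites - count
        if deficit <= 0:
            break
        final_step = deficit < 1.0
        if final_step and rng.random() >= deficit:
            break
        if not eligible:
            raise ConfigurationError(
                "target divergence unattainable: no codons left to mutate"
            )
        pick = int(rng.integers(0, len(eligible)))
        idx = eligible[pick]
        eligible[pick] = eligible[-1]
        eligible.pop()
        options = table[codons[idx]]
        pos, alt = options[int(rng.integers(0, len(options)))]
        new_codon = codons[idx][:pos] + alt + codons[idx][pos + 1:]
        if synonymous:
            sites += syn_nonsyn_sites(new_codon).s - syn_nonsyn_sites(codons[idx]).s
        else:
            sites += syn_nonsyn_sites(new_codon).n - syn_nonsyn_sites(codons[idx]).n
        codons[idx] = new_codon
        blocked.add(idx)
        count += 1
        if final_step:
            break
    return count


def simulate_cds_pair(
    n_codons: int,
    true_ks: float,
    true_ka: float = 0.0,
    kappa: float = 1.0,
    seed: int = 0,
    labels: tuple[str, str] = ("anc", "der"),
) -> tuple[CodonAlignment, CdsPairTruth]:
    """A pair of CDS diverged by planted substitutions at known Ks/Ka.

    The ancestor is drawn uniformly over sense codons and all differences are
    planted on the derived copy, each in a distinct codon, so the truth
    bookkeeping (planted counts, realised proportions) is exact.
    """
    if n_codons < 10:
        raise ConfigurationError("simulate at least 10 codons")
    if true_ks < 0 or true_ka < 0:
        raise ConfigurationError("divergences must be non-negative")
    rng = np.random.default_rng(seed)
    ancestor = _random_codons(rng, n_codons)
    derived = list(ancestor)
    blocked: set[int] = set()
    s_anc = _site_total(ancestor, True)
    n_anc = _site_total(ancestor, False)
    sd = _plant_differences(derived, rng, true_ks, True, s_anc, blocked)
    nd = _plant_differences(derived, rng, true_ka, False, n_anc, blocked)
    s_mean = 0.5 * (s_anc + _site_total(derived, True))
    n_mean = 0.5 * (n_anc + _site_total(derived, False))

    def jc(p):
        return -0.75 * math.log1p(-4.0 * p / 3.0) if p > 0 else 0.0

    truth = CdsPairTruth(
        n_codons=n_codons,
        planted_syn=sd,
        planted_nonsyn=nd,
        s_mean=s_mean,
        n_mean=n_mean,
        realized_ks=jc(sd / s_mean),
        realized_ka=jc(nd / n_mean),
    )
    aln = CodonAlignment("".join(ancestor), "".join(derived), labels)
    return aln, truth


# ---------------------------------------------------------------------------
# gene families under a clock

FamilyTree = tuple  # (age_mya, child, child) nested; leaves are label strings


@dataclass(frozen=True)
class FamilyConfig:
    """Clock simulation settings for a duplicating gene family.

    ``tree`` is a nested ``(age_mya, left, right)`` tuple whose leaves are
    taxon labels, e.g. ``(40.0, (30.0, (17.0, "G1", "G2"), "G3"), "G4")``.
    ``rate`` is in substitutions per synonymous site per year.
    """

    tree: FamilyTree = (40.0, (30.0, (17.0, "G1", "G2"), "G3"), "G4")
    rate: float = 3.2e-9
    n_codons: int = 1000
    ka_ks_ratio: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class SimulatedFamily:
    sequences: dict[str, str]
    divergence_mya: pd.DataFrame  # symmetric matrix of split times
    branch_events: dict[str, int]
    config: FamilyConfig

    def truth_frame(self) -> pd.DataFrame:
        """Long-format truth manifest: pair, split time, expected Ks = 2kT."""
        rows = []
        labels = list(self.divergence_mya.index)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                t = self.divergence_mya.loc[a, b]
                rows.append({
                    "taxon_a": a, "taxon_b": b, "divergence_mya": t,
                    "expected_ks": 2.0 * self.config.rate * t * YEARS_PER_MY,
                })
        return pd.DataFrame(rows)


def _leaf_labels(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    _, left, right = node
    return _leaf_labels(left) + _leaf_labels(right)


def _node_age(node) -> float:
    return 0.0 if isinstance(node, str) else float(node[0])


def _evolve_branch(
    codons: list[str],
    ks_branch: float,
    ka_branch: float,
    rng: np.random.Generator,
) -> int:
    """Apply point substitutions along one branch; multiple hits allowed.

    The number of events is the rounded expectation (branch divergence times
    the current site total), which removes event-count noise while keeping
    placement random.
    """
    events = 0
    for divergence, synonymous in ((ks_branch, True), (ka_branch, False)):
        if divergence <= 0:
            continue
        table = SYN_NEIGHBORS if synonymous else NONSYN_NEIGHBORS
        sites = _site_total(codons, synonymous)
        n_events = int(round(divergence * sites))
        eligible = [i for i in range(len(codons)) if table[codons[i]]]
        for _ in range(n_events):
            while True:
                idx = eligible[int(rng.integers(0, len(eligible)))]
                options = table[codons[idx]]
                if options:
                    break
            pos, alt = options[int(rng.integers(0, len(options)))]
            codons[idx] = codons[idx][:pos] + alt + codons[idx][pos + 1:]
            events += 1
    return events


def simulate_gene_family(config: FamilyConfig) -> SimulatedFamily:
    """Evolve a gene family along a dated duplication tree under a clock."""
    if config.rate <= 0:
        raise ConfigurationError("substitution rate must be positive")
    labels = _leaf_labels(config.tree)
    if len(labels) != len(set(labels)):
        raise ConfigurationError("duplicate taxon labels in family tree")
    rng = np.random.default_rng(config.seed)
    ancestor = _random_codons(rng, config.n_codons)
    sequences: dict[str, str] = {}
    branch_events: dict[str, int] = {}

    def descend(node, codons: list[str], parent_age: float):
        age = _node_age(node)
        dt_years = (parent_age - age) * YEARS_PER_MY
        if dt_years < 0:
            raise ConfigurationError("child node older than its parent")
        ks_branch = config.rate * dt_years
        child = list(codons)
        events = _evolve_branch(
            child, ks_branch, config.ka_ks_ratio * ks_branch, rng
        )
        name = node if isinstance(node, str) else f"node@{age}"
        branch_events[name] = branch_events.get(name, 0) + events
        if isinstance(node, str):
            sequences[node] = "".join(child)
        else:
            _, left, right = node
            descend(left, child, age)
            descend(right, child, age)

    root_age = _node_age(config.tree)
    _, left, right = config.tree
    descend(left, ancestor, root_age)
    descend(right, ancestor, root_age)

    times = pd.DataFrame(0.0, index=labels, columns=labels)

    def fill(node):
        if isinstance(node, str):
            return
        age, l, r = node
        for a in _leaf_labels(l):
            for b in _leaf_labels(r):
                times.loc[a, b] = times.loc[b, a] = float(age)
        fill(l)
        fill(r)

    fill(config.tree)
    return SimulatedFamily(
        sequences=sequences,
        divergence_mya=times,
        branch_events=branch_events,
        config=config,
    )


# ---------------------------------------------------------------------------
# promoters

@dataclass(frozen=True)
class PromoterConfig:
    length: int = 600
    planted_motifs: tuple[tuple[str, str, int], ...] = (
        ("MYC_EBOX", "CANNTG", 3),
        ("MYB_CORE", "CNGTTR", 2),
        ("GT1_MOTIF", "GRWAAW", 2),
    )
    insertion: str = DEFAULT_INSERTION
    insertion_after: int = 300  # 1-based reference position preceding the insert
    background: str | None = None  # explicit background sequence overrides length
    seed: int = 0


@dataclass(frozen=True)
class SimulatedPromoters:
    reference: str
    variant: str
    motif_truth: tuple[MotifHit, ...]
    indel_truth: tuple[IndelCall, ...]


def _concretize(pattern: str, rng: np.random.Generator) -> str:
    out = []
    for code in pattern:
        choices = IUPAC_CODES[code].replace("N", "") or "ACGT"
        out.append(choices[int(rng.integers(0, len(choices)))])
    return "".join(out)


def simulate_promoters(config: PromoterConfig = PromoterConfig()) -> SimulatedPromoters:
    """A reference promoter with planted motifs plus an indel-bearing variant.

    Motif instances are placed without overlap at recorded 1-based positions;
    the variant carries the configured insertion (by default the bundled
    17-bp sequence) after ``insertion_after``.
    """
    rng = np.random.default_rng(config.seed)
    if config.background is not None:
        seq = list(config.background.upper())
    else:
        seq = [BASES[i] for i in rng.integers(0, 4, size=config.length)]
    length = len(seq)
    total_motif = sum(len(p) * c for _, p, c in config.planted_motifs)
    if total_motif > length or (config.insertion
                                and not 0 <= config.insertion_after <= length):
        raise ConfigurationError("planted features do not fit in the promoter")
    occupied: set[int] = set()
    hits: list[MotifHit] = []
    for name, pattern, count in config.planted_motifs:
        for _ in range(count):
            placed = False
            for _attempt in range(1000):
                start = int(rng.integers(0, length - len(pattern) + 1))
                span = range(start, start + len(pattern))
                if any(i in occupied for i in span):
                    continue
                instance = _concretize(pattern, rng)
                seq[start:start + len(pattern)] = list(instance)
                occupied.update(span)
                hits.append(MotifHit(
                    motif=name, seq_id="reference",
                    start=start + 1, end=start + len(pattern),
                    strand="+", match=instance,
                ))
                placed = True
                break
            if not placed:
                raise ConfigurationError(
                    f"could not place motif {name!r} without overlap"
                )
    reference = "".join(seq)
    indels: list[IndelCall] = []
    variant = reference
    if config.insertion:
        pos = config.insertion_after
        variant = reference[:pos] + config.insertion + reference[pos:]
        indels.append(IndelCall(
            reference_id="reference", query_id="variant",
            position=pos, kind="insertion",
            length=len(config.insertion), sequence=config.insertion,
        ))
    hits.sort(key=lambda h: (h.start, h.motif))
    return SimulatedPromoters(
        reference=reference,
        variant=variant,
        motif_truth=tuple(hits),
        indel_truth=tuple(indels),
    )


# ---------------------------------------------------------------------------
# qPCR Ct tables

@dataclass(frozen=True)
class QpcrConfig:
    """Planted fold changes per (genotype, tissue) for one target gene."""

    folds: tuple[tuple[tuple[str, str], float], ...] = (
        (("uncoloured", "lemma"), 1.0),
        (("coloured", "lemma"), 7.0),
        (("coloured", "aleurone"), 8.0),
        (("uncoloured", "aleurone"), 1.5),
    )
    calibrator: tuple[str, str] = ("uncoloured", "lemma")
    gene: str = "target"
    reference_gene: str = "ubiquitin"
    n_bio: int = 3
    n_tech: int = 3
    sigma_ct: float = 0.15
    base_ct_ref: float = 20.0
    base_dct: float = 2.0
    seed: int = 0


def simulate_ct_table(config: QpcrConfig = QpcrConfig()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct table with planted fold changes; returns (records, truth) frames."""
    folds = dict(config.folds)
    if any(f <= 0 for f in folds.values()):
        raise ConfigurationError("planted fold changes must be positive")
    if config.n_bio < 1 or config.n_tech < 1:
        raise ConfigurationError("replicate counts must be >= 1")
    if config.sigma_ct < 0:
        raise ConfigurationError("Ct noise must be non-negative")
    if config.calibrator not in folds:
        raise ConfigurationError("calibrator group missing from fold table")
    rng = np.random.default_rng(config.seed)
    cal_fold = folds[config.calibrator]
    rows = []
    for (genotype, tissue), fold in folds.items():
        dct = config.base_dct - math.log2(fold / cal_fold)
        for bio in range(1, config.n_bio + 1):
            for tech in range(1, config.n_tech + 1):
                noise_ref = rng.normal(0.0, config.sigma_ct) if config.sigma_ct else 0.0
                noise_tgt = rng.normal(0.0, config.sigma_ct) if config.sigma_ct else 0.0
                rows.append({
                    "genotype": genotype, "tissue": tissue,
                    "gene": config.reference_gene, "bio_rep": bio,
                    "tech_rep": tech, "ct": config.base_ct_ref + noise_ref,
                })
                rows.append({
                    "genotype": genotype, "tissue": tissue,
                    "gene": config.gene, "bio_rep": bio,
                    "tech_rep": tech,
                    "ct": config.base_ct_ref + dct + noise_tgt,
                })
    records = pd.DataFrame(rows)
    truth = pd.DataFrame([
        {"genotype": g, "tissue": t, "gene": config.gene, "true_fold": f}
        for (g, t), f in folds.items()
    ])
    return records, truth
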