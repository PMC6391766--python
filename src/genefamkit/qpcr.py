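"""Relative expression from qPCR Ct tables and the associated statistics.

Quantification is the 2^-ddCt method: technical replicates are averaged per
biological replicate, dCt = Ct_target - Ct_reference, ddCt is taken relative
to the mean dCt of a calibrator (genotype, tissue) group, and the summary
fold change is the geometric mean 2^-mean(ddCt) (so the calibrator's own
fold is exactly 1).  Group comparisons are one-way ANOVA with a Tukey HSD
compact letter display, or an exact two-sided Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

CT_COLUMNS = ["genotype", "tissue", "gene", "bio_rep", "tech_rep", "ct"]


@dataclass(frozen=True)
class CtRecord:
    genotype: str
    tissue: str
    gene: str
    bio_rep: int
    tech_rep: int
    ct: float

    def __post_init__(self):
        if not (0 < self.ct < 45):
            raise ConfigurationError(f"Ct value out of range (0, 45): {self.ct}")


@dataclass(frozen=True)
class ExpressionResult:
    genotype: str
    tissue: str
    gene: str
    fold_change: float           # 2^-mean(ddCt) over biological replicates
    rep_folds: tuple[float, ...]  # per-biological-replicate 2^-ddCt
    mean: float                  # arithmetic mean of rep_folds
    se: float                    # standard error of rep_folds


def records_to_frame(records: Sequence[CtRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=CT_COLUMNS)


def relative_expression(
    records: pd.DataFrame | Sequence[CtRecord],
    reference_gene: str,
    calibrator: tuple[str, str],
    efficiency: float = 2.0,
) -> list[ExpressionResult]:
    """Per-group fold changes relative to a calibrator (genotype, tissue).

    Samples missing a matching reference-gene Ct are dropped with a warning;
    a calibrator group absent for some target gene is a configuration error.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    df = records.copy()
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"Ct table missing columns: {missing}")
    if not ((df["ct"] > 0) & (df["ct"] < 45)).all():
        raise ConfigurationError("Ct values must lie in (0, 45)")

    # collapse technical replicates, then pivot reference against targets
    ct = (
        df.groupby(["genotype", "tissue", "gene", "bio_rep"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    ref = ct[ct["gene"] == reference_gene].set_index(
        ["genotype", "tissue", "bio_rep"]
    )["ct"]
    if ref.empty:
        raise ConfigurationError(f"no Ct values for reference gene {reference_gene!r}")
    targets = ct[ct["gene"] != reference_gene].copy()
    keys = list(zip(targets["genotype"], targets["tissue"], targets["bio_rep"]))
    has_ref = [k in ref.index for k in keys]
    if not all(has_ref):
        dropped = sorted({k for k, ok in zip(keys, has_ref) if not ok})
        warnings.warn(
            f"dropping {len(dropped)} sample(s) without reference Ct: {dropped}",
            stacklevel=2,
        )
        targets = targets[has_ref]
        keys = [k for k, ok in zip(keys, has_ref) if ok]
    targets["dct"] = targets["ct"].to_numpy() - ref.loc[keys].to_numpy()

    results: list[ExpressionResult] = []
    for gene, sub in targets.groupby("gene", sort=True):
        cal = sub[
            (sub["genotype"] == calibrator[0]) & (sub["tissue"] == calibrator[1])
        ]
        if cal.empty:
            raise ConfigurationError(
                f"calibrator {calibrator} absent for gene {gene!r}"
            )
        cal_dct = cal["dct"].mean()
        for (genotype, tissue), grp in sub.groupby(["genotype", "tissue"], sort=True):
            ddct = grp["dct"].to_numpy() - cal_dct
            folds = efficiency ** (-ddct)
            n = len(folds)
            se = float(np.std(folds, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
            results.append(ExpressionResult(
                genotype=genotype,
                tissue=tissue,
                gene=gene,
                fold_change=float(efficiency ** (-ddct.mean())),
                rep_folds=tuple(float(f) for f in folds),
                mean=float(folds.mean()),
                se=se,
            ))
    return results


def expression_frame(results: Sequence[ExpressionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "genotype": r.genotype, "tissue": r.tissue, "gene": r.gene,
            "fold_change": r.fold_change, "mean": r.mean, "se": r.se,
            "rep_folds": ",".join(f"{f:.6g}" for f in r.rep_folds),
        })
    return pd.DataFrame(rows)


def anova_letter_groups(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """One-way ANOVA followed by a Tukey HSD compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``; if
    the overall ANOVA is not significant every group gets the single letter
    "a".  Letters are assigned to the maximal cliques of the
    not-significantly-different graph, ordered by group mean.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ConfigurationError("letter display requires at least two groups")
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(d) < 2 for d in data):
        raise ConfigurationError("every group needs at least two values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warning -> nan p
        _, p_overall = stats.f_oneway(*data)
    if not (p_overall <= alpha):  # includes nan (all values identical)
        return {g: "a" for g in labels}
    tukey = stats.tukey_hsd(*data)
    graph = nx.Graph()
    graph.add_nodes_from(range(len(labels)))
    for i, j in itertools.combinations(range(len(labels)), 2):
        if tukey.pvalue[i, j] > alpha:
            graph.add_edge(i, j)
    cliques = list(nx.find_cliques(graph))
    means = [d.mean() for d in data]
    cliques.sort(key=lambda c: (min(means[i] for i in c), sorted(c)))
    letters: dict[str, list[str]] = {g: [] for g in labels}
    for rank, clique in enumerate(cliques):
        letter = chr(ord("a") + rank)
        for i in clique:
            letters[labels[i]].append(letter)
    return {g: "".join(sorted(v)) for g, v in letters.items()}


@dataclass(frozen=True)
class UTestResult:
    u: float
    p: float | None
    tier: str       # "*" strong, "**" weak, "" not significant
    method: str     # "exact" | "exact-ties" | "asymptotic" | "undefined"


def _tier(p: float, strong: float, weak: float) -> str:
    if p <= strong:
        return "*"
    if p <= weak:
        return "**"
    return ""


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def utest_compare(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    strong_alpha: float = 0.005,
    weak_alpha: float = 0.05,
) -> UTestResult:
    """Two-sided Mann-Whitney U with the figure-legend significance tiers.

    The p-value is exact (full enumeration of group assignments) for small
    samples — including tied data — and a tie-corrected normal approximation
    with continuity correction otherwise.  When the minimum attainable exact
    p-value exceeds ``strong_alpha`` a warning notes the unreachable tier.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if min(n1, n2) < 2:
        warnings.warn("insufficient data for a U test (need >= 2 per side)",
                      stacklevel=2)
        return UTestResult(u=float("nan"), p=None, tier="", method="undefined")
    if 2.0 / comb(n1 + n2, n1) > strong_alpha:
        warnings.warn(
            f"minimum attainable exact p = {2.0 / comb(n1 + n2, n1):.4g} exceeds "
            f"the {strong_alpha} tier at n = ({n1}, {n2})",
            stacklevel=2,
        )
    u_obs = _u_statistic(a, b)
    mu = n1 * n2 / 2.0
    ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2
    if not ties and max(n1, n2) <= 12:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact").pvalue)
        method = "exact"
    elif comb(n1 + n2, n1) <= 50000:
        pooled = np.concatenate([a, b])
        dev_obs = abs(u_obs - mu) - 1e-12
        hits = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            hits += abs(u - mu) >= dev_obs
            total += 1
        p = hits / total
        method = "exact-ties"
    else:
        pooled = np.concatenate([a, b])
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
        sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
        if sigma == 0:
            p = 1.0
        else:
            z = (abs(u_obs - mu) - 0.5) / sigma
            p = float(2.0 * stats.norm.sf(max(z, 0.0)))
        p = min(p, 1.0)
        method = "asymptotic"
    return UTestResult(u=u_obs, p=p, tier=_tier(p, strong_alpha, weak_alpha),
                       method=method)
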