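"""Marker-gene-list similarity statistics.

Two complementary statistics compare cluster marker lists:

* **Hypergeometric overrepresentation** — the upper-tail probability of
  observing at least the seen overlap between two gene lists drawn from a
  finite universe of N genes (equivalent to a one-tailed Fisher's exact
  test), with Benjamini–Hochberg correction across a family of
  comparisons.

* **Jaccard-difference score** — for a query list C against two reference
  lists D and E, with unique (exclusive) overlaps A = (C∩D)\\E and
  B = (C∩E)\\D, the Jaccard indices j1 = |A|/|C∪D| and j2 = |B|/|C∪E|
  and their difference Δ = j2 − j1.  Significance comes from an empirical
  null: size-matched triples of gene sets sampled uniformly from the
  genome, each recomputing Δ; the add-one estimator
  p = (1 + #{Δ_null ≥ Δ_obs})/(R + 1) keeps p positive so the reported
  score −log10(p) is finite.  Ties count toward the tail (conservative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneList:
    """A labelled set of gene symbols (duplicates collapse)."""

    label: str
    genes: frozenset[str]

    def __init__(self, label: str, genes):
        self.label = label
        self.genes = frozenset(genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OverlapTestResult:
    label_a: str
    label_b: str
    overlap: int
    size_a: int
    size_b: int
    universe_size: int
    p_value: float
    q_value: float | None = None


@dataclass
class JaccardDiffScore:
    j1: float
    j2: float
    delta: float
    n_reps: int
    empirical_p: float
    score: float  # -log10(empirical_p)
    seed: int
    unique_overlap_a: frozenset[str] = field(default_factory=frozenset)
    unique_overlap_b: frozenset[str] = field(default_factory=frozenset)


def hypergeom_overlap_test(list_a: GeneList, list_b: GeneList,
                           universe_size: int) -> OverlapTestResult:
    """Upper-tail hypergeometric p-value for the overlap of two gene lists.

    With k = |A∩B|, p = P(X ≥ k) for X ~ Hypergeometric(N, |A|, |B|),
    evaluated via the log-space survival function for stability.  k = 0
    gives p = 1 exactly.
    """
    a, b = list_a.genes, list_b.genes
    if universe_size < len(a | b):
        raise ValueError(
            f"universe_size {universe_size} < |A∪B| = {len(a | b)}"
        )
    k = len(a & b)
    if k == 0:
        p = 1.0
    else:
        # P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
        p = min(max(p, 0.0), 1.0)
    return OverlapTestResult(list_a.label, list_b.label, k,
                             len(a), len(b), universe_size, p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def unique_overlaps(c: frozenset, d: frozenset, e: frozenset,
                    ) -> tuple[frozenset, frozenset]:
    """Exclusive overlaps A = (C∩D)\\E and B = (C∩E)\\D."""
    return frozenset((c & d) - e), frozenset((c & e) - d)


def _jaccard_pair(c: frozenset, d: frozenset, e: frozenset,
                  overlap: str) -> tuple[float, float]:
    if overlap == "unique":
        a, b = unique_overlaps(c, d, e)
    elif overlap == "plain":
        a, b = c & d, c & e
    else:
        raise ValueError("overlap must be 'unique' or 'plain'")
    j1 = len(a) / len(c | d)
    j2 = len(b) / len(c | e)
    return j1, j2


def jaccard_diff_score(c: GeneList, d: GeneList, e: GeneList,
                       genome: GeneList, n_reps: int = 999, seed: int = 0,
                       overlap: str = "unique") -> JaccardDiffScore:
    """Jaccard-difference statistic Δ = j2 − j1 with an empirical null.

    The null draws ``n_reps`` iid triples of gene sets, size-matched to
    (C, D, E), uniformly without replacement from the genome, and
    recomputes Δ for each.  ``overlap='plain'`` switches A, B to the
    plain intersections C∩D, C∩E for sensitivity analysis.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    genes = sorted(genome.genes)
    n_genome = len(genes)
    for lst in (c, d, e):
        if not lst.genes <= genome.genes:
            raise ValueError(f"list {lst.label!r} is not a subset of the genome")
        if len(lst) > n_genome:
            raise ValueError("list larger than genome")

    j1, j2 = _jaccard_pair(c.genes, d.genes, e.genes, overlap)
    delta_obs = j2 - j1
    a, b = unique_overlaps(c.genes, d.genes, e.genes)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sizes = (len(c), len(d), len(e))
    universe_idx = np.arange(n_genome)
    count_ge = 0
    for _ in range(n_reps):
        draws = [frozenset(rng.choice(universe_idx, size=s, replace=False))
                 for s in sizes]
        nj1, nj2 = _jaccard_pair(*draws, overlap)
        if nj2 - nj1 >= delta_obs:
            count_ge += 1
    empirical_p = (1 + count_ge) / (n_reps + 1)
    return JaccardDiffScore(
        j1=j1, j2=j2, delta=delta_obs, n_reps=n_reps,
        empirical_p=empirical_p, score=-math.log10(empirical_p), seed=seed,
        unique_overlap_a=a, unique_overlap_b=b,
    )


def pairwise_comparison_matrix(query_lists: list[GeneList],
                               reference_lists: list[GeneList],
                               universe_size: int) -> pd.DataFrame:
    """All query × reference hypergeometric tests with one BH family.

    Returns a long-format table (query, reference, overlap, p, q,
    neg_log10_q); q-values come from a single Benjamini–Hochberg
    correction across every comparison in the matrix, matching how
    cross-dataset heatmaps are corrected.
    """
    if not query_lists or not reference_lists:
        raise ValueError("need non-empty query and reference collections")
    results = [
        hypergeom_overlap_test(q, r, universe_size)
        for q in query_lists for r in reference_lists
    ]
    qvals = bh_adjust([r.p_value for r in results])
    rows = []
    for res, qv in zip(results, qvals):
        res.q_value = float(qv)
        rows.append({
            "query": res.label_a,
            "reference": res.label_b,
            "overlap": res.overlap,
            "size_query": res.size_a,
            "size_reference": res.size_b,
            "p_value": res.p_value,
            "q_value": res.q_value,
            "neg_log10_q": -math.log10(res.q_value) if res.q_value > 0 else math.inf,
        })
    return pd.DataFrame(rows)
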