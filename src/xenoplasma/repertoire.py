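"""Detected-gene repertoires per mouse: overlap and abundance statistics.

Each plasma sample detects a sparse subset of the genome; the repertoire of
genes detected per mouse is compared across mice (UpSet-style shared-gene
summaries), across matched early/late samples of the same mouse (Jaccard index
with a permutation null), and against tissue abundance (detected-versus-
undetected two-sample Kolmogorov–Smirnov test).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "detection_set",
    "jaccard",
    "jaccard_permutation_p",
    "shared_gene_summary",
    "ks_detected_vs_undetected",
]


def detection_set(
    counts: pd.DataFrame,
    species: pd.Series,
    sample: str,
    which_species: str = "human",
    min_count: int = 1,
) -> set:
    """Genes of one species with ≥ min_count reads in one sample."""
    sp = species.reindex(counts.index)
    col = counts.loc[sp == which_species, sample]
    return set(col.index[col >= min_count])


def jaccard(a: set, b: set) -> float:
    """|A∩B| / |A∪B|; symmetric; undefined (error) for two empty sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def jaccard_permutation_p(
    a: set, b: set, universe, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation p-value for the Jaccard overlap of two detection sets.

    Null: both sets are uniform random subsets of the universe of their
    observed sizes. Given the sizes, the null intersection size is exactly
    Hypergeometric(|universe|, |A|, |B|) and the Jaccard index is a
    deterministic function of it, so the null is sampled through
    ``rng.hypergeometric`` — distributionally identical to drawing explicit
    subsets. p = (1 + #{null JI ≥ observed JI}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    universe = set(universe)
    a, b = set(a), set(b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    n, na, nb = len(universe), len(a), len(b)
    if na > n or nb > n:
        raise ValueError("set larger than universe")
    obs = jaccard(a, b)
    rng = np.random.default_rng(seed)
    inter = rng.hypergeometric(na, n - na, nb, size=n_perm)
    null_ji = inter / (na + nb - inter)
    return float((1 + np.sum(null_ji >= obs)) / (n_perm + 1))


def shared_gene_summary(sets: dict[str, set]) -> dict:
    """Exact intersection-region sizes across per-mouse detection sets.

    Returns a dict with:

    * ``regions`` — DataFrame of exclusive membership regions (UpSet-style):
      one row per observed combination of mice, with its gene count;
    * ``at_least_k`` — Series: number of genes detected in ≥ k mice;
    * ``fraction_shared_by_2plus`` — share of union genes seen in ≥ 2 mice.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 detection sets")
    names = list(sets)
    membership: dict[str, frozenset] = {}
    for name in names:
        for g in sets[name]:
            membership[g] = membership.get(g, frozenset()) | {name}
    patterns = pd.Series(list(membership.values()))
    region_counts = patterns.value_counts()
    regions = pd.DataFrame(
        {
            "members": region_counts.index,
            "n_members": [len(m) for m in region_counts.index],
            "count": region_counts.to_numpy(),
        }
    ).sort_values(["n_members", "count"], ascending=[False, False], ignore_index=True)
    k_of_gene = np.array([len(m) for m in membership.values()])
    at_least_k = pd.Series(
        {k: int((k_of_gene >= k).sum()) for k in range(1, len(names) + 1)},
        name="n_genes",
    )
    n_union = len(membership)
    frac2 = at_least_k.get(2, 0) / n_union if n_union else np.nan
    return {
        "regions": regions,
        "at_least_k": at_least_k,
        "fraction_shared_by_2plus": float(frac2),
    }


def ks_detected_vs_undetected(
    tissue_abundance: pd.Series, detected: set
) -> tuple[float, float]:
    """Two-sample KS test: tissue abundance of detected vs undetected genes.

    Tests whether genes detected in plasma are drawn from a different tissue
    abundance distribution than undetected genes (asymptotic p-value).
    """
    detected = set(detected)
    in_det = tissue_abundance.index.isin(detected)
    x = tissue_abundance[in_det].to_numpy(dtype=float)
    y = tissue_abundance[~in_det].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both detected and undetected groups must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)
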