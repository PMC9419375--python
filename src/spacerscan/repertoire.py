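"""Community-level summaries of defense repertoires and spacer diversity.

Covers dominant-species selection from an abundance table, classification of
defense-system prevalence into core/accessory/cloud classes, cross-sample
spacer sharing, accumulation (rarefaction) curves, and descriptive spacer
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import gc_content

PREVALENCE_MIN = 0.02       # species present in > 2% of samples
MEDIAN_ABUNDANCE_MIN = 0.001  # and median overall abundance > 0.1%
CORE_THRESHOLD = 0.90
CLOUD_THRESHOLD = 0.10


@dataclass
class RarefactionCurve:
    """Accumulation curve: points of (k samples, mean unique clusters, sd)."""

    points: list[tuple[int, float, float]]
    n_permutations: int
    seed: int | None = None

    @property
    def plateau(self) -> float:
        return self.points[-1][1] if self.points else 0.0


def dominant_species(abundance: pd.DataFrame,
                     min_prevalence: float = PREVALENCE_MIN,
                     min_median_abundance: float = MEDIAN_ABUNDANCE_MIN) -> list[str]:
    """Species present in >2% of samples with median overall abundance >0.1%.

    ``abundance`` is samples x species with relative abundances in [0, 1].
    The median is taken over all samples, zeros included.
    """
    if abundance.empty:
        return []
    if (abundance.values < 0).any() or (abundance.values > 1).any():
        raise ValueError("abundances must be in [0, 1]")
    prevalence = (abundance > 0).mean(axis=0)
    median = abundance.median(axis=0)
    keep = (prevalence > min_prevalence) & (median > min_median_abundance)
    return [sp for sp in abundance.columns if keep[sp]]


def classify_prevalence(profile: pd.DataFrame,
                        core: float = CORE_THRESHOLD,
                        cloud: float = CLOUD_THRESHOLD) -> pd.DataFrame:
    """Core/accessory/cloud classes for a genomes x systems presence table.

    Core: prevalence > 90% of strains; cloud: < 10%; accessory otherwise
    (boundary prevalences of exactly 10% or 90% fall into accessory).
    Returns per-system prevalence and class.
    """
    if profile.empty:
        return pd.DataFrame(columns=["prevalence", "class"])
    prevalence = (profile > 0).mean(axis=0)
    cls = pd.Series("accessory", index=prevalence.index)
    cls[prevalence > core] = "core"
    cls[prevalence < cloud] = "cloud"
    return pd.DataFrame({"prevalence": prevalence, "class": cls})


def prevalence_class_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Per-class system counts and fractions (fractions sum to 1)."""
    classes = classify_prevalence(profile)["class"]
    counts = classes.value_counts().reindex(["core", "accessory", "cloud"],
                                            fill_value=0)
    return pd.DataFrame({"count": counts, "fraction": counts / max(1, len(classes))})


def sharedness_histogram(sample_sets: dict[str, set[str]]) -> dict:
    """How many clusters occur in exactly k samples, plus the k>2 fraction."""
    membership: dict[str, int] = {}
    for _sample, clusters in sample_sets.items():
        for c in clusters:
            membership[c] = membership.get(c, 0) + 1
    hist: dict[int, int] = {}
    for k in membership.values():
        hist[k] = hist.get(k, 0) + 1
    total = len(membership)
    frac = sum(v for k, v in hist.items() if k > 2) / total if total else 0.0
    return {"histogram": dict(sorted(hist.items())), "fraction_gt2": frac,
            "total_clusters": total}


def rarefaction(sample_sets: dict[str, set[str]], n_perm: int = 100,
                seed: int | None = None) -> RarefactionCurve:
    """Accumulation curve of unique clusters over random sample orderings.

    For each k, the mean and sd over sample orderings of |union of the first
    k sample sets|. All orderings are enumerated exactly when there are no
    more than ``n_perm`` of them; otherwise ``n_perm`` random permutations
    are drawn. Sampling is without replacement over the sample order (a
    cumulative/collector's curve); the point at k = n_samples equals the
    exact total union.
    """
    names = sorted(sample_sets)
    if not names:
        raise ValueError("at least one sample required")
    n = len(names)
    sizes = _accumulation_sizes([sample_sets[x] for x in names], n_perm, seed)
    points = [(k + 1, float(sizes[:, k].mean()), float(sizes[:, k].std(ddof=0)))
              for k in range(n)]
    return RarefactionCurve(points=points, n_permutations=sizes.shape[0], seed=seed)


def _accumulation_sizes(sets: list[set], n_perm: int, seed) -> np.ndarray:
    """Union sizes along sample orderings (exhaustive when cheap enough)."""
    import itertools
    import math as _math
    n = len(sets)
    if _math.factorial(n) <= n_perm:
        orders = list(itertools.permutations(range(n)))
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n) for _ in range(n_perm)]
    sizes = np.empty((len(orders), n))
    for p, order in enumerate(orders):
        seen: set = set()
        for j, idx in enumerate(order):
            seen |= sets[idx]
            sizes[p, j] = len(seen)
    return sizes


def spacer_summaries(spacers: pd.DataFrame) -> pd.DataFrame:
    """Descriptive per-species spacer statistics.

    ``spacers`` needs columns ``species``, ``array`` and ``sequence``; the
    result has median/sd of spacer length and GC, and spacers per array.
    """
    if spacers.empty:
        return pd.DataFrame(columns=["length_median", "length_sd",
                                     "gc_median", "gc_sd",
                                     "spacers_per_array_median",
                                     "spacers_per_array_sd"])
    df = spacers.copy()
    df["length"] = df["sequence"].str.len()
    df["gc"] = df["sequence"].map(gc_content)
    rows = {}
    for sp, grp in df.groupby("species"):
        per_array = grp.groupby("array").size()
        rows[sp] = {
            "length_median": grp["length"].median(),
            "length_sd": grp["length"].std(ddof=1),
            "gc_median": grp["gc"].median(),
            "gc_sd": grp["gc"].std(ddof=1),
            "spacers_per_array_median": per_array.median(),
            "spacers_per_array_sd": per_array.std(ddof=1),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
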