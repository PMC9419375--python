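"""All-pairs genome comparison and the spacer-turnover estimator.

For a pair of closely related genomes the chain of estimators is:

1. *Fragment ANI*: chop each genome into 1-kb fragments, place each fragment
   at its best locus in the partner genome (exact k-mer seeding, gapless
   comparison), keep fragments matching at >= 80% identity in either
   direction; ANI is the mean identity of kept fragments (percent) and
   ``n_fragments`` counts fragments kept over both directions.
2. *SNV estimate*: mismatch fraction times the alignable length,
   ``n_frag_per_genome x frag_len x (100 - ANI)/100`` - the pairwise
   (two-branch) count of nucleotide differences.
3. *Shared spacers*: spacers of the two genomes are compared through their
   100%-identity clusters; the shared fraction uses the union of distinct
   clusters as denominator (Jaccard-style, symmetric and bounded), and
   ``unique_spacers`` counts clusters present in exactly one genome.
4. *Turnover*: new spacers acquired per generation, scaled to a community of
   N cells::

       rate = N * mu * L_aligned * unique_spacers / snv_estimate

   i.e. (spacers per SNV) x (SNVs per generation per cell over the aligned
   length) x community size. Both ``snv_estimate`` and ``unique_spacers``
   are two-branch quantities, so the branch factor cancels and no factor-2
   correction is applied. Pairs without unique spacers or without aligned
   fragments are flagged and excluded from rate distributions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import encode, kmer_codes, revcomp_arr
from .clusterer import assignment_map, cluster

FRAG_LEN = 1000
MIN_FRAG_IDENTITY = 0.8
ANI_SEED_K = 16
DEFAULT_MU = 8.9e-11  # substitutions per bp per generation, lactic acid bacteria
DEFAULT_COMMUNITY_SIZE = 1e7  # cells per community


@dataclass
class PairStats:
    genome_a: str
    genome_b: str
    ani: float
    n_fragments: int
    aligned_len: float
    snv_estimate: float
    shared_clusters: int
    unique_spacers: int
    shared_fraction: float
    snvs_per_unique_spacer: float
    spacers_per_generation: float
    subtype: str | None = None


class _KmerIndex:
    """Sorted exact k-mer index of one genome."""

    def __init__(self, arr: np.ndarray, k: int = ANI_SEED_K):
        self.k = k
        self.n = arr.size
        codes = kmer_codes(arr, k)
        self.order = np.argsort(codes, kind="stable").astype(np.int64)
        self.sorted_codes = codes[self.order]

    def lookup(self, code: int, cap: int = 64) -> np.ndarray:
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        if hi - lo > cap:
            hi = lo + cap
        return self.order[lo:hi]


def _best_placement(frag: np.ndarray, target: np.ndarray, index: _KmerIndex,
                    seed_offsets: np.ndarray) -> float:
    """Best gapless identity of ``frag`` anywhere in ``target`` (one strand)."""
    L = frag.size
    best = 0.0
    seen: set[int] = set()
    for off in seed_offsets:
        code = int(kmer_codes(frag[off:off + index.k], index.k)[0])
        for pos in index.lookup(code):
            start = int(pos) - int(off)
            if start < 0 or start + L > target.size or start in seen:
                continue
            seen.add(start)
            ident = float(np.mean(frag == target[start:start + L]))
            if ident > best:
                best = ident
    return best


def fragment_ani(genome_a: str, genome_b: str, frag_len: int = FRAG_LEN,
                 min_identity: float = MIN_FRAG_IDENTITY,
                 k: int = ANI_SEED_K) -> tuple[float, int]:
    """Bidirectional fragment-based average nucleotide identity.

    Returns ``(ani_percent, n_fragments)`` where ``n_fragments`` is the total
    number of fragments kept over both mapping directions (a pair of
    identical genomes yields ``2 * floor(L / frag_len)``). When no fragment
    reaches ``min_identity`` the pair is unalignable and ``(nan, 0)`` is
    returned.
    """
    if min(len(genome_a), len(genome_b)) < frag_len:
        raise ValueError("genomes must be at least one fragment long")
    identities: list[float] = []
    arrs = (encode(genome_a), encode(genome_b))
    indexes = (_KmerIndex(arrs[0], k), _KmerIndex(arrs[1], k))
    seed_offsets = np.arange(0, frag_len - k + 1, max(1, frag_len // 10))
    for qi, ti in ((0, 1), (1, 0)):
        query, target, index = arrs[qi], arrs[ti], indexes[ti]
        for start in range(0, query.size - frag_len + 1, frag_len):
            frag = query[start:start + frag_len]
            ident = _best_placement(frag, target, index, seed_offsets)
            rc = revcomp_arr(frag)
            ident = max(ident, _best_placement(rc, target, index, seed_offsets))
            if ident >= min_identity:
                identities.append(ident)
    if not identities:
        return float("nan"), 0
    return float(np.mean(identities) * 100.0), len(identities)


def estimate_snvs(ani: float, n_fragments: float, frag_len: int = FRAG_LEN) -> float:
    """Pairwise SNV count implied by ANI over the aligned length.

    ``n_fragments`` here is the number of fragments covering the alignable
    length once (the per-genome count; when using the bidirectional total
    from :func:`fragment_ani`, pass half of it, as :func:`pair_table` does).
    """
    if math.isnan(ani):
        raise ValueError("ANI undefined; pair must be excluded")
    return n_fragments * frag_len * (100.0 - ani) / 100.0


def shared_spacer_fraction(spacers_a: list[str], spacers_b: list[str],
                           cluster_ids: dict[str, str] | None = None,
                           denominator: str = "union") -> dict:
    """Shared/unique spacer-cluster counts for one genome pair.

    ``cluster_ids`` maps spacer sequence -> 100%-cluster id; when omitted the
    pair's spacers are clustered on the fly. ``denominator`` selects the
    shared-fraction normalisation: "union" (distinct clusters across the
    pair; default) or "total" (|A| + |B| cluster sets).
    """
    if cluster_ids is None:
        seqs = list(spacers_a) + list(spacers_b)
        cluster_ids = assignment_map(cluster(seqs, 1.0)) if seqs else {}
    ca = {cluster_ids[s] for s in spacers_a}
    cb = {cluster_ids[s] for s in spacers_b}
    shared = len(ca & cb)
    union = len(ca | cb)
    if denominator == "union":
        denom = union
    elif denominator == "total":
        denom = len(ca) + len(cb)
    else:
        raise ValueError("denominator must be 'union' or 'total'")
    fraction = shared / denom if denom else float("nan")
    return {"shared": shared, "union": union, "fraction": fraction,
            "unique": union - shared}


def spacers_per_generation(snv_estimate: float, unique_spacers: int,
                           mu: float = DEFAULT_MU,
                           aligned_len: float | None = None,
                           community_size: float = DEFAULT_COMMUNITY_SIZE) -> float:
    """Community-scaled spacer acquisition rate for one genome pair.

    ``aligned_len`` is the per-genome aligned length
    (``n_fragments * frag_len / 2`` with the bidirectional fragment count).
    Returns NaN when the pair carries no unique spacers or no SNVs, in which
    case it must be excluded from the rate distribution.
    """
    if aligned_len is None:
        raise ValueError("aligned_len is required")
    if unique_spacers < 1 or not snv_estimate > 0:
        return float("nan")
    return community_size * mu * aligned_len * unique_spacers / snv_estimate


def pair_table(genomes: dict[str, str], spacers: dict[str, list[str]],
               mu: float = DEFAULT_MU,
               community_size: float = DEFAULT_COMMUNITY_SIZE,
               frag_len: int = FRAG_LEN, min_ani: float = 99.0,
               denominator: str = "union",
               subtypes: dict[str, str] | None = None,
               ) -> tuple[pd.DataFrame, dict]:
    """All unordered genome pairs with ANI, SNV, sharing and turnover columns.

    The turnover rate is computed only for pairs with ANI > ``min_ani``.
    The summary reports the shared-fraction-vs-ANI least-squares regression
    and median turnover statistics (stratified by subtype when provided).
    """
    ids = sorted(genomes)
    if len(ids) < 2:
        raise ValueError("need at least two genomes")
    all_seqs, prov = [], []
    for gid in ids:
        for s in spacers.get(gid, []):
            all_seqs.append(s)
            prov.append(gid)
    cluster_ids = assignment_map(cluster(all_seqs, 1.0, provenance=prov)) if all_seqs else {}
    rows = []
    for ga, gb in itertools.combinations(ids, 2):
        ani, n_frag = fragment_ani(genomes[ga], genomes[gb], frag_len=frag_len)
        aligned_len = n_frag * frag_len / 2.0
        snv = estimate_snvs(ani, n_frag / 2, frag_len) if n_frag else float("nan")
        sh = shared_spacer_fraction(spacers.get(ga, []), spacers.get(gb, []),
                                    cluster_ids, denominator)
        unique = sh["unique"]
        spg = float("nan")
        if n_frag and not math.isnan(ani) and ani > min_ani:
            spg = spacers_per_generation(snv, unique, mu, aligned_len, community_size)
        subtype = None
        if subtypes and subtypes.get(ga) == subtypes.get(gb):
            subtype = subtypes.get(ga)
        rows.append(PairStats(
            genome_a=ga, genome_b=gb, ani=ani, n_fragments=n_frag,
            aligned_len=aligned_len, snv_estimate=snv,
            shared_clusters=sh["shared"], unique_spacers=unique,
            shared_fraction=sh["fraction"],
            snvs_per_unique_spacer=snv / unique if unique else float("nan"),
            spacers_per_generation=spg, subtype=subtype))
    table = pd.DataFrame([r.__dict__ for r in rows])
    summary: dict = {}
    reg = table.dropna(subset=["ani", "shared_fraction"])
    if len(reg) >= 3 and reg["ani"].nunique() > 1 and reg["shared_fraction"].nunique() > 1:
        fit = stats.linregress(reg["ani"], reg["shared_fraction"])
        summary["regression"] = {"slope": fit.slope, "intercept": fit.intercept,
                                 "r2": fit.rvalue ** 2}
    else:
        summary["regression"] = {"slope": float("nan"), "intercept": float("nan"),
                                 "r2": float("nan"), "degenerate": True}
    rates = table["spacers_per_generation"].dropna()
    summary["median_spacers_per_generation"] = float(rates.median()) if len(rates) else float("nan")
    spu = table["snvs_per_unique_spacer"].dropna()
    summary["median_snvs_per_unique_spacer"] = float(spu.median()) if len(spu) else float("nan")
    if subtypes:
        by = table.dropna(subset=["spacers_per_generation"]).groupby("subtype")
        summary["by_subtype"] = {k: float(v["spacers_per_generation"].median())
                                 for k, v in by}
    return table, summary
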