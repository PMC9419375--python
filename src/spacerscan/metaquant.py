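"""Repeat-spacer-repeat read recruitment and spacer/protospacer abundance.

Every dereplicated spacer becomes a *repeat-spacer-repeat* (RSR) reference:
the spacer flanked on both sides by its array's consensus repeat. Metagenomic
reads are recruited to these references and classified by where their best
ungapped local alignment falls:

- a read whose aligned block covers most of the spacer but stays out of the
  repeats can only come from the target (phage/plasmid) side - a
  **protospacer** read;
- a read whose block covers spacer *and* repeat sequence must come from a
  CRISPR **array**;
- anything else is ambiguous, counted but excluded from abundances.

Per-reference class counts are normalised to counts per million reads (cpm),
and the spacer-vs-protospacer abundance relation is summarised by ordinary
least squares in log10 space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import encode, revcomp
from .clusterer import assignment_map, cluster

MAP_SEED_K = 15
MATCH = 1
MISMATCH = -3  # block extension must not coast over chance matches

PROTO_MIN_SPACER_COVER = 0.9   # fraction of the spacer interval
PROTO_MAX_REPEAT_INCURSION = 3  # bp; block must extend < this into a repeat
ARRAY_MIN_SPACER_OVERLAP = 15   # bp
ARRAY_MIN_REPEAT_OVERLAP = 5    # bp


@dataclass
class RSRReference:
    """repeat + spacer + repeat, with its fixed layout (0-based half-open)."""

    id: str
    repeat: str
    spacer: str

    @property
    def seq(self) -> str:
        return self.repeat + self.spacer + self.repeat

    @property
    def layout(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        r, s = len(self.repeat), len(self.spacer)
        return (0, r), (r, r + s), (r + s, 2 * r + s)


@dataclass
class ReadHit:
    """Best alignment of one read to an RSR reference (forward coords)."""

    read_id: str
    ref_id: str
    start: int
    end: int
    mismatches: int
    strand: str
    cls: str = ""


def build_rsr_references(arrays, cluster_ids: dict[str, str] | None = None,
                         ) -> list[RSRReference]:
    """One reference per distinct spacer cluster, flanked by its consensus repeat.

    ``cluster_ids`` maps spacer sequence -> 100%-cluster id; if omitted the
    spacers are dereplicated on the fly. The first array carrying a cluster
    supplies the flanking repeat.
    """
    pairs = [(s, arr.consensus_repeat) for arr in arrays for s in arr.spacers]
    if cluster_ids is None:
        seqs = [p[0] for p in pairs]
        cluster_ids = assignment_map(cluster(seqs, 1.0)) if seqs else {}
    refs: list[RSRReference] = []
    seen: set[str] = set()
    for spacer, repeat in pairs:
        cid = cluster_ids[spacer]
        if cid in seen:
            continue
        seen.add(cid)
        refs.append(RSRReference(id=f"rsr_{len(refs):05d}", repeat=repeat,
                                 spacer=spacer))
    return refs


def _best_block(eq: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring ungapped block of a match profile: (score, start, end)."""
    score = np.where(eq, MATCH, MISMATCH).astype(np.int64)
    prefix = np.concatenate(([0], np.cumsum(score)))
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    j = int(gains.argmax())
    best = int(gains[j])
    i = int(np.flatnonzero(prefix[:j + 1] == run_min[j])[0])
    return best, i, j + 1


def map_reads(reads, references: list[RSRReference], max_mm: int = 2,
              k: int = MAP_SEED_K, chunk: int = 100_000) -> list[ReadHit]:
    """Best-hit recruitment of reads to RSR references.

    Exact k-mer seeding against both strands of every reference, then maximal
    ungapped block extension; blocks with more than ``max_mm`` mismatches are
    discarded. One best hit per read (ties: lower reference index, then '+'
    strand, then leftmost block).
    """
    refs = sorted(references, key=lambda r: r.id)
    oriented: list[tuple[int, str, np.ndarray]] = []
    kmer_map: dict[int, list[tuple[int, int]]] = {}
    from ._seq import kmer_codes
    for ri, ref in enumerate(refs):
        for strand, seq in (("+", ref.seq), ("-", revcomp(ref.seq))):
            oi = len(oriented)
            arr = encode(seq)
            oriented.append((ri, strand, arr))
            for pos, code in enumerate(kmer_codes(arr, k)):
                kmer_map.setdefault(int(code), []).append((oi, pos))
    if not kmer_map:
        return []
    ref_codes = np.fromiter(kmer_map.keys(), dtype=np.int64)
    ref_codes.sort()

    if hasattr(reads, "matrix"):
        matrix = reads.matrix
        ids = [reads.id_of(i) for i in range(len(reads))]
    else:
        items = [(r if isinstance(r, tuple) else (f"read_{i:07d}", r))
                 for i, r in enumerate(reads)]
        ids = [i for i, _ in items]
        lens = {len(s) for _, s in items}
        if len(lens) > 1:
            raise ValueError("map_reads requires uniform read length")
        matrix = np.stack([encode(s) for _, s in items]) if items else np.empty((0, 0), np.uint8)

    hits: list[ReadHit] = []
    n, L = matrix.shape if matrix.size else (0, 0)
    W = L - k + 1
    for lo in range(0, n, chunk):
        block = matrix[lo:lo + chunk].astype(np.int64)
        codes = np.zeros((block.shape[0], W), dtype=np.int64)
        for t in range(k):
            codes = codes * 4 + block[:, t:t + W]
        mask = np.isin(codes, ref_codes)
        read_rows = np.flatnonzero(mask.any(axis=1))
        for row in read_rows:
            read_arr = matrix[lo + row]
            cands: set[tuple[int, int]] = set()
            for wpos in np.flatnonzero(mask[row]):
                for oi, rpos in kmer_map.get(int(codes[row, wpos]), ()):
                    cands.add((oi, int(rpos) - int(wpos)))
            best = None
            for oi, shift in sorted(cands):
                ri, strand, ref_arr = oriented[oi]
                o_lo = max(0, shift)
                o_hi = min(ref_arr.size, shift + L)
                if o_hi - o_lo < k:
                    continue
                eq = read_arr[o_lo - shift:o_hi - shift] == ref_arr[o_lo:o_hi]
                score, bi, bj = _best_block(eq)
                if score <= 0:
                    continue
                mm = int(np.count_nonzero(~eq[bi:bj]))
                if mm > max_mm:
                    continue
                start, end = o_lo + bi, o_lo + bj
                if strand == "-":
                    start, end = ref_arr.size - end, ref_arr.size - start
                key = (-score, ri, strand, start)
                if best is None or key < best[0]:
                    best = (key, ReadHit(read_id=ids[lo + row], ref_id=refs[ri].id,
                                         start=start, end=end, mismatches=mm,
                                         strand=strand))
            if best is not None:
                hits.append(best[1])
    return hits


def classify_hit(hit: ReadHit, reference: RSRReference,
                 proto_min_cover: float = PROTO_MIN_SPACER_COVER,
                 proto_max_incursion: int = PROTO_MAX_REPEAT_INCURSION,
                 array_min_spacer: int = ARRAY_MIN_SPACER_OVERLAP,
                 array_min_repeat: int = ARRAY_MIN_REPEAT_OVERLAP) -> str:
    """'protospacer', 'array' or 'ambiguous' from the aligned interval."""
    (l0, l1), (s0, s1), (r0, r1) = reference.layout

    def overlap(a0, a1):
        return max(0, min(hit.end, a1) - max(hit.start, a0))

    sp = overlap(s0, s1)
    left, right = overlap(l0, l1), overlap(r0, r1)
    if sp >= proto_min_cover * (s1 - s0) and left < proto_max_incursion \
            and right < proto_max_incursion:
        return "protospacer"
    if sp >= array_min_spacer and max(left, right) >= array_min_repeat:
        return "array"
    return "ambiguous"


def classify_hits(hits: list[ReadHit], references: list[RSRReference],
                  **kwargs) -> list[ReadHit]:
    by_id = {r.id: r for r in references}
    for h in hits:
        h.cls = classify_hit(h, by_id[h.ref_id], **kwargs)
    return hits


def count_classes(hits: list[ReadHit], references: list[RSRReference]) -> pd.DataFrame:
    """Per-reference counts of array (spacer), protospacer and ambiguous reads."""
    counts = pd.DataFrame(0, index=[r.id for r in references],
                          columns=["spacer_count", "protospacer_count",
                                   "ambiguous_count"])
    col = {"array": "spacer_count", "protospacer": "protospacer_count",
           "ambiguous": "ambiguous_count"}
    for h in hits:
        counts.loc[h.ref_id, col[h.cls]] += 1
    counts.index.name = "reference"
    return counts


def normalize_cpm(counts: pd.DataFrame, total_reads: int) -> pd.DataFrame:
    """Add counts-per-million columns (counts x 1e6 / total sample reads)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    out = counts.copy()
    out["spacer_cpm"] = out["spacer_count"] * 1e6 / total_reads
    out["protospacer_cpm"] = out["protospacer_count"] * 1e6 / total_reads
    return out


def abundance_regressions(table: pd.DataFrame) -> dict:
    """Log-log spacer/protospacer abundance relations plus the class tally.

    Regressions use references observed in both classes; the tally covers all
    references with at least one classified read.
    """
    seen = table[(table["spacer_cpm"] > 0) | (table["protospacer_cpm"] > 0)]
    both = table[(table["spacer_cpm"] > 0) & (table["protospacer_cpm"] > 0)]
    tally = {
        "protospacer_only": int(((seen["protospacer_cpm"] > 0)
                                 & (seen["spacer_cpm"] == 0)).sum()),
        "spacer_only": int(((seen["spacer_cpm"] > 0)
                            & (seen["protospacer_cpm"] == 0)).sum()),
        "both": int(len(both)),
    }
    out: dict = {"tally": tally}
    if len(both) >= 3:
        x = np.log10(both["spacer_cpm"])
        y = np.log10(both["protospacer_cpm"])
        if x.nunique() > 1:
            fit = stats.linregress(x, y)
            out["proto_vs_spacer"] = {"slope": fit.slope, "r2": fit.rvalue ** 2}
            fit2 = stats.linregress(x, y - x)
            out["ratio_vs_spacer"] = {"slope": fit2.slope, "r2": fit2.rvalue ** 2}
    out.setdefault("proto_vs_spacer", {"slope": math.nan, "r2": math.nan})
    out.setdefault("ratio_vs_spacer", {"slope": math.nan, "r2": math.nan})
    return out


def quantify(reads, references: list[RSRReference], total_reads: int | None = None,
             max_mm: int = 2) -> tuple[pd.DataFrame, dict]:
    """Map, classify, count and normalise one sample against the references.

    Returns the per-reference table (counts + cpm) and a summary with the
    class totals and the read-conservation identity
    ``array + protospacer + ambiguous + unmapped == total``.
    """
    n_reads = len(reads) if total_reads is None else total_reads
    hits = classify_hits(map_reads(reads, references, max_mm=max_mm), references)
    counts = count_classes(hits, references)
    table = normalize_cpm(counts, n_reads)
    totals = {
        "array": int(counts["spacer_count"].sum()),
        "protospacer": int(counts["protospacer_count"].sum()),
        "ambiguous": int(counts["ambiguous_count"].sum()),
    }
    totals["unmapped"] = n_reads - sum(totals.values())
    return table, {"totals": totals, "n_reads": n_reads}
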