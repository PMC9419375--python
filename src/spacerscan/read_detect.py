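"""CRISPR spacer extraction directly from raw metagenomic reads.

A read that spans a repeat-spacer-repeat stretch of an array contains two
near-identical substrings separated by a spacer-sized gap. Detection runs in
three stages, per sample:

1. *Candidate repeats.* Each read is compared against itself at every shift
   compatible with a repeat+spacer period; the longest stretch agreeing at
   that shift with at most ``max_mm`` mismatches yields a candidate repeat.
2. *Consensus repeats.* Candidates are tallied across reads (strand-
   canonicalised). A single read cannot place the repeat/spacer boundary
   exactly - flanking bases coincide with spacer bases by chance 1/4 of the
   time - but the true repeat recurs across different spacer junctions while
   each boundary artefact is junction-specific, so the best-supported
   candidate per repeat family is kept as the consensus.
3. *Spacer emission.* Reads are rescanned for occurrences of each consensus
   repeat (<= ``max_mm`` mismatches, both strands); the gap between
   consecutive occurrences is emitted as a spacer, reported in the
   orientation in which the repeat is lexicographically smallest. Identical
   spacers are deduplicated; coverage counts supporting reads.

Filtering then applies the metagenomic retention rules: spacers seen in a
single read (coverage 1) and spacers shorter than 15 bp are removed.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from ._seq import decode, encode, hamming_windows, kmer_codes, revcomp

logger = logging.getLogger(__name__)

MIN_REPEAT = 23
MAX_REPEAT = 47
MIN_SPACER = 15
MAX_SPACER = 49
FAMILY_K = 13


@dataclass
class MetaSpacer:
    """A spacer recovered from reads, with its supporting evidence."""

    sequence: str
    repeat: str
    coverage: int
    sample_id: str = ""
    total_reads: int = 0

    @property
    def cpm(self) -> float:
        """Supporting reads per million sample reads (0 if unknown total)."""
        if self.total_reads <= 0:
            return 0.0
        return self.coverage / self.total_reads * 1e6


def _normalize_reads(reads) -> list[str]:
    if hasattr(reads, "matrix"):  # simdata.ReadSet
        return [decode(row) for row in reads.matrix]
    out = []
    for r in reads:
        if isinstance(r, str):
            out.append(r)
        else:  # (id, seq) pair or Biopython record
            out.append(r[1] if isinstance(r, tuple) else str(r.seq))
    return out


def _best_run(eq: np.ndarray, max_mm: int) -> tuple[int, int]:
    """(start, length) of the longest window with <= max_mm mismatches."""
    mism = np.flatnonzero(~eq)
    n = eq.size
    if mism.size <= max_mm:
        return 0, n
    padded = np.concatenate(([-1], mism, [n]))
    span = max_mm + 1
    lengths = padded[span:] - padded[:-span] - 1
    t = int(lengths.argmax())
    return int(padded[t] + 1), int(lengths[t])


def _read_candidates(arr: np.ndarray, min_rep: int, max_rep: int,
                     min_spacer: int, max_spacer: int, max_mm: int) -> list[str]:
    """Candidate repeat substrings from one read's self-comparison."""
    n = arr.size
    out = []
    for d in range(min_rep + min_spacer, min(max_rep + max_spacer, n - min_rep) + 1):
        eq = arr[:n - d] == arr[d:]
        start, run = _best_run(eq, max_mm)
        rep_len = min(run, d - min_spacer, max_rep)
        if rep_len < max(min_rep, d - max_spacer):
            continue
        out.append(bytes(arr[start:start + rep_len]))
    return out


def _canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def _consensus_repeats(candidate_counts: Counter, min_rep: int) -> list[str]:
    """Column-support consensus repeat per candidate family.

    Candidates sharing a seed k-mer belong to one repeat family: the true
    repeat plus junction-specific boundary extensions and read-edge
    truncations. Members are co-registered via a shared exact k-mer and vote
    (weighted by read support) per column; only columns supported by more
    than half the family survive, which trims any extension seen at a single
    spacer junction while keeping the repeat itself intact.
    """
    ranked = sorted(candidate_counts.items(),
                    key=lambda kv: (-kv[1], len(kv[0]), kv[0]))
    families: list[dict] = []
    for rep, support in ranked:
        placed = False
        for fam in families:
            for oriented in (rep, revcomp(rep)):
                codes = kmer_codes(encode(oriented), FAMILY_K)
                hit = next(((i, fam["kmap"][int(c)])
                            for i, c in enumerate(codes) if int(c) in fam["kmap"]),
                           None)
                if hit is not None:
                    i, apos = hit
                    fam["members"].append((oriented, support, apos - i))
                    placed = True
                    break
            if placed:
                break
        if not placed:
            kmap = {int(c): i
                    for i, c in enumerate(kmer_codes(encode(rep), FAMILY_K))}
            families.append({"anchor": rep, "kmap": kmap,
                             "members": [(rep, support, 0)]})
    accepted: list[tuple[int, str]] = []
    for fam in families:
        members = fam["members"]
        lo = min(off for _s, _w, off in members)
        hi = max(off + len(s) for s, _w, off in members)
        width = hi - lo
        votes = np.zeros((4, width))
        total = 0
        for s, w, off in members:
            a = off - lo
            arr = encode(s)
            votes[arr, np.arange(a, a + arr.size)] += w
            total += w
        # a column survives only if a single base carries more than half the
        # family: junction-specific boundary extensions cover the column but
        # disagree on the base, so they are trimmed
        keep = votes.max(axis=0) > 0.5 * total
        # maximal surviving run
        best = (0, 0)
        run_start = None
        for j in range(width + 1):
            if j < width and keep[j]:
                if run_start is None:
                    run_start = j
            elif run_start is not None:
                if j - run_start > best[1] - best[0]:
                    best = (run_start, j)
                run_start = None
        if best[1] - best[0] < min_rep:
            continue
        cons = decode(votes[:, best[0]:best[1]].argmax(axis=0).astype(np.uint8))
        accepted.append((total, _canonical(cons)))
    accepted.sort(key=lambda t: (-t[0], t[1]))
    return [rep for _t, rep in accepted]


def _occurrences(read_arr: np.ndarray, rep_arr: np.ndarray, max_mm: int) -> np.ndarray:
    mm = hamming_windows(read_arr, rep_arr)
    hits = np.flatnonzero(mm <= max_mm)
    if hits.size <= 1:
        return hits
    keep = [int(hits[0])]
    for h in hits[1:]:
        if h - keep[-1] >= rep_arr.size:
            keep.append(int(h))
    return np.array(keep)


def detect_read_spacers(reads, sample_id: str = "sample",
                        min_rep: int = MIN_REPEAT, max_rep: int = MAX_REPEAT,
                        min_spacer: int = MIN_SPACER, max_spacer: int = MAX_SPACER,
                        max_mm: int = 2,
                        total_reads: int | None = None) -> list[MetaSpacer]:
    """Extract spacers from raw reads of one sample.

    Returns the raw (unfiltered) deduplicated spacer list with coverage;
    apply :func:`filter_read_spacers` for the retention rules.
    """
    seqs = _normalize_reads(reads)
    if total_reads is None:
        total_reads = len(seqs)
    arrs = [encode(s) for s in seqs]
    counts: Counter = Counter()
    for arr in arrs:
        if arr.size < 2 * min_rep + min_spacer:
            continue
        # candidate extraction is exact: a mismatch budget here lets runs
        # coast past the repeat boundary on every read of a junction, so the
        # true repeat would never dominate the tally. Read errors are instead
        # absorbed by the <=max_mm rescan below.
        for cand in _read_candidates(arr, min_rep, max_rep,
                                     min_spacer, max_spacer, 0):
            counts[_canonical(decode(np.frombuffer(cand, dtype=np.uint8)))] += 1
    repeats = _consensus_repeats(counts, min_rep)
    support: dict[tuple[str, str], set[int]] = defaultdict(set)
    for rep in repeats:
        rep_f = encode(rep)
        for ri, arr in enumerate(arrs):
            # scan the orientation in which the repeat is canonical
            for oriented in (arr, (3 - arr)[::-1]):
                occ = _occurrences(oriented, rep_f, max_mm)
                if occ.size < 2:
                    continue
                for a, b in zip(occ, occ[1:]):
                    gap = int(b - (a + rep_f.size))
                    if min_spacer <= gap <= max_spacer:
                        spacer = decode(oriented[a + rep_f.size:b])
                        support[(spacer, rep)].add(ri)
                break  # a read supports an array in one orientation
    out = [MetaSpacer(sequence=sp, repeat=rep, coverage=len(rids),
                      sample_id=sample_id, total_reads=total_reads)
           for (sp, rep), rids in sorted(support.items())]
    return out


def filter_read_spacers(spacers: list[MetaSpacer], min_coverage: int = 2,
                        min_len: int = MIN_SPACER) -> list[MetaSpacer]:
    """Retention filter: drop coverage-1 spacers and spacers shorter than 15 bp.

    Idempotent and order-independent.
    """
    kept = [s for s in spacers
            if s.coverage >= min_coverage and len(s.sequence) >= min_len]
    if len(kept) != len(spacers):
        logger.info("filter_read_spacers removed %d spacer(s)",
                    len(spacers) - len(kept))
    return kept


def spacers_per_million(n_spacers: int, total_reads: int) -> float:
    """Spacer count normalised per million reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return n_spacers / total_reads * 1e6


def per_richness(rate: float, n_species: int) -> float:
    """Further normalise a per-million rate by community richness."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    return rate / n_species
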