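"""CRISPR array detection in assembled genomes.

Arrays are found from first principles: exact k-mer seeds that recur with a
spacing compatible with a repeat-spacer period are extended, column by column,
into full direct-repeat copies; the gaps between consecutive copies become the
spacers. Candidate loci must have at least ``min_copies`` repeat units,
near-identical repeats, and mutually dissimilar spacers (a locus whose
"spacers" resemble each other is a tandem repeat, not CRISPR). Retention
filters then drop spacers outside the plausible length band (15-49 bp).

Column extension requires all repeat copies to agree, which recovers planted
repeat boundaries exactly on assemblies; diverged repeat copies are tolerated
downstream (reads) rather than here, since assemblies are consensus sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import encode, kmer_codes
from .clusterer import identity

logger = logging.getLogger(__name__)

MIN_REPEAT = 23
MAX_REPEAT = 47
MIN_SPACER = 15
MAX_SPACER = 49
SEED_K = 13
REPEAT_IDENTITY_FLOOR = 0.9
# tandem-repeat guard: true CRISPR spacers are mutually random. Under the
# strand-maximised glocal identity score, unrelated 28-42-mers already score
# ~0.55 on average (gaps are cheap relative to the short length), so the
# guard sits at 0.8: far above the random baseline, far below the ~1.0 of
# tandem-repeat units.
MAX_SPACER_IDENTITY = 0.8


@dataclass
class Candidate:
    """A set of near-identical repeat occurrences with CRISPR-like spacing."""

    starts: tuple[int, ...]
    rep_len: int

    @property
    def interval(self) -> tuple[int, int]:
        return self.starts[0], self.starts[-1] + self.rep_len

    @property
    def n_copies(self) -> int:
        return len(self.starts)


@dataclass
class SpacerArray:
    """An ordered repeat/spacer locus on a contig (0-based, half-open)."""

    contig: str
    start: int
    end: int
    repeats: list[str]
    spacers: list[str]
    consensus_repeat: str
    orientation: str = "unknown"
    source: str = "genome"
    genome_id: str = ""
    subtype: str | None = None
    spacer_positions: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.repeats)

    def reconstruct(self) -> str:
        """Interleave repeats and spacers; equals genome[start:end] pre-filter."""
        parts = [self.repeats[0]]
        for s, r in zip(self.spacers, self.repeats[1:]):
            parts.append(s)
            parts.append(r)
        return "".join(parts)


def find_repeat_candidates(seq: str,
                           min_rep: int = MIN_REPEAT,
                           max_rep: int = MAX_REPEAT,
                           min_copies: int = 3,
                           min_spacer: int = MIN_SPACER,
                           max_spacer: int = MAX_SPACER,
                           k: int = SEED_K) -> list[Candidate]:
    """Maximal sets of >=min_copies repeat occurrences at CRISPR-like spacing.

    Seeds are exact k-mers recurring with consecutive gaps in
    ``[min_rep + min_spacer, max_rep + max_spacer]``; each seed set is extended
    outward while every copy agrees on the next column, bounded by
    ``max_rep`` and by keeping every inter-repeat gap >= ``min_spacer``.
    """
    arr = encode(seq)
    codes = kmer_codes(arr, k)
    if codes.size == 0:
        return []
    order = np.argsort(codes, kind="stable")
    sc = codes[order]
    boundaries = np.flatnonzero(np.diff(sc)) + 1
    group_starts = np.concatenate(([0], boundaries))
    group_ends = np.concatenate((boundaries, [sc.size]))
    min_period = min_rep + min_spacer
    max_period = max_rep + max_spacer
    seen: set[tuple] = set()
    out: list[Candidate] = []
    for gs, ge in zip(group_starts, group_ends):
        size = ge - gs
        if size < min_copies or size > 1000:
            continue
        positions = np.sort(order[gs:ge])
        diffs = np.diff(positions)
        ok = (diffs >= min_period) & (diffs <= max_period)
        # maximal runs of consecutive in-range gaps
        run_start = 0
        for i in range(diffs.size + 1):
            if i == diffs.size or not ok[i]:
                if i - run_start + 1 >= min_copies:
                    cand = _extend_run(arr, positions[run_start:i + 1], k,
                                       min_rep, max_rep, min_spacer, max_spacer)
                    for c in cand:
                        key = (c.starts, c.rep_len)
                        if key not in seen:
                            seen.add(key)
                            out.append(c)
                run_start = i + 1
    out.sort(key=lambda c: (c.starts[0], -c.n_copies))
    return out


def _extend_run(arr: np.ndarray, P: np.ndarray, k: int, min_rep: int,
                max_rep: int, min_spacer: int, max_spacer: int) -> list[Candidate]:
    diffs = np.diff(P)
    budget = int(min(max_rep - k, diffs.min() - k - min_spacer))
    if budget < 0:
        return []
    left = 0
    while left < budget and P[0] - left - 1 >= 0:
        col = arr[P - left - 1]
        if not (col == col[0]).all():
            break
        left += 1
    right = 0
    while left + right < budget and P[-1] + k + right < arr.size:
        col = arr[P + k + right]
        if not (col == col[0]).all():
            break
        right += 1
    rep_len = k + left + right
    if rep_len < min_rep:
        return []
    starts = P - left
    # enforce spacer-length bounds; split at violating junctions
    gaps = np.diff(starts) - rep_len
    pieces: list[list[int]] = [[int(starts[0])]]
    for g, s in zip(gaps, starts[1:]):
        if min_spacer <= g <= max_spacer:
            pieces[-1].append(int(s))
        else:
            pieces.append([int(s)])
    return [Candidate(tuple(p), rep_len) for p in pieces if len(p) >= 3]


def _fast_identity(a: str, b: str) -> float:
    """Identity with an equal-length Hamming fast path (a lower bound that is
    exact for the strictly-extended, equal-length repeat copies)."""
    if a == b:
        return 1.0
    if len(a) == len(b):
        ham = sum(x == y for x, y in zip(a, b)) / len(a)
        if ham >= REPEAT_IDENTITY_FLOOR:
            return ham
    return identity(a, b)


def _consensus(repeats: list[str]) -> str:
    mat = np.stack([encode(r) for r in repeats])
    cons = np.empty(mat.shape[1], dtype=np.uint8)
    for j in range(mat.shape[1]):
        counts = np.bincount(mat[:, j], minlength=4)
        cons[j] = counts.argmax()  # ties -> smaller base index (A<C<G<T)
    from ._seq import decode
    return decode(cons)


def build_arrays(candidates: list[Candidate], seq: str,
                 contig: str = "contig", genome_id: str = "",
                 min_copies: int = 3,
                 repeat_identity_floor: float = REPEAT_IDENTITY_FLOOR,
                 max_spacer_identity: float = MAX_SPACER_IDENTITY,
                 ) -> list[SpacerArray]:
    """Convert candidate repeat sets into validated :class:`SpacerArray` s.

    Overlapping candidates are resolved in favour of the one with more units
    (ties: longer repeat, then leftmost); the loser is logged and dropped.
    Candidates failing the repeat-identity floor or whose spacers are mutually
    similar (tandem repeats) are rejected.
    """
    chosen: list[Candidate] = []
    for cand in sorted(candidates, key=lambda c: (-c.n_copies, -c.rep_len, c.starts[0])):
        s, e = cand.interval
        clash = next((c for c in chosen if c.interval[0] < e and s < c.interval[1]), None)
        if clash is not None:
            logger.info("dropping candidate at %d-%d overlapping a larger one", s, e)
            continue
        chosen.append(cand)
    arrays = []
    for cand in sorted(chosen, key=lambda c: c.starts[0]):
        if cand.n_copies < min_copies:
            continue
        repeats = [seq[s:s + cand.rep_len] for s in cand.starts]
        spacers = [seq[cand.starts[i] + cand.rep_len:cand.starts[i + 1]]
                   for i in range(cand.n_copies - 1)]
        # consecutive-unit checks suffice: repeat copies must stay near-identical
        # and a tandem repeat betrays itself by similar *adjacent* gaps
        rep_pairs = list(zip(repeats, repeats[1:]))
        if rep_pairs and min(_fast_identity(a, b) for a, b in rep_pairs) < repeat_identity_floor:
            continue
        sp_pairs = list(zip(spacers, spacers[1:]))
        if sp_pairs and max(identity(a, b) for a, b in sp_pairs) > max_spacer_identity:
            logger.info("rejecting tandem-repeat-like locus at %d", cand.starts[0])
            continue
        positions = [(int(cand.starts[i] + cand.rep_len), int(cand.starts[i + 1]))
                     for i in range(cand.n_copies - 1)]
        arrays.append(SpacerArray(
            contig=contig,
            start=int(cand.starts[0]),
            end=int(cand.starts[-1] + cand.rep_len),
            repeats=repeats,
            spacers=spacers,
            consensus_repeat=_consensus(repeats),
            genome_id=genome_id,
            spacer_positions=positions,
        ))
    return arrays


def filter_arrays(arrays: list[SpacerArray],
                  max_spacer_len: int = MAX_SPACER,
                  min_spacer_len: int = MIN_SPACER) -> list[SpacerArray]:
    """Retention filter: drop spacers of length >49 bp or <15 bp.

    Arrays left without any spacer are dropped entirely. Filtering removes
    spacers from the ordered list but keeps the locus coordinates; the strict
    repeat/spacer interleave therefore only holds for unfiltered arrays.
    Idempotent.
    """
    kept: list[SpacerArray] = []
    n_removed = 0
    for arr in arrays:
        pos = arr.spacer_positions or [(-1, -1)] * len(arr.spacers)
        keep = [i for i, s in enumerate(arr.spacers)
                if min_spacer_len <= len(s) <= max_spacer_len]
        n_removed += len(arr.spacers) - len(keep)
        if not keep:
            continue
        kept.append(SpacerArray(
            contig=arr.contig, start=arr.start, end=arr.end,
            repeats=arr.repeats, spacers=[arr.spacers[i] for i in keep],
            consensus_repeat=arr.consensus_repeat,
            orientation=arr.orientation, source=arr.source,
            genome_id=arr.genome_id, subtype=arr.subtype,
            spacer_positions=[pos[i] for i in keep]))
    if n_removed:
        logger.info("filter_arrays removed %d spacer(s)", n_removed)
    return kept


def detect_arrays(seq: str, contig: str = "contig", genome_id: str = "",
                  apply_filter: bool = True, **params) -> list[SpacerArray]:
    """Full pipeline: seed, extend, validate, and length-filter arrays."""
    find_kwargs = {k: v for k, v in params.items()
                   if k in ("min_rep", "max_rep", "min_copies", "min_spacer",
                            "max_spacer", "k")}
    candidates = find_repeat_candidates(seq, **find_kwargs)
    arrays = build_arrays(candidates, seq, contig=contig, genome_id=genome_id)
    if apply_filter:
        arrays = filter_arrays(arrays)
    return arrays


def spacer_table(arrays: list[SpacerArray]) -> pd.DataFrame:
    """One row per spacer: genome, contig, array id, index, start, end, sequence."""
    rows = []
    for ai, arr in enumerate(arrays):
        positions = arr.spacer_positions or [(-1, -1)] * len(arr.spacers)
        for i, (s, (start, end)) in enumerate(zip(arr.spacers, positions)):
            rows.append({
                "genome": arr.genome_id, "contig": arr.contig,
                "array": f"array_{ai:03d}", "index": i,
                "start": start, "end": end, "sequence": s,
            })
    return pd.DataFrame(rows, columns=["genome", "contig", "array", "index",
                                       "start", "end", "sequence"])


def arrays_to_gff(arrays: list[SpacerArray]) -> str:
    """GFF3 track of array loci (1-based inclusive coordinates per GFF)."""
    lines = ["##gff-version 3"]
    for ai, arr in enumerate(arrays):
        attrs = (f"ID=array_{ai:03d};n_units={arr.n_units};"
                 f"consensus_repeat={arr.consensus_repeat}")
        lines.append("\t".join([
            arr.contig, "spacerscan", "repeat_region",
            str(arr.start + 1), str(arr.end), ".", ".", ".", attrs]))
    return "\n".join(lines) + "\n"
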