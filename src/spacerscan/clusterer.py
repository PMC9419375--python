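"""Greedy incremental sequence clustering at a fixed identity threshold.

Spacer and repeat sequences are grouped the way CD-HIT-EST groups them: sort
by length (descending, ties lexicographic), then let each sequence join the
first existing cluster whose representative it matches at or above the
threshold, founding a new cluster otherwise. Identity between two sequences
is the number of matches in the best global alignment with free end gaps on
the shorter sequence (match +1, mismatch -1, gap -2), divided by the length
of the shorter sequence; both strands are tried and the maximum taken, so
clustering is strand-canonical. The sort rule makes the outcome independent
of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp

GAP = -2
MATCH = 1
MISMATCH = -1


@dataclass
class SpacerCluster:
    """A group of sequences within ``threshold`` identity of a representative."""

    id: str
    representative: str
    threshold: float
    members: list[tuple[str, str, str]] = field(default_factory=list)
    # members: (sequence, source tag, provenance id)

    @property
    def sources(self) -> set[str]:
        return {m[1] for m in self.members}

    @property
    def size(self) -> int:
        return len(self.members)


def _batch_glocal(query: np.ndarray, ref_mat: np.ndarray,
                  ref_lens: np.ndarray) -> np.ndarray:
    """Match counts of the best glocal alignment of ``query`` vs each ref row.

    ``ref_mat`` is (R, n_max) uint8 padded with 255 (never matches). The
    query's ends must align inside the reference (overhangs of the longer
    reference are free); among score-optimal alignments the one with most
    matches is reported. Returns the per-reference match counts.
    """
    m = query.size
    R, n_max = ref_mat.shape
    NEG = -10_000
    cols = np.arange(n_max + 1, dtype=np.int64)
    # The horizontal (left-gap) dependency is resolved with a prefix-max scan:
    # S[j] = max_{j'<=j} (S_noleft[j'] - 2(j - j')). Score, end column and
    # match count are bit-packed so one maximum.accumulate carries the whole
    # tie-break (higher score, then later column = fewer reference gaps,
    # preserving the diagonal-over-gap preference of the canonical alignment).
    OFF = 4 * (m + n_max + 2)
    S_prev = np.zeros((R, n_max + 1), dtype=np.int64)
    M_prev = np.zeros((R, n_max + 1), dtype=np.int64)
    for i in range(1, m + 1):
        eq = (ref_mat == query[i - 1]).astype(np.int64)
        sub = np.where(eq == 1, MATCH, MISMATCH)
        diag = S_prev[:, :-1] + sub
        up = S_prev[:, 1:] + GAP
        take_diag = diag >= up  # prefer diagonal on ties
        s_nl = np.empty((R, n_max + 1), dtype=np.int64)
        m_nl = np.empty((R, n_max + 1), dtype=np.int64)
        s_nl[:, 0] = GAP * i
        m_nl[:, 0] = 0
        s_nl[:, 1:] = np.where(take_diag, diag, up)
        m_nl[:, 1:] = np.where(take_diag, M_prev[:, :-1] + eq, M_prev[:, 1:])
        packed = ((s_nl + 2 * cols + OFF) << 40) | (cols << 20) | m_nl
        packed = np.maximum.accumulate(packed, axis=1)
        S_prev = (packed >> 40) - OFF - 2 * cols
        M_prev = packed & 0xFFFFF
    # free trailing reference overhang: best over end positions j <= ref_len,
    # leftmost optimal end for determinism
    valid = cols[None, :] <= ref_lens[:, None]
    S_final = np.where(valid, S_prev, NEG)
    best = S_final.max(axis=1)
    first = (S_final == best[:, None]).argmax(axis=1)
    return M_prev[np.arange(R), first]


def _identities(query: str, refs: list[str]) -> np.ndarray:
    """Strand-canonical identity of ``query`` against each (longer) reference."""
    if not refs:
        return np.empty(0)
    m = len(query)
    n_max = max(len(r) for r in refs)
    ref_mat = np.full((len(refs), n_max), 255, dtype=np.uint8)
    ref_lens = np.empty(len(refs), dtype=np.int64)
    for i, r in enumerate(refs):
        ref_mat[i, :len(r)] = encode(r)
        ref_lens[i] = len(r)
    fwd = _batch_glocal(encode(query), ref_mat, ref_lens)
    rev = _batch_glocal(encode(revcomp(query)), ref_mat, ref_lens)
    return np.maximum(fwd, rev) / m


def _canonical_strand(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def identities_to_representatives(seq: str, reps: list[str]) -> np.ndarray:
    """Identity of ``seq`` against each representative, batched.

    Uses :func:`identity`'s conventions (strand-canonical forms; the shorter
    sequence is the glocal query, equal lengths resolved lexicographically).
    Representatives must be at least as long as ``seq``, which the
    clustering sort guarantees.
    """
    s_can = _canonical_strand(seq)
    r_can = [_canonical_strand(r) for r in reps]
    ids = np.zeros(len(reps))
    longer = [i for i, r in enumerate(reps) if len(r) > len(seq)]
    if longer:
        ids[longer] = _identities(s_can, [r_can[i] for i in longer])
    for i, r in enumerate(r_can):
        if len(r) == len(s_can) and r != s_can:
            ids[i] = _identities(min(r, s_can), [max(r, s_can)])[0]
        elif r == s_can:
            ids[i] = 1.0
    return ids


def identity(a: str, b: str) -> float:
    """Alignment identity of two sequences in [0, 1], strand-canonical.

    Matches in the best global alignment with free end gaps on the shorter
    sequence (match +1, mismatch -1, gap -2) divided by the shorter length;
    both strands are tried and the maximum taken, so the value is invariant
    under reverse-complementing either argument (sequences are reduced to
    their lexicographically smaller strand first). Raises on empty input.
    """
    if not a or not b:
        raise ValueError("identity of an empty sequence is undefined")
    # deterministic choice of the glocal query: shorter, ties lexicographic
    query, ref = sorted((_canonical_strand(a), _canonical_strand(b)),
                        key=lambda s: (len(s), s))
    return float(_identities(query, [ref])[0])


def cluster(sequences: list[str], threshold: float = 1.0,
            sources: list[str] | None = None,
            provenance: list[str] | None = None) -> list[SpacerCluster]:
    """Greedy incremental clustering at ``threshold`` identity.

    Deterministic and independent of input order: sequences are processed by
    length (descending; ties lexicographic) and each joins the earliest-founded
    cluster whose representative it matches at >= threshold.
    """
    if sources is None:
        sources = ["genomic"] * len(sequences)
    if provenance is None:
        provenance = [str(i) for i in range(len(sequences))]
    items = list(zip(sequences, sources, provenance))
    if any(not s for s in sequences):
        raise ValueError("empty sequences cannot be clustered")
    order = sorted(range(len(items)), key=lambda i: (-len(sequences[i]), sequences[i],
                                                     sources[i], provenance[i]))
    # exact duplicates follow their first occurrence; collapse them up front
    groups: dict[str, list[int]] = {}
    uniq: list[str] = []
    for i in order:
        s = sequences[i]
        if s in groups:
            groups[s].append(i)
        else:
            groups[s] = [i]
            uniq.append(s)
    clusters: list[SpacerCluster] = []
    reps: list[str] = []
    assignment: dict[str, int] = {}
    for s in uniq:
        idx = None
        if reps:
            ids = identities_to_representatives(s, reps)
            hits = np.flatnonzero(ids >= threshold - 1e-9)
            if hits.size:
                idx = int(hits[0])
        if idx is None:
            idx = len(clusters)
            clusters.append(SpacerCluster(id=f"cluster_{idx:05d}",
                                          representative=s,
                                          threshold=threshold))
            reps.append(s)
        assignment[s] = idx
    for s, members in groups.items():
        for i in members:
            clusters[assignment[s]].members.append(items[i])
    return clusters


def cluster_per_source(sequences: list[str], sources: list[str],
                       threshold: float = 0.8,
                       provenance: list[str] | None = None,
                       ) -> dict[str, list[SpacerCluster]]:
    """Clusters computed separately per source category, plus pooled.

    Mirrors keeping sub-identity clusters apart for genomic vs metagenomic
    sequences while also providing the pooled clustering under key "pooled".
    """
    if provenance is None:
        provenance = [str(i) for i in range(len(sequences))]
    out: dict[str, list[SpacerCluster]] = {}
    for cat in sorted(set(sources)):
        idx = [i for i, s in enumerate(sources) if s == cat]
        out[cat] = cluster([sequences[i] for i in idx], threshold,
                           [sources[i] for i in idx],
                           [provenance[i] for i in idx])
    out["pooled"] = cluster(sequences, threshold, sources, provenance)
    return out


def intersect_sources(clusters: list[SpacerCluster],
                      a: str = "genomic", b: str = "metagenomic") -> dict[str, int]:
    """Tally clusters by source-set membership into three disjoint counts."""
    counts = {f"{a}_only": 0, f"{b}_only": 0, "shared": 0}
    for c in clusters:
        src = c.sources
        if a in src and b in src:
            counts["shared"] += 1
        elif a in src:
            counts[f"{a}_only"] += 1
        elif b in src:
            counts[f"{b}_only"] += 1
    return counts


def assignment_map(clusters: list[SpacerCluster]) -> dict[str, str]:
    """Map each member sequence to its cluster id."""
    out: dict[str, str] = {}
    for c in clusters:
        for seq, _src, _prov in c.members:
            out.setdefault(seq, c.id)
    return out
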