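"""Mismatch-tolerant spacer-to-target matching and vOTU coverage.

Spacers are searched against a target database (phages, plasmids,
chromosomes) as exact-length ungapped matches with at most ``max_mm``
mismatches, on both strands, via pigeonhole seeding: a spacer is split into
``max_mm + 1`` parts so that any qualifying occurrence matches at least one
part exactly. Hits falling within a flank of an annotated CRISPR repeat on
the target are self-matches (the target carries the array itself) and are
excluded. Remaining hits are aggregated per vOTU to measure how much of the
known phage diversity the spacer repertoires cover.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from ._seq import encode, revcomp
from .repertoire import RarefactionCurve

SELF_TARGET_FLANK = 2000  # bp scanned around a hit for repeat annotation
CATEGORY_PRECEDENCE = ("phage", "plasmid", "chromosome")


@dataclass
class TargetRecord:
    id: str
    seq: str
    votu: str | None = None
    category: str = "chromosome"


@dataclass
class ProtospacerHit:
    spacer_id: str
    target_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    votu: str | None = None
    category: str = "chromosome"


def parse_target_header(header: str, seq: str) -> TargetRecord:
    """Target from a FASTA header with optional ``vOTU=`` / ``category=`` keys."""
    parts = header.split()
    votu = None
    category = "chromosome"
    for p in parts[1:]:
        if p.startswith("vOTU="):
            votu = p[5:]
        elif p.startswith("category="):
            category = p[9:]
    return TargetRecord(id=parts[0], seq=seq, votu=votu, category=category)


def _search_one_strand(spacer_arr: np.ndarray, target_arr: np.ndarray,
                       target_str: str, spacer_str: str, max_mm: int) -> dict[int, int]:
    """{start: mismatches} of all <=max_mm occurrences (pigeonhole seeded)."""
    m = spacer_arr.size
    n = target_arr.size
    if n < m:
        return {}
    bounds = np.linspace(0, m, max_mm + 2).astype(int)
    found: dict[int, int] = {}
    for b0, b1 in zip(bounds, bounds[1:]):
        part = spacer_str[b0:b1]
        pos = target_str.find(part)
        while pos != -1:
            start = pos - b0
            if 0 <= start <= n - m and start not in found:
                mm = int(np.count_nonzero(spacer_arr != target_arr[start:start + m]))
                found[start] = mm
            pos = target_str.find(part, pos + 1)
    return {s: mm for s, mm in found.items() if mm <= max_mm}


def search_protospacers(spacers: dict[str, str], targets: list[TargetRecord],
                        max_mm: int = 2) -> list[ProtospacerHit]:
    """Ungapped <=max_mm-mismatch hits of every spacer in every target.

    Both target strands are scanned; per (spacer, target) only the best
    single hit is kept (fewest mismatches, ties: leftmost, '+' strand first),
    but every qualifying target is reported. Intervals are on the target
    forward strand and have the spacer's length.
    """
    hits: list[ProtospacerHit] = []
    enc_targets = [(t, encode(t.seq), t.seq) for t in targets]
    for sid in sorted(spacers):
        spacer = spacers[sid]
        if len(spacer) < 1:
            raise ValueError(f"empty spacer {sid!r}")
        arr_f = encode(spacer)
        rc = revcomp(spacer)
        arr_r = encode(rc)
        m = len(spacer)
        for target, tarr, tstr in enc_targets:
            best = None
            for strand, sarr, sstr in (("+", arr_f, spacer), ("-", arr_r, rc)):
                for start, mm in _search_one_strand(sarr, tarr, tstr, sstr, max_mm).items():
                    key = (mm, start, 0 if strand == "+" else 1)
                    if best is None or key < best[0]:
                        best = (key, start, mm, strand)
            if best is not None:
                _, start, mm, strand = best
                hits.append(ProtospacerHit(
                    spacer_id=sid, target_id=target.id, start=start,
                    end=start + m, strand=strand, mismatches=mm,
                    votu=target.votu, category=target.category))
    return hits


def exclude_self_targets(hits: list[ProtospacerHit],
                         repeat_annotations: dict[str, list[tuple[int, int]]],
                         flank: int = SELF_TARGET_FLANK) -> list[ProtospacerHit]:
    """Drop hits within ``flank`` bp of an annotated CRISPR repeat on the target.

    Such hits are the target's own array, not protospacers. Targets without
    annotations keep all their hits.
    """
    kept = []
    for h in hits:
        near = False
        for a0, a1 in repeat_annotations.get(h.target_id, []):
            if h.start < a1 + flank and a0 - flank < h.end:
                near = True
                break
        if not near:
            kept.append(h)
    return kept


def spacer_categories(spacer_ids, hits: list[ProtospacerHit]) -> dict[str, str]:
    """Category per spacer with precedence phage > plasmid > chromosome;
    spacers without any hit get 'none'."""
    by_spacer: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        by_spacer[h.spacer_id].add(h.category)
    out = {}
    for sid in spacer_ids:
        cats = by_spacer.get(sid, set())
        out[sid] = next((c for c in CATEGORY_PRECEDENCE if c in cats), "none")
    return out


def votu_stats(hits: list[ProtospacerHit], genome_of_spacer: dict[str, str],
               catalogue: set[str]) -> dict:
    """Per-genome vOTU targeting summaries.

    Returns distinct vOTUs targeted per genome, the spacers-per-vOTU
    histogram (how many genome-vOTU pairs involve k spacers), and the
    fraction of the vOTU catalogue targeted overall.
    """
    per_pair: dict[tuple[str, str], set[str]] = defaultdict(set)
    targeted: set[str] = set()
    for h in hits:
        if h.votu is None:
            continue
        genome = genome_of_spacer.get(h.spacer_id)
        if genome is None:
            continue
        per_pair[(genome, h.votu)].add(h.spacer_id)
        targeted.add(h.votu)
    per_genome: dict[str, set[str]] = defaultdict(set)
    for (genome, votu) in per_pair:
        per_genome[genome].add(votu)
    histogram: dict[int, int] = {}
    for spacer_set in per_pair.values():
        k = len(spacer_set)
        histogram[k] = histogram.get(k, 0) + 1
    n_pairs = sum(histogram.values())
    return {
        "votus_per_genome": {g: len(v) for g, v in sorted(per_genome.items())},
        "spacers_per_votu_histogram": dict(sorted(histogram.items())),
        "single_spacer_fraction": (histogram.get(1, 0) / n_pairs) if n_pairs else 0.0,
        "fraction_targeted": len(targeted & catalogue) / len(catalogue) if catalogue else 0.0,
        "targeted_votus": targeted,
    }


def votu_rarefaction(genome_votus: dict[str, set[str]], catalogue: set[str],
                     n_perm: int = 100, seed: int | None = None) -> RarefactionCurve:
    """Fraction of the vOTU catalogue covered as genomes accumulate.

    Same accumulation scheme as spacer rarefaction, normalised by catalogue
    size; the plateau equals |union of targeted vOTUs| / |catalogue| exactly,
    independent of the permutations.
    """
    if not catalogue:
        raise ValueError("empty vOTU catalogue")
    names = sorted(genome_votus)
    if not names:
        raise ValueError("at least one genome required")
    from .repertoire import _accumulation_sizes
    sizes = _accumulation_sizes([genome_votus[g] & catalogue for g in names],
                                n_perm, seed)
    denom = len(catalogue)
    n = len(names)
    points = [(k + 1, float(sizes[:, k].mean() / denom),
               float(sizes[:, k].std(ddof=0) / denom)) for k in range(n)]
    return RarefactionCurve(points=points, n_permutations=sizes.shape[0], seed=seed)
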