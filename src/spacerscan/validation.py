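"""End-to-end validation experiments on simulated communities.

Each function simulates data with known ground truth, runs the corresponding
analysis chain, and reports the recovered quantities next to their truth.
These experiments back both the acceptance test suite and the
``scripts/acceptance.py`` reproduction script; problem sizes are chosen so
the full battery runs on a single CPU in minutes (see the methods note).
"""

from __future__ import annotations

import math

import numpy as np

from . import metaquant, pairstats, read_detect, repertoire, targetmatch
from ._seq import encode, hamming_windows, random_seq, revcomp
from .array_detect import detect_arrays, filter_arrays
from .clusterer import cluster, identities_to_representatives, identity
from .simdata import SimConfig, evolve_pair, simulate_ancestor, simulate_metagenome, simulate_phage_pool


def _spawn(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


# ---------------------------------------------------------------------------
# turnover parameter recovery

def turnover_recovery(seed: int = 0, n_pairs: int = 50,
                      config: SimConfig | None = None) -> dict:
    """Recover the planted acquisition rate rho*N from diverged strain pairs.

    For each pair: simulate an ancestor (L=200 kb by default), evolve two
    lineages (mu=1e-8/bp/gen, rho=2e-5/gen, G=5e5), detect arrays in both
    descendants, then run fragment ANI -> SNV estimate -> unique spacer
    clusters -> community-scaled turnover. The turnover distribution is
    restricted to pairs with ANI > 99 as the method prescribes.
    """
    cfg = config or SimConfig()
    rates, spus, snv_ratios, aligned = [], [], [], []
    n_used = 0
    for i in range(n_pairs):
        rng = _spawn(seed, i)
        anc = simulate_ancestor(cfg, rng)
        phages = simulate_phage_pool(cfg, rng)
        a, b, truth = evolve_pair(anc, cfg, phages, rng)
        ani, n_frag = pairstats.fragment_ani(a.seq, b.seq)
        if not n_frag:
            continue
        snv = pairstats.estimate_snvs(ani, n_frag / 2)
        true_snv = sum(len(v) for v in truth.snv_positions.values())
        if true_snv:
            snv_ratios.append(snv / true_snv)
        sp_a = [s for x in detect_arrays(a.seq, genome_id=a.id) for s in x.spacers]
        sp_b = [s for x in detect_arrays(b.seq, genome_id=b.id) for s in x.spacers]
        sh = pairstats.shared_spacer_fraction(sp_a, sp_b)
        if sh["unique"] < 1:
            continue
        spus.append(snv / sh["unique"])
        if math.isnan(ani) or ani <= 99.0:
            continue
        aligned_len = n_frag * pairstats.FRAG_LEN / 2
        aligned.append(aligned_len)
        rate = pairstats.spacers_per_generation(
            snv, sh["unique"], mu=cfg.mu, aligned_len=aligned_len,
            community_size=cfg.community_size)
        if not math.isnan(rate):
            rates.append(rate)
            n_used += 1
    target_rate = cfg.rho * cfg.community_size
    med_aligned = float(np.median(aligned)) if aligned else float("nan")
    target_spu = cfg.mu * med_aligned / cfg.rho
    med_rate = float(np.median(rates)) if rates else float("nan")
    med_spu = float(np.median(spus)) if spus else float("nan")
    return {
        "median_spacers_per_generation": med_rate,
        "target_spacers_per_generation": target_rate,
        "rate_recovery_ratio": med_rate / target_rate,
        "median_snvs_per_unique_spacer": med_spu,
        "target_snvs_per_unique_spacer": target_spu,
        "snvs_per_spacer_recovery_ratio": med_spu / target_spu,
        "median_snv_estimate_ratio": float(np.median(snv_ratios)),
        "n_pairs_used": n_used,
        "n_pairs": n_pairs,
    }


# ---------------------------------------------------------------------------
# read classification exactness

def _expected_read_classes(origins, genome_layouts, proto_intervals, read_len):
    """Geometric truth class per read from its recorded origin."""
    labels = {}
    for rid, row in origins.iterrows():
        src, pos = row["source"], int(row["pos"])
        lo, hi = pos, pos + read_len
        label = "none"
        if src in genome_layouts:
            for s0, s1, r_left, r_right in genome_layouts[src]:
                sp = max(0, min(hi, s1) - max(lo, s0))
                rl = max(0, min(hi, r_left[1]) - max(lo, r_left[0]))
                rr = max(0, min(hi, r_right[1]) - max(lo, r_right[0]))
                if sp >= metaquant.ARRAY_MIN_SPACER_OVERLAP and \
                        max(rl, rr) >= metaquant.ARRAY_MIN_REPEAT_OVERLAP:
                    label = "array"
                    break
        elif src in proto_intervals:
            for p0, p1 in proto_intervals[src]:
                cover = max(0, min(hi, p1) - max(lo, p0))
                if cover >= metaquant.PROTO_MIN_SPACER_COVER * (p1 - p0):
                    label = "protospacer"
                    break
        labels[rid] = label
    return labels


def read_classification(seed: int = 0, n_reads: int = 100_000,
                        read_len: int = 150) -> dict:
    """Precision/recall of spacer vs protospacer read classification.

    Two genomes with 20-spacer arrays plus five phages carrying 10 planted
    protospacers are sequenced error-free; every read's class is compared
    with the geometric truth derived from its recorded origin (reads the
    classifier leaves ambiguous are excluded, as are reads that cannot be
    assigned a truth class). Read-count conservation is checked exactly.
    """
    rng = _spawn(seed, 0)
    cfg = SimConfig(genome_length=50_000, n_initial_spacers=20, seed=seed)
    genomes = [simulate_ancestor(cfg, rng, genome_id=f"g{i}") for i in range(2)]
    arrays = []
    layouts = {}
    for g in genomes:
        det = detect_arrays(g.seq, genome_id=g.id)
        arrays.extend(det)
        spans = []
        for arr in det:
            r = len(arr.repeats[0])
            for (s0, s1) in arr.spacer_positions:
                spans.append((s0, s1, (s0 - r, s0), (s1, s1 + r)))
        layouts[g.id] = spans
    all_spacers = [s for arr in arrays for s in arr.spacers]
    chosen = [all_spacers[int(i)] for i in rng.choice(len(all_spacers), 10, replace=False)]
    phages = []
    proto_intervals = {}
    for i in range(5):
        seq = random_seq(rng, 10_000)
        spans = []
        for j, sp in enumerate(chosen[2 * i:2 * i + 2]):
            pos = 2_000 + j * 5_000
            seq = seq[:pos] + sp + seq[pos + len(sp):]
            spans.append((pos, pos + len(sp)))
        pid = f"phage_{i}"
        phages.append((pid, seq))
        proto_intervals[pid] = spans
    sources = [(g.id, g.seq) for g in genomes] + phages
    reads, origins = simulate_metagenome(sources, np.ones(len(sources)), n_reads,
                                         read_len=read_len, rng=rng)
    refs = metaquant.build_rsr_references(arrays)
    hits = metaquant.classify_hits(metaquant.map_reads(reads, refs), refs)
    truth = _expected_read_classes(origins, layouts, proto_intervals, read_len)
    pred = {h.read_id: h.cls for h in hits}
    counts = {"array": 0, "protospacer": 0, "ambiguous": 0}
    for h in hits:
        counts[h.cls] += 1
    conserved = counts["array"] + counts["protospacer"] + counts["ambiguous"] \
        + (n_reads - len(hits)) == n_reads
    tp = {"array": 0, "protospacer": 0}
    fp = {"array": 0, "protospacer": 0}
    fn = {"array": 0, "protospacer": 0}
    for rid, t in truth.items():
        p = pred.get(rid, "none")
        if p == "ambiguous":
            continue
        for c in ("array", "protospacer"):
            if p == c and t == c:
                tp[c] += 1
            elif p == c and t != c:
                fp[c] += 1
            elif t == c and p != c:
                fn[c] += 1
    out = {"conservation_exact": bool(conserved), "class_counts": counts,
           "n_reads": n_reads}
    for c in ("array", "protospacer"):
        prec = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else float("nan")
        rec = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else float("nan")
        out[f"{c}_precision"] = prec
        out[f"{c}_recall"] = rec
    return out


# ---------------------------------------------------------------------------
# planted abundance correlation

def correlation_recovery(seed: int = 0, n_hosts: int = 30,
                         n_reads: int = 1_000_000) -> dict:
    """Recover a planted spacer/protospacer abundance correlation.

    Each of ``n_hosts`` host strains carries a two-spacer array; one spacer
    is planted as a protospacer in that host's phage. Phage abundance is
    proportional to host abundance, spanning two orders of magnitude, so the
    log-log regression of protospacer on spacer cpm should recover a strong
    positive relation.
    """
    rng = _spawn(seed, 0)
    cfg = SimConfig(genome_length=8_000, n_initial_spacers=2, seed=seed)
    hosts, phages, arrays = [], [], []
    abundances = 10 ** rng.uniform(0, 2, size=n_hosts)  # two orders of magnitude
    for i in range(n_hosts):
        g = simulate_ancestor(cfg, rng, genome_id=f"host_{i:02d}")
        det = detect_arrays(g.seq, genome_id=g.id)
        arrays.extend(det)
        hosts.append((g.id, g.seq))
        sp = det[0].spacers[0]
        seq = random_seq(rng, 5_000)
        pos = 2_500
        seq = seq[:pos] + sp + seq[pos + len(sp):]
        phages.append((f"phage_{i:02d}", seq))
    sources = hosts + phages
    ab = np.concatenate([abundances, abundances])
    reads, _ = simulate_metagenome(sources, ab, n_reads, rng=rng)
    refs = metaquant.build_rsr_references(arrays)
    table, summary = metaquant.quantify(reads, refs)
    reg = metaquant.abundance_regressions(table)
    return {
        "slope": reg["proto_vs_spacer"]["slope"],
        "r2": reg["proto_vs_spacer"]["r2"],
        "ratio_slope": reg["ratio_vs_spacer"]["slope"],
        "tally": reg["tally"],
        "n_refs_both": reg["tally"]["both"],
        "n_reads": n_reads,
    }


# ---------------------------------------------------------------------------
# clustering oracle

def clustering_oracle(seed: int = 0, n_random: int = 300, n_planted: int = 25) -> dict:
    """Greedy clustering against brute-force oracles.

    100%-clusters must equal exact strand-canonical sequence groups; every
    80%-cluster member must verify >=0.8 identity to its representative and
    must not match any earlier-founded representative (greedy contract);
    permuting the input must not change the clustering.
    """
    rng = _spawn(seed, 0)
    seqs = [random_seq(rng, int(rng.integers(28, 43))) for _ in range(n_random)]
    for _ in range(n_planted):  # 83%-identity pairs: 30-mers with 5 mismatches
        a = random_seq(rng, 30)
        arr = encode(a).copy()
        pos = rng.choice(30, 5, replace=False)
        arr[pos] = (arr[pos] + rng.integers(1, 4, size=5)) % 4
        from ._seq import decode
        seqs.extend([a, decode(arr)])
    # some exact and strand duplicates for the 100% oracle
    seqs.extend([seqs[0], revcomp(seqs[1]), seqs[2]])
    c100 = cluster(seqs, 1.0)
    canonical = lambda s: min(s, revcomp(s))
    oracle_groups = {}
    for s in seqs:
        oracle_groups.setdefault(canonical(s), []).append(s)
    mine = sorted(sorted(canonical(m[0]) for m in c.members) for c in c100)
    oracle = sorted(sorted(canonical(s) for s in grp) for grp in oracle_groups.values())
    exact_ok = mine == oracle
    c80 = cluster(seqs, 0.8)
    reps80 = [c.representative for c in c80]
    members_ok = True
    contract_ok = True
    for ci, c in enumerate(c80):
        for m in c.members:
            ids = identities_to_representatives(m[0], reps80[:ci + 1])
            if ids[ci] < 0.8 - 1e-9:
                members_ok = False
            if (ids[:ci] >= 0.8 - 1e-9).any():
                contract_ok = False
    perm = list(seqs)
    rng.shuffle(perm)
    c80p = cluster(perm, 0.8)
    as_sets = lambda cs: sorted(sorted(m[0] for m in c.members) for c in cs)
    stable = as_sets(c80) == as_sets(c80p)
    return {
        "exact_oracle_agreement": float(exact_ok),
        "members_verified": float(members_ok),
        "greedy_contract_ok": float(contract_ok),
        "permutation_stable": float(stable),
        "n_sequences": len(seqs),
        "n_clusters_100": len(c100),
        "n_clusters_80": len(c80),
    }


# ---------------------------------------------------------------------------
# planted array detection

def array_detection_eval(seed: int = 0, n_genomes: int = 10,
                         n_controls: int = 200) -> dict:
    """Exact recovery of planted arrays; false positives on shuffled controls.

    Ten 100-kb genomes carry two planted arrays each (20 arrays total); every
    planted spacer list must be recovered exactly. Controls are
    base-shuffled copies of the same genomes, which must yield no arrays in
    almost every replicate.
    """
    cfg = SimConfig(genome_length=100_000, n_arrays=2, seed=seed)
    recovered = 0
    total = 0
    for i in range(n_genomes):
        rng = _spawn(seed, i)
        g = simulate_ancestor(cfg, rng, genome_id=f"g{i}")
        det = detect_arrays(g.seq, genome_id=g.id)
        found = {tuple(a.spacers) for a in det}
        starts = g.array_starts()
        for arr in sorted(g.arrays, key=lambda a: a.bg_pos):
            total += 1
            if tuple(arr.spacers) in found:
                recovered += 1
    controls_hit = 0
    rng = _spawn(seed, n_genomes + 1)
    for i in range(n_controls):
        shuffled = random_seq(rng, 100_000)
        if detect_arrays(shuffled, genome_id=f"ctrl{i}"):
            controls_hit += 1
    return {
        "arrays_recovered_fraction": recovered / total,
        "n_planted_arrays": total,
        "controls_with_detections": controls_hit,
        "n_controls": n_controls,
    }


# ---------------------------------------------------------------------------
# protospacer search oracle

def search_oracle(seed: int = 0, n_spacers: int = 500,
                  target_len: int = 100_000) -> dict:
    """Seeded <=2-mismatch search vs brute-force Hamming scan, exactly.

    Spacers are planted at 0-3 mismatches on both strands; the seeded search
    must reproduce the brute-force hit set exactly, including the rejection
    of 3-mismatch plantings.
    """
    rng = _spawn(seed, 0)
    target = random_seq(rng, target_len)
    spacers = {}
    for i in range(n_spacers):
        L = int(rng.integers(28, 43))
        if i % 2 == 0:  # planted at 0-3 mismatches, half reverse-complemented
            pos = int(rng.integers(0, target_len - L))
            arr = encode(target[pos:pos + L]).copy()
            mm = i % 4
            if mm:
                idx = rng.choice(L, mm, replace=False)
                arr[idx] = (arr[idx] + rng.integers(1, 4, size=mm)) % 4
            from ._seq import decode
            sp = decode(arr)
            if i % 4 == 2:
                sp = revcomp(sp)
        else:
            sp = random_seq(rng, L)
        spacers[f"sp_{i:04d}"] = sp
    targets = [targetmatch.TargetRecord("t0", target, votu="vOTU_000",
                                        category="phage")]
    hits = targetmatch.search_protospacers(spacers, targets, max_mm=2)
    mine = sorted((h.spacer_id, h.start, h.mismatches, h.strand) for h in hits)
    tarr = encode(target)
    brute = []
    for sid in sorted(spacers):
        sp = spacers[sid]
        best = None
        for strand, s in (("+", sp), ("-", revcomp(sp))):
            mm = hamming_windows(tarr, encode(s))
            for start in np.flatnonzero(mm <= 2):
                key = (int(mm[start]), int(start), 0 if strand == "+" else 1)
                if best is None or key < best:
                    best = key
                    bh = (sid, int(start), int(mm[start]), strand)
        if best is not None:
            brute.append(bh)
    return {
        "oracle_agreement": float(mine == sorted(brute)),
        "n_hits": len(mine),
        "n_spacers": n_spacers,
    }


# ---------------------------------------------------------------------------
# filter ledger

def filter_ledger(seed: int = 0) -> dict:
    """Constructed filter checks with exactly known outcomes.

    Reads are built as repeat+spacer+repeat with known multiplicities,
    including a coverage-1 spacer and a 12-bp spacer; post-filter counts must
    match the construction exactly. The assembly-side length filter is
    checked on an array with a 50-bp spacer.
    """
    rng = _spawn(seed, 0)
    R = random_seq(rng, 36)
    spec = [(random_seq(rng, 33), 5), (random_seq(rng, 31), 1),
            (random_seq(rng, 12), 4), (random_seq(rng, 16), 3)]
    reads = []
    for sp, cov in spec:
        reads.extend([R + sp + R] * cov)
    rng.shuffle(reads)
    raw = read_detect.detect_read_spacers(reads, min_spacer=8)
    filtered = read_detect.filter_read_spacers(raw)
    raw_cov = {m.sequence: m.coverage for m in raw}
    canonical = lambda s: min(s, revcomp(s))
    raw_ok = all(raw_cov.get(sp) == cov or raw_cov.get(revcomp(sp)) == cov
                 for sp, cov in spec)
    expected_kept = {canonical(sp) for sp, cov in spec if cov >= 2 and len(sp) >= 15}
    kept = {canonical(m.sequence) for m in filtered}
    idempotent = read_detect.filter_read_spacers(filtered) == filtered
    # assembly-side spacer length filter
    g = simulate_ancestor(SimConfig(genome_length=30_000, n_initial_spacers=3,
                                    seed=seed), rng)
    arr = detect_arrays(g.seq, apply_filter=False)[0]
    arr.spacers = [random_seq(rng, 32), random_seq(rng, 50), random_seq(rng, 33)]
    arr.spacer_positions = [(-1, -1)] * 3
    filt = filter_arrays([arr])
    assembly_ok = [len(s) for s in filt[0].spacers] == [32, 33]
    return {
        "read_filter_exact": float(raw_ok and kept == expected_kept),
        "assembly_filter_exact": float(assembly_ok),
        "filter_idempotent": float(idempotent),
        "n_raw": len(raw),
        "n_filtered": len(filtered),
    }


# ---------------------------------------------------------------------------
# rarefaction exactness

def rarefaction_exactness(seed: int = 0, n_sets: int = 20) -> dict:
    """Exhaustive two-sample means and exact plateaus of accumulation curves."""
    two = {"m1": {f"c{i}" for i in range(10)},
           "m2": {f"d{i}" for i in range(5)}}
    curve = repertoire.rarefaction(two, n_perm=100, seed=seed)
    k1_mean, k2_mean = curve.points[0][1], curve.points[1][1]
    two_sample_ok = (k1_mean == 7.5) and (k2_mean == 15.0)
    rng = _spawn(seed, 1)
    universe = [f"u{i}" for i in range(200)]
    sets = {f"s{j}": {universe[int(i)] for i in
                      rng.choice(200, int(rng.integers(5, 40)), replace=False)}
            for j in range(n_sets)}
    curve2 = repertoire.rarefaction(sets, n_perm=30, seed=seed)
    union = len(set().union(*sets.values()))
    plateau_ok = curve2.plateau == union
    monotone = all(b[1] >= a[1] for a, b in zip(curve2.points, curve2.points[1:]))
    return {
        "two_sample_mean_k1": k1_mean,
        "two_sample_mean_k2": k2_mean,
        "two_sample_exact": float(two_sample_ok),
        "plateau_exact": float(plateau_ok),
        "monotone": float(monotone),
        "union_size": union,
    }
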