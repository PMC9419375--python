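# spacerscan

Community-level CRISPR spacer dynamics for microbial ecologists: detect
CRISPR arrays in assemblies and raw metagenomic reads, cluster spacers,
estimate how fast near-clonal strains turn their spacer repertoires over,
classify metagenomic reads into spacer vs protospacer evidence, and measure
how much of a phage catalogue (vOTUs) a repertoire covers. A bundled
simulator generates communities with complete ground truth, so every
estimator in the package is validated by parameter recovery.

## The model at the core

Two strains diverging from a common ancestor accumulate substitutions at
rate μ per bp per generation and acquire leader-end spacers at rate ρ per
cell per generation. For a strain pair, the package chains:

1. fragment ANI (1-kb fragments, best gapless placement, ≥80% identity kept),
2. the pairwise SNV count, `snv = n_frag × 1000 × (100 − ANI)/100` over the
   aligned length,
3. unique spacer clusters (100% identity, strand-canonical) present in only
   one of the two genomes,

into a community-scaled acquisition rate

```
rate = N · μ · L_aligned · unique_spacers / snv      [spacers/generation]
```

with community size N (default 10⁷ cells) and μ defaulting to
8.9 × 10⁻¹¹ /bp/generation. Both `snv` and `unique_spacers` are two-branch
quantities, so the branch factor cancels. Computed only for near-clonal
pairs (ANI > 99). See `docs/methods.md` for every rule and threshold.

## Worked example

```python
import spacerscan as ss
from spacerscan import pairstats as ps
from spacerscan.array_detect import detect_arrays

cfg = ss.SimConfig(seed=42)            # 200 kb, mu=1e-8, rho=2e-5, G=5e5
rng = cfg.rng()
ancestor = ss.simulate_ancestor(cfg, rng)
phages   = ss.simulate_phage_pool(cfg, rng)
a, b, truth = ss.evolve_pair(ancestor, cfg, phages, rng)

ani, n_frag = ps.fragment_ani(a.seq, b.seq)
snv  = ps.estimate_snvs(ani, n_frag / 2)
sp_a = [s for arr in detect_arrays(a.seq) for s in arr.spacers]
sp_b = [s for arr in detect_arrays(b.seq) for s in arr.spacers]
sh   = ps.shared_spacer_fraction(sp_a, sp_b)
rate = ps.spacers_per_generation(snv, sh["unique"], mu=cfg.mu,
                                 aligned_len=n_frag * 1000 / 2,
                                 community_size=cfg.community_size)
print(f"ANI {ani:.3f}%  SNVs {snv:.0f}  unique {sh['unique']}  rate {rate:.1f}")
```

prints

```
ANI 98.980%  SNVs 2041  unique 22  rate 215.6
```

The two lineages truly carry 2002 SNVs between them; the estimator reads
2041 off the ANI. They acquired 22 distinct new spacers, giving
215.6 spacers per generation for the 10⁷-cell community against a planted
ρ·N of 200 — within Poisson noise for a single pair; the median over 50
pairs lands within a few percent.

The same functionality is exposed as a CLI:

```
spacerscan simulate --seed 1 --outdir sim/
spacerscan detect-arrays sim/genomes.fasta --out spacers.tsv
spacerscan detect-read-spacers sim/reads.fastq --out meta_spacers.tsv
spacerscan cluster spacers.tsv --threshold 0.8 --out clusters.tsv
spacerscan pair-stats sim/genomes.fasta spacers.tsv --out pairs.tsv
spacerscan quantify sim/reads.fastq rsr.tsv --out abundance.tsv
spacerscan match-targets spacers.tsv sim/phages.fasta --out hits.tsv
```

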