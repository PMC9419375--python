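"""Synthetic communities with known ground truth.

This module generates the inputs the rest of the package analyses: bacterial
genomes carrying planted CRISPR arrays, pools of phages grouped into vOTUs,
pairs of strains diverging from a common ancestor by point substitutions and
leader-end spacer acquisition, and shotgun metagenomes sampled from those
sources. Every stochastic event is recorded in a :class:`SimTruth` ledger so
that detection, classification and rate estimation can be scored against a
complete truth.

The divergence model is deliberately minimal: per-lineage substitutions are a
Poisson process at rate ``mu`` per base pair per generation, spacer
acquisitions a Poisson process at rate ``rho`` per cell per generation
(each new spacer is a random substring of a random phage, inserted at the
leader end of the array together with a fresh repeat copy), and spacer loss
an optional exponential decay at rate ``loss`` per spacer per generation.
There are no indels outside of spacer turnover, no recombination and no
selection. Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import decode, encode, random_seq, revcomp


@dataclass
class SimConfig:
    """Parameters of the synthetic community.

    Rates are per generation: ``mu`` substitutions per base pair, ``rho``
    spacer acquisitions per cell, ``loss`` losses per resident spacer.
    ``seed`` fully determines every output.
    """

    genome_length: int = 200_000
    gc: float = 0.5
    mu: float = 1e-8
    rho: float = 2e-5
    loss: float = 0.0
    generations: int = 500_000
    repeat_length: int = 36
    spacer_length_range: tuple[int, int] = (28, 42)
    n_initial_spacers: int = 10
    n_arrays: int = 1
    n_phages: int = 12
    phage_length: int = 10_000
    phages_per_votu: int = 3
    votu_divergence: float = 0.02
    community_size: float = 1e7
    shield_arrays: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        for name in ("mu", "rho", "loss", "votu_divergence"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 23 <= self.repeat_length <= 47:
            raise ValueError("repeat_length must be in [23, 47]")
        lo, hi = self.spacer_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid spacer_length_range")
        for name in ("genome_length", "generations", "n_initial_spacers",
                     "n_arrays", "n_phages", "phage_length", "phages_per_votu"):
            if getattr(self, name) < (0 if name == "generations" else 1):
                raise ValueError(f"{name} must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PlantedArray:
    """A planted repeat-spacer-...-repeat locus, anchored in background coords."""

    bg_pos: int
    repeat: str
    spacers: list[str]

    def sequence(self) -> str:
        return self.repeat + "".join(s + self.repeat for s in self.spacers)

    @property
    def footprint(self) -> int:
        return len(self.repeat) * (len(self.spacers) + 1) + sum(map(len, self.spacers))


@dataclass
class Genome:
    """A synthetic genome: random background plus planted arrays.

    ``background`` excludes the arrays; :meth:`assemble` splices them in.
    """

    id: str
    background: str
    arrays: list[PlantedArray] = field(default_factory=list)

    @property
    def seq(self) -> str:
        return self.assemble()

    def assemble(self) -> str:
        parts = []
        prev = 0
        for arr in sorted(self.arrays, key=lambda a: a.bg_pos):
            parts.append(self.background[prev:arr.bg_pos])
            parts.append(arr.sequence())
            prev = arr.bg_pos
        parts.append(self.background[prev:])
        return "".join(parts)

    def array_starts(self) -> list[int]:
        """Start of each array in assembled-genome coordinates."""
        starts = []
        offset = 0
        for arr in sorted(self.arrays, key=lambda a: a.bg_pos):
            starts.append(arr.bg_pos + offset)
            offset += arr.footprint
        return starts

    def copy(self) -> "Genome":
        return Genome(self.id, self.background,
                      [dataclasses.replace(a, spacers=list(a.spacers))
                       for a in self.arrays])


@dataclass
class Phage:
    id: str
    votu: str
    seq: str

    @property
    def header(self) -> str:
        return f"{self.id} vOTU={self.votu} category=phage"


@dataclass
class Acquisition:
    generation: float
    spacer: str
    phage_id: str
    strand: str


@dataclass
class SimTruth:
    """Ground-truth ledger of a simulation.

    ``snv_positions`` are assembled-genome coordinates of each lineage;
    ``acquisitions`` are in acquisition order (oldest first);
    ``read_origins`` maps read id -> (source id, start, strand).
    """

    snv_positions: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    acquisitions: dict[str, list[Acquisition]] = field(default_factory=dict)
    losses: dict[str, list[tuple[float, int]]] = field(default_factory=dict)
    read_origins: pd.DataFrame | None = None


def simulate_ancestor(config: SimConfig, rng: np.random.Generator | None = None,
                      genome_id: str = "ancestor") -> Genome:
    """Random genome with ``config.n_arrays`` planted CRISPR arrays.

    The assembled genome has length ``genome_length`` plus the array
    footprints. Raises :class:`ValueError` when the background cannot hold the
    requested arrays.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    L = config.genome_length
    background = random_seq(rng, L, config.gc)
    lo, hi = config.spacer_length_range
    # keep array anchors well separated so planted loci never interleave
    margin = config.n_arrays * (config.repeat_length + hi + 1) * (config.n_initial_spacers + 2)
    if L <= margin:
        raise ValueError(
            f"genome_length {L} too small for {config.n_arrays} array(s) "
            f"of {config.n_initial_spacers} spacers")
    positions = np.sort(rng.choice(L - 1, size=config.n_arrays, replace=False) + 1)
    while config.n_arrays > 1 and np.diff(positions).min() < 2:
        positions = np.sort(rng.choice(L - 1, size=config.n_arrays, replace=False) + 1)
    arrays = []
    for pos in positions:
        repeat = random_seq(rng, config.repeat_length, config.gc)
        spacers = [random_seq(rng, int(rng.integers(lo, hi + 1)), config.gc)
                   for _ in range(config.n_initial_spacers)]
        arrays.append(PlantedArray(int(pos), repeat, spacers))
    return Genome(genome_id, background, arrays)


def simulate_phage_pool(config: SimConfig, rng: np.random.Generator | None = None) -> list[Phage]:
    """Random phage pool; members of a shared template form one vOTU."""
    config.validate()
    if rng is None:
        rng = config.rng()
    n = config.n_phages
    k = config.phages_per_votu
    n_votus = math.ceil(n / k)
    phages = []
    for j in range(n_votus):
        template = encode(random_seq(rng, config.phage_length, config.gc))
        for m in range(k):
            i = j * k + m
            if i >= n:
                break
            member = template.copy()
            n_sub = rng.poisson(config.votu_divergence * member.size)
            if n_sub:
                pos = rng.choice(member.size, size=min(n_sub, member.size), replace=False)
                member[pos] = (member[pos] + rng.integers(1, 4, size=pos.size)) % 4
            phages.append(Phage(f"phage_{i:03d}", f"vOTU_{j:03d}", decode(member)))
    return phages


def _draw_spacer(rng: np.random.Generator, phages: list[Phage],
                 length_range: tuple[int, int]) -> tuple[str, str, str]:
    lo, hi = length_range
    phage = phages[int(rng.integers(len(phages)))]
    length = int(rng.integers(lo, hi + 1))
    if length > len(phage.seq):
        raise ValueError("phage shorter than requested spacer length")
    start = int(rng.integers(len(phage.seq) - length + 1))
    spacer = phage.seq[start:start + length]
    strand = "+"
    if rng.random() < 0.5:
        spacer, strand = revcomp(spacer), "-"
    return spacer, phage.id, strand


def _apply_substitutions(genome: Genome, n_sub_rate: float, G: float,
                         shield_arrays: bool, rng: np.random.Generator,
                         ) -> list[tuple[str, int]]:
    """Poisson substitutions on the assembled genome, avoiding shielded positions.

    Shielded positions are the planted repeat units (always) and, when
    ``shield_arrays`` is set, the whole array footprints. The mutated
    background and spacer strings are written back onto ``genome`` so it
    remains a consistent background+arrays decomposition.
    """
    seq = encode(genome.assemble())
    shield = np.zeros(seq.size, dtype=bool)
    starts = genome.array_starts()
    arrays = sorted(genome.arrays, key=lambda a: a.bg_pos)
    for start, arr in zip(starts, arrays):
        if shield_arrays:
            shield[start:start + arr.footprint] = True
        else:
            pos = start
            r = len(arr.repeat)
            shield[pos:pos + r] = True
            for s in arr.spacers:
                pos += r + len(s)
                shield[pos:pos + r] = True
    mutable = np.flatnonzero(~shield)
    n = rng.poisson(n_sub_rate * G * mutable.size)
    n = min(n, mutable.size)
    hit = rng.choice(mutable, size=n, replace=False) if n else np.empty(0, dtype=int)
    if n:
        seq[hit] = (seq[hit] + rng.integers(1, 4, size=n)) % 4
    # write the mutated sequence back into the background/array decomposition
    mutated = decode(seq)
    pieces = []
    prev_end = 0
    bg_parts = []
    for start, arr in zip(starts, arrays):
        bg_parts.append(mutated[prev_end:start])
        pos = start + len(arr.repeat)
        new_spacers = []
        for s in arr.spacers:
            new_spacers.append(mutated[pos:pos + len(s)])
            pos += len(s) + len(arr.repeat)
        arr.spacers = new_spacers
        prev_end = start + arr.footprint
        pieces.append(arr)
    bg_parts.append(mutated[prev_end:])
    genome.background = "".join(bg_parts)
    return [(genome.id, int(p)) for p in sorted(hit)]


def _evolve_lineage(ancestor: Genome, config: SimConfig, phages: list[Phage],
                    rng: np.random.Generator, lineage_id: str):
    genome = ancestor.copy()
    genome.id = lineage_id
    G = config.generations
    n_acq = rng.poisson(config.rho * G)
    if n_acq and not phages:
        raise ValueError("spacer acquisition requested but the phage pool is empty")
    gens = np.sort(rng.uniform(0, G, size=n_acq))
    acquisitions = []
    leader_array = min(genome.arrays, key=lambda a: a.bg_pos) if genome.arrays else None
    if n_acq and leader_array is None:
        raise ValueError("cannot acquire spacers: ancestor has no array")
    for g in gens:
        spacer, phage_id, strand = _draw_spacer(rng, phages, config.spacer_length_range)
        leader_array.spacers.insert(0, spacer)  # leader end = position 0
        acquisitions.append(Acquisition(float(g), spacer, phage_id, strand))
    losses: list[tuple[float, int]] = []
    if config.loss > 0 and genome.arrays:
        for arr in genome.arrays:
            survivors = []
            for idx, s in enumerate(arr.spacers):
                t_loss = rng.exponential(1.0 / config.loss)
                if t_loss < G:
                    losses.append((float(G - t_loss), idx))
                else:
                    survivors.append(s)
            arr.spacers = survivors
    snvs = _apply_substitutions(genome, config.mu, G, config.shield_arrays, rng)
    return genome, acquisitions, losses, snvs


def evolve_pair(ancestor: Genome, config: SimConfig, phages: list[Phage],
                rng: np.random.Generator | None = None,
                ids: tuple[str, str] = ("strain_A", "strain_B"),
                ) -> tuple[Genome, Genome, SimTruth]:
    """Two lineages independently diverged from ``ancestor``.

    Each lineage accumulates Poisson(mu * mutable_length * G) substitutions,
    Poisson(rho * G) leader-end spacer acquisitions drawn from the phage pool,
    and exponential spacer losses at rate ``loss``.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    truth = SimTruth()
    genomes = []
    for lid in ids:
        genome, acq, losses, snvs = _evolve_lineage(ancestor, config, phages, rng, lid)
        truth.snv_positions[lid] = snvs
        truth.acquisitions[lid] = acq
        truth.losses[lid] = losses
        genomes.append(genome)
    return genomes[0], genomes[1], truth


@dataclass
class ReadSet:
    """Simulated reads held as an (n_reads, read_len) uint8 matrix."""

    matrix: np.ndarray
    prefix: str = "read"

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def read_len(self) -> int:
        return self.matrix.shape[1]

    def id_of(self, i: int) -> str:
        return f"{self.prefix}_{i:07d}"

    def sequence(self, i: int) -> str:
        return decode(self.matrix[i])

    def records(self):
        for i in range(len(self)):
            yield self.id_of(i), self.sequence(i)


def simulate_metagenome(sources: list[tuple[str, str]],
                        abundances,
                        n_reads: int,
                        read_len: int = 150,
                        error_rate: float = 0.0,
                        rng: np.random.Generator | None = None,
                        seed: int | None = None,
                        prefix: str = "read",
                        ) -> tuple[ReadSet, pd.DataFrame]:
    """Shotgun reads from ``sources`` at the given relative abundances.

    Reads are drawn from sources proportional to abundance x source length,
    with uniform start and random strand, then per-base substitution errors at
    ``error_rate``. Returns the reads plus an origins table (read id index;
    columns ``source``, ``pos``, ``strand``) covering every read exactly once.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ab = np.asarray(abundances, dtype=float)
    if ab.size != len(sources):
        raise ValueError("one abundance per source required")
    if (ab < 0).any() or ab.sum() == 0:
        raise ValueError("abundances must be >= 0 and not all zero")
    lengths = np.array([len(s) for _, s in sources])
    short = (lengths < read_len) & (ab > 0)
    if short.any():
        bad = sources[int(np.flatnonzero(short)[0])][0]
        raise ValueError(f"source {bad!r} shorter than read_len {read_len}")
    weights = ab * lengths
    p = weights / weights.sum()
    src_idx = rng.choice(len(sources), size=n_reads, p=p)
    starts = np.empty(n_reads, dtype=np.int64)
    for i, (sid, seq) in enumerate(sources):
        mask = src_idx == i
        if mask.any():
            starts[mask] = rng.integers(0, len(seq) - read_len + 1, size=int(mask.sum()))
    strands = rng.random(n_reads) < 0.5  # True = '-'
    matrix = np.empty((n_reads, read_len), dtype=np.uint8)
    offsets = np.arange(read_len)
    for i, (sid, seq) in enumerate(sources):
        mask = np.flatnonzero(src_idx == i)
        if mask.size == 0:
            continue
        arr = encode(seq)
        matrix[mask] = arr[starts[mask, None] + offsets]
    minus = np.flatnonzero(strands)
    if minus.size:
        matrix[minus] = (3 - matrix[minus])[:, ::-1]
    if error_rate > 0:
        chunk = 200_000
        for lo in range(0, n_reads, chunk):
            block = matrix[lo:lo + chunk]
            mask = rng.random(block.shape) < error_rate
            n_err = int(mask.sum())
            if n_err:
                block[mask] = (block[mask] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
    reads = ReadSet(matrix, prefix=prefix)
    origins = pd.DataFrame({
        "source": [sources[i][0] for i in src_idx],
        "pos": starts,
        "strand": np.where(strands, "-", "+"),
    }, index=[reads.id_of(i) for i in range(n_reads)])
    return reads, origins
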