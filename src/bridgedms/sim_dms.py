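"""Seeded simulator of NNS sort-seq experiments with paired-end reads.

The generator emulates a five-site saturation-mutagenesis screen of a
GPCR-like gene read out by 2 x 75 bp Illumina paired-end sequencing:

* a library whose mutated codons are drawn uniformly from the 32 NNS
  codons per site (N = A/C/G/T at codon positions 1-2, S = C/G at
  position 3), so every amino acid plus exactly one stop codon (TAG) is
  reachable with the natural NNS degeneracy;
* a multiplicative per-variant fitness (log-normal), with stop-containing
  variants fixed at zero fitness;
* repeated sort rounds in which functional variants grow in proportion
  to frequency x fitness while stop variants persist only through a
  nonspecific carryover fraction ``lambda`` (``f_{k+1} = lambda * f_k``
  on the stop-read mass);
* FASTQ emission in which the two variable loci are split across the
  mates near their 5' ends, both mates of a template share one unique
  flow-cell coordinate, qualities decline toward the 3' end, and
  substitution errors are drawn per base from the Phred-implied
  probability.  Optional indel injection, mate dropout, and coordinate
  collisions exercise the corresponding filters.

Every read identifier also encodes the template index in its instrument
field, so ground truth is recoverable from the FASTQ alone and pairing
can be audited for mispairings exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .bridge_core import AnchorSpec, Locus, reverse_complement
from .fastq_io import ClusterKey, SequenceRead, write_fastq
from .variant_quant import CODON_TO_AA

__all__ = [
    "NNS_CODONS",
    "NNS_AA_DEGENERACY",
    "SimConfig",
    "VariantPool",
    "SortSeries",
    "GroundTruth",
    "default_anchor_specs",
    "flanking_regions",
    "generate_library",
    "simulate_rounds",
    "emit_fastq",
    "simulate_experiment",
]

#: The 32 NNS codons (third base C or G).
NNS_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "CG"
)
#: How many NNS codons encode each amino acid (and the TAG stop).
NNS_AA_DEGENERACY: dict[str, int] = {}
for _codon in NNS_CODONS:
    _aa = CODON_TO_AA[_codon]
    NNS_AA_DEGENERACY[_aa] = NNS_AA_DEGENERACY.get(_aa, 0) + 1

# Read architecture: anchors bracketing each mate's variable inner
# region, with constant context around the mutated codons.  The constant
# stretches immediately inside the anchors double as known-truth flanks
# for observed-error analysis.
FWD_ANCHOR_5 = "CGTCCTGG"
FWD_ANCHOR_3 = "CCATCTTCA"
REV_ANCHOR_5 = "GCAGTTGA"  # in reverse-read frame
REV_ANCHOR_3 = "GCAGAGG"
FWD_FLANK_5 = "TCCTC"
FWD_FLANK_3 = "AGCT"
REV_FLANK_5 = "ATCA"  # sense-strand coordinates
REV_LINKER = "GTCGAC"  # constant codons between W246 and L249
REV_FLANK_3 = "CTGCCC"
TAIL = "TGACGGATCCAAGCTTGGCACTGGCCGTCGTTTTACAACGTCGTGACTGGGAAAACCCTGGCG"

#: Wild-type codons for T88, Q89, W246, L249, H250 ("TQWLH").
WT_CODONS: tuple[str, ...] = ("ACC", "CAG", "TGG", "CTG", "CAC")

_FWD_INNER_LEN = len(FWD_FLANK_5) + 6 + len(FWD_FLANK_3)  # 15
_REV_INNER_LEN = len(REV_FLANK_5) + 3 + len(REV_LINKER) + 6 + len(REV_FLANK_3)  # 25


def default_anchor_specs(max_mismatches: int = 0) -> tuple[AnchorSpec, AnchorSpec]:
    """Anchor/locus layout matching the simulator's read architecture."""
    return (
        AnchorSpec(
            mate=1,
            five_prime_anchor=FWD_ANCHOR_5,
            three_prime_anchor=FWD_ANCHOR_3,
            expected_inner_length=_FWD_INNER_LEN,
            loci=(Locus("T88", 5), Locus("Q89", 8)),
            max_mismatches=max_mismatches,
        ),
        AnchorSpec(
            mate=2,
            five_prime_anchor=REV_ANCHOR_5,
            three_prime_anchor=REV_ANCHOR_3,
            expected_inner_length=_REV_INNER_LEN,
            loci=(Locus("W246", 4), Locus("L249", 13), Locus("H250", 16)),
            max_mismatches=max_mismatches,
        ),
    )


def flanking_regions() -> dict[int, list[tuple[int, str]]]:
    """Constant (known-truth) regions per mate, in sense inner coordinates."""
    return {
        1: [(0, FWD_FLANK_5), (_FWD_INNER_LEN - len(FWD_FLANK_3), FWD_FLANK_3)],
        2: [
            (0, REV_FLANK_5),
            (len(REV_FLANK_5) + 3, REV_LINKER),
            (_REV_INNER_LEN - len(REV_FLANK_3), REV_FLANK_3),
        ],
    }


@dataclass(frozen=True)
class SimConfig:
    """All knobs of one simulated screen; the seed fully determines output.

    Defaults mirror the emulated study conditions: a five-site NNS
    library split 2|3 across 2 x 75 bp mates, four sort rounds, variable
    bases near the 5' end at quality ~35-38, qualities decaying toward
    the 3' end, and stop variants as built-in null controls.
    """

    seed: int = 0
    library_size: int = 2000
    rounds: int = 4
    reads_per_round: int = 100_000
    read_length: int = 75
    carryover: float = 0.3
    fitness_log_mu: float = 0.0
    fitness_log_sigma: float = 1.0
    include_wild_type: bool = True
    q_start: float = 38.0
    q_end: float = 25.0
    substitution_errors: bool = True
    indel_rate: float = 0.0
    mate_drop_rate: float = 0.0
    collision_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("carryover", "indel_rate", "mate_drop_rate", "collision_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.rounds < 1 or self.library_size < 1 or self.reads_per_round < 1:
            raise ValueError("rounds, library_size and reads_per_round must be >= 1")

    def quality_profile(self) -> np.ndarray:
        """Per-position mean Q, declining linearly 3'-ward."""
        return np.round(
            np.linspace(self.q_start, self.q_end, self.read_length)
        ).astype(int)


@dataclass(frozen=True)
class VariantPool:
    """Unique library variants with naive frequencies and fitness weights."""

    codons: tuple[tuple[str, ...], ...]
    aa: tuple[str, ...]
    weights: np.ndarray
    naive_freqs: np.ndarray

    def __len__(self) -> int:
        return len(self.aa)


@dataclass(frozen=True)
class SortSeries:
    """True per-round frequencies and sampled read counts of one screen.

    ``freqs[k]`` is the true population composition of round k (k = 0 is
    the naive library); ``counts[k]`` the multinomially sampled read
    counts at the configured sequencing depth.
    """

    pool: VariantPool
    freqs: np.ndarray
    counts: np.ndarray

    @property
    def round_labels(self) -> list[str]:
        return ["naive"] + [f"PS{k}" for k in range(1, self.freqs.shape[0])]

    def stop_fractions(self, sampled: bool = True) -> list[float]:
        is_stop = np.array(["*" in aa for aa in self.pool.aa])
        mat = self.counts if sampled else self.freqs
        out = []
        for row in mat:
            total = row.sum()
            out.append(float(row[is_stop].sum() / total))
        return out


@dataclass
class GroundTruth:
    """Per-read template identity and every deliberate corruption."""

    aa_by_key: dict[ClusterKey, str]
    codons_by_key: dict[ClusterKey, tuple[str, ...]]
    variant_index_by_key: dict[ClusterKey, int]
    dropped_r2: set[ClusterKey]
    indel_keys: set[ClusterKey]
    collided_keys: set[ClusterKey]
    n_substitutions: dict[int, int] = field(default_factory=dict)
    n_variable_bases: dict[int, int] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.aa_by_key)

    def surviving_pairs(self) -> int:
        """Pairs expected to bridge: not mate-dropped, no indel, no collision."""
        bad = self.dropped_r2 | self.indel_keys | self.collided_keys
        return sum(1 for k in self.aa_by_key if k not in bad)


def generate_library(cfg: SimConfig, rng: np.random.Generator | None = None) -> VariantPool:
    """Draw the naive library: NNS codons per site, log-normal fitness.

    ``library_size`` independent templates are drawn with replacement
    from the 32^5 codon space; identical genotypes merge, and naive
    frequencies carry the resulting multiplicity.  Stop-containing
    variants get fitness 0; the wild type, if requested, is guaranteed
    present with fitness 1 (the reference).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    draws = rng.integers(0, len(NNS_CODONS), size=(cfg.library_size, len(WT_CODONS)))
    genotype_counts: dict[tuple[str, ...], int] = {}
    for row in draws:
        genotype = tuple(NNS_CODONS[i] for i in row)
        genotype_counts[genotype] = genotype_counts.get(genotype, 0) + 1
    if cfg.include_wild_type:
        genotype_counts.setdefault(WT_CODONS, 0)
        genotype_counts[WT_CODONS] += max(1, cfg.library_size // 200)
    genotypes = sorted(genotype_counts)
    aa = tuple("".join(CODON_TO_AA[c] for c in g) for g in genotypes)
    weights = rng.lognormal(cfg.fitness_log_mu, cfg.fitness_log_sigma, len(genotypes))
    for i, a in enumerate(aa):
        if "*" in a:
            weights[i] = 0.0
        elif cfg.include_wild_type and genotypes[i] == WT_CODONS:
            weights[i] = 1.0
    mult = np.array([genotype_counts[g] for g in genotypes], dtype=float)
    return VariantPool(
        codons=tuple(genotypes),
        aa=aa,
        weights=weights,
        naive_freqs=mult / mult.sum(),
    )


def simulate_rounds(
    pool: VariantPool, cfg: SimConfig, rng: np.random.Generator | None = None
) -> SortSeries:
    """Propagate frequencies through the sort rounds and sample reads.

    Per round, the stop-variant read mass shrinks to exactly
    ``carryover`` times its previous value (the defining carryover
    relation), while functional variants share the remaining mass in
    proportion to frequency x fitness.  Each round's reads are then a
    multinomial sample at ``reads_per_round`` depth.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    weights = np.asarray(pool.weights, dtype=float)
    if not np.any(weights > 0):
        raise ValueError("all fitness weights are zero; population would go extinct")
    is_stop = weights == 0.0
    freqs = [np.asarray(pool.naive_freqs, dtype=float)]
    for _ in range(cfg.rounds):
        f = freqs[-1]
        new = np.zeros_like(f)
        stop_mass = float(f[is_stop].sum()) * cfg.carryover
        functional = f * weights
        func_total = functional.sum()
        if func_total > 0:
            new[~is_stop] = functional[~is_stop] / func_total * (1.0 - stop_mass)
        if stop_mass > 0:
            prev_stop = f[is_stop]
            new[is_stop] = prev_stop / prev_stop.sum() * stop_mass
        freqs.append(new)
    freq_mat = np.vstack(freqs)
    counts = np.vstack(
        [rng.multinomial(cfg.reads_per_round, f / f.sum()) for f in freq_mat]
    )
    return SortSeries(pool=pool, freqs=freq_mat, counts=counts)


def _template_reads(genotype: Sequence[str]) -> tuple[str, str, str]:
    """R1 body, R2 body (both anchor-to-tail, no spacer), sense inner2."""
    c = list(genotype)
    inner1 = FWD_FLANK_5 + c[0] + c[1] + FWD_FLANK_3
    inner2 = REV_FLANK_5 + c[2] + REV_LINKER + c[3] + c[4] + REV_FLANK_3
    r1 = FWD_ANCHOR_5 + inner1 + FWD_ANCHOR_3 + TAIL
    r2 = REV_ANCHOR_5 + reverse_complement(inner2) + REV_ANCHOR_3 + TAIL
    return r1, r2, inner2


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _inject_substitutions(
    reads: np.ndarray, p_by_pos: np.ndarray, rng: np.random.Generator
) -> int:
    """Mutate bases of a (n_reads, read_len) uint8 array in place."""
    n_sub = 0
    chunk = 20_000
    for start in range(0, reads.shape[0], chunk):
        block = reads[start : start + chunk]
        mask = rng.random(block.shape) < p_by_pos[None, : block.shape[1]]
        idx = np.argwhere(mask)
        for i, j in idx:
            current = block[i, j]
            choices = _BASES[_BASES != current]
            block[i, j] = rng.choice(choices)
        n_sub += len(idx)
    return n_sub


def emit_fastq(
    pool: VariantPool,
    freqs: np.ndarray,
    n_reads: int,
    cfg: SimConfig,
    r1_path: str | Path,
    r2_path: str | Path,
    rng: np.random.Generator,
    population: str = "naive",
) -> GroundTruth:
    """Write one population as shuffled R1/R2 FASTQ and return the truth.

    Every template pair gets a unique flow-cell coordinate (unless
    collisions are injected) and an instrument field encoding the true
    variant index, so pairing accuracy is fully auditable.  Record order
    in the two files is shuffled independently, forcing any downstream
    pairing to rely on coordinates rather than file position.
    """
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum()
    template_idx = rng.choice(len(pool), size=n_reads, p=freqs)
    qprof = cfg.quality_profile()
    quals = tuple(int(q) for q in qprof)
    p_by_pos = 10.0 ** (-qprof / 10.0)

    bodies = [_template_reads(g) for g in pool.codons]
    spacer_lens = rng.integers(0, 4, size=n_reads)
    spacer_bases = rng.integers(0, 4, size=(n_reads, 3))

    L = cfg.read_length
    r1_mat = np.empty((n_reads, L), dtype=np.uint8)
    r2_mat = np.empty((n_reads, L), dtype=np.uint8)
    base_lut = "ACGT"
    for i in range(n_reads):
        s = int(spacer_lens[i])
        spacer = "".join(base_lut[b] for b in spacer_bases[i, :s])
        b1, b2, _ = bodies[template_idx[i]]
        r1_mat[i] = np.frombuffer(((spacer + b1) + TAIL)[:L].encode(), dtype=np.uint8)
        r2_mat[i] = np.frombuffer(((spacer + b2) + TAIL)[:L].encode(), dtype=np.uint8)

    truth = GroundTruth(
        aa_by_key={},
        codons_by_key={},
        variant_index_by_key={},
        dropped_r2=set(),
        indel_keys=set(),
        collided_keys=set(),
    )
    if cfg.substitution_errors:
        truth.n_substitutions[1] = _inject_substitutions(r1_mat, p_by_pos, rng)
        truth.n_substitutions[2] = _inject_substitutions(r2_mat, p_by_pos, rng)
    truth.n_variable_bases = {1: n_reads * L, 2: n_reads * L}

    # Unique coordinates; optionally force some pairs to share coordinates.
    xs = 1000 + np.arange(n_reads) % 30000
    ys = 1000 + np.arange(n_reads) // 30000
    keys = [ClusterKey("SIMFC", 1, 11101, int(x), int(y)) for x, y in zip(xs, ys)]
    if cfg.collision_rate > 0 and n_reads > 1:
        collide = np.nonzero(rng.random(n_reads) < cfg.collision_rate)[0]
        for i in collide:
            j = (i + 1) % n_reads
            keys[i] = keys[j]
            truth.collided_keys.add(keys[j])

    drop_r2 = rng.random(n_reads) < cfg.mate_drop_rate
    indel = rng.random(n_reads) < cfg.indel_rate

    r1_records: list[SequenceRead] = []
    r2_records: list[SequenceRead] = []
    for i in range(n_reads):
        key = keys[i]
        t = int(template_idx[i])
        truth.aa_by_key[key] = pool.aa[t]
        truth.codons_by_key[key] = pool.codons[t]
        truth.variant_index_by_key[key] = t
        bases1 = r1_mat[i].tobytes().decode()
        bases2 = r2_mat[i].tobytes().decode()
        if indel[i]:
            # Delete one base inside the R1 inner region; length restored
            # from the tail, so only the anchor spacing shifts.
            pos = int(spacer_lens[i]) + len(FWD_ANCHOR_5) + int(rng.integers(0, 10))
            bases1 = (bases1[:pos] + bases1[pos + 1 :] + TAIL)[:L]
            truth.indel_keys.add(key)
        head = f"SIM{t}:1:{key.flowcell}:{key.lane}:{key.tile}:{key.x}:{key.y}"
        r1_records.append(
            SequenceRead(
                raw_id=f"{head} 1:N:0:1",
                instrument=f"SIM{t}",
                run=1,
                flowcell=key.flowcell,
                lane=key.lane,
                tile=key.tile,
                x=key.x,
                y=key.y,
                mate=1,
                bases=bases1,
                quals=quals,
            )
        )
        if drop_r2[i]:
            truth.dropped_r2.add(key)
        else:
            r2_records.append(
                SequenceRead(
                    raw_id=f"{head} 2:N:0:1",
                    instrument=f"SIM{t}",
                    run=1,
                    flowcell=key.flowcell,
                    lane=key.lane,
                    tile=key.tile,
                    x=key.x,
                    y=key.y,
                    mate=2,
                    bases=bases2,
                    quals=quals,
                )
            )
    write_fastq([r1_records[i] for i in rng.permutation(len(r1_records))], r1_path)
    write_fastq([r2_records[i] for i in rng.permutation(len(r2_records))], r2_path)
    return truth


def simulate_experiment(
    cfg: SimConfig, out_dir: str | Path
) -> tuple[SortSeries, dict[str, GroundTruth]]:
    """Run a full screen and write per-round FASTQ pairs plus ground truth.

    Files land in ``out_dir`` as ``<round>_R1.fastq.gz`` /
    ``<round>_R2.fastq.gz`` for naive and PS1..PSn.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    pool = generate_library(cfg, rng)
    series = simulate_rounds(pool, cfg, rng)
    truths: dict[str, GroundTruth] = {}
    for k, label in enumerate(series.round_labels):
        truths[label] = emit_fastq(
            pool,
            series.freqs[k],
            cfg.reads_per_round,
            cfg,
            out / f"{label}_R1.fastq.gz",
            out / f"{label}_R2.fastq.gz",
            rng,
            population=label,
        )
    return series, truths
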