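"""Variant calling, counting, enrichment, and library-level statistics.

A bridged template is reduced to its multi-locus protein variant — one
amino acid per configured codon position, in fixed locus order (for the
five-site A2aR library: T88, Q89, W246, L249, H250, so the wild type is
``"TQWLH"``).  Variants are tallied per sorted population, and each
variant's *enrichment rate* is the ratio of its relative frequency in a
sorted population to its relative frequency in the naive library.  A
minimum naive read count guards the rate against shot noise.

The module also provides the supporting screen diagnostics:

* *epistasis classes* — whether a variant's substitutions fall in one
  read's locus group (proximal) or span both distal groups, the
  distinction a single short read could never resolve;
* *carryover* — the per-round survival fraction ``lambda`` of
  loss-of-function (stop-containing) variants, estimated from
  ``f_{k+1} = lambda * f_k`` on the stop-read fraction per round;
* *codon adaptation index* — geometric mean of per-codon relative
  adaptiveness against a highly-expressed reference gene set;
* *library coverage* — observed unique variants over the theoretical
  diversity of an NNS site-saturation design (20 amino acids + the TAG
  stop = 21 states per site).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .bridge_core import AnchorSpec, BridgedTemplate, Rejection, RejectReason

__all__ = [
    "CODON_TO_AA",
    "VariantCall",
    "CountTable",
    "EnrichmentRecord",
    "CarryoverEstimate",
    "CAIReference",
    "call_variant",
    "tally",
    "enrichment_rate",
    "classify",
    "class_summary",
    "stop_fraction",
    "estimate_carryover",
    "cai",
    "library_coverage",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: Standard genetic code, stops mapped to '*'.
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _TABLE.stop_codons})

CLASS_NAMES = (
    "wild_type",
    "stop",
    "single",
    "proximal_double",
    "proximal_triple",
    "distal_multi",
)


@dataclass(frozen=True, slots=True)
class VariantCall:
    """Codon and amino-acid identity of one bridged template."""

    codons: tuple[str, ...]
    aa_string: str

    @property
    def codon_string(self) -> str:
        return "".join(self.codons)


def call_variant(
    template: BridgedTemplate, specs: Sequence[AnchorSpec]
) -> VariantCall | Rejection:
    """Extract and translate the configured codons of one template.

    ``specs`` order must match the template's segment order (mate 1 then
    mate 2); loci are read in configuration order, which fixes the
    position order of ``aa_string``.  Any ``N`` within a codon makes the
    call ambiguous and the template is rejected rather than guessed.
    """
    if len(template.segments) != len(specs):
        raise ValueError(
            f"template has {len(template.segments)} segments for {len(specs)} specs"
        )
    codons: list[str] = []
    for segment, spec in zip(template.segments, specs):
        if len(segment) != spec.expected_inner_length:
            raise ValueError(
                f"segment length {len(segment)} != expected "
                f"{spec.expected_inner_length} for mate {spec.mate}"
            )
        for locus in spec.loci:
            codon = segment[locus.codon_offset : locus.codon_offset + 3]
            if "N" in codon:
                return Rejection(
                    RejectReason.AMBIGUOUS_BASE, f"N in codon at locus {locus.label}"
                )
            codons.append(codon)
    try:
        aa = "".join(CODON_TO_AA[c] for c in codons)
    except KeyError as exc:
        return Rejection(RejectReason.AMBIGUOUS_BASE, f"unknown codon {exc}")
    return VariantCall(codons=tuple(codons), aa_string=aa)


@dataclass
class CountTable:
    """Variant read counts per named population (naive, PS1..PS4, ...)."""

    populations: list[str]
    counts: dict[str, Counter]

    @property
    def totals(self) -> dict[str, int]:
        return {p: sum(self.counts[p].values()) for p in self.populations}

    def frequency(self, population: str, variant: str) -> float:
        total = sum(self.counts[population].values())
        if total == 0:
            raise ValueError(f"population {population!r} has zero total count")
        return self.counts[population][variant] / total

    def variants(self) -> list[str]:
        seen: set[str] = set()
        for p in self.populations:
            seen.update(self.counts[p])
        return sorted(seen)

    def to_frame(self) -> pd.DataFrame:
        data = {p: pd.Series(self.counts[p], dtype="int64") for p in self.populations}
        frame = pd.DataFrame(data).fillna(0).astype("int64")
        frame.index.name = "variant"
        return frame.sort_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        pops = list(frame.columns)
        counts = {
            p: Counter({v: int(c) for v, c in frame[p].items() if c}) for p in pops
        }
        return cls(populations=pops, counts=counts)


def tally(calls_by_population: Mapping[str, Iterable[str]]) -> CountTable:
    """Count variant keys (amino-acid or codon strings) per population."""
    populations = list(calls_by_population)
    counts = {p: Counter(calls_by_population[p]) for p in populations}
    return CountTable(populations=populations, counts=counts)


@dataclass(frozen=True, slots=True)
class EnrichmentRecord:
    """One variant's enrichment from the naive to a sorted population.

    ``rate`` is the frequency ratio and is only defined when the naive
    count reaches the minimum threshold (``passes_threshold``); a variant
    absent from the sorted population has rate 0.
    """

    aa_string: str
    naive_count: int
    sorted_count: int
    rate: float | None
    klass: str | None
    passes_threshold: bool


def enrichment_rate(
    table: CountTable,
    from_pop: str,
    to_pop: str,
    min_naive: int = 15,
    wild_type: str | None = None,
    locus_groups: Sequence[Sequence[int]] | None = None,
) -> list[EnrichmentRecord]:
    """Frequency-ratio enrichment of every variant between two populations.

    rate = (count_to / total_to) / (count_from / total_from).  Variants
    with fewer than ``min_naive`` reads in ``from_pop`` are flagged and
    carry no rate (low naive counts make the ratio dominated by noise).
    When ``wild_type`` and ``locus_groups`` are given, each record also
    carries its epistasis class.
    """
    for pop in (from_pop, to_pop):
        if pop not in table.populations:
            raise ValueError(f"population {pop!r} not in table")
    totals = table.totals
    if totals[from_pop] == 0 or totals[to_pop] == 0:
        raise ValueError("cannot compute enrichment against a zero-total population")
    records = []
    for variant in table.variants():
        n_from = table.counts[from_pop][variant]
        n_to = table.counts[to_pop][variant]
        if n_from == 0 and n_to == 0:
            continue
        passes = n_from >= min_naive
        rate = None
        if passes:
            rate = (n_to / totals[to_pop]) / (n_from / totals[from_pop])
        klass = None
        if wild_type is not None and locus_groups is not None:
            klass = classify(variant, wild_type, locus_groups)
        records.append(
            EnrichmentRecord(
                aa_string=variant,
                naive_count=n_from,
                sorted_count=n_to,
                rate=rate,
                klass=klass,
                passes_threshold=passes,
            )
        )
    return records


def classify(aa: str, wild_type: str, locus_groups: Sequence[Sequence[int]]) -> str:
    """Epistasis-relevant class of a variant relative to the wild type.

    ``locus_groups`` partitions the positions by sequencing read (for the
    A2aR library: ``[[0, 1], [2, 3, 4]]`` — TM3 sites on the forward
    read, TM6 sites on the reverse).  Substitutions confined to one group
    are *proximal* (resolvable by one read); substitutions spanning both
    groups are *distal* and only resolvable by bridged read pairs.
    """
    if len(aa) != len(wild_type):
        raise ValueError(f"variant length {len(aa)} != wild-type length {len(wild_type)}")
    positions = sorted(p for g in locus_groups for p in g)
    if positions != list(range(len(wild_type))):
        raise ValueError("locus_groups must partition all positions exactly once")
    if "*" in aa:
        return "stop"
    diffs = [i for i, (a, w) in enumerate(zip(aa, wild_type)) if a != w]
    if not diffs:
        return "wild_type"
    if len(diffs) == 1:
        return "single"
    groups_hit = {
        gi for gi, group in enumerate(locus_groups) if any(d in group for d in diffs)
    }
    if len(groups_hit) > 1:
        return "distal_multi"
    return "proximal_double" if len(diffs) == 2 else "proximal_triple"


def class_summary(
    records: Iterable[EnrichmentRecord], decimals: int = 1
) -> dict[str, dict[str, float]]:
    """Per-class maximum rate and distal-over-proximal fold ratios.

    Returns ``{"max_rate": {class: max}, "fold_vs_distal": {class:
    round(max(distal_multi)/max(class), decimals)}}``; classes with no
    record carrying a defined rate are simply absent.
    """
    best: dict[str, float] = {}
    for rec in records:
        if rec.rate is None or rec.klass is None:
            continue
        if rec.klass not in best or rec.rate > best[rec.klass]:
            best[rec.klass] = rec.rate
    folds: dict[str, float] = {}
    if "distal_multi" in best:
        top = best["distal_multi"]
        for klass, rate in best.items():
            if klass != "distal_multi" and rate > 0:
                folds[klass] = round(top / rate, decimals)
    return {"max_rate": best, "fold_vs_distal": folds}


def stop_fraction(calls_by_round: Mapping[str, Iterable[str]]) -> list[float]:
    """Fraction of reads whose variant contains >= 1 stop, per round.

    Computed over the configured loci only — the rest of the gene is
    constant, so any stop must sit at a mutated site.
    """
    fractions = []
    for label, calls in calls_by_round.items():
        calls = list(calls)
        if not calls:
            raise ValueError(f"round {label!r} has no reads")
        fractions.append(sum("*" in aa for aa in calls) / len(calls))
    return fractions


@dataclass(frozen=True, slots=True)
class CarryoverEstimate:
    """Per-round stop-read fractions and the implied carryover rates.

    ``lambdas[k]`` is ``fractions[k+1] / fractions[k]``; ``None`` (and a
    flag) where the preceding round had no stop reads, which leaves the
    ratio undefined.
    """

    fractions: tuple[float, ...]
    lambdas: tuple[float | None, ...]
    flagged: tuple[bool, ...]


def estimate_carryover(fractions: Sequence[float]) -> CarryoverEstimate:
    """Estimate the nonspecific carryover rate from stop-read depletion.

    Stop-containing variants are complete loss-of-function, so any reads
    they contribute to a sorted round are carryover; under
    ``f_{k+1} = lambda * f_k`` each consecutive pair of rounds gives one
    lambda estimate.
    """
    if len(fractions) < 2:
        raise ValueError("need at least two rounds to estimate carryover")
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"stop fraction {f} outside [0, 1]")
    lambdas: list[float | None] = []
    flagged: list[bool] = []
    for f_k, f_next in zip(fractions, fractions[1:]):
        if f_k > 0:
            lambdas.append(f_next / f_k)
            flagged.append(False)
        else:
            lambdas.append(None)
            flagged.append(f_next > 0)
    return CarryoverEstimate(tuple(fractions), tuple(lambdas), tuple(flagged))


@dataclass(frozen=True)
class CAIReference:
    """Relative adaptiveness ``w`` per sense codon.

    Within each synonymous family the most used codon of the reference
    gene set has ``w = 1``; single-codon families (ATG, TGG) are 1 by
    construction and cannot move the index.
    """

    w: Mapping[str, float]

    def __post_init__(self) -> None:
        families: dict[str, float] = {}
        for codon, weight in self.w.items():
            aa = CODON_TO_AA.get(codon)
            if aa is None or aa == "*":
                raise ValueError(f"{codon!r} is not a sense codon")
            if not 0 < weight <= 1:
                raise ValueError(f"w[{codon}] = {weight} outside (0, 1]")
            families[aa] = max(families.get(aa, 0.0), weight)
        bad = {aa for aa, m in families.items() if not math.isclose(m, 1.0)}
        if bad:
            raise ValueError(f"synonymous families without a w=1 codon: {sorted(bad)}")

    @classmethod
    def from_frequencies(cls, freqs: Mapping[str, float]) -> "CAIReference":
        """Build from reference codon frequencies (any consistent unit)."""
        family_max: dict[str, float] = {}
        for codon, f in freqs.items():
            aa = CODON_TO_AA.get(codon)
            if aa is None or aa == "*":
                continue
            family_max[aa] = max(family_max.get(aa, 0.0), f)
        w = {
            codon: f / family_max[CODON_TO_AA[codon]]
            for codon, f in freqs.items()
            if CODON_TO_AA.get(codon) not in (None, "*") and f > 0
        }
        return cls(w=w)

    @classmethod
    def yeast_highly_expressed(cls) -> "CAIReference":
        """Packaged reference for highly expressed S. cerevisiae genes."""
        text = (
            resources.files("bridgedms")
            .joinpath("data/cai_yeast_highly_expressed.tsv")
            .read_text()
        )
        w = {}
        for line in text.splitlines():
            if not line or line.startswith("#") or line.startswith("codon"):
                continue
            codon, weight = line.split("\t")
            w[codon] = float(weight)
        return cls(w=w)


def cai(codon_sequence: str | Sequence[str], ref: CAIReference) -> float:
    """Codon adaptation index: geometric mean of w over sense codons.

    Stop codons are skipped (they have no adaptiveness); any other codon
    missing from the reference is an error.
    """
    if isinstance(codon_sequence, str):
        if len(codon_sequence) % 3:
            raise ValueError("codon sequence length must be divisible by 3")
        codons = [codon_sequence[i : i + 3] for i in range(0, len(codon_sequence), 3)]
    else:
        codons = list(codon_sequence)
    logs = []
    for codon in codons:
        if CODON_TO_AA.get(codon) == "*":
            continue
        if codon not in ref.w:
            raise ValueError(f"codon {codon!r} not in the CAI reference")
        logs.append(math.log(ref.w[codon]))
    if not logs:
        raise ValueError("no sense codons to average")
    return math.exp(float(np.mean(logs)))


def library_coverage(
    observed_unique: int, n_sites: int, alphabet_size: int = 21
) -> float:
    """Percentage of the theoretical protein diversity that was observed.

    For an NNS site-saturation design the per-site alphabet is 21: the 20
    amino acids plus the single reachable stop (TAG is the only NNS stop
    codon).
    """
    if n_sites <= 0 or alphabet_size <= 0 or observed_unique < 0:
        raise ValueError("inputs must be positive (observed may be zero)")
    theoretical = alphabet_size**n_sites
    if observed_unique > theoretical:
        raise ValueError(
            f"observed {observed_unique} exceeds theoretical diversity {theoretical}"
        )
    return 100.0 * observed_unique / theoretical
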