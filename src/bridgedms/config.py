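"""Structured run configuration: anchors, loci, thresholds, wild type.

The YAML schema mirrors the experiment design::

    wild_type: TQWLH
    locus_groups: [[0, 1], [2, 3, 4]]
    min_q: 20
    min_naive: 15
    network_threshold: 1.0
    anchors:
      - mate: 1
        five_prime: CGTCCTGG
        three_prime: CCATCTTCA
        inner_length: 15
        search_window: 6
        loci: [{label: T88, offset: 5}, {label: Q89, offset: 8}]
      - mate: 2
        ...
    flanking:          # optional; sense inner coordinates, for qstats
      - {mate: 1, start: 0, seq: TCCTC}

Configurations round-trip exactly through :func:`save_config` /
:func:`load_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import yaml

from .bridge_core import AnchorSpec, Locus

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    anchors: tuple[AnchorSpec, ...]
    wild_type: str
    locus_groups: tuple[tuple[int, ...], ...]
    min_q: int = 20
    min_naive: int = 15
    network_threshold: float = 1.0
    flanking: tuple[tuple[int, int, str], ...] = ()  # (mate, start, seq)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_q < 0 or self.min_naive < 0 or self.network_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        n_loci = sum(len(a.loci) for a in self.anchors)
        if len(self.wild_type) != n_loci:
            raise ValueError(
                f"wild type {self.wild_type!r} has {len(self.wild_type)} residues "
                f"but the anchors declare {n_loci} loci"
            )
        positions = sorted(p for g in self.locus_groups for p in g)
        if positions != list(range(n_loci)):
            raise ValueError("locus_groups must partition the locus positions")

    def anchor_for_mate(self, mate: int) -> AnchorSpec:
        for spec in self.anchors:
            if spec.mate == mate:
                return spec
        raise KeyError(f"no AnchorSpec for mate {mate}")


def _spec_to_dict(spec: AnchorSpec) -> dict:
    return {
        "mate": spec.mate,
        "five_prime": spec.five_prime_anchor,
        "three_prime": spec.three_prime_anchor,
        "inner_length": spec.expected_inner_length,
        "search_window": spec.search_window,
        "max_mismatches": spec.max_mismatches,
        "loci": [{"label": l.label, "offset": l.codon_offset} for l in spec.loci],
    }


def _spec_from_dict(d: dict) -> AnchorSpec:
    return AnchorSpec(
        mate=int(d["mate"]),
        five_prime_anchor=d["five_prime"],
        three_prime_anchor=d["three_prime"],
        expected_inner_length=int(d["inner_length"]),
        search_window=int(d.get("search_window", 6)),
        max_mismatches=int(d.get("max_mismatches", 0)),
        loci=tuple(Locus(l["label"], int(l["offset"])) for l in d.get("loci", [])),
    )


def save_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    doc = {
        "wild_type": cfg.wild_type,
        "locus_groups": [list(g) for g in cfg.locus_groups],
        "min_q": cfg.min_q,
        "min_naive": cfg.min_naive,
        "network_threshold": cfg.network_threshold,
        "seed": cfg.seed,
        "anchors": [_spec_to_dict(a) for a in cfg.anchors],
        "flanking": [
            {"mate": m, "start": s, "seq": seq} for m, s, seq in cfg.flanking
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path: Union[str, Path]) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return RunConfig(
            anchors=tuple(_spec_from_dict(a) for a in doc["anchors"]),
            wild_type=doc["wild_type"],
            locus_groups=tuple(tuple(g) for g in doc["locus_groups"]),
            min_q=int(doc.get("min_q", 20)),
            min_naive=int(doc.get("min_naive", 15)),
            network_threshold=float(doc.get("network_threshold", 1.0)),
            flanking=tuple(
                (int(f["mate"]), int(f["start"]), f["seq"])
                for f in doc.get("flanking", [])
            ),
            seed=int(doc.get("seed", 0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid run configuration {path}: {exc}") from exc
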