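"""Rule-based secondary-metabolite cluster prediction.

Clusters are seeded at backbone synthetase genes (NRPS/PKS) and extended
gene-by-gene in both directions while neighbours carry cluster-associated
roles, tolerating a bounded run of non-associated genes and a bounded
intergenic distance. Two presets ship: a tight rule and a permissive rule,
which on real loci typically produce a smaller call nested inside a larger
one. They are parameter presets of one extension algorithm, not
re-implementations of any published predictor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .genome_model import (
    BACKBONE_ROLES,
    GeneModel,
    GenomeAnnotation,
    intergenic_gap,
)

logger = logging.getLogger(__name__)

#: roles counted as cluster-associated during extension
DEFAULT_SM_ROLES = frozenset(
    {
        "backbone_nrps",
        "backbone_pks",
        "tailoring",
        "regulator",
        "transport",
        "racemase",
        "aminotransferase",
        "cyclophilin",
    }
)


@dataclass(frozen=True)
class RuleParams:
    sm_roles: frozenset[str] = DEFAULT_SM_ROLES
    max_gap_genes: int = 1
    max_gap_bp: int = 10_000
    merge_backbones: bool = True

    def __post_init__(self) -> None:
        if self.max_gap_genes < 0 or self.max_gap_bp < 0:
            raise ValueError("gap tolerances must be >= 0")


#: tight preset: short extension reach, small gaps
RULE_A = RuleParams(max_gap_genes=1, max_gap_bp=10_000)
#: permissive preset: sweeps in more distant associated genes
RULE_B = RuleParams(max_gap_genes=3, max_gap_bp=20_000)

PRESETS = {"rule_A": RULE_A, "rule_B": RULE_B}


@dataclass
class ClusterCall:
    """A contiguous run of genes attributed to one prediction method."""

    method: str
    scaffold: str
    gene_ids: list[str]
    start_bp: int
    end_bp: int
    backbone_id: str
    flags: list[str] = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "scaffold": self.scaffold,
            "gene_ids": list(self.gene_ids),
            "start_bp": self.start_bp,
            "end_bp": self.end_bp,
            "span_bp": self.span_bp,
            "backbone_id": self.backbone_id,
            "flags": list(self.flags),
        }


def _extend(
    scaffold_genes: list[GeneModel],
    seed_idx: int,
    qualifies,
    max_gap_genes: int,
    max_gap_bp: int | None,
) -> tuple[int, int]:
    """Greedy bidirectional extension with gap tolerance and bp cutoff.

    Walks outward from ``seed_idx``; a qualifying gene resets the
    non-qualifying streak, a streak longer than ``max_gap_genes`` or an
    intergenic gap beyond ``max_gap_bp`` stops that direction. Trailing
    non-qualifying genes are trimmed so both ends qualify (the seed always
    qualifies implicitly). Returns inclusive index bounds.
    """
    lo = hi = seed_idx
    for direction in (-1, +1):
        i = seed_idx
        streak = 0
        last_kept = seed_idx
        while True:
            j = i + direction
            if j < 0 or j >= len(scaffold_genes):
                break
            a, b = sorted((scaffold_genes[i], scaffold_genes[j]), key=lambda g: g.start)
            if max_gap_bp is not None and intergenic_gap(a, b) > max_gap_bp:
                break
            if qualifies(scaffold_genes[j]):
                streak = 0
                last_kept = j
            else:
                streak += 1
                if streak > max_gap_genes:
                    break
            i = j
        if direction < 0:
            lo = min(lo, last_kept)
        else:
            hi = max(hi, last_kept)
    return lo, hi


def predict_clusters(
    ann: GenomeAnnotation, params: RuleParams, method: str = "rule"
) -> list[ClusterCall]:
    """One cluster call per backbone gene, merged when calls overlap.

    Extension proceeds while neighbours have roles in ``params.sm_roles``;
    genes whose role is outside the set count toward the gap-gene streak.
    Without backbone genes the result is empty (logged, not an error).
    """
    if len(ann) == 0:
        raise ValueError("annotation is empty")
    calls: list[ClusterCall] = []
    for scaffold in sorted({g.scaffold for g in ann.genes}):
        genes = ann.scaffold_genes(scaffold)
        backbone_idx = [i for i, g in enumerate(genes) if g.role in BACKBONE_ROLES]
        if not backbone_idx:
            continue
        intervals = []
        for bi in backbone_idx:
            lo, hi = _extend(
                genes,
                bi,
                lambda g: g.role in params.sm_roles,
                params.max_gap_genes,
                params.max_gap_bp,
            )
            intervals.append([lo, hi, bi])
        intervals.sort()
        if params.merge_backbones:
            merged = [intervals[0]]
            for lo, hi, bi in intervals[1:]:
                if lo <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], hi)
                else:
                    merged.append([lo, hi, bi])
            intervals = merged
        else:
            # drop calls fully contained in an earlier one
            pruned = []
            for iv in intervals:
                if not pruned or iv[1] > pruned[-1][1]:
                    pruned.append(iv)
            intervals = pruned
        for lo, hi, bi in intervals:
            members = genes[lo : hi + 1]
            calls.append(
                ClusterCall(
                    method=method,
                    scaffold=scaffold,
                    gene_ids=[g.gene_id for g in members],
                    start_bp=members[0].start,
                    end_bp=members[-1].end,
                    backbone_id=genes[bi].gene_id,
                )
            )
    if not calls:
        logger.info("no backbone genes in %s; no clusters predicted", ann.genome_id)
    return calls


def predict_presets(ann: GenomeAnnotation) -> dict[str, ClusterCall | None]:
    """Run both shipped presets; returns the call containing each preset's
    first backbone (None when nothing is predicted)."""
    out: dict[str, ClusterCall | None] = {}
    for name, params in PRESETS.items():
        calls = predict_clusters(ann, params, method=name)
        out[name] = calls[0] if calls else None
    return out


def write_bed(calls: Sequence[ClusterCall], path: str | Path) -> None:
    """BED6 export; internal 1-based inclusive becomes 0-based half-open."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.scaffold}\t{c.start_bp - 1}\t{c.end_bp}\t{c.method}\t0\t+\n"
            )


def write_calls_json(calls: Sequence[ClusterCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in calls], fh, indent=1, sort_keys=True)
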