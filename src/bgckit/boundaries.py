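"""Transcriptional cluster delineation and boundary concordance.

A gene qualifies as a transcriptional cluster member when it is
upregulated — q-value below ``alpha`` with positive log2 fold change — at a
minimum number of timepoints. The cluster is the maximal run of qualifying
genes around the backbone synthetase, tolerating a bounded run of
non-qualifying interior genes (constitutively expressed members can fail
the upregulation filter without splitting the cluster).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd

from .clusterpred import ClusterCall, _extend
from .genome_model import GenomeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001
DEFAULT_MIN_TIMEPOINTS = 1
DEFAULT_GAP_TOLERANCE = 1


def upregulated_genes(
    de: pd.DataFrame, alpha: float, min_timepoints: int = DEFAULT_MIN_TIMEPOINTS
) -> set[str]:
    """Genes upregulated (q < alpha and log2fc > 0) at >= min_timepoints."""
    hit = de[(de["q_value"] < alpha) & (de["log2fc"] > 0)]
    per_gene = hit.groupby("gene_id").size()
    return set(per_gene[per_gene >= min_timepoints].index)


def call_expression_cluster(
    ann: GenomeAnnotation,
    de: pd.DataFrame,
    backbone_id: str,
    alpha: float = DEFAULT_ALPHA,
    min_timepoints: int = DEFAULT_MIN_TIMEPOINTS,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
) -> ClusterCall:
    """Maximal run of upregulated genes around the backbone gene.

    Extension tolerates up to ``gap_tolerance`` consecutive non-qualifying
    genes; both call ends are trimmed back to qualifying genes. If the
    backbone itself does not qualify the call is still emitted, flagged
    ``backbone_not_significant``. A call swallowing the whole scaffold is
    flagged ``saturated`` (usually a sign of a mis-specified alpha).
    """
    backbone = ann.get(backbone_id)
    if backbone_id not in set(de["gene_id"]):
        raise ValueError(f"backbone {backbone_id!r} absent from DE table")
    qualifying = upregulated_genes(de, alpha, min_timepoints)
    genes = ann.scaffold_genes(backbone.scaffold)
    seed_idx = next(i for i, g in enumerate(genes) if g.gene_id == backbone_id)
    lo, hi = _extend(
        genes,
        seed_idx,
        lambda g: g.gene_id in qualifying,
        gap_tolerance,
        max_gap_bp=None,
    )
    flags = []
    if backbone_id not in qualifying:
        flags.append("backbone_not_significant")
    members = genes[lo : hi + 1]
    if lo == 0 and hi == len(genes) - 1:
        flags.append("saturated")
        logger.warning(
            "expression call saturates scaffold %s; check alpha", backbone.scaffold
        )
    return ClusterCall(
        method="expression",
        scaffold=backbone.scaffold,
        gene_ids=[g.gene_id for g in members],
        start_bp=members[0].start,
        end_bp=members[-1].end,
        backbone_id=backbone_id,
        flags=flags,
    )


@dataclass
class ConcordanceReport:
    """Pairwise boundary agreement and gene-set overlap between calls."""

    methods: list[str]
    calls: dict[str, dict]
    pairs: dict[str, dict] = field(default_factory=dict)

    def pair(self, m1: str, m2: str) -> dict:
        key = "|".join(sorted((m1, m2)))
        return self.pairs[key]

    def to_dict(self) -> dict:
        return {"methods": self.methods, "calls": self.calls, "pairs": self.pairs}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def compare_calls(calls: Sequence[ClusterCall]) -> ConcordanceReport:
    """Five-prime/three-prime boundary matches (by gene id) and Jaccard
    overlap of gene sets for every pair of calls on one scaffold."""
    if len(calls) < 2:
        raise ValueError("need >= 2 calls to compare")
    scaffolds = {c.scaffold for c in calls}
    if len(scaffolds) > 1:
        raise ValueError(f"calls on different scaffolds: {sorted(scaffolds)}")
    report = ConcordanceReport(
        methods=[c.method for c in calls],
        calls={c.method: c.to_dict() for c in calls},
    )
    for a, b in combinations(calls, 2):
        sa, sb = set(a.gene_ids), set(b.gene_ids)
        union = sa | sb
        jaccard = len(sa & sb) / len(union) if union else 1.0
        report.pairs["|".join(sorted((a.method, b.method)))] = {
            "five_prime_match": a.gene_ids[0] == b.gene_ids[0],
            "three_prime_match": a.gene_ids[-1] == b.gene_ids[-1],
            "jaccard": jaccard,
        }
    return report
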