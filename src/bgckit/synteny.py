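"""Orthology, flank microsynteny, and cluster-origin classification.

Orthologs are operationalised as unique reciprocal best hits (RBH) under
Smith-Waterman local alignment (match +2, mismatch -1; opening a gap costs
3 including its first position, each extension 1). Flank synteny around a
cluster is summarised per comparator genome: the fraction of flanking genes
with orthologs, the collinearity of their order, the intervening distance
between the innermost mapped flank orthologs, and where the comparator's
cluster-gene homologs sit relative to that span. A rule cascade then labels
the cluster's likely evolutionary origin in that comparator: a conserved
cluster, a candidate horizontal transfer (cluster block intact, flanks
foreign), a lineage-specific locus (flanks syntenic and nearly adjacent,
cluster homologs absent or dispersed), or a rearrangement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .clusterpred import ClusterCall
from .genome_model import (
    BACKBONE_ROLES,
    GenomeAnnotation,
    ProteinRecord,
    intergenic_gap,
    neighbor_window,
)

logger = logging.getLogger(__name__)

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -1, -3, -1

DEFAULT_MIN_SCORE = 30.0
DEFAULT_MIN_RATIO = 0.3


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


_ALIGNER = _aligner()


def local_align_score(a: str, b: str) -> float:
    """Smith-Waterman local alignment score; empty input scores 0."""
    if not a or not b:
        return 0.0
    return float(_ALIGNER.score(a, b))


@dataclass
class OrthologMap:
    """Unique reciprocal-best-hit pairs between two proteomes."""

    pairs: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        self.a_to_b = {a: (b, s) for a, b, s in self.pairs}
        self.b_to_a = {b: (a, s) for a, b, s in self.pairs}
        if len(self.a_to_b) != len(self.pairs) or len(self.b_to_a) != len(self.pairs):
            raise ValueError("a gene appears in more than one ortholog pair")

    def __len__(self) -> int:
        return len(self.pairs)

    def get(self, focal_gene: str) -> str | None:
        hit = self.a_to_b.get(focal_gene)
        return hit[0] if hit else None

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.pairs, columns=["focal_gene", "other_gene", "score"]).to_csv(
            path, sep="\t", index=False
        )


def _best_hits(
    queries: Mapping[str, ProteinRecord],
    targets: Mapping[str, ProteinRecord],
    scores: dict[tuple[str, str], float],
) -> dict[str, tuple[str, bool]]:
    """Best-scoring target per query; bool marks a unique maximum.

    Score ties are broken toward the lexicographically smallest target id
    and logged.
    """
    best: dict[str, tuple[str, bool]] = {}
    for q in queries:
        ranked = sorted(
            ((scores[(q, t)], t) for t in targets), key=lambda st: (-st[0], st[1])
        )
        if not ranked:
            continue
        top_score, top_t = ranked[0]
        unique = len(ranked) == 1 or ranked[1][0] < top_score
        if not unique:
            logger.info("best-hit tie for %s at score %.1f", q, top_score)
        best[q] = (top_t, unique)
    return best


def rbh_map(
    proteome_a: Mapping[str, ProteinRecord],
    proteome_b: Mapping[str, ProteinRecord],
    min_score: float = DEFAULT_MIN_SCORE,
    min_ratio: float = DEFAULT_MIN_RATIO,
) -> OrthologMap:
    """All-vs-all reciprocal best hits between two proteomes.

    A pair enters the map only if each side is the other's *unique* best
    hit, the score reaches ``min_score``, and the score reaches
    ``min_ratio`` times the self-alignment score of the shorter sequence
    (a length-normalised stand-in for an e-value cutoff).
    """
    if not proteome_a or not proteome_b:
        return OrthologMap(pairs=[])
    scores: dict[tuple[str, str], float] = {}
    for ida, pa in proteome_a.items():
        for idb, pb in proteome_b.items():
            scores[(ida, idb)] = local_align_score(pa.sequence, pb.sequence)
    fwd = _best_hits(proteome_a, proteome_b, scores)
    rev = _best_hits(
        proteome_b, proteome_a, {(b, a): s for (a, b), s in scores.items()}
    )
    pairs = []
    for a, (b, a_unique) in fwd.items():
        back = rev.get(b)
        if back is None or back[0] != a or not a_unique or not back[1]:
            continue
        score = scores[(a, b)]
        if score < min_score:
            continue
        shorter = min(
            proteome_a[a].sequence, proteome_b[b].sequence, key=len
        )
        if score < min_ratio * local_align_score(shorter, shorter):
            continue
        pairs.append((a, b, score))
    return OrthologMap(pairs=sorted(pairs))


ORIGIN_LABELS = (
    "lineage_specific",
    "conserved_cluster",
    "rearranged",
    "candidate_transfer",
    "unresolved",
)


@dataclass
class SyntenyReport:
    genome_id: str
    flank5_conserved: float
    flank3_conserved: float
    order_conserved: float
    intervening_gap_bp: int | None
    gap_flags: list[str]
    cluster_orthologs_total: int
    cluster_orthologs_inside_gap: int
    cluster_orthologs_dispersed: int
    cluster_size: int
    flank_n: int
    origin_label: str = "unresolved"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class OriginThresholds:
    """Decision thresholds for origin classification.

    ``gap_max_bp`` encodes the empirical observation that when a cluster is
    missing from a relative, its conserved flanks sit within a few kb of
    each other.
    """

    cluster_frac_hi: float = 0.8
    cluster_frac_lo: float = 0.3
    flank_frac_hi: float = 0.7
    flank_frac_lo: float = 0.5
    gap_max_bp: int = 5_000


def _lis_length(seq: Sequence[int]) -> int:
    """Longest strictly increasing subsequence (patience algorithm)."""
    import bisect

    tails: list[int] = []
    for x in seq:
        i = bisect.bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def flank_synteny_report(
    focal_ann: GenomeAnnotation,
    cluster: ClusterCall,
    flank_n: int,
    ortho: OrthologMap,
    other_ann: GenomeAnnotation,
    other_genome_id: str | None = None,
) -> SyntenyReport:
    """Measure flank conservation, collinearity, the intervening gap, and
    the placement of cluster-gene orthologs in one comparator genome.

    The intervening gap is the intergenic distance between the orthologs of
    the innermost mapped 5' and 3' flank genes; it is undefined (flagged)
    when the two land on different scaffolds, which covers rearrangements.
    Order conservation is the longest collinear (same scaffold, increasing
    position) subsequence of mapped flank orthologs divided by the number
    found.
    """
    if flank_n < 1:
        raise ValueError("flank_n must be >= 1")
    up, _ = neighbor_window(focal_ann, cluster.gene_ids[0], flank_n)
    _, down = neighbor_window(focal_ann, cluster.gene_ids[-1], flank_n)
    flank5 = [g.gene_id for g in up]
    flank3 = [g.gene_id for g in down]

    def mapped(ids: list[str]) -> list[tuple[str, str]]:
        out = []
        for gid in ids:
            other = ortho.get(gid)
            if other is not None and other in other_ann:
                out.append((gid, other))
        return out

    m5, m3 = mapped(flank5), mapped(flank3)
    flank5_frac = len(m5) / len(flank5) if flank5 else 0.0
    flank3_frac = len(m3) / len(flank3) if flank3 else 0.0

    # collinearity of mapped flank orthologs, in focal order
    positions: list[tuple[str, int]] = []
    scaffold_index: dict[str, dict[str, int]] = {}
    for _, other in m5 + m3:
        g = other_ann.get(other)
        idx = scaffold_index.setdefault(
            g.scaffold,
            {x.gene_id: k for k, x in enumerate(other_ann.scaffold_genes(g.scaffold))},
        )
        positions.append((g.scaffold, idx[other]))
    n_found = len(positions)
    if n_found:
        best = 0
        for scaf in {s for s, _ in positions}:
            best = max(best, _lis_length([p for s, p in positions if s == scaf]))
        order_frac = best / n_found
    else:
        order_frac = 0.0

    gap_flags: list[str] = []
    gap: int | None = None
    if not m5 or not m3:
        gap_flags.append("flank_orthologs_missing")
    else:
        inner5 = other_ann.get(m5[-1][1])  # ortholog of flank gene nearest cluster
        inner3 = other_ann.get(m3[0][1])
        if inner5.scaffold != inner3.scaffold:
            gap_flags.append("flanks_on_different_scaffolds")
        else:
            a, b = sorted((inner5, inner3), key=lambda g: g.start)
            gap = intergenic_gap(a, b)

    # cluster ortholog placement
    total = inside = 0
    for gid in cluster.gene_ids:
        other = ortho.get(gid)
        if other is None or other not in other_ann:
            continue
        total += 1
        if gap is not None:
            g = other_ann.get(other)
            a, b = sorted(
                (other_ann.get(m5[-1][1]), other_ann.get(m3[0][1])),
                key=lambda x: x.start,
            )
            if g.scaffold == a.scaffold and a.end < g.start and g.end < b.start:
                inside += 1

    return SyntenyReport(
        genome_id=other_genome_id or other_ann.genome_id,
        flank5_conserved=flank5_frac,
        flank3_conserved=flank3_frac,
        order_conserved=order_frac,
        intervening_gap_bp=gap,
        gap_flags=gap_flags,
        cluster_orthologs_total=total,
        cluster_orthologs_inside_gap=inside,
        cluster_orthologs_dispersed=total - inside,
        cluster_size=len(cluster.gene_ids),
        flank_n=flank_n,
    )


def classify_origin(
    report: SyntenyReport, thresholds: OriginThresholds = OriginThresholds()
) -> str:
    """Rule cascade assigning an evolutionary-origin label to a comparator.

    Evaluated in order: conserved cluster, candidate horizontal transfer,
    lineage-specific locus, rearrangement, else unresolved. The fractions
    compare against the focal cluster size and per-side flank counts.
    """
    th = thresholds
    cluster_frac = (
        report.cluster_orthologs_total / report.cluster_size
        if report.cluster_size
        else 0.0
    )
    flank_min = min(report.flank5_conserved, report.flank3_conserved)
    gap = report.intervening_gap_bp

    if (
        cluster_frac >= th.cluster_frac_hi
        and report.cluster_orthologs_inside_gap >= report.cluster_size / 2
    ):
        label = "conserved_cluster"
    elif cluster_frac >= th.cluster_frac_hi and flank_min < th.flank_frac_lo:
        label = "candidate_transfer"
    elif (
        flank_min >= th.flank_frac_hi
        and cluster_frac <= th.cluster_frac_lo
        and gap is not None
        and gap <= th.gap_max_bp
    ):
        label = "lineage_specific"
    elif (
        flank_min >= th.flank_frac_hi
        and (gap is None or gap > th.gap_max_bp)
        and report.cluster_orthologs_inside_gap == 0
    ):
        label = "rearranged"
    else:
        label = "unresolved"
    report.origin_label = label
    return label


def homolog_cluster_scan(
    cluster_proteins: Mapping[str, ProteinRecord],
    genome_panel: Sequence[tuple[GenomeAnnotation, Mapping[str, ProteinRecord]]],
    window_genes: int = 20,
    min_fraction: float = 0.5,
    min_score: float = DEFAULT_MIN_SCORE,
    min_ratio: float = DEFAULT_MIN_RATIO,
    backbone_roles_required: Sequence[str] = ("backbone_nrps", "backbone_pks"),
    cluster_roles: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Scan a genome panel for co-located blocks of cluster-gene homologs.

    For each panel genome, every cluster protein's best local-alignment hit
    is kept when it clears the score and self-score-ratio thresholds. A
    sliding window of ``window_genes`` consecutive genes (per scaffold)
    then finds the maximal fraction of distinct cluster genes whose
    homologs co-locate. The genome is flagged ``detected`` only if that
    fraction reaches ``min_fraction`` and the window holds homologs of both
    backbone classes (NRPS and PKS), the signature of an intact cluster.
    """
    if window_genes < 2:
        raise ValueError("window_genes must be >= 2")
    rows = []
    for ann, proteome in genome_panel:
        homolog_of: dict[str, str] = {}  # panel gene -> cluster gene
        for cid, cp in cluster_proteins.items():
            best_t, best_s = None, -1.0
            for tid, tp in proteome.items():
                s = local_align_score(cp.sequence, tp.sequence)
                if s > best_s or (s == best_s and (best_t is None or tid < best_t)):
                    best_t, best_s = tid, s
            if best_t is None or best_s < min_score:
                continue
            self_s = local_align_score(cp.sequence, cp.sequence)
            if best_s < min_ratio * self_s:
                continue
            homolog_of[best_t] = cid
        n_cluster = len(cluster_proteins)
        frac_with_homologs = len(set(homolog_of.values())) / n_cluster
        max_frac = 0.0
        detected = False
        for scaffold in sorted({g.scaffold for g in ann.genes}):
            genes = ann.scaffold_genes(scaffold)
            for i in range(max(1, len(genes) - window_genes + 1)):
                window = genes[i : i + window_genes]
                hits = {homolog_of[g.gene_id] for g in window if g.gene_id in homolog_of}
                frac = len(hits) / n_cluster
                if frac > max_frac:
                    max_frac = frac
                if frac >= min_fraction and cluster_roles is not None:
                    roles_here = {cluster_roles.get(h) for h in hits}
                    if set(backbone_roles_required) <= roles_here:
                        detected = True
                elif frac >= min_fraction and cluster_roles is None:
                    detected = True
        rows.append(
            {
                "genome_id": ann.genome_id,
                "fraction_with_homologs": frac_with_homologs,
                "max_colocated_fraction": max_frac,
                "detected": detected,
            }
        )
    return pd.DataFrame(rows)


def write_synteny_reports(
    reports: Sequence[SyntenyReport], json_path: str | Path, tsv_path: str | Path
) -> None:
    with open(json_path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1, sort_keys=True)
    pd.DataFrame([r.to_dict() for r in reports]).to_csv(tsv_path, sep="\t", index=False)
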