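import numpy as np
import pytest

from bgckit.clusterpred import ClusterCall
from bgckit.genome_model import GeneModel, GenomeAnnotation, ProteinRecord
from bgckit.simulate import SimConfig, _random_protein, mutate_protein, simulate_scenario
from bgckit.synteny import (
    GAP_EXTEND,
    GAP_OPEN,
    MATCH,
    MISMATCH,
    OriginThresholds,
    SyntenyReport,
    classify_origin,
    flank_synteny_report,
    homolog_cluster_scan,
    local_align_score,
    rbh_map,
)


def sw_oracle(a: str, b: str) -> float:
    """Independent Gotoh local-alignment DP (gap of length L costs
    |open| + (L-1)*|extend|, matching the implementation's convention)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]  # best ending in match/mismatch or 0
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXTEND)
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return best


class TestLocalAlignScore:
    def test_identical_sequences(self):
        assert local_align_score("ACDEFGHIKL", "ACDEFGHIKL") == 20.0

    def test_disjoint_alphabets_floor_at_zero(self):
        assert local_align_score("AAAA", "WWWW") == 0.0

    def test_empty_sequence_scores_zero(self):
        assert local_align_score("", "ACD") == 0.0

    def test_single_gap_case_matches_oracle(self):
        assert local_align_score("ACDEFG", "ACDFG") == sw_oracle("ACDEFG", "ACDFG") == 7.0

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = _random_protein(rng, 5, 60)
            b = _random_protein(rng, 5, 60)
            assert local_align_score(a, b) == sw_oracle(a, b)
            assert local_align_score(a, b) == local_align_score(b, a)


def rbh_oracle(A, B, min_score, min_ratio, score_fn):
    """Brute-force reciprocal-best derivation from a full score matrix."""
    scores = {(a, b): score_fn(A[a].sequence, B[b].sequence) for a in A for b in B}
    pairs = []
    for a in A:
        by_score = sorted(B, key=lambda b: (-scores[(a, b)], b))
        if len(by_score) > 1 and scores[(a, by_score[0])] == scores[(a, by_score[1])]:
            continue
        b = by_score[0]
        back = sorted(A, key=lambda x: (-scores[(x, b)], x))
        if len(back) > 1 and scores[(back[0], b)] == scores[(back[1], b)]:
            continue
        if back[0] != a:
            continue
        s = scores[(a, b)]
        shorter = min(A[a].sequence, B[b].sequence, key=len)
        if s >= min_score and s >= min_ratio * score_fn(shorter, shorter):
            pairs.append((a, b, s))
    return sorted(pairs)


class TestRbhMap:
    def _proteomes(self, seed, n=20, divergence=0.1):
        rng = np.random.default_rng(seed)
        A = {f"a{i:02d}": ProteinRecord(f"a{i:02d}", _random_protein(rng, 60, 120))
             for i in range(n)}
        B = {f"b{i:02d}": ProteinRecord(f"b{i:02d}",
                                        mutate_protein(A[f"a{i:02d}"].sequence, divergence, rng))
             for i in range(n)}
        return A, B

    def test_identical_proteomes_identity_map(self):
        A, _ = self._proteomes(1)
        m = rbh_map(A, A)
        assert {(a, b) for a, b, _ in m.pairs} == {(a, a) for a in A}

    def test_empty_proteome_empty_map(self):
        A, _ = self._proteomes(2)
        assert len(rbh_map(A, {})) == 0

    def test_matches_brute_force_oracle(self):
        for seed in range(5):
            A, B = self._proteomes(seed, n=20)
            got = rbh_map(A, B, min_score=30, min_ratio=0.3)
            expected = rbh_oracle(A, B, 30, 0.3, local_align_score)
            assert sorted(got.pairs) == expected

    def test_pairs_are_unique_per_gene(self):
        A, B = self._proteomes(3, n=30)
        m = rbh_map(A, B)
        lefts = [a for a, _, _ in m.pairs]
        rights = [b for _, b, _ in m.pairs]
        assert len(set(lefts)) == len(lefts) and len(set(rights)) == len(rights)


def _truth_call(study):
    t = study.truth
    return ClusterCall(
        method="truth", scaffold="scaffold_1", gene_ids=t.cluster_gene_ids,
        start_bp=t.cluster_start_bp, end_bp=t.cluster_end_bp, backbone_id=t.backbone_id,
    )


class TestFlankSynteny:
    def test_self_comparison_is_fully_conserved(self, study):
        _, s = study
        call = _truth_call(s)
        ortho = rbh_map(s.focal_proteins, s.focal_proteins)
        rep = flank_synteny_report(s.focal, call, 10, ortho, s.focal)
        assert rep.flank5_conserved == rep.flank3_conserved == 1.0
        assert rep.order_conserved == 1.0
        assert rep.cluster_orthologs_inside_gap == len(call.gene_ids)

    def test_lineage_specific_gap_and_dispersal(self, study):
        cfg, s = study
        spec, cann, cprot = s.comparators[0]
        ortho = rbh_map(s.focal_proteins, cprot)
        rep = flank_synteny_report(s.focal, _truth_call(s), 10, ortho, cann)
        assert rep.intervening_gap_bp == cfg.intervening_gap_bp
        assert rep.cluster_orthologs_total == cfg.n_dispersed
        assert rep.cluster_orthologs_dispersed == cfg.n_dispersed
        assert rep.cluster_orthologs_inside_gap == 0

    def test_inversion_undefined_gap_and_broken_order(self, study):
        _, s = study
        spec, cann, cprot = s.comparators[2]
        assert spec.label == "inversion"
        ortho = rbh_map(s.focal_proteins, cprot)
        rep = flank_synteny_report(s.focal, _truth_call(s), 10, ortho, cann)
        assert rep.intervening_gap_bp is None
        assert "flanks_on_different_scaffolds" in rep.gap_flags
        assert rep.order_conserved < 1.0
        assert rep.flank5_conserved == rep.flank3_conserved == 1.0

    def test_inside_plus_dispersed_equals_total(self, study):
        _, s = study
        for _, cann, cprot in s.comparators:
            ortho = rbh_map(s.focal_proteins, cprot)
            rep = flank_synteny_report(s.focal, _truth_call(s), 10, ortho, cann)
            assert (
                rep.cluster_orthologs_inside_gap + rep.cluster_orthologs_dispersed
                == rep.cluster_orthologs_total
            )


class TestClassifyOrigin:
    def _report(self, **kw):
        base = dict(
            genome_id="x", flank5_conserved=1.0, flank3_conserved=1.0,
            order_conserved=1.0, intervening_gap_bp=3000, gap_flags=[],
            cluster_orthologs_total=1, cluster_orthologs_inside_gap=0,
            cluster_orthologs_dispersed=1, cluster_size=12, flank_n=10,
        )
        base.update(kw)
        return SyntenyReport(**base)

    def test_lineage_specific_rule(self):
        rep = self._report(cluster_orthologs_total=1, cluster_orthologs_dispersed=1)
        assert classify_origin(rep) == "lineage_specific"

    def test_gap_above_threshold_blocks_lineage_specific(self):
        rep = self._report(intervening_gap_bp=20_000, cluster_orthologs_total=0,
                           cluster_orthologs_dispersed=0)
        assert classify_origin(rep) == "rearranged"

    def test_conserved_cluster_rule(self):
        rep = self._report(cluster_orthologs_total=12, cluster_orthologs_inside_gap=12,
                           cluster_orthologs_dispersed=0)
        assert classify_origin(rep) == "conserved_cluster"

    def test_candidate_transfer_rule(self):
        rep = self._report(flank5_conserved=0.1, flank3_conserved=0.2,
                           intervening_gap_bp=None,
                           cluster_orthologs_total=12, cluster_orthologs_dispersed=12)
        assert classify_origin(rep) == "candidate_transfer"

    def test_unresolved_fallback(self):
        rep = self._report(flank5_conserved=0.6, flank3_conserved=0.6,
                           cluster_orthologs_total=6, cluster_orthologs_dispersed=6)
        assert classify_origin(rep) == "unresolved"

    def test_scenario_round_trip(self, study):
        _, s = study
        expected = {
            "lineage_specific": "lineage_specific",
            "conserved_cluster": "conserved_cluster",
            "inversion": "rearranged",
            "hgt_candidate": "candidate_transfer",
        }
        for spec, cann, cprot in s.comparators:
            ortho = rbh_map(s.focal_proteins, cprot)
            rep = flank_synteny_report(s.focal, _truth_call(s), 10, ortho, cann)
            assert classify_origin(rep) == expected[spec.label]


class TestHomologClusterScan:
    def test_focal_genome_detects_itself(self, study):
        _, s = study
        t = s.truth
        cluster_proteins = {g: s.focal_proteins[g] for g in t.cluster_gene_ids}
        df = homolog_cluster_scan(
            cluster_proteins, [(s.focal, s.focal_proteins)],
            window_genes=len(t.cluster_gene_ids) + 2,
            cluster_roles={g: t.gene_roles[g] for g in t.cluster_gene_ids},
        )
        row = df.iloc[0]
        assert row["max_colocated_fraction"] == 1.0
        assert bool(row["detected"])

    def test_dispersed_homologs_not_detected(self, study):
        cfg, s = study
        t = s.truth
        cluster_proteins = {g: s.focal_proteins[g] for g in t.cluster_gene_ids}
        spec, cann, cprot = s.comparators[0]  # lineage_specific
        df = homolog_cluster_scan(
            cluster_proteins, [(cann, cprot)], window_genes=14, min_fraction=0.5,
            cluster_roles={g: t.gene_roles[g] for g in t.cluster_gene_ids},
        )
        row = df.iloc[0]
        assert not bool(row["detected"])
        assert row["max_colocated_fraction"] < 0.5

    def test_window_arithmetic_single_scaffold_homologs(self):
        # homologs each on a different scaffold: co-located fraction 1/n
        rng = np.random.default_rng(9)
        cluster = {
            f"c{i}": ProteinRecord(f"c{i}", _random_protein(rng, 80, 120))
            for i in range(4)
        }
        genes, proteome = [], {}
        for i, (cid, rec) in enumerate(cluster.items()):
            gid = f"p{i}"
            genes.append(GeneModel(gid, f"sc{i}", 100, 1000, "+", "hypothetical"))
            proteome[gid] = ProteinRecord(gid, rec.sequence)
        panel = GenomeAnnotation(genome_id="panel", genes=genes)
        df = homolog_cluster_scan(cluster, [(panel, proteome)], window_genes=2,
                                  min_fraction=0.5)
        assert df.iloc[0]["max_colocated_fraction"] == 0.25
        assert not bool(df.iloc[0]["detected"])
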