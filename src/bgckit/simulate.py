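"""Synthetic study generator: focal genome with a planted biosynthetic
cluster, comparator genomes with controlled synteny scenarios, diverged
proteomes, and negative-binomial time-course counts.

The generator emulates a fungal secondary-metabolite locus: one backbone
nonribosomal peptide synthetase (NRPS) plus accessory genes (a polyketide
synthase, a D-alanine racemase, a cytochrome P450, an aminotransferase, a
dehydrogenase, transcription factors, and a highly constitutively expressed
cyclophilin-like gene), flanked on both sides by conserved housekeeping
genes. In the treatment condition the cluster switches on as a step at a
mid-series timepoint, with class-specific log2 fold changes: strongly
induced accessory genes (9), the backbone synthetase class (5), and the
cyclophilin-like gene (3.18), which is distinguished by a high constitutive
baseline.

Comparator genomes realise evolutionary scenarios: ``lineage_specific``
keeps the flanks syntenic with a small intervening gap and scatters a few
cluster-gene homologs elsewhere; ``conserved_cluster`` keeps the whole
locus; ``inversion`` moves the 3' flank to another scaffold in reversed
order; ``hgt_candidate`` keeps the cluster block intact but destroys flank
synteny.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_model import (
    CountsMatrix,
    GeneModel,
    GenomeAnnotation,
    ProteinRecord,
    SampleMeta,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

SCENARIO_LABELS = ("lineage_specific", "conserved_cluster", "inversion", "hgt_candidate")

# fixed sub-stream labels so adding an output never perturbs earlier ones
_STREAMS = {"layout": 11, "proteins": 12, "counts": 13, "comparator": 100}


def _default_baseline_means() -> dict[str, float]:
    # cluster genes sit near-silent in the control condition; the
    # cyclophilin-like gene and housekeeping background are well expressed
    return {"housekeeping": 50.0, "cyclophilin": 500.0, "default": 5.0}


def _default_induced_lfc() -> dict[str, float]:
    return {"accessory": 9.0, "backbone": 5.0, "cyclophilin": 3.18}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator."""

    seed: int = 0
    n_timepoints: int = 6
    n_replicates: int = 3
    baseline_means: dict[str, float] = field(default_factory=_default_baseline_means)
    dispersion: float = 0.1
    library_size_factors: Sequence[float] | None = None
    induced_lfc: dict[str, float] = field(default_factory=_default_induced_lfc)
    induction_start: int = 3
    cluster_size: int = 12
    flank_size: int = 10
    n_background: int = 150
    n_dispersed: int = 3
    intervening_gap_bp: int = 3000
    protein_divergence: float = 0.1
    protein_length: tuple[int, int] = (80, 160)
    n_constitutive_accessory: int = 0

    def validate(self) -> None:
        if self.n_timepoints < 2 or self.n_replicates < 2:
            raise ValueError("need >= 2 timepoints and >= 2 replicates")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 1 <= self.induction_start <= self.n_timepoints:
            raise ValueError("induction_start must lie in 1..n_timepoints")
        if self.cluster_size < 2:
            raise ValueError("cluster_size must be >= 2")
        if self.intervening_gap_bp < 0:
            raise ValueError("intervening_gap_bp must be >= 0")
        if any(v <= 0 for v in self.baseline_means.values()):
            raise ValueError("baseline means must be > 0")


@dataclass
class ScenarioSpec:
    """One comparator genome's evolutionary scenario."""

    label: str
    cluster_present: bool = False
    flanks_syntenic: bool = True
    inversion_applied: bool = False
    extra_insert_bp: int = 0

    @classmethod
    def from_label(cls, label: str) -> "ScenarioSpec":
        if label not in SCENARIO_LABELS:
            raise ValueError(f"unknown scenario label {label!r}")
        return cls(
            label=label,
            cluster_present=label in ("conserved_cluster", "hgt_candidate"),
            flanks_syntenic=label != "hgt_candidate",
            inversion_applied=label == "inversion",
        )


@dataclass
class Truth:
    """Planted ground truth for downstream validation."""

    cluster_gene_ids: list[str]
    backbone_id: str
    cluster_start_bp: int
    cluster_end_bp: int
    flank5_ids: list[str]
    flank3_ids: list[str]
    gene_roles: dict[str, str]
    gene_classes: dict[str, str]  # expression class per cluster gene
    comparators: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SimulatedStudy:
    focal: GenomeAnnotation
    focal_proteins: dict[str, ProteinRecord]
    comparators: list[tuple[ScenarioSpec, GenomeAnnotation, dict[str, ProteinRecord]]]
    truth: Truth


def _rng(cfg_seed: int, label: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, label])


def _random_protein(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(AA[i] for i in rng.integers(0, len(AA), size=n))


def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with the given probability.

    A substituted site always changes to a *different* residue, drawn
    uniformly from the other 19; length is preserved.
    """
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must lie in [0, 1]")
    out = list(seq)
    hits = rng.random(len(seq)) < divergence
    for i in np.flatnonzero(hits):
        choices = AA.replace(seq[i], "") if seq[i] in AA else AA
        out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def _cluster_roles_and_classes(n: int) -> tuple[list[str], list[str]]:
    """Role layout of the planted cluster: backbone NRPS first (it forms
    the 5' cluster boundary), then accessory members drawn from the
    field's vocabulary; exactly one PKS and one cyclophilin-like gene."""
    base = [
        ("backbone_nrps", "backbone"),
        ("tailoring", "accessory"),  # cytochrome P450
        ("backbone_pks", "backbone"),
        ("racemase", "accessory"),
        ("tailoring", "accessory"),  # dehydrogenase
        ("aminotransferase", "accessory"),
        ("regulator", "accessory"),  # bZIP transcription factor
        ("cyclophilin", "cyclophilin"),
        ("hypothetical", "accessory"),
        ("transport", "accessory"),
        ("regulator", "accessory"),
        ("hypothetical", "accessory"),
    ]
    while len(base) < n:
        base.append(("hypothetical", "accessory") if len(base) % 2 else ("tailoring", "accessory"))
    roles, classes = zip(*base[:n])
    return list(roles), list(classes)


def _place_genes(
    rng: np.random.Generator,
    specs: list[tuple[str, str, int]],  # (gene_id, role, length_bp)
    scaffold: str,
    gaps: list[int] | None = None,
    start: int = 1001,
) -> list[GeneModel]:
    """Lay genes on a scaffold left to right with given intergenic gaps."""
    genes = []
    pos = start
    for i, (gid, role, length) in enumerate(specs):
        if i > 0:
            gap = gaps[i - 1] if gaps else int(rng.integers(200, 2000))
            pos = genes[-1].end + gap + 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(gene_id=gid, scaffold=scaffold, start=pos, end=pos + length - 1,
                      strand=strand, role=role)
        )
    return genes


def simulate_scenario(
    cfg: SimConfig, scenarios: Sequence[ScenarioSpec | str]
) -> SimulatedStudy:
    """Build the focal genome and one comparator genome per scenario.

    Deterministic in ``cfg.seed``: the layout, proteins and each comparator
    draw from fixed sub-streams of the seed, so outputs are byte-identical
    across runs.
    """
    cfg.validate()
    scenarios = [
        ScenarioSpec.from_label(s) if isinstance(s, str) else s for s in scenarios
    ]
    if not scenarios:
        raise ValueError("at least one scenario is required")

    rng = _rng(cfg.seed, _STREAMS["layout"])
    roles, classes = _cluster_roles_and_classes(cfg.cluster_size)

    flank5 = [(f"FOC{i:05d}", "housekeeping", int(rng.integers(800, 3000)))
              for i in range(1, cfg.flank_size + 1)]
    cluster = []
    for j, (role, klass) in enumerate(zip(roles, classes)):
        length = 20000 if role == "backbone_nrps" else int(rng.integers(1000, 4000))
        cluster.append((f"FOC{cfg.flank_size + 1 + j:05d}", role, length))
    flank3 = [
        (f"FOC{cfg.flank_size + cfg.cluster_size + 1 + i:05d}", "housekeeping",
         int(rng.integers(800, 3000)))
        for i in range(cfg.flank_size)
    ]
    focal_genes = _place_genes(rng, flank5 + cluster + flank3, "scaffold_1")
    # housekeeping background on a second scaffold keeps median-of-ratios
    # normalization anchored on non-induced genes
    background = [
        (f"BKG{i:05d}", "housekeeping", int(rng.integers(800, 3000)))
        for i in range(1, cfg.n_background + 1)
    ]
    focal_genes += _place_genes(rng, background, "scaffold_2")
    focal = GenomeAnnotation(genome_id="focal", genes=focal_genes)

    prng = _rng(cfg.seed, _STREAMS["proteins"])
    proteins = {
        g.gene_id: ProteinRecord(g.gene_id, _random_protein(prng, *cfg.protein_length))
        for g in focal_genes
    }

    cluster_ids = [gid for gid, _, _ in cluster]
    gene_classes = dict(zip(cluster_ids, classes))
    if cfg.n_constitutive_accessory:
        acc = [g for g in cluster_ids if gene_classes[g] == "accessory"]
        for gid in acc[: cfg.n_constitutive_accessory]:
            gene_classes[gid] = "constitutive"
    truth = Truth(
        cluster_gene_ids=cluster_ids,
        backbone_id=cluster_ids[0],
        cluster_start_bp=focal.get(cluster_ids[0]).start,
        cluster_end_bp=focal.get(cluster_ids[-1]).end,
        flank5_ids=[gid for gid, _, _ in flank5],
        flank3_ids=[gid for gid, _, _ in flank3],
        gene_roles={g.gene_id: g.role for g in focal_genes},
        gene_classes=gene_classes,
    )

    comparators = []
    for c_idx, spec in enumerate(scenarios):
        crng = _rng(cfg.seed, _STREAMS["comparator"] + c_idx)
        cid = f"CMP{c_idx}"
        ortho_pairs: list[tuple[str, str]] = []
        specs_main: list[tuple[str, str, int]] = []
        gaps_main: list[int] = []

        def ortholog(gid: str) -> tuple[str, str, int]:
            g = focal.get(gid)
            new_id = f"{cid}_{gid}"
            ortho_pairs.append((gid, new_id))
            seq = mutate_protein(proteins[gid].sequence, cfg.protein_divergence, crng)
            comp_proteins[new_id] = ProteinRecord(new_id, seq)
            return (new_id, g.role, g.length_bp)

        comp_proteins: dict[str, ProteinRecord] = {}
        dispersed_ids: list[str] = []

        if spec.label == "lineage_specific":
            for gid, _, _ in flank5:
                specs_main.append(ortholog(gid))
                gaps_main.append(int(crng.integers(200, 2000)))
            gaps_main[-1] = cfg.intervening_gap_bp  # innermost flank-to-flank gap
            for gid, _, _ in flank3:
                specs_main.append(ortholog(gid))
                gaps_main.append(int(crng.integers(200, 2000)))
            gaps_main.pop()
            genes = _place_genes(crng, specs_main, f"{cid}_sc1", gaps_main)
            # a few cluster homologs scattered on another scaffold
            filler = [(f"{cid}_bg{i:03d}", "housekeeping", int(crng.integers(800, 3000)))
                      for i in range(12)]
            scattered = cluster_ids[1 : 1 + cfg.n_dispersed]
            sc2_specs: list[tuple[str, str, int]] = []
            for i, item in enumerate(filler):
                sc2_specs.append(item)
                if i % 4 == 3 and scattered:
                    sc2_specs.append(ortholog(scattered.pop(0)))
            while scattered:
                sc2_specs.append(ortholog(scattered.pop(0)))
            genes += _place_genes(crng, sc2_specs, f"{cid}_sc2")
            dispersed_ids = [b for a, b in ortho_pairs if a in cluster_ids]
            for gid, _, _ in [s for s in sc2_specs if s[0].startswith(f"{cid}_bg")]:
                comp_proteins[gid] = ProteinRecord(
                    gid, _random_protein(crng, *cfg.protein_length)
                )

        elif spec.label == "conserved_cluster":
            for gid, _, _ in flank5 + cluster + flank3:
                specs_main.append(ortholog(gid))
            genes = _place_genes(crng, specs_main, f"{cid}_sc1")

        elif spec.label == "inversion":
            for gid, _, _ in flank5:
                specs_main.append(ortholog(gid))
            genes = _place_genes(crng, specs_main, f"{cid}_sc1")
            inv_specs = [ortholog(gid) for gid, _, _ in reversed(flank3)]
            genes += _place_genes(crng, inv_specs, f"{cid}_sc2")

        elif spec.label == "hgt_candidate":
            # intact cluster block, flank synteny destroyed: only two flank
            # orthologs survive, scattered among background genes
            for gid, _, _ in cluster:
                specs_main.append(ortholog(gid))
            genes = _place_genes(crng, specs_main, f"{cid}_sc1")
            kept_flanks = [flank5[0][0], flank3[-1][0]]
            bg_specs: list[tuple[str, str, int]] = []
            for i in range(10):
                gid = f"{cid}_bg{i:03d}"
                bg_specs.append((gid, "housekeeping", int(crng.integers(800, 3000))))
                comp_proteins[gid] = ProteinRecord(
                    gid, _random_protein(crng, *cfg.protein_length)
                )
                if i in (3, 7) and kept_flanks:
                    bg_specs.append(ortholog(kept_flanks.pop(0)))
            genes += _place_genes(crng, bg_specs, f"{cid}_sc2")
        else:  # pragma: no cover
            raise ValueError(f"unknown scenario {spec.label!r}")

        comp = GenomeAnnotation(genome_id=cid, genes=genes)
        truth.comparators[cid] = {
            "label": spec.label,
            "ortholog_pairs": ortho_pairs,
            "planted_gap_bp": cfg.intervening_gap_bp
            if spec.label == "lineage_specific"
            else None,
            "dispersed_cluster_orthologs": dispersed_ids,
        }
        comparators.append((spec, comp, comp_proteins))

    return SimulatedStudy(
        focal=focal, focal_proteins=proteins, comparators=comparators, truth=truth
    )


def _mean_for(
    cfg: SimConfig, role: str, klass: str | None, condition: str, timepoint: int
) -> float:
    base = cfg.baseline_means
    if klass == "cyclophilin" or role == "cyclophilin":
        mu0 = base.get("cyclophilin", base["default"])
    elif klass == "constitutive":
        mu0 = base.get("cyclophilin", base["default"])
    elif role == "housekeeping":
        mu0 = base.get("housekeeping", base["default"])
    else:
        mu0 = base.get(role, base["default"])
    if klass is None or condition == "control" or timepoint < cfg.induction_start:
        return mu0
    lfc_key = {"backbone": "backbone", "cyclophilin": "cyclophilin"}.get(klass, "accessory")
    if klass == "constitutive":
        lfc = cfg.induced_lfc.get("constitutive", 2.0)
    else:
        lfc = cfg.induced_lfc[lfc_key]
    return mu0 * 2.0**lfc


def expected_mean(
    cfg: SimConfig, truth: Truth, gene_id: str, condition: str, timepoint: int
) -> float:
    """Model mean for one gene/condition/timepoint (before size factors)."""
    role = truth.gene_roles[gene_id]
    klass = truth.gene_classes.get(gene_id)
    return _mean_for(cfg, role, klass, condition, timepoint)


def simulate_counts(
    cfg: SimConfig, ann: GenomeAnnotation, truth: Truth
) -> tuple[CountsMatrix, list[SampleMeta]]:
    """Draw NB counts for the full two-condition time course.

    Counts are NB with mean ``s_j * mu_g(condition, timepoint)`` and
    quadratic variance ``mu + phi * mu**2``; cluster genes in treatment at
    or after the induction-start timepoint use ``mu0 * 2**lfc`` for their
    expression class, everything else its class baseline.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _STREAMS["counts"])
    samples = []
    for cond in ("control", "treatment"):
        for t in range(1, cfg.n_timepoints + 1):
            for r in range(1, cfg.n_replicates + 1):
                samples.append(
                    SampleMeta(f"{cond[:4]}_t{t}_r{r}", cond, t, r)
                )
    factors = (
        np.asarray(cfg.library_size_factors, dtype=float)
        if cfg.library_size_factors is not None
        else np.ones(len(samples))
    )
    if len(factors) != len(samples):
        raise ValueError("library_size_factors length must equal sample count")
    r_size = 1.0 / cfg.dispersion
    counts = np.empty((len(ann.genes), len(samples)), dtype=np.int64)
    for i, g in enumerate(ann.genes):
        for j, s in enumerate(samples):
            mu = factors[j] * expected_mean(cfg, truth, g.gene_id, s.condition, s.timepoint)
            counts[i, j] = rng.negative_binomial(r_size, r_size / (r_size + mu))
    cm = CountsMatrix(gene_ids=[g.gene_id for g in ann.genes], samples=samples, counts=counts)
    return cm, samples


# ---------------------------------------------------------------------------
# reference layout fixture


def demo_dataset(seed: int = 0) -> tuple[GenomeAnnotation, CountsMatrix, Truth, SimConfig]:
    """A 42-gene single-scaffold genome emulating a published cluster layout.

    Positions 1-8 and 31-42 are housekeeping background. Positions 9-14
    carry secondary-metabolite-like roles but are *not* induced (conserved
    genes that rule-based predictors sweep up). Positions 15-16 are
    housekeeping. The transcriptional cluster occupies positions 17-30:
    the backbone NRPS at 17 (the 5' boundary), accessory genes through 26,
    two induced hypothetical genes at 27-28, and two induced
    secondary-metabolite-role genes at 29-30 (the 3' boundary).

    Under the shipped presets this layout yields a tight 10-gene rule call
    (17-26), a permissive 22-gene call (9-30), and an expression call
    (17-30) sharing the tight call's 5' boundary and the permissive call's
    3' boundary.
    """
    rng = np.random.default_rng([seed, 77])
    layout = (
        [("housekeeping", None)] * 8
        + [("tailoring", None), ("transport", None), ("regulator", None),
           ("tailoring", None), ("aminotransferase", None), ("racemase", None)]
        + [("housekeeping", None)] * 2
        + [("backbone_nrps", "backbone"),
           ("tailoring", "accessory"), ("backbone_pks", "accessory"),
           ("racemase", "accessory"), ("tailoring", "accessory"),
           ("aminotransferase", "accessory"), ("cyclophilin", "cyclophilin"),
           ("transport", "accessory"), ("regulator", "accessory"),
           ("tailoring", "accessory")]
        + [("hypothetical", "accessory")] * 2
        + [("regulator", "accessory"), ("tailoring", "accessory")]
        + [("housekeeping", None)] * 12
    )
    specs = []
    for i, (role, _) in enumerate(layout, start=1):
        length = 20000 if role == "backbone_nrps" else int(rng.integers(1000, 4000))
        specs.append((f"DG{i:03d}", role, length))
    genes = _place_genes(rng, specs, "scaffold_1")
    background = [
        (f"DBK{i:03d}", "housekeeping", int(rng.integers(800, 3000)))
        for i in range(1, 151)
    ]
    genes += _place_genes(rng, background, "scaffold_2")
    ann = GenomeAnnotation(genome_id="demo", genes=genes)

    cluster_ids = [f"DG{i:03d}" for i in range(17, 31)]
    classes = {gid: layout[int(gid[2:]) - 1][1] for gid in cluster_ids}
    truth = Truth(
        cluster_gene_ids=cluster_ids,
        backbone_id="DG017",
        cluster_start_bp=ann.get("DG017").start,
        cluster_end_bp=ann.get("DG030").end,
        flank5_ids=[f"DG{i:03d}" for i in range(7, 17)],
        flank3_ids=[f"DG{i:03d}" for i in range(31, 41)],
        gene_roles={g.gene_id: g.role for g in genes},
        gene_classes=classes,
    )
    cfg = SimConfig(seed=seed, cluster_size=14)
    cm, _ = simulate_counts(cfg, ann, truth)
    return ann, cm, truth, cfg
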