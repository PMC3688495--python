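"""Domain types and I/O for gene annotations, proteomes and count matrices.

Coordinates follow the GFF3 convention throughout: 1-based, inclusive on
both ends, always on the forward axis. Strand never affects gene order or
intergenic distances; clusters are treated positionally because real
clusters mix genes from both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: Functional roles a gene can carry. "backbone" roles seed cluster
#: prediction; the rest describe accessory cluster members or background.
ROLES = frozenset(
    {
        "backbone_nrps",
        "backbone_pks",
        "tailoring",
        "regulator",
        "transport",
        "racemase",
        "aminotransferase",
        "cyclophilin",
        "hypothetical",
        "housekeeping",
    }
)

BACKBONE_ROLES = frozenset({"backbone_nrps", "backbone_pks"})

CONDITIONS = ("control", "treatment")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene interval on a scaffold, 1-based inclusive."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"
    role: str = "housekeeping"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise AnnotationError(f"{self.gene_id}: start must be >= 1")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if self.role not in ROLES:
            logger.warning(
                "gene %s: unknown role %r mapped to 'hypothetical'",
                self.gene_id,
                self.role,
            )
            object.__setattr__(self, "role", "hypothetical")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeAnnotation:
    """Ordered gene models, sorted by (scaffold, start); ids are unique."""

    genome_id: str
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.scaffold, g.start))
        self._by_id = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise AnnotationError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def scaffold_genes(self, scaffold: str) -> list[GeneModel]:
        return [g for g in self.genes if g.scaffold == scaffold]

    def index_on_scaffold(self, gene_id: str) -> int:
        """Position of the gene within its scaffold's sorted gene list."""
        g = self.get(gene_id)
        for i, other in enumerate(self.scaffold_genes(g.scaffold)):
            if other.gene_id == gene_id:
                return i
        raise AssertionError("unreachable")


@dataclass(frozen=True)
class ProteinRecord:
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty protein sequence")
        if not self.sequence.isupper():
            object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    condition: str
    timepoint: int
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"{self.sample_id}: condition must be one of {CONDITIONS}"
            )
        if self.timepoint < 1:
            raise ValueError(f"{self.sample_id}: timepoint must be >= 1")


@dataclass
class CountsMatrix:
    """Integer read counts, genes x samples, with per-sample metadata."""

    gene_ids: list[str]
    samples: list[SampleMeta]
    counts: "np.ndarray"

    def __post_init__(self) -> None:
        import numpy as np

        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        triples = [(s.condition, s.timepoint, s.replicate) for s in self.samples]
        if len(set(triples)) != len(triples):
            raise ValueError("(condition, timepoint, replicate) triples not unique")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# coordinate arithmetic


def intergenic_gap(a: GeneModel, b: GeneModel) -> int:
    """Intervening sequence length between two genes on one scaffold.

    Excludes both gene bodies, so adjacent genes have gap 0 and
    overlapping genes clamp to 0. Callers must pass genes with
    ``a.start <= b.start``.
    """
    if a.scaffold != b.scaffold:
        raise ValueError(
            f"gap undefined across scaffolds ({a.scaffold!r} vs {b.scaffold!r})"
        )
    if a.start > b.start:
        raise ValueError("genes must be given in positional order")
    return max(0, b.start - a.end - 1)


def neighbor_window(
    ann: GenomeAnnotation, gene_id: str, n: int
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Up to ``n`` genes on each side of a gene, same scaffold, in order.

    Truncated silently at scaffold ends.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    g = ann.get(gene_id)
    scaffold = ann.scaffold_genes(g.scaffold)
    i = next(j for j, other in enumerate(scaffold) if other.gene_id == gene_id)
    return scaffold[max(0, i - n) : i], scaffold[i + 1 : i + 1 + n]


# ---------------------------------------------------------------------------
# readers / writers


def parse_annotation(
    path: str | Path, genome_id: str | None = None, role_attr: str = "role"
) -> GenomeAnnotation:
    """Read gene features from a GFF3 file.

    Only ``gene`` features are kept. The functional role is taken from the
    ``role_attr`` attribute when present, defaulting to ``housekeeping``.
    """
    path = Path(path)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise AnnotationError(
                    f"{path.name}:{lineno}: malformed GFF3 line "
                    f"(expected 9 tab-separated fields, got {line.count(chr(9)) + 1})"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise AnnotationError(
                    f"{path.name}:{lineno}: malformed GFF3 line ({exc})"
                ) from exc
            if feat.featuretype != "gene":
                continue
            ids = feat.attributes.get("ID", [])
            if not ids:
                raise AnnotationError(f"{path.name}:{lineno}: gene without ID")
            role = feat.attributes.get(role_attr, ["housekeeping"])[0]
            genes.append(
                GeneModel(
                    gene_id=ids[0],
                    scaffold=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand if feat.strand in ("+", "-") else "+",
                    role=role,
                )
            )
    return GenomeAnnotation(genome_id=genome_id or path.stem, genes=genes)


def write_annotation(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write gene features as GFF3 (source column ``bgckit``)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            fh.write(
                f"{g.scaffold}\tbgckit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}"
                f"\t.\tID={g.gene_id};role={g.role}\n"
            )


def read_proteome(path: str | Path) -> dict[str, ProteinRecord]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = ProteinRecord(gene_id=rec.id, sequence=str(rec.seq))
    return records


def write_proteome(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(p.sequence), id=p.gene_id, description="") for p in proteins),
        str(path),
        "fasta",
    )


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "condition", "timepoint", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            condition=row.condition,
            timepoint=int(row.timepoint),
            replicate=int(row.replicate),
        )
        for row in df.itertuples()
    ]


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "condition": [s.condition for s in samples],
            "timepoint": [s.timepoint for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, meta: Sequence[SampleMeta]) -> CountsMatrix:
    """Read a genes x samples TSV whose header must match the metadata."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_ids = [s.sample_id for s in meta]
    if list(df.columns) != meta_ids:
        extra = set(df.columns) - set(meta_ids)
        missing = set(meta_ids) - set(df.columns)
        raise ValueError(
            f"counts header does not match sample metadata "
            f"(unknown: {sorted(extra)}, missing: {sorted(missing)})"
        )
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="raise")
        bad = (vals % 1 != 0) | (vals < 0)
        if bad.any():
            gene = vals.index[bad][0]
            raise ValueError(
                f"non-integer or negative count for gene {gene!r}, sample {col!r}"
            )
    return CountsMatrix(
        gene_ids=list(df.index),
        samples=list(meta),
        counts=df.to_numpy(dtype="int64"),
    )


def write_counts(cm: CountsMatrix, path: str | Path) -> None:
    cm.to_dataframe().rename_axis("gene_id").to_csv(path, sep="\t")
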