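"""Genome, annotation, metadata and plaque-count I/O.

This module fixes the conventions everything downstream relies on:

* coordinates are 0-based half-open on the forward strand internally;
  GenBank's 1-based inclusive coordinates exist only at the file boundary
  (Biopython performs the conversion);
* gene identifiers are ``"<genome_id>|<locus_tag-or-index>"`` and are unique
  cohort-wide;
* gene lists are always sorted by start coordinate, whatever the feature
  order in the input file;
* metadata always carries the keys ``starter``, ``factory`` and ``year``,
  with the string ``"unknown"`` standing in for missing values.

Genomes are treated as linear in the orientation deposited; any
re-orientation happens downstream in the core-scaffold step, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

UNKNOWN = "unknown"
METADATA_KEYS = ("starter", "factory", "year")


class GenomeIOError(ValueError):
    pass


@dataclass
class GeneRecord:
    """One annotated coding gene on a phage genome."""

    gene_id: str
    genome_id: str
    start: int          # 0-based, half-open on the forward strand
    end: int
    strand: str         # "+" or "-"
    protein_seq: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"{self.gene_id}: invalid coordinates [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PhageGenome:
    """An annotated phage genome with collection metadata.

    ``metadata`` always has the keys starter / factory / year; unknown values
    are the string ``"unknown"``.
    """

    genome_id: str
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        for g in self.genes:
            if g.end > len(self.sequence):
                raise GenomeIOError(
                    f"{g.gene_id}: end {g.end} beyond genome length {len(self.sequence)}"
                )
        coords = [(g.start, g.end) for g in self.genes]
        if len(set(coords)) != len(coords):
            raise GenomeIOError(f"{self.genome_id}: duplicate gene coordinates")
        for key in METADATA_KEYS:
            self.metadata.setdefault(key, UNKNOWN)

    @property
    def gc_content(self) -> float:
        s = self.sequence.upper()
        acgt = sum(s.count(b) for b in "ACGT")
        return (s.count("G") + s.count("C")) / acgt if acgt else 0.0

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class PlaqueCount:
    """One plate of a plaque-assay dilution series."""

    host_label: str
    phage_label: str
    dilution_exponent: int       # <= 0, e.g. -6 for the 10^-6 dilution
    plaques: int
    plated_volume_ml: float

    def __post_init__(self) -> None:
        if self.dilution_exponent > 0:
            raise GenomeIOError("dilution_exponent must be <= 0")
        if self.plaques < 0:
            raise GenomeIOError("plaques must be a non-negative count")
        if self.plated_volume_ml <= 0:
            raise GenomeIOError("plated_volume_ml must be positive")


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def read_genbank(path: str | Path) -> list[PhageGenome]:
    """Read annotated genomes from a GenBank flat file.

    Every CDS must carry a ``translation`` qualifier; compound (join)
    locations are rejected — the cohorts handled here have no spliced genes.
    Returns one :class:`PhageGenome` per record.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise GenomeIOError(f"no GenBank records in {path}")
    genomes = []
    for record in records:
        genome_id = record.name if record.name and record.name != "<unknown name>" else record.id
        genes = []
        idx = 0
        for feat in record.features:
            if feat.type != "CDS":
                continue
            idx += 1
            tag = feat.qualifiers.get("locus_tag", [f"g{idx:03d}"])[0]
            if isinstance(feat.location, CompoundLocation):
                raise GenomeIOError(
                    f"{genome_id}/{tag}: compound (join) CDS locations are not supported"
                )
            if "translation" not in feat.qualifiers:
                raise GenomeIOError(f"{genome_id}/{tag}: CDS without translation")
            strand = "+" if feat.location.strand != -1 else "-"
            genes.append(
                GeneRecord(
                    gene_id=f"{genome_id}|{tag}",
                    genome_id=genome_id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand=strand,
                    protein_seq=str(feat.qualifiers["translation"][0]),
                    product=feat.qualifiers.get("product", [""])[0],
                )
            )
        genomes.append(PhageGenome(genome_id=genome_id, sequence=str(record.seq), genes=genes))
    return genomes


def write_genbank(genomes: Iterable[PhageGenome], path: str | Path) -> None:
    """Write genomes to one GenBank flat file (inverse of :func:`read_genbank`)."""
    records = []
    for genome in genomes:
        record = SeqRecord(
            Seq(genome.sequence),
            id=genome.genome_id,
            name=genome.genome_id,
            description=f"synthetic phage genome {genome.genome_id}",
            annotations={"molecule_type": "DNA", "topology": "linear"},
        )
        for gene in genome.genes:
            loc = SimpleLocation(gene.start, gene.end, strand=1 if gene.strand == "+" else -1)
            feat = SeqFeature(
                loc,
                type="CDS",
                qualifiers={
                    "locus_tag": [gene.gene_id.split("|", 1)[1]],
                    "product": [gene.product],
                    "translation": [gene.protein_seq],
                    "codon_start": ["1"],
                    "transl_table": ["11"],
                },
            )
            record.features.append(feat)
        records.append(record)
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "genbank")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Tabular metadata
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> dict[str, dict]:
    """Read per-genome collection metadata (TSV: genome_id, starter, factory, year).

    Blank or missing cells normalise to ``"unknown"``; duplicate genome ids
    are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", *METADATA_KEYS}
    if not required.issubset(df.columns):
        raise GenomeIOError(f"metadata must have columns {sorted(required)}")
    dup = df["genome_id"][df["genome_id"].duplicated()].tolist()
    if dup:
        raise GenomeIOError(f"duplicate genome_id rows in metadata: {sorted(set(dup))}")
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        entry = {}
        for key in METADATA_KEYS:
            val = row[key]
            if pd.isna(val) or str(val).strip() == "":
                entry[key] = UNKNOWN
            elif key == "year":
                entry[key] = UNKNOWN if str(val).strip().lower() == UNKNOWN else int(float(val))
            else:
                entry[key] = str(val).strip()
        out[str(row["genome_id"])] = entry
    return out


def write_metadata(genomes: Iterable[PhageGenome], path: str | Path) -> None:
    rows = [
        {"genome_id": g.genome_id, **{k: g.metadata.get(k, UNKNOWN) for k in METADATA_KEYS}}
        for g in genomes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def attach_metadata(genomes: Iterable[PhageGenome], metadata: Mapping[str, dict]) -> None:
    """Attach metadata in place; genomes absent from the table get all-unknown."""
    for genome in genomes:
        entry = metadata.get(genome.genome_id, {})
        for key in METADATA_KEYS:
            genome.metadata[key] = entry.get(key, UNKNOWN)


def read_plaque_counts(path: str | Path) -> list[PlaqueCount]:
    """Read a plaque-count table (TSV: host_label, phage_label, dilution_exponent,
    plaques, plated_volume_ml)."""
    df = pd.read_csv(path, sep="\t")
    return [
        PlaqueCount(
            host_label=str(r.host_label),
            phage_label=str(r.phage_label),
            dilution_exponent=int(r.dilution_exponent),
            plaques=int(r.plaques),
            plated_volume_ml=float(r.plated_volume_ml),
        )
        for r in df.itertuples()
    ]


def cohort_proteins(genomes: Iterable[PhageGenome]) -> dict[str, str]:
    """gene_id -> protein sequence over a cohort (gene order by start within genome)."""
    out: dict[str, str] = {}
    for genome in genomes:
        for gene in genome.genes:
            if gene.gene_id in out:
                raise GenomeIOError(f"gene_id {gene.gene_id} not unique cohort-wide")
            out[gene.gene_id] = gene.protein_seq
    return out
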