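"""Synthetic phage cohorts with known ground truth.

The generator emulates a cohort of ~30 kb lytic dairy-phage genomes: a
conserved single-copy core scaffold in three functional modules
(morphogenesis / replication / regulation), lineages tied one-to-one to
starter cultures, lineage-specific accessory gene families, and HNH
endonuclease genes of three families planted at a small set of inter-core
loci with lineage-correlated divergence and occasional 5' truncation.  The
DNA-packaging-associated family (GVE2-like) sits between the terminase
large subunit and portal protein genes and is present in every genome, as
in real cohorts.

HEG ancestors derive from the packaged reference proteins so the
classifier's reference-scoring path is realistic; the catalytic triple is
protected from simulated substitution (purifying selection on the active
site), while :func:`mutate_protein` itself applies uniform independent
substitution.  Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._align import AMINO_ACIDS
from .classify import load_references
from .io import GeneRecord, PhageGenome, write_genbank, write_metadata

# rough natural amino-acid frequencies used for random proteins
_AA_FREQ = {
    "A": 8.3, "C": 1.4, "D": 5.4, "E": 6.8, "F": 3.9, "G": 7.1, "H": 2.3,
    "I": 6.0, "K": 5.8, "L": 9.7, "M": 2.4, "N": 4.1, "P": 4.7, "Q": 3.9,
    "R": 5.5, "S": 6.6, "T": 5.4, "V": 6.9, "W": 1.1, "Y": 2.9,
}
_AA = list(AMINO_ACIDS)
_AA_P = np.array([_AA_FREQ[a] for a in _AA])
_AA_P = _AA_P / _AA_P.sum()

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOP = "TAA"

MARKER_PRODUCTS = {
    "terminase large subunit": "morphogenesis",
    "portal protein": "morphogenesis",
    "DNA polymerase": "replication",
    "transcriptional regulator": "regulation",
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the real cohort's scale: ~50 genes per ~30 kb genome,
    a fully conserved single-copy core, three starter-culture lineages,
    eleven insertion loci with the DNA-packaging (GVE2-like) HEG in every
    genome, ~8% per-residue divergence applied at the lineage and then the
    genome level, and roughly a fifth of HEG copies truncated.
    """

    n_genomes: int = 89
    n_lineages: int = 3
    n_core: int = 40
    core_protein_length_range: tuple[int, int] = (120, 300)
    n_loci: int = 11
    locus_positions: list[int] | None = None      # inter-core gaps (after core rank g)
    family_of_locus: dict[int, str] | None = None  # locus index -> IHMU|PACI|GVE2
    heg_presence_prob: float = 0.5
    presence_of_locus: dict[int, float] = field(default_factory=dict)
    truncation_prob: float = 0.2
    mutation_rate: float = 0.08                    # per residue, lineage then genome
    accessory_gene_rate: float = 0.6               # per-genome inclusion prob per lineage family
    n_accessory_families: int = 10                 # lineage-specific accessory families
    orphan_gene_rate: float = 0.0                  # Poisson mean of genome-unique genes
    family_divergence: float = 0.25                # locus ancestor vs packaged reference
    core_deletion_prob: float = 0.0
    truncation_retention: tuple[float, float] = (0.20, 0.55)
    intergenic_range: tuple[int, int] = (15, 60)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci > max(0, self.n_core - 1):
            raise ValueError("n_loci must be <= n_core - 1 (loci exceed inter-core gaps)")
        for name in (
            "heg_presence_prob", "truncation_prob", "mutation_rate",
            "accessory_gene_rate", "family_divergence", "core_deletion_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.locus_positions is None:
            self.locus_positions = self._auto_positions()
        if len(self.locus_positions) != self.n_loci:
            raise ValueError("locus_positions length must equal n_loci")
        if len(set(self.locus_positions)) != self.n_loci:
            raise ValueError("locus_positions must be distinct gaps")
        for g in self.locus_positions:
            if not (0 <= g <= self.n_core - 2):
                raise ValueError(f"locus gap {g} outside [0, n_core-2]")
        if self.family_of_locus is None:
            self.family_of_locus = self._auto_families()
        for fam in self.family_of_locus.values():
            if fam not in ("IHMU", "PACI", "GVE2"):
                raise ValueError(f"unknown HEG family {fam}")

    def _auto_positions(self) -> list[int]:
        if self.n_loci == 0:
            return []
        positions: list[int] = [0]            # GVE2 between terL (rank 0) and portal (rank 1)
        if self.n_loci >= 2:
            positions.append(2)               # PacI-like locus in the morphogenesis module
        n_rest = self.n_loci - len(positions)
        if n_rest > 0:
            lo, hi = 4, self.n_core - 2
            rest = np.unique(np.linspace(lo, hi, n_rest).round().astype(int)).tolist()
            while len(rest) < n_rest:  # collisions on tiny scaffolds
                cand = max(rest) + 1 if rest else lo
                rest.append(cand)
            positions.extend(int(r) for r in rest[:n_rest])
        return positions

    def _auto_families(self) -> dict[int, str]:
        fams = {}
        for i in range(self.n_loci):
            fams[i] = "GVE2" if i == 0 else ("PACI" if i == 1 else "IHMU")
        return fams

    def presence(self, locus: int) -> float:
        if locus in self.presence_of_locus:
            return self.presence_of_locus[locus]
        return 1.0 if self.family_of_locus.get(locus) == "GVE2" else self.heg_presence_prob


@dataclass
class TruthTable:
    """Ground truth of one synthetic cohort, consistent gene-for-gene."""

    genomes: pd.DataFrame   # genome_id, lineage, starter, factory, year
    genes: pd.DataFrame     # gene_id, genome_id, category, core_rank, is_core,
                            # is_heg, heg_family, heg_locus, is_truncated
    loci: pd.DataFrame      # locus, gap, family, upstream_rank, downstream_rank
    modules: pd.DataFrame   # core_rank, product, module, is_marker

    def heg_members(self, locus: int) -> set[str]:
        sub = self.genes[(self.genes.is_heg) & (self.genes.heg_locus == locus)]
        return set(sub.gene_id)


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Uniform independent substitution: each residue replaced with
    probability ``rate`` by one of the other 19 amino acids."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [a for a in _AA if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _mutate_masked(seq: str, rate: float, rng: np.random.Generator, protected: set[int]) -> str:
    """Like mutate_protein but never touching ``protected`` 0-based positions
    (purifying selection on catalytic residues)."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        if int(i) in protected:
            continue
        choices = [a for a in _AA if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_P))


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS[a][rng.integers(len(_CODONS[a]))] for a in protein]
    return "".join(codons) + _STOP


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _core_products(n_core: int) -> list[str]:
    products = ["hypothetical protein"] * n_core
    products[0] = "terminase large subunit"
    if n_core > 1:
        products[1] = "portal protein"
    if n_core > 4:
        for i in range(2, max(3, n_core // 3)):
            if products[i] == "hypothetical protein":
                products[i] = "structural protein"
    mid = n_core // 2
    if mid > 1:
        products[mid] = "DNA polymerase"
    reg = 5 * n_core // 6
    if reg > mid:
        products[reg] = "transcriptional regulator"
    return products


def _module_truth(n_core: int, products: list[str]) -> pd.DataFrame:
    """Module labels implied by the marker-midpoint rule (the generator's
    definition of module truth)."""
    import math

    markers = [
        (i, MARKER_PRODUCTS[p]) for i, p in enumerate(products) if p in MARKER_PRODUCTS
    ]
    labels = ["unassigned"] * n_core
    for idx, (pos, module) in enumerate(markers):
        lo = 0 if idx == 0 else (
            markers[idx - 1][0] + 1
            if markers[idx - 1][1] == module
            else math.ceil((markers[idx - 1][0] + pos) / 2)
        )
        hi = n_core if idx == len(markers) - 1 else (
            markers[idx + 1][0]
            if markers[idx + 1][1] == module
            else math.ceil((pos + markers[idx + 1][0]) / 2)
        )
        for p in range(lo, hi):
            labels[p] = module
    return pd.DataFrame(
        {
            "core_rank": range(n_core),
            "product": products,
            "module": labels,
            "is_marker": [p in MARKER_PRODUCTS for p in products],
        }
    )


def simulate_phage_cohort(config: SyntheticConfig) -> tuple[list[PhageGenome], TruthTable]:
    """Draw one cohort and its truth table (fully reproducible from the seed)."""
    rng = np.random.default_rng(config.seed)
    refs = load_references()

    lo, hi = config.core_protein_length_range
    core_anc = [_random_protein(int(rng.integers(lo, hi + 1)), rng) for _ in range(config.n_core)]
    products = _core_products(config.n_core)
    modules = _module_truth(config.n_core, products)

    # locus ancestors: packaged reference mutated by family-level divergence,
    # catalytic triple protected
    locus_anc: list[str] = []
    protected: list[set[int]] = []
    for locus in range(config.n_loci):
        ref = refs[config.family_of_locus[locus]]
        keep = {p - 1 for p, _ in ref.catalytic_positions}
        locus_anc.append(_mutate_masked(ref.protein_seq, config.family_divergence, rng, keep))
        protected.append(keep)

    # lineage level: core + HEG ancestors mutated once per lineage; accessory
    # families are born at the lineage level
    lineage_core = []
    lineage_heg = []
    lineage_acc = []
    for _ in range(config.n_lineages):
        lineage_core.append([mutate_protein(p, config.mutation_rate, rng) for p in core_anc])
        lineage_heg.append(
            [
                _mutate_masked(locus_anc[k], config.mutation_rate, rng, protected[k])
                for k in range(config.n_loci)
            ]
        )
        fams = []
        for _ in range(config.n_accessory_families):
            length = int(rng.integers(80, 250))
            fams.append((_random_protein(length, rng), int(rng.integers(0, config.n_core - 1))))
        lineage_acc.append(fams)

    # genomes, lineages in contiguous blocks of near-equal size
    bounds = np.linspace(0, config.n_genomes, config.n_lineages + 1).round().astype(int)
    lineage_of = np.zeros(config.n_genomes, dtype=int)
    for l in range(config.n_lineages):
        lineage_of[bounds[l] : bounds[l + 1]] = l

    genomes: list[PhageGenome] = []
    gene_rows = []
    genome_rows = []
    for g in range(config.n_genomes):
        genome_id = f"P{g + 1:03d}"
        lineage = int(lineage_of[g])
        # plan the gene list: (protein, product, category, core_rank, heg_locus, truncated)
        plan: list[tuple] = []
        gap_contents: dict[int, list[tuple]] = {i: [] for i in range(config.n_core - 1)}
        for locus, gap in enumerate(config.locus_positions):
            if rng.random() < config.presence(locus):
                prot = _mutate_masked(
                    lineage_heg[lineage][locus], config.mutation_rate, rng, protected[locus]
                )
                truncated = rng.random() < config.truncation_prob
                if truncated:
                    r0, r1 = config.truncation_retention
                    keep = max(10, int(round(len(prot) * rng.uniform(r0, r1))))
                    prot = prot[:keep]
                product = "hypothetical protein" if truncated else "HNH endonuclease"
                gap_contents[gap].append((prot, product, "heg", -1, locus, truncated))
        for prot_anc, home_gap in lineage_acc[lineage]:
            if rng.random() < config.accessory_gene_rate:
                prot = mutate_protein(prot_anc, config.mutation_rate, rng)
                gap_contents[home_gap].append(
                    (prot, "hypothetical protein", "accessory", -1, -1, False)
                )
        if config.orphan_gene_rate > 0:
            for _ in range(rng.poisson(config.orphan_gene_rate)):
                prot = _random_protein(int(rng.integers(80, 250)), rng)
                gap = int(rng.integers(0, config.n_core - 1))
                gap_contents[gap].append(
                    (prot, "hypothetical protein", "orphan", -1, -1, False)
                )
        for rank in range(config.n_core):
            if rng.random() >= config.core_deletion_prob:
                prot = mutate_protein(lineage_core[lineage][rank], config.mutation_rate, rng)
                plan.append((prot, products[rank], "core", rank, -1, False))
            if rank < config.n_core - 1:
                contents = gap_contents[rank]
                order = rng.permutation(len(contents))
                plan.extend(contents[i] for i in order)

        # lay the plan onto a DNA sequence
        seq_parts: list[str] = []
        genes: list[GeneRecord] = []
        cursor = 0
        s_lo, s_hi = config.intergenic_range
        for idx, (prot, product, category, core_rank, heg_locus, truncated) in enumerate(plan):
            spacer = "".join(rng.choice(list("ACGT"), size=int(rng.integers(s_lo, s_hi + 1))))
            seq_parts.append(spacer)
            cursor += len(spacer)
            cds = _back_translate(prot, rng)
            if category in ("accessory", "orphan") and rng.random() < 0.5:
                strand = "-"
                seq_parts.append(cds.translate(_COMPLEMENT)[::-1])
            else:
                strand = "+"
                seq_parts.append(cds)
            gene_id = f"{genome_id}|g{idx + 1:03d}"
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome_id,
                    start=cursor,
                    end=cursor + len(cds),
                    strand=strand,
                    protein_seq=prot,
                    product=product,
                )
            )
            cursor += len(cds)
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "genome_id": genome_id,
                    "category": category,
                    "core_rank": core_rank,
                    "is_core": category == "core",
                    "is_heg": category == "heg",
                    "heg_family": config.family_of_locus[heg_locus] if heg_locus >= 0 else "",
                    "heg_locus": heg_locus,
                    "is_truncated": truncated,
                }
            )
        tail = "".join(rng.choice(list("ACGT"), size=int(rng.integers(s_lo, s_hi + 1))))
        seq_parts.append(tail)
        metadata = {
            "starter": f"SM{lineage + 1}",
            "factory": f"F{int(rng.integers(1, 5))}",
            "year": int(rng.integers(2019, 2026)),
        }
        genomes.append(
            PhageGenome(
                genome_id=genome_id,
                sequence="".join(seq_parts),
                genes=genes,
                metadata=metadata,
            )
        )
        genome_rows.append({"genome_id": genome_id, "lineage": lineage, **metadata})

    loci_rows = [
        {
            "locus": k,
            "gap": gap,
            "family": config.family_of_locus[k],
            "upstream_rank": gap,
            "downstream_rank": gap + 1,
        }
        for k, gap in enumerate(config.locus_positions)
    ]
    truth = TruthTable(
        genomes=pd.DataFrame(genome_rows),
        genes=pd.DataFrame(
            gene_rows,
            columns=[
                "gene_id", "genome_id", "category", "core_rank", "is_core",
                "is_heg", "heg_family", "heg_locus", "is_truncated",
            ],
        ),
        loci=pd.DataFrame(
            loci_rows,
            columns=["locus", "gap", "family", "upstream_rank", "downstream_rank"],
        ),
        modules=modules,
    )
    return genomes, truth


def write_cohort(
    genomes: list[PhageGenome], truth: TruthTable, outdir: str | Path
) -> None:
    """Emit the cohort as GenBank + metadata + truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genbank(genomes, outdir / "cohort.gbk")
    write_metadata(genomes, outdir / "metadata.tsv")
    truth.genomes.to_csv(outdir / "truth_genomes.tsv", sep="\t", index=False)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth.loci.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    truth.modules.to_csv(outdir / "truth_modules.tsv", sep="\t", index=False)
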