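"""HNH endonuclease detection and family classification.

Each candidate gene is aligned to three packaged reference HNHEs
(I-HmuI-like, PacI-like, GVE2-like; the shipped sequences are synthetic
stand-ins carrying the documented catalytic geometry — D74/H75/N96 on the
I-HmuI-like reference) and assigned to the best-scoring family when the
alignment covers enough of the reference and the protein carries the
H-x(~20)-N-x(~20)-(H/N) active-site motif.  Genes with clear reference
similarity but low reference coverage or no motif are called TRUNCATED
(remnants of formerly complete HNHE genes); genes below the score floor are
UNCLASSIFIED.

Profile-profile search (HHPred and kin) is deliberately not used:
classification relies on deterministic pairwise scoring against the packaged
references, trading remote-homology sensitivity for a self-contained,
reproducible decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._align import local_align, validate_protein
from .io import GeneRecord, PhageGenome

FAMILIES = ("IHMU", "PACI", "GVE2")
TRUNCATED = "TRUNCATED"
UNCLASSIFIED = "UNCLASSIFIED"

#: inclusive bounds on the offset between consecutive catalytic residues
#: (H -> N and N -> H/N); brackets the I-HmuI H75->N96 spacing of 21
MOTIF_SPACING = (10, 35)

#: default floor on the local alignment score against the best reference;
#: below it a gene is not considered an HNHE at all
DEFAULT_FLOOR_SCORE = 75.0

#: default minimum reference coverage for an intact (non-truncated) call
DEFAULT_MIN_COVERAGE_INTACT = 0.6


@dataclass(frozen=True)
class ReferenceHnhe:
    family: str
    protein_seq: str
    catalytic_positions: tuple[tuple[int, str], ...]  # 1-based (position, residue)


@dataclass(frozen=True)
class MotifHit:
    """One H-x-N-x-(H/N) active-site window on a query protein."""

    gene_id: str
    motif_span: tuple[int, int]        # 0-based half-open on the protein
    matched_pattern: str               # e.g. "H-x(20)-N-x(20)-H"
    catalytic_map: dict                # reference 1-based pos -> query 1-based pos | "absent"
    score: float


@dataclass(frozen=True)
class HnheAssignment:
    gene_id: str
    family: str                        # IHMU | PACI | GVE2 | TRUNCATED | UNCLASSIFIED
    best_reference: str | None
    reference_coverage: float
    pct_identity: float
    motif: MotifHit | None
    score: float


def load_references() -> dict[str, ReferenceHnhe]:
    """The packaged reference HNHEs (synthetic stand-in sequences)."""
    pkg = resources.files("heg_atlas") / "data"
    seqs: dict[str, str] = {}
    name = None
    for line in (pkg / "synthetic_reference_hnhe.faa").read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line.strip()
    cat = pd.read_csv(pkg / "synthetic_reference_hnhe_catalytic.tsv", sep="\t")
    refs = {}
    for family, seq in seqs.items():
        rows = cat[cat["family"] == family].sort_values("position")
        positions = tuple((int(r.position), str(r.residue)) for r in rows.itertuples())
        refs[family] = ReferenceHnhe(family=family, protein_seq=seq, catalytic_positions=positions)
    return refs


def _catalytic_region(reference: ReferenceHnhe, pad: int = 5) -> tuple[int, str]:
    """(0-based region start, region sequence) around the catalytic residues."""
    pos = [p for p, _ in reference.catalytic_positions]
    lo = max(0, min(pos) - 1 - pad)
    hi = min(len(reference.protein_seq), max(pos) - 1 + pad + 1)
    return lo, reference.protein_seq[lo:hi]


def scan_hnh_motif(
    protein_seq: str,
    gene_id: str = "<query>",
    reference: ReferenceHnhe | None = None,
) -> MotifHit | None:
    """Locate the highest-scoring H-x-N-x-(H/N) active-site window.

    Candidate windows are triples (H, N, H|N) with both inter-residue
    offsets inside :data:`MOTIF_SPACING`; each window is scored by local
    alignment to the I-HmuI-like reference's catalytic region, and the best
    is returned.  ``None`` means no spacing-valid window exists — absence is
    a value, not an error.
    """
    validate_protein(protein_seq, gene_id)
    if reference is None:
        reference = load_references()["IHMU"]
    region_start, region = _catalytic_region(reference)
    lo, hi = MOTIF_SPACING
    h_pos = [i for i, a in enumerate(protein_seq) if a == "H"]
    n_pos = [j for j, a in enumerate(protein_seq) if a == "N"]
    hn_pos = sorted(set(h_pos) | set(n_pos))

    def window_score(i: int, k: int) -> float:
        window = protein_seq[max(0, i - 5) : min(len(protein_seq), k + 6)]
        return local_align(window, region).score

    best: tuple[float, int, int, int] | None = None
    for i in h_pos:
        for j in n_pos:
            if not (lo <= j - i <= hi):
                continue
            for k in hn_pos:
                if not (lo <= k - j <= hi):
                    continue
                score = window_score(i, k)
                cand = (score, -i, -j, -k)
                if best is None or cand > (best[0], -best[1], -best[2], -best[3]):
                    best = (score, i, j, k)
    if best is None:
        return None
    catalytic_map = _map_catalytic_positions(protein_seq, reference, region_start, region)
    # when the catalytic-region alignment itself lands on a spacing-valid
    # triple, trust it over raw window scores (which tie across windows that
    # merely contain the aligned region)
    triple = _mapped_triple(protein_seq, reference, catalytic_map, lo, hi)
    if triple is not None:
        i, j, k = triple
        score = window_score(i, k)
    else:
        score, i, j, k = best
    return MotifHit(
        gene_id=gene_id,
        motif_span=(i, k + 1),
        matched_pattern=f"H-x({j - i - 1})-N-x({k - j - 1})-{protein_seq[k]}",
        catalytic_map=catalytic_map,
        score=score,
    )


def _mapped_triple(
    protein_seq: str,
    reference: ReferenceHnhe,
    catalytic_map: dict,
    lo: int,
    hi: int,
) -> tuple[int, int, int] | None:
    """The (H, N, H|N) triple implied by the catalytic-region alignment, if
    the mapped positions carry the right residues at valid spacing."""
    motif_refpos = [p for p, r in reference.catalytic_positions if r in "HN"]
    if len(motif_refpos) < 3:
        return None
    mapped = [catalytic_map.get(p) for p in motif_refpos[:3]]
    if any(not isinstance(m, int) for m in mapped):
        return None
    i, j, k = (m - 1 for m in mapped)  # back to 0-based
    n = len(protein_seq)
    if not (0 <= i < j < k < n):
        return None
    if protein_seq[i] != "H" or protein_seq[j] != "N" or protein_seq[k] not in "HN":
        return None
    if not (lo <= j - i <= hi and lo <= k - j <= hi):
        return None
    return i, j, k


def _map_catalytic_positions(
    protein_seq: str, reference: ReferenceHnhe, region_start: int, region: str
) -> dict:
    """Map the reference's annotated catalytic positions onto the query via a
    local alignment of the query to the catalytic region (both 1-based)."""
    from ._align import _aligner

    best = _aligner("local").align(protein_seq, region)[0]
    seg_q, seg_r = best.aligned
    out: dict = {}
    for pos, _residue in reference.catalytic_positions:
        local = pos - 1 - region_start  # 0-based offset within the region
        query_pos = "absent"
        for (sq, eq), (sr, er) in zip(seg_q, seg_r):
            if sr <= local < er:
                query_pos = int(sq + (local - sr) + 1)  # 1-based on the query
                break
        out[pos] = query_pos
    return out


def classify_hnhe(
    gene: GeneRecord | tuple[str, str],
    references: Mapping[str, ReferenceHnhe],
    min_coverage_intact: float = DEFAULT_MIN_COVERAGE_INTACT,
    floor_score: float = DEFAULT_FLOOR_SCORE,
) -> HnheAssignment:
    """Assign one gene to an HNHE family (or TRUNCATED / UNCLASSIFIED).

    The query is locally aligned to every reference; the best-scoring family
    wins when its alignment covers ``min_coverage_intact`` of the reference
    and the query carries the active-site motif.  Reference similarity with
    insufficient coverage or a missing motif means TRUNCATED; nothing above
    ``floor_score`` means UNCLASSIFIED.
    """
    if not references:
        raise ValueError("empty reference set")
    missing = set(FAMILIES) - set(references)
    if missing:
        raise ValueError(f"references missing families: {sorted(missing)}")
    if isinstance(gene, GeneRecord):
        gene_id, seq = gene.gene_id, gene.protein_seq
    else:
        gene_id, seq = gene
    validate_protein(seq, gene_id)
    best_family, best_res = None, None
    for family in FAMILIES:
        res = local_align(seq, references[family].protein_seq)
        if best_res is None or res.score > best_res.score:
            best_family, best_res = family, res
    assert best_res is not None
    if best_res.score < floor_score:
        return HnheAssignment(gene_id, UNCLASSIFIED, None, 0.0, 0.0, None, best_res.score)
    coverage = best_res.cov_b  # fraction of the reference covered
    motif = scan_hnh_motif(seq, gene_id, references["IHMU"])
    if coverage >= min_coverage_intact and motif is not None:
        family = best_family
    else:
        family = TRUNCATED
    return HnheAssignment(
        gene_id=gene_id,
        family=family,
        best_reference=best_family,
        reference_coverage=coverage,
        pct_identity=best_res.pct_identity,
        motif=motif,
        score=best_res.score,
    )


def classify_cohort(
    genomes: Sequence[PhageGenome],
    references: Mapping[str, ReferenceHnhe] | None = None,
    min_coverage_intact: float = DEFAULT_MIN_COVERAGE_INTACT,
    floor_score: float = DEFAULT_FLOOR_SCORE,
) -> list[HnheAssignment]:
    """Detect and classify HNHE candidates across a cohort.

    A gene is a candidate when its annotation mentions HNH *or* it clears the
    reference score floor — an annotation-independent recall path mirroring a
    BLASTP sweep.  Only candidates receive assignments.
    """
    refs = references or load_references()
    out: list[HnheAssignment] = []
    for genome in genomes:
        for gene in genome.genes:
            annotated = "hnh" in gene.product.lower()
            assignment = classify_hnhe(gene, refs, min_coverage_intact, floor_score)
            if annotated and assignment.family == UNCLASSIFIED:
                # annotation says HNHE but nothing scored: keep as unclassified hit
                out.append(assignment)
            elif assignment.family != UNCLASSIFIED:
                out.append(assignment)
    return out


def assignments_frame(assignments: Iterable[HnheAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append(
            {
                "gene_id": a.gene_id,
                "family": a.family,
                "best_reference": a.best_reference or "",
                "reference_coverage": round(a.reference_coverage, 4),
                "pct_identity": round(a.pct_identity, 2),
                "motif_span": f"{a.motif.motif_span[0]}-{a.motif.motif_span[1]}" if a.motif else "",
                "score": a.score,
            }
        )
    return pd.DataFrame(rows)
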