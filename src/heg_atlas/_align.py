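"""Shared pairwise-alignment primitives.

Every similarity, classification and distance computation in the package goes
through the two helpers here so that scoring conventions are defined exactly
once: BLOSUM62, affine gap penalty of ``11 + k`` for a gap of length ``k``
(open ``-12``, extend ``-1``), local (Smith-Waterman) or global
(Needleman-Wunsch) mode via :class:`Bio.Align.PairwiseAligner`.

Identity is counted over all alignment columns of the (local) aligned region,
gap columns included in the denominator; coverage of a sequence is the aligned
span divided by its full length.  The gap-excluded p-distance used by the
phylogeny module counts mismatches only over columns where both sequences
have a residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

GAP_OPEN = -12.0
GAP_EXTEND = -1.0


class InvalidSequenceError(ValueError):
    """A protein sequence contains a symbol outside the 20 canonical residues."""


def validate_protein(seq: str, name: str = "<sequence>") -> str:
    if not seq:
        raise InvalidSequenceError(f"empty protein sequence for {name}")
    bad = set(seq) - _AA_SET
    if bad:
        raise InvalidSequenceError(
            f"non-amino-acid symbols {sorted(bad)} in sequence of {name}"
        )
    return seq


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@dataclass(frozen=True)
class PairwiseResult:
    """Summary of one optimal pairwise alignment of sequences a and b."""

    score: float
    matches: int
    columns: int            # alignment columns, gap columns included
    a_span: tuple[int, int]  # 0-based half-open aligned span on a
    b_span: tuple[int, int]
    a_len: int
    b_len: int

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0

    @property
    def cov_a(self) -> float:
        return (self.a_span[1] - self.a_span[0]) / self.a_len

    @property
    def cov_b(self) -> float:
        return (self.b_span[1] - self.b_span[0]) / self.b_len


def _summarize(a: str, b: str, alignment, score: float) -> PairwiseResult:
    seg_a, seg_b = alignment.aligned
    if len(seg_a) == 0:  # empty local alignment (all-negative scores)
        return PairwiseResult(score, 0, 0, (0, 0), (0, 0), len(a), len(b))
    matches = 0
    columns = 0
    for (sa, ea), (sb, eb) in zip(seg_a, seg_b):
        columns += ea - sa
        matches += sum(1 for x, y in zip(a[sa:ea], b[sb:eb]) if x == y)
    for i in range(1, len(seg_a)):
        columns += int(seg_a[i][0] - seg_a[i - 1][1])
        columns += int(seg_b[i][0] - seg_b[i - 1][1])
    a_span = (int(seg_a[0][0]), int(seg_a[-1][1]))
    b_span = (int(seg_b[0][0]), int(seg_b[-1][1]))
    return PairwiseResult(score, matches, columns, a_span, b_span, len(a), len(b))


def local_align(a: str, b: str) -> PairwiseResult:
    """Best local alignment of a vs b under the package-wide scoring scheme."""
    aligner = _aligner("local")
    alignments = aligner.align(a, b)
    best = alignments[0]
    return _summarize(a, b, best, float(best.score))


def global_align(a: str, b: str) -> PairwiseResult:
    """Best global alignment of a vs b (end gaps penalized)."""
    aligner = _aligner("global")
    alignments = aligner.align(a, b)
    best = alignments[0]
    return _summarize(a, b, best, float(best.score))


def global_p_distance(a: str, b: str) -> float:
    """Gap-excluded p-distance from one optimal global alignment.

    Columns where either sequence is gapped are dropped; the distance is the
    mismatch fraction over the remaining (residue-residue) columns.
    """
    aligner = _aligner("global")
    best = aligner.align(a, b)[0]
    seg_a, seg_b = best.aligned
    matches = 0
    paired = 0
    for (sa, ea), (sb, eb) in zip(seg_a, seg_b):
        paired += ea - sa
        matches += sum(1 for x, y in zip(a[sa:ea], b[sb:eb]) if x == y)
    if paired == 0:
        return 1.0
    return 1.0 - matches / paired


def shared_kmers(a: str, b: str, k: int = 4) -> int:
    """Number of distinct k-mers shared by two sequences (prescreen heuristic)."""
    if len(a) < k or len(b) < k:
        return 0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb)
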