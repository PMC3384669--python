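"""Semi-global pairwise alignment, percent identity, coverage and distances.

All three identification methods consume the same alignment quantities:

* ``identity_pct`` — 100 x matches / aligned columns, where columns under
  a terminal gap in either sequence are excluded and internal gap columns
  count as mismatches (the conservative, BLAST-like convention);
* ``coverage`` — the aligned (non-terminal-gap) span of the shorter
  sequence divided by its length, so a short amplicon fully contained in
  a longer reference scores 1.0.

Terminal gaps are free because trimmed amplicons of the same locus
routinely differ in length; penalizing overhangs would conflate length
differences with sequence divergence.  Dynamic programming is delegated
to :class:`Bio.Align.PairwiseAligner`; traceback ties are resolved by its
deterministic first-alignment order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .model import MarkerSequence


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme for semi-global nucleotide alignment.

    ``gap_open`` is the score of the first residue of a gap and
    ``gap_extend`` of each subsequent residue, so a length-k internal gap
    scores ``gap_open + (k - 1) * gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    terminal_gaps_free: bool = True

    def __post_init__(self):
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")


@dataclass(frozen=True)
class AlignmentResult:
    identity_pct: float
    coverage: float
    score: float
    aligned_pair: tuple[str, str]


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if params.terminal_gaps_free:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    return aligner


def _identity_cov_from_blocks(a: str, b: str, blocks) -> tuple[float, float]:
    """Identity% and coverage from Biopython aligned-block coordinates."""
    ablocks, bblocks = blocks
    if len(ablocks) == 0:
        return 0.0, 0.0
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    matches = 0
    columns = 0
    prev = None
    for (as_, ae), (bs, be) in zip(ablocks, bblocks):
        matches += int(np.count_nonzero(arr_a[as_:ae] == arr_b[bs:be]))
        columns += ae - as_
        if prev is not None:
            pae, pbe = prev
            columns += (as_ - pae) + (bs - pbe)  # internal gap columns
        prev = (ae, be)
    a_span = int(ablocks[-1][1] - ablocks[0][0])
    b_span = int(bblocks[-1][1] - bblocks[0][0])
    identity = 100.0 * matches / columns if columns else 0.0
    if len(a) < len(b):
        coverage = a_span / len(a)
    elif len(b) < len(a):
        coverage = b_span / len(b)
    else:
        coverage = min(a_span, b_span) / len(a)
    return identity, coverage


class PairwiseScorer:
    """Cached semi-global aligner over raw nucleotide strings.

    Results are cached per unordered sequence pair; inputs are aligned in
    lexicographic order so identity and coverage are symmetric by
    construction.
    """

    def __init__(self, params: AlignParams | None = None):
        self.params = params or AlignParams()
        self._aligner = _make_aligner(self.params)
        self._cache: dict[tuple[str, str], tuple[float, float, float]] = {}

    def identity_coverage(self, a: str, b: str) -> tuple[float, float, float]:
        """Return ``(identity_pct, coverage, score)`` for a pair of sequences."""
        if not a or not b:
            raise ValueError("cannot align an empty sequence")
        key = (a, b) if a <= b else (b, a)
        hit = self._cache.get(key)
        if hit is None:
            aln = self._aligner.align(key[0], key[1])
            best = aln[0]
            identity, coverage = _identity_cov_from_blocks(
                key[0], key[1], best.aligned
            )
            hit = (identity, coverage, float(aln.score))
            self._cache[key] = hit
        return hit


def align_global(a: str, b: str, params: AlignParams | None = None) -> AlignmentResult:
    """Optimal semi-global alignment of two nucleotide sequences."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    params = params or AlignParams()
    aligner = _make_aligner(params)
    alignments = aligner.align(a, b)
    best = alignments[0]
    identity, coverage = _identity_cov_from_blocks(a, b, best.aligned)
    return AlignmentResult(
        identity_pct=identity,
        coverage=coverage,
        score=float(alignments.score),
        aligned_pair=(best[0], best[1]),
    )


def p_distance(result: AlignmentResult | float) -> float:
    """Uncorrected distance 1 - identity/100 from an alignment result."""
    identity = result if isinstance(result, (int, float)) else result.identity_pct
    return 1.0 - identity / 100.0


def distance_matrix(
    seqs: list[MarkerSequence],
    params: AlignParams | None = None,
    scorer: PairwiseScorer | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Symmetric p-distance matrix over one marker's sequences.

    Each unordered pair is aligned once, so the matrix is exactly
    symmetric with a zero diagonal.  Returns the matrix and the seq_id
    label order.
    """
    if len(seqs) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    markers = {s.marker for s in seqs}
    if len(markers) != 1:
        raise ValueError(f"mixed markers in distance matrix: {sorted(markers)}")
    ids = [s.seq_id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate seq_ids in distance matrix input")
    scorer = scorer or PairwiseScorer(params)
    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            identity, _, _ = scorer.identity_coverage(
                seqs[i].sequence, seqs[j].sequence
            )
            mat[i, j] = mat[j, i] = p_distance(identity)
    return mat, ids


def write_phylip(path, matrix: np.ndarray, labels: list[str]) -> None:
    """Write a square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for lab, row in zip(labels, matrix):
            fh.write(lab + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
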