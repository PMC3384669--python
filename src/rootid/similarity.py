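"""Similarity (top-hit) identification with distribution filtering.

Codifies the manual BLAST workflow of regional barcoding studies as a
deterministic rule: rank reference hits by percent identity (coverage
threshold applied first), keep the taxa tied with the best hit within a
small identity margin, optionally discard taxa that do not occur in the
study region, and resolve to the most specific rank on which the
remaining taxa agree.

E-values are deliberately not emulated: they depend on database size,
whereas the decisive quantities in the manual workflow are maximum
identity, the set of near-tied species, and distribution.  The default
identity thresholds (99% for species, 95% for genus) are configuration,
not measurements; they separate the intra- and interspecific divergence
scales of the synthetic scenarios and should be re-tuned per study.
"""

from __future__ import annotations

from dataclasses import dataclass

from sklearn.base import BaseEstimator

from .align import AlignParams, PairwiseScorer
from .model import (
    Identification,
    MarkerSequence,
    Taxonomy,
    unidentified,
)


@dataclass(frozen=True)
class SimilarityParams:
    min_identity_species: float = 99.0
    min_identity_genus: float = 95.0
    min_coverage: float = 0.9
    tie_margin: float = 0.5
    apply_region_filter: bool = True

    def __post_init__(self):
        if self.min_identity_species < self.min_identity_genus:
            raise ValueError("species threshold must be >= genus threshold")
        if self.tie_margin < 0:
            raise ValueError("tie_margin must be >= 0")


@dataclass(frozen=True)
class Hit:
    ref_id: str
    species: str
    identity: float
    coverage: float


def rank_hits(
    query: MarkerSequence,
    references: list[MarkerSequence],
    params: SimilarityParams | None = None,
    scorer: PairwiseScorer | None = None,
) -> list[Hit]:
    """All references meeting the coverage threshold, best identity first.

    Ties in identity are broken by reference id (ascending) for
    determinism.
    """
    params = params or SimilarityParams()
    scorer = scorer or PairwiseScorer()
    hits = []
    for ref in references:
        if ref.marker != query.marker:
            raise ValueError(
                f"reference {ref.seq_id} marker {ref.marker} does not match "
                f"query marker {query.marker}"
            )
        identity, coverage, _ = scorer.identity_coverage(
            query.sequence, ref.sequence
        )
        if coverage >= params.min_coverage:
            hits.append(Hit(ref.seq_id, ref.owner_id, identity, coverage))
    hits.sort(key=lambda h: (-h.identity, h.ref_id))
    return hits


def decide_from_hits(
    hits: list[Hit],
    taxonomy: Taxonomy,
    params: SimilarityParams | None = None,
    marker: str = "combined",
) -> Identification:
    """Resolve a ranked hit list to the most specific unambiguous rank.

    The tie set is every hit within ``tie_margin`` percent identity of
    the best remaining hit; region-absent taxa are removed first when
    ``apply_region_filter`` is set (unless that would empty the list, in
    which case the distribution datum is deemed uninformative and
    ignored).
    """
    params = params or SimilarityParams()
    if not hits:
        return unidentified("similarity", marker, "no_hits")
    pool = hits
    if params.apply_region_filter:
        present = [h for h in hits if taxonomy.record(h.species).occurs_in_region]
        if present:
            pool = present
    best = pool[0].identity
    tied = [h for h in pool if h.identity >= best - params.tie_margin]
    species = {taxonomy.record(h.species).species_name for h in tied}
    genera = {taxonomy.genus_of(h.species) for h in tied}
    families = {taxonomy.family_of(h.species) for h in tied}
    if best >= params.min_identity_species and len(species) == 1:
        return Identification("species", next(iter(species)), "similarity", marker)
    if best >= params.min_identity_genus and len(genera) == 1:
        return Identification("genus", next(iter(genera)), "similarity", marker)
    if len(families) == 1:
        return Identification("family", next(iter(families)), "similarity", marker)
    return unidentified("similarity", marker, "ambiguous")


class SimilarityIdentifier(BaseEstimator):
    """Top-hit identifier over a fitted multi-marker reference database.

    Parameters mirror :class:`SimilarityParams`.  ``fit`` takes the
    reference database (mapping marker -> list of reference
    :class:`MarkerSequence`) and the taxonomy; ``predict`` maps query
    sequences to :class:`Identification` objects, one per input.
    """

    def __init__(
        self,
        min_identity_species: float = 99.0,
        min_identity_genus: float = 95.0,
        min_coverage: float = 0.9,
        tie_margin: float = 0.5,
        apply_region_filter: bool = True,
        align_params: AlignParams | None = None,
    ):
        self.min_identity_species = min_identity_species
        self.min_identity_genus = min_identity_genus
        self.min_coverage = min_coverage
        self.tie_margin = tie_margin
        self.apply_region_filter = apply_region_filter
        self.align_params = align_params

    def _params(self) -> SimilarityParams:
        return SimilarityParams(
            min_identity_species=self.min_identity_species,
            min_identity_genus=self.min_identity_genus,
            min_coverage=self.min_coverage,
            tie_margin=self.tie_margin,
            apply_region_filter=self.apply_region_filter,
        )

    def fit(self, refdb: dict[str, list[MarkerSequence]], taxonomy: Taxonomy, scorer: PairwiseScorer | None = None):
        self.refdb_ = {m: list(seqs) for m, seqs in refdb.items()}
        self.taxonomy_ = taxonomy
        self.scorer_ = scorer or PairwiseScorer(self.align_params)
        return self

    def predict(self, queries: list[MarkerSequence]) -> list[Identification]:
        if not hasattr(self, "refdb_"):
            raise RuntimeError("identifier is not fitted")
        params = self._params()
        out = []
        for q in queries:
            refs = self.refdb_.get(q.marker, [])
            if not refs:
                out.append(unidentified("similarity", q.marker, "no_reference"))
                continue
            hits = rank_hits(q, refs, params, self.scorer_)
            out.append(
                decide_from_hits(hits, self.taxonomy_, params, marker=q.marker)
            )
        return out
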