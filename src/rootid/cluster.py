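"""Blastclust-style single-linkage identity clustering.

Two sequences are neighbors when their semi-global percent identity
meets the marker-specific threshold (100% for the coding plastid locus,
98% for the non-coding loci — the slow locus needs exact matching
because congeners are often identical, while the faster loci tolerate a
little intraspecific noise) *and* the aligned region covers at least
90% of the shorter sequence.  Clusters are the connected components of
the neighbor graph, so membership chains through intermediates; a query
is identified by the taxa of the references it clusters with.

"Similarity" is operationalized as the package's percent identity
(terminal-gap-free, internal gaps as mismatches), not Blastclust's
score-density; coverage is one-sided (shorter sequence), and both
threshold comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator

from .align import AlignParams, PairwiseScorer
from .model import Identification, MarkerSequence, Taxonomy, unidentified


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: dict = field(
        default_factory=lambda: {"rpoC1": 100.0, "psbA-trnH": 98.0, "ITS": 98.0}
    )
    min_length_coverage: float = 0.9

    def __post_init__(self):
        for t in self.identity_threshold.values():
            if not (0.0 < t <= 100.0):
                raise ValueError("identity thresholds must lie in (0, 100]")
        if not (0.0 < self.min_length_coverage <= 1.0):
            raise ValueError("coverage threshold must lie in (0, 1]")


@dataclass(frozen=True)
class ClusterPartition:
    """A partition of sequence ids into single-linkage clusters."""

    clusters: tuple[frozenset[str], ...]

    def cluster_of(self, seq_id: str) -> frozenset[str]:
        for c in self.clusters:
            if seq_id in c:
                return c
        raise KeyError(f"{seq_id!r} not in partition")

    def __len__(self) -> int:
        return len(self.clusters)


def neighbors(
    a: MarkerSequence,
    b: MarkerSequence,
    params: ClusterParams | None = None,
    scorer: PairwiseScorer | None = None,
) -> bool:
    """True iff the pair meets both the identity and coverage thresholds."""
    params = params or ClusterParams()
    if a.marker != b.marker:
        raise ValueError(f"marker mismatch: {a.marker} vs {b.marker}")
    scorer = scorer or PairwiseScorer()
    identity, coverage, _ = scorer.identity_coverage(a.sequence, b.sequence)
    return (
        identity >= params.identity_threshold[a.marker]
        and coverage >= params.min_length_coverage
    )


def single_linkage(
    seqs: list[MarkerSequence],
    params: ClusterParams | None = None,
    scorer: PairwiseScorer | None = None,
) -> ClusterPartition:
    """Connected components of the neighbor graph over one marker.

    The partition is returned in a canonical order (clusters sorted by
    their smallest member id) so output is independent of input order.
    """
    if not seqs:
        raise ValueError("cannot cluster an empty sequence set")
    params = params or ClusterParams()
    scorer = scorer or PairwiseScorer()
    graph = nx.Graph()
    graph.add_nodes_from(s.seq_id for s in seqs)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if neighbors(seqs[i], seqs[j], params, scorer):
                graph.add_edge(seqs[i].seq_id, seqs[j].seq_id)
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: min(c))
    return ClusterPartition(clusters=tuple(comps))


def cluster_assign(
    query_id: str,
    partition: ClusterPartition,
    references: list[MarkerSequence],
    taxonomy: Taxonomy,
    marker: str = "combined",
) -> Identification:
    """Identify a query from the reference composition of its cluster."""
    cluster = partition.cluster_of(query_id)
    ref_species = sorted(
        {
            taxonomy.record(r.owner_id).species_name
            for r in references
            if r.seq_id in cluster
        }
    )
    if not ref_species:
        return unidentified("cluster", marker, "query_only_cluster")
    if len(ref_species) == 1:
        return Identification("species", ref_species[0], "cluster", marker)
    genera = {taxonomy.genus_of(sp) for sp in ref_species}
    if len(genera) == 1:
        return Identification("genus", next(iter(genera)), "cluster", marker)
    families = {taxonomy.family_of(sp) for sp in ref_species}
    if len(families) == 1:
        return Identification("family", next(iter(families)), "cluster", marker)
    return unidentified("cluster", marker, "mixed_cluster")


def identity_histogram(
    seqs: list[MarkerSequence],
    bins=None,
    scorer: PairwiseScorer | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of all pairwise identities for one marker.

    A survey utility for choosing clustering thresholds by eye (the
    pairwise-distance summary step); it carries no decision logic.
    """
    scorer = scorer or PairwiseScorer()
    vals = [
        scorer.identity_coverage(seqs[i].sequence, seqs[j].sequence)[0]
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    ]
    if bins is None:
        bins = np.linspace(80.0, 100.0, 41)
    return np.histogram(np.array(vals), bins=bins)


class ClusterIdentifier(BaseEstimator):
    """Single-linkage cluster identifier over a fitted reference database.

    ``predict`` clusters the queries of each marker jointly with that
    marker's references and assigns each query from its cluster's
    reference taxa.
    """

    def __init__(
        self,
        identity_threshold: dict | None = None,
        min_length_coverage: float = 0.9,
        align_params: AlignParams | None = None,
    ):
        self.identity_threshold = identity_threshold
        self.min_length_coverage = min_length_coverage
        self.align_params = align_params

    def _params(self) -> ClusterParams:
        kwargs = {}
        if self.identity_threshold is not None:
            kwargs["identity_threshold"] = self.identity_threshold
        return ClusterParams(min_length_coverage=self.min_length_coverage, **kwargs)

    def fit(self, refdb: dict[str, list[MarkerSequence]], taxonomy: Taxonomy, scorer: PairwiseScorer | None = None):
        self.refdb_ = {m: list(seqs) for m, seqs in refdb.items()}
        self.taxonomy_ = taxonomy
        self.scorer_ = scorer or PairwiseScorer(self.align_params)
        return self

    def predict(self, queries: list[MarkerSequence]) -> list[Identification]:
        if not hasattr(self, "refdb_"):
            raise RuntimeError("identifier is not fitted")
        params = self._params()
        by_marker: dict[str, list[MarkerSequence]] = {}
        for q in queries:
            by_marker.setdefault(q.marker, []).append(q)
        assigned: dict[str, Identification] = {}
        for marker, qs in by_marker.items():
            refs = self.refdb_.get(marker, [])
            if not refs:
                for q in qs:
                    assigned[q.seq_id] = unidentified(
                        "cluster", marker, "no_reference"
                    )
                continue
            partition = single_linkage(refs + qs, params, self.scorer_)
            for q in qs:
                assigned[q.seq_id] = cluster_assign(
                    q.seq_id, partition, refs, self.taxonomy_, marker=marker
                )
        return [assigned[q.seq_id] for q in queries]
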