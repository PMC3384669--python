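"""Tree building and clade-based taxonomic assignment.

Queries are placed in a phylogram together with the reference sequences
and identified by where they attach:

* species level only when the query sits *inside* a species-specific
  clade (all reference tips below some ancestor belong to one species,
  with at least two reference tips), not when it is merely sister to
  such a clade — with one exception: a query at patristic distance ~0
  from a reference it forms a clade with is deemed identified to that
  reference's species, because a sequence identical to a reference
  cannot be placed more precisely by any method;
* genus or family level when the query is clustered at least one node
  into a clade whose reference tips all share that genus or family;
* support values play no role.

Trees come either from the internal neighbor-joining constructor (over
semi-global p-distances) or from any external program via newick import;
branch lengths are required because the identical-sequence exception is
defined on patristic distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .align import AlignParams, PairwiseScorer, distance_matrix
from .model import Identification, MarkerSequence, Taxonomy, unidentified
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TreeAssignParams:
    identical_epsilon: float = 1e-8
    rooting: str = "midpoint"  # or "outgroup"

    def __post_init__(self):
        if self.identical_epsilon < 0:
            raise ValueError("identical_epsilon must be >= 0")
        if self.rooting not in ("midpoint", "outgroup"):
            raise ValueError("rooting must be 'midpoint' or 'outgroup'")


def nj_tree(matrix: np.ndarray, labels: list[str]) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative estimated branch lengths are clamped to zero.  The result
    is unrooted (trifurcating at the arbitrary root node).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if matrix.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    return nj(DistanceMatrix(matrix, labels), neg_as_zero=True)


def root_tree(
    tree: TreeNode,
    params: TreeAssignParams | None = None,
    outgroup_tips: list[str] | None = None,
) -> TreeNode:
    """Root a tree for clade-rule evaluation.

    With outgroup tips, roots on the branch separating them from the
    rest; otherwise roots at the midpoint of the longest tip-to-tip
    path.  Total branch length is preserved.
    """
    params = params or TreeAssignParams()
    if outgroup_tips:
        names = {t.name for t in tree.tips()}
        missing = sorted(set(outgroup_tips) - names)
        if missing:
            raise ValueError(f"outgroup tips not in tree: {missing}")
        return tree.root_by_outgroup(outgroup_tips)
    return tree.root_at_midpoint()


def total_branch_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse() if not n.is_root())


def import_newick(path, known_tips=None, taxonomy: Taxonomy | None = None) -> TreeNode:
    """Read a newick tree, requiring branch lengths on every non-root edge.

    ``known_tips`` (an iterable of valid tip labels) and/or a taxonomy
    validate the tip set; unknown labels raise with the offending names.
    """
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse():
        if node.is_root():
            continue
        if node.length is None:
            raise ValueError(
                f"{path}: tree lacks branch lengths (required for the "
                "identical-sequence rule)"
            )
    if known_tips is not None or taxonomy is not None:
        valid = set(known_tips or [])
        unknown = []
        for tip in tree.tips():
            ok = tip.name in valid or (
                taxonomy is not None and tip.name in taxonomy
            )
            if not ok:
                unknown.append(tip.name)
        if unknown:
            raise ValueError(f"{path}: unknown tip labels {sorted(unknown)}")
    return tree


def assign_from_tree(
    tree: TreeNode,
    query_tip: str,
    tip_species: Mapping[str, str],
    taxonomy: Taxonomy,
    params: TreeAssignParams | None = None,
    query_tips: set[str] | None = None,
    marker: str = "combined",
    seq_lookup: Mapping[str, str] | None = None,
) -> Identification:
    """Apply the clade rules to one query tip of a rooted tree.

    ``tip_species`` maps reference tip labels to species names; tips in
    ``query_tips`` (default: every tip not in ``tip_species``) carry no
    taxonomy and are ignored when testing clade uniformity.  Rules, in
    order: identical-sequence exception, species-specific clade, genus
    clade, family clade.
    """
    params = params or TreeAssignParams()
    q = tree.find(query_tip)
    if not q.is_tip():
        raise ValueError(f"{query_tip!r} is not a tip")
    all_tips = list(tree.tips())
    names = {t.name for t in all_tips}
    if query_tips is None:
        query_tips = names - set(tip_species)
    else:
        unmapped = sorted(names - set(tip_species) - set(query_tips))
        if unmapped:
            raise ValueError(f"unmapped reference tips: {unmapped}")
    ref_tips = [t for t in all_tips if t.name in tip_species]

    def _species(tip):
        return taxonomy.record(tip_species[tip.name]).species_name

    # (1) identical-sequence exception
    eps_refs = sorted(
        ((q.distance(r), r.name, r) for r in ref_tips),
        key=lambda x: (x[0], x[1]),
    )
    identical = [(d, name, r) for d, name, r in eps_refs if d <= params.identical_epsilon]
    if identical:
        species = {_species(r) for _, _, r in identical}
        if len(species) == 1:
            target = next(iter(species))
            for _, _, r in identical:
                clade = tree.lca([q, r])
                clade_species = {
                    _species(t) for t in clade.tips() if t.name in tip_species
                }
                if clade_species == {target}:
                    if seq_lookup is not None:
                        sq = seq_lookup.get(query_tip)
                        sr = seq_lookup.get(r.name)
                        if sq is not None and sr is not None and sq != sr:
                            logger.warning(
                                "tree-identical pair %s/%s has unequal "
                                "sequences", query_tip, r.name,
                            )
                    return Identification(
                        "species", target, "tree", marker, "identical_exception"
                    )
        # identical to references of several species: fall through

    # ancestor statistics, bottom-up; the first ancestor (the query's
    # parent) never qualifies — that is the sister-placement case
    ancestors = q.ancestors()
    stats = []
    for v in ancestors:
        refs_v = [t for t in v.tips() if t.name in tip_species]
        if not refs_v:
            stats.append(None)
            continue
        spp = {_species(t) for t in refs_v}
        gen = {taxonomy.genus_of(s) for s in spp}
        fam = {taxonomy.family_of(s) for s in spp}
        stats.append((len(refs_v), spp, gen, fam))

    def _first(rank_ok):
        for v, st in zip(ancestors[1:], stats[1:]):
            if st is None:
                continue
            hit = rank_ok(st)
            if hit is not None:
                return hit
        return None

    # (2) species-specific clade, >= 2 reference tips
    hit = _first(lambda st: next(iter(st[1])) if len(st[1]) == 1 and st[0] >= 2 else None)
    if hit is not None:
        return Identification("species", hit, "tree", marker, "species_clade")
    # (3) genus clade, >= 1 reference tip
    hit = _first(lambda st: next(iter(st[2])) if len(st[2]) == 1 else None)
    if hit is not None:
        return Identification("genus", hit, "tree", marker, "genus_clade")
    # (4) family clade
    hit = _first(lambda st: next(iter(st[3])) if len(st[3]) == 1 else None)
    if hit is not None:
        return Identification("family", hit, "tree", marker, "family_clade")
    return unidentified("tree", marker, "no_clade")


class TreeIdentifier(BaseEstimator):
    """Clade-rule identifier on internally built neighbor-joining trees.

    For each marker, queries and references are placed in one NJ tree
    over pairwise p-distances, the tree is midpoint-rooted (or
    outgroup-rooted when outgroup tip labels are supplied at fit time),
    and every query tip is assigned independently.
    """

    def __init__(
        self,
        identical_epsilon: float = 1e-8,
        rooting: str = "midpoint",
        align_params: AlignParams | None = None,
    ):
        self.identical_epsilon = identical_epsilon
        self.rooting = rooting
        self.align_params = align_params

    def _params(self) -> TreeAssignParams:
        return TreeAssignParams(
            identical_epsilon=self.identical_epsilon, rooting=self.rooting
        )

    def fit(
        self,
        refdb: dict[str, list[MarkerSequence]],
        taxonomy: Taxonomy,
        scorer: PairwiseScorer | None = None,
        outgroup_tips: dict | None = None,
    ):
        self.refdb_ = {m: list(seqs) for m, seqs in refdb.items()}
        self.taxonomy_ = taxonomy
        self.scorer_ = scorer or PairwiseScorer(self.align_params)
        self.outgroup_tips_ = outgroup_tips or {}
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
                    assigned[q.seq_id] = unidentified("tree", marker, "no_reference")
                continue
            seqs = refs + qs
            if len(seqs) < 3:
                for q in qs:
                    assigned[q.seq_id] = unidentified(
                        "tree", marker, "too_few_sequences"
                    )
                continue
            mat, labels = distance_matrix(seqs, scorer=self.scorer_)
            tree = nj_tree(mat, labels)
            rooted = root_tree(tree, params, self.outgroup_tips_.get(marker))
            tip_species = {r.seq_id: r.owner_id for r in refs}
            qnames = {q.seq_id for q in qs}
            seq_lookup = {s.seq_id: s.sequence for s in seqs}
            for q in qs:
                assigned[q.seq_id] = assign_from_tree(
                    rooted,
                    q.seq_id,
                    tip_species,
                    self.taxonomy_,
                    params,
                    query_tips=qnames,
                    marker=marker,
                    seq_lookup=seq_lookup,
                )
        return [assigned[q.seq_id] for q in queries]
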