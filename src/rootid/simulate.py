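"""Synthetic multi-marker barcode datasets with market-sample structure.

The generator emulates the statistical situation a regional barcoding
study faces: a reference database sequenced from *different populations*
than the query material (so conspecific reference-query pairs are never
identical unless the intraspecific depth is zero), marker-specific
substitution rates (the coding plastid locus slowest, nuclear ITS
fastest), indels and A/T homopolymers in the non-coding loci,
per-marker sequencing dropout, ITS losses to paralog polymorphism and
fungal contamination, incomplete reference species coverage, and
adulterated samples whose pharmacopoeia-derived putative name points at
a different genus than the material's true identity.

Sequences evolve by Jukes-Cantor substitutions along an ultrametric
species tree: a fixed family/genus backbone with a random coalescent-style
crown per genus, rescaled so the expected divergence between congeneric
species equals ``interspecific_depth`` (in substitutions/site at the
reference rate of 1.0; each marker multiplies this by its own rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import write_fasta, write_taxonomy
from .model import MARKERS, MarkerSequence, QuerySample, TaxonRecord, Taxonomy

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: backbone depths, in units of the congeneric divergence
#: (tip-to-tip path through a genus crown = 1 unit = interspecific_depth)
GENUS_SPLIT_FACTOR = 4.0  # cross-genus divergence within a family
FAMILY_SPLIT_FACTOR = 8.0  # cross-family divergence
OUTGROUP_DIVERGENCE = 1.5  # substitutions/site, query-to-plant, "fungal" lineage

_GENUS_SYLLABLES = [
    "bar", "cor", "dal", "fen", "gal", "hel", "kar", "lam", "mor", "nar",
    "pol", "quer", "ras", "sil", "tam", "ver", "zal", "bel", "cam", "dor",
]
_EPITHETS = [
    "alba", "aurea", "borealis", "cana", "dubia", "elegans", "fragilis",
    "gracilis", "humilis", "incana", "laxa", "minor", "nitida", "ovata",
    "pallida", "rigida", "sativa", "tenuis", "undulata", "vulgaris",
]


@dataclass(frozen=True)
class SimParams:
    """Scenario knobs for one synthetic study.

    Defaults describe the clean baseline: complete reference coverage,
    a small but nonzero reference-query population offset
    (``intraspecific_depth`` = 0.002 substitutions/site versus a
    congeneric divergence of 0.02), no sequencing degradation, and a
    modest adulteration rate comparable to a market survey.
    """

    n_families: int = 5
    genera_per_family: int = 2
    species_per_genus: int = 3
    n_queries: int = 60
    marker_rate: dict = field(
        default_factory=lambda: {"rpoC1": 0.3, "psbA-trnH": 1.0, "ITS": 2.0}
    )
    marker_len: dict = field(
        default_factory=lambda: {
            "rpoC1": (409, 545),
            "psbA-trnH": (141, 658),
            "ITS": (194, 748),
        }
    )
    interspecific_depth: float = 0.02
    intraspecific_depth: float = 0.002
    indel_rate_noncoding: float = 0.001
    homopolymer_len: int = 10
    dropout_prob: dict = field(
        default_factory=lambda: {"rpoC1": 0.0, "psbA-trnH": 0.0, "ITS": 0.0}
    )
    its_polymorphism_prob: float = 0.0
    its_contamination_prob: float = 0.0
    adulteration_prob: float = 0.1
    ref_coverage: float = 1.0
    fraction_absent_region: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for p in (
            self.its_polymorphism_prob,
            self.its_contamination_prob,
            self.adulteration_prob,
            self.ref_coverage,
            self.fraction_absent_region,
            *self.dropout_prob.values(),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(r <= 0 for r in self.marker_rate.values()):
            raise ValueError("marker rates must be positive")
        if min(self.n_families, self.genera_per_family, self.species_per_genus) < 1:
            raise ValueError("taxonomy counts must be >= 1")


def market_scenario(**overrides) -> SimParams:
    """A degraded scenario emulating dried market-root material.

    Dropout, ITS polymorphism and fungal-contamination rates follow the
    magnitudes reported for market samples in regional barcoding surveys
    of processed roots (roughly 10-30% dropout depending on marker, a
    third of ITS reads lost to polymorphism, a tenth to fungal reads).
    """
    base = dict(
        dropout_prob={"rpoC1": 0.12, "psbA-trnH": 0.25, "ITS": 0.30},
        its_polymorphism_prob=0.35,
        its_contamination_prob=0.11,
        adulteration_prob=0.1,
    )
    base.update(overrides)
    return SimParams(**base)


# --- taxonomy --------------------------------------------------------------


def simulate_taxonomy(params: SimParams) -> Taxonomy:
    """Generate a nested synthetic taxonomy of plausible-looking names.

    Produces ``n_families x genera_per_family x species_per_genus``
    species; a seeded fraction ``fraction_absent_region`` is flagged as
    not occurring in the study region (for distribution-filter tests).
    """
    rng = np.random.default_rng(params.seed)
    records = []
    gidx = 0
    for f in range(params.n_families):
        family = f"Simulaceae{f + 1}"
        clade = "monocot" if f % 3 == 2 else "eudicot"
        for g in range(params.genera_per_family):
            syl = _GENUS_SYLLABLES[gidx % len(_GENUS_SYLLABLES)]
            genus = (syl + f"ia{gidx // len(_GENUS_SYLLABLES) or ''}").capitalize()
            gidx += 1
            for s in range(params.species_per_genus):
                epithet = _EPITHETS[s % len(_EPITHETS)]
                if s >= len(_EPITHETS):
                    epithet += str(s // len(_EPITHETS))
                records.append(
                    TaxonRecord(
                        species_name=f"{genus} {epithet}",
                        genus=genus,
                        family=family,
                        major_clade=clade,
                        occurs_in_region=True,
                        endemic=False,
                    )
                )
    n_absent = round(params.fraction_absent_region * len(records))
    absent = set(rng.choice(len(records), size=n_absent, replace=False).tolist())
    records = [
        replace(rec, occurs_in_region=i not in absent)
        for i, rec in enumerate(records)
    ]
    return Taxonomy(records)


# --- sequence evolution ----------------------------------------------------


def _jc_mutate(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a sequence by expected ``d`` substitutions/site (Jukes-Cantor)."""
    if d <= 0:
        return seq.copy()
    p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < p)[0]
    if hits.size:
        # substitute with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(BASES, out[hits])
        out[hits] = BASES[(idx + shift) % 4]
    return out


def _apply_indels(seq: np.ndarray, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Indels (geometric length, mean 2) plus one A/T homopolymer.

    Events never touch the first or last 20 bp so terminal trimming
    stays comparable across sequences.
    """
    margin = 20
    if seq.size <= 2 * margin + 2:
        return seq.copy()
    parts = []
    i = margin
    parts.append(seq[:margin])
    while i < seq.size - margin:
        if rng.random() < params.indel_rate_noncoding:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # deletion
                i += length
                continue
            parts.append(BASES[rng.integers(0, 4, size=length)])
        parts.append(seq[i : i + 1])
        i += 1
    parts.append(seq[seq.size - margin :])
    out = np.concatenate(parts)
    # one A/T homopolymer per sequence, at a random interior position
    pos = int(rng.integers(margin, out.size - margin))
    homo = np.full(params.homopolymer_len, BASES[0] if rng.random() < 0.5 else BASES[3])
    return np.concatenate([out[:pos], homo, out[pos:]])


@dataclass
class _SpeciesNode:
    """Ultrametric species-tree node; depth measured from the tips (time units)."""

    depth: float
    children: list = field(default_factory=list)
    species: str | None = None


def _mean_mrca_depth(root: _SpeciesNode) -> float:
    """Mean depth of the MRCA over all unordered tip pairs."""
    total = 0.0
    npairs = 0

    def _tips(node) -> int:
        nonlocal total, npairs
        if node.species is not None:
            return 1
        counts = [_tips(c) for c in node.children]
        crossing = 0
        for i in range(len(counts)):
            for j in range(i + 1, len(counts)):
                crossing += counts[i] * counts[j]
        total += node.depth * crossing
        npairs += crossing
        return sum(counts)

    _tips(root)
    return total / npairs if npairs else 0.0


def _genus_crown(species: list[str], depth: float, rng: np.random.Generator) -> _SpeciesNode:
    """Random binary crown over one genus, rescaled so the *mean*
    tip-to-tip path equals 2 x ``depth``."""
    nodes = [_SpeciesNode(0.0, species=s) for s in species]
    if len(nodes) == 1:
        return nodes[0]
    depths = np.sort(rng.uniform(0.0, 1.0, size=len(nodes) - 1))
    depths[-1] = 1.0  # crown node closes the genus
    for d in depths:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = _SpeciesNode(float(d), children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    root = nodes[0]
    # cap so the crown never reaches the genus split (at 2 x depth)
    factor = min(depth / _mean_mrca_depth(root), 1.8 * depth)

    def _scale(node):
        node.depth *= factor
        for c in node.children:
            _scale(c)

    _scale(root)
    return root


def _species_tree(taxonomy: Taxonomy, params: SimParams, rng: np.random.Generator) -> _SpeciesNode:
    """Fixed family/genus backbone with a random crown per genus."""
    half = params.interspecific_depth / 2.0  # tip-to-crown time within a genus
    by_family: dict[str, dict[str, list[str]]] = {}
    for rec in taxonomy:
        by_family.setdefault(rec.family, {}).setdefault(rec.genus, []).append(
            rec.species_name
        )
    # MRCA depth for a tip-pair divergence of k x interspecific_depth is k x half
    genus_depth = half * GENUS_SPLIT_FACTOR
    family_depth = half * FAMILY_SPLIT_FACTOR
    family_nodes = []
    for family in sorted(by_family):
        genus_nodes = [
            _genus_crown(sorted(spp), half, rng)
            for genus, spp in sorted(by_family[family].items())
        ]
        if len(genus_nodes) == 1:
            family_nodes.append(genus_nodes[0])
        else:
            family_nodes.append(_SpeciesNode(genus_depth, children=genus_nodes))
    if len(family_nodes) == 1:
        return family_nodes[0]
    return _SpeciesNode(family_depth, children=family_nodes)


@dataclass
class SimulatedSequences:
    """Per-species, per-population sequences for every marker.

    ``variants[marker][species]`` is a pair of population sequences; the
    reference database takes population 0, the query set population 1.
    ``fungal[marker]`` is a deeply divergent outgroup ("fungal") sequence
    used for contaminated ITS reads.
    """

    variants: dict[str, dict[str, tuple[str, str]]]
    fungal: dict[str, str]


def simulate_sequences(
    taxonomy: Taxonomy, params: SimParams, rng: np.random.Generator | None = None
) -> SimulatedSequences:
    """Evolve every marker along the species tree with two population
    variants per species separated by ``intraspecific_depth``."""
    rng = rng or np.random.default_rng(params.seed + 1)
    tree = _species_tree(taxonomy, params, rng)
    variants: dict[str, dict[str, tuple[str, str]]] = {}
    fungal: dict[str, str] = {}
    for marker in MARKERS:
        rate = params.marker_rate[marker]
        lo, hi = params.marker_len[marker]
        length = int(rng.integers(lo, hi + 1))
        root_seq = BASES[rng.integers(0, 4, size=length)]
        per_species: dict[str, np.ndarray] = {}

        def _evolve(node, seq, node_depth):
            for child in node.children:
                d = (node_depth - child.depth) * rate
                child_seq = _jc_mutate(seq, d, rng)
                _evolve(child, child_seq, child.depth)
            if node.species is not None:
                per_species[node.species] = seq

        _evolve(tree, root_seq, tree.depth)
        noncoding = marker != "rpoC1"
        out: dict[str, tuple[str, str]] = {}
        half_intra = params.intraspecific_depth / 2.0 * rate
        for species in sorted(per_species):
            seq = per_species[species]
            if noncoding:
                seq = _apply_indels(seq, params, rng)
            pop0 = _jc_mutate(seq, half_intra, rng)
            pop1 = _jc_mutate(seq, half_intra, rng)
            out[species] = (
                pop0.tobytes().decode(),
                pop1.tobytes().decode(),
            )
        variants[marker] = out
        fungal[marker] = (
            _jc_mutate(root_seq, OUTGROUP_DIVERGENCE * 0.75, rng).tobytes().decode()
        )
    return SimulatedSequences(variants=variants, fungal=fungal)


# --- reference database and query set -------------------------------------


def ref_seq_id(species: str, marker: str) -> str:
    # reference headers follow the Genus_species convention so FASTA and
    # newick tip labels resolve to taxonomy entries on re-import
    return species.replace(" ", "_")


def build_reference_db(
    sim: SimulatedSequences,
    taxonomy: Taxonomy,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> dict[str, list[MarkerSequence]]:
    """Reference FASTA content: population 0 of each included species.

    A seeded random fraction ``1 - ref_coverage`` of species is omitted
    entirely (from every marker), emulating incomplete reference
    sampling.
    """
    rng = rng or np.random.default_rng(params.seed + 2)
    species = sorted(r.species_name for r in taxonomy)
    n_keep = round(params.ref_coverage * len(species))
    keep = sorted(
        np.array(species)[
            np.sort(rng.choice(len(species), size=n_keep, replace=False))
        ].tolist()
    )
    refdb: dict[str, list[MarkerSequence]] = {}
    for marker in MARKERS:
        refdb[marker] = [
            MarkerSequence(
                seq_id=ref_seq_id(sp, marker),
                owner_id=sp,
                marker=marker,
                sequence=sim.variants[marker][sp][0],
                role="reference",
            )
            for sp in keep
        ]
    return refdb


@dataclass
class SimTruth:
    """Ground truth for one simulated market sample."""

    sample_id: str
    true_species: str
    putative_taxa: tuple[str, ...]
    adulterated: bool
    markers_present: tuple[str, ...]
    its_excluded: str = ""  # "", "polymorphism" or "contamination"
    extraction_failed: bool = False


def build_query_set(
    sim: SimulatedSequences,
    taxonomy: Taxonomy,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[QuerySample], list[SimTruth]]:
    """Draw market-style queries from population 1 of the simulation.

    Applies per-marker dropout, ITS paralog-polymorphism discards, ITS
    fungal-contamination swaps and putative-name adulteration; a sample
    losing every marker is flagged extraction-failed (and carries no
    sequences).
    """
    rng = rng or np.random.default_rng(params.seed + 3)
    species = sorted(r.species_name for r in taxonomy)
    genera: dict[str, list[str]] = {}
    for sp in species:
        genera.setdefault(taxonomy.genus_of(sp), []).append(sp)
    samples, truths = [], []
    for i in range(params.n_queries):
        sample_id = f"MK{i + 1:03d}"
        true_sp = species[int(rng.integers(len(species)))]
        adulterated = bool(rng.random() < params.adulteration_prob)
        if adulterated and len(genera) > 1:
            other = [g for g in sorted(genera) if g != taxonomy.genus_of(true_sp)]
            g = other[int(rng.integers(len(other)))]
            putative = (genera[g][int(rng.integers(len(genera[g])))],)
        else:
            adulterated = False
            putative = (true_sp,)
        marker_seqs: dict[str, MarkerSequence] = {}
        its_excluded = ""
        for marker in MARKERS:
            if rng.random() < params.dropout_prob[marker]:
                continue
            seq = sim.variants[marker][true_sp][1]
            if marker == "ITS":
                if rng.random() < params.its_polymorphism_prob:
                    its_excluded = "polymorphism"
                    continue
                if rng.random() < params.its_contamination_prob:
                    its_excluded = "contamination"
                    seq = _jc_mutate(
                        np.frombuffer(sim.fungal[marker].encode(), dtype=np.uint8),
                        0.01,
                        rng,
                    ).tobytes().decode()
            marker_seqs[marker] = MarkerSequence(
                seq_id=f"{sample_id}__{marker.replace('-', '_')}",
                owner_id=sample_id,
                marker=marker,
                sequence=seq,
                role="query",
            )
        truths.append(
            SimTruth(
                sample_id=sample_id,
                true_species=true_sp,
                putative_taxa=putative,
                adulterated=adulterated,
                markers_present=tuple(sorted(marker_seqs)),
                its_excluded=its_excluded,
                extraction_failed=not marker_seqs,
            )
        )
        samples.append(
            QuerySample(
                sample_id=sample_id,
                vernacular_name=f"product-{1 + i % max(1, params.n_queries // 3)}",
                putative_taxa=list(putative),
                marker_seqs=marker_seqs,
            )
        )
    return samples, truths


@dataclass
class SimulatedDataset:
    """One complete synthetic study."""

    params: SimParams
    taxonomy: Taxonomy
    sequences: SimulatedSequences
    refdb: dict[str, list[MarkerSequence]]
    queries: list[QuerySample]
    truth: list[SimTruth]


def simulate_dataset(params: SimParams | None = None) -> SimulatedDataset:
    """Run the full generator with sub-streams seeded from ``params.seed``."""
    params = params or SimParams()
    taxonomy = simulate_taxonomy(params)
    sequences = simulate_sequences(taxonomy, params)
    refdb = build_reference_db(sequences, taxonomy, params)
    queries, truth = build_query_set(sequences, taxonomy, params)
    return SimulatedDataset(params, taxonomy, sequences, refdb, queries, truth)


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write reference/query FASTA per marker plus taxonomy, sample
    metadata and truth TSVs, all in deterministic order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_taxonomy(outdir / "taxonomy.tsv", dataset.taxonomy)
    for marker in MARKERS:
        tag = marker.replace("-", "_")
        write_fasta(outdir / f"reference_{tag}.fasta", dataset.refdb[marker])
        qseqs = [
            q.marker_seqs[marker]
            for q in dataset.queries
            if marker in q.marker_seqs
        ]
        write_fasta(outdir / f"query_{tag}.fasta", qseqs)
    pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "vernacular_name": q.vernacular_name,
                "putative_taxa": "; ".join(q.putative_taxa),
            }
            for q in dataset.queries
        ]
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "sample_id": t.sample_id,
                "true_species": t.true_species,
                "putative_taxa": "; ".join(t.putative_taxa),
                "adulterated": t.adulterated,
                "markers_present": ",".join(t.markers_present),
                "its_excluded": t.its_excluded,
                "extraction_failed": t.extraction_failed,
            }
            for t in dataset.truth
        ]
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
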