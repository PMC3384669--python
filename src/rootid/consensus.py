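"""Cross-marker consensus, concordance classification and success tables.

A market sample ends up with up to nine verdicts (three markers x three
methods).  ``combine`` replaces the manual case-by-case synthesis of
such verdict grids with a deterministic cascade: drop empty verdicts,
discount verdicts contradicted only by markers whose reference database
could not have contained the winning species, then resolve nested
lineages to the most specific rank and conflicts upward to the lowest
shared rank.

``classify_concordance`` compares the final identification against the
sample's pharmacopoeia-derived putative name(s) and yields the standard
concordance classes (confirmed at species/genus/family rank, different
at each rank, previously unknown, unidentified); ``tally_concordance``
and ``tabulate_success`` produce the summary tables.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .model import (
    ConcordanceRecord,
    Identification,
    Taxonomy,
    canonical_species,
    unidentified,
)

METHOD_ORDER_DEFAULT = ("similarity", "tree", "cluster")


@dataclass(frozen=True)
class ConsensusParams:
    """Settings for cross-marker verdict combination.

    ``method_order`` fixes the precedence used when several equivalent
    verdicts could supply the reported taxon string (the similarity
    method first, reflecting its empirically highest success rate).
    ``require_reference_presence`` enables the discounting step: a
    verdict contradicting a species-level verdict is ignored when the
    contradicting marker's reference database lacks that species — the
    marker never had a chance to find it.
    """

    method_order: tuple = METHOD_ORDER_DEFAULT
    require_reference_presence: bool = True

    def __post_init__(self):
        if sorted(self.method_order) != sorted(METHOD_ORDER_DEFAULT):
            raise ValueError(
                "method_order must be a permutation of "
                f"{METHOD_ORDER_DEFAULT}"
            )


def _lineage(ident: Identification, taxonomy: Taxonomy):
    """(species, genus, family) of a verdict, with None below its rank."""
    if ident.rank == "species":
        rec = taxonomy.record(ident.taxon)
        return rec.species_name, rec.genus, rec.family
    if ident.rank == "genus":
        return None, ident.taxon, taxonomy.family_of_genus(ident.taxon)
    if ident.rank == "family":
        return None, None, ident.taxon
    return None, None, None


def combine(
    ids: Mapping[tuple, Identification],
    taxonomy: Taxonomy,
    ref_presence: Mapping[str, set] | None = None,
    params: ConsensusParams | None = None,
) -> Identification:
    """Combine per-(marker, method) verdicts into one final identification.

    ``ids`` maps ``(marker, method)`` to a verdict; ``ref_presence``
    maps each marker to the set of species present in its reference
    database (species names, any capitalization).
    """
    params = params or ConsensusParams()
    rank_of = {m: i for i, m in enumerate(params.method_order)}
    verdicts = [
        (marker, method, ident)
        for (marker, method), ident in sorted(
            ids.items(), key=lambda kv: (rank_of.get(kv[0][1], 99), kv[0][0])
        )
        if ident.identified
    ]
    if not verdicts:
        return unidentified("consensus", "combined", "all_unidentified")

    if params.require_reference_presence and ref_presence is not None:
        presence = {
            m: {canonical_species(s) for s in spp}
            for m, spp in ref_presence.items()
        }

        def _compatible(a: Identification, b: Identification) -> bool:
            sa, ga, fa = _lineage(a, taxonomy)
            sb, gb, fb = _lineage(b, taxonomy)
            if sb is not None:
                return canonical_species(sa) == canonical_species(sb) if sa else False
            if gb is not None:
                return ga == gb
            return fa == fb

        dropped = set()
        for i, (mi, methi, a) in enumerate(verdicts):
            if a.rank != "species" or i in dropped:
                continue
            for j, (mj, methj, b) in enumerate(verdicts):
                if j == i or j in dropped or mj == mi:
                    continue
                lacks = canonical_species(a.taxon) not in presence.get(mj, set())
                if lacks and not _compatible(a, b):
                    dropped.add(j)
        verdicts = [v for k, v in enumerate(verdicts) if k not in dropped]
        if not verdicts:
            return unidentified("consensus", "combined", "all_unidentified")

    lineages = [_lineage(v, taxonomy) for _, _, v in verdicts]
    species = {canonical_species(s) for s, _, _ in lineages if s}
    genera = {g for _, g, _ in lineages if g}
    families = {f for _, _, f in lineages if f}

    def _first_taxon(rank: str) -> str:
        for (_, _, v), (s, g, f) in zip(verdicts, lineages):
            val = {"species": s, "genus": g, "family": f}[rank]
            if val:
                return val
        raise AssertionError("no taxon at rank " + rank)

    if len(species) <= 1 and len(genera) <= 1 and len(families) <= 1:
        # all verdicts nested along one lineage: take the most specific
        if species:
            return Identification(
                "species", _first_taxon("species"), "consensus", "combined"
            )
        if genera:
            return Identification(
                "genus", _first_taxon("genus"), "consensus", "combined"
            )
        return Identification(
            "family", _first_taxon("family"), "consensus", "combined"
        )
    if len(genera) == 1 and len(families) == 1:
        return Identification("genus", next(iter(genera)), "consensus", "combined")
    if len(families) == 1:
        return Identification("family", next(iter(families)), "consensus", "combined")
    return unidentified("consensus", "combined", "conflict")


def classify_concordance(
    final: Identification,
    putative_taxa: Iterable[str],
    taxonomy: Taxonomy,
    sample_id: str = "",
    vernacular_name: str = "",
) -> ConcordanceRecord:
    """Compare a final identification with the putative species list.

    Multi-candidate putative lists match if any candidate matches; the
    comparison rank is the final identification's rank.
    """
    putative = tuple(putative_taxa)
    for name in putative:
        taxonomy.record(name)  # raises naming an unresolvable putative
    if not final.identified:
        label = "unidentified"
    elif not putative:
        label = "previously_unknown"
    else:
        put_species = {canonical_species(p) for p in putative}
        put_genera = {taxonomy.genus_of(p) for p in putative}
        put_families = {taxonomy.family_of(p) for p in putative}
        _, genus, family = _lineage(final, taxonomy)
        if final.rank == "species":
            if canonical_species(final.taxon) in put_species:
                label = "species_confirmed"
            elif genus in put_genera:
                label = "different_species"
            elif family in put_families:
                label = "different_genus"
            else:
                label = "different_family"
        elif final.rank == "genus":
            if genus in put_genera:
                label = "genus_confirmed"
            elif family in put_families:
                label = "different_genus"
            else:
                label = "different_family"
        else:  # family rank
            label = (
                "family_confirmed" if family in put_families else "different_family"
            )
    return ConcordanceRecord(
        sample_id=sample_id,
        putative_taxa=putative,
        final_id=final,
        concordance=label,
        vernacular_name=vernacular_name,
        final_text=final.taxon,
    )


def tally_concordance(
    records: list[ConcordanceRecord],
) -> tuple[Counter, int]:
    """Counts per concordance class and the misidentification percentage.

    The percentage counts samples whose final identification falls in a
    *different genus or family* than every putative name, over all
    analyzed samples, rounded to the nearest integer.
    """
    if not records:
        raise ValueError("no concordance records to tally")
    counts = Counter(r.concordance for r in records)
    discordant = counts["different_genus"] + counts["different_family"]
    pct = round(100.0 * discordant / len(records))
    return counts, pct


def tabulate_success(
    ids: pd.DataFrame,
    sample_meta: Mapping[str, Mapping[str, str]] | None = None,
    grouping: str = "marker",
) -> pd.DataFrame:
    """Identification-success percentages per group.

    ``ids`` needs columns ``sample_id``, ``marker``, ``method`` and
    ``rank`` with one row per obtained sequence per method, so group
    denominators automatically include only samples with a sequence for
    that marker.  ``grouping`` is one of marker/method/major_clade/family
    (the latter two resolved through ``sample_meta``).
    """
    valid = ("marker", "method", "major_clade", "family")
    if grouping not in valid:
        raise ValueError(f"grouping must be one of {valid}")
    df = ids.copy()
    if grouping in ("major_clade", "family"):
        if sample_meta is None:
            raise ValueError(f"grouping {grouping!r} needs sample_meta")
        df[grouping] = [sample_meta[s][grouping] for s in df["sample_id"]]
    rows = []
    for group, sub in df.groupby(grouping, sort=True):
        n = len(sub)
        ranks = sub["rank"].value_counts()
        rows.append(
            {
                grouping: group,
                "n": n,
                "pct_species": 100.0 * ranks.get("species", 0) / n,
                "pct_genus": 100.0 * ranks.get("genus", 0) / n,
                "pct_family": 100.0 * ranks.get("family", 0) / n,
                "pct_unidentified": 100.0 * ranks.get("unidentified", 0) / n,
            }
        )
    return pd.DataFrame(rows).set_index(grouping)
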