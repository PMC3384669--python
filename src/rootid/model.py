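"""Domain types for multi-marker barcode identification.

The package works with three loci routinely used to identify processed
plant material: the coding plastid region *rpoC1* (slowly evolving, easy
to sequence), the non-coding plastid spacer *psbA-trnH*, and the nuclear
ribosomal ITS region (fast evolving, but prone to paralogy and fungal
contamination in root material).  Everything downstream — similarity
search, identity clustering, tree placement, consensus — speaks in terms
of the small record types defined here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

MARKERS = ("rpoC1", "psbA-trnH", "ITS")
PLASTID_MARKERS = frozenset({"rpoC1", "psbA-trnH"})

MAJOR_CLADES = ("monocot", "eudicot", "basal_angiosperm", "outgroup")

#: IUPAC nucleotide one-letter codes (upper case), including ambiguity
#: codes and the alignment gap character used in imported sequences.
IUPAC_NT = frozenset("ACGTURYSWKMBDHVN-")

RANKS = ("species", "genus", "family", "unidentified")
METHODS = ("similarity", "cluster", "tree", "consensus")

_MARKER_ALIASES = {
    "rpoc1": "rpoC1",
    "psba-trnh": "psbA-trnH",
    "psba_trnh": "psbA-trnH",
    "psbatrnh": "psbA-trnH",
    "its": "ITS",
}


def normalize_marker(name: str) -> str:
    """Map common spellings of a marker name onto the canonical form."""
    try:
        return _MARKER_ALIASES[name.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown marker {name!r}; expected one of {MARKERS}") from None


_INFRASPECIFIC = {"subsp.", "ssp.", "var.", "f.", "subvar.", "forma"}


def canonical_species(name: str) -> str:
    """Reduce a scientific name to a lower-case species-rank binomial.

    Author strings are dropped (anything beyond the epithet), hybrid
    signs are preserved ("Iris x germanica"), and infraspecific epithets
    are removed so that a subspecies compares equal to its species.
    """
    tokens = name.replace("×", "x").split()
    if not tokens:
        return ""
    out = [tokens[0].lower()]
    i = 1
    if i < len(tokens) and tokens[i].lower() == "x":
        out.append("x")
        i += 1
    if i < len(tokens):
        epithet = tokens[i].lower()
        if epithet not in _INFRASPECIFIC and not epithet.endswith("."):
            out.append(epithet)
    return " ".join(out)


def is_binomial(name: str) -> bool:
    """True for a species-rank name like "Daucus crinitus" (not "Daucus sp.")."""
    parts = canonical_species(name).split()
    return len(parts) >= 2


@dataclass(frozen=True)
class TaxonRecord:
    """One reference taxon with its rank lineage and distribution flags."""

    species_name: str
    genus: str
    family: str
    major_clade: str
    occurs_in_region: bool = True
    endemic: bool = False

    def __post_init__(self):
        if self.major_clade not in MAJOR_CLADES:
            raise ValueError(
                f"major_clade {self.major_clade!r} not in {MAJOR_CLADES}"
            )
        if not self.species_name.split()[0].lower() == self.genus.lower():
            raise ValueError(
                f"species_name {self.species_name!r} does not begin with "
                f"genus {self.genus!r}"
            )


class Taxonomy:
    """A validated species → lineage lookup table.

    Enforces that a genus maps to a single family across the table and
    offers rank resolution for free-text names (case-insensitive, author
    strings and infraspecific epithets ignored at species rank).
    """

    def __init__(self, records: Iterable[TaxonRecord]):
        self._by_species: dict[str, TaxonRecord] = {}
        genus_family: dict[str, str] = {}
        for rec in records:
            key = canonical_species(rec.species_name)
            if key in self._by_species:
                raise ValueError(f"duplicate species {rec.species_name!r}")
            g = rec.genus.lower()
            if g in genus_family and genus_family[g] != rec.family:
                raise ValueError(
                    f"genus {rec.genus!r} mapped to two families: "
                    f"{genus_family[g]!r} and {rec.family!r}"
                )
            genus_family[g] = rec.family
            self._by_species[key] = rec
        self._genus_family = genus_family

    def __len__(self) -> int:
        return len(self._by_species)

    def __iter__(self):
        return iter(self._by_species.values())

    def __contains__(self, species_name: str) -> bool:
        return canonical_species(species_name) in self._by_species

    def record(self, species_name: str) -> TaxonRecord:
        key = canonical_species(species_name)
        try:
            return self._by_species[key]
        except KeyError:
            raise KeyError(f"species {species_name!r} not in taxonomy") from None

    def genus_of(self, species_name: str) -> str:
        return self.record(species_name).genus

    def family_of(self, species_name: str) -> str:
        return self.record(species_name).family

    def family_of_genus(self, genus: str) -> str:
        try:
            return self._genus_family[genus.lower()]
        except KeyError:
            raise KeyError(f"genus {genus!r} not in taxonomy") from None

    def has_genus(self, genus: str) -> bool:
        return genus.lower() in self._genus_family

    def species(self) -> list[str]:
        return [r.species_name for r in self._by_species.values()]


@dataclass(frozen=True)
class MarkerSequence:
    """One nucleotide sequence tied to a marker and an owner (sample or taxon)."""

    seq_id: str
    owner_id: str
    marker: str
    sequence: str
    role: str = "reference"  # or "query"

    def __post_init__(self):
        object.__setattr__(self, "marker", normalize_marker(self.marker))
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"empty sequence for record {self.seq_id!r}")
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ValueError(
                f"record {self.seq_id!r} contains non-IUPAC characters "
                f"{sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)
        if self.role not in ("reference", "query"):
            raise ValueError(f"role must be reference/query, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_fraction(self) -> float:
        return self.sequence.count("N") / len(self.sequence)


@dataclass
class QuerySample:
    """One market sample: vernacular name, putative taxa, per-marker sequences."""

    sample_id: str
    vernacular_name: str = ""
    putative_taxa: list[str] = field(default_factory=list)
    marker_seqs: dict[str, MarkerSequence] = field(default_factory=dict)

    @property
    def analyzable(self) -> bool:
        return bool(self.marker_seqs)


@dataclass(frozen=True)
class Identification:
    """A (rank, taxon) assignment produced by one method for one marker."""

    rank: str
    taxon: str
    method: str
    marker: str
    note: str = ""

    def __post_init__(self):
        if self.rank not in RANKS:
            raise ValueError(f"rank {self.rank!r} not in {RANKS}")
        if self.method not in METHODS:
            raise ValueError(f"method {self.method!r} not in {METHODS}")
        if (self.rank == "unidentified") != (self.taxon == ""):
            raise ValueError("taxon must be empty iff rank is unidentified")

    @property
    def identified(self) -> bool:
        return self.rank != "unidentified"


def unidentified(method: str, marker: str, note: str = "") -> Identification:
    return Identification("unidentified", "", method, marker, note)


CONCORDANCE_CLASSES = (
    "species_confirmed",
    "genus_confirmed",
    "family_confirmed",
    "different_species",
    "different_genus",
    "different_family",
    "previously_unknown",
    "unidentified",
)


@dataclass(frozen=True)
class ConcordanceRecord:
    """A sample's final identification versus its pharmacopoeia-derived name."""

    sample_id: str
    putative_taxa: tuple[str, ...]
    final_id: Identification
    concordance: str
    vernacular_name: str = ""
    final_text: str = ""

    def __post_init__(self):
        if self.concordance not in CONCORDANCE_CLASSES:
            raise ValueError(
                f"concordance {self.concordance!r} not in {CONCORDANCE_CLASSES}"
            )


@dataclass(frozen=True)
class FilterParams:
    """Reference-pool quality thresholds.

    Sequences longer than the marker cap (700 bp for the plastid loci,
    800 bp for ITS) or with more than ``max_n_fraction`` undetermined
    bases (Ns) are discarded before analysis; both comparisons are
    strict-greater, so a 700 bp plastid sequence or one with exactly 5%
    Ns is kept.
    """

    max_len_plastid: int = 700
    max_len_its: int = 800
    max_n_fraction: float = 0.05

    def __post_init__(self):
        if self.max_len_plastid <= 0 or self.max_len_its <= 0:
            raise ValueError("length caps must be positive")
        if not (0.0 < self.max_n_fraction < 1.0):
            raise ValueError("max_n_fraction must lie in (0, 1)")

    def max_len(self, marker: str) -> int:
        return self.max_len_plastid if normalize_marker(marker) in PLASTID_MARKERS else self.max_len_its
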