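"""Reading and writing the pipeline's file formats.

FASTA in/out goes through Biopython; tabular files (taxonomy, sample
metadata, the packaged market-identification table) are plain TSV read
with pandas.  All writers emit records in a deterministic order so that
a fixed seed reproduces byte-identical output files.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ConcordanceRecord,
    FilterParams,
    Identification,
    MarkerSequence,
    QuerySample,
    TaxonRecord,
    Taxonomy,
    is_binomial,
    normalize_marker,
    unidentified,
)

TAXONOMY_COLUMNS = ["species", "genus", "family", "major_clade", "occurs_in_region", "endemic"]


def load_fasta(path, marker: str, role: str = "reference") -> list[MarkerSequence]:
    """Read one marker's sequences from a FASTA file.

    The header token before the first whitespace becomes both ``seq_id``
    and ``owner_id``; sequences are uppercased and validated against the
    IUPAC nucleotide alphabet.
    """
    marker = normalize_marker(marker)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append(
                MarkerSequence(
                    seq_id=rec.id,
                    owner_id=rec.id,
                    marker=marker,
                    sequence=str(rec.seq),
                    role=role,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return out


def write_fasta(path, seqs: Iterable[MarkerSequence]) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.seq_id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def load_taxonomy(path) -> Taxonomy:
    """Read a taxonomy TSV (species/genus/family/major_clade/occurs_in_region/endemic)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(TAXONOMY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: taxonomy table lacks columns {sorted(missing)}")
    records = [
        TaxonRecord(
            species_name=row.species,
            genus=row.genus,
            family=row.family,
            major_clade=row.major_clade,
            occurs_in_region=str(row.occurs_in_region).lower() in ("true", "1", "yes"),
            endemic=str(row.endemic).lower() in ("true", "1", "yes"),
        )
        for row in df.itertuples()
    ]
    return Taxonomy(records)


def write_taxonomy(path, taxonomy: Taxonomy) -> None:
    rows = [
        {
            "species": r.species_name,
            "genus": r.genus,
            "family": r.family,
            "major_clade": r.major_clade,
            "occurs_in_region": r.occurs_in_region,
            "endemic": r.endemic,
        }
        for r in taxonomy
    ]
    pd.DataFrame(rows, columns=TAXONOMY_COLUMNS).rename(
        columns={"species": "species"}
    ).to_csv(path, sep="\t", index=False)


def filter_reference_pool(
    seqs: Iterable[MarkerSequence], params: FilterParams | None = None
) -> tuple[list[MarkerSequence], list[tuple[MarkerSequence, str]]]:
    """Apply the reference-pool quality filters.

    Returns ``(kept, removed)`` where each removed sequence carries a
    reason tag: ``"length"`` for sequences strictly longer than the
    marker cap, ``"n_fraction"`` for a fraction of Ns strictly above the
    threshold.  Length is checked first, so an over-long N-rich sequence
    is tagged ``"length"``.
    """
    params = params or FilterParams()
    kept, removed = [], []
    for s in seqs:
        if len(s) > params.max_len(s.marker):
            removed.append((s, "length"))
        elif s.n_fraction > params.max_n_fraction:
            removed.append((s, "n_fraction"))
        else:
            kept.append(s)
    return kept, removed


# --- packaged market-identification table ---------------------------------

_LABEL_MAP = {
    "species confirmed": "species_confirmed",
    "genus confirmed": "genus_confirmed",
    "family confirmed": "family_confirmed",
    "different species": "different_species",
    "different genus": "different_genus",
    "different family": "different_family",
    "previously unknown": "previously_unknown",
    "unidentified": "unidentified",
}


def _split_names(text: str) -> tuple[str, ...]:
    text = text.strip()
    if not text or text.lower() == "unidentified":
        return ()
    return tuple(part.strip() for part in text.split(";") if part.strip())


def _final_to_identification(text: str) -> Identification:
    """Interpret a printed final identification as a ranked assignment.

    A binomial (or list of candidate binomials) is species rank, a
    "Genus sp." form is genus rank, and a bare family name (-aceae) is
    family rank.  Multi-candidate finals keep the first candidate as the
    representative taxon; the full text is preserved on the record.
    """
    candidates = _split_names(text)
    if not candidates:
        return unidentified("consensus", "combined")
    first = candidates[0]
    if first.endswith("aceae") or first == "Poaceae":
        return Identification("family", first, "consensus", "combined")
    if first.endswith("sp."):
        genus = first.split()[0]
        return Identification("genus", genus, "consensus", "combined")
    if is_binomial(first):
        return Identification("species", first, "consensus", "combined")
    return Identification("genus", first.split()[0], "consensus", "combined")


def _data_text(name: str) -> str:
    return (
        importlib.resources.files("rootid").joinpath("data", name).read_text()
    )


def load_market_table() -> list[ConcordanceRecord]:
    """Load the packaged Marrakech market identification table (83 samples).

    Each row carries the sample's vernacular name, the pharmacopoeia-derived
    putative scientific name(s), the printed concordance label (which is
    authoritative for all tallies) and the final molecular identification.
    """
    import io as _io

    text = _data_text("marrakech_market_table.tsv")
    df = pd.read_csv(_io.StringIO(text), sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples():
        label = _LABEL_MAP.get(row.id_confirmed.strip().lower())
        if label is None:
            raise ValueError(
                f"market table row {row.sample_id}: unknown concordance "
                f"label {row.id_confirmed!r}"
            )
        records.append(
            ConcordanceRecord(
                sample_id=row.sample_id,
                putative_taxa=_split_names(row.putative_name),
                final_id=_final_to_identification(row.final_id),
                concordance=label,
                vernacular_name=row.vernacular_name,
                final_text=row.final_id,
            )
        )
    if len(records) != 83:
        raise ValueError(
            f"market table fixture corrupt: expected 83 rows, got {len(records)}"
        )
    return records


def load_market_table_skiplist() -> frozenset[str]:
    """Sample ids whose printed label is not mechanically re-derivable."""
    lines = _data_text("market_table_skiplist.txt").splitlines()
    return frozenset(
        ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")
    )
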