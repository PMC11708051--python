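"""Lineage model consulted by screening and gene-tree classification.

Every subject species seen in a homology hit table or a gene tree is mapped
to an ordered seven-rank lineage (domain, phylum, class, order, family,
genus, species).  Screening needs three things from it: whether a species is
part of the recipient's own kingdom (ingroup, here fungi), part of the
candidate donor pool (outgroup: bacteria, archaea, viruses, non-fungal
eukaryotes), or so close to the recipient that hits to it must be ignored
("self", by convention the recipient's genus).  Donor attribution reads the
phylum for bacteria and the domain otherwise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
DOMAINS = {"Bacteria", "Archaea", "Viruses", "Eukaryota"}

#: kingdom marker used to recognize ingroup taxa inside Eukaryota; synthetic
#: and real lineage tables place it in the phylum column prefix or class
FUNGAL_PHYLA = {
    "Ascomycota",
    "Basidiomycota",
    "Mucoromycota",
    "Zoopagomycota",
    "Chytridiomycota",
    "Blastocladiomycota",
    "Cryptomycota",
    "Microsporidia",
    "Fungi",  # generic marker accepted for synthetic worlds
}


class GroupLabel(enum.Enum):
    """Partition of hit/leaf species relative to the recipient genome."""

    INGROUP = "INGROUP"
    OUTGROUP = "OUTGROUP"
    SELF = "SELF"


class UnknownSpeciesError(KeyError):
    """Raised when a species has no lineage record."""

    def __init__(self, species: str):
        super().__init__(species)
        self.species = species

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"species not present in taxonomy: {self.species!r}"


@dataclass
class TaxonomyDB:
    """Rank-labelled lineage map.

    Parameters
    ----------
    lineages
        ``species -> tuple of 7 rank names`` (domain .. species).
    fungal_phyla
        Phylum names treated as fungal (ingroup) within Eukaryota.
    """

    lineages: dict[str, tuple[str, ...]]
    fungal_phyla: set[str] = field(default_factory=lambda: set(FUNGAL_PHYLA))

    # ------------------------------------------------------------------ io
    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyDB":
        """Load a lineage table: columns species, domain, phylum, class,
        order, family, genus (tab-separated, header required)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"species", "domain", "phylum", "class", "order", "family", "genus"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"lineage table missing columns: {sorted(missing)}")
        cols = ["domain", "phylum", "class", "order", "family", "genus"]
        lineages = {
            rec["species"]: (*(rec[c] for c in cols), rec["species"])
            for rec in df.to_dict("records")
        }
        return cls(lineages=lineages)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"species": sp, **dict(zip(RANKS[:-1], lin[:-1]))}
            for sp, lin in self.lineages.items()
        ]
        pd.DataFrame(rows, columns=["species", *RANKS[:-1]]).to_csv(
            path, sep="\t", index=False
        )

    # -------------------------------------------------------------- queries
    def validate(self, species: "pd.Series | list[str]") -> None:
        """Check that every species in ``species`` has a lineage."""
        known = self.lineages.keys()
        unknown = sorted({s for s in species if s not in known})
        if unknown:
            raise UnknownSpeciesError(unknown[0])

    def lineage(self, species: str) -> tuple[str, ...]:
        try:
            return self.lineages[species]
        except KeyError:
            raise UnknownSpeciesError(species) from None

    def is_fungal(self, species: str) -> bool:
        lin = self.lineage(species)
        return lin[0] == "Eukaryota" and lin[1] in self.fungal_phyla

    def genus(self, species: str) -> str:
        return self.lineage(species)[5]


def classify_species(db: TaxonomyDB, species: str, recipient: str) -> GroupLabel:
    """Assign SELF / INGROUP / OUTGROUP for ``species`` relative to the
    recipient genome's species.

    SELF is any species of the recipient's genus (self-hits would otherwise
    mask transfers when taking best ingroup hits); INGROUP is any other
    fungus; everything else — bacteria, archaea, viruses, and non-fungal
    eukaryotes — is OUTGROUP.
    """
    if db.genus(species) == db.genus(recipient):
        return GroupLabel.SELF
    if db.is_fungal(species):
        return GroupLabel.INGROUP
    return GroupLabel.OUTGROUP


def donor_group(db: TaxonomyDB, species: str) -> str:
    """Donor attribution label: phylum for bacteria, domain otherwise.

    Bacterial donors are reported at phylum resolution (Proteobacteria,
    Actinobacteria, ...); archaea, viruses and non-fungal eukaryotes are
    reported at domain level.
    """
    lin = db.lineage(species)
    if lin[0] == "Bacteria":
        return lin[1]
    return lin[0]


def shared_rank_fraction(db: TaxonomyDB, species: str, recipient: str) -> float:
    """Fraction (0..1) of shared lineage ranks between a hit species and the
    recipient, used as the lineage-coherence weight in LPI scoring.

    The six ranks domain..genus are compared top-down; sharing stops at the
    first mismatch.  A congeneric species scores 1; a species of another
    domain scores 0.
    """
    a = db.lineage(species)
    b = db.lineage(recipient)
    shared = 0
    for ra, rb in zip(a[:6], b[:6]):
        if ra != rb:
            break
        shared += 1
    return shared / 6.0
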