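"""Culture-collection rosters: strain records, name matching and overlap.

A roster is a list of deposited strains with taxonomic lineage.  Matching of
metagenomic taxon names against cultured species is synonym-aware: a small
:class:`SynonymMap` (symmetric closure of name pairs) resolves reclassified
binomials such as Phocaeicola vulgatus / Bacteroides vulgatus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .exceptions import ValidationError

# suffix qualifiers stripped during normalization ("Genus sp." -> "genus")
_QUALIFIER_TOKENS = {"sp.", "sp", "spp.", "spp"}

#: Synonym pairs shipped with the package (extendable via CSV).
DEFAULT_SYNONYM_PAIRS: tuple[tuple[str, str], ...] = (
    ("Phocaeicola vulgatus", "Bacteroides vulgatus"),
)


def normalize_name(name: str) -> str:
    """Normalize a taxon name for comparison.

    Case-folds, maps underscores to spaces, collapses internal whitespace and
    strips trailing "sp."-style qualifiers.  Abbreviated genus names are NOT
    expanded; inputs must carry full genus names.
    """
    tokens = name.replace("_", " ").split()
    while tokens and tokens[-1].lower() in _QUALIFIER_TOKENS:
        tokens.pop()
    return " ".join(t.casefold() for t in tokens)


class SynonymMap:
    """Symmetric (and transitively closed) equivalence of species names."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._group_of: dict[str, int] = {}
        self._members: dict[int, set[str]] = {}
        for a, b in pairs:
            self.add_pair(a, b)

    @classmethod
    def default(cls) -> "SynonymMap":
        return cls(DEFAULT_SYNONYM_PAIRS)

    @classmethod
    def from_csv(cls, path, include_defaults: bool = True) -> "SynonymMap":
        """Load two-column CSV (name_a, name_b); a header row is permitted."""
        syn = cls(DEFAULT_SYNONYM_PAIRS if include_defaults else ())
        with open(path, "r", encoding="utf-8", newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower() in {"name_a", "name-a"}:
                    continue
                if len(row) < 2:
                    raise ValidationError(f"synonym row needs two columns: {row!r}")
                syn.add_pair(row[0], row[1])
        return syn

    def add_pair(self, a: str, b: str) -> None:
        na, nb = normalize_name(a), normalize_name(b)
        if not na or not nb:
            raise ValidationError("synonym names must be non-empty")
        ga = self._group_of.get(na)
        gb = self._group_of.get(nb)
        if ga is None and gb is None:
            gid = len(self._members)
            self._members[gid] = {na, nb}
            self._group_of[na] = gid
            self._group_of[nb] = gid
        elif ga is None:
            self._members[gb].add(na)
            self._group_of[na] = gb
        elif gb is None:
            self._members[ga].add(nb)
            self._group_of[nb] = ga
        elif ga != gb:
            # merge the two equivalence classes
            for name in self._members.pop(gb):
                self._group_of[name] = ga
                self._members[ga].add(name)

    def expand(self, name: str) -> frozenset[str]:
        """All normalized names equivalent to ``name`` (always includes itself)."""
        n = normalize_name(name)
        gid = self._group_of.get(n)
        if gid is None:
            return frozenset({n})
        return frozenset(self._members[gid])

    def equivalent(self, a: str, b: str) -> bool:
        return normalize_name(b) in self.expand(a)


@dataclass(frozen=True)
class StrainRecord:
    """One deposited strain with its taxonomic lineage."""

    strain_id: str
    species: str
    genus: str = ""
    family: str = ""
    phylum: str = ""
    novel: bool = False
    deposit_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.species.strip():
            raise ValidationError(f"strain {self.strain_id!r} has an empty species name")
        if not self.genus:
            object.__setattr__(self, "genus", self.species.split()[0])


class BiobankRoster:
    """A named collection of strain records with unique strain IDs."""

    def __init__(self, name: str, strains: Sequence[StrainRecord]):
        ids = [s.strain_id for s in strains]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate strain_id(s) in roster {name!r}: {dupes}")
        self.name = name
        self.strains = list(strains)
        self._species_by_norm: dict[str, str] = {}
        self._genus_by_norm: dict[str, str] = {}
        for s in self.strains:
            self._species_by_norm.setdefault(normalize_name(s.species), s.species)
            self._genus_by_norm.setdefault(normalize_name(s.genus), s.genus)

    @property
    def species_names(self) -> list[str]:
        seen: dict[str, str] = {}
        for s in self.strains:
            seen.setdefault(normalize_name(s.species), s.species)
        return list(seen.values())

    @property
    def genus_names(self) -> list[str]:
        return list(self._genus_by_norm.values())

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "BiobankRoster":
        """Load a roster CSV with header:
        strain_id, species, genus, family, phylum, novel, deposits.
        """
        strains = []
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "strain_id" not in reader.fieldnames:
                raise ValidationError(f"roster CSV {path} must have a header with 'strain_id'")
            for row in reader:
                deposits = tuple(
                    d for d in (row.get("deposits") or "").split(";") if d.strip()
                )
                strains.append(
                    StrainRecord(
                        strain_id=row["strain_id"].strip(),
                        species=row["species"].strip(),
                        genus=(row.get("genus") or "").strip(),
                        family=(row.get("family") or "").strip(),
                        phylum=(row.get("phylum") or "").strip(),
                        novel=(row.get("novel") or "").strip().lower() in {"true", "1", "yes"},
                        deposit_ids=deposits,
                    )
                )
        return cls(name or str(path), strains)

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["strain_id", "species", "genus", "family", "phylum", "novel", "deposits"])
            for s in self.strains:
                writer.writerow(
                    [
                        s.strain_id,
                        s.species,
                        s.genus,
                        s.family,
                        s.phylum,
                        str(s.novel).lower(),
                        ";".join(s.deposit_ids),
                    ]
                )


def roster_summarize(roster: BiobankRoster) -> dict[str, int]:
    """Counts of strains and of distinct names per rank, plus novel species."""
    species = {normalize_name(s.species) for s in roster.strains}
    genera = {normalize_name(s.genus) for s in roster.strains if s.genus}
    families = {normalize_name(s.family) for s in roster.strains if s.family}
    phyla = {normalize_name(s.phylum) for s in roster.strains if s.phylum}
    novel = {normalize_name(s.species) for s in roster.strains if s.novel}
    return {
        "strains": len(roster.strains),
        "species": len(species),
        "genera": len(genera),
        "families": len(families),
        "phyla": len(phyla),
        "novel_species": len(novel),
    }


def match_taxon(
    name: str,
    roster: BiobankRoster,
    syn: SynonymMap | None = None,
    rank: str = "species",
) -> str | None:
    """Match a metagenomic taxon name against the roster.

    Species-rank queries match cultured species directly or through the
    synonym map; genus-rank queries match the roster's genus-name set.
    Returns the roster's spelling of the matched name, or None.
    """
    if not normalize_name(name):
        raise ValidationError("cannot match an empty taxon name")
    syn = syn or SynonymMap()
    if rank == "genus":
        for candidate in syn.expand(name):
            hit = roster._genus_by_norm.get(candidate)
            if hit is not None:
                return hit
        return None
    if rank != "species":
        raise ValidationError(f"rank must be 'species' or 'genus', got {rank!r}")
    for candidate in syn.expand(name):
        hit = roster._species_by_norm.get(candidate)
        if hit is not None:
            return hit
    return None


@dataclass(frozen=True)
class CrossBiobankResult:
    """Species unique to the target roster relative to a union of others."""

    unique_species: tuple[str, ...]
    others_union_size: int


def cross_biobank_unique(
    target: BiobankRoster,
    others: Sequence[Iterable[str]],
    syn: SynonymMap | None = None,
) -> CrossBiobankResult:
    """Target species with no synonym-aware match in the union of other rosters."""
    syn = syn or SynonymMap()
    union: set[str] = set()
    for name_set in others:
        union.update(normalize_name(n) for n in name_set)
    unique = [
        sp
        for sp in target.species_names
        if not (syn.expand(sp) & union)
    ]
    return CrossBiobankResult(unique_species=tuple(sorted(unique)), others_union_size=len(union))
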