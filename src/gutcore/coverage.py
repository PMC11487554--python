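"""Coverage of a metagenomic taxon profile by a culture collection.

Three views: stratified count coverage (what fraction of the detected taxa in
an abundance stratum have a cultured representative), the cultured-but-
undetected complement, and abundance-mass coverage (the share of total
relative-abundance mass carried by roster-matched taxa).  Percentages are
reported to one decimal using half-away-from-zero rounding in exact integer
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .abundance import (
    STRATA,
    STRATUM_HIGH,
    STRATUM_LOW,
    STRATUM_MEDIUM,
    AbundanceTable,
    StrataConfig,
    TaxonProfile,
)
from .exceptions import UndefinedPercentError, ValidationError
from .roster import BiobankRoster, SynonymMap, match_taxon, normalize_name

STRATUM_ALL = "all"


def round1(numerator: int, denominator: int) -> float:
    """One-decimal percentage 100*n/d, rounded half away from zero.

    Pure integer arithmetic scaled by 10 — no floating-point rounding is
    involved, so 145/280 -> 51.8 and 25/26 -> 96.2 exactly.
    """
    if denominator <= 0:
        raise UndefinedPercentError(f"denominator must be positive, got {denominator}")
    scaled = 1000 * numerator
    q, r = divmod(abs(scaled), denominator)
    if 2 * r >= denominator:
        q += 1
    return (-q if scaled < 0 else q) / 10.0


@dataclass(frozen=True)
class CoverageReport:
    """Covered/total counts for one (rank, stratum) with a one-decimal percent."""

    rank: str
    stratum: str
    covered: int
    total: int
    percent: float | None
    uncovered_taxa: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "stratum": self.stratum,
            "covered": self.covered,
            "total": self.total,
            "percent": self.percent,
            "uncovered_taxa": list(self.uncovered_taxa),
        }


@dataclass(frozen=True)
class UndetectedReport:
    """Cultured species absent from the metagenomically detected set."""

    cultured_total: int
    undetected: tuple[str, ...]
    percent: float

    def to_dict(self) -> dict:
        return {
            "cultured_total": self.cultured_total,
            "undetected": list(self.undetected),
            "percent": self.percent,
        }


def _in_stratum(profile_stratum: str, selector: str) -> bool:
    # medium_above is nested: it includes the high stratum
    if selector == STRATUM_ALL:
        return True
    if selector == STRATUM_MEDIUM:
        return profile_stratum in (STRATUM_MEDIUM, STRATUM_HIGH)
    if selector in (STRATUM_LOW, STRATUM_HIGH):
        return profile_stratum == selector
    raise ValidationError(f"unknown stratum selector {selector!r}")


def stratified_coverage(
    profiles: Sequence[TaxonProfile],
    roster: BiobankRoster,
    syn: SynonymMap | None = None,
    cfg: StrataConfig | None = None,
    stratum: str = STRATUM_ALL,
    rank: str = "species",
) -> CoverageReport:
    """Coverage of the profiles falling in ``stratum`` by the roster.

    ``stratum='medium_above'`` includes the high stratum (nested strata).
    ``percent`` is None when the stratum is empty.
    """
    syn = syn or SynonymMap()
    for p in profiles:
        if p.rank != rank:
            raise ValidationError(
                f"profile for {p.taxon!r} has rank {p.rank!r}, expected {rank!r}"
            )
    selected = [p for p in profiles if _in_stratum(p.stratum, stratum)]
    uncovered = sorted(
        p.taxon for p in selected if match_taxon(p.taxon, roster, syn, rank=rank) is None
    )
    total = len(selected)
    covered = total - len(uncovered)
    percent = round1(covered, total) if total > 0 else None
    return CoverageReport(
        rank=rank,
        stratum=stratum,
        covered=covered,
        total=total,
        percent=percent,
        uncovered_taxa=tuple(uncovered),
    )


def undetected_cultured(
    roster: BiobankRoster,
    detected_species: Iterable[str],
    syn: SynonymMap | None = None,
) -> UndetectedReport:
    """Roster species with no synonym-aware match in the detected set."""
    syn = syn or SynonymMap()
    detected_norm = {normalize_name(n) for n in detected_species}
    species = roster.species_names
    undetected = sorted(sp for sp in species if not (syn.expand(sp) & detected_norm))
    total = len(species)
    percent = round1(len(undetected), total) if total > 0 else 0.0
    return UndetectedReport(
        cultured_total=total, undetected=tuple(undetected), percent=percent
    )


def mass_coverage(
    table: AbundanceTable,
    roster: BiobankRoster,
    syn: SynonymMap | None = None,
) -> float:
    """Percent of total abundance mass carried by roster-matched taxa.

    A taxon-level approximation of sequence-level coverage; it is NOT a
    read-mapping statistic.
    """
    syn = syn or SynonymMap()
    matched = np.array(
        [match_taxon(t, roster, syn, rank=table.rank) is not None for t in table.taxa]
    )
    total = float(table.values.sum())
    if total == 0:
        raise ValidationError("table has zero total abundance mass")
    return 100.0 * float(table.values[matched].sum()) / total
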