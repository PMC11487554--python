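"""Relative-abundance tables and per-taxon summary profiles.

The central object is :class:`AbundanceTable`, a taxa x samples matrix of
relative abundances in percent units.  Columns of a normalized table are
compositional: each sample sums to 100.  Profiles summarize a taxon by its
mean relative abundance over *all* samples (zeros included) and its
prevalence (frequency of occurrence), both in percent, and assign an
abundance stratum (low / medium_above / high) with inclusive thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateSampleError,
    TaxonNameError,
    UnknownTaxonError,
    ValidationError,
)

CLOSURE_TOTAL = 100.0
CLOSURE_RTOL = 1e-9

STRATUM_LOW = "low"
STRATUM_MEDIUM = "medium_above"
STRATUM_HIGH = "high"
STRATA = (STRATUM_LOW, STRATUM_MEDIUM, STRATUM_HIGH)

RANK_SPECIES = "species"
RANK_GENUS = "genus"


@dataclass(frozen=True)
class StrataConfig:
    """Thresholds (percent units) controlling strata, prevalence and detection.

    All cuts are inclusive (``>=``): a mean relative abundance of exactly
    ``medium_cut`` places a taxon in the medium_above stratum.
    ``detection_threshold`` is strict: a taxon is present in a sample when its
    abundance is strictly greater than the threshold.
    """

    medium_cut: float = 0.2
    high_cut: float = 1.0
    prevalence_cut: float = 80.0
    detection_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.detection_threshold < self.medium_cut < self.high_cut <= 100):
            raise ValidationError(
                "require 0 <= detection_threshold < medium_cut < high_cut <= 100, got "
                f"({self.detection_threshold}, {self.medium_cut}, {self.high_cut})"
            )
        if not (0 < self.prevalence_cut <= 100):
            raise ValidationError(f"prevalence_cut must be in (0, 100], got {self.prevalence_cut}")

    def stratum_of(self, mean_ra: float) -> str:
        if mean_ra >= self.high_cut:
            return STRATUM_HIGH
        if mean_ra >= self.medium_cut:
            return STRATUM_MEDIUM
        return STRATUM_LOW


@dataclass(frozen=True)
class TaxonProfile:
    """Summary statistics for one taxon across a cohort.

    ``mean_ra`` and ``prevalence`` are percent; ``prevalence`` is the paper
    convention often called FO (frequency of occurrence).
    """

    taxon: str
    mean_ra: float
    prevalence: float
    stratum: str
    rank: str = RANK_SPECIES


class AbundanceTable:
    """Taxa x samples matrix of relative abundances in percent.

    Parameters
    ----------
    taxa
        Ordered taxon identifiers, unique within the table's rank.
    samples
        Ordered sample identifiers, unique.
    values
        Nonnegative matrix of shape ``(len(taxa), len(samples))``.
    rank
        ``"species"`` or ``"genus"``.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        samples: Sequence[str],
        values: np.ndarray,
        rank: str = RANK_SPECIES,
    ):
        taxa = list(taxa)
        samples = list(samples)
        values = np.asarray(values, dtype=float)
        if rank not in (RANK_SPECIES, RANK_GENUS):
            raise ValidationError(f"rank must be 'species' or 'genus', got {rank!r}")
        if len(taxa) == 0 or len(samples) == 0:
            raise ValidationError("table requires at least one taxon and one sample")
        if values.shape != (len(taxa), len(samples)):
            raise ValidationError(
                f"values shape {values.shape} does not match ({len(taxa)}, {len(samples)})"
            )
        if len(set(taxa)) != len(taxa):
            raise ValidationError("taxon identifiers must be unique within a rank")
        if len(set(samples)) != len(samples):
            raise ValidationError("sample identifiers must be unique")
        if not np.all(np.isfinite(values)):
            raise ValidationError("abundance values must be finite")
        if np.any(values < 0):
            raise ValidationError("abundance values must be nonnegative")
        self.taxa = taxa
        self.samples = samples
        self.values = values
        self.rank = rank
        self._index = {t: i for i, t in enumerate(taxa)}

    # -- basic protocol ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.values[self._index[taxon]]
        except KeyError:
            raise UnknownTaxonError(taxon) from None

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def column_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def is_normalized(self, rtol: float = CLOSURE_RTOL) -> bool:
        return bool(np.allclose(self.column_sums(), CLOSURE_TOTAL, rtol=rtol, atol=0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.samples)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path, rank: str | None = None) -> "AbundanceTable":
        """Read a TSV table: first column ``taxon``, remaining columns samples.

        ``#``-prefixed comment lines are ignored, except a pragma line
        ``#rank=species`` or ``#rank=genus`` which declares the rank when the
        ``rank`` argument is not given.
        """
        pragma_rank = None
        with open(path, "r", encoding="utf-8") as fh:
            lines = []
            for line in fh:
                if line.startswith("#"):
                    stripped = line[1:].strip()
                    if stripped.startswith("rank="):
                        pragma_rank = stripped.split("=", 1)[1].strip()
                    continue
                lines.append(line)
        if not lines:
            raise ValidationError(f"no data rows in {path}")
        from io import StringIO

        df = pd.read_csv(
            StringIO("".join(lines)), sep="\t", index_col=0, float_precision="round_trip"
        )
        resolved = rank or pragma_rank or RANK_SPECIES
        return cls(
            taxa=[str(t) for t in df.index],
            samples=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            rank=resolved,
        )

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"#rank={self.rank}\n")
            fh.write("taxon\t" + "\t".join(self.samples) + "\n")
            for i, taxon in enumerate(self.taxa):
                row = "\t".join(repr(float(v)) for v in self.values[i])
                fh.write(f"{taxon}\t{row}\n")


def normalize_to_relative(table: AbundanceTable) -> AbundanceTable:
    """Close each sample column to 100%.

    Raises :class:`DegenerateSampleError` for any all-zero sample column
    rather than silently propagating NaNs.  Idempotent on already-normalized
    tables (up to 1e-9 relative tolerance).
    """
    totals = table.column_sums()
    zero = np.nonzero(totals == 0)[0]
    if zero.size:
        raise DegenerateSampleError(table.samples[int(zero[0])])
    # divide before scaling: each quotient is <= 1, so tiny (even subnormal)
    # column totals cannot overflow
    values = (table.values / totals) * CLOSURE_TOTAL
    return AbundanceTable(table.taxa, table.samples, values, rank=table.rank)


def taxon_profile(table: AbundanceTable, taxon: str, cfg: StrataConfig) -> TaxonProfile:
    """Profile one taxon: cohort mean R.A., prevalence (FO) and stratum.

    The mean is the arithmetic mean over *all* samples, zeros included.
    Prevalence counts samples with abundance strictly above
    ``cfg.detection_threshold``.
    """
    row = table.row(taxon)
    mean_ra = float(row.mean())
    prevalence = 100.0 * float(np.count_nonzero(row > cfg.detection_threshold)) / table.n_samples
    return TaxonProfile(
        taxon=taxon,
        mean_ra=mean_ra,
        prevalence=prevalence,
        stratum=cfg.stratum_of(mean_ra),
        rank=table.rank,
    )


def profile_all(table: AbundanceTable, cfg: StrataConfig) -> list[TaxonProfile]:
    """Profile every taxon in the table (vectorized equivalent of per-taxon calls)."""
    means = table.values.mean(axis=1)
    prev = 100.0 * (table.values > cfg.detection_threshold).sum(axis=1) / table.n_samples
    return [
        TaxonProfile(t, float(m), float(p), cfg.stratum_of(float(m)), rank=table.rank)
        for t, m, p in zip(table.taxa, means, prev)
    ]


def genus_of(species: str, annotations: Mapping[str, str] | None = None) -> str:
    """Genus of a species identifier: explicit annotation, else first token."""
    if annotations and species in annotations:
        return annotations[species]
    tokens = species.split()
    if len(tokens) < 2:
        raise TaxonNameError(
            f"cannot derive genus from non-binomial identifier {species!r}; "
            "provide an explicit genus annotation"
        )
    return tokens[0]


def aggregate_to_genus(
    table: AbundanceTable, annotations: Mapping[str, str] | None = None
) -> AbundanceTable:
    """Sum species rows into genus rows; column sums are conserved."""
    if table.rank != RANK_SPECIES:
        raise ValidationError("aggregate_to_genus requires a species-rank table")
    genera: list[str] = []
    index: dict[str, int] = {}
    out_rows: list[np.ndarray] = []
    for i, species in enumerate(table.taxa):
        g = genus_of(species, annotations)
        if g not in index:
            index[g] = len(genera)
            genera.append(g)
            out_rows.append(table.values[i].copy())
        else:
            out_rows[index[g]] += table.values[i]
    return AbundanceTable(genera, table.samples, np.vstack(out_rows), rank=RANK_GENUS)
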