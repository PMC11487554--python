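"""Dual-threshold core-taxon extraction.

A taxon is *dominant* when its cohort-mean relative abundance meets the
medium cut, *common* when its prevalence (FO) meets the prevalence cut, and
*core* when it is both.  Both gates are inclusive (>=).  The ranked core list
orders by mean relative abundance descending with an alphabetical tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import AbundanceTable, StrataConfig, profile_all
from .exceptions import ValidationError


@dataclass(frozen=True)
class CoreResult:
    """Per-taxon dominance/commonness/core flags plus the ranked core list."""

    taxa: tuple[str, ...]
    mean_ra: np.ndarray
    prevalence: np.ndarray
    dominant: np.ndarray
    common: np.ndarray
    core: np.ndarray
    rank: str

    @property
    def core_taxa(self) -> tuple[str, ...]:
        """Core taxa ordered by (mean_ra desc, name asc)."""
        entries = [
            (t, float(m))
            for t, m, c in zip(self.taxa, self.mean_ra, self.core)
            if c
        ]
        entries.sort(key=lambda e: (-e[1], e[0]))
        return tuple(t for t, _ in entries)

    @property
    def n_dominant(self) -> int:
        return int(self.dominant.sum())

    @property
    def n_common(self) -> int:
        return int(self.common.sum())

    @property
    def n_core(self) -> int:
        return int(self.core.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": list(self.taxa),
                "mean_ra": self.mean_ra,
                "FO": self.prevalence,
                "dominant": self.dominant,
                "common": self.common,
                "core": self.core,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, lineterminator="\n")


def extract_core(table: AbundanceTable, cfg: StrataConfig | None = None) -> CoreResult:
    """Flag dominant, common and core taxa of a normalized abundance table."""
    cfg = cfg or StrataConfig()
    if not table.is_normalized(rtol=1e-6):
        raise ValidationError("extract_core requires a normalized table (columns sum to 100)")
    profiles = profile_all(table, cfg)
    mean_ra = np.array([p.mean_ra for p in profiles])
    prevalence = np.array([p.prevalence for p in profiles])
    dominant = mean_ra >= cfg.medium_cut
    common = prevalence >= cfg.prevalence_cut
    return CoreResult(
        taxa=tuple(table.taxa),
        mean_ra=mean_ra,
        prevalence=prevalence,
        dominant=dominant,
        common=common,
        core=dominant & common,
        rank=table.rank,
    )


def top_core(result: CoreResult, k: int) -> tuple[str, ...]:
    """First ``min(k, n_core)`` core taxa by the ranking rule."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    return result.core_taxa[:k]
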