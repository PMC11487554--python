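"""Taxon-clinical association and two-cohort comparison.

Spearman rank correlation (mid-ranks for ties; exact permutation p for small
n, t-approximation otherwise) associates core-taxon abundances with clinical
indices; the Wilcoxon rank-sum test (exact enumeration for small groups,
tie- and continuity-corrected normal approximation otherwise) compares taxa
between cohorts.  Significance stars follow the strict-inequality convention
p < 0.05/0.01/0.001/0.0001 -> * / ** / *** / ****.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable
from .core import CoreResult
from .exceptions import (
    AlignmentError,
    InsufficientDataError,
    UndefinedCorrelationError,
    ValidationError,
)

SPEARMAN_EXACT_MAX_N = 10
WILCOXON_EXACT_MAX_MIN_N = 8
_WILCOXON_EXACT_MAX_LABELINGS = 500_000
_PERM_CHUNK = 100_000


class ClinicalTable:
    """Per-sample clinical indices, optionally with a two-level cohort label.

    ``data`` is a samples x indices float frame; NaN marks missing values.
    """

    def __init__(self, data: pd.DataFrame, cohort: pd.Series | None = None):
        if data.index.has_duplicates:
            raise ValidationError("clinical sample IDs must be unique")
        self.data = data.astype(float)
        self.cohort = cohort

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def indices(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @classmethod
    def from_tsv(cls, path) -> "ClinicalTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        cohort = None
        if "cohort" in df.columns:
            cohort = df.pop("cohort").astype(str)
        return cls(df, cohort)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        if self.cohort is not None:
            out["cohort"] = self.cohort
        out.index.name = "sample"
        out.to_csv(path, sep="\t", lineterminator="\n")


def star_annotation(p_value: float) -> str:
    """Map a p-value to the star convention (strict inequalities)."""
    if not (0 < p_value <= 1):
        raise ValidationError(f"p-value must be in (0, 1], got {p_value}")
    if p_value < 0.0001:
        return "****"
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def _drop_missing_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be paired 1-D vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by full enumeration of rank permutations of y."""
    n = rx.size
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt(float(cx @ cx) * float(cy @ cy))
    thresh = abs(rho_obs) - 1e-12
    count = 0
    total = math.factorial(n)
    perm_iter = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perm_iter, _PERM_CHUNK))
        if not chunk:
            break
        P = np.array(chunk, dtype=np.intp)
        s = cy[P] @ cx
        count += int(np.count_nonzero(np.abs(s / denom) >= thresh))
    return count / total


def spearman_assoc(x, y) -> tuple[float, float, int]:
    """Spearman correlation of paired vectors with missing-pair deletion.

    Returns ``(rho, p_value, n_used)``.  rho is the Pearson correlation of
    mid-ranks.  The two-sided p comes from exact permutation enumeration for
    n_used <= 10 and from the t-approximation otherwise.
    """
    x, y = _drop_missing_pairs(x, y)
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need at least 4 complete pairs, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("zero variance in a ranked vector")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_MAX_N:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        # t-approximation with n-2 degrees of freedom
        if abs(rho) >= 1.0:
            p = float(np.nextafter(0, 1))  # keep p in (0, 1]
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = 2 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0), n


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided rank-sum comparison of one taxon between two cohorts."""

    statistic: float  # rank sum of group a
    p_value: float
    direction: str  # 'higher-in-a' | 'higher-in-b' | 'none'
    star: str
    exact: bool


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided p by enumeration of all group-a labelings (symmetric deviation)."""
    n = ranks.size
    mu = ranks.sum() * n_a / n
    dev_obs = abs(w_obs - mu) - 1e-9
    total = math.comb(n, n_a)
    count = 0
    combo_iter = itertools.combinations(range(n), n_a)
    while True:
        chunk = list(itertools.islice(combo_iter, _PERM_CHUNK))
        if not chunk:
            break
        C = np.array(chunk, dtype=np.intp)
        w = ranks[C].sum(axis=1)
        count += int(np.count_nonzero(np.abs(w - mu) >= dev_obs))
    return count / total


def wilcoxon_compare(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum comparison of two independent groups.

    The null is enumerated exactly (on mid-ranks, so ties are handled) when
    the smaller group has <= 8 observations and the number of labelings is
    tractable; otherwise a normal approximation with tie correction and
    continuity correction is used.  Direction is decided by median difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n_a, n_b = a.size, b.size
    if min(n_a, n_b) < 3:
        raise InsufficientDataError(f"each group needs >= 3 observations, got {n_a} and {n_b}")
    n = n_a + n_b
    ranks = stats.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n_a].sum())
    exact = min(n_a, n_b) <= WILCOXON_EXACT_MAX_MIN_N and (
        math.comb(n, n_a) <= _WILCOXON_EXACT_MAX_LABELINGS
    )
    if exact:
        p = _exact_ranksum_p(ranks, n_a, w)
    else:
        mu = n_a * (n + 1) / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = max(abs(w - mu) - 0.5, 0.0) / math.sqrt(var)
            p = min(2 * float(stats.norm.sf(z)), 1.0)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        direction = "higher-in-a"
    elif med_a < med_b:
        direction = "higher-in-b"
    else:
        direction = "none"
    return WilcoxonResult(
        statistic=w,
        p_value=p,
        direction=direction,
        star=star_annotation(p),
        exact=exact,
    )


@dataclass(frozen=True)
class AssociationResult:
    """Long-format (taxon, index) association matrix."""

    frame: pd.DataFrame  # columns: taxon, index, rho, p, q, n_used, star

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")

    def to_json_matrix(self) -> str:
        """Nested {taxon: {index: {rho, p, q, n_used, star}}} JSON string."""
        matrix: dict[str, dict] = {}
        for taxon, index_name, rho, p, q, n_used, star in self.frame.itertuples(index=False):
            cell = {
                "rho": None if pd.isna(rho) else rho,
                "p": None if pd.isna(p) else p,
                "q": None if pd.isna(q) else q,
                "n_used": int(n_used),
                "star": star,
            }
            matrix.setdefault(taxon, {})[index_name] = cell
        return json.dumps(matrix, indent=1, sort_keys=True)


def associate_all(
    table: AbundanceTable,
    core: CoreResult,
    clinical: ClinicalTable,
    correction: str = "none",
) -> AssociationResult:
    """One Spearman association per (core taxon, clinical index).

    Samples are aligned by ID; missing clinical values are dropped pairwise
    per cell, and ``n_used`` records the pairs actually correlated.  With
    ``correction='BH'`` a Benjamini-Hochberg q-value is computed across the
    full matrix; the default is uncorrected (q = NaN).
    """
    if correction not in ("none", "BH"):
        raise ValidationError(f"correction must be 'none' or 'BH', got {correction!r}")
    clinical_samples = set(clinical.samples)
    shared = [s for s in table.samples if s in clinical_samples]
    if not shared:
        raise AlignmentError("no overlapping samples between abundance and clinical tables")
    col_idx = [table.samples.index(s) for s in shared]
    rows = []
    for taxon in core.core_taxa:
        x_full = table.row(taxon)[col_idx]
        for index_name in clinical.indices:
            y_full = clinical.data.loc[shared, index_name].to_numpy(dtype=float)
            keep = ~np.isnan(y_full)
            try:
                rho, p, n_used = spearman_assoc(x_full[keep], y_full[keep])
                star = star_annotation(p)
            except (InsufficientDataError, UndefinedCorrelationError):
                rho, p, n_used, star = np.nan, np.nan, int(keep.sum()), ""
            rows.append((taxon, index_name, rho, p, n_used, star))
    frame = pd.DataFrame(rows, columns=["taxon", "index", "rho", "p", "n_used", "star"])
    frame["q"] = np.nan
    if correction == "BH":
        from statsmodels.stats.multitest import multipletests

        mask = frame["p"].notna().to_numpy()
        if mask.any():
            _, q, _, _ = multipletests(frame.loc[mask, "p"], method="fdr_bh")
            frame.loc[mask, "q"] = q
    frame = frame[["taxon", "index", "rho", "p", "q", "n_used", "star"]]
    return AssociationResult(frame=frame)
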