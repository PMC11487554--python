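"""Seeded synthetic two-cohort generator with planted ground truth.

The generative model is zero-inflated log-normal: taxon i occurs in a sample
with probability pi_i and, when present, draws a latent abundance from
LogNormal(mu_i, sigma_i); sample columns are then closed to 100%.  Planted
structure — core taxa, cohort-differential taxa (a fold multiplier in cohort
B), and monotone taxon-index associations built on rank scores — is recorded
in a truth record holding only generator parameters, never analyzer output,
so recovery checks cannot be tautological.

One global seed feeds a splittable stream per artifact (cohort A, cohort B,
clinical, roster): adding artifacts never perturbs earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import RANK_SPECIES, AbundanceTable, StrataConfig, normalize_to_relative
from .association import ClinicalTable, spearman_assoc, wilcoxon_compare
from .core import extract_core
from .exceptions import ValidationError
from .roster import BiobankRoster, StrainRecord


@dataclass(frozen=True)
class PlantedAssociation:
    """A monotone taxon-index effect: index = slope * rank-score + noise."""

    taxon_index: int
    index_name: str
    slope: float
    noise_sd: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the cohort simulator.

    ``occurrence_probs``, ``lognormal_mu`` and ``lognormal_sigma`` are
    per-taxon arrays of length ``n_taxa``.  ``planted_differential`` maps
    taxon index -> fold multiplier applied in cohort B.  Identical spec and
    seed yield byte-identical outputs.
    """

    n_taxa: int
    n_samples_a: int
    n_samples_b: int
    occurrence_probs: tuple[float, ...]
    lognormal_mu: tuple[float, ...]
    lognormal_sigma: tuple[float, ...]
    planted_core: tuple[int, ...] = ()
    planted_differential: tuple[tuple[int, float], ...] = ()
    planted_assoc: tuple[PlantedAssociation, ...] = ()
    clinical_indices: tuple[str, ...] = ("ESR", "CRP", "anti_CCP")
    roster_fraction: float = 0.6
    n_extra_roster_species: int = 0
    n_genera: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 1:
            raise ValidationError(f"n_taxa must be >= 1, got {self.n_taxa}")
        if self.n_samples_a < 1 or self.n_samples_b < 0:
            raise ValidationError("need n_samples_a >= 1 and n_samples_b >= 0")
        for name in ("occurrence_probs", "lognormal_mu", "lognormal_sigma"):
            arr = getattr(self, name)
            if len(arr) != self.n_taxa:
                raise ValidationError(f"{name} must have length n_taxa={self.n_taxa}")
        probs = np.asarray(self.occurrence_probs, dtype=float)
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValidationError("occurrence probabilities must lie in [0, 1]")
        if np.any(np.asarray(self.lognormal_sigma, dtype=float) <= 0):
            raise ValidationError("lognormal sigma values must be positive")
        if not (0 <= self.roster_fraction <= 1):
            raise ValidationError(f"roster_fraction must be in [0, 1], got {self.roster_fraction}")
        if self.n_extra_roster_species < 0:
            raise ValidationError("n_extra_roster_species must be >= 0")
        for idx in self.planted_core:
            if not (0 <= idx < self.n_taxa):
                raise ValidationError(f"planted_core index {idx} out of range")
        for idx, fold in self.planted_differential:
            if not (0 <= idx < self.n_taxa):
                raise ValidationError(f"planted_differential index {idx} out of range")
            if fold <= 0 or fold == 1:
                raise ValidationError(f"fold multiplier must be positive and != 1, got {fold}")
        for pa in self.planted_assoc:
            if not (0 <= pa.taxon_index < self.n_taxa):
                raise ValidationError(f"planted_assoc taxon index {pa.taxon_index} out of range")
            if pa.index_name not in self.clinical_indices:
                raise ValidationError(f"planted_assoc index {pa.index_name!r} not declared")
            if pa.noise_sd < 0:
                raise ValidationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Planted structure by taxon *name* (parameters only, no analyzer output)."""

    core_taxa: tuple[str, ...]
    differential: tuple[tuple[str, float], ...]
    associations: tuple[tuple[str, str, float], ...]  # (taxon, index, slope)
    taxa: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


@dataclass(frozen=True)
class SimulationResult:
    table_a: AbundanceTable
    table_b: AbundanceTable | None
    clinical: ClinicalTable
    roster: BiobankRoster
    truth: TruthRecord


@dataclass(frozen=True)
class RecoveryReport:
    """Fractions of planted structure recovered by the analysis chain.

    Fields are None when the corresponding planted set is empty.
    """

    core_recovered_fraction: float | None
    core_exact: bool | None
    differential_detected_fraction: float | None
    association_detected_fraction: float | None
    false_positive_core: int


def _taxon_names(spec: SyntheticSpec) -> list[str]:
    n_genera = spec.n_genera or max(1, spec.n_taxa // 3)
    return [f"Genus{i % n_genera:03d} epithet{i:04d}" for i in range(spec.n_taxa)]


def _draw_cohort(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    n_samples: int,
    sample_prefix: str,
    fold: np.ndarray,
) -> AbundanceTable:
    """Zero-inflated log-normal draws, columns closed to 100%."""
    pi = np.asarray(spec.occurrence_probs, dtype=float)
    mu = np.asarray(spec.lognormal_mu, dtype=float)
    sigma = np.asarray(spec.lognormal_sigma, dtype=float)
    shape = (spec.n_taxa, n_samples)
    present = rng.random(shape) < pi[:, None]
    latent = rng.lognormal(mean=mu[:, None], sigma=sigma[:, None], size=shape)
    values = np.where(present, latent * fold[:, None], 0.0)
    # a sample where every taxon is absent cannot be closed; redraw it
    for _ in range(1000):
        empty = values.sum(axis=0) == 0
        if not empty.any():
            break
        k = int(empty.sum())
        re_present = rng.random((spec.n_taxa, k)) < pi[:, None]
        re_latent = rng.lognormal(mean=mu[:, None], sigma=sigma[:, None], size=(spec.n_taxa, k))
        values[:, empty] = np.where(re_present, re_latent * fold[:, None], 0.0)
    else:
        raise ValidationError("could not draw non-empty samples; occurrence probabilities too low")
    samples = [f"{sample_prefix}{j:04d}" for j in range(n_samples)]
    raw = AbundanceTable(_taxon_names(spec), samples, values, rank=RANK_SPECIES)
    return normalize_to_relative(raw)


def _draw_clinical(
    spec: SyntheticSpec, rng: np.random.Generator, table_a: AbundanceTable
) -> ClinicalTable:
    n = table_a.n_samples
    planted_by_index: dict[str, list[PlantedAssociation]] = {}
    for pa in spec.planted_assoc:
        planted_by_index.setdefault(pa.index_name, []).append(pa)
    data = {}
    for index_name in spec.clinical_indices:
        values = rng.normal(0.0, 1.0, size=n)
        for pa in planted_by_index.get(index_name, ()):
            x = table_a.values[pa.taxon_index]
            rank_score = stats.rankdata(x) / (n + 1)
            values = pa.slope * rank_score + rng.normal(0.0, pa.noise_sd, size=n)
        data[index_name] = values
    frame = pd.DataFrame(data, index=table_a.samples)
    cohort = pd.Series("A", index=table_a.samples, name="cohort")
    return ClinicalTable(frame, cohort)


def _draw_roster(
    spec: SyntheticSpec, rng: np.random.Generator, taxa: list[str]
) -> BiobankRoster:
    n_in = int(round(spec.roster_fraction * spec.n_taxa))
    chosen = sorted(rng.choice(spec.n_taxa, size=n_in, replace=False).tolist())
    strains = []
    for k, idx in enumerate(chosen):
        species = taxa[idx]
        genus = species.split()[0]
        strains.append(
            StrainRecord(
                strain_id=f"SYN{k:04d}",
                species=species,
                genus=genus,
                family=f"Family{int(genus[5:8]) % 12:02d}",
                phylum=f"Phylum{int(genus[5:8]) % 5:d}",
                novel=bool(rng.random() < 0.1),
            )
        )
    for k in range(spec.n_extra_roster_species):
        strains.append(
            StrainRecord(
                strain_id=f"SYNX{k:04d}",
                species=f"Cultigenus{k:03d} cultum",
                family="FamilyX",
                phylum="PhylumX",
                novel=True,
            )
        )
    return BiobankRoster("synthetic-biobank", strains)


def simulate_cohort(spec: SyntheticSpec) -> SimulationResult:
    """Generate abundance tables, clinical metadata, a roster and the truth record."""
    spec.validate()
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rng_a, rng_b, rng_clin, rng_roster = (np.random.default_rng(s) for s in streams)
    taxa = _taxon_names(spec)
    no_fold = np.ones(spec.n_taxa)
    fold_b = no_fold.copy()
    for idx, fold in spec.planted_differential:
        fold_b[idx] = fold
    table_a = _draw_cohort(spec, rng_a, spec.n_samples_a, "A", no_fold)
    table_b = (
        _draw_cohort(spec, rng_b, spec.n_samples_b, "B", fold_b)
        if spec.n_samples_b > 0
        else None
    )
    clinical = _draw_clinical(spec, rng_clin, table_a)
    roster = _draw_roster(spec, rng_roster, taxa)
    truth = TruthRecord(
        core_taxa=tuple(taxa[i] for i in spec.planted_core),
        differential=tuple((taxa[i], f) for i, f in spec.planted_differential),
        associations=tuple(
            (taxa[pa.taxon_index], pa.index_name, pa.slope) for pa in spec.planted_assoc
        ),
        taxa=tuple(taxa),
    )
    return SimulationResult(table_a, table_b, clinical, roster, truth)


def truth_check(
    result: SimulationResult,
    truth: TruthRecord,
    cfg: StrataConfig | None = None,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Recovery of planted core, differential and association structure.

    Raises :class:`ValidationError` if the truth record does not belong to
    the simulated outputs.
    """
    cfg = cfg or StrataConfig()
    if tuple(result.table_a.taxa) != truth.taxa:
        raise ValidationError("truth record does not match the simulated table's taxa")

    core_fraction = core_exact = None
    recovered = set(extract_core(result.table_a, cfg).core_taxa)
    false_positive_core = len(recovered - set(truth.core_taxa))
    if truth.core_taxa:
        planted = set(truth.core_taxa)
        core_fraction = len(recovered & planted) / len(planted)
        core_exact = recovered == planted

    diff_fraction = None
    if truth.differential:
        if result.table_b is None:
            raise ValidationError("differential truth requires a cohort B table")
        hits = 0
        for taxon, _fold in truth.differential:
            res = wilcoxon_compare(result.table_a.row(taxon), result.table_b.row(taxon))
            hits += res.p_value < alpha
        diff_fraction = hits / len(truth.differential)

    assoc_fraction = None
    if truth.associations:
        hits = 0
        for taxon, index_name, slope in truth.associations:
            x = result.table_a.row(taxon)
            y = result.clinical.data.loc[result.table_a.samples, index_name].to_numpy()
            rho, p, _ = spearman_assoc(x, y)
            hits += (p < alpha) and (np.sign(rho) == np.sign(slope))
        assoc_fraction = hits / len(truth.associations)

    return RecoveryReport(
        core_recovered_fraction=core_fraction,
        core_exact=core_exact,
        differential_detected_fraction=diff_fraction,
        association_detected_fraction=assoc_fraction,
        false_positive_core=false_positive_core,
    )


def strong_effect_spec(
    seed: int,
    n_taxa: int = 150,
    n_samples_a: int = 96,
    n_samples_b: int = 96,
    n_core: int = 10,
    n_differential: int = 5,
    differential_fold: float = 8.0,
    assoc_slope: float = 1.0,
    assoc_noise_sd: float = 0.15,
) -> SyntheticSpec:
    """Documented strong-effect defaults.

    Planted core taxa: occurrence probability 0.95 and a latent scale large
    enough that their expected closed mean abundance sits far above the 0.2%
    dominance cut; background taxa have occurrence probability <= 0.5 (so
    they fail the 80% prevalence gate) and a small latent scale.
    """
    param_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    pi = param_rng.uniform(0.05, 0.5, size=n_taxa)
    mu = np.full(n_taxa, np.log(0.5))
    sigma = np.full(n_taxa, 1.0)
    core_idx = tuple(range(n_core))
    for i in core_idx:
        pi[i] = 0.95
        mu[i] = np.log(20.0)
        sigma[i] = 0.5
    diff_idx = tuple(range(n_core, n_core + n_differential))
    # differential taxa occur often (power for the rank-sum test) but at a
    # latent scale far below the dominance cut, so they never leak into core
    for i in diff_idx:
        pi[i] = 0.85
        mu[i] = np.log(0.1)
        sigma[i] = 0.7
    indices = ("ESR", "CRP", "anti_CCP")
    assoc = tuple(
        PlantedAssociation(core_idx[j], indices[j % len(indices)], assoc_slope, assoc_noise_sd)
        for j in range(min(3, n_core))
    )
    return SyntheticSpec(
        n_taxa=n_taxa,
        n_samples_a=n_samples_a,
        n_samples_b=n_samples_b,
        occurrence_probs=tuple(pi),
        lognormal_mu=tuple(mu),
        lognormal_sigma=tuple(sigma),
        planted_core=core_idx,
        planted_differential=tuple((i, differential_fold) for i in diff_idx),
        planted_assoc=assoc,
        clinical_indices=indices,
        roster_fraction=0.6,
        seed=seed,
    )


def null_spec(seed: int, n_taxa: int = 60, n_samples_a: int = 96, n_core: int = 10) -> SyntheticSpec:
    """A spec with core structure but no planted clinical associations or
    cohort differences: every (taxon, index) pair is null."""
    base = strong_effect_spec(seed, n_taxa=n_taxa, n_samples_a=n_samples_a, n_samples_b=0, n_core=n_core)
    return dataclasses.replace(base, planted_differential=(), planted_assoc=(), n_samples_b=0)
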