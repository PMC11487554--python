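import numpy as np
import pytest

from gutcore import (
    AbundanceTable,
    BiobankRoster,
    StrainRecord,
    StrataConfig,
    TaxonProfile,
)

GENERA = [
    "Bacteroides",
    "Faecalibacterium",
    "Bifidobacterium",
    "Eubacterium",
    "Escherichia",
    "Blautia",
    "Prevotella",
    "Roseburia",
]


def make_species_names(n: int, n_genera: int = 8) -> list[str]:
    """Deterministic synthetic binomials spread over a few genera."""
    return [f"{GENERA[i % n_genera]} taxon{i:03d}" for i in range(n)]


def make_roster(species: list[str], name: str = "bank") -> BiobankRoster:
    return BiobankRoster(
        name,
        [StrainRecord(strain_id=f"S{i:04d}", species=sp) for i, sp in enumerate(species)],
    )


def make_profiles(
    names: list[str], stratum: str, rank: str = "species", prevalence: float = 100.0
) -> list[TaxonProfile]:
    mean_by_stratum = {"low": 0.05, "medium_above": 0.5, "high": 2.0}
    return [
        TaxonProfile(n, mean_by_stratum[stratum], prevalence, stratum, rank=rank)
        for n in names
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def cfg() -> StrataConfig:
    return StrataConfig()


@pytest.fixture
def small_table() -> AbundanceTable:
    taxa = [
        "Bacteroides uniformis",
        "Bacteroides ovatus",
        "Faecalibacterium prausnitzii",
        "Escherichia coli",
    ]
    values = np.array(
        [
            [40.0, 10.0, 25.0],
            [10.0, 40.0, 25.0],
            [30.0, 30.0, 25.0],
            [20.0, 20.0, 25.0],
        ]
    )
    return AbundanceTable(taxa, ["s1", "s2", "s3"], values)


def random_table(
    rng: np.random.Generator, n_taxa: int = 50, n_samples: int = 10, zero_frac: float = 0.3
) -> AbundanceTable:
    values = rng.gamma(2.0, 1.0, size=(n_taxa, n_samples))
    values[rng.random(values.shape) < zero_frac] = 0.0
    values[0] += 1.0  # guard against an all-zero column
    return AbundanceTable(make_species_names(n_taxa), [f"s{j}" for j in range(n_samples)], values)
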