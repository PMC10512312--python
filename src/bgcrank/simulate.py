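"""Synthetic predictor-output generator with planted statistical structure.

Real inputs to this kind of comparative genome-mining study are per-genome
prediction tables: counts of backbone-enzyme classes from a secondary
metabolite screen, and hit lists of putative metabolites / antimicrobial
peptides carrying a % sequence match to a known reference plus a free-text
annotation. This module emulates exactly that statistical shape so every
downstream stage can be exercised without any genome download:

* per-(species, category) counts are independent Poisson draws, with a
  multiplicative rate bump for one optionally *planted* section — a known
  enrichment signal the network ranking should recover;
* each counted event becomes one hit row with a similarity percentage
  drawn from a named distribution over [0, 100] (one decimal place) and an
  annotation drawn from a keyword mixture.

Each table draws from its own pseudorandom stream spawned from the master
seed, so adding or regenerating one table never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .errors import ConfigurationError

#: child-stream indices off the master seed, one per generated table
_STREAM_SPECIES, _STREAM_COUNTS, _STREAM_HITS = 0, 1, 2

#: infrageneric section names used for default labelling, matching the
#: aggregation units of a Trichoderma-style comparative screen
DEFAULT_SECTION_NAMES = (
    "Harzianum",
    "Trichoderma",
    "Longibrachiatum",
    "Brevicompactum",
    "Pachybasium",
)

MATCH_DISTRIBUTIONS = ("uniform", "high_skew")


@dataclass
class SimulationConfig:
    """Parameters of the planted-signal generative model.

    Parameters
    ----------
    n_sections
        Number of taxonomic sections (aggregation units).
    species_per_section
        Genomes per section; the study this emulates had roughly 4–7.
    categories
        Feature-category labels (e.g. backbone-enzyme classes).
    base_rate
        Poisson mean count per species per category (λ).
    planted_section
        Section whose rates are multiplied by ``effect_multiplier``;
        ``None`` plants no signal.
    effect_multiplier
        Multiplicative enrichment (≥ 1) applied to the planted section.
    match_percent_distribution
        Name of the similarity distribution: ``uniform`` over [0, 100] or
        ``high_skew`` (Beta(5, 1) scaled to [0, 100], mimicking screens
        dominated by close homologs).
    keyword_pool
        ``(annotation, weight)`` mixture the hit annotations are drawn
        from; weights need not be normalized.
    seed
        Master seed for all three tables' independent streams.
    """

    n_sections: int = 5
    species_per_section: int = 5
    categories: tuple[str, ...] = ("T1PKS", "NRPS", "terpene", "NRPS-like", "other")
    base_rate: float = 4.0
    planted_section: str | None = None
    effect_multiplier: float = 1.0
    match_percent_distribution: str = "uniform"
    keyword_pool: tuple[tuple[str, float], ...] = (
        ("hypothetical protein", 6.0),
        ("glycoside hydrolase family protein", 1.5),
        ("cytochrome P450 family protein", 1.0),
        ("non-ribosomal peptide synthetase", 1.0),
        ("ABC transporter", 0.5),
        ("glycosyltransferase", 0.5),
        ("peptidase", 0.5),
    )
    seed: int = 0
    section_names: tuple[str, ...] = field(default=DEFAULT_SECTION_NAMES)

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ConfigurationError(f"n_sections must be ≥ 1, got {self.n_sections}")
        if self.species_per_section < 1:
            raise ConfigurationError(
                f"species_per_section must be ≥ 1, got {self.species_per_section}"
            )
        if not self.categories:
            raise ConfigurationError("categories must be non-empty")
        if self.base_rate < 0:
            raise ConfigurationError(f"base_rate must be ≥ 0, got {self.base_rate}")
        if self.effect_multiplier < 1:
            raise ConfigurationError(
                f"effect_multiplier must be ≥ 1, got {self.effect_multiplier}"
            )
        if self.match_percent_distribution not in MATCH_DISTRIBUTIONS:
            raise ConfigurationError(
                "match_percent_distribution must be one of "
                f"{MATCH_DISTRIBUTIONS}, got {self.match_percent_distribution!r}"
            )
        weights = [w for _, w in self.keyword_pool]
        if any(w < 0 for w in weights):
            raise ConfigurationError("keyword_pool weights must be non-negative")
        if self.keyword_pool and sum(weights) <= 0:
            raise ConfigurationError("keyword_pool weights must sum to a positive total")

    def sections(self) -> list[str]:
        """Section labels: named where defaults suffice, numbered beyond."""
        names = list(self.section_names[: self.n_sections])
        names += [f"Section{i + 1}" for i in range(len(names), self.n_sections)]
        return names

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


def generate_species_table(config: SimulationConfig) -> pd.DataFrame:
    """Assign ``n_sections × species_per_section`` species to sections.

    Deterministic given the config; species labels are unique and encode
    their section for readability (``Harzianum_sp1`` etc.).
    """
    rows = []
    for section in config.sections():
        for j in range(config.species_per_section):
            rows.append(
                {
                    "species_id": f"{section}_sp{j + 1}",
                    "section": section,
                    "strain": f"SYN-{section[:3].upper()}{j + 1}",
                }
            )
    return pd.DataFrame(rows, columns=io.TAXONOMY_COLUMNS)


def generate_count_table(
    species: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Draw per-(species, category) Poisson counts.

    λ = ``base_rate`` everywhere except species of ``planted_section``,
    where λ = ``base_rate × effect_multiplier``.
    """
    sections = set(species["section"])
    if config.planted_section is not None and config.planted_section not in sections:
        raise ConfigurationError(
            f"planted_section {config.planted_section!r} not among sections "
            f"{sorted(sections)}"
        )
    rng = config._rng(_STREAM_COUNTS)
    rows = []
    for _, sp in species.iterrows():
        rate = config.base_rate
        if sp["section"] == config.planted_section:
            rate *= config.effect_multiplier
        draws = rng.poisson(rate, size=len(config.categories))
        for category, count in zip(config.categories, draws):
            rows.append(
                {"species_id": sp["species_id"], "category": category, "count": int(count)}
            )
    frame = pd.DataFrame(rows, columns=io.COUNT_COLUMNS)
    frame["count"] = frame["count"].astype("int64")
    return frame


def _draw_match_percent(rng: np.random.Generator, n: int, name: str) -> np.ndarray:
    if name == "uniform":
        raw = rng.uniform(0.0, 100.0, size=n)
    else:  # high_skew
        raw = 100.0 * rng.beta(5.0, 1.0, size=n)
    # one decimal place: keeps bin-boundary membership unambiguous
    return np.round(raw, 1)


def generate_hit_table(
    species: pd.DataFrame, counts: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Expand counts into one hit row per counted event.

    The number of rows for each (species, category) equals its count;
    each row gets a similarity percentage and a keyword-mixture
    annotation. The category is carried as ``feature_name``.
    """
    total = int(counts["count"].sum())
    rng = config._rng(_STREAM_HITS)
    if total > 0 and not config.keyword_pool:
        raise ConfigurationError("keyword_pool is empty but annotations are requested")
    matches = _draw_match_percent(rng, total, config.match_percent_distribution)
    if config.keyword_pool:
        labels = [k for k, _ in config.keyword_pool]
        weights = np.array([w for _, w in config.keyword_pool], dtype=float)
        annotations = rng.choice(labels, size=total, p=weights / weights.sum())
    else:
        annotations = np.array([], dtype=object)
    rows = []
    pos = 0
    for _, rec in counts.iterrows():
        for _ in range(int(rec["count"])):
            rows.append(
                {
                    "species_id": rec["species_id"],
                    "feature_name": rec["category"],
                    "match_percent": float(matches[pos]),
                    "annotation": str(annotations[pos]),
                }
            )
            pos += 1
    frame = pd.DataFrame(rows, columns=io.HIT_COLUMNS)
    frame["match_percent"] = frame["match_percent"].astype("float64")
    return frame


def write_fixture_bundle(
    dir_path: str | Path,
    species: pd.DataFrame,
    counts: pd.DataFrame,
    hits: pd.DataFrame,
) -> list[Path]:
    """Write taxonomy/counts/hits TSVs; returns the three paths.

    Re-reading via :mod:`bgcrank.io` reproduces the in-memory tables
    exactly.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    return [
        io.write_taxonomy(species, dir_path / "taxonomy.tsv"),
        io.write_counts(counts, dir_path / "counts.tsv"),
        io.write_hits(hits, dir_path / "hits.tsv"),
    ]


def simulate_bundle(config: SimulationConfig, dir_path: str | Path) -> list[Path]:
    """Generate all three tables under ``config`` and write them."""
    species = generate_species_table(config)
    counts = generate_count_table(species, config)
    hits = generate_hit_table(species, counts, config)
    return write_fixture_bundle(dir_path, species, counts, hits)
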