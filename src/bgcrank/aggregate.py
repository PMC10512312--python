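"""Binning and averaging rules applied to prediction tables.

Four reductions turn raw per-genome predictions into the matrices the
network analysis consumes:

* a similarity-threshold split of metabolite hits into high (≥ 75 %) and
  low (< 75 %) sequence-match classes;
* six-way binning of antimicrobial-peptide %-match values, with everything
  below 51.0 % excluded from further analysis;
* keyword categorization of free-text annotations (first matching
  category wins; unmatched text falls through to a fallback label);
* per-section averaging of count tables, where every species assigned to
  a section counts in the denominator whether or not it recorded a hit.

Bin and keyword schemes are plain dataclasses validated on construction;
the shipped defaults encode the standard AMP match bins and annotation
categories, and alternatives can be supplied via YAML config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from . import io
from .errors import ConfigurationError

METABOLITE_MATCH_THRESHOLD = 75.0


@dataclass(frozen=True)
class Bin:
    label: str
    lower: float
    upper: float
    lower_inclusive: bool = True
    upper_inclusive: bool = False

    def contains(self, value: float) -> bool:
        above = value > self.lower or (self.lower_inclusive and value == self.lower)
        below = value < self.upper or (self.upper_inclusive and value == self.upper)
        return above and below


@dataclass(frozen=True)
class BinScheme:
    """Ordered, pairwise-disjoint %-match bins plus an exclusion floor.

    Values strictly below ``exclusion_threshold`` are dropped. Every value
    in ``[exclusion_threshold, 100]`` must land in exactly one bin, which
    is checked on construction over a 0.1 grid (the resolution at which
    match percentages are recorded).
    """

    bins: tuple[Bin, ...]
    exclusion_threshold: float

    def __post_init__(self) -> None:
        if not self.bins:
            raise ConfigurationError("BinScheme needs at least one bin")
        lowers = [b.lower for b in self.bins]
        if lowers != sorted(lowers, reverse=True):
            raise ConfigurationError("bins must be ordered by decreasing lower bound")
        grid = np.round(np.arange(self.exclusion_threshold, 100.0001, 0.1), 1)
        for value in grid:
            n = sum(b.contains(float(value)) for b in self.bins)
            if n != 1:
                raise ConfigurationError(
                    f"bins must cover [{self.exclusion_threshold}, 100] disjointly; "
                    f"value {value} falls in {n} bins"
                )

    def assign(self, value: float) -> str | None:
        """Bin label for ``value``, or ``None`` when excluded."""
        if value < self.exclusion_threshold:
            return None
        for b in self.bins:
            if b.contains(value):
                return b.label
        return None

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bins]


def default_amp_bin_scheme() -> BinScheme:
    """The six standard AMP %-match bins with the 51.0 % exclusion floor.

    A value of exactly 100 gets its own bin; the remaining bins are
    half-open ``[lower, upper)``, so the printed gapped labels
    (… 94.9–90.0, 89.9–80.0 …) are decidable at every 0.1 step.
    """
    return BinScheme(
        bins=(
            Bin("100", 100.0, 100.0, True, True),
            Bin("99.9–95.0", 95.0, 100.0),
            Bin("94.9–90.0", 90.0, 95.0),
            Bin("89.9–80.0", 80.0, 90.0),
            Bin("79.9–70.0", 70.0, 80.0),
            Bin("69.9–51.0", 51.0, 70.0),
        ),
        exclusion_threshold=51.0,
    )


@dataclass(frozen=True)
class KeywordScheme:
    """Ordered annotation categories matched by case-insensitive substring.

    The first category whose any pattern occurs in the annotation wins;
    annotations matching nothing (including empty ones) are assigned
    ``fallback_label``.
    """

    categories: tuple[tuple[str, tuple[str, ...]], ...]
    fallback_label: str = "unannotated"

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.categories]
        if len(labels) != len(set(labels)):
            raise ConfigurationError("keyword category labels must be unique")
        for label, patterns in self.categories:
            if not patterns:
                raise ConfigurationError(f"category {label!r} has no patterns")

    def assign(self, annotation: str) -> str:
        text = annotation.lower()
        if text:
            for label, patterns in self.categories:
                if any(p.lower() in text for p in patterns):
                    return label
        return self.fallback_label

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.categories] + [self.fallback_label]


def default_keyword_scheme() -> KeywordScheme:
    """Annotation categories typical of NCBI keyword summaries of AMP hits."""
    return KeywordScheme(
        categories=(
            ("hypothetical protein", ("hypothetical protein",)),
            ("glycoside hydrolase family", ("glycoside hydrolase",)),
            ("cytochrome P450 family", ("cytochrome p450",)),
            ("non-ribosomal peptide synthetase", ("non-ribosomal peptide", "nrps")),
            ("ABC transporter", ("abc transporter",)),
            ("glycosyltransferase", ("glycosyltransferase",)),
            ("peptidase", ("peptidase",)),
        ),
        fallback_label="unannotated",
    )


def _empty_counts() -> pd.DataFrame:
    frame = pd.DataFrame(columns=io.COUNT_COLUMNS)
    frame["count"] = frame["count"].astype("int64")
    return frame


def _tally(pairs: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Count (species_id, category) occurrences into a CountTable."""
    frame = pd.DataFrame(list(pairs), columns=["species_id", "category"])
    if frame.empty:
        return _empty_counts()
    out = (
        frame.groupby(["species_id", "category"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    out["count"] = out["count"].astype("int64")
    return out


def split_by_threshold(
    hits: pd.DataFrame, threshold: float = METABOLITE_MATCH_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split hits at a %-match threshold into (high, low) count tables.

    Hits with ``match_percent >= threshold`` (the bound is inclusive)
    are tallied per (species, feature) into the high table, the rest into
    the low table; total counts are conserved.
    """
    high_mask = hits["match_percent"] >= threshold
    high = _tally(zip(hits.loc[high_mask, "species_id"], hits.loc[high_mask, "feature_name"]))
    low = _tally(zip(hits.loc[~high_mask, "species_id"], hits.loc[~high_mask, "feature_name"]))
    return high, low


@dataclass(frozen=True)
class BinnedHits:
    """Result of %-match binning: per-bin counts plus exclusion bookkeeping."""

    counts: pd.DataFrame  # CountTable with category = bin label
    per_bin: dict[str, pd.DataFrame]  # bin label -> HitTable subset
    n_excluded: int
    n_retained: int


def bin_amp_matches(hits: pd.DataFrame, scheme: BinScheme | None = None) -> BinnedHits:
    """Assign each hit to exactly one %-match bin, dropping excluded hits.

    Returns per-(species, bin) counts, the hit rows grouped by bin, and
    the number of hits excluded below the scheme's threshold.
    """
    scheme = scheme if scheme is not None else default_amp_bin_scheme()
    labels = [scheme.assign(float(v)) for v in hits["match_percent"]]
    retained = [lab is not None for lab in labels]
    pairs = [
        (sp, lab)
        for sp, lab in zip(hits["species_id"], labels)
        if lab is not None
    ]
    per_bin = {
        label: hits.loc[[lab == label for lab in labels]].reset_index(drop=True)
        for label in scheme.labels
    }
    return BinnedHits(
        counts=_tally(pairs),
        per_bin=per_bin,
        n_excluded=int(len(labels) - sum(retained)),
        n_retained=int(sum(retained)),
    )


def bin_keywords(hits: pd.DataFrame, scheme: KeywordScheme | None = None) -> pd.DataFrame:
    """Tally hits per (species, annotation category); counts conserved."""
    scheme = scheme if scheme is not None else default_keyword_scheme()
    pairs = [
        (sp, scheme.assign(str(ann)))
        for sp, ann in zip(hits["species_id"], hits["annotation"])
    ]
    return _tally(pairs)


def hypothetical_fraction(
    keyword_counts: pd.DataFrame, hypothetical_label: str = "hypothetical protein"
) -> pd.Series:
    """Per-species fraction of hits in the hypothetical-protein category.

    Species with zero total counts are absent from the result rather than
    reported as zero — no hits means the fraction is undefined.
    """
    totals = keyword_counts.groupby("species_id")["count"].sum()
    hyp = (
        keyword_counts[keyword_counts["category"] == hypothetical_label]
        .groupby("species_id")["count"]
        .sum()
    )
    totals = totals[totals > 0]
    frac = hyp.reindex(totals.index, fill_value=0) / totals
    return frac.rename("hypothetical_fraction")


def top_k_annotations(
    keyword_counts: pd.DataFrame,
    k: int = 5,
    exclude: tuple[str, ...] = ("unannotated",),
) -> dict[str, list[str]]:
    """Per species, the k highest-count categories.

    Ties break lexicographically by category label. Categories named in
    ``exclude`` (by default only the fallback) never appear; pass
    ``exclude=()`` to rank every category.
    """
    if k < 1:
        raise ConfigurationError(f"k must be ≥ 1, got {k}")
    result: dict[str, list[str]] = {}
    kept = keyword_counts[~keyword_counts["category"].isin(exclude)]
    for species_id, group in kept.groupby("species_id"):
        ordered = group.sort_values(
            ["count", "category"], ascending=[False, True], kind="mergesort"
        )
        result[str(species_id)] = ordered["category"].head(k).tolist()
    return result


def genome_totals(
    counts: pd.DataFrame, species: pd.DataFrame | None = None
) -> pd.Series:
    """Per-species total count over all categories.

    When a species table is given, species with no count rows appear with
    total 0 and the result follows the taxonomy's row order.
    """
    totals = counts.groupby("species_id")["count"].sum()
    if species is not None:
        totals = totals.reindex(species["species_id"], fill_value=0)
    return totals.rename("total").astype("int64")


@dataclass(frozen=True)
class SectionMatrix:
    """Section × category matrix of average counts per species.

    ``values[s, c] × species_counts[s]`` equals the summed raw count over
    the species of section ``s`` — species without a recorded count for a
    category contribute zero to the numerator but still sit in the
    denominator.
    """

    values: pd.DataFrame  # index: sections; columns: categories; float cells
    species_counts: pd.Series  # per-section denominator

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="section", lineterminator="\n")


def section_average(counts: pd.DataFrame, species: pd.DataFrame) -> SectionMatrix:
    """Average each category's counts over all species of each section."""
    unknown = sorted(set(counts["species_id"]) - set(species["species_id"]))
    if unknown:
        raise ConfigurationError(f"count table species missing from taxonomy: {unknown}")
    n_species = species.groupby("section", sort=True)["species_id"].nunique()
    if (n_species == 0).any():
        raise ConfigurationError("section with zero species")
    merged = counts.merge(
        species[["species_id", "section"]], on="species_id", how="left"
    )
    sums = (
        merged.pivot_table(
            index="section", columns="category", values="count",
            aggfunc="sum", fill_value=0,
        )
        if not merged.empty
        else pd.DataFrame(index=n_species.index)
    )
    sums = sums.reindex(index=n_species.index, fill_value=0).astype(float)
    sums = sums[sorted(sums.columns)]
    values = sums.div(n_species.astype(float), axis=0)
    return SectionMatrix(values=values, species_counts=n_species.rename("n_species"))
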