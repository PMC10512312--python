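"""Reading and writing the canonical prediction tables.

Three tab-separated dialects, UTF-8 with Unix newlines and a mandatory
header row, carry everything the pipeline consumes:

``taxonomy.tsv``
    ``species_id``, ``section``, ``strain`` — one row per genome, mapping
    each species/strain to its infrageneric section (the aggregation unit).
``counts.tsv``
    ``species_id``, ``category``, ``count`` — per-genome non-negative
    observation counts over feature categories (e.g. backbone-enzyme
    classes such as T1PKS or NRPS).
``hits.tsv``
    ``species_id``, ``feature_name``, ``match_percent``, ``annotation`` —
    one row per predicted hit (putative metabolite or AMP candidate) with
    its % sequence match to a known reference and a free-text annotation.

Readers validate exhaustively and raise typed errors; a malformed file is
never partially loaded. Labels are stripped of surrounding whitespace and
compared case-sensitively thereafter.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

TAXONOMY_COLUMNS = ["species_id", "section", "strain"]
COUNT_COLUMNS = ["species_id", "category", "count"]
HIT_COLUMNS = ["species_id", "feature_name", "match_percent", "annotation"]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False,
            quoting=csv.QUOTE_NONE, encoding="utf-8",
        )
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: missing header row") from None
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    frame = frame[required].copy()
    for col in required:
        frame[col] = frame[col].str.strip()
    return frame


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Load a species→section table, preserving row order.

    Returns a DataFrame with columns ``species_id``, ``section``,
    ``strain`` (strain may be empty).
    """
    frame = _read_tsv(path, TAXONOMY_COLUMNS)
    if (frame["species_id"] == "").any():
        rows = (frame.index[frame["species_id"] == ""] + 2).tolist()
        raise ValidationError(f"{path}: empty species_id at file row(s) {rows}")
    dup = frame["species_id"][frame["species_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"{path}: duplicate species_id values: {sorted(set(dup))}"
        )
    if (frame["section"] == "").any():
        bad = frame.loc[frame["section"] == "", "species_id"].tolist()
        raise ValidationError(f"{path}: empty section for species {bad}")
    return frame.reset_index(drop=True)


def read_counts(
    path: str | Path, species: pd.DataFrame | None = None, *, strict: bool = True
) -> pd.DataFrame:
    """Load a per-species count table.

    ``count`` must parse as a non-negative integer. When ``species`` is
    given, unknown species ids raise in strict mode and are flagged on the
    returned frame (boolean ``known_species`` column dropped after check)
    in lenient mode.
    """
    frame = _read_tsv(path, COUNT_COLUMNS)
    counts = []
    for i, raw in enumerate(frame["count"]):
        try:
            value = int(raw)
        except ValueError:
            raise ValidationError(
                f"{path}: non-integer count '{raw}' at file row {i + 2}"
            ) from None
        if value < 0:
            raise ValidationError(
                f"{path}: negative count {value} at file row {i + 2}"
            )
        counts.append(value)
    frame["count"] = pd.array(counts, dtype="int64")
    dup = frame.duplicated(subset=["species_id", "category"])
    if dup.any():
        pairs = frame.loc[dup, ["species_id", "category"]].values.tolist()
        raise ValidationError(f"{path}: duplicate (species_id, category) pairs: {pairs}")
    if species is not None:
        unknown = sorted(set(frame["species_id"]) - set(species["species_id"]))
        if unknown and strict:
            raise ValidationError(
                f"{path}: species not present in taxonomy: {unknown}"
            )
    return frame.reset_index(drop=True)


def read_hits(
    path: str | Path, species: pd.DataFrame | None = None, *, strict: bool = True
) -> pd.DataFrame:
    """Load a hit table; ``match_percent`` must be a real in [0, 100]."""
    frame = _read_tsv(path, HIT_COLUMNS)
    values = []
    for i, raw in enumerate(frame["match_percent"]):
        try:
            value = float(raw)
        except ValueError:
            raise FormatError(
                f"{path}: unparseable match_percent '{raw}' at file row {i + 2}"
            ) from None
        if not 0.0 <= value <= 100.0:
            raise ValidationError(
                f"{path}: match_percent {value} outside [0, 100] at file row {i + 2}"
            )
        values.append(value)
    frame["match_percent"] = pd.array(values, dtype="float64")
    if (frame["species_id"] == "").any():
        rows = (frame.index[frame["species_id"] == ""] + 2).tolist()
        raise ValidationError(f"{path}: empty species_id at file row(s) {rows}")
    if species is not None:
        unknown = sorted(set(frame["species_id"]) - set(species["species_id"]))
        if unknown and strict:
            raise ValidationError(
                f"{path}: species not present in taxonomy: {unknown}"
            )
    return frame.reset_index(drop=True)


def _write_tsv(frame: pd.DataFrame, path: str | Path, columns: list[str]) -> Path:
    path = Path(path)
    frame = frame.reindex(columns=columns)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


def write_taxonomy(frame: pd.DataFrame, path: str | Path) -> Path:
    return _write_tsv(frame, path, TAXONOMY_COLUMNS)


def write_counts(frame: pd.DataFrame, path: str | Path) -> Path:
    return _write_tsv(frame, path, COUNT_COLUMNS)


def write_hits(frame: pd.DataFrame, path: str | Path) -> Path:
    return _write_tsv(frame, path, HIT_COLUMNS)
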