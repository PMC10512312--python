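"""YAML configuration for bin schemes, keyword schemes and solver knobs.

A config file overrides any subset of the shipped defaults::

    bins:
      exclusion_threshold: 51.0
      intervals:
        - {label: "100", lower: 100, upper: 100, lower_inclusive: true, upper_inclusive: true}
        - {label: "99.9–95.0", lower: 95, upper: 100}
        # ...
    keywords:
      fallback_label: unannotated
      categories:
        - {label: hypothetical protein, patterns: [hypothetical protein]}
        # ...
    pagerank:
      damping: 0.85
      tolerance: 1.0e-10
      max_iterations: 1000
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .aggregate import Bin, BinScheme, KeywordScheme
from .errors import ConfigurationError
from .network import PageRankParams


def _bin_scheme_from(mapping: dict) -> BinScheme:
    try:
        bins = tuple(
            Bin(
                label=str(item["label"]),
                lower=float(item["lower"]),
                upper=float(item["upper"]),
                lower_inclusive=bool(item.get("lower_inclusive", True)),
                upper_inclusive=bool(item.get("upper_inclusive", False)),
            )
            for item in mapping["intervals"]
        )
        return BinScheme(bins=bins, exclusion_threshold=float(mapping["exclusion_threshold"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed bins config: {exc}") from exc


def _keyword_scheme_from(mapping: dict) -> KeywordScheme:
    try:
        categories = tuple(
            (str(item["label"]), tuple(str(p) for p in item["patterns"]))
            for item in mapping["categories"]
        )
        return KeywordScheme(
            categories=categories,
            fallback_label=str(mapping.get("fallback_label", "unannotated")),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed keywords config: {exc}") from exc


def load_config(path: str | Path) -> dict:
    """Parse a YAML config into scheme/params objects.

    Returns a dict with any of the keys ``bin_scheme``, ``keyword_scheme``,
    ``pagerank`` present, ready to splat into :class:`PipelineConfig`.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    out: dict = {}
    if "bins" in raw:
        out["bin_scheme"] = _bin_scheme_from(raw["bins"])
    if "keywords" in raw:
        out["keyword_scheme"] = _keyword_scheme_from(raw["keywords"])
    if "pagerank" in raw:
        section = raw["pagerank"]
        out["pagerank"] = PageRankParams(
            damping=float(section.get("damping", 0.85)),
            tolerance=float(section.get("tolerance", 1e-10)),
            max_iterations=int(section.get("max_iterations", 1000)),
        )
    return out
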