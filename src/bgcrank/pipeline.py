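"""End-to-end orchestration: ingest → aggregate → graph → centrality → ranks.

Five shipped analysis recipes mirror the five published graph analyses of
this kind of comparative screen:

=================  ==========================================================
selector           feature nodes of the bipartite graph
=================  ==========================================================
backbone           backbone-enzyme categories, straight from the count table
metabolites_high   putative metabolites with ≥ 75 % match to known clusters
metabolites_low    putative metabolites with < 75 % match
amp_bins           AMP %-match bins (100, 99.9–95.0, …, 69.9–51.0)
amp_keywords       annotation keyword categories of AMP hits
=================  ==========================================================

Every recipe ends in the same place: a section × feature average matrix,
its bipartite graph, strengths and broadcasting/receiving PageRank, and a
rank table. All drops (AMP hits excluded below the %-match floor) are
counted and reported in the run manifest — exclusions are never silent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, aggregate, io, network
from .aggregate import BinScheme, KeywordScheme
from .errors import BgcrankError, ConfigurationError, PipelineError
from .network import PageRankParams

logger = logging.getLogger(__name__)

ANALYSES = (
    "backbone",
    "metabolites_high",
    "metabolites_low",
    "amp_bins",
    "amp_keywords",
)

MEASURES = ("strength_out", "strength_in", "broadcast", "receive")

_MEASURE_COLUMNS = {
    "strength_out": ("out_strength", None),
    "strength_in": ("in_strength", None),
    "broadcast": ("broadcast_raw", "broadcast_norm"),
    "receive": ("receive_raw", "receive_norm"),
}


@dataclass
class PipelineConfig:
    """Inputs, recipe selector and knobs for one pipeline run."""

    taxonomy: Path
    counts: Path | None = None
    hits: Path | None = None
    analysis: str = "backbone"
    out_dir: Path = Path("bgcrank_out")
    bin_scheme: BinScheme | None = None
    keyword_scheme: KeywordScheme | None = None
    pagerank: PageRankParams = field(default_factory=PageRankParams)
    metabolite_threshold: float = aggregate.METABOLITE_MATCH_THRESHOLD
    binarize: bool = False
    # restrict keyword categorization to hits in the ≥95% match bins
    restrict_keywords_to_high_match: bool = True

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ConfigurationError(
                f"unknown analysis {self.analysis!r}; expected one of {ANALYSES}"
            )
        self.taxonomy = Path(self.taxonomy)
        self.counts = Path(self.counts) if self.counts is not None else None
        self.hits = Path(self.hits) if self.hits is not None else None
        self.out_dir = Path(self.out_dir)


def _count_table_for(config: PipelineConfig, species: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Produce the per-species count table the selected recipe analyses."""
    meta: dict = {"dropped_records": 0}
    if config.analysis == "backbone":
        if config.counts is None:
            raise ConfigurationError("analysis 'backbone' requires a counts table")
        return io.read_counts(config.counts, species), meta
    if config.hits is None:
        raise ConfigurationError(f"analysis {config.analysis!r} requires a hits table")
    hits = io.read_hits(config.hits, species)
    if config.analysis in ("metabolites_high", "metabolites_low"):
        high, low = aggregate.split_by_threshold(hits, config.metabolite_threshold)
        return (high if config.analysis == "metabolites_high" else low), meta
    if config.analysis == "amp_bins":
        binned = aggregate.bin_amp_matches(hits, config.bin_scheme)
        meta["dropped_records"] = binned.n_excluded
        logger.info(
            "amp_bins: retained %d hits, excluded %d below the match floor",
            binned.n_retained, binned.n_excluded,
        )
        return binned.counts, meta
    # amp_keywords
    scheme = config.bin_scheme or aggregate.default_amp_bin_scheme()
    if config.restrict_keywords_to_high_match:
        binned = aggregate.bin_amp_matches(hits, scheme)
        high_labels = [b.label for b in scheme.bins if b.lower >= 95.0]
        kept = pd.concat(
            [binned.per_bin[label] for label in high_labels], ignore_index=True
        )
        meta["dropped_records"] = len(hits) - len(kept)
        hits = kept
    return aggregate.bin_keywords(hits, config.keyword_scheme), meta


def rank_nodes(result: network.CentralityResult, measure: str) -> pd.DataFrame:
    """Dense per-class ranking of nodes under one centrality measure.

    Rank 1 is the highest raw score; ties break by ascending node label;
    ranks within each (class, measure) group are 1..k with no gaps.
    """
    if measure not in MEASURES:
        raise ConfigurationError(
            f"unknown measure {measure!r}; expected one of {MEASURES}"
        )
    raw_col, norm_col = _MEASURE_COLUMNS[measure]
    rows = []
    for node_class in sorted(result.frame["node_class"].unique()):
        sub = result.frame[result.frame["node_class"] == node_class]
        ordered = sub.assign(_label=sub.index.astype(str)).sort_values(
            [raw_col, "_label"], ascending=[False, True], kind="mergesort"
        )
        for position, (node, rec) in enumerate(ordered.iterrows(), start=1):
            rows.append(
                {
                    "node": node,
                    "node_class": node_class,
                    "measure": measure,
                    "raw": float(rec[raw_col]),
                    "normalized": float(rec[norm_col]) if norm_col else float("nan"),
                    "rank": position,
                }
            )
    return pd.DataFrame(
        rows, columns=["node", "node_class", "measure", "raw", "normalized", "rank"]
    )


def rank_all_measures(result: network.CentralityResult) -> pd.DataFrame:
    return pd.concat(
        [rank_nodes(result, m) for m in MEASURES], ignore_index=True
    )


def _config_digest(config: PipelineConfig) -> str:
    payload = {
        "analysis": config.analysis,
        "metabolite_threshold": config.metabolite_threshold,
        "binarize": config.binarize,
        "restrict_keywords_to_high_match": config.restrict_keywords_to_high_match,
        "damping": config.pagerank.damping,
        "tolerance": config.pagerank.tolerance,
        "max_iterations": config.pagerank.max_iterations,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
) -> tuple[network.CentralityResult, pd.DataFrame, list[Path]]:
    """Execute the selected recipe end-to-end and write its outputs.

    Writes four TSV tables (section matrix, edge list, centrality table,
    rank table) plus a JSON run manifest into ``config.out_dir``; returns
    the centrality result, the rank table, and the list of written data
    files. Deterministic: identical inputs and config give byte-identical
    outputs. Stage failures raise :class:`PipelineError` naming the
    stage, and no partial output files are left behind.
    """
    stage = "ingest"
    try:
        species = io.read_taxonomy(config.taxonomy)
        stage = "aggregate"
        counts, meta = _count_table_for(config, species)
        matrix = aggregate.section_average(counts, species)
        stage = "graph"
        graph = network.build_graph(matrix, binarize=config.binarize)
        stage = "centrality"
        result = network.broadcast_receive(graph, config.pagerank)
        stage = "rank"
        ranks = rank_all_measures(result)
    except PipelineError:
        raise
    except BgcrankError as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "write"
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        path = out / "section_matrix.tsv"
        matrix.to_tsv(path)
        written.append(path)
        path = out / "edges.tsv"
        network.write_edge_list(graph, path)
        written.append(path)
        path = out / "centrality.tsv"
        result.to_tsv(path)
        written.append(path)
        path = out / "ranks.tsv"
        ranks.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
        manifest = {
            "package_version": __version__,
            "analysis": config.analysis,
            "inputs": {
                "taxonomy": str(config.taxonomy),
                "counts": str(config.counts) if config.counts else None,
                "hits": str(config.hits) if config.hits else None,
            },
            "config_digest": _config_digest(config),
            "dropped_records": meta["dropped_records"],
            "n_sections": int(matrix.values.shape[0]),
            "n_features": int(graph.number_of_nodes() - matrix.values.shape[0]),
            "n_edges": int(graph.number_of_edges()),
            "solver": result.solver_info,
            "outputs": [p.name for p in written],
        }
        with open(out / "run_manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc
    return result, ranks, written
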