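"""End-to-end orchestration: maps -> matrix -> search -> bootstrap -> report.

A :class:`RunConfig` fully determines a run (including every seed), and a
run writes all intermediates — the coded matrix (NEXUS), the MP trees and the
rooted, support-annotated consensus (Newick), and a JSON + text report — so
every reported number can be recomputed from the archived files by invoking
the stage functions directly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import __version__
from .coding import CharacterMatrix, build_matrix, classification_counts
from .homology import parse_homology_tsv
from .matrix_io import read_matrix, write_matrix
from .parsimony import (
    BootstrapResult,
    SearchResult,
    bootstrap,
    exhaustive_search,
    heuristic_search,
    strict_consensus,
    tree_statistics,
)
from .trees import Phylotree, robinson_foulds, root_on_outgroup, write_trees

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    output_dir: str
    seed: int
    coding_mode: str = "auto"              # "auto" (code from maps) | "explicit-matrix"
    maps_path: Optional[str] = None
    matrix_path: Optional[str] = None
    matrix_format: str = "nexus"
    taxa: Optional[list[str]] = None       # optional subset/order restriction
    outgroup: list[str] = field(default_factory=list)
    search_method: str = "auto"            # "auto" | "exhaustive" | "heuristic"
    n_addition_replicates: int = 10
    maxtrees: Optional[int] = None
    bootstrap_replicates: int = 1000
    majority_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)

    def validate(self) -> None:
        if self.coding_mode not in ("auto", "explicit-matrix"):
            raise ValueError(f"unknown coding mode {self.coding_mode!r}")
        if self.coding_mode == "auto" and not self.maps_path:
            raise ValueError("coding_mode 'auto' needs maps_path")
        if self.coding_mode == "explicit-matrix" and not self.matrix_path:
            raise ValueError("coding_mode 'explicit-matrix' needs matrix_path")
        if self.seed is None:
            raise ValueError("a seed is mandatory (bootstrap and heuristic "
                             "search are stochastic)")


@dataclass
class RunReport:
    """The quantities a full run prints; all recomputable from the archived
    intermediates."""

    ntaxa: int
    ncharacters: int
    character_counts: dict
    search_method: str
    n_mp_trees: int
    length: int
    ci: float
    hi: float
    ri: Optional[float]
    clade_supports: dict
    bootstrap_replicates: int
    outgroup: list[str]
    outgroup_monophyletic: Optional[bool]
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _load_matrix(config: RunConfig) -> CharacterMatrix:
    if config.coding_mode == "explicit-matrix":
        matrix = read_matrix(config.matrix_path, format=config.matrix_format)
    else:
        maps = parse_homology_tsv(config.maps_path)
        if config.taxa:
            by_name = {m.taxon: m for m in maps}
            maps = [by_name[t] for t in config.taxa]
        matrix = build_matrix(list(maps))
    if config.taxa and config.coding_mode == "explicit-matrix":
        matrix = matrix.subset_taxa(config.taxa)
    for t in config.outgroup:
        if t not in matrix.taxa:
            raise ValueError(f"outgroup taxon {t!r} not in matrix")
    return matrix


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute coding (or matrix load), search, statistics, bootstrap,
    outgroup rooting and consensus; write all intermediates to
    ``config.output_dir``.  Idempotent for a fixed config."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = _stage("load-matrix")(_load_matrix)(config)
    write_matrix(matrix, out / "matrix.nex", format="nexus")
    counts = classification_counts(matrix)

    method = config.search_method
    if method == "auto":
        method = "exhaustive" if matrix.ntaxa <= 10 else "heuristic"
    if method == "exhaustive":
        result = _stage("search")(exhaustive_search)(matrix)
    else:
        result = _stage("search")(heuristic_search)(
            matrix, n_addition_replicates=config.n_addition_replicates,
            seed=config.seed, maxtrees=config.maxtrees)
    write_trees(result.mp_trees, out / "mp_trees.nwk")

    boot = None
    supports: dict = {}
    if config.bootstrap_replicates > 0:
        boot = _stage("bootstrap")(bootstrap)(
            matrix, replicates=config.bootstrap_replicates, seed=config.seed,
            search={"method": "heuristic", "n_addition_replicates": 2}
            if matrix.ntaxa >= 4 else {"method": "exhaustive"})
        supports = {"+".join(sorted(k)): v
                    for k, v in boot.clade_supports().items()}

    consensus = _stage("consensus")(strict_consensus)(result.mp_trees)
    if boot is not None:
        consensus.supports = {m: boot.split_support.get(m, 0.0)
                              for m in consensus.splits()}
    outgroup_mono = None
    if config.outgroup:
        import warnings as _w
        with _w.catch_warnings(record=True) as caught:
            _w.simplefilter("always")
            consensus = root_on_outgroup(consensus, config.outgroup)
            outgroup_mono = not any("monophyletic" in str(w.message)
                                    for w in caught)
    write_trees([consensus], out / "consensus.nwk")

    report = RunReport(
        ntaxa=matrix.ntaxa, ncharacters=matrix.ncharacters,
        character_counts=counts, search_method=method,
        n_mp_trees=result.n_trees, length=result.length,
        ci=result.ci, hi=result.hi, ri=result.ri,
        clade_supports=supports,
        bootstrap_replicates=config.bootstrap_replicates if boot else 0,
        outgroup=list(config.outgroup), outgroup_monophyletic=outgroup_mono,
        provenance={"package_version": __version__, "seed": config.seed,
                    "search_log": {k: v for k, v in result.search_log.items()}})

    payload = report.to_dict()
    (out / "report.json").write_text(
        json.dumps(payload, indent=2, default=str) + "\n", encoding="utf-8")
    (out / "report.txt").write_text(_format_report(payload), encoding="utf-8")
    return report


def _format_report(payload: dict) -> str:
    lines = [
        f"generated: {time.strftime('%Y-%m-%d %H:%M:%S')}",
        f"taxa: {payload['ntaxa']}   characters: {payload['ncharacters']} "
        f"({payload['character_counts']})",
        f"search: {payload['search_method']}   MP trees: {payload['n_mp_trees']}"
        f"   length: {payload['length']}",
        f"CI: {payload['ci']:.4f}   HI: {payload['hi']:.4f}   RI: "
        + (f"{payload['ri']:.4f}" if payload["ri"] is not None else "undefined"),
    ]
    if payload["clade_supports"]:
        lines.append(f"bootstrap ({payload['bootstrap_replicates']} replicates):")
        for clade, pct in sorted(payload["clade_supports"].items(),
                                 key=lambda kv: -kv[1]):
            lines.append(f"  {pct:5.1f}%  {clade}")
    return "\n".join(lines) + "\n"


def compare_trees(report_tree: Phylotree, reference: Phylotree) -> dict:
    """Robinson–Foulds distance plus the named clades the trees share."""
    rf = robinson_foulds(report_tree, reference)
    shared = report_tree.splits() & reference.splits()
    names = []
    for mask in sorted(shared, key=lambda m: (m.bit_count(), m)):
        names.append(sorted(report_tree.taxa[i]
                            for i in range(len(report_tree.taxa))
                            if mask >> i & 1))
    return {"rf": rf, "shared_clades": names}
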