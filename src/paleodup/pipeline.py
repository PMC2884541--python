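"""End-to-end orchestration of the three screening analyses.

* Analysis I — clusters with prokaryotic and eukaryotic members: outgroup
  rooting → orthogroup delineation → node-scan duplication detection →
  retention patterns → summary table.
* Analysis II — eukaryote-only clusters: unrooted edge-scan (bipartition)
  duplication detection → summary.
* Analysis III — identical logic to analysis I applied to an independently
  built cluster set; the distinction is pure metadata here.

The in-memory entry points (:func:`screen_outgroup_trees`,
:func:`screen_bipartition_trees`) take parsed trees; :func:`run_analysis`
wraps them with file I/O for the CLI and writes deterministic TSV/JSON
reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import duplications as dup
from .errors import PaleodupError
from .orthogroups import Orthogroup, delineate_orthogroups
from .summaries import SummaryTable, build_summary, pattern_distribution, _pct
from .taxa import TaxonMap
from .trees import GeneTree, parse_newick, root_by_prokaryotes, write_newick

__all__ = [
    "PipelineConfig",
    "ScreenResult",
    "screen_outgroup_trees",
    "screen_bipartition_trees",
    "read_tree_dir",
    "run_analysis",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one pipeline run."""

    trees_dir: Union[str, Path]
    genes_tsv: Optional[Union[str, Path]]
    species_tsv: Union[str, Path]
    analysis: str = "I"
    support: float = 50.0
    criterion: str = "relaxed"
    method_label: str = "NJ-BS"
    seed: int = 0
    out_dir: Union[str, Path] = "paleodup_out"

    def __post_init__(self):
        if self.analysis not in ("I", "II", "III"):
            raise PaleodupError(f"unknown analysis {self.analysis!r}")
        if not (0.0 <= self.support <= 100.0):
            raise PaleodupError("support threshold must lie in [0, 100]")
        if self.criterion not in ("relaxed", "stringent"):
            raise PaleodupError(f"unknown criterion {self.criterion!r}")


@dataclass
class ScreenResult:
    """Everything one screening pass produced."""

    analysis: str
    method: str
    threshold: float
    criterion: str
    orthogroups: list[Orthogroup] = field(default_factory=list)
    calls: list[dup.DuplicationCall] = field(default_factory=list)
    patterns: dict[str, str] = field(default_factory=dict)  # orthogroup id → pattern
    n_trees: int = 0
    errors: list[dict] = field(default_factory=list)  # {"tree_id", "stage", "error"}

    @property
    def duplicated_ids(self) -> set[str]:
        key = "orthogroup_id" if self.analysis in ("I", "III") else "tree_id"
        return {getattr(c, key) for c in self.calls}

    def summary(self) -> SummaryTable:
        if self.analysis == "II":
            raise PaleodupError("analysis II has no type I/II structure; use summary_row()")
        return build_summary(
            self.orthogroups, self.calls, self.method, self.threshold, self.criterion
        )

    def summary_row(self) -> dict:
        if self.analysis in ("I", "III"):
            return self.summary().to_row()
        with_dup = len(self.duplicated_ids)
        return {
            "method": self.method,
            "threshold": self.threshold,
            "criterion": self.criterion,
            "total_dup": with_dup,
            "total": self.n_trees,
            "percentage": _pct(with_dup, self.n_trees),
        }

    def pattern_table(self) -> pd.DataFrame:
        return pattern_distribution(self.patterns.values())


def screen_outgroup_trees(
    trees: Sequence[GeneTree],
    taxa: TaxonMap,
    threshold: float,
    criterion: str = "relaxed",
    method: str = "",
    analysis: str = "I",
) -> ScreenResult:
    """Analyses I/III: root each tree on its prokaryotic outgroup, delineate
    orthogroups and call duplications.  Per-tree failures are recorded, not
    raised."""
    stringent = criterion == "stringent"
    result = ScreenResult(analysis, method, threshold, criterion, n_trees=len(trees))
    for tree in trees:
        stage = "rooting"
        try:
            rooted = root_by_prokaryotes(tree, taxa)
            stage = "orthogroups"
            ogs = delineate_orthogroups(rooted, taxa)
            stage = "duplications"
            for og in ogs:
                result.orthogroups.append(og)
                calls = dup.detect_duplications(og, taxa, threshold, stringent, method)
                result.calls.extend(calls)
                if calls:
                    result.patterns[og.orthogroup_id] = dup.classify_pattern(
                        og, calls, taxa
                    )
        except PaleodupError as exc:
            result.errors.append(
                {"tree_id": tree.name, "stage": stage, "error": str(exc)}
            )
    return result


def screen_bipartition_trees(
    trees: Sequence[GeneTree],
    taxa: TaxonMap,
    threshold: float,
    criterion: str = "relaxed",
    method: str = "",
) -> ScreenResult:
    """Analysis II: edge-scan each eukaryote-only tree for duplication
    bipartitions."""
    stringent = criterion == "stringent"
    result = ScreenResult("II", method, threshold, criterion, n_trees=len(trees))
    for tree in trees:
        try:
            calls = dup.detect_bipartition_duplication(
                tree, taxa, threshold, stringent, method
            )
            result.calls.extend(calls)
        except PaleodupError as exc:
            result.errors.append(
                {"tree_id": tree.name, "stage": "bipartitions", "error": str(exc)}
            )
    return result


# ---------------------------------------------------------------------------
# file-level driver
# ---------------------------------------------------------------------------

_TREE_SUFFIXES = (".nwk", ".newick", ".tree", ".tre")


def read_tree_dir(trees_dir: Union[str, Path], dialect: str = "support") -> list[GeneTree]:
    trees = []
    for path in sorted(Path(trees_dir).iterdir()):
        if path.suffix.lower() in _TREE_SUFFIXES:
            trees.append(parse_newick(path.read_text().strip(), dialect, name=path.stem))
    if not trees:
        raise PaleodupError(f"no input trees found under {trees_dir}")
    return trees


def run_analysis(config: PipelineConfig) -> ScreenResult:
    """Run one full screening pass from files and write the report bundle.

    Outputs under ``config.out_dir``: orthogroups.tsv, calls.tsv,
    summary.tsv, patterns.tsv (analyses I/III only), errors.tsv and
    manifest.json.  Byte-identical across reruns with identical inputs.
    """
    if config.genes_tsv is not None:
        taxa = TaxonMap.from_tsv(config.genes_tsv, config.species_tsv)
    else:
        taxa = TaxonMap.from_tsv_species_only(config.species_tsv)
    trees = read_tree_dir(config.trees_dir)
    if config.analysis in ("I", "III"):
        result = screen_outgroup_trees(
            trees, taxa, config.support, config.criterion, config.method_label, config.analysis
        )
    else:
        result = screen_bipartition_trees(
            trees, taxa, config.support, config.criterion, config.method_label
        )
    write_reports(result, config.out_dir, config)
    return result


def write_reports(result: ScreenResult, out_dir: Union[str, Path], config=None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    og_rows = [
        {
            "tree_id": og.tree_id,
            "orthogroup_id": og.orthogroup_id,
            "type": og.og_type,
            "n_leaves": og.size,
            "n_R": og.n_R,
            "n_O": og.n_O,
            "leaves": ",".join(sorted(og.leaf_labels)),
        }
        for og in result.orthogroups
    ]
    pd.DataFrame(
        og_rows,
        columns=["tree_id", "orthogroup_id", "type", "n_leaves", "n_R", "n_O", "leaves"],
    ).to_csv(out / "orthogroups.tsv", sep="\t", index=False)

    call_rows = [
        {
            "tree_id": c.tree_id,
            "orthogroup_id": c.orthogroup_id,
            "gate_support": c.gate,
            "stringent_ok": c.stringent_ok,
            "shared_species": ",".join(sorted(c.shared_species)),
            "node_leaves": ",".join(sorted(c.node_leaves)),
        }
        for c in result.calls
    ]
    pd.DataFrame(
        call_rows,
        columns=[
            "tree_id", "orthogroup_id", "gate_support", "stringent_ok",
            "shared_species", "node_leaves",
        ],
    ).to_csv(out / "calls.tsv", sep="\t", index=False)

    pd.DataFrame([result.summary_row()]).to_csv(out / "summary.tsv", sep="\t", index=False)
    if result.analysis in ("I", "III"):
        result.pattern_table().to_csv(out / "patterns.tsv", sep="\t", index=False)
    pd.DataFrame(
        result.errors, columns=["tree_id", "stage", "error"]
    ).to_csv(out / "errors.tsv", sep="\t", index=False)

    manifest = {
        "analysis": result.analysis,
        "method": result.method,
        "threshold": result.threshold,
        "criterion": result.criterion,
        "n_trees": result.n_trees,
        "n_orthogroups": len(result.orthogroups),
        "n_calls": len(result.calls),
        "n_errors": len(result.errors),
    }
    if config is not None:
        manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
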