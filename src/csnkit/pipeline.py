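"""End-to-end pipeline: molecule table → fingerprints → similarity →
t-SNE CSN → groups → reports, with a JSON run manifest.

The manifest is the reproducibility unit: it records the full
configuration (the underlying method reports no seeds, so ours must be
explicit), library versions, and the stage counts
``n_input = n_participating + n_isolated`` and
``n_participating = n_grouped + n_unassigned``.  Rerunning with the same
configuration reproduces every tabular output byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import fingerprints as fp_mod
from . import grouping as grouping_mod
from . import io as io_mod
from . import network as network_mod

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Defaults follow the method's stated parameters: Morgan radius 2,
    1024 bits, similarity threshold 0.45, minimum group size 3.
    """

    input_path: str | Path
    out_dir: str | Path
    input_format: str | None = None
    radius: int = fp_mod.DEFAULT_RADIUS
    n_bits: int = fp_mod.DEFAULT_N_BITS
    similarity_threshold: float = network_mod.DEFAULT_SIMILARITY_THRESHOLD
    seed: int = network_mod.DEFAULT_SEED
    perplexity: float | None = None
    embedding_metric: str = "euclidean"
    edge_length_threshold: float | None = None
    edge_length_quantile: float = grouping_mod.DEFAULT_LENGTH_QUANTILE
    min_group_size: int = grouping_mod.DEFAULT_MIN_GROUP_SIZE
    mwgs_denominator: str = "n-1"
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_path"] = str(self.input_path)
        d["out_dir"] = str(self.out_dir)
        return d


@dataclass
class PipelineResult:
    config: RunConfig
    table: io_mod.MoleculeTable
    matrix: fp_mod.SimilarityMatrix
    network: network_mod.ChemSpaceNetwork
    grouping: grouping_mod.GroupingResult
    manifest: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _library_versions() -> dict[str, str]:
    import networkx
    import numpy
    import pandas
    import rdkit
    import scipy
    import sklearn

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
        "rdkit": rdkit.__version__,
    }


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute every stage and write the artifact bundle to ``cfg.out_dir``.

    Outputs: ``similarity.csv``, ``network.graphml``, ``network.json``,
    ``groups.tsv``, ``rejects.json``, ``manifest.json`` and, unless
    disabled, ``heatmap.png`` and ``network.png``.  Any stage error
    propagates as :class:`StageError` with the stage name.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
            timings[name] = round(time.perf_counter() - t0, 4)
            logger.info("stage %s done in %.2fs", name, timings[name])
            return result

        return deco

    @stage("ingest")
    def table():
        t = io_mod.read_molecule_table(cfg.input_path, format=cfg.input_format)
        if not t.records:
            raise ValueError("no valid molecules in input")
        return t

    names = {r.mol_id: r.name for r in table.records}

    @stage("fingerprint")
    def fps():
        return fp_mod.compute_fingerprints(table.records, radius=cfg.radius, n_bits=cfg.n_bits)

    @stage("similarity")
    def matrix():
        m = fp_mod.similarity_matrix(fps)
        paths["similarity"] = out_dir / "similarity.csv"
        m.to_csv(paths["similarity"])
        return m

    @stage("network")
    def net():
        n = network_mod.assemble_network(
            table.records,
            fps,
            matrix,
            threshold=cfg.similarity_threshold,
            seed=cfg.seed,
            perplexity=cfg.perplexity,
            metric=cfg.embedding_metric,
        )
        paths["graphml"] = out_dir / "network.graphml"
        paths["node_link"] = out_dir / "network.json"
        n.to_graphml(paths["graphml"])
        n.to_node_link_json(paths["node_link"])
        return n

    @stage("grouping")
    def grouping():
        g = grouping_mod.group_network(
            net,
            matrix,
            edge_length_threshold=cfg.edge_length_threshold,
            edge_length_quantile=cfg.edge_length_quantile,
            min_group_size=cfg.min_group_size,
            names=names,
            denominator=cfg.mwgs_denominator,
        )
        paths["groups"] = out_dir / "groups.tsv"
        if g.groups:
            io_mod.write_group_report(g.groups, paths["groups"], names=names)
        else:
            paths["groups"].write_text(
                "group_id\tmol_id\tname\tmwgs\tis_representative\n", encoding="utf-8"
            )
        return g

    @stage("report")
    def manifest():
        paths["rejects"] = out_dir / "rejects.json"
        io_mod.write_rejects(table, paths["rejects"])
        if cfg.make_figures:
            paths["heatmap"] = out_dir / "heatmap.png"
            fp_mod.plot_similarity_heatmap(matrix, paths["heatmap"])
            paths["network_figure"] = out_dir / "network.png"
            network_mod.plot_network(
                net, paths["network_figure"], group_of=grouping.membership(), names=names
            )
        n_grouped = sum(g.size for g in grouping.groups)
        counts = {
            "n_input_rows": len(table.records) + len(table.rejects),
            "n_input": len(table.records),
            "n_rejected": len(table.rejects),
            "n_participating": len(net.nodes),
            "n_isolated": len(net.isolated_ids),
            "n_edges": len(net.edges),
            "n_grouped": n_grouped,
            "n_unassigned": len(grouping.unassigned_ids),
            "n_groups": len(grouping.groups),
        }
        assert counts["n_input"] == counts["n_participating"] + counts["n_isolated"]
        assert counts["n_participating"] == counts["n_grouped"] + counts["n_unassigned"]
        data = {
            "config": cfg.to_dict(),
            "grouping_params": grouping.params,
            "library_versions": _library_versions(),
            "counts": counts,
            "groups": [
                {
                    "group_id": g.group_id,
                    "label": g.label,
                    "size": g.size,
                    "representative_id": g.representative_id,
                    "representative_mwgs": g.mwgs_by_member[g.representative_id],
                }
                for g in grouping.groups
            ],
        }
        paths["manifest"] = out_dir / "manifest.json"
        paths["manifest"].write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
        return data

    return PipelineResult(
        config=cfg,
        table=table,
        matrix=matrix,
        network=net,
        grouping=grouping,
        manifest=manifest,
        paths=paths,
    )
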