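"""Orchestration: filter -> diversity -> differentiation -> relatedness ->
network (-> optional dispersal) from one configuration, with a
machine-readable manifest.

A single global seed is fanned out per stage by a stable hash of the stage
name, so adding a stage never perturbs the randomness of earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_io import GenotypeMatrix, LocusMetadata, read_locus_metadata, read_site_table, read_structure_genotypes
from .snp_filtering import FilterReport, FilterThresholds, apply_quality_filters, deduplicate_clone_snps, hwe_screen
from .diversity import diversity_report
from .differentiation import amova_three_level, great_circle_matrix, mantel_test, pairwise_matrices
from .relatedness import classify_pairs
from .network import mutual_knn_graph, one_minus_ibs

log = logging.getLogger("sandpop")

__all__ = ["RunConfig", "run_full_analysis", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    return (zlib.crc32(stage.encode()) ^ (global_seed & 0x7FFFFFFF)) % (2**31)


@dataclass
class RunConfig:
    genotypes: str | Path | None = None
    matrix: GenotypeMatrix | None = None
    metadata: str | Path | LocusMetadata | None = None
    sites: str | Path | pd.DataFrame | None = None
    out_dir: str | Path = "sandpop_out"
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    run_filters: bool = True
    n_perm_fst: int = 10_000
    n_perm_amova: int = 999
    n_perm_mantel: int = 999
    network_k: int = 30
    relatedness_pops: list[str] | None = None  # default: all
    include_ne: bool = True
    seed: int = 0

    def load_matrix(self) -> GenotypeMatrix:
        if self.matrix is not None:
            return self.matrix
        if self.genotypes is None:
            raise ValueError("config needs either a genotype path or an in-memory matrix")
        return read_structure_genotypes(self.genotypes)


def _sha256_of(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Outputs in ``out_dir``: filter_report.csv, hwe_pvalues.csv,
    diversity.csv, pairwise_fst.csv / pairwise_fst_p.csv / pairwise_ds.csv
    (+ combined pairwise.csv, Fst below / Ds above the diagonal),
    amova.csv, mantel.csv (when sites given), relatedness.csv,
    relatedness_pairs.csv, network_edges.csv, network.graphml and
    manifest.json.  Returns the manifest dict.  A stage failure aborts with
    the stage named; outputs written so far are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "sandpop",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    matrix = config.load_matrix()
    stage = "load"
    try:
        # ----- filtering ------------------------------------------------
        stage = "filter"
        if config.run_filters and config.metadata is not None:
            meta = (config.metadata if isinstance(config.metadata, LocusMetadata)
                    else read_locus_metadata(config.metadata))
            report = FilterReport()
            matrix, entry = deduplicate_clone_snps(matrix, meta)
            report.stages.append(entry)
            matrix, report = apply_quality_filters(matrix, meta, config.thresholds, report)
            report.to_frame().to_csv(out / "filter_report.csv", index=False)
            hwe_p, flagged = hwe_screen(matrix, alpha=config.thresholds.hwe_alpha,
                                        correction=config.thresholds.hwe_correction)
            hwe_p.to_csv(out / "hwe_pvalues.csv")
            if flagged:
                matrix = matrix.subset_loci(~np.isin(matrix.loci, flagged))
            manifest["stages"]["filter"] = {
                "loci_out": matrix.n_loci, "hwe_removed": len(flagged),
            }
        # ----- diversity ------------------------------------------------
        stage = "diversity"
        div = diversity_report(matrix, include_ne=config.include_ne)
        div.to_csv(out / "diversity.csv")
        manifest["stages"]["diversity"] = {"populations": list(div.index)}
        # ----- differentiation -------------------------------------------
        stage = "differentiation"
        seed = stage_seed(config.seed, "differentiation")
        mats = pairwise_matrices(matrix, n_perm=config.n_perm_fst, seed=seed)
        mats["fst"].to_csv(out / "pairwise_fst.csv")
        mats["fst_p"].to_csv(out / "pairwise_fst_p.csv")
        mats["ds"].to_csv(out / "pairwise_ds.csv")
        combined = mats["ds"].copy()
        tri = np.tril_indices(len(combined), k=-1)
        combined.values[tri] = mats["fst"].values[tri]
        combined.to_csv(out / "pairwise.csv")
        amova = amova_three_level(matrix, n_perm=config.n_perm_amova,
                                  seed=stage_seed(config.seed, "amova"))
        pd.DataFrame({
            "component": list(amova.components),
            "variance": list(amova.components.values()),
            "percent": [amova.percentages[k] for k in amova.components],
            "p_value": [amova.p_values.get(k, np.nan) for k in amova.components],
        }).to_csv(out / "amova.csv", index=False)
        manifest["stages"]["differentiation"] = {
            "seed": seed,
            "amova_percent": amova.percentages,
            "fst_mean": float(np.mean(mats["fst"].values[np.triu_indices(len(combined), 1)])),
        }
        if config.sites is not None:
            sites = (config.sites if isinstance(config.sites, pd.DataFrame)
                     else read_site_table(config.sites))
            sites = sites.set_index("population").loc[list(mats["fst"].index)].reset_index()
            geo = great_circle_matrix(sites)
            theta = mats["fst"].to_numpy()
            lin = theta / (1.0 - theta)
            np.fill_diagonal(lin, 0.0)
            r, p = mantel_test(lin, geo.to_numpy(), n_perm=config.n_perm_mantel,
                               seed=stage_seed(config.seed, "mantel"))
            pd.DataFrame([{"r": r, "p": p, "n_perm": config.n_perm_mantel,
                           "genetic_matrix": "linearized_fst"}]).to_csv(out / "mantel.csv", index=False)
            manifest["stages"]["mantel"] = {"r": r, "p": p}
        # ----- relatedness -----------------------------------------------
        stage = "relatedness"
        pops = config.relatedness_pops or matrix.pop_labels
        summaries, pair_tables = [], []
        for pop in pops:
            res = classify_pairs(matrix, pop)
            s = res.summary()
            s.insert(0, "population", pop)
            summaries.append(s.reset_index())
            t = res.table.copy()
            t.insert(0, "population", pop)
            pair_tables.append(t)
        pd.concat(summaries, ignore_index=True).to_csv(out / "relatedness.csv", index=False)
        pd.concat(pair_tables, ignore_index=True).to_csv(out / "relatedness_pairs.csv", index=False)
        manifest["stages"]["relatedness"] = {
            "counts": {
                s["population"].iloc[0]: dict(zip(s["relationship"], s["count"]))
                for s in summaries
            }
        }
        # ----- network ----------------------------------------------------
        stage = "network"
        dist = one_minus_ibs(matrix)
        k = min(config.network_k, matrix.n_individuals - 1)
        net = mutual_knn_graph(dist, k=k)
        net.edge_list().to_csv(out / "network_edges.csv", index=False)
        net.write_graphml(out / "network.graphml")
        manifest["stages"]["network"] = {
            "k": k,
            "n_edges": net.graph.number_of_edges(),
            "n_components": int(len(list(
                __import__("networkx").connected_components(net.graph)))),
        }
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for f in sorted(out.glob("*.csv")):
        manifest["outputs"][f.name] = _sha256_of(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
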