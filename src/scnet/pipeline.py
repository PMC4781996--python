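"""End-to-end orchestration: cohort tables in, result tables out.

`run_pipeline` chains the stages for each morphological measure and group:
residualize -> shrunk covariance -> partial correlation -> sparsity sweep
-> graph/small-world metrics -> permutation comparison, and writes plain
TSV/JSON results plus a manifest (config, seeds, versions, file list) that
is sufficient to reproduce every number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import DEFAULT_COVARIATES, load_cohort, residualize
from .compare import betweenness_difference_map, permutation_test
from .metrics import global_metrics, node_metrics
from .network import ledoit_wolf_covariance, partial_correlation, sparsity_grid, sparsity_sweep
from .nulls import small_world

MEASURES = ("thickness", "volume", "area", "curvature", "jacobian", "sulc")

__all__ = ["RunConfig", "run_pipeline", "MEASURES"]


@dataclass
class RunConfig:
    """Fully materialized run configuration (no implicit defaults at run time)."""

    schema_version: int = 1
    measures: tuple[str, ...] = ("thickness",)
    s_min: float = 0.05
    s_max: float = 0.35
    s_step: float = 0.01
    nodal_sparsity: float = 0.11
    n_rand: int = 1000
    n_perm: int = 1000
    seed: int = 0
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    pooled_residualization: bool = False
    rank_by: str = "absolute"
    swaps_per_edge: int = 10
    divide_by_n: bool = False

    def __post_init__(self) -> None:
        self.measures = tuple(self.measures)
        self.covariates = tuple(self.covariates)
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(
                f"unknown measure(s) {sorted(unknown)}; valid: {MEASURES}"
            )
        if self.rank_by not in ("absolute", "positive"):
            raise ValueError("rank_by must be 'absolute' or 'positive'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["measures"] = list(self.measures)
        d["covariates"] = list(self.covariates)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _write_matrix(path: Path, values: np.ndarray, labels: list[str]) -> None:
    pd.DataFrame(values, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def run_pipeline(
    config: RunConfig, cohort_paths: dict[str, str | Path], out_dir: str | Path
) -> dict:
    """Run every stage for every configured measure; return the manifest.

    ``cohort_paths`` maps measure name -> cohort TSV/CSV path. Outputs per
    measure land under ``out_dir/<measure>/``; the manifest is written to
    ``out_dir/manifest.json`` and returned.
    """
    missing = set(config.measures) - set(cohort_paths)
    if missing:
        raise ValueError(f"no cohort path for measure(s): {sorted(missing)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = [float(s) for s in sparsity_grid(config.s_min, config.s_max, config.s_step)]
    manifest: dict = {
        "scnet_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "sparsities": grid,
        "measures": {},
    }

    for measure in config.measures:
        stage = "load_cohort"
        try:
            mdir = out_dir / measure
            mdir.mkdir(exist_ok=True)
            cohort = load_cohort(cohort_paths[measure])
            stage = "residualize/covariance"
            residuals = residualize(
                cohort, config.covariates, config.pooled_residualization
            )
            graph_files: list[str] = []
            global_rows = []
            sw_rows = []
            node_frames = []
            for group, rm in residuals.items():
                sigma, a = ledoit_wolf_covariance(rm)
                assoc = partial_correlation(sigma, cohort.regions, a, group)
                _write_matrix(mdir / f"{group}_association.tsv", assoc.values, cohort.regions)
                stage = "sparsity_sweep/metrics"
                graphs = sparsity_sweep(
                    assoc, config.s_min, config.s_max, config.s_step,
                    config.rank_by, measure,
                )
                for g in graphs:
                    ef = mdir / f"{group}_s{g.sparsity:.2f}_edges.txt"
                    ef.write_text(
                        "".join(f"{u}\t{v}\n" for u, v in g.edge_list())
                    )
                    graph_files.append(ef.name)
                    gm = global_metrics(g, config.divide_by_n)
                    global_rows.append(
                        dict(
                            group=group, sparsity=g.sparsity, C=gm.clustering,
                            L=gm.path_length, edges=gm.n_edges,
                            connected=gm.connected,
                            unreachable_pairs=gm.unreachable_pairs,
                            shrinkage=a,
                        )
                    )
                    stage = "small_world"
                    sw = small_world(
                        g, config.n_rand, config.seed, config.swaps_per_edge,
                        divide_by_n=config.divide_by_n,
                    )
                    sw_rows.append(
                        dict(
                            group=group, sparsity=g.sparsity, C_rand=sw.c_rand,
                            L_rand=sw.l_rand, gamma=sw.gamma, lam=sw.lam,
                            sigma=sw.sigma, small_world=sw.small_world,
                        )
                    )
                    if np.isclose(g.sparsity, config.nodal_sparsity):
                        nm = node_metrics(g, config.divide_by_n)
                        nm.insert(0, "group", group)
                        nm.insert(1, "sparsity", g.sparsity)
                        node_frames.append(nm)
            pd.DataFrame(global_rows).to_csv(
                mdir / "global_metrics.tsv", sep="\t", index=False, float_format="%.10g"
            )
            pd.DataFrame(sw_rows).to_csv(
                mdir / "smallworld.tsv", sep="\t", index=False, float_format="%.10g"
            )
            if node_frames:
                pd.concat(node_frames, ignore_index=True).to_csv(
                    mdir / "node_metrics.tsv", sep="\t", index=False,
                    float_format="%.10g",
                )

            stage = "permutation_test"
            bc_sparsities = [
                s for s in grid if np.isclose(s, config.nodal_sparsity)
            ]
            results = permutation_test(
                cohort, tuple(grid), ("C_p", "L_p"), config.n_perm, config.seed,
                config.covariates, config.pooled_residualization, config.rank_by,
                config.divide_by_n,
            )
            comp_rows = []
            for r in results:
                comp_rows.append(
                    dict(
                        metric=r.metric, sparsity=r.sparsity, node="",
                        observed=r.observed, crit_low=r.crit_low,
                        crit_high=r.crit_high,
                        increase=bool(r.significant_increase),
                        decrease=bool(r.significant_decrease),
                    )
                )
            if bc_sparsities:
                bc_results = permutation_test(
                    cohort, tuple(bc_sparsities), ("bc",), config.n_perm,
                    config.seed, config.covariates,
                    config.pooled_residualization, config.rank_by,
                    config.divide_by_n,
                )
                bc_map = betweenness_difference_map(bc_results, bc_sparsities[0])
                bc_map.to_csv(
                    mdir / "betweenness_differences.tsv", sep="\t", index=False,
                    float_format="%.10g",
                )
                r = bc_results[0]
                for i, node in enumerate(r.nodes):
                    comp_rows.append(
                        dict(
                            metric="bc", sparsity=r.sparsity, node=node,
                            observed=r.observed[i], crit_low=r.crit_low[i],
                            crit_high=r.crit_high[i],
                            increase=bool(r.significant_increase[i]),
                            decrease=bool(r.significant_decrease[i]),
                        )
                    )
            pd.DataFrame(comp_rows).to_csv(
                mdir / "comparison.tsv", sep="\t", index=False, float_format="%.10g"
            )
            manifest["measures"][measure] = {
                "cohort": str(cohort_paths[measure]),
                "groups": cohort.groups,
                "n_subjects": cohort.n_subjects,
                "n_regions": len(cohort.regions),
                "graphs": graph_files,
            }
        except Exception as err:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed for measure {measure!r}: {err}"
            ) from err

    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest["config_sha256"] = hashlib.sha256(cfg_yaml.encode()).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
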