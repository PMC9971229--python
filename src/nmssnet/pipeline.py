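"""End-to-end pipeline: psychometrics -> networks -> stability -> comparison.

A single master seed deterministically derives per-stage seeds (layout,
stability bootstrap, comparison permutations), so any stage can be rerun in
isolation with identical results.  Every run writes the resolved config and
a manifest listing each artifact with its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .centrality import fruchterman_reingold, strength, to_graph
from .compare import network_comparison_test
from .network import EstimatorSettings, estimate_network
from .psych import acceptability, reliability, table_one
from .scale import ItemMatrix, aggregate_domains, read_item_csv
from .stability import (
    DEFAULT_DROP_GRID,
    case_dropping_bootstrap,
    cs_coefficient,
    edge_ci_bootstrap,
)

__all__ = ["PipelineConfig", "run_full_pipeline", "stage_seed"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    baseline_csv: str
    followup_csv: str
    output_dir: str
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    bootstrap_B: int = 1000
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    n_perm: int = 1000
    scheme: str = "paired"
    master_seed: int = 0
    solver_tol: float = 1e-4
    solver_max_iter: int = 500

    def settings(self) -> EstimatorSettings:
        return EstimatorSettings(
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            solver_tol=self.solver_tol,
            solver_max_iter=self.solver_max_iter,
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["drop_grid"] = [float(h) for h in self.drop_grid]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "drop_grid" in d:
            d["drop_grid"] = tuple(d["drop_grid"])
        return cls(**d)


_STAGES = ("layout", "stability", "comparison")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the master seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(master_seed), _STAGES.index(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_network_bundle(out: Path, stem: str, net, path, layout_seed: int) -> list[Path]:
    files = []
    edge_csv = out / f"{stem}_edges.csv"
    net.edge_list().to_csv(edge_csv, index=False, float_format="%.6f")
    files.append(edge_csv)

    cent = strength(net)
    cent_csv = out / f"{stem}_centrality.csv"
    cent.to_frame().rename_axis("node").reset_index().to_csv(
        cent_csv, index=False, float_format="%.6f"
    )
    files.append(cent_csv)

    layout = fruchterman_reingold(net, seed=layout_seed)
    g = to_graph(net)
    for k, node in enumerate(net.node_ids):
        g.nodes[node]["x"] = float(layout.xy[k, 0])
        g.nodes[node]["y"] = float(layout.xy[k, 1])
    import networkx as nx

    graphml = out / f"{stem}.graphml"
    nx.write_graphml(g, graphml)
    files.append(graphml)

    bundle = out / f"{stem}.json"
    bundle.write_text(
        json.dumps(
            {
                "node_ids": list(net.node_ids),
                "weights": np.round(net.weights, 8).tolist(),
                "lambda_selected": net.lambda_selected,
                "gamma": net.gamma,
                "n_obs": net.n_obs,
                "n_edges": net.n_edges,
                "ebic_path": path.to_dataframe().round(6).to_dict(orient="list"),
                "layout": {"seed": layout.seed, "xy": np.round(layout.xy, 6).tolist()},
            },
            indent=1,
        )
    )
    files.append(bundle)
    return files


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    timings: dict[str, float] = {}
    stage = "load"
    try:
        baseline = read_item_csv(config.baseline_csv, timepoint="baseline")
        followup = read_item_csv(config.followup_csv, timepoint="followup")

        stage = "psychometrics"
        t0 = time.time()
        for tag, m in (("baseline", baseline), ("followup", followup)):
            acc = acceptability(m)
            rel = reliability(m)
            f = out / f"acceptability_{tag}.csv"
            acc.to_frame().rename_axis("item").reset_index().to_csv(f, index=False)
            files.append(f)
            f = out / f"reliability_{tag}.csv"
            rel.to_frame().rename_axis("domain").reset_index().to_csv(
                f, index=False, float_format="%.6f"
            )
            files.append(f)
        f = out / "table_one.csv"
        table_one(baseline, followup).to_csv(f, index=False, float_format="%.6f")
        files.append(f)
        timings[stage] = time.time() - t0

        stage = "estimation"
        t0 = time.time()
        settings = config.settings()
        layout_seed = stage_seed(config.master_seed, "layout")
        nets = {}
        for tag, m in (("baseline", baseline), ("followup", followup)):
            net, pathd = estimate_network(m, settings)
            nets[tag] = net
            files += _write_network_bundle(out, f"network_{tag}", net, pathd, layout_seed)
            dnet, dpath = estimate_network(aggregate_domains(m), settings)
            files += _write_network_bundle(out, f"network_{tag}_domains", dnet, dpath, layout_seed)
        timings[stage] = time.time() - t0

        stage = "stability"
        t0 = time.time()
        sseed = stage_seed(config.master_seed, "stability")
        for tag, m in (("baseline", baseline), ("followup", followup)):
            cd = case_dropping_bootstrap(
                m, settings, config.drop_grid, B=config.bootstrap_B, seed=sseed
            )
            cs = cs_coefficient(cd)
            f = out / f"casedrop_{tag}.csv"
            cd.to_long_frame().to_csv(f, index=False, float_format="%.6f")
            files.append(f)
            boot = edge_ci_bootstrap(m, settings, B=config.bootstrap_B, seed=sseed)
            f = out / f"edge_ci_{tag}.csv"
            boot.table.to_csv(f, index=False, float_format="%.6f")
            files.append(f)
            f = out / f"stability_{tag}.json"
            f.write_text(
                json.dumps(
                    {
                        "cs_coefficient": cs.value,
                        "criterion_correlation": cs.criterion_correlation,
                        "criterion_probability": cs.criterion_probability,
                        "bootstrap_B": config.bootstrap_B,
                        "edge_ci_failed": boot.n_failed,
                    },
                    indent=1,
                )
            )
            files.append(f)
        timings[stage] = time.time() - t0

        stage = "comparison"
        t0 = time.time()
        nct = network_comparison_test(
            baseline,
            followup,
            settings,
            n_perm=config.n_perm,
            scheme=config.scheme,
            seed=stage_seed(config.master_seed, "comparison"),
        )
        f = out / "nct_edges.csv"
        nct.edge_table.to_csv(f, index=False, float_format="%.6f")
        files.append(f)
        f = out / "nct.json"
        f.write_text(
            json.dumps(
                {
                    "M": nct.m_observed,
                    "S": nct.s_observed,
                    "p_M": nct.p_m,
                    "p_S": nct.p_s,
                    "n_permutations": nct.n_permutations,
                    "scheme": nct.scheme,
                    "n_edges_significant_raw": nct.n_edges_significant_raw,
                    "n_edges_significant_holm": nct.n_edges_significant_holm,
                },
                indent=1,
            )
        )
        files.append(f)
        timings[stage] = time.time() - t0
    except Exception as exc:
        log.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    # config.yaml records paths (output_dir), so it is listed but not part
    # of the checksummed numeric artifacts
    config.to_yaml(out / "config.yaml")
    manifest = {
        "config": "config.yaml",
        "version": __version__,
        "master_seed": config.master_seed,
        "stage_seeds": {s: stage_seed(config.master_seed, s) for s in _STAGES},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "elapsed_s": round(time.time() - t_start, 3),
        "artifacts": {f.name: _sha256(f) for f in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
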