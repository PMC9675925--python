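"""End-to-end reproduction run: load -> train -> report -> importance -> optimize.

``run_pipeline`` executes the whole chain on a study dataset and writes a
report bundle (fit_report.csv, importance.csv, optimization.json,
network.json, run.log) whose contents are a pure function of the
configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .design import StudyDataset, load_dataset, load_packaged_dataset
from .desirability import optimize, spec_from_dataset
from .errors import NlcoptError
from .importance import garson_importance, importance_table, permutation_importance
from .surrogate import TrainConfig, train

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("nlcopt")


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end run."""

    dataset: str = "builtin:table2"  # path or builtin fixture tag
    layer_sizes: tuple[int, ...] = (4, 9, 9, 4)
    n_restarts: int = 20
    k: int = 5
    seed: int = 0
    zeta_mode: str = "raw"
    grid_step: float = 0.05
    n_perm: int = 20
    out_dir: str = "nlcopt_report"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    config: PipelineConfig
    fit_report: "object"
    importance: "object"
    optimization: "object"
    network: "object"
    out_dir: Path


def _load(config: PipelineConfig) -> StudyDataset:
    if config.dataset == "builtin:table2":
        return load_packaged_dataset()
    path = Path(config.dataset)
    if not path.exists():
        raise NlcoptError(f"dataset not found: {path}")
    return load_dataset(path)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis chain and write the report bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "load"
    try:
        log.info("stage=load seed=%d config=%s version=%s",
                 config.seed, config.config_hash(), __version__)
        data = _load(config)

        stage = "train"
        log.info("stage=train restarts=%d k=%d", config.n_restarts, config.k)
        net, report = train(
            data,
            layer_sizes=config.layer_sizes,
            config=TrainConfig(n_restarts=config.n_restarts, k=config.k),
            seed=config.seed,
        )

        stage = "importance"
        log.info("stage=importance n_perm=%d", config.n_perm)
        results = []
        for resp in net.response_names:
            results.append(garson_importance(net, resp))
            results.append(
                permutation_importance(net, data.actual, resp,
                                       seed=config.seed, n_perm=config.n_perm)
            )
        imp = importance_table(results)

        stage = "optimize"
        log.info("stage=optimize grid_step=%g", config.grid_step)
        spec = spec_from_dataset(data, zeta_mode=config.zeta_mode)
        opt = optimize(net, spec, data.factors, grid_step=config.grid_step)

        stage = "write"
        report.to_csv(out / "fit_report.csv")
        imp.to_csv(out / "importance.csv", index=False)
        meta = {"config_hash": config.config_hash(), "seed": config.seed,
                "package_version": __version__}
        with open(out / "optimization.json", "w") as fh:
            json.dump({**meta, **opt.to_dict()}, fh, indent=1)
        with open(out / "network.json", "w") as fh:
            json.dump({**meta, **net.to_dict()}, fh, indent=1)
        log.info("stage=done wall_s=%.1f", time.time() - t0)
    except Exception:
        (out / "FAILED").write_text(f"stage={stage}\n")
        log.exception("stage=%s failed", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return ReportBundle(config=config, fit_report=report, importance=imp,
                        optimization=opt, network=net, out_dir=out)
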