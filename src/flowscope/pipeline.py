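"""End-to-end pipeline: LCC -> sweep -> plateaus -> RBS -> RMST -> roles ->
role mixes -> organigrams, with all artifacts written to an output directory.

Every run writes its resolved configuration and the package version next to
the outputs, and is deterministic given the master seed: running the same
config twice produces byte-identical summary files.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from . import __version__
from .dynamics import DEFAULT_TAU
from .graph_io import (
    DirectedNetwork,
    largest_weakly_connected_component,
    read_edge_list,
    write_graphml,
    write_partition_csv,
)
from .rbs import DEFAULT_BETA, build_feature_matrix, cosine_similarity
from .rmst import DEFAULT_GAMMA, rmst, similarity_to_distance
from .roles import DEFAULT_ROLE_GAMMA, cluster_role_mixes, detect_roles, role_mix
from .sweep import select_robust_partitions, stability_sweep
from .partition import Partition

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage (partial artifacts are retained)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully serializable configuration of an end-to-end run."""

    edges: str = ""
    out_dir: str = "flowscope_out"
    delimiter: str | None = None
    weighted: bool = True
    tau: float = DEFAULT_TAU
    t_min: float = 1e-2
    t_max: float = 1e1
    n_times: int = 100
    n_runs: int = 100
    vi_tol: float | None = None
    min_plateau: int = 5
    beta: float = DEFAULT_BETA
    k_max: int | str = "auto"
    gamma: float = DEFAULT_GAMMA
    role_gamma: float = DEFAULT_ROLE_GAMMA
    role_n_times: int = 64
    role_n_runs: int = 12
    organigram_k: int | str = "auto"
    kmeans_restarts: int = 50
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not serializable: {type(x)}")


def run_pipeline(cfg: RunConfig, network: DirectedNetwork | None = None) -> dict:
    """Execute the full flow analysis and write artifacts to ``cfg.out_dir``.

    ``network`` may be passed directly (e.g. from a synthetic generator);
    otherwise it is read from ``cfg.edges``.  Returns the machine-readable
    summary dict that is also written to ``summary.json``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _json_dump({"config": cfg.to_dict(), "version": __version__},
               out / "config.json")

    summary: dict = {"version": __version__, "seed": cfg.seed}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - report stage and re-raise
            logger.error("stage=%s failed: %s", name, exc)
            raise PipelineError(name, exc) from exc
        logger.info("stage=%s seed=%d wall=%.2fs", name, cfg.seed,
                    time.perf_counter() - t0)
        return result

    # --- read + largest weakly connected component ------------------------
    def _read():
        net = network if network is not None else read_edge_list(
            cfg.edges, delimiter=cfg.delimiter, weighted=cfg.weighted
        )
        if net.has_self_loops:
            net = net.without_self_loops()
        return largest_weakly_connected_component(net)

    net = stage("read", _read)
    summary["n_nodes"] = net.N
    summary["n_edges"] = net.n_edges

    # --- multiscale sweep --------------------------------------------------
    times = np.logspace(np.log10(cfg.t_min), np.log10(cfg.t_max), cfg.n_times)

    def _sweep():
        seq = stability_sweep(
            net, times=times, n_runs=cfg.n_runs, tau=cfg.tau, seed=cfg.seed
        )
        seq.save(out)
        return seq

    seq = stage("sweep", _sweep)
    summary["k_per_time"] = {
        format(t, ".17g"): int(k) for t, k in zip(seq.times, seq.k)
    }

    # --- robust plateaus ----------------------------------------------------
    def _plateaus():
        wins = select_robust_partitions(
            seq, vi_tol=cfg.vi_tol, min_plateau=cfg.min_plateau
        )
        for i, ((t0, t1), part) in enumerate(wins):
            write_partition_csv(part, out / f"plateau_{i}.csv")
        return wins

    windows = stage("plateaus", _plateaus)
    summary["plateaus"] = [
        {"t_start": format(t0, ".17g"), "t_end": format(t1, ".17g"),
         "k": part.k}
        for (t0, t1), part in windows
    ]

    # --- RBS ---------------------------------------------------------------
    def _rbs():
        Xf = build_feature_matrix(net, beta=cfg.beta, k_max=cfg.k_max)
        Y = cosine_similarity(Xf)
        scipy.io.mmwrite(out / "X.mtx", scipy.sparse.csr_matrix(Xf.X))
        scipy.io.mmwrite(out / "Y.mtx", scipy.sparse.csr_matrix(Y.Y))
        return Xf, Y

    Xf, Y = stage("rbs", _rbs)
    summary["k_max"] = Xf.k_max
    summary["alpha"] = Xf.alpha

    # --- RMST --------------------------------------------------------------
    def _rmst():
        rsg = rmst(similarity_to_distance(Y), gamma=cfg.gamma, similarity=Y)
        write_graphml(rsg.to_network(), out / "rmst.graphml")
        return rsg

    rsg = stage("rmst", _rmst)
    summary["rmst_edges"] = rsg.n_edges

    # --- roles -------------------------------------------------------------
    def _roles():
        # a denser role graph than the exported RMST artifact: see
        # roles.DEFAULT_ROLE_GAMMA
        role_rsg = rmst(
            similarity_to_distance(Y), gamma=cfg.role_gamma, similarity=Y
        )
        role_times = np.logspace(
            np.log10(cfg.t_min), np.log10(cfg.t_max), cfg.role_n_times
        )
        roles = detect_roles(
            role_rsg, net, times=role_times, n_runs=cfg.role_n_runs,
            seed=cfg.seed, min_plateau=cfg.min_plateau,
        )
        roles.to_frame().to_csv(out / "roles.csv", index=False)
        return roles

    roles = stage("roles", _roles)
    summary["n_roles"] = roles.n_roles
    summary["roles_fallback"] = roles.fallback

    # --- role mixes + organigrams ------------------------------------------
    def _mixes():
        part = windows[-1][1] if windows else seq.partitions[len(times) // 2]
        mix = role_mix(part, roles)
        mix.to_frame().to_csv(out / "role_mixes.csv", index=False,
                              float_format="%.17g")
        return part, mix

    part, mix = stage("mixes", _mixes)
    summary["mix_partition_k"] = part.k

    def _organigrams():
        if part.k < 2:
            return None
        org = cluster_role_mixes(
            mix, k=cfg.organigram_k, n_restarts=cfg.kmeans_restarts,
            seed=cfg.seed,
        )
        frame = mix.to_frame()
        frame["organigram"] = org.labels
        frame.to_csv(out / "organigrams.csv", index=False, float_format="%.17g")
        return org

    org = stage("organigrams", _organigrams)
    summary["organigram_types"] = None if org is None else int(org.k)
    summary["organigram_labels"] = (
        None if org is None else [int(x) for x in org.labels]
    )

    _json_dump(summary, out / "summary.json")
    return summary
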