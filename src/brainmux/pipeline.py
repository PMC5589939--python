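"""End-to-end orchestration: ingest -> connectivity -> networks -> metrics
-> statistics -> classification, with data-driven threshold selection.

Every stage writes its outputs under the configured directory; the summary
JSON records the config hash and seed so runs can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as bio
from .bands import DEFAULT_BANDS
from .classify import feature_grid_search
from .graph_metrics import modularity_partition, participation_coefficient
from .multiplex import layer_degree_cv, multi_participation_coefficient
from .netbuild import build_multiplex, threshold_to_mean_degree
from .spectral import (
    BandConnectome,
    EpochSignals,
    average_epochs,
    band_average,
    coherence_matrix,
    imaginary_coherence_matrix,
)
from .stats import fdr_adjust, nodewise_group_test, permutation_ttest, spearman_correlation

__all__ = ["PipelineConfig", "select_threshold", "run_pipeline"]

logger = logging.getLogger("brainmux.pipeline")


@dataclass
class PipelineConfig:
    """Tunable parameters of one full analysis run."""

    k_grid: tuple[int, ...] = (1, 3, 6, 12, 24, 48)
    measure: str = "coherence"  # or "imcoh"
    n_permutations: int = 10000
    fdr_q: float = 0.05
    alpha: float = 0.05
    cv_iterations: int = 200
    max_k_features: int = 2
    modularity_restarts: int = 10
    seed: int = 0
    fallback_k: int = 12
    run_classification: bool = True
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.k_grid or list(self.k_grid) != sorted(set(self.k_grid)):
            raise ValueError("k grid must be nonempty and strictly ascending")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.measure not in ("coherence", "imcoh"):
            raise ValueError("measure must be 'coherence' or 'imcoh'")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "k_grid" in data:
            data["k_grid"] = tuple(data["k_grid"])
        return cls(**data)

    def config_hash(self) -> str:
        params = asdict(self)
        params.pop("out_dir")  # run location is not an analysis parameter
        canon = json.dumps(params, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def select_threshold(
    global_results_per_k: dict[int, tuple[float, float]], alpha: float = 0.05
) -> int | None:
    """Smallest k whose single-layer AND multiplex global tests are both
    significant; ``None`` if no k qualifies."""
    if not global_results_per_k:
        raise ValueError("no per-threshold results supplied")
    for k in sorted(global_results_per_k):
        entry = global_results_per_k[k]
        if entry is None or len(entry) != 2:
            raise ValueError(f"missing or malformed result for k={k}")
        p_pc, p_mpc = entry
        if p_pc < alpha and p_mpc < alpha:
            return k
    return None


def _load_subject_connectome(subj: dict, base: Path, measure: str) -> BandConnectome:
    """Entry-point flexibility: per-band matrices if present, else signals."""
    if "matrices_dir" in subj:
        return bio.read_band_connectome(base / subj["matrices_dir"])
    if "signals" in subj:
        fs = subj["fs"]
        per_epoch = []
        estimator = coherence_matrix if measure == "coherence" else imaginary_coherence_matrix
        for path in subj["signals"]:
            data = np.loadtxt(base / path, delimiter=",")
            sc = estimator(EpochSignals(data=data, fs=fs))
            per_epoch.append(band_average(sc, DEFAULT_BANDS))
        return average_epochs(per_epoch)
    raise ValueError(f"subject {subj.get('id')!r} has neither 'matrices_dir' nor 'signals'")


def _subject_metrics(
    bc: BandConnectome, k: int, seed: int, restarts: int, gamma_band: str = "gamma"
) -> dict:
    """Threshold all layers at degree k; global/local MPC and gamma-band PC."""
    layers = [threshold_to_mean_degree(m, k) for m in bc.matrices]
    mx = build_multiplex(layers, layer_names=bc.scheme.names)
    mpc_i, mpc_g = multi_participation_coefficient(mx)
    cv_i, cv_g = layer_degree_cv(mx)
    gamma = layers[bc.scheme.index(gamma_band)]
    if gamma.sum() > 0:
        part = modularity_partition(gamma, seed=seed, restarts=restarts)
        pc_i, pc_g = participation_coefficient(gamma, part)
    else:
        pc_i, pc_g = np.zeros(mx.n_nodes), 0.0
    return {"mpc_i": mpc_i, "mpc": mpc_g, "cv": cv_g, "pc_i": pc_i, "pc": pc_g}


def run_pipeline(config: PipelineConfig, manifest_path: str | Path) -> dict:
    """Run the full analysis and write a machine-readable summary.

    Stage order: ingest (signals or matrices) -> per-threshold global tests
    -> threshold selection -> local tests with FDR at k* -> score
    correlations (AD group) -> classification grid on the top-ranked local
    features. Deterministic under ``config.seed``.
    """
    t0 = time.time()
    manifest_path = Path(manifest_path)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "pipeline.log")
    logger.info("stage=config hash=%s seed=%d", config.config_hash(), config.seed)

    manifest = bio.read_manifest(manifest_path)
    base = manifest_path.parent
    subjects = manifest["subjects"]

    stage_t = time.time()
    connectomes, labels, ids = [], [], []
    for subj in subjects:
        connectomes.append(_load_subject_connectome(subj, base, config.measure))
        labels.append(subj["group"])
        ids.append(subj["id"])
    labels = np.array(labels)
    logger.info("stage=ingest n_subjects=%d elapsed=%.2fs", len(ids), time.time() - stage_t)

    # per-threshold global statistics
    per_k_results: dict[int, tuple[float, float]] = {}
    per_k_metrics: dict[int, list[dict]] = {}
    summary_per_k = {}
    for k in config.k_grid:
        stage_t = time.time()
        try:
            metrics = [
                _subject_metrics(bc, k, config.seed, config.modularity_restarts)
                for bc in connectomes
            ]
        except ValueError as exc:
            raise RuntimeError(f"stage=metrics k={k} failed: {exc}") from exc
        per_k_metrics[k] = metrics
        mpc = np.array([m["mpc"] for m in metrics])
        pc = np.array([m["pc"] for m in metrics])
        ad, hc = labels == "AD", labels == "HC"
        res_mpc = permutation_ttest(
            mpc[ad], mpc[hc], B=config.n_permutations, seed=config.seed, feature_id="MPC"
        )
        res_pc = permutation_ttest(
            pc[ad], pc[hc], B=config.n_permutations, seed=config.seed, feature_id="PC_gamma"
        )
        per_k_results[k] = (res_pc.p, res_mpc.p)
        summary_per_k[str(k)] = {
            "PC_gamma": {"z": res_pc.z, "p": res_pc.p},
            "MPC": {"z": res_mpc.z, "p": res_mpc.p},
        }
        logger.info("stage=global_tests k=%d elapsed=%.2fs", k, time.time() - stage_t)

    k_star = select_threshold(per_k_results, alpha=config.alpha)
    if k_star is None:
        logger.warning(
            "stage=threshold_selection no k significant for both analyses; "
            "falling back to k=%d", config.fallback_k,
        )
        k_used = config.fallback_k if config.fallback_k in per_k_metrics else min(per_k_metrics)
    else:
        k_used = k_star
    logger.info("stage=threshold_selection k_star=%s k_used=%d", k_star, k_used)

    # local tests at the selected threshold
    stage_t = time.time()
    metrics = per_k_metrics[k_used]
    mpc_local = np.stack([m["mpc_i"] for m in metrics])
    pc_local = np.stack([m["pc_i"] for m in metrics])
    local = {}
    for name, feats in (("MPC", mpc_local), ("PC_gamma", pc_local)):
        res = nodewise_group_test(
            feats, labels, B=config.n_permutations, seed=config.seed
        )
        reject, p_adj = fdr_adjust(np.array([r.p for r in res]), q=config.fdr_q)
        local[name] = {
            "n_significant": int(reject.sum()),
            "significant_nodes": np.flatnonzero(reject).tolist(),
            "p": [r.p for r in res],
            "z": [r.z for r in res],
            "p_adjusted": p_adj.tolist(),
        }
        _write_local_tsv(out / f"local_{name}.tsv", res, reject, p_adj)
    logger.info("stage=local_tests k=%d elapsed=%.2fs", k_used, time.time() - stage_t)

    # score correlations within the AD group
    correlations = {}
    ad_mask = labels == "AD"
    scores = {s["id"]: s for s in subjects}
    for score_name, feat_name, feat_vec in (
        ("MMSE", "PC_gamma", np.array([m["pc"] for m in metrics])),
        ("TR", "MPC", np.array([m["mpc"] for m in metrics])),
    ):
        vals = np.array([scores[i].get(score_name, np.nan) for i in ids], dtype=float)
        sel = ad_mask & np.isfinite(vals)
        if sel.sum() >= 3 and np.ptp(vals[sel]) > 0 and np.ptp(feat_vec[sel]) > 0:
            r, p = spearman_correlation(
                feat_vec[sel], vals[sel], B=config.n_permutations, seed=config.seed
            )
            correlations[f"{feat_name}_vs_{score_name}"] = {"R": r, "p": p, "n": int(sel.sum())}

    # classification on top-ranked local features
    classification = None
    if config.run_classification:
        stage_t = time.time()
        grid = feature_grid_search(
            pc_local,
            mpc_local,
            labels,
            max_k_each=config.max_k_features,
            n_iter=config.cv_iterations,
            seed=config.seed,
        )
        classification = {
            "best_cell": list(grid["best_cell"]),
            "best_acc": grid["best_acc"],
            "acc": _grid_to_list(grid["acc"]),
            "sens": _grid_to_list(grid["sens"]),
            "spec": _grid_to_list(grid["spec"]),
            "auc": _grid_to_list(grid["auc"]),
        }
        logger.info("stage=classification elapsed=%.2fs", time.time() - stage_t)

    summary = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_subjects": len(ids),
        "global_tests_per_k": summary_per_k,
        "k_star": k_star,
        "k_used": k_used,
        "local_tests": {
            name: {kk: vv for kk, vv in d.items() if kk != "p_adjusted"}
            for name, d in local.items()
        },
        "correlations": correlations,
        "classification": classification,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("stage=done elapsed=%.2fs", time.time() - t0)
    return summary


def _grid_to_list(mat: np.ndarray) -> list:
    return [[None if np.isnan(v) else float(v) for v in row] for row in mat]


def _write_local_tsv(path: Path, results, reject, p_adj) -> None:
    with open(path, "w") as fh:
        fh.write("node_id\tstatistic\tZ\tp\tp_adjusted\tsignificant\n")
        for r, rej, pa in zip(results, reject, p_adj):
            fh.write(
                f"{r.feature_id}\t{r.statistic:.6f}\t{r.z:.6f}\t{r.p:.6g}\t"
                f"{pa:.6g}\t{int(rej)}\n"
            )


def _setup_logging(logfile: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(logfile)):
        handler.setFormatter(fmt)
        logger.addHandler(handler)
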