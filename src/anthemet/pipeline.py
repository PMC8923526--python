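"""End-to-end orchestration: simulate -> preprocess -> rates -> fit (M/E/C)
-> refit panel -> PCA/clustering -> CA networks & diurnal screen.

Every stage writes plain-text outputs that the next stage can reload, and
``run_all`` records a reproducibility manifest (seeds, thresholds, stage
outputs and their SHA-256 checksums).  Identical configuration and seed
give byte-identical outputs and manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .canet import (aggregate_by_characteristic, correspondence_analysis,
                    cross_distances, diurnal_stability, metabolite_network,
                    nonneg_shift, percentile_threshold)
from .lasso import default_alpha_grid, refit_panel
from .model import AnthesisLassoModel
from .preprocess import MetaboliteMatrix, PeakTable, preprocess_peak_table, standardize
from .rates import AnthesisSeries, assign_rates_to_samples, rate_table
from .simulate import SyntheticSpec, spec_from_yaml, write_dataset
from .structure import correlation_distance_matrix, cut_clusters, pca, select_linkage

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "rates", "fit", "refit", "structure", "network"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; the study-stated constants
    (S/N 2, half-fraction, alpha in [5e-5, 0.5], k = 10, 15th percentile,
    cluster cut 0.5) are defaults here, never hard-coded in the stages."""

    seed: int = 7
    snr_threshold: float = 2.0
    min_fraction: float = 0.5
    alpha_min: float = 5e-5
    alpha_max: float = 0.5
    n_alphas: int = 50
    k_folds: int = 10
    elbow_tol: float = 0.02
    ca_percentile: float = 0.15
    cut_height: float = 0.5
    characteristics: tuple[str, ...] = ("experiment", "cultivar", "sampling_time", "day_night")
    variants: tuple[str, ...] = ("metabolome", "environment", "combined")
    timeseries_experiment: str = "TK01"
    synthetic: SyntheticSpec | None = None   # None -> full three-experiment study

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if isinstance(synth, str):
            cfg.synthetic = spec_from_yaml(synth)
        elif isinstance(synth, dict):
            from .simulate import ExperimentSpec
            exps = synth.pop("experiments", None)
            if exps is not None:
                synth["experiments"] = tuple(
                    ExperimentSpec(**{**e, "cultivars": tuple(e["cultivars"])
                                      if e.get("cultivars") else None}) for e in exps)
            for key in ("cultivars", "support_indices", "beta", "diurnal_amplitudes"):
                if synth.get(key) is not None:
                    synth[key] = tuple(synth[key])
            cfg.synthetic = SyntheticSpec(**synth)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(path: Path, payload) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def run_all(config: RunConfig, out_dir) -> dict:
    """Execute every stage in order under ``out_dir``; returns the manifest
    (also written to manifest.json).  Any stage failure aborts with the
    stage name attached."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()
                   if k != "synthetic"},
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        logger.info("stage %s", stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "outputs": {name: str(Path(p).relative_to(out)) for name, p in outputs.items()},
            "checksums": {name: _sha256(Path(p)) for name, p in outputs.items()},
        }
    manifest["n_stages"] = len(STAGES)
    _write_json(out / "manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    spec = config.synthetic or SyntheticSpec.full_study(seed=config.seed)
    spec = dataclasses.replace(spec, seed=config.seed)
    paths = write_dataset(spec, out / "data")
    state["spec"] = spec
    state["data_paths"] = paths
    return {k: str(p) for k, p in paths.items()}


def _stage_preprocess(config: RunConfig, out: Path, state: dict) -> dict:
    paths = state["data_paths"]
    table = PeakTable.from_csv(paths["peaks"], paths["blanks"])
    matrix = preprocess_peak_table(
        table, snr_threshold=config.snr_threshold, min_fraction=config.min_fraction
    )
    state["matrix_raw"] = matrix
    state["matrix_std"] = standardize(matrix)
    p = out / "matrix_relative.csv"
    matrix.to_csv(p)
    return {"matrix": str(p)}


def _stage_rates(config: RunConfig, out: Path, state: dict) -> dict:
    anthesis = pd.read_csv(state["data_paths"]["anthesis"], parse_dates=["date"])
    series = AnthesisSeries.from_frame(anthesis)
    rates = rate_table(series)
    meta = state["matrix_raw"].sample_meta.copy()
    meta["group"] = meta["experiment"] + ":" + meta["cultivar"]
    y = assign_rates_to_samples(rates, meta)
    state["rates"] = rates
    state["y"] = y
    p = out / "rates.csv"
    rates.to_csv(p, index=False, float_format="%.8g")
    return {"rates": str(p)}


def _fit_variant(config: RunConfig, state: dict, variant: str):
    matrix = state["matrix_std"]
    mask = matrix.sample_meta["experiment"] == config.timeseries_experiment
    sub = state["matrix_raw"].select_samples(mask.to_numpy())
    env = pd.read_csv(state["data_paths"]["environment"], index_col=0)
    env = env.loc[sub.values.index] if variant != "metabolome" else None
    model = AnthesisLassoModel.from_matrix(
        sub, state["y"][mask.to_numpy()], environment=env, variant=variant
    )
    grid = default_alpha_grid(config.alpha_min, config.alpha_max, config.n_alphas)
    sweep = model.sweep(grid, k=config.k_folds, seed=config.seed)
    return model, sweep


def _stage_fit(config: RunConfig, out: Path, state: dict) -> dict:
    outputs = {}
    state["fits"] = {}
    for variant in config.variants:
        model, sweep = _fit_variant(config, state, variant)
        chosen = sweep.select_elbow(config.elbow_tol)
        results = sweep.results_at(chosen)
        state["fits"][variant] = {"model": model, "sweep": sweep,
                                  "chosen": chosen, "results": results}
        sweep_path = out / f"sweep_{variant}.csv"
        sweep.frame.to_csv(sweep_path, index=False, float_format="%.8g")
        chosen_path = out / f"model_{variant}.json"
        _write_json(chosen_path, {
            "variant": variant,
            "n_samples": model.design.n,
            "alpha": chosen.alpha,
            "train_r2": chosen.train_r2,
            "cv_r2": chosen.cv_r2,
            "cv_mse": chosen.cv_mse,
            "support_size": chosen.support_size,
            "support_ids": chosen.support_ids,
            "intercept": results.intercept,
            "coefficients": {k: float(v) for k, v in
                             results.params[results.params != 0].items()},
        })
        outputs[f"sweep_{variant}"] = str(sweep_path)
        outputs[f"model_{variant}"] = str(chosen_path)
    state["panel"] = state["fits"]["metabolome"]["chosen"].support_ids
    return outputs


def _stage_refit(config: RunConfig, out: Path, state: dict) -> dict:
    from .lasso import DesignMatrix

    matrix = state["matrix_raw"]
    panel = state["panel"]
    designs = []
    for exp in sorted(matrix.sample_meta["experiment"].unique()):
        mask = (matrix.sample_meta["experiment"] == exp).to_numpy()
        sub = matrix.select_samples(mask)
        designs.append(DesignMatrix(
            sub.values.to_numpy(), state["y"][mask].to_numpy(),
            list(sub.values.columns),
        ))
    grid = default_alpha_grid(config.alpha_min, config.alpha_max, config.n_alphas)
    solution, record, records = refit_panel(
        panel, designs, grid, k=config.k_folds, seed=config.seed
    )
    state["refit"] = {"solution": solution, "record": record}
    p = out / "refit_panel.json"
    _write_json(p, {
        "panel_size": len(panel),
        "alpha": record.alpha,
        "train_r2": record.train_r2,
        "cv_r2": record.cv_r2,
        "cv_mse": record.cv_mse,
        "support_size": record.support_size,
        "support_ids": record.support_ids,
        "coefficients": {fid: float(w) for fid, w in
                         zip(solution.feature_ids, solution.w) if w != 0},
    })
    return {"refit": str(p)}


def _stage_structure(config: RunConfig, out: Path, state: dict) -> dict:
    matrix = state["matrix_std"]
    panel = state["panel"]
    result = pca(matrix, n_components=2)
    scores_path = out / "pca_scores.csv"
    loadings_path = out / "pca_loadings.csv"
    result.scores.assign(**{
        "contribution_PC1": result.contribution_ratios[0],
        "contribution_PC2": result.contribution_ratios[1] if len(result.contribution_ratios) > 1 else np.nan,
    }).to_csv(scores_path, float_format="%.8g")
    result.loadings.to_csv(loadings_path, float_format="%.8g")

    dist = correlation_distance_matrix(matrix, panel)
    method, dendro, table = select_linkage(dist)
    clusters = cut_clusters(dendro, config.cut_height)
    state["clusters"] = clusters
    coph_path = out / "cophenetic_table.csv"
    table.to_csv(coph_path, index=False, float_format="%.10g")
    tree_path = out / "dendrogram.nwk"
    tree_path.write_text(dendro.to_newick() + "\n")
    clusters_path = out / "clusters.csv"
    clusters.to_csv(clusters_path, header=True)
    return {"pca_scores": str(scores_path), "pca_loadings": str(loadings_path),
            "cophenetic_table": str(coph_path), "dendrogram": str(tree_path),
            "clusters": str(clusters_path)}


def _stage_network(config: RunConfig, out: Path, state: dict) -> dict:
    matrix = state["matrix_std"]
    panel = state["panel"]
    shifted = nonneg_shift(matrix.subset(panel))
    ca = correspondence_analysis(shifted.values)
    dists = cross_distances(ca)
    threshold, edge_list = percentile_threshold(dists, config.ca_percentile)
    outputs = {}
    edges_path = out / "metabolite_sample_edges.tsv"
    edge_list.passed.to_csv(edges_path, sep="\t", index=False, float_format="%.8g")
    outputs["metabolite_sample_edges"] = str(edges_path)
    meta = matrix.sample_meta
    char_nets = {}
    for characteristic in config.characteristics:
        net = aggregate_by_characteristic(edge_list, meta, characteristic)
        char_nets[characteristic] = net
        p = out / f"network_{characteristic}.tsv"
        net.to_csv(p, sep="\t", index=False, float_format="%.8g")
        outputs[f"network_{characteristic}"] = str(p)
    mthr, mnet = metabolite_network(ca.col_coords, config.ca_percentile)
    mpath = out / "metabolite_network.graphml"
    mnet.to_graphml(mpath)
    outputs["metabolite_network"] = str(mpath)

    ts_mask = (meta["experiment"] == config.timeseries_experiment).to_numpy()
    ts_matrix = state["matrix_raw"].select_samples(ts_mask)
    dn_net = char_nets.get("day_night")
    records = diurnal_stability(ts_matrix, panel, dn_net)
    stab = pd.DataFrame([dataclasses.asdict(r) for r in records])
    spath = out / "diurnal_stability.csv"
    stab.to_csv(spath, index=False, float_format="%.8g")
    state["stability"] = stab
    state["ca_threshold"] = threshold
    outputs["diurnal_stability"] = str(spath)
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "rates": _stage_rates,
    "fit": _stage_fit,
    "refit": _stage_refit,
    "structure": _stage_structure,
    "network": _stage_network,
}


def compare_variants(manifests_or_dirs) -> pd.DataFrame:
    """Tabulate train R^2, CV R^2 and CV MSE per model variant from one or
    more run directories (or already-loaded manifests)."""
    rows = []
    for item in manifests_or_dirs:
        if isinstance(item, (str, Path)):
            run_dir = Path(item)
            with open(run_dir / "manifest.json") as fh:
                manifest = json.load(fh)
        else:
            manifest = item
            run_dir = None
        fit_outputs = manifest["stages"]["fit"]["outputs"]
        for name, rel in sorted(fit_outputs.items()):
            if not name.startswith("model_"):
                continue
            if run_dir is None:
                continue
            with open(run_dir / rel) as fh:
                payload = json.load(fh)
            rows.append({
                "variant": payload["variant"],
                "train_r2": payload["train_r2"],
                "cv_r2": payload["cv_r2"],
                "cv_mse": payload["cv_mse"],
                "support_size": payload["support_size"],
            })
    return pd.DataFrame(rows)
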