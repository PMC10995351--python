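"""End-to-end orchestration: simulate -> screen -> extract -> train ->
prune -> retrain -> explain -> evaluate -> report.

:func:`run_pipeline` executes the whole chain from a validated
:class:`~pathshap.config.RunConfig`, returns every intermediate product
in memory, and (optionally) writes a run directory of CSV/JSON artifacts
plus a manifest with the configuration, all derived seeds, and SHA-256
hashes of every written file — reruns with the same config hash
identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import features, metrics, pathweights, screening, shapley, snn, synthetic
from .config import RunConfig
from .synthetic import CATEGORIES


@dataclass
class PipelineResult:
    config: RunConfig
    cohort: synthetic.Cohort
    selected_stimuli: dict[str, list[int]]
    train_instances: pd.DataFrame
    test_instances: pd.DataFrame
    best_params: snn.NetworkParams
    search_table: pd.DataFrame
    elbows: list[pathweights.ElbowResult]
    retrained_params: snn.NetworkParams
    prune_report: dict
    shap_hidden: shapley.ShapResult
    shap_input: shapley.ShapResult
    shap_summary: dict[str, pd.DataFrame]
    explained_instances: pd.DataFrame
    confusions: dict[str, metrics.ConfusionMatrix]
    accuracies: dict[str, float]
    recovery: pd.DataFrame


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    vals = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(names))]
    return dict(zip(names, vals))


def informative_ic_ranks(
    shap_input: shapley.ShapResult,
    truth: synthetic.GroundTruth,
    labels: np.ndarray,
) -> pd.DataFrame:
    """Rank each truly informative IC for its own category's output.

    For category c, ICs are ordered by decreasing mean |phi| on output c
    over the explained instances *of category c*; the table reports each
    informative IC's 1-based rank among the 125.
    """
    labels = np.asarray(labels)
    rows = []
    for k, cat in enumerate(CATEGORIES):
        sel = labels == cat
        phi = shap_input.phi[sel][:, :, k] if sel.any() else shap_input.phi[:, :, k]
        mean_abs = np.abs(phi).mean(axis=0)
        order = np.argsort(-mean_abs, kind="stable")
        rank_of = np.empty_like(order)
        rank_of[order] = np.arange(1, len(order) + 1)
        for ic in truth.informative.get(cat, ()):
            rows.append((cat, f"IC{ic + 1}", int(rank_of[ic]), mean_abs[ic]))
    return pd.DataFrame(rows, columns=["category", "ic", "rank", "mean_abs_phi"])


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    cfg = config.effective()
    seeds = _stage_seeds(
        cfg.seed,
        ["ratings", "selection", "cohort", "train", "retrain", "background",
         "shap", "explain_subset"],
    )

    # -- simulate & screen ------------------------------------------------
    ratings = synthetic.gen_ratings(cfg.screening.n_stimuli, seed=seeds["ratings"])
    preferred, indifferent = screening.screen_and_select(
        ratings, n_per_group=cfg.screening.n_per_group, seed=seeds["selection"]
    )
    truth = synthetic.GroundTruth.default(
        effect_size=cfg.cohort.effect_size, noise_sd=cfg.cohort.noise_sd
    )
    cohort = synthetic.gen_cohort(
        truth=truth,
        n_train=cfg.cohort.n_train,
        n_test=cfg.cohort.n_test,
        seed=seeds["cohort"],
        n_per_category=cfg.cohort.n_per_category,
        n_volumes=cfg.cohort.n_volumes,
        n_ics=cfg.cohort.n_ics,
        tr_seconds=cfg.cohort.tr_seconds,
    )

    # -- extract ----------------------------------------------------------
    instances = features.build_instances(
        cohort, volume_offset=cfg.features.volume_offset
    )
    train_df, test_df = features.split_instances(instances)
    train_df, test_df = features.standardize(
        train_df, test_df, mode=cfg.features.standardize_mode
    )
    X_tr, y_tr = features.as_xy(train_df)
    X_te, y_te = features.as_xy(test_df)
    T_tr = snn.one_hot(y_tr)

    # -- train ------------------------------------------------------------
    best_params, search_table = snn.grid_search(
        X_tr, T_tr, X_te, y_te,
        lr_grid=cfg.train.lr_grid,
        momentum_grid=cfg.train.momentum_grid,
        epochs=cfg.train.epochs,
        n_restarts=cfg.train.n_restarts,
        seed=seeds["train"],
        init_scale=cfg.train.init_scale,
        n_hidden=cfg.train.n_hidden,
    )

    # -- prune & retrain --------------------------------------------------
    pw = pathweights.compute_path_weights(best_params)
    elbows = [pathweights.find_elbows(pw, k) for k in range(pw.shape[2])]
    masks = pathweights.build_prune_masks(pw, elbows)
    retrained, prune_report = pathweights.prune_and_retrain(
        best_params, masks, X_tr, T_tr, X_te, y_te,
        lr_grid=cfg.retrain.lr_grid,
        momentum_grid=cfg.retrain.momentum_grid,
        epochs=cfg.retrain.epochs,
        n_restarts=cfg.retrain.n_restarts,
        seed=seeds["retrain"],
    )
    pruned = best_params.with_masks(*masks)

    # -- explain ----------------------------------------------------------
    background = shapley.draw_background(
        X_tr, n=min(cfg.explain.background_n, len(X_tr)), seed=seeds["background"]
    )
    n_expl = cfg.explain.n_instances
    if n_expl is None or n_expl >= len(X_te):
        expl_idx = np.arange(len(X_te))
    else:
        # stratified by category so every output has explained instances
        rng = np.random.default_rng(seeds["explain_subset"])
        per_cat = max(1, n_expl // len(CATEGORIES))
        picks = []
        for cat in CATEGORIES:
            pool = np.flatnonzero(y_te == cat)
            picks.append(rng.choice(pool, size=min(per_cat, len(pool)), replace=False))
        expl_idx = np.sort(np.concatenate(picks))
    X_expl = X_te[expl_idx]
    explained_df = test_df.iloc[expl_idx].reset_index(drop=True)

    g, to_hidden = shapley.hidden_submodel(retrained)
    shap_hidden = shapley.shap_exact(
        g, to_hidden(X_expl), to_hidden(background),
        feature_names=[f"h{j + 1}" for j in range(retrained.n_hidden)],
    )
    shap_input = shapley.shap_sampling(
        shapley.model_fn(retrained), X_expl, background,
        n_permutations=cfg.explain.n_permutations,
        seed=seeds["shap"],
        feature_names=features.feature_columns(retrained.n_in),
    )
    shap_summary = shapley.summarize(shap_input, X_expl, top_n=cfg.explain.top_n)
    recovery = informative_ic_ranks(
        shap_input, truth, explained_df["category"].to_numpy()
    )

    # -- evaluate ---------------------------------------------------------
    networks = {"best": best_params, "pruned": pruned, "retrained": retrained}
    confusions = {
        name: metrics.confusion(y_te, snn.predict(p, X_te))
        for name, p in networks.items()
    }
    accuracies = {
        name: metrics.global_accuracy(cm) for name, cm in confusions.items()
    }

    result = PipelineResult(
        config=cfg,
        cohort=cohort,
        selected_stimuli={"preferred": preferred, "indifferent": indifferent},
        train_instances=train_df,
        test_instances=test_df,
        best_params=best_params,
        search_table=search_table,
        elbows=elbows,
        retrained_params=retrained,
        prune_report=prune_report,
        shap_hidden=shap_hidden,
        shap_input=shap_input,
        shap_summary=shap_summary,
        explained_instances=explained_df,
        confusions=confusions,
        accuracies=accuracies,
        recovery=recovery,
    )
    if out_dir is not None:
        write_run_dir(result, Path(out_dir), seeds)
    return result


# --------------------------------------------------------------------------
# Artifacts
# --------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_run_dir(result: PipelineResult, out_dir: Path, seeds: dict[str, int]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config

    result.train_instances.to_csv(out_dir / "train.csv", index=False)
    result.test_instances.to_csv(out_dir / "test.csv", index=False)
    result.search_table.to_csv(out_dir / "search_table.csv", index=False)
    result.best_params.to_json(out_dir / "network_best.json")
    result.retrained_params.to_json(out_dir / "network_retrained.json")

    pw = pathweights.compute_path_weights(result.best_params)
    keep = pathweights.surviving_paths(pw, result.elbows)
    pathweights.path_weight_frame(pw, keep).to_csv(
        out_dir / "pathweights.csv", index=False
    )
    elbow_payload = [
        {
            "output": e.output,
            "negative_rank": e.negative_rank,
            "positive_rank": e.positive_rank,
            "negative_threshold": e.negative_threshold,
            "positive_threshold": e.positive_threshold,
        }
        for e in result.elbows
    ]
    (out_dir / "elbows.json").write_text(json.dumps(elbow_payload, indent=2))

    result.shap_input.to_frame().to_csv(out_dir / "shap_input.csv", index=False)
    result.shap_hidden.to_frame().to_csv(out_dir / "shap_hidden.csv", index=False)
    for name, df in result.shap_summary.items():
        df.to_csv(out_dir / f"shap_{name}.csv", index=False)
    result.recovery.to_csv(out_dir / "recovery.csv", index=False)

    for name, cm in result.confusions.items():
        metrics.report_table(cm).to_csv(out_dir / f"report_{name}.csv")
    summary = {
        "accuracies": result.accuracies,
        "connections_before": result.prune_report["connections_before"],
        "connections_after": result.prune_report["connections_after"],
        "selection_accuracies": {
            k: result.prune_report[f"accuracy_{k}"]
            for k in ("best", "pruned", "retrained")
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))

    artifacts = sorted(
        p for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": cfg.model_dump(),
        "stage_seeds": seeds,
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
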