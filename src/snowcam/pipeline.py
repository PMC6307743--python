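"""End-to-end orchestration of the snow-detection chain.

Stage order: synthetic generation (or manifest loading) → crowd consensus →
bad-image exclusion → dataset filter → fold construction → SVM
cross-validation under both designs plus the overfit bound → satellite
binarization and validation → OR-fusion → stratified / seasonal / per-site
sensitivity reports → reported-rate consistency table.

Every artifact is a headered CSV or sorted JSON stamped with the resolved
config and its hash; a rerun with the same config reproduces every byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from . import consensus as cns
from . import modis as mod
from .classifier import DEFAULT_COST, predict, train_svm
from .consistency import consistency_report
from .evaluation import (
    make_random_folds,
    make_site_folds,
    overfit_bound,
    pairwise_agreement,
    run_cross_validation,
)
from .metrics import percent
from .synthetic import NetworkBundle, SimulationConfig, simulate_network, stable_rng
from .types import BinaryOutcome, Canopy, SnowLabel, TopLevel

logger = logging.getLogger(__name__)

DATASET_FILTERS = {"all": ("I", "II", "III"), "type_I_II": ("I", "II"), "type_I": ("I",)}


@dataclass
class RunConfig:
    """Fully-resolved configuration of one pipeline run."""

    seed: int = 42
    dataset: str = "all"  # 'type_I' | 'type_I_II' | 'all'
    k_folds: int = 10
    cost_parameter: float = DEFAULT_COST
    min_seasonal_images: int = 5
    gold_fraction: float = 0.01
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.dataset not in DATASET_FILTERS:
            raise ValueError(f"dataset must be one of {sorted(DATASET_FILTERS)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.6f")


def run_pipeline(
    config: RunConfig,
    outdir: Union[str, Path],
    network: Optional[NetworkBundle] = None,
) -> Dict[str, object]:
    """Run every stage and write the run directory; returns the summary.

    ``network`` may supply a pre-built dataset bundle; by default one is
    simulated from ``config.simulation`` (with the run seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if network is None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        network = simulate_network(sim)
    logger.info("stage=simulate images=%d sites=%d", len(network.records), len(network.sites))
    network.write_csv(outdir / "manifests")

    # --- crowd consensus -------------------------------------------------
    consensus_df = cns.aggregate_votes_table(network.votes)
    _csv(consensus_df, outdir / "consensus.csv")
    unresolved = consensus_df.loc[
        consensus_df["top_level"] == TopLevel.UNRESOLVED.value, "image_id"
    ]
    _csv(unresolved.to_frame(), outdir / "unresolved.csv")
    logger.info("stage=consensus images=%d unresolved=%d", len(consensus_df), len(unresolved))

    cons_top = pd.Series(
        consensus_df["top_level"].to_numpy(),
        index=consensus_df["image_id"],
    )
    cons_binary = cons_top[cons_top.isin([TopLevel.SNOW.value, TopLevel.NO_SNOW.value])].eq(
        TopLevel.SNOW.value
    )

    # gold standard audit: an expert-labeled random subset (truth plays the
    # expert role in the synthetic setting)
    rng = stable_rng(config.seed, "gold_sample")
    all_ids = network.records["image_id"].to_numpy()
    n_gold = max(1, int(round(config.gold_fraction * len(all_ids))))
    gold_ids = np.sort(rng.choice(all_ids, size=n_gold, replace=False))
    gold = {
        i: SnowLabel(v) for i, v in network.true_labels.loc[gold_ids].items()
    }
    results = cns.consensus_frame_to_results(consensus_df)
    gold_counts, gold_cross = cns.compare_to_gold(results, gold)
    _csv(gold_cross, outdir / "gold_confusion_5way.csv", index=True)

    unanimity = cns.unanimity_rate_table(network.votes)

    # --- exclusions and dataset filter -----------------------------------
    bad_ids = set(consensus_df.loc[consensus_df["top_level"] == TopLevel.BAD.value, "image_id"])
    records = network.records
    usable = records[~records["image_id"].isin(bad_ids)]
    allowed_types = DATASET_FILTERS[config.dataset]
    filtered = usable[usable["site_type"].isin(allowed_types)]
    logger.info(
        "stage=filter total=%d usable=%d dataset=%s kept=%d",
        len(records), len(usable), config.dataset, len(filtered),
    )

    ids = filtered["image_id"]
    X = network.features.loc[ids]
    # classifier trains against the crowd labels, as at full scale
    y = cons_binary.reindex(ids)
    keep = y.notna()
    X, y = X.loc[keep.to_numpy()], y[keep].astype(bool)

    # --- folds and cross-validation --------------------------------------
    rand_folds = make_random_folds(list(X.index), k=config.k_folds, seed=config.seed)
    site_folds = make_site_folds(
        filtered[filtered["image_id"].isin(X.index)], k=config.k_folds, seed=config.seed
    )
    _csv(rand_folds.to_frame(), outdir / "folds_random.csv")
    _csv(site_folds.to_frame(), outdir / "folds_by_site.csv")

    cv_random = run_cross_validation(X, y, rand_folds, config.cost_parameter, config.dataset)
    cv_site = run_cross_validation(X, y, site_folds, config.cost_parameter, config.dataset)
    bound = overfit_bound(X, y, config.cost_parameter)
    if (bound.accuracy or 0) < max(cv_random.pooled.accuracy or 0, cv_site.pooled.accuracy or 0):
        logger.warning("overfit bound below a CV accuracy (solver noise)")
    _write_json(outdir / "cv_random.json", cv_random.to_dict())
    _write_json(outdir / "cv_by_site.json", cv_site.to_dict())
    _write_json(outdir / "overfit.json", bound.to_dict(percent=True))

    model = train_svm(X, y, config.cost_parameter)
    model.save(outdir / "svm_model.txt")

    # held-out predictions (every image predicted by the model that did not
    # train on it) for downstream fusion
    cnn_pred = _heldout_predictions(X, y, rand_folds, config.cost_parameter)
    pred_df = pd.DataFrame(
        {"image_id": cnn_pred.index, "label": cnn_pred.to_numpy()}
    )
    _csv(pred_df, outdir / "cnn_predictions.csv")

    # --- satellite validation and fusion ---------------------------------
    outcomes = mod.binarize_modis_table(network.modis)
    outcomes = outcomes.loc[outcomes.index.intersection(X.index)]
    reference = cons_binary.loc[cons_binary.index.intersection(X.index)]
    modis_counts = mod.validate_binary(outcomes, reference)
    coverage = float((outcomes != BinaryOutcome.MISSING.value).mean())

    observed = outcomes[outcomes != BinaryOutcome.MISSING.value]
    fused = mod.combine_or_table(outcomes, cnn_pred)
    fused_counts = mod.validate_binary(
        pd.Series(
            np.where(fused, BinaryOutcome.SNOW.value, BinaryOutcome.NO_SNOW.value),
            index=fused.index,
        ),
        reference,
    )
    snow_ids = reference[reference].index
    agreement_snow = pairwise_agreement(
        (observed == BinaryOutcome.SNOW.value), cnn_pred, restrict_ids=snow_ids
    )

    # --- strata, season, sites -------------------------------------------
    canopy = {s.site_id: s.canopy for s in network.sites}
    site_of = network.records.set_index("image_id")["site_id"]
    tree_strata = {
        i: ("trees" if canopy[site_of[i]] is not Canopy.NONE else "no_trees")
        for i in outcomes.index
    }
    strata_tree = mod.stratified_metrics(outcomes, reference, tree_strata)

    # foliage strata: among consensus-snow images at tree sites, was snow on
    # the foliage or only on the ground beneath it
    sub = pd.Series(
        consensus_df["sub_label"].to_numpy(), index=consensus_df["image_id"]
    ).reindex(outcomes.index)
    foliage_ids = [
        i
        for i in outcomes.index
        if sub.get(i) in (SnowLabel.SNOW_ON_TREES.value, SnowLabel.SNOW_GROUND_ONLY.value)
    ]
    foliage_strata = {
        i: ("snow_on_trees" if sub[i] == SnowLabel.SNOW_ON_TREES.value else "snow_ground_only")
        for i in foliage_ids
    }
    strata_foliage = mod.stratified_metrics(
        outcomes.loc[foliage_ids], reference.loc[foliage_ids], foliage_strata
    )

    dates = network.records.set_index("image_id")["date"]
    seasonal = mod.seasonal_sensitivity(
        outcomes, reference, dates, min_images=config.min_seasonal_images
    )
    _csv(seasonal.rename_axis("day_of_year").to_frame(), outdir / "seasonal_sensitivity.csv", index=True)

    site_summary = mod.site_sensitivity_summary(outcomes, reference, network.records)
    _csv(site_summary, outdir / "site_summary.csv")
    fit_points = site_summary.dropna(subset=["sensitivity"])
    fit_points = fit_points[fit_points["fraction_snow_days"] > 0]
    if len(fit_points) >= 3 and fit_points["fraction_snow_days"].nunique() > 1:
        a, b, r2 = mod.fit_log_curve(
            fit_points["fraction_snow_days"], fit_points["sensitivity"]
        )
        logfit = {"intercept": a, "slope": b, "r_squared": r2, "n_sites": len(fit_points)}
    else:
        logfit = {"intercept": None, "slope": None, "r_squared": None, "n_sites": len(fit_points)}
    _write_json(outdir / "logfit.json", logfit)

    # --- consistency table and summary -----------------------------------
    _csv(consistency_report(), outdir / "consistency_report.csv")

    summary = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_images": len(records),
        "n_usable": len(usable),
        "n_classified": int(len(X)),
        "bad_image_pct": percent(len(bad_ids) / len(records)),
        "snow_prevalence_pct": percent(float(network.truth["snow"].mean())),
        "consensus_snow_pct": percent(float(cons_binary.mean())),
        "unanimity_pct": percent(unanimity),
        "gold": gold_counts.to_dict(percent=True),
        "cv_random": cv_random.pooled.to_dict(percent=True),
        "cv_by_site": cv_site.pooled.to_dict(percent=True),
        "overfit": bound.to_dict(percent=True),
        "modis_coverage_pct": percent(coverage),
        "modis_vs_consensus": modis_counts.to_dict(percent=True),
        "fused_vs_consensus": fused_counts.to_dict(percent=True),
        "modis_cnn_agreement_on_snow_pct": percent(agreement_snow),
        "strata_tree": {k: v.to_dict(percent=True) for k, v in strata_tree.items()},
        "strata_foliage": {k: v.to_dict(percent=True) for k, v in strata_foliage.items()},
        "logfit": logfit,
    }
    _write_json(outdir / "summary.json", {"config": config.to_dict(), **summary})
    logger.info("stage=done outdir=%s", outdir)
    return summary


def _heldout_predictions(
    X: pd.DataFrame, y: pd.Series, folds, cost: float
) -> pd.Series:
    """Predict every image from the fold model that excluded it."""
    fold_of = np.array([folds.mapping[i] for i in X.index])
    out = pd.Series(index=X.index, dtype=bool)
    Xv = X.to_numpy(dtype=float)
    yv = y.loc[X.index].to_numpy(dtype=bool)
    for f in range(1, folds.k + 1):
        test = fold_of == f
        model = train_svm(Xv[~test], yv[~test], cost)
        out.iloc[np.flatnonzero(test)] = model.decision(Xv[test]) > 0
    return out
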