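"""End-to-end three-setup experiment: the same slides are indexed and searched
(1) with the plain mosaic, (2) with the mosaic pruned by an Isolation Forest
atlas and (3) pruned by a one-class-SVM atlas; each setup is evaluated with
leave-one-patient-out top-k consensus, and the atlas setups report their patch
reduction against the base setup.

A run is fully determined by its config (one global seed; per-stage seeds are
derived from it), and a run directory records the config snapshot alongside the
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

from normatlas.atlas import METHOD_IFOREST, METHOD_OCSVM, fit_atlas, prune_selection
from normatlas.config import PipelineConfig, config_snapshot
from normatlas.evaluation import lopo_evaluate, reduction_report
from normatlas.features import FeatureBag
from normatlas.mosaic import build_mosaic
from normatlas.search import build_index
from normatlas.synthetic_data import simulate_feature_dataset

logger = logging.getLogger("normatlas")

SETUPS = ("base", METHOD_IFOREST, METHOD_OCSVM)


def run_pipeline(
    cfg: PipelineConfig,
    out_dir: str | Path | None = None,
    labeled_bags: list[FeatureBag] | None = None,
    normal_bags: list[FeatureBag] | None = None,
) -> dict:
    """Run the three-setup experiment and return a JSON-serializable bundle.

    Input bags may be supplied (e.g. from a feature store built from real
    slides); otherwise they are simulated from ``cfg.simulate``.  The bundle
    holds one LOPO report per setup and k, patch reductions vs base, per-stage
    counts and the config snapshot.
    """
    sim_cfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
    mosaic_cfg = dataclasses.replace(cfg.mosaic, seed=cfg.seed + 1)

    if labeled_bags is None or normal_bags is None:
        logger.info("simulating feature dataset (seed=%d)", sim_cfg.seed)
        sim_normal, sim_labeled = simulate_feature_dataset(sim_cfg)
        normal_bags = normal_bags or sim_normal
        labeled_bags = labeled_bags or sim_labeled
    total_patches = sum(b.n_patches for b in labeled_bags)
    logger.info(
        "dataset: %d labeled slides (%d patches), %d normal atlas slides",
        len(labeled_bags), total_patches, len(normal_bags),
    )

    atlases = {
        method: fit_atlas(
            normal_bags, dataclasses.replace(cfg.atlas, method=method, seed=cfg.seed + 2)
        )
        for method in (METHOD_IFOREST, METHOD_OCSVM)
    }
    for method, atlas in atlases.items():
        logger.info(
            "atlas %s: %d training vectors, %.3f flagged",
            method, atlas.n_training_vectors, atlas.training_flagged_fraction,
        )

    selections = {
        bag.wsi_id: build_mosaic(bag.patches, bag.vectors, mosaic_cfg)
        for bag in labeled_bags
    }
    n_selected = sum(len(s.selected) for s in selections.values())
    logger.info("mosaic: %d of %d patches selected", n_selected, total_patches)

    setup_bags: dict[str, list[FeatureBag]] = {"base": [], METHOD_IFOREST: [], METHOD_OCSVM: []}
    for bag in labeled_bags:
        sel = selections[bag.wsi_id]
        setup_bags["base"].append(bag.subset(sel.selected))
        for method, atlas in atlases.items():
            pruned = prune_selection(sel, bag, atlas)
            setup_bags[method].append(bag.subset(pruned.selected))
    for method in (METHOD_IFOREST, METHOD_OCSVM):
        kept = sum(b.n_patches for b in setup_bags[method])
        logger.info("pruning (%s): %d of %d mosaic patches kept", method, kept, n_selected)

    reports = {}
    for setup in SETUPS:
        index = build_index(
            setup_bags[setup],
            provenance={"setup": setup, "mosaic": dataclasses.asdict(mosaic_cfg)},
        )
        reports[setup] = lopo_evaluate(index, k_values=cfg.search.k_values)

    k_ref = cfg.search.k_values[0]
    reductions = {
        method: reduction_report(reports["base"][k_ref], reports[method][k_ref])
        for method in (METHOD_IFOREST, METHOD_OCSVM)
    }

    bundle = {
        "config": config_snapshot(cfg),
        "counts": {
            "labeled_slides": len(labeled_bags),
            "normal_atlas_slides": len(normal_bags),
            "total_patches": total_patches,
            "mosaic_selected": n_selected,
            "kept_after_pruning": {
                m: sum(b.n_patches for b in setup_bags[m])
                for m in (METHOD_IFOREST, METHOD_OCSVM)
            },
        },
        "reports": {
            setup: {str(k): rep.to_dict() for k, rep in reports[setup].items()}
            for setup in SETUPS
        },
        "reduction_vs_base": reductions,
        "training_flagged_fraction": {
            m: atlases[m].training_flagged_fraction for m in atlases
        },
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "summary.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        (out_dir / "config_snapshot.json").write_text(
            json.dumps(config_snapshot(cfg), indent=2, sort_keys=True)
        )
        for setup in SETUPS:
            (out_dir / f"report_{setup}.json").write_text(
                json.dumps(bundle["reports"][setup], indent=2, sort_keys=True)
            )
        logger.info("wrote run outputs to %s", out_dir)
    return bundle
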