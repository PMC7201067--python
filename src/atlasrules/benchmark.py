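"""Scaled-down atlas benchmark: marker recovery through the full pipeline.

Runs the whole selection cascade on a synthetic 18-tissue atlas at 2% of
the real atlas's per-tissue cell counts (~1,085 cells) with 5 planted
markers per tissue (90 markers), 400 background genes, an effect size of
2 on noise sd 1, and 30% dropout — the package's standing desk-scale
analogue of the full-atlas experiment.  Stage parameters are sized for a
single CPU: Boruta runs 50 shadow iterations, MCFS its default 30x50
trees, IFS evaluates the MCFS ranking up to k = 200 with 10-fold CV, and
PART is scored on the top 100 MCFS genes.

Returns the per-stage marker-recovery metrics used by the acceptance
machinery and by anyone wanting a one-call health check of the method.
"""

from __future__ import annotations

import numpy as np

from .boruta import run_boruta
from .data_model import subset_features
from .ifs_eval import ClassifierSpec, cross_validate, run_ifs
from .mcfs import MCFSParams, run_mcfs
from .mi_filter import mi_screen
from .overlap_stats import overlap_report
from .part_rules import train_part
from .synthetic_data import generate_dataset, scaled_atlas_spec

__all__ = ["run_atlas_benchmark"]


def run_atlas_benchmark(seed: int, scale: float = 0.02,
                        with_mrmr: bool = False) -> dict:
    """Run the pipeline on the scaled synthetic atlas; return metrics.

    All stage seeds derive from ``seed``.  With ``with_mrmr`` the mRMR
    ranking and the ranking-overlap report are additionally computed.
    """
    rng = np.random.default_rng(seed)
    seeds = {name: int(rng.integers(2**31))
             for name in ("data", "boruta", "mcfs", "ifs", "part")}

    spec = scaled_atlas_spec(scale, seed=seeds["data"], markers_per_class=5,
                             n_noise_genes=400, effect_size=2.0,
                             dropout_rate=0.3)
    ds, truth = generate_dataset(spec)
    markers = set(truth.marker_ids)

    mi = mi_screen(ds, threshold=0.02, bins=5)
    mi_ids = {ds.gene_ids[i] for i in mi.surviving}

    bres = run_boruta(ds, features=mi.surviving, max_iter=50,
                      seed=seeds["boruta"])
    confirmed_ids = {ds.gene_ids[i] for i in bres.confirmed}

    fM = run_mcfs(ds, features=bres.confirmed,
                  params=MCFSParams(seed=seeds["mcfs"]))
    top120 = set(fM.gene_ids[: min(120, len(fM))])

    curve = run_ifs(ds, fM, ClassifierSpec(seed=seeds["ifs"]), step=5,
                    max_k=min(200, len(fM)), folds=10, seed=seeds["ifs"])

    part_view = subset_features(ds, fM.top(min(100, len(fM))))
    part_cv = cross_validate(part_view, ClassifierSpec(kind="part"),
                             folds=10, seed=seeds["part"])
    ruleset = train_part(part_view)
    covered = sum(r.coverage for r in ruleset.rules)

    out = {
        "n_cells": ds.n_cells,
        "n_markers": len(markers),
        "mi_survivors": int(mi.surviving.size),
        "mi_marker_recovery": truth.recovery_fraction(mi_ids),
        "boruta_confirmed": int(bres.confirmed.size),
        "boruta_marker_recovery": truth.recovery_fraction(confirmed_ids),
        "boruta_noise_confirmed": len(confirmed_ids - markers),
        "mcfs_top120_marker_recovery": truth.recovery_fraction(top120),
        "ifs_rf_optimum_k": curve.optimum_k,
        "ifs_rf_optimum_mcc": curve.optimum_mcc,
        "ifs_rf_optimum_accuracy": float(
            curve.overall_accs[curve.optimum_index]),
        "part_cv_mcc": part_cv.mcc,
        "part_rule_count": len(ruleset),
        "part_training_coverage": covered,
    }
    if with_mrmr:
        from .mrmr import rank_mrmr

        fm = rank_mrmr(ds, features=bres.confirmed, bins=5)
        top_m = min(curve.optimum_k, len(fm))
        rep = overlap_report(fm, top_m, fM, curve.optimum_k,
                             universe=int(bres.confirmed.size))
        out["overlap_top_sets"] = rep.overlap
        out["overlap_p_value"] = rep.p_value
    return out
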