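"""End-to-end orchestration: data -> MI screen -> Boruta -> {mRMR, MCFS}
-> IFS with RF and PART -> rule files + overlap report.

Every stage writes its artifact into the run directory (TSV/JSON text
files) and is a pure function of (config, derived stage seed, upstream
artifacts); the manifest records config, seeds and artifact hashes so a
run can be audited or resumed stage by stage.  Per-stage seeds are
derived by hashing the stage name with the global seed, so adding a
stage never perturbs earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import boruta as boruta_mod
from . import mcfs as mcfs_mod
from .data_model import ExpressionDataset, load_dataset, subset_features, write_dataset
from .ifs_eval import ClassifierSpec, run_ifs
from .mi_filter import mi_screen
from .mrmr import RankedFeatureList, rank_mrmr
from .overlap_stats import overlap_report
from .part_rules import export_rules, train_part
from .synthetic_data import SyntheticSpec, generate_dataset, scaled_atlas_spec

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline", "report"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """Validated configuration of a full run (one YAML file)."""

    out_dir: str
    seed: int = 1
    synthetic: dict | None = None      # SyntheticSpec kwargs, or {'scale': ...}
    input: dict | None = None          # matrix/genes/cells/labels paths + fmt
    mi: dict = field(default_factory=dict)
    boruta: dict = field(default_factory=dict)
    mcfs: dict = field(default_factory=dict)
    ifs: dict = field(default_factory=dict)
    part: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input is None):
            raise ValueError(
                "config must give exactly one of 'synthetic' or 'input'"
            )
        if self.input is not None:
            for key in ("matrix", "genes", "cells", "labels"):
                if key not in self.input:
                    raise ValueError(f"input config is missing '{key}' path")
        self.mi = {"threshold": 0.02, "bins": 5, **self.mi}
        self.boruta = {"max_iter": 100, "alpha": 0.05, "n_estimators": 100,
                       **self.boruta}
        self.mcfs = {"m": 30, "t": 50, "s": None, **self.mcfs}
        self.ifs = {"step": 5, "max_k": 200, "folds": 10, **self.ifs}
        # PART IFS grids are truncated harder: the rule learner is slow.
        self.part = {"prune_cf": 0.25, "min_leaf": 2,
                     "max_k_fm": 200, "max_k_fM": 400, **self.part}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _load_or_generate(cfg: PipelineConfig, out: str, resume: bool = False):
    if cfg.synthetic is not None:
        prefix = os.path.join(out, "dataset")
        if resume and os.path.exists(prefix + ".mtx"):
            return load_dataset(prefix + ".mtx", prefix + ".genes.tsv",
                                prefix + ".cells.tsv", prefix + ".labels.tsv",
                                fmt="mtx")
        kwargs = dict(cfg.synthetic)
        kwargs.setdefault("seed", stage_seed(cfg.seed, "synthetic"))
        if "scale" in kwargs:
            scale = kwargs.pop("scale")
            spec = scaled_atlas_spec(scale, kwargs.pop("seed"), **kwargs)
        else:
            spec = SyntheticSpec(**kwargs)
        ds, truth = generate_dataset(spec)
        prefix = os.path.join(out, "dataset")
        write_dataset(ds, prefix, fmt="mtx")
        with open(os.path.join(out, "truth.tsv"), "w") as fh:
            fh.writelines(f"{g}\t{t}\n" for g, t in truth.marker_to_class.items())
        return ds
    inp = cfg.input
    return load_dataset(inp["matrix"], inp["genes"], inp["cells"],
                        inp["labels"], fmt=inp.get("fmt", "mtx"))


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute all stages; returns (and writes) the run manifest.

    With ``resume=True`` the dataset, MI, Boruta and ranking stages are
    loaded from existing artifacts in ``cfg.out_dir`` instead of being
    recomputed; downstream stages always rerun.
    """
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "config": {
            "seed": cfg.seed, "synthetic": cfg.synthetic, "input": cfg.input,
            "mi": cfg.mi, "boruta": cfg.boruta, "mcfs": cfg.mcfs,
            "ifs": cfg.ifs, "part": cfg.part,
        },
        "stage_seeds": {}, "stages": {}, "artifacts": {}, "summary": None,
    }

    def _record(stage: str, paths: list[str], started: float, **extra) -> None:
        manifest["stages"][stage] = {
            "status": "ok", "seconds": round(time.time() - started, 3), **extra,
        }
        for p in paths:
            manifest["artifacts"][os.path.relpath(p, out)] = _sha256(p)
        _write_manifest()

    def _write_manifest() -> None:
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    def _resumable(*paths: str) -> bool:
        return resume and all(os.path.exists(p) for p in paths)

    stage = "dataset"
    try:
        t0 = time.time()
        ds = _load_or_generate(cfg, out, resume=resume)
        paths = [os.path.join(out, f"dataset{ext}")
                 for ext in (".mtx", ".genes.tsv", ".cells.tsv", ".labels.tsv")
                 if os.path.exists(os.path.join(out, f"dataset{ext}"))]
        _record(stage, paths, t0, n_cells=ds.n_cells, n_genes=ds.n_genes,
                n_classes=len(ds.class_names))

        # ---- MI screen -------------------------------------------------
        stage = "mi"
        t0 = time.time()
        mi_path = os.path.join(out, "mi.tsv")
        if _resumable(mi_path):
            df = pd.read_csv(mi_path, sep="\t")
            mi_surviving = np.flatnonzero(df["passed"].to_numpy())
        else:
            mi_res = mi_screen(ds, threshold=cfg.mi["threshold"],
                               bins=cfg.mi["bins"])
            mi_res.to_frame(ds.gene_ids).to_csv(mi_path, sep="\t", index=False)
            mi_surviving = mi_res.surviving
        _record(stage, [mi_path], t0, survivors=int(mi_surviving.size))

        # ---- Boruta ----------------------------------------------------
        stage = "boruta"
        t0 = time.time()
        manifest["stage_seeds"]["boruta"] = stage_seed(cfg.seed, "boruta")
        bpath = os.path.join(out, "boruta.tsv")
        pos = {g: i for i, g in enumerate(ds.gene_ids)}
        if _resumable(bpath):
            df = pd.read_csv(bpath, sep="\t")
            confirmed = np.array(
                [pos[g] for g in df.loc[df["status"] == "confirmed",
                                        "gene_id"]], dtype=np.intp)
            extra = {}
        else:
            bres = boruta_mod.run_boruta(
                ds, features=mi_surviving,
                max_iter=cfg.boruta["max_iter"], alpha=cfg.boruta["alpha"],
                n_estimators=cfg.boruta["n_estimators"],
                seed=stage_seed(cfg.seed, "boruta"),
            )
            bres.to_frame(ds.gene_ids).to_csv(bpath, sep="\t", index=False)
            confirmed = bres.confirmed
            extra = {"iterations": bres.n_iter}
        if confirmed.size == 0:
            raise RuntimeError("Boruta confirmed no features; nothing to rank")
        _record(stage, [bpath], t0, confirmed=int(confirmed.size), **extra)

        # ---- rankings --------------------------------------------------
        stage = "mrmr"
        t0 = time.time()
        fm_path = os.path.join(out, "Fm.tsv")
        if _resumable(fm_path):
            fm = RankedFeatureList.from_frame(
                pd.read_csv(fm_path, sep="\t"), ds, "mRMR")
        else:
            fm = rank_mrmr(ds, features=confirmed, bins=cfg.mi["bins"])
            fm.to_frame().to_csv(fm_path, sep="\t", index=False)
        _record(stage, [fm_path], t0)

        stage = "mcfs"
        t0 = time.time()
        params = mcfs_mod.MCFSParams(
            m=cfg.mcfs["m"], t=cfg.mcfs["t"], s=cfg.mcfs["s"],
            seed=stage_seed(cfg.seed, "mcfs"),
        )
        manifest["stage_seeds"]["mcfs"] = params.seed
        fM_path = os.path.join(out, "FM.tsv")
        if _resumable(fM_path):
            fM = RankedFeatureList.from_frame(
                pd.read_csv(fM_path, sep="\t"), ds, "MCFS")
        else:
            fM = mcfs_mod.run_mcfs(ds, features=confirmed, params=params)
            fM.to_frame().to_csv(fM_path, sep="\t", index=False)
        _record(stage, [fM_path], t0)

        # ---- IFS curves ------------------------------------------------
        curves = {}
        summary_rows = []
        for clf_kind, tag in (("random_forest", "rf"), ("part", "part")):
            for ranked, list_tag in ((fm, "Fm"), (fM, "FM")):
                stage = f"ifs_{tag}_{list_tag}"
                t0 = time.time()
                if clf_kind == "part":
                    cap = cfg.part["max_k_fm"] if list_tag == "Fm" else cfg.part["max_k_fM"]
                    spec_params = {"prune_cf": cfg.part["prune_cf"],
                                   "min_leaf": cfg.part["min_leaf"]}
                else:
                    cap = cfg.ifs["max_k"]
                    spec_params = {}
                seed = stage_seed(cfg.seed, stage)
                manifest["stage_seeds"][stage] = seed
                cspec = ClassifierSpec(kind=clf_kind, params=spec_params, seed=seed)
                curve = run_ifs(ds, ranked, cspec, step=cfg.ifs["step"],
                                max_k=min(cap, len(ranked)),
                                folds=cfg.ifs["folds"], seed=seed)
                cpath = os.path.join(out, f"ifs_{tag}_{list_tag}.tsv")
                curve.to_frame().to_csv(cpath, sep="\t", index=False)
                opath = os.path.join(out, f"optimum_{tag}_{list_tag}.json")
                with open(opath, "w") as fh:
                    json.dump({"optimum_k": curve.optimum_k,
                               "optimum_mcc": curve.optimum_mcc,
                               "classifier": clf_kind,
                               "ranking": ranked.method}, fh, indent=1)
                curves[(tag, list_tag)] = curve
                _record(stage, [cpath, opath], t0,
                        optimum_k=curve.optimum_k,
                        optimum_mcc=round(curve.optimum_mcc, 4))

        # ---- PART rule files at the optimum k -------------------------
        rule_counts = {}
        for ranked, list_tag in ((fm, "Fm"), (fM, "FM")):
            stage = f"rules_{list_tag}"
            t0 = time.time()
            k = curves[("part", list_tag)].optimum_k
            view = subset_features(ds, ranked.top(k))
            rs = train_part(view, prune_cf=cfg.part["prune_cf"],
                            min_leaf=cfg.part["min_leaf"])
            rpath = os.path.join(out, f"rules_{list_tag}.txt")
            export_rules(rs, rpath)
            rule_counts[list_tag] = len(rs)
            _record(stage, [rpath, rpath + ".json"], t0, n_rules=len(rs))

        # ---- overlap of the RF optimum sets ---------------------------
        stage = "overlap"
        t0 = time.time()
        rep = overlap_report(
            fm, curves[("rf", "Fm")].optimum_k,
            fM, curves[("rf", "FM")].optimum_k,
            universe=int(confirmed.size),
        )
        ov_path = os.path.join(out, "overlap.json")
        with open(ov_path, "w") as fh:
            json.dump(rep.to_dict(), fh, indent=1)
        _record(stage, [ov_path], t0, overlap=rep.overlap,
                p_value=rep.p_value)

        # ---- summary table (ranking, classifier, k, rules, MCC, acc) --
        stage = "summary"
        t0 = time.time()
        for (tag, list_tag), curve in curves.items():
            summary_rows.append({
                "feature_ranking": "mRMR" if list_tag == "Fm" else "MCFS",
                "classifier": "RF" if tag == "rf" else "PART",
                "optimum_features": curve.optimum_k,
                "rules": rule_counts.get(list_tag) if tag == "part" else "",
                "mcc": round(curve.optimum_mcc, 4),
                "overall_accuracy": round(
                    float(curve.overall_accs[curve.optimum_index]), 4),
            })
        summary = pd.DataFrame(summary_rows)
        spath = os.path.join(out, "summary.tsv")
        summary.to_csv(spath, sep="\t", index=False)
        manifest["summary"] = summary_rows
        _record(stage, [spath], t0)
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_manifest()
        raise
    _write_manifest()
    return manifest


def report(run_dir: str) -> list[str]:
    """Render IFS curves and per-tissue accuracy bars from a run directory."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with open(os.path.join(run_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    rep_dir = os.path.join(run_dir, "report")
    os.makedirs(rep_dir, exist_ok=True)
    written = []
    for tag in ("rf", "part"):
        for list_tag in ("Fm", "FM"):
            cpath = os.path.join(run_dir, f"ifs_{tag}_{list_tag}.tsv")
            if not os.path.exists(cpath):
                continue
            df = pd.read_csv(cpath, sep="\t")
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.plot(df["k"], df["mcc"], marker="o", ms=3)
            ax.set_xlabel("number of top-ranked genes")
            ax.set_ylabel("MCC (10-fold CV)")
            ax.set_title(f"IFS: {tag.upper()} on "
                         f"{'mRMR' if list_tag == 'Fm' else 'MCFS'} list")
            fig.tight_layout()
            p = os.path.join(rep_dir, f"ifs_{tag}_{list_tag}.png")
            fig.savefig(p, dpi=120)
            plt.close(fig)
            written.append(p)
            # per-tissue accuracy bars at the optimum row
            acc_cols = [c for c in df.columns if c.startswith("acc_")]
            if tag == "rf" and acc_cols:
                opt = df.loc[df["mcc"].idxmax()]
                fig, ax = plt.subplots(figsize=(7, 3.2))
                names = [c[len("acc_"):] for c in acc_cols]
                ax.bar(range(len(names)), [opt[c] for c in acc_cols])
                ax.set_xticks(range(len(names)))
                ax.set_xticklabels(names, rotation=60, ha="right", fontsize=7)
                ax.set_ylabel("per-tissue accuracy")
                ax.set_ylim(0, 1.05)
                fig.tight_layout()
                p = os.path.join(rep_dir, f"acc_{tag}_{list_tag}.png")
                fig.savefig(p, dpi=120)
                plt.close(fig)
                written.append(p)
    summary_path = os.path.join(run_dir, "summary.tsv")
    if os.path.exists(summary_path):
        txt = os.path.join(rep_dir, "summary.txt")
        with open(txt, "w") as fh:
            fh.write(pd.read_csv(summary_path, sep="\t").to_string(index=False))
            fh.write("\n")
        written.append(txt)
    return written
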