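"""Configuration-driven orchestration: simulate -> prep -> mvpa -> dfc -> report.

A single YAML file (or a RunConfig built in code) drives the whole run.
Every stage reads its inputs from, and writes its outputs to, the run
directory; a manifest records the configuration snapshot, per-stage
configuration hashes, wall-clock times, output checksums and any warnings
(for instance the two-sided-p caveat on borderline contrasts). Stages are
skipped on re-runs when their configuration hash matches the manifest and
their outputs are present.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from .cohort import ClusterSpec, CohortConfig, CouplingSpec, generate_cohort
from .dfc import (
    DFCParams,
    WindowGrid,
    dfc_behavior_correlation,
    seed_group_contrast,
    subject_fraction_table,
)
from .mvpa import (
    ClusterCriteria,
    PermutationSpec,
    SearchlightSpec,
    build_searchlight,
    cluster_univariate_test,
    correlate_with_behavior,
    make_fold_scheme,
    permutation_test_cluster,
    searchlight_classify,
    threshold_clusters,
)
from .prep import (
    AcquisitionSpec,
    bandpass,
    compare_fd_groups,
    framewise_displacement,
    regress_out_fd,
)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "report", "load_config"]

STAGES = ("simulate", "prep", "mvpa", "dfc", "report")


@dataclass
class RunConfig:
    """All knobs of a full run, with the study-design defaults."""

    out_dir: str = "run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    searchlight: SearchlightSpec = field(default_factory=SearchlightSpec)
    cluster_criteria: ClusterCriteria = field(default_factory=ClusterCriteria)
    permutation: PermutationSpec = field(default_factory=PermutationSpec)
    window_grid: WindowGrid = field(default_factory=WindowGrid)
    dfc_params: DFCParams = field(default_factory=DFCParams)
    n_folds: int = 10
    seed_classes: tuple[str, ...] = ("APC", "PPC", "OFC")
    regress_fd: bool = True
    stages: tuple[str, ...] = STAGES
    seeds: dict = field(
        default_factory=lambda: {"simulate": 0, "mvpa": 1, "dfc": 2}
    )

    def stage_config(self, stage: str) -> dict:
        """The sub-configuration a stage depends on (for cache hashing)."""
        d = dataclasses.asdict(self)
        dep = {
            "simulate": ["cohort", "seeds"],
            "prep": ["cohort", "acquisition", "regress_fd", "seeds"],
            "mvpa": [
                "cohort",
                "searchlight",
                "cluster_criteria",
                "permutation",
                "n_folds",
                "seeds",
            ],
            "dfc": ["cohort", "window_grid", "dfc_params", "seed_classes", "seeds"],
            "report": list(d.keys()),
        }[stage]
        sub = {k: d[k] for k in dep}
        if stage in ("simulate", "prep"):
            sub["seeds"] = {"simulate": d["seeds"].get("simulate", 0)}
        elif stage == "mvpa":
            sub["seeds"] = {k: d["seeds"].get(k, 0) for k in ("simulate", "mvpa")}
        elif stage == "dfc":
            sub["seeds"] = {k: d["seeds"].get(k, 0) for k in ("simulate", "dfc")}
        return sub


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file; omitted keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "cohort" in raw:
        c = dict(raw["cohort"])
        if "planted_clusters" in c:
            c["planted_clusters"] = tuple(
                ClusterSpec(
                    center_voxel=tuple(p["center_voxel"]),
                    radius_vox=p["radius_vox"],
                    effect_style=p.get("effect_style", "pattern"),
                    effect_size=p.get("effect_size", 3.0),
                )
                for p in c["planted_clusters"]
            )
        if "coupling_edges" in c:
            c["coupling_edges"] = tuple(CouplingSpec(**e) for e in c["coupling_edges"])
        if "grid_shape" in c:
            c["grid_shape"] = tuple(c["grid_shape"])
        kwargs["cohort"] = CohortConfig(**c)
    for key, cls in (
        ("acquisition", AcquisitionSpec),
        ("searchlight", SearchlightSpec),
        ("cluster_criteria", ClusterCriteria),
        ("permutation", PermutationSpec),
        ("dfc_params", DFCParams),
    ):
        if key in raw:
            kwargs[key] = cls(**raw[key])
    if "window_grid" in raw:
        g = dict(raw["window_grid"])
        if "widths_tr" in g:
            g["widths_tr"] = tuple(g["widths_tr"])
        kwargs["window_grid"] = WindowGrid(**g)
    for key in ("out_dir", "n_folds", "regress_fd", "seeds"):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("seed_classes", "stages"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    return RunConfig(**kwargs)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)  # name -> {hash, seconds, outputs}
    warnings: list = field(default_factory=list)

    def save(self, out_dir: Path) -> None:
        (out_dir / "manifest.json").write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))

    @classmethod
    def load(cls, out_dir: Path) -> "RunManifest | None":
        p = out_dir / "manifest.json"
        if not p.exists():
            return None
        d = json.loads(p.read_text())
        return cls(
            config=d["config"],
            version=d["version"],
            stages=d["stages"],
            warnings=d["warnings"],
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cfg_hash(sub: dict) -> str:
    return hashlib.sha256(json.dumps(sub, sort_keys=True, default=str).encode()).hexdigest()


def _stage_cached(manifest: RunManifest | None, stage: str, h: str, out: Path) -> bool:
    if manifest is None or stage not in manifest.stages:
        return False
    rec = manifest.stages[stage]
    if rec.get("hash") != h:
        return False
    return all((out / f).exists() for f in rec.get("outputs", []))


def _stage_simulate(cfg: RunConfig, out: Path, manifest: RunManifest) -> None:
    cohort_cfg = dataclasses.replace(cfg.cohort, seed=cfg.seeds.get("simulate", 0))
    cohort = generate_cohort(cohort_cfg)
    oio.save_cohort(cohort, out)


def _stage_prep(cfg: RunConfig, out: Path, manifest: RunManifest) -> None:
    subjects = oio.load_subjects(out / "subjects.tsv")
    ids = subjects["subject_id"].tolist()
    motion = oio.load_motion(out / "motion", ids)
    ts_list = oio.load_timeseries(out / "ts", ids)
    acq = dataclasses.replace(cfg.acquisition, n_volumes=cfg.cohort.n_volumes, tr_s=cfg.cohort.tr_s)

    fd_series = [framewise_displacement(m) for m in motion]
    fd_df = pd.DataFrame(
        {sid: f.fd for sid, f in zip(ids, fd_series)}
    )
    fd_df.to_csv(out / "fd.tsv", sep="\t", index=False)
    fd_means = np.array([f.mean_fd for f in fd_series])
    res = compare_fd_groups(fd_means, subjects["group"].to_numpy())
    (out / "fd_group_test.json").write_text(
        json.dumps(dataclasses.asdict(res), indent=2)
    )
    if 0.05 <= res.p < 0.06:
        manifest.warnings.append(
            "FD group contrast: two-sided p in [0.05, 0.06); borderline under a one-sided reading"
        )

    filtered = []
    for ts, fd in zip(ts_list, fd_series):
        f = dataclasses.replace(ts, data=bandpass(ts.data, acq))
        if cfg.regress_fd:
            f = regress_out_fd(f, fd)
        filtered.append(f)
    oio.save_timeseries(filtered, out / "ts_filtered")


def _stage_mvpa(cfg: RunConfig, out: Path, manifest: RunManifest) -> None:
    subjects = oio.load_subjects(out / "subjects.tsv")
    ids = subjects["subject_id"].tolist()
    labels = subjects["group"].to_numpy()
    maps, affine = oio.load_gm_maps(out / "gm", ids, cfg.cohort.voxel_size_mm)
    seed = cfg.seeds.get("mvpa", 0)

    sl = build_searchlight(maps[0].brain_mask, maps[0].voxel_size_mm, cfg.searchlight)
    folds = make_fold_scheme(labels, n_folds=cfg.n_folds, seed=seed)
    acc = searchlight_classify(maps, labels, sl, folds)
    import nibabel as nib

    nib.Nifti1Image(acc.values.astype(np.float32), affine).to_filename(
        out / "accuracy_map.nii.gz"
    )
    clusters = threshold_clusters(acc, cfg.cluster_criteria, affine)
    perm = dataclasses.replace(cfg.permutation, seed=seed)
    rows = []
    follow = []
    tdi = subjects["TDI"].to_numpy(dtype=float)
    for c in clusters:
        permutation_test_cluster(c, maps, labels, perm, n_folds=cfg.n_folds)
        x, y, z = c.peak_coord_world
        rows.append(
            {
                "label": c.label,
                "x": x,
                "y": y,
                "z": z,
                "size": c.cluster_size,
                "accuracy": c.peak_accuracy,
                "perm_p": c.perm_p,
            }
        )
        means, t_res = cluster_univariate_test(maps, labels, c)
        try:
            corr = correlate_with_behavior(means, tdi, method="pearson")
            corr_d = dataclasses.asdict(corr)
        except ValueError:
            corr_d = {"coefficient": np.nan, "note": "too few scored subjects"}
        follow.append(
            {"label": c.label, **{f"t_{k}": v for k, v in dataclasses.asdict(t_res).items()},
             **{f"tdi_{k}": v for k, v in corr_d.items()}}
        )
        if 0.05 <= t_res.p < 0.06:
            manifest.warnings.append(
                f"cluster {c.label} univariate contrast: two-sided p={t_res.p:.3f} "
                "is borderline; a one-sided reading would call it significant"
            )
    pd.DataFrame(
        rows, columns=["label", "x", "y", "z", "size", "accuracy", "perm_p"]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    pd.DataFrame(follow).to_csv(out / "cluster_followup.tsv", sep="\t", index=False)


def _stage_dfc(cfg: RunConfig, out: Path, manifest: RunManifest) -> None:
    subjects = oio.load_subjects(out / "subjects.tsv")
    ids = subjects["subject_id"].tolist()
    labels = subjects["group"].to_numpy()
    atlas = oio.load_atlas(out / "atlas.nii.gz", out / "labels.tsv")
    ts_dir = out / "ts_filtered" if (out / "ts_filtered").exists() else out / "ts"
    ts_list = oio.load_timeseries(ts_dir, ids)

    tables = []
    for sid, grp, ts in zip(ids, labels, ts_list):
        t = subject_fraction_table(
            ts, atlas, cfg.window_grid, cfg.dfc_params, cfg.seed_classes
        )
        t.insert(0, "subject_id", sid)
        t.insert(1, "group", grp)
        tables.append(t)
    fractions = pd.concat(tables, ignore_index=True)
    fractions.to_csv(out / "fractional_connectivity.tsv", sep="\t", index=False)

    contrasts = []
    for sc in cfg.seed_classes:
        contrasts.append(seed_group_contrast(fractions, sc))
    contrast_df = pd.concat(contrasts, ignore_index=True)
    contrast_df.to_csv(out / "dfc_contrasts.tsv", sep="\t", index=False)

    # behaviour link: for each seed class, the top-|t| target edge vs TDI
    tdi = dict(zip(ids, subjects["TDI"].to_numpy(dtype=float)))
    behav = {}
    for sc in cfg.seed_classes:
        top = contrast_df[contrast_df["seed_class"] == sc].iloc[0]
        edge = fractions[
            (fractions["seed_class"] == sc)
            & (fractions["target_pair"] == top["target_pair"])
        ]
        vals = edge["fraction"].to_numpy(dtype=float)
        scores = np.array([tdi[s] for s in edge["subject_id"]])
        try:
            res = dfc_behavior_correlation(vals, scores)
            behav[f"{sc}-{top['target_pair']}"] = dataclasses.asdict(res)
        except ValueError as e:
            behav[f"{sc}-{top['target_pair']}"] = {"error": str(e)}
    (out / "dfc_behavior.json").write_text(json.dumps(behav, indent=2, default=float))


def report(out_dir: str | Path) -> dict:
    """Merge stage outputs into human-readable summary tables.

    Emits report_clusters.tsv with the columns (label, x, y, z, size,
    accuracy, p), report_contrasts.tsv sorted by |t| descending, and
    summary.json. Partial results produce a partial report with warnings.
    """
    out = Path(out_dir)
    summary: dict = {"warnings": []}
    if (out / "clusters.tsv").exists():
        cl = pd.read_csv(out / "clusters.tsv", sep="\t")
        cl = cl.rename(columns={"perm_p": "p"})[
            ["label", "x", "y", "z", "size", "accuracy", "p"]
        ]
        cl.to_csv(out / "report_clusters.tsv", sep="\t", index=False)
        summary["n_clusters"] = int(len(cl))
    else:
        summary["warnings"].append("no morphometry cluster table found")
    if (out / "dfc_contrasts.tsv").exists():
        con = pd.read_csv(out / "dfc_contrasts.tsv", sep="\t")
        con = con.reindex(con["t"].abs().sort_values(ascending=False).index)
        con.to_csv(out / "report_contrasts.tsv", sep="\t", index=False)
        summary["n_contrast_rows"] = int(len(con))
        summary["n_significant_uncorrected"] = int((con["p"] < 0.05).sum())
    else:
        summary["warnings"].append("no connectivity contrast table found")
    if (out / "fd_group_test.json").exists():
        summary["fd_group_test"] = json.loads((out / "fd_group_test.json").read_text())
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "mvpa": _stage_mvpa,
    "dfc": _stage_dfc,
}

_STAGE_OUTPUTS = {
    "simulate": ["subjects.tsv", "labels.tsv", "atlas.nii.gz", "ground_truth.json"],
    "prep": ["fd.tsv", "fd_group_test.json"],
    "mvpa": ["accuracy_map.nii.gz", "clusters.tsv", "cluster_followup.tsv"],
    "dfc": [
        "fractional_connectivity.tsv",
        "dfc_contrasts.tsv",
        "dfc_behavior.json",
    ],
    "report": ["summary.json"],
}

_STAGE_INPUTS = {
    "simulate": [],
    "prep": ["subjects.tsv"],
    "mvpa": ["subjects.tsv", "gm/mask.nii.gz"],
    "dfc": ["subjects.tsv", "atlas.nii.gz", "labels.tsv"],
    "report": [],
}


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    Stage outputs are cached: a stage whose configuration hash matches the
    existing manifest and whose outputs are on disk is skipped. Missing
    inputs raise a named, actionable error before the stage starts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prev = RunManifest.load(out)
    from . import __version__

    manifest = RunManifest(
        config=dataclasses.asdict(cfg), version=__version__,
        warnings=list(prev.warnings) if prev else [],
    )
    if prev:
        manifest.stages.update(prev.stages)
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        h = _cfg_hash(cfg.stage_config(stage))
        if _stage_cached(prev, stage, h, out):
            manifest.stages[stage] = prev.stages[stage]
            continue
        for inp in _STAGE_INPUTS[stage]:
            if not (out / inp).exists():
                raise FileNotFoundError(
                    f"stage '{stage}' needs '{inp}' under {out}; "
                    "run the producing stage first (e.g. 'simulate')"
                )
        t0 = time.perf_counter()
        if stage == "report":
            report(out)
        else:
            _STAGE_FUNCS[stage](cfg, out, manifest)
        dt = time.perf_counter() - t0
        outputs = [f for f in _STAGE_OUTPUTS[stage] if (out / f).exists()]
        manifest.stages[stage] = {
            "hash": h,
            "seconds": round(dt, 3),
            "outputs": outputs,
            "checksums": {f: _sha256(out / f) for f in outputs},
        }
    manifest.save(out)
    return manifest
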