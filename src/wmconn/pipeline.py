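"""End-to-end orchestration: simulate -> mask -> parcellate -> clean ->
connectome -> metrics -> stats, with a manifest and reproducible outputs.

Two synthetic entry points are wired in:

* the volume path exercises every image-level stage (tissue maps, WM
  masking, region growing, motion scrubbing, bandpass, node extraction)
  on a miniature grid;
* the cohort path generates node-level series for two groups with a
  controllable effect and runs the statistical layer (AUC t-tests,
  Bonferroni, clinical correlation).

A single run seed fans out into independent per-stage substreams, so
e.g. changing the null-network count does not perturb the parcellation.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import correlation_matrix, node_timeseries
from .io import write_motion, write_nifti, write_tsv
from .masking import exclude_labels, group_wm_mask, individual_wm_mask
from .metrics import (
    GLOBAL_METRIC_NAMES,
    NODAL_METRIC_NAMES,
    NullSpec,
    default_sparsity_grid,
    metric_curves,
)
from .parcellation import parcel_report, region_grow_parcellation
from .preprocess import bandpass, drop_initial, framewise_displacement, scrub
from .stats import clinical_correlation, compare_global, compare_nodal
from .synthetic import (
    SyntheticCohortSpec,
    SyntheticVolumeSpec,
    make_bold_volume,
    make_cohort_connectomes,
    make_tissue_maps,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study-standard values."""

    mode: str = "cohort"  # "cohort", "volumes", or "full"
    wm_threshold: float = 0.90
    group_overlap: float = 0.80
    exclude_label_ids: tuple[int, ...] = ()
    n_nodes: int = 128
    connectivity: int = 26
    n_drop: int = 10
    fd_threshold: float = 0.5
    n_forward: int = 1
    n_back: int = 2
    band: tuple[float, float] = (0.01, 0.10)
    sparsity: tuple[float, float, float] = (0.07, 0.30, 0.01)
    n_nulls: int = 100
    swaps_per_edge: int = 10
    alpha: float = 0.05
    seed: int = 0
    # synthetic input specs
    n_subjects_volumes: int = 4
    volume: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("cohort", "volumes", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.wm_threshold < 1:
            raise ValueError("wm_threshold must be in (0, 1)")
        if not 0 < self.group_overlap <= 1:
            raise ValueError("group_overlap must be in (0, 1]")
        lo, hi, step = self.sparsity
        if not (0 < lo < hi < 1 and step > 0):
            raise ValueError("sparsity grid must satisfy 0 < lo < hi < 1, step > 0")
        if self.band[0] >= self.band[1]:
            raise ValueError("band must be (low, high) with low < high")

    def grid(self) -> np.ndarray:
        lo, hi, step = self.sparsity
        return default_sparsity_grid(lo, hi, step)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["exclude_label_ids"] = list(self.exclude_label_ids)
        d["band"] = list(self.band)
        d["sparsity"] = list(self.sparsity)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        for key in ("exclude_label_ids", "band", "sparsity"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir: str | Path, log=None) -> Path:
    """Run every configured stage and write outputs plus a manifest.

    Reruns with an identical config produce byte-identical TSV outputs.
    Stage failures abort with the stage name (and subject id where one
    applies) in the exception message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}

    def _log(msg: str) -> None:
        if log is not None:
            log(f"[wmconn +{time.time() - t0:6.1f}s] {msg}")

    if config.mode in ("volumes", "full"):
        _run_volume_path(config, out, _log, timings)
    if config.mode in ("cohort", "full"):
        _run_cohort_path(config, out, _log, timings)

    manifest = {
        "package_version": __version__,
        "config": config.as_dict(),
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    _log("done")
    return out


def _run_volume_path(config: RunConfig, out: Path, _log, timings) -> None:
    """Image-level stages on synthetic miniature volumes."""
    t0 = time.time()
    vol_kwargs = dict(config.volume)
    n_subj = config.n_subjects_volumes
    specs = [
        SyntheticVolumeSpec(seed=_stage_seed(config.seed, 10 + i), **vol_kwargs)
        for i in range(n_subj)
    ]
    subj_dir = out / "subjects"
    subj_dir.mkdir(exist_ok=True)

    _log(f"simulating {n_subj} subject volumes")
    wm_maps, bolds, motions = [], [], []
    for i, spec in enumerate(specs):
        wm, gm, csf = make_tissue_maps(spec)
        bold, motion = make_bold_volume(spec, wm)
        wm_maps.append(wm)
        bolds.append(bold)
        motions.append(motion)
        write_nifti(wm, spec.affine, subj_dir / f"sub-{i:02d}_wm_prob.nii.gz")
        write_motion(motion, subj_dir / f"sub-{i:02d}_motion.txt")
    timings["simulate_volumes"] = time.time() - t0

    t0 = time.time()
    _log("building WM masks")
    affine = specs[0].affine
    try:
        masks = [
            individual_wm_mask(wm, config.wm_threshold, affine) for wm in wm_maps
        ]
        group = group_wm_mask(masks, config.group_overlap)
        if config.exclude_label_ids:
            raise ValueError("volume path generates no label volume to exclude from")
    except Exception as exc:
        raise RuntimeError(f"stage wm_masking failed: {exc}") from exc
    write_nifti(group.grid, affine, out / "group_wm_mask.nii.gz")
    timings["wm_masking"] = time.time() - t0

    t0 = time.time()
    n_nodes = min(config.n_nodes, max(2, group.n_true // 8))
    _log(f"region-growing parcellation into {n_nodes} nodes")
    try:
        parc = region_grow_parcellation(
            group, n_nodes, config.connectivity, seed=_stage_seed(config.seed, 2)
        )
    except Exception as exc:
        raise RuntimeError(f"stage parcellation failed: {exc}") from exc
    write_nifti(parc.labels, affine, out / "parcellation.nii.gz")
    write_tsv(parcel_report(parc), out / "parcel_table.tsv")
    timings["parcellation"] = time.time() - t0

    t0 = time.time()
    _log("cleaning BOLD and extracting node series")
    conns = []
    kept_rows = []
    for i, spec in enumerate(specs):
        sid = f"sub-{i:02d}"
        try:
            bold = drop_initial(bolds[i], config.n_drop)
            motion = motions[i][config.n_drop :]
            fd = framewise_displacement(motion)
            censor = scrub(fd, config.fd_threshold, config.n_forward, config.n_back)
            voxels = bold[group.grid]
            voxels = bandpass(voxels, spec.tr, config.band[0], config.band[1])
            ts = node_timeseries(voxels, parc, censor, subject_id=sid)
            conns.append(correlation_matrix(ts))
            kept_rows.append(
                {"subject_id": sid, "n_frames": len(censor.keep), "n_kept": censor.n_kept}
            )
            pd.DataFrame({"keep": censor.keep.astype(int)}).to_csv(
                subj_dir / f"{sid}_censor.tsv", sep="\t", index=False
            )
        except Exception as exc:
            raise RuntimeError(f"stage signal_cleaning failed for {sid}: {exc}") from exc
    write_tsv(pd.DataFrame(kept_rows), out / "frames_kept.tsv")
    for c in conns:
        write_tsv(pd.DataFrame(c.z), subj_dir / f"{c.subject_id}_connectome.tsv")
    timings["signal_cleaning"] = time.time() - t0

    t0 = time.time()
    _log("computing metric curves for volume subjects")
    grid = config.grid()
    rows = []
    for c in conns:
        curves = metric_curves(c, grid, null_spec=None, compute_nodal=False)
        for name, curve in curves.global_curves.items():
            for s, v in zip(grid, curve.values):
                rows.append(
                    {"subject_id": c.subject_id, "metric": name,
                     "sparsity": float(s), "value": float(v)}
                )
    write_tsv(pd.DataFrame(rows), out / "volume_metric_curves.tsv")
    timings["volume_metrics"] = time.time() - t0


def _run_cohort_path(config: RunConfig, out: Path, _log, timings) -> None:
    """Node-series cohort, metric sweep with nulls, statistical layer."""
    t0 = time.time()
    cohort_kwargs = dict(config.cohort)
    cohort_spec = SyntheticCohortSpec(
        seed=_stage_seed(config.seed, 1), **cohort_kwargs
    )
    _log(
        f"simulating cohort: {cohort_spec.n_per_group}+{cohort_spec.n_per_group} "
        f"subjects, {cohort_spec.n_nodes} nodes"
    )
    cohort = make_cohort_connectomes(cohort_spec)
    write_tsv(cohort.clinical, out / "clinical.tsv")
    timings["simulate_cohort"] = time.time() - t0

    t0 = time.time()
    grid = config.grid()
    null_spec = NullSpec(
        n_nulls=config.n_nulls,
        n_swaps_per_edge=config.swaps_per_edge,
        seed=_stage_seed(config.seed, 3),
    )
    _log(
        f"metric sweep: {len(grid)} sparsities x {len(cohort.series)} subjects, "
        f"{config.n_nulls} nulls each"
    )
    global_rows = {}
    nodal_tables = {name: [] for name in NODAL_METRIC_NAMES}
    curve_rows = []
    for ts in cohort.series:
        try:
            c = correlation_matrix(ts)
            curves = metric_curves(c, grid, null_spec=null_spec)
        except Exception as exc:
            raise RuntimeError(
                f"stage graph_metrics failed for {ts.subject_id}: {exc}"
            ) from exc
        global_rows[ts.subject_id] = curves.global_auc()
        for name in NODAL_METRIC_NAMES:
            nodal_tables[name].append(curves.nodal_auc()[name])
        for name, curve in curves.global_curves.items():
            for s, v in zip(grid, curve.values):
                curve_rows.append(
                    {"subject_id": ts.subject_id, "metric": name,
                     "sparsity": float(s), "value": float(v)}
                )
    auc_global = pd.DataFrame.from_dict(global_rows, orient="index")
    auc_global = auc_global[list(GLOBAL_METRIC_NAMES)]
    auc_global.index.name = "subject_id"
    write_tsv(auc_global.reset_index(), out / "auc_global.tsv")
    nodal_auc = {k: np.vstack(v) for k, v in nodal_tables.items()}
    for name, table in nodal_auc.items():
        df = pd.DataFrame(
            table, columns=[f"node_{i + 1}" for i in range(table.shape[1])]
        )
        df.insert(0, "subject_id", list(global_rows))
        write_tsv(df, out / f"auc_nodal_{name}.tsv")
    write_tsv(pd.DataFrame(curve_rows), out / "metric_curves.tsv")
    timings["graph_metrics"] = time.time() - t0

    t0 = time.time()
    _log("group inference")
    try:
        global_results = compare_global(
            auc_global, cohort.groups, alpha=config.alpha
        )
        nodal_results = compare_nodal(nodal_auc, cohort.groups, alpha=config.alpha)
    except Exception as exc:
        raise RuntimeError(f"stage group_inference failed: {exc}") from exc
    write_tsv(
        pd.DataFrame([asdict(r) for r in global_results]).drop(columns="node"),
        out / "global_comparisons.tsv",
    )
    write_tsv(
        pd.DataFrame([asdict(r) for r in nodal_results]),
        out / "nodal_comparisons.tsv",
    )

    smokers = [g == "smoker" for g in cohort.groups]
    onset = cohort.clinical.set_index("subject_id").loc[
        [ts.subject_id for ts, s in zip(cohort.series, smokers) if s], "onset_age"
    ].to_numpy()
    corr_rows = []
    for metric in ("cp", "e_local"):
        vals = auc_global.loc[
            [ts.subject_id for ts, s in zip(cohort.series, smokers) if s], metric
        ].to_numpy()
        for method in ("pearson", "spearman"):
            res = clinical_correlation(
                vals, onset, method=method, x_name=f"{metric}_auc", y_name="onset_age"
            )
            corr_rows.append(asdict(res))
    write_tsv(pd.DataFrame(corr_rows), out / "clinical_correlations.tsv")
    timings["group_inference"] = time.time() - t0
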