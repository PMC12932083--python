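"""Synthetic stand-ins for every input of a WM-connectome study.

Two generators cover the two entry points of the pipeline:

* volume-level — miniature tissue-probability maps, 4-D BOLD runs whose
  voxels share latent band-limited signals within ground-truth parcels,
  and realignment-parameter files with controllable motion spikes;

* cohort-level — node-by-time series for two groups drawn from a block
  (modular) factor model,  x_i = sqrt(w) f_m(i) + sqrt(1-w) sigma eps_i,
  which has closed-form expected within-module correlation (equal to w
  at the default unit noise scale) so group effects on clustering and
  local efficiency can be injected monotonically through w, plus a
  clinical covariate table whose age-of-first-smoking column is coupled
  to each smoker's realized network coherence through a Gaussian copula
  with a chosen target correlation.

Every generator is a pure function of its spec (seeded determinism).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import NodeTimeSeries

__all__ = [
    "SyntheticVolumeSpec",
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "make_tissue_maps",
    "ground_truth_parcels",
    "make_bold_volume",
    "make_cohort_connectomes",
    "make_clinical_table",
    "pack_years",
    "TABLE1_SMOKERS",
]

# Cohort summary statistics (mean, sd) used to draw clinical covariates.
TABLE1_SMOKERS = {
    "age": (19.50, 2.12),
    "duration": (4.40, 2.96),
    "ftnd": (6.95, 1.97),
    "cpd": (16.23, 5.60),
    "onset_age": (14.23, 2.57),
}
_CONTROL_AGE = (19.55, 1.86)


def pack_years(duration: float, cpd: float) -> float:
    """Cumulative smoking exposure: smoking years x cigarettes/day / 20."""
    if duration < 0 or cpd < 0:
        raise ValueError("duration and cigarettes/day must be non-negative")
    return duration * cpd / 20.0


@dataclass(frozen=True)
class SyntheticVolumeSpec:
    """Miniature fMRI-acquisition stand-in: grid, timing, motion spikes."""

    grid_dims: tuple[int, int, int] = (16, 16, 16)
    voxel_size: float = 3.0
    n_timepoints: int = 120
    tr: float = 2.0
    n_parcels_truth: int = 8
    fd_spike_times: tuple[int, ...] = ()
    fd_spike_mm: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 8 for d in self.grid_dims):
            raise ValueError("each grid dimension must be at least 8")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if any(t < 0 or t >= self.n_timepoints for t in self.fd_spike_times):
            raise ValueError("spike times must lie within the run")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -np.asarray(self.grid_dims) * self.voxel_size / 2.0
        return aff


def make_tissue_maps(
    spec: SyntheticVolumeSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """WM / GM / CSF probability maps on the spec's grid.

    A central ellipsoidal blob carries WM probability above 0.9, wrapped
    in a GM shell and a CSF rim; probabilities sum to at most 1 voxelwise.
    """
    dims = np.asarray(spec.grid_dims)
    center = (dims - 1) / 2.0
    ii = np.indices(spec.grid_dims).astype(float)
    r = np.sqrt(sum(((ii[a] - center[a]) / (dims[a] / 2.0)) ** 2 for a in range(3)))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 11]))
    jitter = 0.01 * rng.standard_normal(spec.grid_dims)
    # logistic fall-off: deep blob ~0.98 WM, shell ~GM, outside ~CSF
    wm = np.clip(0.98 / (1.0 + np.exp((r - 0.55) / 0.06)) + jitter, 0.0, 0.98)
    gm = np.clip(0.90 / (1.0 + np.exp((r - 0.80) / 0.06)) - wm, 0.0, None)
    csf = np.clip(0.95 - wm - gm, 0.0, None) * (r < 1.05)
    total = wm + gm + csf
    over = total > 1.0
    scale = np.where(over, total, 1.0)
    wm, gm, csf = wm / scale, gm / scale, csf / scale
    if int((wm > 0.9).sum()) < spec.n_parcels_truth:
        raise ValueError(
            f"grid {spec.grid_dims} too small to host {spec.n_parcels_truth} "
            "ground-truth parcels in a >0.9 WM core"
        )
    return wm, gm, csf


def ground_truth_parcels(spec: SyntheticVolumeSpec, wm_map: np.ndarray) -> np.ndarray:
    """Partition the WM blob (prob > 0.5) into seeded Voronoi parcels.

    These are the parcels whose shared latent signals drive the BOLD
    generator; they are the recovery target for parcellation and
    node-extraction tests.
    """
    if wm_map.shape != spec.grid_dims:
        raise ValueError("wm_map is not on the spec's grid")
    coords = np.argwhere(wm_map > 0.5)
    if coords.shape[0] < spec.n_parcels_truth:
        raise ValueError("WM blob too small for the requested parcel count")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    seed_idx = rng.choice(coords.shape[0], size=spec.n_parcels_truth, replace=False)
    seed_pts = coords[seed_idx]
    d2 = ((coords[:, None, :] - seed_pts[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1) + 1
    labels = np.zeros(spec.grid_dims, dtype=np.int32)
    labels[tuple(coords.T)] = assign
    return labels


def _bandlimited_signals(
    rng: np.random.Generator, n: int, t: int, tr: float
) -> np.ndarray:
    """Unit-variance signals with power confined to 0.01-0.10 Hz."""
    freqs = np.fft.rfftfreq(t, d=tr)
    band = (freqs >= 0.01) & (freqs <= 0.10)
    spec = np.fft.rfft(rng.standard_normal((n, t)), axis=-1)
    spec[:, ~band] = 0
    x = np.fft.irfft(spec, n=t, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def make_bold_volume(
    spec: SyntheticVolumeSpec,
    wm_map: np.ndarray,
    parcel_latents: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """A 4-D BOLD run plus its T x 6 realignment-parameter table.

    Voxels inside a ground-truth parcel share that parcel's latent
    band-limited signal plus independent noise of scale ``noise_sd``.
    The motion table carries step displacements at ``fd_spike_times``
    sized ``fd_spike_mm`` so the downstream FD trace spikes exactly
    there, and sub-0.2 mm background motion elsewhere.  Custom parcel
    latents (n_parcels_truth x n_timepoints) may be supplied, e.g. to
    impose modular structure across parcels; by default each parcel
    gets an independent band-limited signal.
    """
    labels = ground_truth_parcels(spec, wm_map)
    t = spec.n_timepoints
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 37]))
    if parcel_latents is None:
        latents = _bandlimited_signals(rng, spec.n_parcels_truth, t, spec.tr)
    else:
        latents = np.asarray(parcel_latents, dtype=float)
        if latents.shape != (spec.n_parcels_truth, t):
            raise ValueError("parcel_latents must be n_parcels_truth x n_timepoints")
        rng.standard_normal((spec.n_parcels_truth, t))  # keep stream alignment
    bold = rng.standard_normal((*spec.grid_dims, t)) * max(spec.noise_sd, 0.0)
    if spec.noise_sd == 0:
        bold[:] = 0.0
    for p in range(1, spec.n_parcels_truth + 1):
        inside = labels == p
        bold[inside] += latents[p - 1]
    bold += 100.0  # arbitrary scanner baseline

    motion = np.zeros((t, 6))
    motion[:, :3] = np.cumsum(rng.uniform(-0.005, 0.005, size=(t, 3)), axis=0)
    motion[:, 3:] = np.cumsum(rng.uniform(-5e-5, 5e-5, size=(t, 3)), axis=0)
    step = np.zeros(t)
    for k, spike in enumerate(spec.fd_spike_times):
        step[spike:] += spec.fd_spike_mm * (1 if k % 2 == 0 else -1)
    motion[:, 0] += step
    return bold, motion


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Two-group modular cohort: block-factor node signals per subject."""

    n_per_group: int = 42
    n_nodes: int = 128
    n_timepoints: int = 120
    n_modules: int = 4
    within_module_corr: float = 0.4
    noise_sd: float = 1.0
    effect: float = 0.0
    clinical_r: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if not 1 <= self.n_modules <= self.n_nodes:
            raise ValueError("need n_nodes >= n_modules >= 1")
        if not 0 <= self.within_module_corr < 1:
            raise ValueError("within_module_corr must lie in [0, 1)")
        if self.within_module_corr + self.effect >= 1 or (
            self.within_module_corr + self.effect
        ) < 0:
            raise ValueError(
                "infeasible correlation target: within_module_corr + effect "
                "must lie in [0, 1) (factor loading would exceed 1)"
            )
        if not -1 < self.clinical_r < 1:
            raise ValueError("clinical_r must lie in (-1, 1)")

    def module_of_node(self) -> np.ndarray:
        return (np.arange(self.n_nodes) * self.n_modules) // self.n_nodes


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort: node series, group labels, clinical table."""

    spec: SyntheticCohortSpec
    series: list[NodeTimeSeries]
    groups: list[str]
    clinical: pd.DataFrame
    coherence: np.ndarray  # per-subject realized modular coherence
    module_of_node: np.ndarray = field(repr=False, default=None)


def _modular_coherence(values: np.ndarray, modules: np.ndarray) -> float:
    """Mean within-module Fisher-z correlation of one subject's series."""
    r = np.corrcoef(values)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    same = modules[:, None] == modules[None, :]
    off = ~np.eye(len(modules), dtype=bool)
    return float(z[same & off].mean())


def make_cohort_connectomes(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Draw the full two-group cohort of node time series.

    Smokers receive within-module correlation ``within_module_corr +
    effect``; controls ``within_module_corr``.  Across smokers, age of
    first smoking is coupled to the subject's realized modular coherence
    by a Gaussian copula targeting Pearson r = ``clinical_r``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    modules = spec.module_of_node()
    series: list[NodeTimeSeries] = []
    groups: list[str] = []
    coherence = np.full(2 * spec.n_per_group, np.nan)
    for idx in range(2 * spec.n_per_group):
        smoker = idx < spec.n_per_group
        w = spec.within_module_corr + (spec.effect if smoker else 0.0)
        f = rng.standard_normal((spec.n_modules, spec.n_timepoints))
        eps = rng.standard_normal((spec.n_nodes, spec.n_timepoints))
        x = np.sqrt(w) * f[modules] + np.sqrt(1.0 - w) * spec.noise_sd * eps
        sid = f"{'smoker' if smoker else 'control'}_{idx % spec.n_per_group:03d}"
        series.append(NodeTimeSeries(x, subject_id=sid))
        groups.append("smoker" if smoker else "control")
        coherence[idx] = _modular_coherence(x, modules)
    clinical = make_clinical_table(spec, coherence[: spec.n_per_group], rng)
    return SyntheticCohort(
        spec=spec,
        series=series,
        groups=groups,
        clinical=clinical,
        coherence=coherence,
        module_of_node=modules,
    )


def make_clinical_table(
    spec: SyntheticCohortSpec,
    smoker_coherence: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical covariates: smokers get full smoking history, controls none.

    ``onset_age`` is generated from the smokers' normal scores of
    realized coherence through a Gaussian copula with correlation
    ``clinical_r``, then mapped onto the cohort's onset-age scale.
    """
    n = spec.n_per_group
    ranks = stats.rankdata(smoker_coherence)
    z_coh = stats.norm.ppf(ranks / (n + 1))
    z_coh = (z_coh - z_coh.mean()) / z_coh.std()
    r = spec.clinical_r
    latent = r * z_coh + np.sqrt(1 - r * r) * rng.standard_normal(n)
    mu, sd = TABLE1_SMOKERS["onset_age"]
    onset = mu + sd * latent

    age_s = TABLE1_SMOKERS["age"][0] + TABLE1_SMOKERS["age"][1] * rng.standard_normal(n)
    dur = np.maximum(
        TABLE1_SMOKERS["duration"][0]
        + TABLE1_SMOKERS["duration"][1] * rng.standard_normal(n),
        0.5,
    )
    ftnd = np.clip(
        np.round(
            TABLE1_SMOKERS["ftnd"][0] + TABLE1_SMOKERS["ftnd"][1] * rng.standard_normal(n)
        ),
        2,
        10,
    )
    cpd = np.maximum(
        TABLE1_SMOKERS["cpd"][0] + TABLE1_SMOKERS["cpd"][1] * rng.standard_normal(n),
        1.0,
    )
    age_c = _CONTROL_AGE[0] + _CONTROL_AGE[1] * rng.standard_normal(n)

    rows = []
    for i in range(n):
        rows.append(
            {
                "subject_id": f"smoker_{i:03d}",
                "group": "smoker",
                "age": age_s[i],
                "ftnd": ftnd[i],
                "cpd": cpd[i],
                "duration": dur[i],
                "onset_age": onset[i],
                "pack_years": pack_years(dur[i], cpd[i]),
            }
        )
    for i in range(n):
        rows.append(
            {
                "subject_id": f"control_{i:03d}",
                "group": "control",
                "age": age_c[i],
                "ftnd": np.nan,
                "cpd": np.nan,
                "duration": np.nan,
                "onset_age": np.nan,
                "pack_years": np.nan,
            }
        )
    return pd.DataFrame(rows)
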