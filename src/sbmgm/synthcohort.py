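"""Synthetic gray-matter cohort with known ground truth.

The generative model mirrors the one source-based morphometry assumes:
each subject's masked gray-matter map is a linear mixture ``X = A @ S`` of
``K_true`` smooth spatial sources (rows of ``S``, unit variance over the
mask) weighted by per-subject loading coefficients (rows of ``A``), plus a
smooth baseline template and spatially smoothed Gaussian noise, clipped at
zero because GM volume is nonnegative.

Planted structure, chosen to emulate a two-group depression cohort with a
morning-cortisol biomarker:

* selected components carry a between-group mean shift on their loadings,
  expressed in pooled-SD units (Cohen's d); patients are shifted downward;
* one component's loadings are rank-coupled to cortisol within the patient
  group through a Gaussian copula calibrated so the expected Spearman
  correlation equals ``rho_target``;
* cortisol is log-normal per group, moment-matched to the group mean/SD in
  nmol/L (healthy 9.6 +/- 3.6, patients 12.3 +/- 5.1 by default);
* age and sex roughly match the emulated cohort margins but carry no
  planted effect.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter

from .errors import SimulationError
from .gmio import GMVolume, save_volume

GROUP_HS = "HS"
GROUP_MDD = "MDD"

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

# fixed stream tags so the three generator stages draw independent,
# reproducible substreams from one user-facing seed
_STREAM_SOURCES = 11
_STREAM_COHORT = 22
_STREAM_NOISE = 33


@dataclass(frozen=True)
class CortisolParams:
    """Group-wise cortisol summaries (nmol/L) to moment-match log-normally."""

    mean_hs: float = 9.6
    sd_hs: float = 3.6
    mean_mdd: float = 12.3
    sd_mdd: float = 5.1


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the emulated study conditions: 39 healthy subjects
    (HS) and 42 patients (MDD); eight planted networks on a 32^3 grid of
    4-mm voxels; group effects of d = 0.85 and d = 0.7 on two components;
    the d = 0.7 component negatively rank-correlated with cortisol
    (rho = -0.35) within the patient group.
    """

    n_hs: int = 39
    n_mdd: int = 42
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: float = 4.0
    k_true: int = 8
    blobs_per_source: int = 3
    blob_fwhm_mm: float = 24.0
    smoothing_fwhm_mm: float = 8.0
    noise_sd: float = 0.5
    effect_d: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.85, 1: 0.7}
    )
    cortisol_component: int = 1
    rho_target: float = -0.35
    cortisol_params: CortisolParams = field(default_factory=CortisolParams)
    baseline_factor: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_hs, self.n_mdd) < 1:
            raise SimulationError("group sizes must be >= 1")
        if self.k_true < 1 or self.blobs_per_source < 1:
            raise SimulationError("k_true and blobs_per_source must be >= 1")
        if self.smoothing_fwhm_mm < 0 or self.noise_sd < 0:
            raise SimulationError("smoothing_fwhm_mm and noise_sd must be >= 0")
        if abs(self.rho_target) > 1:
            raise SimulationError("|rho_target| must be <= 1")
        if abs(self.rho_target) == 1 and self.noise_sd > 0:
            raise SimulationError(
                "a perfect rank coupling (|rho_target| = 1) is infeasible "
                "with noise_sd > 0"
            )

    @property
    def n_subjects(self) -> int:
        return self.n_hs + self.n_mdd

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect bookkeeping carried alongside the ground truth."""

    effect_d: dict[int, float]
    cortisol_component: int
    rho_target: float


@dataclass
class GroundTruth:
    """Planted sources, loadings and subject table of one synthetic cohort."""

    sources_true: np.ndarray  # K x V, unit variance over mask voxels
    mask: np.ndarray  # 3-D boolean
    loadings_true: np.ndarray  # N x K
    subject_table: pd.DataFrame
    effect_spec: EffectSpec


def _ellipsoid_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal 'brain' filling ~80% of each axis, slightly flattened in z."""
    shape = np.asarray(grid_shape, dtype=float)
    center = (shape - 1.0) / 2.0
    semi = shape * np.array([0.42, 0.42, 0.38])
    grids = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return r2 <= 1.0


def _sigma_vox(fwhm_mm: float, voxel_size_mm: float) -> float:
    return fwhm_mm * _FWHM_TO_SIGMA / voxel_size_mm


def _blob_map(
    grid_shape: tuple[int, int, int],
    centers: np.ndarray,
    sigma: float,
) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    vol = np.zeros(grid_shape)
    for c in centers:
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        vol += np.exp(-d2 / (2.0 * sigma**2))
    return vol


def generate_sources(
    config: SimulationConfig,
    *,
    max_corr: float = 0.2,
    max_attempts: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Plant ``k_true`` smooth nonnegative source maps inside an ellipsoid.

    Each source is a sum of Gaussian blobs centred at random interior
    voxels, smoothed to ``smoothing_fwhm_mm``, flattened over the mask and
    scaled to unit variance.  Sources are rejection-sampled so every
    pairwise absolute correlation stays below ``max_corr``.

    Returns
    -------
    sources : (K, V) ndarray
    mask : 3-D boolean ndarray
    """
    config.validate()
    mask = _ellipsoid_mask(config.grid_shape)
    n_vox = int(mask.sum())
    if n_vox < 10 * config.k_true:
        raise SimulationError(
            f"grid {config.grid_shape} yields only {n_vox} mask voxels; "
            f"need >= {10 * config.k_true} for k_true={config.k_true}"
        )
    interior = binary_erosion(mask, iterations=2)
    coords = np.argwhere(interior if interior.any() else mask)

    rng = np.random.default_rng([config.seed, _STREAM_SOURCES])
    sigma_blob = _sigma_vox(config.blob_fwhm_mm, config.voxel_size_mm)
    sigma_smooth = _sigma_vox(config.smoothing_fwhm_mm, config.voxel_size_mm)

    # rejection-sample each source; if a late source cannot be placed the
    # earlier draws blocked the space, so restart the whole set
    for _restart in range(20):
        rows: list[np.ndarray] = []
        for _k in range(config.k_true):
            for _ in range(max_attempts):
                centers = coords[
                    rng.integers(len(coords), size=config.blobs_per_source)
                ]
                vol = _blob_map(config.grid_shape, centers, sigma_blob)
                if sigma_smooth > 0:
                    vol = gaussian_filter(vol, sigma_smooth)
                vec = vol[mask]
                sd = vec.std()
                if sd <= 0:
                    continue
                vec = vec / sd
                if all(
                    abs(np.corrcoef(vec, prev)[0, 1]) < max_corr
                    for prev in rows
                ):
                    rows.append(vec)
                    break
            else:
                break  # placement failed; restart the whole set
        if len(rows) == config.k_true:
            return np.vstack(rows), mask
    raise SimulationError(
        f"could not place {config.k_true} sources with pairwise |corr| < "
        f"{max_corr}; grid too small for the requested number of sources"
    )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def _copula_pearson(rho_spearman: float) -> float:
    """Latent Pearson correlation giving the target Spearman under a
    Gaussian copula: rho_s = (6/pi) * asin(r/2)."""
    return 2.0 * math.sin(math.pi * rho_spearman / 6.0)


def generate_cohort(config: SimulationConfig) -> GroundTruth:
    """Draw sources, loadings, demographics and cortisol for one cohort."""
    config.validate()
    sources, mask = generate_sources(config)
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])

    n, k = config.n_subjects, config.k_true
    loadings = rng.standard_normal((n, k))
    hs = slice(0, config.n_hs)
    mdd = slice(config.n_hs, n)

    cp = config.cortisol_params
    mu_h, sig_h = _lognormal_params(cp.mean_hs, cp.sd_hs)
    mu_m, sig_m = _lognormal_params(cp.mean_mdd, cp.sd_mdd)
    cort_hs = np.exp(mu_h + sig_h * rng.standard_normal(config.n_hs))

    c = config.cortisol_component
    if not 0 <= c < k:
        raise SimulationError(f"cortisol_component {c} out of range for k_true={k}")
    # Gaussian-copula coupling: reuse the (still standard normal) loading
    # column as one latent coordinate so the loading marginal is untouched.
    r = _copula_pearson(config.rho_target)
    z1 = loadings[mdd, c]
    z2 = r * z1 + math.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal(
        config.n_mdd
    )
    cort_mdd = np.exp(mu_m + sig_m * z2)

    for comp, d in config.effect_d.items():
        if not 0 <= comp < k:
            raise SimulationError(f"effect component {comp} out of range")
        loadings[hs, comp] += d / 2.0
        loadings[mdd, comp] -= d / 2.0

    age = np.concatenate(
        [
            rng.normal(43.3, 11.6, config.n_hs),
            rng.normal(48.1, 14.3, config.n_mdd),
        ]
    )
    age = np.clip(np.round(age), 20, 80).astype(int)
    sex = np.concatenate(
        [
            np.where(rng.random(config.n_hs) < 26 / 39, "M", "F"),
            np.where(rng.random(config.n_mdd) < 0.5, "M", "F"),
        ]
    )
    table = pd.DataFrame(
        {
            "subject_id": [f"HS{i + 1:03d}" for i in range(config.n_hs)]
            + [f"MDD{i + 1:03d}" for i in range(config.n_mdd)],
            "group": [GROUP_HS] * config.n_hs + [GROUP_MDD] * config.n_mdd,
            "age": age,
            "sex": sex,
            "cortisol_nmol_l": np.concatenate([cort_hs, cort_mdd]),
        }
    )
    spec = EffectSpec(
        effect_d=dict(config.effect_d),
        cortisol_component=c,
        rho_target=config.rho_target,
    )
    return GroundTruth(
        sources_true=sources,
        mask=mask,
        loadings_true=loadings,
        subject_table=table,
        effect_spec=spec,
    )


def baseline_template(
    truth: GroundTruth, config: SimulationConfig
) -> np.ndarray:
    """Constant baseline GM level over mask voxels.

    Amplitude is ``baseline_factor`` times the worst-case voxelwise SD of
    signal plus noise (``sqrt(max_v sum_k s_kv^2 + noise_sd^2)`` for
    unit-variance loadings), so the zero-clip sits ~5 sigma below the data
    at every voxel and the mixture stays essentially exactly linear.
    """
    worst_var = float(np.max(np.sum(truth.sources_true**2, axis=0)))
    amp = config.baseline_factor * math.sqrt(worst_var + config.noise_sd**2)
    return np.full(truth.sources_true.shape[1], amp)


def synthesize_matrix(
    truth: GroundTruth, config: SimulationConfig
) -> np.ndarray:
    """Subjects x masked-voxels data matrix (the in-memory cohort).

    ``X[i] = loadings[i] @ sources + baseline + smoothed noise``, clipped
    at zero.  Per-subject noise fields are smoothed to the configured FWHM
    and rescaled so their SD over the mask equals ``noise_sd`` exactly.
    """
    if truth.loadings_true.shape[1] != truth.sources_true.shape[0]:
        raise SimulationError(
            "loadings_true and sources_true disagree on the number of "
            "components"
        )
    rng = np.random.default_rng([config.seed, _STREAM_NOISE])
    x = truth.loadings_true @ truth.sources_true
    x = x + baseline_template(truth, config)[None, :]
    if config.noise_sd > 0:
        sigma = _sigma_vox(config.smoothing_fwhm_mm, config.voxel_size_mm)
        for i in range(x.shape[0]):
            field_ = rng.standard_normal(config.grid_shape)
            if sigma > 0:
                field_ = gaussian_filter(field_, sigma)
            noise = field_[truth.mask]
            x[i] += noise * (config.noise_sd / noise.std())
    np.maximum(x, 0.0, out=x)
    return x


def synthesize_volumes(
    truth: GroundTruth,
    config: SimulationConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[GMVolume], pd.DataFrame]:
    """Materialize the cohort as per-subject 3-D volumes (float32).

    When ``out_dir`` is given, writes one NIfTI-1 per subject
    (``<subject_id>.nii.gz``), the mask, the subject table as TSV, and a
    ground-truth bundle (JSON + .npz) for downstream oracles.
    """
    x = synthesize_matrix(truth, config)
    affine = config.affine
    volumes = []
    for i, sid in enumerate(truth.subject_table["subject_id"]):
        vol = np.zeros(config.grid_shape, dtype=np.float32)
        vol[truth.mask] = x[i].astype(np.float32)
        volumes.append(GMVolume(data=vol, affine=affine, subject_id=str(sid)))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for v in volumes:
            save_volume(v, out / f"{v.subject_id}.nii.gz")
        save_volume(
            GMVolume(
                data=truth.mask.astype(np.uint8), affine=affine, subject_id="mask"
            ),
            out / "mask.nii.gz",
        )
        truth.subject_table.to_csv(out / "subjects.tsv", sep="\t", index=False)
        np.savez(
            out / "ground_truth.npz",
            sources_true=truth.sources_true,
            loadings_true=truth.loadings_true,
            mask=truth.mask,
        )
        meta = {
            "effect_spec": {
                "effect_d": {str(k): v for k, v in truth.effect_spec.effect_d.items()},
                "cortisol_component": truth.effect_spec.cortisol_component,
                "rho_target": truth.effect_spec.rho_target,
            },
            "config": _config_as_json(config),
        }
        (out / "ground_truth.json").write_text(json.dumps(meta, indent=2))
    return volumes, truth.subject_table


def _config_as_json(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["effect_d"] = {str(k): v for k, v in config.effect_d.items()}
    d["grid_shape"] = list(config.grid_shape)
    return d


def simulate(config: SimulationConfig, out_dir: str | Path | None = None):
    """One-call convenience: cohort ground truth plus materialized volumes."""
    truth = generate_cohort(config)
    volumes, table = synthesize_volumes(truth, config, out_dir=out_dir)
    return truth, volumes, table
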