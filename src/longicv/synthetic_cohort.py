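"""Synthetic cohort generator: behavioural tables and paired GMD volumes.

The original study's MRI scans are not available, so method validation runs
on simulated grey-matter-density (GMD) volumes whose generative model
mirrors the structure the longitudinal analysis assumes:

    GMD(i, t, v) = baseline_i(v) + a(v) * tau_t
                   + b_V(v) * e_V(i, t) + b_P(v) * e_P(i, t) + eps(i, t, v)

with ``tau_t`` in {-1, +1}, the signed-change encoding ``e_V(i, T1) =
-d_viq(i)`` / ``e_V(i, T2) = +d_viq(i)`` (likewise PIQ), slope maps that are
non-zero only on planted effect regions, and Gaussian noise smoothed to a
target FWHM so that cluster-level inference faces realistic spatial
autocorrelation.  Subject baselines are smooth random fields drawn once and
repeated at both time points, so they cancel exactly in within-subject
differences — as subject indicator columns cancel them in the GLM.

Because the effect enters through the same +/-d encoding the analysis design
uses, a planted slope ``b`` produces a within-subject difference of
``2*a + 2*b*d`` at an effect voxel: slope units are GMD units per encoded
IQ point, and the regression of the difference image on ``d`` recovers
``2*b``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml
from scipy import ndimage

from .iq_data import IQRecord, IQTable, MEASURES

__all__ = [
    "GroundTruth",
    "CohortVolumes",
    "make_ground_truth",
    "simulate_iq",
    "simulate_volumes",
    "smoothed_noise_sd",
    "theoretical_r2",
    "calibrate_slope",
]

FWHM_TO_SIGMA = 1.0 / (8.0 * np.log(2.0)) ** 0.5

#: Behavioural marginals of the reference cohort (means/SDs at the two time
#: points and the test-retest correlations), used as simulation defaults.
REFERENCE_MARGINALS = {
    "viq": {"mean_t1": 113.0, "sd_t1": 15.1, "mean_t2": 116.0, "sd_t2": 18.0, "retest_r": 0.81},
    "piq": {"mean_t1": 108.0, "sd_t1": 12.3, "mean_t2": 107.0, "sd_t2": 9.6, "retest_r": 0.59},
}


def _smooth_sigma_vox(fwhm_mm: float, voxel_size: float) -> float:
    return fwhm_mm * FWHM_TO_SIGMA / voxel_size


def _sphere_mask(shape: tuple[int, int, int], center: tuple[int, int, int], radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure behind a simulated cohort.

    ``region_v``/``region_p`` are disjoint voxel masks where GMD change is
    coupled to the VIQ / PIQ change scores with slopes ``slope_v`` /
    ``slope_p`` (GMD units per encoded IQ point).  ``age_map`` is the shared
    longitudinal drift a(v) (GMD units per encoded time unit).  Noise is
    white Gaussian with SD ``noise_sd`` before smoothing to ``smooth_fwhm``
    mm; the effective post-smoothing voxel SD is much smaller (see
    :func:`smoothed_noise_sd`).
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 3.0  # mm, isotropic
    region_v: np.ndarray = None
    region_p: np.ndarray = None
    center_v: tuple[int, int, int] = (9, 16, 16)
    center_p: tuple[int, int, int] = (23, 16, 16)
    slope_v: float = 0.0
    slope_p: float = 0.0
    age_map: np.ndarray = None
    noise_sd: float = 1.0
    smooth_fwhm: float = 8.0  # mm
    baseline_mean: float = 0.5
    baseline_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("region_v", "region_p", "age_map"):
            arr = getattr(self, name)
            if arr is not None and tuple(arr.shape) != tuple(self.shape):
                raise ValueError(f"{name} shape {arr.shape} does not match grid {self.shape}")
        if self.region_v is not None and self.region_p is not None:
            if np.any(self.region_v & self.region_p):
                raise ValueError("region_v and region_p must be disjoint")
        for name in ("center_v", "center_p"):
            c = getattr(self, name)
            if any(not (0 <= ci < si) for ci, si in zip(c, self.shape)):
                raise ValueError(f"{name}={c} lies outside the grid {self.shape}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size * (np.asarray(self.shape) - 1) / 2.0
        return aff

    def region(self, measure: str) -> np.ndarray:
        return self.region_v if measure == "viq" else self.region_p

    def center(self, measure: str) -> tuple[int, int, int]:
        return self.center_v if measure == "viq" else self.center_p

    def slope(self, measure: str) -> float:
        return self.slope_v if measure == "viq" else self.slope_p

    def to_yaml(self, path: Union[str, Path]) -> None:
        doc = {
            "shape": list(self.shape),
            "voxel_size": float(self.voxel_size),
            "center_v": list(self.center_v),
            "center_p": list(self.center_p),
            "slope_v": float(self.slope_v),
            "slope_p": float(self.slope_p),
            "noise_sd": float(self.noise_sd),
            "smooth_fwhm": float(self.smooth_fwhm),
            "baseline_mean": float(self.baseline_mean),
            "baseline_sd": float(self.baseline_sd),
            "region_v_voxels": np.argwhere(self.region_v).tolist(),
            "region_p_voxels": np.argwhere(self.region_p).tolist(),
            "age_map_flat": np.asarray(self.age_map, dtype=float).ravel().tolist(),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "GroundTruth":
        doc = yaml.safe_load(Path(path).read_text())
        shape = tuple(doc["shape"])
        region_v = np.zeros(shape, dtype=bool)
        region_p = np.zeros(shape, dtype=bool)
        for idx in doc["region_v_voxels"]:
            region_v[tuple(idx)] = True
        for idx in doc["region_p_voxels"]:
            region_p[tuple(idx)] = True
        age_map = np.asarray(doc["age_map_flat"], dtype=float).reshape(shape)
        return cls(
            shape=shape,
            voxel_size=doc["voxel_size"],
            region_v=region_v,
            region_p=region_p,
            center_v=tuple(doc["center_v"]),
            center_p=tuple(doc["center_p"]),
            slope_v=doc["slope_v"],
            slope_p=doc["slope_p"],
            age_map=age_map,
            noise_sd=doc["noise_sd"],
            smooth_fwhm=doc["smooth_fwhm"],
            baseline_mean=doc["baseline_mean"],
            baseline_sd=doc["baseline_sd"],
        )


@dataclass(frozen=True)
class CohortVolumes:
    """Paired per-subject 3-D GMD arrays sharing one grid."""

    subject_ids: tuple[int, ...]
    vol_t1: np.ndarray  # (n_subjects, *shape)
    vol_t2: np.ndarray
    voxel_size: float
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.vol_t1.shape != self.vol_t2.shape:
            raise ValueError("vol_t1 and vol_t2 shapes differ")
        if self.vol_t1.shape[0] != len(self.subject_ids):
            raise ValueError("number of volumes does not match subject_ids")
        if not (np.all(np.isfinite(self.vol_t1)) and np.all(np.isfinite(self.vol_t2))):
            raise ValueError("volumes contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.vol_t1.shape[1:])

    def differences(self) -> np.ndarray:
        """Within-subject difference images, t2 - t1, shape (n, *grid)."""
        return self.vol_t2 - self.vol_t1

    def subset(self, subject_ids) -> "CohortVolumes":
        index = {sid: i for i, sid in enumerate(self.subject_ids)}
        rows = [index[s] for s in subject_ids]
        return CohortVolumes(
            subject_ids=tuple(subject_ids),
            vol_t1=self.vol_t1[rows],
            vol_t2=self.vol_t2[rows],
            voxel_size=self.voxel_size,
            affine=self.affine,
        )


def make_ground_truth(
    shape: tuple[int, int, int] = (32, 32, 32),
    voxel_size: float = 3.0,
    region_radius_vox: Optional[float] = None,
    center_v: Optional[tuple[int, int, int]] = None,
    center_p: Optional[tuple[int, int, int]] = None,
    slope_v: float = 0.0,
    slope_p: float = 0.0,
    noise_sd: float = 1.0,
    smooth_fwhm: float = 8.0,
    baseline_mean: float = 0.5,
    baseline_sd: float = 0.05,
    age_amplitude: float = 0.005,
    seed: int = 0,
) -> GroundTruth:
    """Construct a ground truth with spherical effect regions.

    The two regions sit on the x axis at opposite sides of the grid (well
    separated so the difference-contrast conjunction can distinguish them);
    the age drift map is a smooth random field of amplitude
    ``age_amplitude`` so the shared time effect is spatially varying, as a
    real maturational drift would be.
    """
    shape = tuple(shape)
    if region_radius_vox is None:
        # ~8% of the grid side: 2.5 voxels on the default 32-voxel grid,
        # shrinking with the grid so the two regions stay well separated
        region_radius_vox = max(1.0, 0.08 * shape[0])
    if center_v is None:
        center_v = (round(shape[0] * 0.28), shape[1] // 2, shape[2] // 2)
    if center_p is None:
        center_p = (round(shape[0] * 0.72), shape[1] // 2, shape[2] // 2)
    region_v = _sphere_mask(shape, center_v, region_radius_vox)
    region_p = _sphere_mask(shape, center_p, region_radius_vox)
    rng = np.random.default_rng(seed)
    sigma = _smooth_sigma_vox(2 * smooth_fwhm, voxel_size)
    age = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = age.std()
    if sd > 0:
        age *= age_amplitude / sd
    return GroundTruth(
        shape=shape,
        voxel_size=voxel_size,
        region_v=region_v,
        region_p=region_p,
        center_v=center_v,
        center_p=center_p,
        slope_v=slope_v,
        slope_p=slope_p,
        age_map=age,
        noise_sd=noise_sd,
        smooth_fwhm=smooth_fwhm,
        baseline_mean=baseline_mean,
        baseline_sd=baseline_sd,
    )


def simulate_iq(
    n: int,
    seed: int,
    marginals: Optional[dict] = None,
) -> IQTable:
    """Draw a behavioural table with the reference cohort's marginals.

    Per measure, (t1, t2) are bivariate normal with the stated means, SDs
    and test-retest correlation, then rounded to integer IQ points (the
    granularity of the published scales).  VIQ and PIQ are drawn
    independently of each other.
    """
    if n < 3:
        raise ValueError("need n >= 3 subjects")
    marginals = marginals or REFERENCE_MARGINALS
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for m in MEASURES:
        p = marginals[m]
        r = p["retest_r"]
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"invalid retest correlation {r}")
        cov = np.array(
            [
                [p["sd_t1"] ** 2, r * p["sd_t1"] * p["sd_t2"]],
                [r * p["sd_t1"] * p["sd_t2"], p["sd_t2"] ** 2],
            ]
        )
        mean = np.array([p["mean_t1"], p["mean_t2"]])
        draws = rng.multivariate_normal(mean, cov, size=n)  # svd handles |r| = 1
        scores = np.rint(draws)
        scores = np.clip(scores, 1, None)  # IQ scores are positive
        cols[f"{m}_t1"], cols[f"{m}_t2"] = scores[:, 0], scores[:, 1]
    records = tuple(
        IQRecord(
            subject_id=i + 1,
            viq_t1=cols["viq_t1"][i],
            piq_t1=cols["piq_t1"][i],
            viq_t2=cols["viq_t2"][i],
            piq_t2=cols["piq_t2"][i],
        )
        for i in range(n)
    )
    return IQTable(records)


def simulate_volumes(table: IQTable, truth: GroundTruth, seed: int) -> CohortVolumes:
    """Generate paired GMD volumes for every subject in ``table``.

    Deterministic for fixed (table, truth, seed).  Noise is sampled white
    and then smoothed; the subject baseline field is drawn once and reused
    at both time points.
    """
    n = len(table)
    shape = truth.shape
    rng = np.random.default_rng(seed)
    sigma = _smooth_sigma_vox(truth.smooth_fwhm, truth.voxel_size)

    b_v = np.where(truth.region_v, truth.slope_v, 0.0)
    b_p = np.where(truth.region_p, truth.slope_p, 0.0)
    d_v = table.changes("viq")
    d_p = table.changes("piq")

    vol_t1 = np.empty((n,) + shape)
    vol_t2 = np.empty((n,) + shape)
    baseline_sigma = _smooth_sigma_vox(2 * truth.smooth_fwhm, truth.voxel_size)
    for i in range(n):
        base = ndimage.gaussian_filter(rng.standard_normal(shape), baseline_sigma, mode="wrap")
        sd = base.std()
        if sd > 0:
            base = truth.baseline_mean + truth.baseline_sd * base / sd
        else:
            base = np.full(shape, truth.baseline_mean)
        for t, (tau, store) in enumerate([(-1.0, vol_t1), (+1.0, vol_t2)]):
            e_v = d_v[i] * tau  # -d at T1, +d at T2
            e_p = d_p[i] * tau
            eps = rng.standard_normal(shape) * truth.noise_sd
            if sigma > 0:
                eps = ndimage.gaussian_filter(eps, sigma, mode="wrap")
            store[i] = base + truth.age_map * tau + b_v * e_v + b_p * e_p + eps
    return CohortVolumes(
        subject_ids=tuple(table.subject_ids),
        vol_t1=vol_t1,
        vol_t2=vol_t2,
        voxel_size=truth.voxel_size,
        affine=truth.affine,
    )


def smoothed_noise_sd(truth: GroundTruth, seed: int = 12345, n_fields: int = 50) -> float:
    """Empirical per-voxel SD of the smoothed noise field.

    Smoothing a white field of SD ``noise_sd`` shrinks the voxel-wise SD by
    a kernel-dependent factor; this estimates the post-smoothing SD by
    direct simulation of noise-only fields (periodic boundary, matching the
    generator).
    """
    if truth.noise_sd == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    sigma = _smooth_sigma_vox(truth.smooth_fwhm, truth.voxel_size)
    total = 0.0
    for _ in range(n_fields):
        eps = rng.standard_normal(truth.shape) * truth.noise_sd
        if sigma > 0:
            eps = ndimage.gaussian_filter(eps, sigma, mode="wrap")
        total += float(np.mean(eps**2))
    return (total / n_fields) ** 0.5


def theoretical_r2(truth: GroundTruth, table: IQTable, measure: str) -> float:
    """Planted proportion of difference-image variance explained at the peak.

    The within-subject difference at the planted peak is
    ``2*a + 2*b*d + (eps_t2 - eps_t1)``, so the population R-squared of the
    regression of the difference on the change score d is

        Var(2*b*d) / (Var(2*b*d) + 2*sd_eff**2)

    with ``sd_eff`` the post-smoothing voxel noise SD.
    """
    b = truth.slope(measure)
    d = table.changes(measure)
    signal = float(np.var(2.0 * b * d))
    sd_eff = smoothed_noise_sd(truth)
    total = signal + 2.0 * sd_eff**2
    if total == 0:
        raise ValueError("zero total variance: no signal and no noise")
    return signal / total


def calibrate_slope(
    truth: GroundTruth, table: IQTable, measure: str, target_r2: float
) -> float:
    """Slope giving a planted peak R-squared of ``target_r2`` for ``table``."""
    if not 0 <= target_r2 < 1:
        raise ValueError("target_r2 must be in [0, 1)")
    d = table.changes(measure)
    var_d = float(np.var(d))
    if var_d == 0:
        raise ValueError("change scores have zero variance")
    sd_eff = smoothed_noise_sd(truth)
    return float(np.sqrt(target_r2 / (1 - target_r2) * 2.0 * sd_eff**2 / (4.0 * var_d)))


def search_mask_around_truth(truth: GroundTruth, margin_vox: int = 6) -> np.ndarray:
    """Synthetic analogue of an anatomically defined search space.

    A box of half-width ``margin_vox`` around each planted region centre,
    standing in for the atlas-based mask a real analysis would use when the
    training sample is too small for whole-brain correction.  With the
    default grid and margin the mask covers roughly a tenth of the volume.
    """
    mask = np.zeros(truth.shape, dtype=bool)
    for center in (truth.center_v, truth.center_p):
        sl = tuple(
            slice(max(0, c - margin_vox), min(s, c + margin_vox + 1))
            for c, s in zip(center, truth.shape)
        )
        mask[sl] = True
    return mask


def with_calibrated_slopes(
    truth: GroundTruth, table: IQTable, target_r2: float
) -> GroundTruth:
    """Copy of ``truth`` with both slopes set to hit ``target_r2`` at the peaks."""
    return replace(
        truth,
        slope_v=calibrate_slope(truth, table, "viq", target_r2),
        slope_p=calibrate_slope(truth, table, "piq", target_r2),
    )
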