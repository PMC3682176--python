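"""Mass-univariate longitudinal GLM, permutation FWE control and region selection.

Region selection ("Step 1") fits, at every voxel, an ANCOVA-style general
linear model to the 2N scans of an N-subject training set:

    GMD(i, t, v) = subject_i(v) + a(v) * tau_t + b_V(v) * e_V(i, t)
                   + b_P(v) * e_P(i, t) + error

Subject indicator columns absorb each subject's average density; ``tau``
(-1 at time 1, +1 at time 2) carries the shared age/time drift; and the
signed-change covariates ``e_V``/``e_P`` (minus the IQ change at time 1,
plus the change at time 2) carry the coupling between density change and
VIQ / PIQ change.  One-sided t contrasts over (tau, e_V, e_P) — (0,1,0),
(0,0,1) and the difference contrasts (0,1,-1) / (0,-1,1) — are converted to
Z scores with df = N - 3.

Because every regressor of interest is antisymmetric within subject, this
full model is algebraically equivalent to regressing the within-subject
difference images on [1, d_viq, d_piq]; the package exploits that reduction
for the permutation loop and asserts the equivalence in its test suite.

Family-wise error control uses sign-flipping permutation: each permutation
randomly negates each subject's encoded change covariates, and the maximum
t and maximum supra-threshold cluster size over the volume are recorded to
build the null distributions for height and extent corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .iq_data import IQTable, MEASURES
from .synthetic_cohort import CohortVolumes

__all__ = [
    "DesignMatrix",
    "Contrast",
    "StatMap",
    "Cluster",
    "SelectedCluster",
    "MeasureThresholds",
    "RegionSelection",
    "CONTRASTS",
    "Z_CAP",
    "build_design",
    "fit_contrast",
    "fwe_thresholds",
    "fwe_thresholds_both",
    "extract_clusters",
    "select_regions",
]

#: Cap applied to Z scores at degenerate (zero-residual) voxels.
Z_CAP = 38.0

#: The four standard contrasts over (tau, e_V, e_P).
CONTRASTS = {
    "viq": (0.0, 1.0, 0.0),
    "piq": (0.0, 0.0, 1.0),
    "v_minus_p": (0.0, 1.0, -1.0),
    "p_minus_v": (0.0, -1.0, 1.0),
}


@dataclass(frozen=True)
class Contrast:
    """One-sided t contrast with weights over (tau, e_V, e_P)."""

    weights: tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        if not any(w != 0 for w in self.weights):
            raise ValueError("contrast weights are all zero")


@dataclass(frozen=True)
class DesignMatrix:
    """2N x (N + 3) longitudinal design: subject indicators, tau, e_V, e_P.

    Rows are ordered subject-major (subject 1 time 1, subject 1 time 2,
    subject 2 time 1, ...).  ``degenerate`` lists covariates that are
    identically zero (e.g. a cohort with no IQ change), which make the
    corresponding contrast unestimable.
    """

    subject_ids: tuple[int, ...]
    matrix: np.ndarray
    column_labels: tuple[str, ...]
    d_viq: np.ndarray
    d_piq: np.ndarray
    degenerate: tuple[str, ...] = ()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def df(self) -> int:
        return self.n_subjects - 3

    def covariate_weights(self, contrast: Contrast) -> np.ndarray:
        """Full-length contrast vector (zeros over the subject indicators)."""
        c = np.zeros(self.matrix.shape[1])
        c[-3:] = contrast.weights
        return c


@dataclass(frozen=True)
class StatMap:
    """Voxel-wise t and Z statistic volumes for one contrast."""

    t_values: np.ndarray
    z_values: np.ndarray
    df: int
    contrast: Contrast
    voxel_size: float
    affine: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.t_values.shape)


@dataclass(frozen=True)
class Cluster:
    """Connected supra-threshold component of a statistic map."""

    voxels: tuple[tuple[int, int, int], ...]
    peak: tuple[int, int, int]
    peak_t: float
    peak_z: float

    @property
    def size(self) -> int:
        return len(self.voxels)

    def contains(self, voxel: Sequence[int]) -> bool:
        return tuple(voxel) in set(self.voxels)


@dataclass(frozen=True)
class SelectedCluster:
    """A retained cluster plus the basis on which it was selected."""

    cluster: Cluster
    basis: str  # 'height-FWE' | 'extent-FWE' | 'search-space-max'
    conjunction_z: float
    conjunction_pass: bool


@dataclass(frozen=True)
class MeasureThresholds:
    """Thresholds governing selection for one IQ measure."""

    forming_t: float  # cluster-forming t threshold
    height_t_crit: float  # FWE-corrected peak-height threshold
    extent_k_crit: float  # FWE-corrected cluster-extent threshold (voxels)


@dataclass(frozen=True)
class RegionSelection:
    """Per-measure retained clusters for one training set."""

    clusters: dict  # measure -> list[SelectedCluster], best first
    type2_flag: dict  # measure -> bool (nothing survived FWE correction)
    shape: tuple[int, int, int]
    thresholds: dict = field(default_factory=dict)  # measure -> MeasureThresholds
    connectivity: int = 26

    def top(self, measure: str) -> Optional[SelectedCluster]:
        sel = self.clusters.get(measure) or []
        return sel[0] if sel else None

    def n_selected(self) -> int:
        return sum(len(v) for v in self.clusters.values())


def build_design(table: IQTable) -> DesignMatrix:
    """Longitudinal design matrix for the training table.

    Raises for n <= 3 subjects: with N subject indicators plus three
    covariates the model has no residual degrees of freedom below n = 4.
    """
    n = len(table)
    if n <= 3:
        raise ValueError(f"design is unidentifiable with n={n} (need n >= 4)")
    d_v = table.changes("viq")
    d_p = table.changes("piq")
    x = np.zeros((2 * n, n + 3))
    for i in range(n):
        rows = (2 * i, 2 * i + 1)
        x[rows, i] = 1.0  # subject indicator
        x[rows[0], n] = -1.0  # tau at time 1
        x[rows[1], n] = +1.0
        x[rows[0], n + 1] = -d_v[i]  # e_V
        x[rows[1], n + 1] = +d_v[i]
        x[rows[0], n + 2] = -d_p[i]  # e_P
        x[rows[1], n + 2] = +d_p[i]
    labels = tuple(f"subject_{sid}" for sid in table.subject_ids) + ("tau", "e_viq", "e_piq")
    degenerate = tuple(
        lab for lab, col in zip(labels[-2:], (d_v, d_p)) if not np.any(col)
    )
    return DesignMatrix(
        subject_ids=tuple(table.subject_ids),
        matrix=x,
        column_labels=labels,
        d_viq=d_v,
        d_piq=d_p,
        degenerate=degenerate,
    )


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map one-sided t p-values through the standard-normal inverse."""
    with np.errstate(invalid="ignore"):
        z = np.where(
            t >= 0,
            -stats.norm.ppf(stats.t.sf(t, df)),
            stats.norm.ppf(stats.t.sf(-t, df)),
        )
    return np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CAP, neginf=-Z_CAP), -Z_CAP, Z_CAP)


def _check_contrast_estimable(design: DesignMatrix, contrast: Contrast) -> None:
    for lab, w in zip(("tau", "e_viq", "e_piq"), contrast.weights):
        if w != 0 and lab in design.degenerate:
            raise ValueError(
                f"contrast {contrast.weights} weights degenerate column {lab!r} "
                "(covariate identically zero; design is rank deficient)"
            )


def fit_contrast(
    volumes: CohortVolumes, design: DesignMatrix, contrast: Contrast
) -> StatMap:
    """Voxel-wise OLS t map for ``contrast`` on the full 2N-scan design.

    Zero-residual voxels (perfect fit, e.g. noiseless simulations) get an
    infinite t sentinel and a Z capped at :data:`Z_CAP`.
    """
    if tuple(volumes.subject_ids) != tuple(design.subject_ids):
        raise ValueError("volumes and design refer to different subjects or orders")
    _check_contrast_estimable(design, contrast)

    x = design.matrix
    n2, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {p} columns); "
            f"degenerate columns: {design.degenerate or 'unknown'}"
        )
    df = n2 - p  # = N - 3
    shape = volumes.shape
    nvox = int(np.prod(shape))

    # scans stacked subject-major, time within subject, matching the design rows
    y = np.empty((n2, nvox))
    y[0::2] = volumes.vol_t1.reshape(volumes.n_subjects, nvox)
    y[1::2] = volumes.vol_t2.reshape(volumes.n_subjects, nvox)

    gram_inv = np.linalg.inv(x.T @ x)
    beta = gram_inv @ (x.T @ y)
    resid = y - x @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df

    c = design.covariate_weights(contrast)
    effect = c @ beta
    var_c = float(c @ gram_inv @ c)
    se = np.sqrt(sigma2 * var_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    # perfect-fit voxels: residual at floating-point rounding level (exactly
    # zero in noiseless simulations up to arithmetic error) -> infinite t
    degenerate = se <= 1e-8 * np.abs(effect)
    t = np.where(
        degenerate,
        np.where(effect > 0, np.inf, np.where(effect < 0, -np.inf, 0.0)),
        t,
    )
    t = np.where((se == 0) & (effect == 0), 0.0, t)
    t3 = t.reshape(shape)
    return StatMap(
        t_values=t3,
        z_values=_t_to_z(t3, df),
        df=df,
        contrast=contrast,
        voxel_size=volumes.voxel_size,
        affine=volumes.affine,
    )


def _difference_t_maps(
    diffs: np.ndarray, d_viq: np.ndarray, d_piq: np.ndarray, contrasts: Sequence[Contrast]
) -> list[np.ndarray]:
    """t maps via the equivalent difference-image regression [1, d_viq, d_piq].

    Used inside the permutation loop where refitting the full 2N design per
    permutation would be wasteful; identical t values (equivalence is
    asserted in the tests).
    """
    n = diffs.shape[0]
    shape = diffs.shape[1:]
    d = diffs.reshape(n, -1)
    m = np.column_stack([np.ones(n), d_viq, d_piq])
    gram_inv = np.linalg.inv(m.T @ m)
    beta = gram_inv @ (m.T @ d)
    resid = d - m @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / (n - 3)
    out = []
    for con in contrasts:
        c = np.asarray(con.weights)
        effect = c @ beta
        var_c = float(c @ gram_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = effect / np.sqrt(sigma2 * var_c)
        t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
        out.append(t.reshape(shape))
    return out


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if order is None:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, order)


def _max_cluster_size(mask: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))))


def fwe_thresholds_both(
    volumes: CohortVolumes,
    design: DesignMatrix,
    n_perm: int,
    seed: int,
    cluster_forming_p: dict,
    alpha: float = 0.05,
    connectivity: int = 26,
) -> dict:
    """Permutation FWE thresholds for the VIQ and PIQ contrasts in one pass.

    Sign-flipping scheme: each permutation independently negates each
    subject's encoded change covariates (equivalently, the sign of that
    subject's covariate-difference relation after the shared time effect is
    absorbed by the intercept), then records the volume-wise maximum t and
    the maximum supra-threshold cluster size at each measure's
    cluster-forming threshold.  Returns per-measure
    :class:`MeasureThresholds` with the 100*(1-alpha) percentiles.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm={n_perm} too small for a stable {1 - alpha:.0%} percentile (need >= 100)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    structure = _connectivity_structure(connectivity)
    df = design.df
    forming_t = {m: float(stats.t.isf(cluster_forming_p[m], df)) for m in MEASURES}
    contrasts = [Contrast(CONTRASTS[m], m) for m in MEASURES]

    diffs = volumes.differences()
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    max_t = {m: np.empty(n_perm) for m in MEASURES}
    max_k = {m: np.empty(n_perm, dtype=int) for m in MEASURES}
    for j in range(n_perm):
        signs = rng.integers(0, 2, size=n) * 2.0 - 1.0
        tmaps = _difference_t_maps(diffs, signs * design.d_viq, signs * design.d_piq, contrasts)
        for m, tmap in zip(MEASURES, tmaps):
            max_t[m][j] = np.max(tmap)
            max_k[m][j] = _max_cluster_size(tmap >= forming_t[m], structure)

    out = {}
    for m in MEASURES:
        out[m] = MeasureThresholds(
            forming_t=forming_t[m],
            height_t_crit=float(np.quantile(max_t[m], 1 - alpha, method="higher")),
            extent_k_crit=float(np.quantile(max_k[m], 1 - alpha, method="higher")),
        )
    return out


def fwe_thresholds(
    volumes: CohortVolumes,
    design: DesignMatrix,
    contrast: Contrast,
    n_perm: int,
    seed: int,
    cluster_forming_p: float,
    alpha: float = 0.05,
    connectivity: int = 26,
) -> tuple[float, float]:
    """(height_t_crit, extent_k_crit) for a single measure contrast."""
    measure = "viq" if tuple(contrast.weights) == CONTRASTS["viq"] else "piq"
    both = fwe_thresholds_both(
        volumes,
        design,
        n_perm=n_perm,
        seed=seed,
        cluster_forming_p={m: cluster_forming_p for m in MEASURES},
        alpha=alpha,
        connectivity=connectivity,
    )
    th = both[measure]
    return th.height_t_crit, th.extent_k_crit


def extract_clusters(
    stat_map: StatMap, t_threshold: float, connectivity: int = 26
) -> list[Cluster]:
    """Connected components of {v : t(v) >= t_threshold}, best peak first.

    The peak is the voxel with maximum t; ties break to the smallest linear
    index with x varying fastest (Fortran ravel order), making extraction
    independent of traversal order.
    """
    if not np.isfinite(t_threshold):
        raise ValueError("cluster-forming threshold must be finite")
    structure = _connectivity_structure(connectivity)
    mask = stat_map.t_values >= t_threshold
    labels, n = ndimage.label(mask, structure=structure)
    clusters: list[Cluster] = []
    shape = stat_map.shape
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        t_vals = stat_map.t_values[tuple(coords.T)]
        best = np.max(t_vals)
        tied = coords[t_vals == best]
        lin = np.ravel_multi_index(tuple(tied.T), shape, order="F")
        peak = tuple(int(v) for v in tied[np.argmin(lin)])
        clusters.append(
            Cluster(
                voxels=tuple(map(tuple, coords.tolist())),
                peak=peak,
                peak_t=float(best),
                peak_z=float(stat_map.z_values[peak]),
            )
        )
    clusters.sort(key=lambda c: (-c.peak_t, np.ravel_multi_index(c.peak, shape, order="F")))
    return clusters


def _masked_fallback_cluster(
    stat_map: StatMap, forming_t: float, search_mask: np.ndarray, connectivity: int
) -> Cluster:
    """Most significant contiguous supra-threshold cluster inside the mask.

    If no voxel in the mask reaches the forming threshold, degrades to the
    single best voxel in the mask so that a selection is always produced.
    """
    masked_t = np.where(search_mask, stat_map.t_values, -np.inf)
    masked = StatMap(
        t_values=masked_t,
        z_values=np.where(search_mask, stat_map.z_values, -np.inf),
        df=stat_map.df,
        contrast=stat_map.contrast,
        voxel_size=stat_map.voxel_size,
        affine=stat_map.affine,
    )
    clusters = extract_clusters(masked, forming_t, connectivity)
    if clusters:
        return clusters[0]
    flat = np.argmax(masked_t)
    peak = tuple(int(v) for v in np.unravel_index(flat, stat_map.shape))
    return Cluster(
        voxels=(peak,),
        peak=peak,
        peak_t=float(stat_map.t_values[peak]),
        peak_z=float(stat_map.z_values[peak]),
    )


def select_regions(
    maps: dict,
    thresholds: dict,
    conjunction_p: float = 0.01,
    search_mask: Optional[np.ndarray] = None,
    connectivity: int = 26,
) -> RegionSelection:
    """Retain clusters that survive FWE correction and the difference conjunction.

    ``maps`` holds the four stat maps keyed 'viq', 'piq', 'v_minus_p',
    'p_minus_v'.  A VIQ cluster is retained when its peak survives the
    height FWE threshold or its extent survives the extent FWE threshold,
    AND the V-P difference map at the peak voxel is significant one-sided at
    ``conjunction_p`` uncorrected (symmetrically for PIQ with P-V).  When
    nothing survives for a measure and a search mask is supplied, the most
    significant contiguous supra-threshold cluster inside the mask is
    selected instead (basis ``search-space-max``, conjunction not required)
    and the measure's type-II flag is set.
    """
    if search_mask is not None and not np.any(search_mask):
        raise ValueError("search mask is empty")
    z_conj = float(stats.norm.isf(conjunction_p))
    diff_key = {"viq": "v_minus_p", "piq": "p_minus_v"}
    selected: dict[str, list[SelectedCluster]] = {}
    type2: dict[str, bool] = {}
    shape = maps["viq"].shape
    for m in MEASURES:
        th: MeasureThresholds = thresholds[m]
        stat_map = maps[m]
        diff_map = maps[diff_key[m]]
        retained: list[SelectedCluster] = []
        for cluster in extract_clusters(stat_map, th.forming_t, connectivity):
            if cluster.peak_t >= th.height_t_crit:
                basis = "height-FWE"
            elif cluster.size >= th.extent_k_crit:
                basis = "extent-FWE"
            else:
                continue
            cz = float(diff_map.z_values[cluster.peak])
            if cz >= z_conj:
                retained.append(
                    SelectedCluster(cluster=cluster, basis=basis, conjunction_z=cz, conjunction_pass=True)
                )
        type2[m] = not retained
        if not retained and search_mask is not None:
            fb = _masked_fallback_cluster(stat_map, th.forming_t, search_mask, connectivity)
            cz = float(diff_map.z_values[fb.peak])
            retained = [
                SelectedCluster(
                    cluster=fb,
                    basis="search-space-max",
                    conjunction_z=cz,
                    conjunction_pass=bool(cz >= z_conj),
                )
            ]
        selected[m] = retained
    return RegionSelection(
        clusters=selected,
        type2_flag=type2,
        shape=shape,
        thresholds=dict(thresholds),
        connectivity=connectivity,
    )
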