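"""Cross-validation engine: exhaustive Leave-One-Out and stratified split-half.

Both schemes share the same region-selection stage ("Step 1",
:mod:`longicv.vbm_glm`) and differ in how the cohort is partitioned and how
the prediction stage ("Step 2") is scored:

* **Leave-One-Out** — Step 1 runs once per subject on the other n-1
  subjects; the held-out subject's grey-matter-density change at the
  training peak is fed through the training regression to yield a genuinely
  out-of-sample prediction.  After all folds, the proportion of variance in
  the *measured* changes accounted for by the *predicted* changes is the
  out-of-sample R².

* **Stratified split-half** — subjects are median-split into high/low IQ
  strata by a full-scale proxy and randomly halved within strata; Step 1
  runs on each half and Step 2 fits the regression *within* the other half
  (region selection is independent of the test subjects, the regression
  parameters are not — deliberately mirroring the original procedure's
  asymmetry).  Repeated splits map out the variability that the single
  exhaustive Leave-One-Out enumeration does not have.

All randomness descends from one master seed through named substreams
(splits, permutations, simulation), so a run is exactly reproducible from
its manifest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cli_io import RunConfig
from .iq_data import IQTable, MEASURES
from .synthetic_cohort import CohortVolumes
from .vbm_glm import (
    CONTRASTS,
    Contrast,
    RegionSelection,
    SelectedCluster,
    build_design,
    fit_contrast,
    fwe_thresholds_both,
    select_regions,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SplitAssignment",
    "FoldResult",
    "MeasureCV",
    "CVResult",
    "stratified_split",
    "predict_held_out",
    "hierarchical_r2",
    "loo_run",
    "split_half_run",
]

# substream tags keeping the per-purpose RNGs independent of one another
_STREAM_PERM = 11
_STREAM_SPLIT = 23


@dataclass(frozen=True)
class SplitAssignment:
    """One stratified half-split of the cohort."""

    repeat_index: int
    group_a: tuple[int, ...]
    group_b: tuple[int, ...]
    strata: dict  # subject_id -> 'high' | 'low'


@dataclass
class FoldResult:
    """One training/validation analysis (a LOO fold or one split orientation)."""

    fold_index: int
    held_out: tuple[int, ...]
    training: tuple[int, ...]
    selected: dict = field(default_factory=dict)  # measure -> SelectedCluster | None
    type2: dict = field(default_factory=dict)  # measure -> bool (no FWE survivor)
    # LOO out-of-sample quantities, per measure (absent for skipped measures)
    predicted_change: dict = field(default_factory=dict)
    measured_change: dict = field(default_factory=dict)
    predicted_t2: dict = field(default_factory=dict)
    measured_t2: dict = field(default_factory=dict)
    held_out_density: dict = field(default_factory=dict)
    # split-half within-test-sample quantities, per measure
    r2_change: dict = field(default_factory=dict)
    r2_t1_only: dict = field(default_factory=dict)
    r2_t2_full: dict = field(default_factory=dict)
    r2_increment: dict = field(default_factory=dict)
    flagged: dict = field(default_factory=dict)  # measure -> reason string


@dataclass
class MeasureCV:
    """Aggregated Step-2 results for one IQ measure."""

    r2_change: float
    r2_t2: float
    r2_t2_after_t1: Optional[float] = None
    r2_change_values: Optional[np.ndarray] = None  # split-half distributions
    r2_t2_values: Optional[np.ndarray] = None
    r2_increment_values: Optional[np.ndarray] = None
    n_used: int = 0


@dataclass
class CVResult:
    """Full result of one cross-validation run."""

    scheme: str  # 'loo' | 'split-half'
    folds: list
    measures: dict  # measure -> MeasureCV
    type2_rate: dict  # measure -> proportion of training analyses w/o FWE survivor
    n_subjects: int
    config: RunConfig
    selection_freq: dict = field(default_factory=dict)  # measure -> count volume
    n_warnings: int = 0

    @property
    def n_selected_clusters(self) -> int:
        """Selected clusters summed over analyses and measures (one per
        analysis-measure with a non-empty selection)."""
        return sum(
            1 for f in self.folds for m in MEASURES if f.selected.get(m) is not None
        )


def _fsiq_proxy(table: IQTable) -> dict:
    """Full-scale IQ proxy: mean of the four printed scores per subject."""
    return {
        r.subject_id: (r.viq_t1 + r.piq_t1 + r.viq_t2 + r.piq_t2) / 4.0
        for r in table
    }


def stratified_split(table: IQTable, repeat_index: int, seed: int) -> SplitAssignment:
    """Half-split stratified on a full-scale-IQ median split.

    Subjects are ranked by the full-scale proxy; the top half is the 'high'
    stratum (the larger stratum when n is odd).  Within each stratum half
    the subjects go to group A at random; an odd stratum's extra subject is
    assigned by coin flip.  Deterministic for fixed (seed, repeat_index).
    """
    n = len(table)
    if n < 4:
        raise ValueError("stratified split needs n >= 4")
    proxy = _fsiq_proxy(table)
    ranked = sorted(table.subject_ids, key=lambda s: (-proxy[s], s))
    n_high = math.ceil(n / 2)
    strata = {s: ("high" if i < n_high else "low") for i, s in enumerate(ranked)}
    rng = np.random.default_rng([seed, _STREAM_SPLIT, repeat_index])
    group_a: list[int] = []
    group_b: list[int] = []
    for label in ("high", "low"):
        members = [s for s in ranked if strata[s] == label]
        perm = list(rng.permutation(members))
        k = len(members) // 2
        if len(members) % 2 == 1 and rng.integers(0, 2) == 1:
            k += 1  # coin flip for the odd subject
        group_a.extend(int(s) for s in perm[:k])
        group_b.extend(int(s) for s in perm[k:])
    order = {s: i for i, s in enumerate(table.subject_ids)}
    group_a.sort(key=order.get)
    group_b.sort(key=order.get)
    return SplitAssignment(
        repeat_index=repeat_index,
        group_a=tuple(group_a),
        group_b=tuple(group_b),
        strata=strata,
    )


def predict_held_out(
    training_pairs: Sequence[tuple[float, float]], held_out_density: float
) -> float:
    """Predict IQ change from density change via the training OLS line."""
    if len(training_pairs) < 3:
        raise ValueError("need at least 3 training pairs")
    x = np.array([p[0] for p in training_pairs], dtype=float)
    y = np.array([p[1] for p in training_pairs], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in training density changes")
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept + slope * held_out_density)


def _ols_r2(design: np.ndarray, y: np.ndarray) -> float:
    """R-squared of an OLS fit with intercept already in ``design``."""
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return float("nan")
    return 1.0 - float(resid @ resid) / tss


def hierarchical_r2(
    t1: np.ndarray, t2: np.ndarray, densities: np.ndarray
) -> tuple[float, float, float]:
    """Nested regressions of Time-2 IQ: first on Time-1 IQ, then adding
    density change.  Returns (r2_t1_only, r2_full, increment).
    """
    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    dd = np.asarray(densities, float)
    if len(t1) < 4:
        raise ValueError("hierarchical regression needs >= 4 records")
    ones = np.ones_like(t1)
    x1 = np.column_stack([ones, t1])
    x2 = np.column_stack([ones, t1, dd])
    r2_t1 = _ols_r2(x1, t2)
    if np.linalg.matrix_rank(x2) < 3:
        logger.warning("density change collinear with Time-1 IQ; increment reported as 0")
        return r2_t1, r2_t1, 0.0
    r2_full = _ols_r2(x2, t2)
    return r2_t1, r2_full, r2_full - r2_t1


def _predicted_vs_measured_r2(predicted: np.ndarray, measured: np.ndarray) -> float:
    """R² of the regression of measured on predicted values.

    For a simple regression this equals the squared Pearson correlation —
    the identity is asserted on every aggregation.
    """
    if np.ptp(predicted) == 0 or np.ptp(measured) == 0:
        return float("nan")
    r2 = _ols_r2(np.column_stack([np.ones_like(predicted), predicted]), measured)
    r = np.corrcoef(predicted, measured)[0, 1]
    assert abs(r2 - r * r) < 1e-8, "regression R2 and squared correlation disagree"
    return r2


def _step1(
    train_table: IQTable,
    train_volumes: CohortVolumes,
    config: RunConfig,
    perm_seed: int,
    search_mask: Optional[np.ndarray],
) -> RegionSelection:
    """Region selection on a training set: GLM, FWE thresholds, selection."""
    design = build_design(train_table)
    maps = {
        name: fit_contrast(train_volumes, design, Contrast(w, name))
        for name, w in CONTRASTS.items()
    }
    thresholds = fwe_thresholds_both(
        train_volumes,
        design,
        n_perm=config.n_perm,
        seed=perm_seed,
        cluster_forming_p=config.cluster_forming_p,
        alpha=config.fwe_alpha,
        connectivity=config.connectivity,
    )
    return select_regions(
        maps,
        thresholds,
        conjunction_p=config.conjunction_p,
        search_mask=search_mask,
        connectivity=config.connectivity,
    )


def _extract_density(
    volumes: CohortVolumes, selected: SelectedCluster, mode: str
) -> np.ndarray:
    """Per-subject density change at the selected region (peak or cluster mean)."""
    diffs = volumes.differences()
    if mode == "peak":
        return diffs[(slice(None), *selected.cluster.peak)]
    idx = tuple(np.array(selected.cluster.voxels).T)
    return diffs[:, idx[0], idx[1], idx[2]].mean(axis=1)


def loo_run(
    table: IQTable,
    volumes: CohortVolumes,
    config: RunConfig,
    search_mask: Optional[np.ndarray] = None,
) -> CVResult:
    """Exhaustive Leave-One-Out cross-validation.

    For every subject, Step 1 runs on the remaining n-1 subjects; the
    highest-peak selected cluster per measure supplies the voxel at which
    the held-out subject's density change is read out, and the training-set
    regressions (change ~ density; t2 ~ t1 + density) supply the
    out-of-sample predictions.  Aggregated R² values regress measured on
    predicted across the n held-out subjects.
    """
    n = len(table)
    if n < 5:
        raise ValueError("Leave-One-Out needs n >= 5")
    if tuple(table.subject_ids) != tuple(volumes.subject_ids):
        raise ValueError("table and volumes subject order mismatch")
    folds: list[FoldResult] = []
    n_warn = 0
    for i, sid in enumerate(table.subject_ids):
        train_ids = [s for s in table.subject_ids if s != sid]
        train_table = table.subset(train_ids)
        train_vols = volumes.subset(train_ids)
        # independence audit: the held-out subject must not shape the design
        assert sid not in train_table.subject_ids
        selection = _step1(
            train_table, train_vols, config,
            perm_seed=_perm_seed(config.seed, i), search_mask=search_mask,
        )
        fold = FoldResult(
            fold_index=i, held_out=(sid,), training=tuple(train_ids),
            type2=dict(selection.type2_flag),
        )
        rec = table.subset([sid]).records[0]
        for m in MEASURES:
            top = selection.top(m)
            fold.selected[m] = top
            if top is None:
                fold.flagged[m] = "no region survived correction"
                n_warn += 1
                continue
            dens_train = _extract_density(train_vols, top, config.extraction)
            dens_held = float(_extract_density(volumes.subset([sid]), top, config.extraction)[0])
            if np.ptp(dens_train) == 0:
                fold.flagged[m] = "zero training density variance at peak"
                n_warn += 1
                continue
            pairs = list(zip(dens_train, train_table.changes(m)))
            fold.predicted_change[m] = predict_held_out(pairs, dens_held)
            fold.measured_change[m] = float(rec.change(m))
            # joint training fit of t2 on (t1, density change)
            x = np.column_stack(
                [np.ones(n - 1), train_table.scores(m, 1), dens_train]
            )
            beta, *_ = np.linalg.lstsq(x, train_table.scores(m, 2), rcond=None)
            fold.predicted_t2[m] = float(beta @ [1.0, rec.score(m, 1), dens_held])
            fold.measured_t2[m] = float(rec.score(m, 2))
            fold.held_out_density[m] = dens_held
        folds.append(fold)
        logger.info("LOO fold %d/%d (held out subject %s) done", i + 1, n, sid)

    measures: dict[str, MeasureCV] = {}
    type2_rate: dict[str, float] = {}
    for m in MEASURES:
        ok = [f for f in folds if m in f.predicted_change]
        pred_c = np.array([f.predicted_change[m] for f in ok])
        meas_c = np.array([f.measured_change[m] for f in ok])
        pred_t2 = np.array([f.predicted_t2[m] for f in ok])
        meas_t2 = np.array([f.measured_t2[m] for f in ok])
        measures[m] = MeasureCV(
            r2_change=_predicted_vs_measured_r2(pred_c, meas_c) if len(ok) >= 3 else float("nan"),
            r2_t2=_predicted_vs_measured_r2(pred_t2, meas_t2) if len(ok) >= 3 else float("nan"),
            n_used=len(ok),
        )
        type2_rate[m] = float(np.mean([f.type2[m] for f in folds]))
    return CVResult(
        scheme="loo",
        folds=folds,
        measures=measures,
        type2_rate=type2_rate,
        n_subjects=n,
        config=config,
        n_warnings=n_warn,
    )


def _perm_seed(master: int, analysis_index: int) -> int:
    rng = np.random.default_rng([master, _STREAM_PERM, analysis_index])
    return int(rng.integers(0, 2**31 - 1))


def split_half_run(
    table: IQTable,
    volumes: CohortVolumes,
    config: RunConfig,
    search_mask: np.ndarray,
    repeats: Optional[int] = None,
) -> CVResult:
    """Repeated stratified split-half cross-validation.

    Each repeat contributes two analyses (train A / test B and train B /
    test A).  Step 1 uses the search-mask fallback so a region is always
    available; Step 2 fits the regressions within the test half and records
    R² for the change model and the hierarchical Time-2 pair.  Per-voxel
    selection-frequency counts accumulate across analyses.
    """
    if search_mask is None:
        raise ValueError("split-half requires a search mask for the fallback selection")
    n = len(table)
    if n < 8:
        raise ValueError("split-half needs n >= 8")
    if tuple(table.subject_ids) != tuple(volumes.subject_ids):
        raise ValueError("table and volumes subject order mismatch")
    repeats = config.repeats if repeats is None else repeats
    folds: list[FoldResult] = []
    freq = {m: np.zeros(volumes.shape, dtype=int) for m in MEASURES}
    n_warn = 0
    analysis = 0
    for rep in range(repeats):
        assignment = stratified_split(table, rep, config.seed)
        pairs = [
            (assignment.group_a, assignment.group_b),
            (assignment.group_b, assignment.group_a),
        ]
        for train_ids, test_ids in pairs:
            if len(test_ids) < 4:
                raise ValueError("test group has fewer than 4 subjects")
            train_table = table.subset(train_ids)
            train_vols = volumes.subset(train_ids)
            test_table = table.subset(test_ids)
            test_vols = volumes.subset(test_ids)
            selection = _step1(
                train_table, train_vols, config,
                perm_seed=_perm_seed(config.seed, 10_000 + analysis),
                search_mask=search_mask,
            )
            fold = FoldResult(
                fold_index=analysis,
                held_out=tuple(test_ids),
                training=tuple(train_ids),
                type2=dict(selection.type2_flag),
            )
            for m in MEASURES:
                top = selection.top(m)
                fold.selected[m] = top
                if top is None:
                    fold.flagged[m] = "no region selected"
                    n_warn += 1
                    continue
                for vox in top.cluster.voxels:
                    freq[m][vox] += 1
                dens_test = _extract_density(test_vols, top, config.extraction)
                if np.ptp(dens_test) == 0:
                    fold.flagged[m] = "zero test density variance at peak"
                    n_warn += 1
                    continue
                ones = np.ones(len(test_ids))
                fold.r2_change[m] = _ols_r2(
                    np.column_stack([ones, dens_test]), test_table.changes(m)
                )
                r2_t1, r2_full, inc = hierarchical_r2(
                    test_table.scores(m, 1), test_table.scores(m, 2), dens_test
                )
                fold.r2_t1_only[m] = r2_t1
                fold.r2_t2_full[m] = r2_full
                fold.r2_increment[m] = inc
            folds.append(fold)
            analysis += 1
            logger.info("split-half analysis %d/%d done", analysis, 2 * repeats)

    measures: dict[str, MeasureCV] = {}
    type2_rate: dict[str, float] = {}
    for m in MEASURES:
        r2c = np.array([f.r2_change[m] for f in folds if m in f.r2_change])
        r2full = np.array([f.r2_t2_full[m] for f in folds if m in f.r2_t2_full])
        incs = np.array([f.r2_increment[m] for f in folds if m in f.r2_increment])
        measures[m] = MeasureCV(
            r2_change=float(np.mean(r2c)) if len(r2c) else float("nan"),
            r2_t2=float(np.mean(r2full)) if len(r2full) else float("nan"),
            r2_t2_after_t1=float(np.mean(incs)) if len(incs) else float("nan"),
            r2_change_values=r2c,
            r2_t2_values=r2full,
            r2_increment_values=incs,
            n_used=len(r2c),
        )
        type2_rate[m] = float(np.mean([f.type2[m] for f in folds]))
    return CVResult(
        scheme="split-half",
        folds=folds,
        measures=measures,
        type2_rate=type2_rate,
        n_subjects=n,
        config=config,
        selection_freq=freq,
        n_warnings=n_warn,
    )
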