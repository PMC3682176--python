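"""Numeric tables, histograms, overlap maps and scheme comparisons.

All reporting is a pure function of stored run results: the fold table and
summary dictionaries regenerate bit-identically from ``folds.csv`` /
``summary.json``.  Plots are optional conveniences layered on the numeric
tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cv_engine import CVResult
from .iq_data import MEASURES
from .vbm_glm import RegionSelection

__all__ = [
    "SchemeComparison",
    "overlap_map",
    "fold_table",
    "r2_histogram",
    "compare_schemes",
    "summary_dict",
    "write_results",
]


@dataclass(frozen=True)
class SchemeComparison:
    """Side-by-side summary of the two cross-validation schemes."""

    loo_r2: dict  # measure -> LOO out-of-sample r2_change
    split_r2_mean: dict  # measure -> mean split-half r2_change
    split_r2_values: dict  # measure -> per-analysis distribution
    peak_dispersion_mm: dict  # (scheme, measure) -> max pairwise peak distance
    type2_rate: dict  # scheme -> measure -> rate
    step1_fits: dict  # scheme -> number of Step-1 model fits


def overlap_map(
    selections: Sequence[RegionSelection],
    shape: tuple[int, int, int],
    measure: str,
) -> np.ndarray:
    """Per-voxel count of selections whose retained clusters cover the voxel."""
    counts = np.zeros(shape, dtype=int)
    for sel in selections:
        if tuple(sel.shape) != tuple(shape):
            raise ValueError(f"selection grid {sel.shape} does not match {shape}")
        covered = np.zeros(shape, dtype=bool)
        for sc in sel.clusters.get(measure, []):
            for vox in sc.cluster.voxels:
                covered[vox] = True
        counts += covered
    return counts


def fold_table(result: CVResult, affine: Optional[np.ndarray] = None) -> pd.DataFrame:
    """One row per analysis per measure: peak location, statistics, basis,
    difference-conjunction Z, and the fold's Step-2 numbers."""
    if not result.folds:
        raise ValueError("empty cross-validation result")
    rows = []
    for fold in result.folds:
        for m in MEASURES:
            sc = fold.selected.get(m)
            row = {
                "fold": fold.fold_index,
                "held_out": ";".join(str(s) for s in fold.held_out),
                "measure": m,
                "basis": sc.basis if sc else "none",
                "type2": bool(fold.type2.get(m, False)),
                "flagged": fold.flagged.get(m, ""),
            }
            if sc is not None:
                px, py, pz = sc.cluster.peak
                row.update(
                    peak_x=px, peak_y=py, peak_z=pz,
                    size=sc.cluster.size,
                    peak_t=sc.cluster.peak_t,
                    peak_z_score=sc.cluster.peak_z,
                    diff_z=sc.conjunction_z,
                )
                if affine is not None:
                    world = affine @ np.array([px, py, pz, 1.0])
                    row.update(world_x=world[0], world_y=world[1], world_z=world[2])
            for attr in (
                "predicted_change", "measured_change", "predicted_t2", "measured_t2",
                "r2_change", "r2_t1_only", "r2_t2_full", "r2_increment",
            ):
                val = getattr(fold, attr).get(m)
                if val is not None:
                    row[attr] = val
            rows.append(row)
    return pd.DataFrame(rows)


def r2_histogram(
    values: Union[CVResult, np.ndarray, Sequence[float]],
    measure: str = "viq",
    which: str = "r2_change",
    bin_width: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of analyses per R² band over 0-100%.

    ``values`` may be a split-half :class:`CVResult` (the named per-analysis
    distribution is used) or an explicit sequence of R² values in percent.
    Returns (counts, bin_edges); counts sum to the number of analyses.
    """
    if isinstance(values, CVResult):
        if values.scheme != "split-half":
            raise ValueError("R2 histograms summarise split-half distributions")
        attr = {"r2_change": "r2_change_values", "r2_t2": "r2_t2_values",
                "r2_increment": "r2_increment_values"}[which]
        vals = np.asarray(getattr(values.measures[measure], attr), dtype=float) * 100.0
    else:
        vals = np.asarray(values, dtype=float)
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(np.clip(vals, 0.0, 100.0), bins=edges)
    return counts, edges


def _peak_dispersion(result: CVResult, measure: str, voxel_size: float) -> float:
    peaks = np.array(
        [f.selected[measure].cluster.peak for f in result.folds if f.selected.get(measure)],
        dtype=float,
    )
    if len(peaks) < 2:
        return 0.0
    d = peaks[:, None, :] - peaks[None, :, :]
    return float(np.max(np.sqrt((d**2).sum(-1))) * voxel_size)


def compare_schemes(
    loo: CVResult, split: CVResult, voxel_size: float = 1.0
) -> SchemeComparison:
    """Summaries contrasting the two schemes: point estimates, spread of the
    split-half distribution, peak dispersion, type-II rates and cost."""
    return SchemeComparison(
        loo_r2={m: loo.measures[m].r2_change for m in MEASURES},
        split_r2_mean={m: split.measures[m].r2_change for m in MEASURES},
        split_r2_values={m: np.asarray(split.measures[m].r2_change_values) for m in MEASURES},
        peak_dispersion_mm={
            (res.scheme, m): _peak_dispersion(res, m, voxel_size)
            for res in (loo, split)
            for m in MEASURES
        },
        type2_rate={res.scheme: dict(res.type2_rate) for res in (loo, split)},
        step1_fits={"loo": len(loo.folds), "split-half": len(split.folds)},
    )


def summary_dict(result: CVResult) -> dict:
    """JSON-serialisable summary of a run."""
    out = {
        "scheme": result.scheme,
        "n_subjects": result.n_subjects,
        "n_analyses": len(result.folds),
        "n_selected_clusters": result.n_selected_clusters,
        "type2_rate": result.type2_rate,
        "n_warnings": result.n_warnings,
        "measures": {},
    }
    for m, mc in result.measures.items():
        entry = {"r2_change": mc.r2_change, "r2_t2": mc.r2_t2, "n_used": mc.n_used}
        if mc.r2_t2_after_t1 is not None:
            entry["r2_t2_after_t1"] = mc.r2_t2_after_t1
        if mc.r2_change_values is not None:
            entry["r2_change_values"] = [float(v) for v in mc.r2_change_values]
            entry["r2_t2_values"] = [float(v) for v in mc.r2_t2_values]
            entry["r2_increment_values"] = [float(v) for v in mc.r2_increment_values]
        out["measures"][m] = entry
    return out


def write_results(
    result: CVResult,
    out_dir: Union[str, Path],
    affine: Optional[np.ndarray] = None,
) -> dict:
    """Write folds.csv, summary.json and (split-half) selection-frequency
    NIfTI volumes into ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    table = fold_table(result, affine=affine)
    paths["folds"] = out / f"folds_{result.scheme.replace('-', '')}.csv"
    table.to_csv(paths["folds"], index=False)
    paths["summary"] = out / f"summary_{result.scheme.replace('-', '')}.json"
    paths["summary"].write_text(json.dumps(summary_dict(result), indent=2))
    if result.selection_freq and affine is not None:
        from .cli_io import save_volume

        for m, vol in result.selection_freq.items():
            p = out / f"selection_freq_{m}.nii.gz"
            save_volume(vol.astype(float), affine, p)
            paths[f"freq_{m}"] = p
    return paths


def plot_r2_histograms(result: CVResult, path: Union[str, Path]) -> None:
    """Save split-half R² histograms (one panel per measure/quantity)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(MEASURES), 3, figsize=(12, 6), squeeze=False)
    titles = ["change", "Time 2 (full)", "Time 2 after Time 1"]
    for i, m in enumerate(MEASURES):
        for j, which in enumerate(["r2_change", "r2_t2", "r2_increment"]):
            counts, edges = r2_histogram(result, measure=m, which=which)
            axes[i][j].bar(edges[:-1], counts, width=np.diff(edges), align="edge")
            axes[i][j].set_title(f"{m.upper()} {titles[j]}")
            axes[i][j].set_xlabel("R2 (%)")
            axes[i][j].set_ylabel("analyses")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
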