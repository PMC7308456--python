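"""Ground-truth evaluation of the detection + measurement pipeline.

Detections are matched one-to-one to simulated truth records by centroid
proximity (greedy nearest-pair assignment). From the matched table the
module derives recall, per-fiber relative length error, measured-vs-true
regression, and the dynamic-range sweeps (the smallest and largest fiber
lengths the pipeline recovers reliably).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibration import CalibrationConfig
from .detect import DetectionConfig, detect_fibers
from .measure import measure_scene
from .simulate import SceneSpec, ground_truth_frame, render_scene


def run_scene(
    spec: SceneSpec,
    config: DetectionConfig | None = None,
    terminal_only: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one scene, run detection + measurement; return
    (truth table, per-fiber measurement table)."""
    pair, records = render_scene(spec)
    cal = CalibrationConfig(
        pixel_size_um=spec.pixel_size_um,
        stretch_factor_kb_per_um=spec.stretch_factor_kb_per_um,
        combing_axis_deg=spec.combing_axis_deg,
    )
    if config is None:
        config = DetectionConfig(combing_axis_deg=spec.combing_axis_deg)
    accepted = detect_fibers(pair, config)
    _, table = measure_scene(accepted, pair, cal, terminal_only=terminal_only)
    return ground_truth_frame(records), table


def match_to_truth(
    truth: pd.DataFrame, table: pd.DataFrame, max_dist_px: float = 15.0
) -> pd.DataFrame:
    """Greedy one-to-one nearest-centroid matching of measurements to truth.

    Returns one row per truth fiber with the matched measurement's length
    (NaN where unmatched) and the relative length error.
    """
    t_mid = truth[["row0", "row1"]].mean(axis=1).to_numpy(), truth[["col0", "col1"]].mean(
        axis=1
    ).to_numpy()
    truth_xy = np.column_stack(t_mid)
    meas_xy = table[["centroid_row", "centroid_col"]].to_numpy() if len(table) else np.empty((0, 2))

    pairs = []
    if len(truth_xy) and len(meas_xy):
        d = np.linalg.norm(truth_xy[:, None, :] - meas_xy[None, :, :], axis=2)
        d = d.copy()
        while True:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if not np.isfinite(d[i, j]) or d[i, j] > max_dist_px:
                break
            pairs.append((i, j, d[i, j]))
            d[i, :] = np.inf
            d[:, j] = np.inf

    matched_kb = np.full(len(truth), np.nan)
    matched_dist = np.full(len(truth), np.nan)
    for i, j, dist in pairs:
        matched_kb[i] = table["length_kb"].to_numpy()[j]
        matched_dist[i] = dist
    out = truth.copy()
    out["measured_kb"] = matched_kb
    out["match_dist_px"] = matched_dist
    out["rel_error"] = np.abs(out["measured_kb"] - out["true_length_kb"]) / out["true_length_kb"]
    return out


def _match_tolerance_px(spec: SceneSpec, length_kb: float) -> float:
    # centroid displacement grows with fiber length when gaps clip one end
    return max(15.0, 0.25 * length_kb / spec.kb_per_px)


def evaluate_fixed_length(
    length_kb: float,
    base_spec: SceneSpec,
    config: DetectionConfig,
    seeds: list[int],
) -> pd.DataFrame:
    """Pool matched tables over seeds for scenes of a single fiber length."""
    frames = []
    for seed in seeds:
        spec = base_spec.replace(
            length_dist=base_spec.length_dist.__class__("fixed", length_kb, 0.0), seed=seed
        )
        truth, table = run_scene(spec, config)
        frames.append(match_to_truth(truth, table, _match_tolerance_px(spec, length_kb)))
    return pd.concat(frames, ignore_index=True)


def sweep_lengths(
    lengths_kb: list[float],
    spec_for_length,
    config: DetectionConfig,
    seeds: list[int],
) -> pd.DataFrame:
    """Recall and median relative error per fiber length.

    ``spec_for_length(length_kb)`` builds the base scene spec for a length
    (image size may depend on it). Returns a table with columns
    (length_kb, n_fibers, recall, median_rel_error).
    """
    rows = []
    for L in lengths_kb:
        pooled = evaluate_fixed_length(L, spec_for_length(L), config, seeds)
        matched = pooled["measured_kb"].notna()
        recall = float(matched.mean()) if len(pooled) else 0.0
        med_err = float(pooled.loc[matched, "rel_error"].median()) if matched.any() else np.nan
        rows.append(
            dict(length_kb=L, n_fibers=len(pooled), recall=recall, median_rel_error=med_err)
        )
    return pd.DataFrame(rows)


def min_reliable_length(
    sweep: pd.DataFrame, recall_min: float = 0.9, error_max: float = 0.25
) -> float:
    """Smallest swept length meeting the recall and error requirements
    (NaN when none does)."""
    ok = sweep[(sweep["recall"] >= recall_min) & (sweep["median_rel_error"] <= error_max)]
    return float(ok["length_kb"].min()) if len(ok) else float("nan")


def max_reliable_length(
    sweep: pd.DataFrame, error_max: float = 0.10, recall_min: float = 0.5
) -> float:
    """Largest swept length measured within the error bound (NaN when
    none is)."""
    ok = sweep[(sweep["recall"] >= recall_min) & (sweep["median_rel_error"] <= error_max)]
    return float(ok["length_kb"].max()) if len(ok) else float("nan")
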