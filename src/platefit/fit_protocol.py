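"""Plate-length selection, measurement layout, distances, and fit criteria.

The anatomical-fit protocol scores a placed plate with three criteria:

* **Criterion 1** — plate–bone distance <= 1 mm at the single most
  anterior distal location on the plate head;
* **Criterion 2** — distance <= 2 mm at nine points over the metaphyseal
  region (three rows of anterior/centre/posterior points, including the
  distal tip);
* **Criterion 3** — distance <= 3 mm at anterior/centre/posterior points
  along the shaft at ~4 cm intervals, including the proximal tip
  (16 / 19 / 22 points for 9- / 11- / 13-hole plates).

Every distance is the Euclidean distance from the (placed) plate point to
the nearest *vertex* of the outer cortex mesh.  Overall anatomical fit is
the conjunction of all three criteria; thresholds are inclusive (<=).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PlatefitError, PlateSelectionError, UnconvergedPositioningError
from .mesh_core import nearest_vertex_distances
from .plate_positioning import (
    PositioningConfig,
    PositioningResult,
    initial_alignment,
    refine_position,
)
from .synthetic_anatomy import (
    FemurModel,
    PlateModel,
    canonicalize_side,
    make_femur_from_row,
)

DEFAULT_THRESHOLDS = {"c1": 1.0, "c2": 2.0, "c3": 3.0}


@dataclass
class MeasurementLayout:
    """Named measurement points in the plate's own frame."""

    c1_points: np.ndarray    # (1, 3)
    c2_points: np.ndarray    # (9, 3)
    c3_points: np.ndarray    # (3*rows + 1, 3)
    c1_ids: list = field(default_factory=lambda: ["c1"])
    c2_ids: list = field(default_factory=list)
    c3_ids: list = field(default_factory=list)

    def counts(self) -> dict:
        return {"c1": len(self.c1_points), "c2": len(self.c2_points),
                "c3": len(self.c3_points)}


@dataclass
class FitReport:
    """Per-point distances and criterion verdicts for one bone."""

    distances: dict          # point id -> mm
    criteria: dict           # 'c1'/'c2'/'c3' -> {max_distance, pass, n_points}
    overall_fit: bool
    holes: int
    proximal_tip_distance: float
    distal_tip_distance: float
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))


# ---------------------------------------------------------------------------
# Plate length selection
# ---------------------------------------------------------------------------

def select_plate_length(bone: FemurModel, plates: dict,
                        min_tip_clearance: float = 20.0,
                        distal_margin: float = 9.0) -> int:
    """Longest plate whose proximal tip stays >= 2 cm from the lesser
    trochanter base (inclusive), measured along the shaft axis with the
    plate seated flush distally.

    ``plates`` maps hole count -> :class:`PlateModel`.
    """
    from .bow_roc import _shaft_axis  # local import avoids a cycle

    axis, origin = _shaft_axis(bone)
    s_lt = float(np.asarray(
        bone.landmarks["lesser_trochanter_base"], float) @ axis - origin)
    s_distal_end = float((bone.outer.vertices @ axis).max() - origin)
    for holes in sorted(plates, reverse=True):
        plate = plates[holes]
        s_tip = s_distal_end - distal_margin - plate.params.length
        if s_tip >= s_lt + min_tip_clearance:
            return holes
    raise PlateSelectionError(
        "bone too short: even the shortest plate violates the proximal-tip "
        "clearance rule")


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------

def build_layout(plate: PlateModel) -> MeasurementLayout:
    """Measurement layout from the plate's anchors, with exact counts.

    Rows are numbered distal -> proximal.  Criterion 3 has
    ``3 * rows + 1`` points where rows = 5/6/7 for 9/11/13 holes.
    """
    a = plate.anchors
    for key in ("c1", "c2", "c3"):
        if key not in a:
            raise PlatefitError(f"plate anchors missing {key!r}")
    layout = MeasurementLayout(
        c1_points=np.atleast_2d(np.asarray(a["c1"], float)),
        c2_points=np.asarray(a["c2"], float),
        c3_points=np.asarray(a["c3"], float),
        c2_ids=list(a.get("c2_ids", [f"c2_{i}" for i in range(len(a["c2"]))])),
        c3_ids=list(a.get("c3_ids", [f"c3_{i}" for i in range(len(a["c3"]))])),
    )
    rows = plate.params.shaft_rows
    expected = {"c1": 1, "c2": 9, "c3": 3 * rows + 1}
    if layout.counts() != expected:
        raise PlatefitError(
            f"layout counts {layout.counts()} do not match the expected "
            f"{expected} for a {plate.holes}-hole plate")
    return layout


# ---------------------------------------------------------------------------
# Criterion evaluation
# ---------------------------------------------------------------------------

def evaluate_criteria(distances_by_criterion: dict,
                      thresholds: dict | None = None) -> tuple[dict, bool]:
    """Apply the inclusive per-criterion thresholds to distance vectors.

    ``distances_by_criterion`` maps 'c1'/'c2'/'c3' to arrays of mm
    distances.  Returns (criteria dict, overall_fit).
    """
    thresholds = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    criteria = {}
    for crit, dists in distances_by_criterion.items():
        dists = np.asarray(dists, dtype=float)
        passed = bool(np.all(dists <= thresholds[crit]))
        criteria[crit] = {"max_distance": float(dists.max()),
                          "mean_distance": float(dists.mean()),
                          "pass": passed, "n_points": int(len(dists))}
    overall = all(criteria[c]["pass"] for c in criteria)
    return criteria, overall


def measure_fit(plate: PlateModel, bone: FemurModel,
                positioning: PositioningResult,
                layout: MeasurementLayout | None = None,
                thresholds: dict | None = None) -> FitReport:
    """Measure plate–bone distances at all layout points and apply the
    three fit criteria.

    Requires a converged positioning result; distances are nearest-vertex
    distances to the outer cortex mesh.
    """
    if not positioning.converged:
        raise UnconvergedPositioningError(
            "plate positioning did not satisfy the placement constraints")
    layout = layout or build_layout(plate)
    thresholds = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    t = positioning.transform

    dists = {}
    by_crit = {}
    for crit, pts, ids in (("c1", layout.c1_points, layout.c1_ids),
                           ("c2", layout.c2_points, layout.c2_ids),
                           ("c3", layout.c3_points, layout.c3_ids)):
        d = nearest_vertex_distances(t.apply(pts), bone.outer)
        by_crit[crit] = d
        for pid, val in zip(ids, d):
            dists[pid] = float(val)
    criteria, overall = evaluate_criteria(by_crit, thresholds)

    tip_pts = t.apply(np.vstack([plate.anchors["proximal_tip"],
                                 plate.anchors["distal_tip"]]))
    tip_d = nearest_vertex_distances(tip_pts, bone.outer)
    return FitReport(distances=dists, criteria=criteria, overall_fit=overall,
                     holes=plate.holes,
                     proximal_tip_distance=float(tip_d[0]),
                     distal_tip_distance=float(tip_d[1]),
                     thresholds=thresholds)


# ---------------------------------------------------------------------------
# Cohort runs
# ---------------------------------------------------------------------------

def fit_one(bone: FemurModel, plates: dict,
            config: PositioningConfig | None = None,
            thresholds: dict | None = None,
            holes: int | None = None) -> tuple[FitReport, PositioningResult, int]:
    """Select a plate, position it, measure fit for one bone."""
    bone = canonicalize_side(bone)
    holes = holes if holes is not None else select_plate_length(bone, plates)
    plate = plates[holes]
    init = initial_alignment(plate, bone)
    positioning = refine_position(plate, bone, init, config)
    report = measure_fit(plate, bone, positioning, thresholds=thresholds)
    return report, positioning, holes


def cohort_fit_run(cohort_table: pd.DataFrame, plates: dict,
                   config: PositioningConfig | None = None,
                   thresholds: dict | None = None,
                   resolution: float = 1.0,
                   holes: int | None = None,
                   progress: bool = False) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Run the full protocol over a cohort metadata table.

    Femur meshes are generated one at a time from the table rows.  Bones
    whose positioning fails to converge are excluded with a reason.
    Returns (long-format distances, per-bone summary, failures).
    """
    long_rows = []
    summary_rows = []
    failures = []
    iterator = cohort_table.iterrows()
    if progress:
        from tqdm import tqdm
        iterator = tqdm(list(iterator), desc="cohort fit")
    for _, row in iterator:
        bone_id = row["id"]
        try:
            bone = make_femur_from_row(row, resolution=resolution)
            report, positioning, used_holes = fit_one(
                bone, plates, config, thresholds, holes=holes)
        except PlateSelectionError as exc:
            failures.append({"id": bone_id, "reason": f"plate_selection: {exc}"})
            continue
        except UnconvergedPositioningError:
            failures.append({"id": bone_id, "reason": "positioning_unconverged"})
            continue
        for pid, dist in report.distances.items():
            crit = pid.split("_")[0]
            long_rows.append({
                "id": bone_id, "criterion": crit, "point": pid,
                "distance_mm": dist,
                "pass_point": dist <= report.thresholds[crit],
            })
        srow = {k: row[k] for k in ("id", "ethnicity", "age", "age_group",
                                    "sex", "height_cm", "true_R_bow_mm")}
        srow.update({
            "holes": used_holes,
            "c1_mean_mm": report.criteria["c1"]["mean_distance"],
            "c2_mean_mm": report.criteria["c2"]["mean_distance"],
            "c3_mean_mm": report.criteria["c3"]["mean_distance"],
            "c1_pass": report.criteria["c1"]["pass"],
            "c2_pass": report.criteria["c2"]["pass"],
            "c3_pass": report.criteria["c3"]["pass"],
            "overall_pass": report.overall_fit,
            "proximal_tip_mm": report.proximal_tip_distance,
            "distal_tip_mm": report.distal_tip_distance,
        })
        summary_rows.append(srow)
    return (pd.DataFrame(long_rows), pd.DataFrame(summary_rows), failures)
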