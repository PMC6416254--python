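"""Length variables and shape ratios from 11-landmark scale configurations.

A rhombic scale in crown view is summarized by up to eight inter-landmark
lengths (mm). The anatomical landmark numbering is:

1. tip of the peg
2. tip of the anterodorsal process
3. midpoint of the dorsal margin of the crown
4. intersection of the anterior crown margin and the anterodorsal process
5. intersection of the dorsal and posterior crown margins
6. projection of landmark 5 onto the anterior crown margin
7. intersection of the posterior and ventral crown margins
8. projection of landmark 5 onto the posterior base margin
9. intersection of the posterior and dorsal base margins
10. intersection of the posterior and ventral base margins
11. intersection of the keel and the ventral base margin

The length definitions are a configurable landmark-pair/projection table;
the defaults below are the simplest constructions consistent with those
anatomical definitions. All lengths are invariant under rigid motions and
reflections and scale linearly with the coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import LandmarkConfiguration, ScaleRecord
from .errors import GeometryError, UndefinedRatioError

_EPS = 1e-12


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a - b))


def peg_length(cfg: LandmarkConfiguration) -> float:
    """L1: how far the peg tip extends beyond the dorsal crown margin.

    Measured as the perpendicular distance of landmark 1 from the line
    through landmarks 4 and 5, counted positive on the side away from the
    crown interior (represented by the centroid of landmarks 6 and 7) and
    clamped at 0 for a peg that does not protrude.
    """
    p1, p4, p5 = cfg.landmark(1), cfg.landmark(4), cfg.landmark(5)
    edge = p5 - p4
    norm = np.linalg.norm(edge)
    if norm < _EPS:
        raise GeometryError("landmarks 4 and 5 coincide: dorsal margin degenerate")
    normal = np.array([-edge[1], edge[0]]) / norm
    interior = 0.5 * (cfg.landmark(6) + cfg.landmark(7))
    if np.dot(interior - p4, normal) > 0:  # point the normal away from the crown
        normal = -normal
    return max(0.0, float(np.dot(p1 - p4, normal)))


def longitudinal_extent(cfg: LandmarkConfiguration) -> float:
    """L4: anteroposterior extent of the crown landmarks 2..7.

    The anteroposterior axis of an isolated scale is taken as the unit
    vector from landmark 6 to landmark 5 (no body frame is available).
    """
    p5, p6 = cfg.landmark(5), cfg.landmark(6)
    axis = p5 - p6
    norm = np.linalg.norm(axis)
    if norm < _EPS:
        raise GeometryError("landmarks 5 and 6 coincide: scale length degenerate")
    u = axis / norm
    proj = cfg.points[1:7] @ u  # landmarks 2..7
    return float(proj.max() - proj.min())


def compute_length_variables(cfg: LandmarkConfiguration) -> dict[str, float]:
    """Derive length variables (mm) from one crown-view configuration.

    Returns L1-L6 and L8. L7 (the concealed field) has no defining landmark
    and is a directly measured quantity; it is never derived here. L2 (keel
    length) is approximated by the landmark 1 - landmark 11 chord; both L2
    and L7 are discarded by variable selection before clustering, so these
    conventions never reach the analysis.
    """
    if not cfg.conforming:
        raise GeometryError(
            f"configuration {cfg.scale_id!r} has {cfg.points.shape[0]} landmarks, "
            "need exactly 11"
        )
    return {
        "L1": peg_length(cfg),
        "L2": _dist(cfg.landmark(1), cfg.landmark(11)),
        "L3": _dist(cfg.landmark(2), cfg.landmark(4)),
        "L4": longitudinal_extent(cfg),
        "L5": _dist(cfg.landmark(5), cfg.landmark(6)),
        "L6": _dist(cfg.landmark(5), cfg.landmark(7)),
        "L8": _dist(cfg.landmark(9), cfg.landmark(10)),
    }


def record_from_landmarks(cfg: LandmarkConfiguration, **metadata) -> ScaleRecord:
    """Build a measurement record from landmarks; metadata passed through."""
    return ScaleRecord(scale_id=cfg.scale_id, lengths=compute_length_variables(cfg), **metadata)


@dataclass
class RatioVector:
    """Dimensionless shape ratios of one scale.

    ``L6_over_L5`` is the height/length ratio; ``L7_over_L5`` is the
    concealed-field fraction and is absent when L7 was not measured.
    """

    L6_over_L5: float
    L1_over_L6: float
    L3_over_L6: float
    L7_over_L5: float | None = None

    def as_dict(self) -> dict:
        d = {
            "L6_over_L5": self.L6_over_L5,
            "L1_over_L6": self.L1_over_L6,
            "L3_over_L6": self.L3_over_L6,
        }
        if self.L7_over_L5 is not None:
            d["L7_over_L5"] = self.L7_over_L5
        return d


def compute_ratios(record: ScaleRecord) -> RatioVector:
    """Per-scale ratios; group statistics average these per-scale values."""
    L5 = record.lengths.get("L5")
    L6 = record.lengths.get("L6")
    if not L5 or not L6:
        raise UndefinedRatioError(
            f"scale {record.scale_id!r}: L5 and L6 must be > 0 for ratios "
            f"(got L5={L5!r}, L6={L6!r})"
        )
    L7 = record.lengths.get("L7")
    return RatioVector(
        L6_over_L5=L6 / L5,
        L1_over_L6=record.lengths.get("L1", 0.0) / L6,
        L3_over_L6=record.lengths.get("L3", 0.0) / L6,
        L7_over_L5=(L7 / L5) if L7 is not None else None,
    )
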