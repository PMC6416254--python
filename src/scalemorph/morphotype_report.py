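"""Per-morphotype statistics, matching of anonymous clusters to named
morphotypes, and the 4-belt / 16-area squamation map.

The built-in reference parameters describe the eight flank-scale
morphotypes that were delimited quantitatively (morphotypes 1, 2, 3, 6, 8,
10, 11 and 12 of *Guiyu oneiros*): per-morphotype mean and standard
deviation of the scale length L5 and scale height L6 in millimetres, of the
per-scale shape ratios L6/L5, L1/L6 and L3/L6, plus the average
concealed-field fraction of the scale length, ridge-count range and body
area. Five further morphotypes (4, 5, 7, 9, 13) were delimited
qualitatively and carry positions in the squamation map but no length
statistics.

Statistics use the population standard deviation (divisor n): a
single-scale morphotype then has SD exactly 0, matching the published
convention, whereas the n-1 convention would leave it undefined. Ratio
means are means of per-scale ratios, not ratios of group means — only that
convention reproduces the published ratio columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clustering import Partition
from .data_io import MeasurementTable
from .errors import MapLookupError, UndefinedRatioError
from .morphometry import compute_ratios

# ---------------------------------------------------------------------------
# Reference parameters for the 8 quantitatively delimited morphotypes.
# Keys: morphotype id -> (area, ridge range, L5 mean/SD, L6 mean/SD,
# ratio means/SDs, concealed-field % of scale length).
# Where the running text prints a different height/length ratio than the
# measurement table (morphotype 6: 2.34 vs 2.73; morphotype 11: 1.04 vs
# 1.11), the table value is the reference and the text reading is carried
# under `text_ratio_variant`.

REFERENCE_MORPHOTYPES: dict[int, dict] = {
    1:  dict(area="M1", ridges="25-35", L5=(1.75, 0.18), L6=(8.25, 0.51),
             L6_over_L5=(4.75, 0.55), L1_over_L6=(0.25, 0.06),
             L3_over_L6=(0.16, 0.04), concealed_pct=38.0),
    2:  dict(area="M2", ridges="25-30", L5=(2.03, 0.18), L6=(7.17, 0.41),
             L6_over_L5=(3.55, 0.34), L1_over_L6=(0.32, 0.05),
             L3_over_L6=(0.29, 0.04), concealed_pct=34.0),
    3:  dict(area="M3", ridges="10-25", L5=(1.76, 0.27), L6=(5.24, 0.46),
             L6_over_L5=(3.06, 0.63), L1_over_L6=(0.12, 0.07),
             L3_over_L6=(0.15, 0.07), concealed_pct=35.0),
    6:  dict(area="D2", ridges="15-20", L5=(1.48, 0.26), L6=(3.90, 0.38),
             L6_over_L5=(2.73, 0.65), L1_over_L6=(0.08, 0.09),
             L3_over_L6=(0.14, 0.09), concealed_pct=35.0,
             text_ratio_variant=2.34),
    8:  dict(area="V1", ridges="15-25", L5=(1.95, 0.28), L6=(6.55, 0.40),
             L6_over_L5=(3.41, 0.53), L1_over_L6=(0.18, 0.07),
             L3_over_L6=(0.18, 0.05), concealed_pct=38.0),
    10: dict(area="V3", ridges="5-10", L5=(1.42, 0.27), L6=(2.27, 0.52),
             L6_over_L5=(1.66, 0.44), L1_over_L6=(0.10, 0.13),
             L3_over_L6=(0.30, 0.21), concealed_pct=37.0),
    11: dict(area="V4", ridges="~10", L5=(2.37, 0.39), L6=(2.55, 0.50),
             L6_over_L5=(1.11, 0.32), L1_over_L6=(0.31, 0.07),
             L3_over_L6=(0.36, 0.20), concealed_pct=35.0,
             text_ratio_variant=1.04),
    12: dict(area="V5", ridges="10-15", L5=(3.35, 0.00), L6=(5.66, 0.00),
             L6_over_L5=(1.69, 0.00), L1_over_L6=(0.14, 0.00),
             L3_over_L6=(0.14, 0.00), concealed_pct=None),
}

#: published sizes of the 8 clustered groups, paired with the reference
#: morphotypes in table order (the size-1 group is morphotype 12)
REFERENCE_GROUP_SIZES: dict[int, int] = {
    1: 23, 2: 64, 3: 49, 6: 37, 8: 27, 10: 15, 11: 10, 12: 1,
}


@dataclass
class GroupSummary:
    group: int
    n: int
    L5_mean: float
    L5_sd: float
    L6_mean: float
    L6_sd: float
    L6_over_L5_mean: float
    L6_over_L5_sd: float
    L1_over_L6_mean: float
    L1_over_L6_sd: float
    L3_over_L6_mean: float
    L3_over_L6_sd: float
    concealed_pct_mean: float | None = None

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        return d


@dataclass
class MorphotypeSummary:
    groups: list[GroupSummary]
    total_n: int

    def __post_init__(self) -> None:
        assert sum(g.n for g in self.groups) == self.total_n
        for g in self.groups:
            if g.n == 1:
                assert g.L5_sd == 0.0 and g.L6_sd == 0.0

    def as_dict(self) -> dict:
        return {"total_n": self.total_n, "groups": [g.as_dict() for g in self.groups]}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([g.as_dict() for g in self.groups])


def summarize_groups(table: MeasurementTable, labels: Partition) -> MorphotypeSummary:
    """Per-group n, L5/L6 means and SDs, and per-scale ratio statistics.

    SDs use the population convention (divisor n). The concealed-field
    percentage (100 * L7/L5) is reported only when L7 is measured.
    """
    if len(labels.scale_ids) != len(table):
        raise ValueError("partition does not cover the table")
    summaries: list[GroupSummary] = []
    for g in range(labels.k):
        members = [table.records[i] for i in np.flatnonzero(labels.labels == g)]
        ratios = [compute_ratios(rec) for rec in members]  # raises on L5/L6 == 0
        L5 = np.array([rec.lengths["L5"] for rec in members])
        L6 = np.array([rec.lengths["L6"] for rec in members])
        r65 = np.array([r.L6_over_L5 for r in ratios])
        r16 = np.array([r.L1_over_L6 for r in ratios])
        r36 = np.array([r.L3_over_L6 for r in ratios])
        concealed = [r.L7_over_L5 for r in ratios if r.L7_over_L5 is not None]
        summaries.append(GroupSummary(
            group=g, n=len(members),
            L5_mean=float(L5.mean()), L5_sd=float(L5.std()),
            L6_mean=float(L6.mean()), L6_sd=float(L6.std()),
            L6_over_L5_mean=float(r65.mean()), L6_over_L5_sd=float(r65.std()),
            L1_over_L6_mean=float(r16.mean()), L1_over_L6_sd=float(r16.std()),
            L3_over_L6_mean=float(r36.mean()), L3_over_L6_sd=float(r36.std()),
            concealed_pct_mean=(100.0 * float(np.mean(concealed))) if concealed else None,
        ))
    return MorphotypeSummary(groups=summaries, total_n=len(table))


def match_to_reference(
    summary: MorphotypeSummary,
    reference: Mapping[int, dict] | None = None,
) -> tuple[dict[int, int], float]:
    """Optimal one-to-one map from anonymous groups to named morphotypes.

    Solves the assignment problem minimizing total Euclidean distance
    between group mean vectors (L5, L6, L6/L5) and reference means. Returns
    (group -> morphotype mapping, total assignment cost); a large cost
    signals a poor match. If group and reference counts differ, the min
    count is matched and the leftovers are simply absent from the mapping.
    """
    reference = dict(reference if reference is not None else REFERENCE_MORPHOTYPES)
    mts = sorted(reference)
    cost = np.zeros((len(summary.groups), len(mts)))
    for i, g in enumerate(summary.groups):
        v = np.array([g.L5_mean, g.L6_mean, g.L6_over_L5_mean])
        for j, mt in enumerate(mts):
            ref = reference[mt]
            w = np.array([ref["L5"][0], ref["L6"][0], ref["L6_over_L5"][0]])
            cost[i, j] = np.linalg.norm(v - w)
    rows, cols = linear_sum_assignment(cost)
    mapping = {summary.groups[i].group: mts[j] for i, j in zip(rows, cols)}
    total = float(cost[rows, cols].sum())
    return mapping, total


# ---------------------------------------------------------------------------
# Squamation map: 4 belts, 16 areas


@dataclass(frozen=True)
class Area:
    area_id: str
    belt: str
    morphotype: int | None
    bounds: str
    preserved: bool = True

    def as_dict(self) -> dict:
        return {
            "area": self.area_id, "belt": self.belt,
            "morphotype": self.morphotype, "bounds": self.bounds,
            "preserved": self.preserved,
        }


@dataclass
class SquamationMap:
    """The body-scale zonation: dorsal, middle, ventral and unpaired belts
    split into 16 areas, each tied to at most one morphotype, plus the
    auxiliary squamation elements that sit outside the area grid."""

    areas: dict[str, Area]
    auxiliary: dict[str, str]
    lateral_line_morphotypes: tuple[int, ...] = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        assert len(self.areas) == 16, "squamation map must have exactly 16 areas"
        belts = {"dorsal": 0, "middle": 0, "ventral": 0, "unpaired": 0}
        for a in self.areas.values():
            belts[a.belt] += 1
        assert (belts["dorsal"], belts["middle"], belts["ventral"], belts["unpaired"]) == (3, 5, 6, 2)
        mts = [a.morphotype for a in self.areas.values() if a.morphotype is not None]
        assert len(mts) == len(set(mts)), "each area maps to at most one morphotype"
        assert self.areas["M5"].morphotype is None

    def by_morphotype(self, morphotype: int) -> list[Area]:
        return [a for a in self.areas.values() if a.morphotype == morphotype]

    def as_dict(self) -> dict:
        return {
            "areas": {aid: a.as_dict() for aid, a in self.areas.items()},
            "auxiliary": dict(self.auxiliary),
            "lateral_line_morphotypes": list(self.lateral_line_morphotypes),
        }


def build_squamation_map() -> SquamationMap:
    """The built-in squamation model of *Guiyu oneiros*."""
    A = Area
    areas = {a.area_id: a for a in [
        A("D1", "dorsal", 5, "around the three median dorsal plates"),
        A("D2", "dorsal", 6, "post-temporal to the base of the second dorsal fin spine"),
        A("D3", "dorsal", 7, "behind D2 to the posterior edge of the caudal peduncle"),
        A("M1", "middle", 1, "median extrascapular to the base of the first dorsal fin spine"),
        A("M2", "middle", 2, "behind M1, ending at the anterior edge of the pelvic girdle"),
        A("M3", "middle", 3, "behind M2, ending at the anterior edge of the pelvic girdle"),
        A("M4", "middle", 4, "behind M3, ending at the posterior edge of the pelvic girdle"),
        A("M5", "middle", None, "behind M4; this region is not preserved on the fossil",
          preserved=False),
        A("V1", "ventral", 8, "under M1-M3, ending at the posterior edge of the pelvic girdle"),
        A("V2", "ventral", 9, "behind V1 to the posterior edge of the caudal peduncle"),
        A("V3", "ventral", 10, "immediately behind the pectoral girdle"),
        A("V4", "ventral", 11, "below V1 and behind V3"),
        A("V5", "ventral", 12, "near the ventral midline, pectoral girdle to interpelvic plate"),
        A("V6", "ventral", 13, "near the ventral midline, interpelvic plate to anal fin"),
        A("I", "unpaired", None, "dorsal median ridge scales between the two dorsal fins"),
        A("II", "unpaired", None, "dorsal median ridge scales between the second dorsal fin and the tail"),
    ]}
    auxiliary = {
        "basal_fin_scales": "small rhombic scales covering the pectoral and pelvic fin peduncles",
        "lepidotrichia": "elongated rhomboid fin-ray elements of uniform shape and size",
        "lateral_line": "canal-bearing flank scales of morphotypes 1-4 along the middle flank row",
        "median_dorsal_plates": "three unpaired dermal plates behind the median extrascapular",
    }
    return SquamationMap(areas=areas, auxiliary=auxiliary)


_DEFAULT_MAP: SquamationMap | None = None


def squamation_lookup(query: str, smap: SquamationMap | None = None) -> dict:
    """Look up an area id (``"D2"``) or morphotype id (``"Mt6"`` or ``6``).

    Returns the matching entries: for an area, its belt/morphotype/bounds;
    for a morphotype, the area(s) assigned to it.
    """
    global _DEFAULT_MAP
    if smap is None:
        if _DEFAULT_MAP is None:
            _DEFAULT_MAP = build_squamation_map()
        smap = _DEFAULT_MAP
    q = str(query).strip()
    if q in smap.areas:
        return smap.areas[q].as_dict()
    mt: int | None = None
    if q.lower().startswith("mt"):
        try:
            mt = int(q[2:])
        except ValueError:
            mt = None
    elif q.isdigit():
        mt = int(q)
    if mt is not None and 1 <= mt <= 13:
        hits = smap.by_morphotype(mt)
        return {"morphotype": mt, "areas": [a.as_dict() for a in hits]}
    valid = sorted(smap.areas) + [f"Mt{i}" for i in range(1, 14)]
    raise MapLookupError(f"unknown id {query!r}; valid ids: {', '.join(valid)}")
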