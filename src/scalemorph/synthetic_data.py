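"""Synthetic measurement tables with the cluster structure the analysis assumes.

The default specification emulates the published study conditions: eight
multivariate clusters of flank scales whose L5/L6 (and ratio-derived L1/L3)
means and standard deviations follow the per-morphotype reference
parameters, with group sizes 23, 64, 49, 37, 27, 15, 10 and 1 (226 scales
in total, the single scale on morphotype 12). Variables are drawn as
independent normals per cluster (only marginal SDs are published), truncated
at 0; an optional per-cluster covariance hook exists for harder tests.

Dependent variables L2, L8 (proportional to the crown height L6) and L7
(the concealed field, a fixed fraction of the scale length L5) can be
generated as well, so the correlation-pruning stage sees the redundancy
structure the real variables exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import MeasurementTable, ScaleRecord
from .errors import ConstructionError
from .data_io import LandmarkConfiguration
from .morphotype_report import REFERENCE_GROUP_SIZES, REFERENCE_MORPHOTYPES

CLUSTER_VARIABLES = ("L1", "L3", "L4", "L5", "L6")

#: measurement noise SD (mm) of the dependent variables around their linear
#: relations; at sub-millimetre CT measurement precision this keeps the
#: published "strong correlation" of (L2, L6, L8) and of (L5, L7)
DEPENDENT_NOISE_SD = 0.02

#: fallback concealed-field fraction where none is published (morphotype 12)
DEFAULT_CONCEALED_FRACTION = 0.35


@dataclass
class ClusterSpec:
    morphotype: int
    size: int
    mean: dict[str, float]        # over CLUSTER_VARIABLES, mm
    sd: dict[str, float]          # over CLUSTER_VARIABLES, mm
    concealed_fraction: float = DEFAULT_CONCEALED_FRACTION
    cov: np.ndarray | None = None  # optional (5,5) covariance overriding sd

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"cluster size must be >= 1, got {self.size}")
        for v in CLUSTER_VARIABLES:
            if v not in self.mean or v not in self.sd:
                raise ValueError(f"cluster for morphotype {self.morphotype} lacks {v}")
            if self.sd[v] < 0:
                raise ValueError(f"negative SD for {v}")


@dataclass
class SyntheticSpec:
    clusters: list[ClusterSpec]
    label_noise: float = 0.0      # fraction of records relabeled at random
    seed: int = 0
    include_dependent_variables: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must be in [0, 1)")

    @property
    def total_size(self) -> int:
        return sum(c.size for c in self.clusters)


@dataclass
class SyntheticSample:
    table: MeasurementTable
    true_labels: np.ndarray       # cluster index per record, 0..n_clusters-1
    noisy_labels: np.ndarray      # == true_labels when label_noise == 0
    morphotypes: tuple[int, ...]  # morphotype id of each cluster index


def default_reference_spec(
    label_noise: float = 0.0, seed: int = 0,
    include_dependent_variables: bool = True,
) -> SyntheticSpec:
    """The study-condition specification built from the reference parameters.

    L5 and L6 means/SDs are the published per-morphotype values. L1 and L3
    are only published as ratios to L6, so their means are ratio_mean * L6_mean
    and their SDs follow first-order error propagation,
    sd^2 = (ratio_mean * L6_sd)^2 + (L6_mean * ratio_sd)^2. L4 (longitudinal
    extent) has no published statistics and defaults to L5's, both measuring
    anteroposterior size.
    """
    clusters: list[ClusterSpec] = []
    for mt in sorted(REFERENCE_MORPHOTYPES):
        ref = REFERENCE_MORPHOTYPES[mt]
        L5m, L5s = ref["L5"]
        L6m, L6s = ref["L6"]
        mean = {"L5": L5m, "L6": L6m, "L4": L5m}
        sd = {"L5": L5s, "L6": L6s, "L4": L5s}
        for var, ratio_key in (("L1", "L1_over_L6"), ("L3", "L3_over_L6")):
            rm, rs = ref[ratio_key]
            mean[var] = rm * L6m
            sd[var] = float(np.hypot(rm * L6s, L6m * rs))
        pct = ref.get("concealed_pct")
        clusters.append(ClusterSpec(
            morphotype=mt,
            size=REFERENCE_GROUP_SIZES[mt],
            mean=mean, sd=sd,
            concealed_fraction=(pct / 100.0) if pct else DEFAULT_CONCEALED_FRACTION,
        ))
    return SyntheticSpec(
        clusters=clusters, label_noise=label_noise, seed=seed,
        include_dependent_variables=include_dependent_variables,
    )


def generate_measurements(
    spec: SyntheticSpec, seed: int | None = None
) -> SyntheticSample:
    """Draw one measurement table from a cluster specification.

    Each record's variables come from normal(mean, SD) per cluster (or a
    multivariate normal when the cluster carries a covariance), truncated at
    0. Fixed seeds give byte-identical tables. True labels are returned
    separately; when ``label_noise > 0`` the noisy labels relabel that
    fraction of records to a uniformly chosen different cluster.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records: list[ScaleRecord] = []
    truth: list[int] = []
    variables = list(CLUSTER_VARIABLES)
    if spec.include_dependent_variables:
        variables = ["L1", "L2", "L3", "L4", "L5", "L6", "L7", "L8"]
    counter = 0
    for ci, cluster in enumerate(spec.clusters):
        if cluster.cov is not None:
            mu = np.array([cluster.mean[v] for v in CLUSTER_VARIABLES])
            draws = rng.multivariate_normal(mu, cluster.cov, size=cluster.size)
        else:
            mu = np.array([cluster.mean[v] for v in CLUSTER_VARIABLES])
            sigma = np.array([cluster.sd[v] for v in CLUSTER_VARIABLES])
            draws = rng.normal(mu, sigma, size=(cluster.size, len(CLUSTER_VARIABLES)))
        draws = np.clip(draws, 0.0, None)
        for row in draws:
            counter += 1
            lengths = dict(zip(CLUSTER_VARIABLES, (float(x) for x in row)))
            if spec.include_dependent_variables:
                eps = rng.normal(0.0, DEPENDENT_NOISE_SD, size=3)
                lengths["L2"] = max(0.0, 0.9 * lengths["L6"] + eps[0])
                lengths["L8"] = max(0.0, 1.1 * lengths["L6"] + eps[1])
                lengths["L7"] = max(0.0, cluster.concealed_fraction * lengths["L5"] + eps[2])
            records.append(ScaleRecord(
                scale_id=f"syn{counter:04d}",
                specimen_id="synthetic",
                lengths={v: lengths[v] for v in variables},
            ))
            truth.append(ci)

    truth_arr = np.array(truth)
    noisy = truth_arr.copy()
    if spec.label_noise > 0 and len(spec.clusters) > 1:
        n = len(noisy)
        n_flip = int(round(spec.label_noise * n))
        flip = rng.choice(n, size=n_flip, replace=False)
        for i in flip:
            choices = [c for c in range(len(spec.clusters)) if c != truth_arr[i]]
            noisy[i] = rng.choice(choices)
    table = MeasurementTable(
        records=records,
        variable_names=tuple(variables),
        provenance=f"synthetic(seed={spec.seed if seed is None else seed})",
    )
    return SyntheticSample(
        table=table, true_labels=truth_arr, noisy_labels=noisy,
        morphotypes=tuple(c.morphotype for c in spec.clusters),
    )


def generate_landmarks(
    template: int = 2,
    L5: float | None = None,
    L6: float | None = None,
    L1: float | None = None,
    L3: float | None = None,
    jitter: float = 0.0,
    seed: int = 0,
    scale_id: str = "",
) -> LandmarkConfiguration:
    """Build an 11-landmark rhombic-scale outline with prescribed lengths.

    The inverse construction places the crown corners so the forward length
    computation returns exactly the requested L5, L6, L1 and L3 (to 1e-9)
    at zero jitter; unspecified lengths default to the template morphotype's
    reference means. ``jitter`` adds isotropic normal noise (mm SD) to every
    landmark afterwards.
    """
    ref = REFERENCE_MORPHOTYPES.get(template)
    if ref is None:
        raise ConstructionError(f"unknown template morphotype {template}")
    if L5 is None:
        L5 = ref["L5"][0]
    if L6 is None:
        L6 = ref["L6"][0]
    if L1 is None:
        L1 = ref["L1_over_L6"][0] * ref["L6"][0]
    if L3 is None:
        L3 = ref["L3_over_L6"][0] * ref["L6"][0]
    for name, val in (("L5", L5), ("L6", L6)):
        if val <= 0:
            raise ConstructionError(f"{name} must be > 0, got {val}")
    if L1 < 0 or L3 < 0:
        raise ConstructionError("L1 and L3 must be >= 0")

    # crown-view frame: anteroposterior axis along +x, dorsal margin on y=0,
    # crown interior below it.
    lm5 = np.array([0.0, 0.0])
    lm6 = np.array([-L5, 0.0])                   # anterior projection of lm5
    lm7 = np.array([0.0, -L6])                   # posteroventral crown corner
    lm4 = np.array([-0.6 * L5, 0.0])             # anterodorsal crown corner
    lm3 = 0.5 * (lm4 + lm5)                      # dorsal-margin midpoint
    # peg tip: L1 above the dorsal margin (away from the crown interior)
    lm1 = np.array([-0.25 * L5, L1])
    # anterodorsal process tip at distance L3 from lm4
    theta = np.deg2rad(155.0)
    lm2 = lm4 + L3 * np.array([np.cos(theta), np.sin(theta)])
    # base outline: posterior base margin anterior to the crown's posterior edge
    lm9 = np.array([-0.12 * L5, 0.05 * L6])
    lm10 = np.array([-0.12 * L5, -0.88 * L6])
    lm8 = np.array([-0.12 * L5, 0.0])            # projection of lm5 on that margin
    lm11 = np.array([-0.55 * L5, -0.92 * L6])    # keel meets ventral base margin

    pts = np.vstack([lm1, lm2, lm3, lm4, lm5, lm6, lm7, lm8, lm9, lm10, lm11])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    return LandmarkConfiguration(
        points=pts, scale_id=scale_id or f"template_mt{template}"
    )
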