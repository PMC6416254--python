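"""One-call orchestration: select variables -> cluster -> CVA refine ->
summarize -> match morphotypes -> squamation map."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import clustering, cva, feature_selection, morphotype_report
from .clustering import Dendrogram, Partition
from .data_io import MeasurementTable, read_measurement_table
from .errors import ScalemorphError
from .feature_selection import CorrelationReport
from .morphotype_report import MorphotypeSummary, SquamationMap
from .synthetic_data import default_reference_spec, generate_measurements

log = logging.getLogger("scalemorph")


@dataclass
class PipelineConfig:
    input_table: str | None = None        # CSV path; None -> default synthetic spec
    schema: dict | None = None
    threshold: float = feature_selection.DEFAULT_THRESHOLD
    priority: Sequence[str] = feature_selection.DEFAULT_PRIORITY
    ks: Sequence[int] = (7, 8, 9)
    k: int = 8
    max_rounds: int = 1
    ridge: float = 0.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class PipelineResult:
    correlation: CorrelationReport
    dendrogram: Dendrogram
    k: int
    partition: Partition
    accuracy_history: list[float]
    refined_partition: Partition
    summary: MorphotypeSummary
    morphotype_mapping: dict[int, int]
    mapping_cost: float
    squamation: SquamationMap
    compare_k: dict[int, dict]
    canonical_scores: np.ndarray
    timestamp: float = field(default_factory=time.time)

    def as_dict(self) -> dict:
        return {
            "correlation": self.correlation.as_dict(),
            "dendrogram": self.dendrogram.as_dict(),
            "k": self.k,
            "partition": self.partition.as_dict(),
            "accuracy_history": list(self.accuracy_history),
            "refined_partition": self.refined_partition.as_dict(),
            "summary": self.summary.as_dict(),
            "morphotype_mapping": {str(k): v for k, v in self.morphotype_mapping.items()},
            "mapping_cost": self.mapping_cost,
            "compare_k": {
                str(k): {
                    "group_sizes": d["group_sizes"],
                    "within_dispersion": d["within_dispersion"],
                    "mean_silhouette": d["mean_silhouette"],
                }
                for k, d in self.compare_k.items()
            },
            "squamation": self.squamation.as_dict(),
            "canonical_scores": self.canonical_scores.tolist(),
            "timestamp": self.timestamp,
        }


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except ScalemorphError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
            log.info("stage %s: %.3fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(
    config: PipelineConfig, table: MeasurementTable | None = None
) -> PipelineResult:
    """Execute the full analysis on a table (read, or synthesized by default).

    Stages run in order; every intermediate lands in the result so the JSON
    report reproduces the whole analysis. All randomness comes from
    ``config.seed`` (only the synthetic stage is stochastic; the analysis
    itself is deterministic).
    """
    if table is None:
        if config.input_table:
            table = _stage("read")(read_measurement_table)(
                config.input_table, config.schema
            )
        else:
            spec = default_reference_spec(seed=config.seed)
            table = generate_measurements(spec).table
            log.info("no input table: generated default synthetic table (n=%d)", len(table))

    report = _stage("select_variables")(feature_selection.select_variables)(
        table, config.threshold, config.priority
    )
    selected = report.kept
    dendro = _stage("cluster")(clustering.agglomerate)(table, selected)
    diagnostics = _stage("compare_k")(clustering.compare_k)(table, selected, config.ks)
    partition = _stage("cut")(clustering.cut_k)(dendro, config.k)
    refined, history = _stage("cva_refine")(cva.refine_labels)(
        table, partition, selected, max_rounds=config.max_rounds, ridge=config.ridge
    )
    summary = _stage("summarize")(morphotype_report.summarize_groups)(table, refined)
    mapping, cost = _stage("match")(morphotype_report.match_to_reference)(summary)
    smap = morphotype_report.build_squamation_map()

    model = cva.fit_cva(table, refined, selected, ridge=config.ridge)
    scores = model.transform(table.matrix(selected))

    assert len(history) <= config.max_rounds + 1
    return PipelineResult(
        correlation=report,
        dendrogram=dendro,
        k=config.k,
        partition=partition,
        accuracy_history=[h.accuracy for h in history],
        refined_partition=refined,
        summary=summary,
        morphotype_mapping=mapping,
        mapping_cost=cost,
        squamation=smap,
        compare_k=diagnostics,
        canonical_scores=scores,
    )
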