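"""End-to-end orchestration: cohort -> ERP -> sources -> networks -> features.

Each stage function takes the previous stage's output so partial runs are
easy; :func:`run_pipeline` chains them for a whole cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import connectivity, erp, graphmetrics, groupstats
from .inverse import ELoreta, extract_roi
from .synthgen import SynthCohort

__all__ = ["PipelineResult", "erp_stage", "network_stage", "compare_stage", "run_pipeline"]

CONDITIONS = ("S1", "S2", "S1-S2")


@dataclass
class PipelineResult:
    """All per-subject products of the pipeline for one cohort."""

    erp_table: pd.DataFrame
    net_table: pd.DataFrame
    networks: dict  # condition -> subjects x n x n array (valid subjects)
    subjects: list[str]
    labels: list[str]
    segments: dict = field(default_factory=dict)


def erp_stage(
    cohort: SynthCohort,
    band: tuple[float, float] = (1.0, 40.0),
    reject_threshold_uv: float = 100.0,
    min_s1_uv: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Sensor-level ERP measures and condition segments for every subject."""
    vertex = cohort.vertex_channels
    rows, segments = [], {}
    for epochs, group in zip(cohort.epochs, cohort.labels):
        measures, segs, _ = erp.measure_subject(
            epochs,
            band=band,
            reject_threshold_uv=reject_threshold_uv,
            channel_subset=vertex,
            min_s1_uv=min_s1_uv,
        )
        segments[epochs.subject] = segs
        rows.append(
            {
                "subject": epochs.subject,
                "group": group,
                "s1_amp": measures.s1_amp,
                "s1_latency": measures.s1_latency,
                "s2_amp": measures.s2_amp,
                "s2_latency": measures.s2_latency,
                "diff": measures.diff,
                "ratio": measures.ratio if measures.ratio is not None else np.nan,
                "valid": measures.valid,
            }
        )
    return pd.DataFrame(rows), segments


def network_stage(
    cohort: SynthCohort,
    segments: dict,
    alpha: float = 0.05,
    bins: int | None = None,
    density: float = 0.2,
) -> tuple[pd.DataFrame, dict]:
    """Source projection, NMI networks and graph metrics per subject."""
    inv = ELoreta(alpha=alpha).fit(cohort.lead_field)
    per_cond: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    rows = []
    for epochs in cohort.epochs:
        segs = segments[epochs.subject].as_dict()
        mats = {}
        for cond in CONDITIONS:
            src = inv.apply(segs[cond])
            rois = extract_roi(src, cohort.atlas, condition=cond, fs=epochs.fs)
            mats[cond] = connectivity.build_matrix(
                rois, bins=bins, condition=cond, subject=epochs.subject
            )
            per_cond[cond].append(mats[cond].values)
        rows.append(
            {"subject": epochs.subject, **graphmetrics.metrics_for_subject(mats, density)}
        )
    networks = {c: np.stack(v) for c, v in per_cond.items()}
    return pd.DataFrame(rows), networks


def compare_stage(
    networks: dict,
    labels,
    pairs=(("FESZ", "HC"), ("UHR", "HC"), ("FESZ", "UHR")),
    n_perm: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    valid_mask=None,
) -> dict:
    """Edge-wise permutation tests for each condition and group pair."""
    labels = np.asarray(labels)
    if valid_mask is None:
        valid_mask = np.ones(labels.size, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    results: dict = {}
    for cond, stack in networks.items():
        for a, b in pairs:
            sel_a = stack[(labels == a) & valid_mask]
            sel_b = stack[(labels == b) & valid_mask]
            results[(cond, a, b)] = groupstats.edge_permutation_test(
                sel_a,
                sel_b,
                n_perm=n_perm,
                alpha=alpha,
                seed=seed,
                group_pair=(a, b),
            )
    return results


def run_pipeline(
    cohort: SynthCohort,
    band: tuple[float, float] = (1.0, 40.0),
    reject_threshold_uv: float = 100.0,
    min_s1_uv: float = 0.5,
    alpha: float = 0.05,
    bins: int | None = None,
    density: float = 0.2,
) -> PipelineResult:
    """Cohort -> ERP measures, NMI networks and graph-metric features."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        erp_table, segments = erp_stage(
            cohort,
            band=band,
            reject_threshold_uv=reject_threshold_uv,
            min_s1_uv=min_s1_uv,
        )
        net_table, networks = network_stage(
            cohort, segments, alpha=alpha, bins=bins, density=density
        )
    return PipelineResult(
        erp_table=erp_table,
        net_table=net_table,
        networks=networks,
        subjects=[e.subject for e in cohort.epochs],
        labels=list(cohort.labels),
        segments=segments,
    )
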