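"""End-to-end orchestration: training (discovery) and apply (held-out) flows.

The training flow runs simulate/ingest -> morphometry -> connectivity ->
network inference -> classification; the apply flow bypasses all discovery,
extracting the stored network edges from a new cohort's connectivity
matrices and feeding them to the trained classifiers.

A single global seed expands into per-stage child seeds through
``numpy.random.SeedSequence(seed, spawn_key=(stage,))``, so any stage can be
re-run in isolation and reproduce its exact output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify as cl
from . import nbs as nb
from .connectivity import ConnectivityStack, TimeSeriesMatrix, compute_connectivity
from .errors import AlignmentError
from .morphometry import GmStack, RoiSet, discover_rois
from .synth import (
    GroundTruth,
    PlantedEdge,
    PlantedFocus,
    PsychometricTable,
    edge_effect_for_target_correlation,
    effective_samples,
    generate_gm_maps,
    generate_parcellation,
    generate_scores,
    generate_timeseries,
)

__all__ = ["PipelineConfig", "CohortData", "RunManifest", "simulate_cohort", "run_training", "run_apply"]


@dataclass
class PipelineConfig:
    """All stage parameters (defaults follow the reference analysis) plus
    the synthetic-cohort settings used when no cohort is supplied."""

    # morphometry
    alpha_unc: float = 0.001
    alpha_fwe: float = 0.05
    diameter_mm: float = 5.0
    n_perm_vbm: int = 1000
    # connectivity
    low_hz: float = 0.01
    high_hz: float = 0.1
    # network inference
    primary_p: float = 0.005
    n_perm: int = 5000
    target_edges: int = 15
    alpha: float = 0.05
    # classification
    n_classes: int = 8
    c_grid: tuple = tuple(cl.DEFAULT_C_GRID)
    gamma_grid: tuple = tuple(cl.DEFAULT_GAMMA_GRID)
    # reproducibility
    seed: int = 0
    # synthetic cohort
    n_subjects: int = 150
    n_parameters: int = 2
    n_rois: int = 30
    T: int = 480
    tr_seconds: float = 1.0
    grid: tuple = (12, 12, 12)
    voxel_size_mm: float = 4.0
    n_parcels: int = 27
    score_mean: float = 58.38
    score_sd: float = 10.40
    n_planted_edges: int = 10
    edge_target_r: float = 0.4  # 0 disables the planted network (null cohort)
    vbm_snr: float = 2.0  # focus effect amplitude per score SD, in noise-SD units
    gm_noise_sd: float = 0.05
    run_morphometry: bool = True

    def child_seed(self, stage: int) -> int:
        ss = np.random.SeedSequence(self.seed, spawn_key=(stage,))
        return int(ss.generate_state(1)[0] % (2**31))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        for key in ("c_grid", "gamma_grid", "grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class CohortData:
    """One cohort's inputs: scores, structural maps, time series, truth."""

    table: PsychometricTable
    series: list[TimeSeriesMatrix]
    confounds: list[np.ndarray]
    truth: GroundTruth | None = None
    gm: GmStack | None = None
    parcellation: np.ndarray | None = None

    def __post_init__(self):
        ids = self.table.subject_ids
        if [ts.subject_id for ts in self.series] != ids:
            raise AlignmentError("time-series subject ids do not align with the score table")
        if self.gm is not None and self.gm.subject_ids != ids:
            raise AlignmentError("GM-stack subject ids do not align with the score table")


def simulate_cohort(config: PipelineConfig, seed: int | None = None) -> CohortData:
    """Generate a full synthetic cohort from the config's planted-truth settings.

    Parameter 1 carries the planted structure: one gray-matter focus (at the
    center of the middle parcel) and, when ``edge_target_r > 0``, a star
    network of ``n_planted_edges`` edges among the first ROIs with the edge
    effect sized to reach the requested edge-score correlation after
    bandpass filtering.
    """
    seed = config.seed if seed is None else seed
    params = [f"param-{k + 1:02d}" for k in range(config.n_parameters)]
    moments = {p: (config.score_mean, config.score_sd) for p in params}
    table = generate_scores(config.n_subjects, params, moments, seed=seed)

    shape = tuple(config.grid)
    center = tuple(s // 2 for s in shape)
    parcellation = generate_parcellation(shape, config.n_parcels)
    foci = []
    if config.vbm_snr > 0:
        beta_vbm = config.vbm_snr * config.gm_noise_sd / config.score_sd
        foci.append(
            PlantedFocus(
                parameter=params[0],
                parcel=int(parcellation[center]),
                center=center,
                beta_vbm=beta_vbm,
            )
        )
    edges = []
    if config.edge_target_r > 0 and config.n_planted_edges > 0:
        n_eff = effective_samples(config.T, config.tr_seconds, config.low_hz, config.high_hz)
        beta_edge = edge_effect_for_target_correlation(config.edge_target_r, n_eff)
        edges = [
            PlantedEdge(parameter=params[0], i=0, j=j + 1, beta_edge=beta_edge)
            for j in range(config.n_planted_edges)
        ]
    truth = GroundTruth(
        planted_foci=foci,
        planted_edges=edges,
        score_model=moments,
        seed=seed,
    )
    gm = generate_gm_maps(
        table,
        truth,
        grid=shape,
        voxel_size_mm=config.voxel_size_mm,
        noise_sd=config.gm_noise_sd,
    )
    series, confounds = generate_timeseries(
        table, truth, n_rois=config.n_rois, T=config.T, tr_seconds=config.tr_seconds
    )
    return CohortData(
        table=table, series=series, confounds=confounds, truth=truth, gm=gm,
        parcellation=parcellation,
    )


@dataclass
class RunManifest:
    """Bookkeeping for one pipeline run: per-parameter outcomes and counts.

    Count consistency is a structural invariant: parameters with significant
    classifiers are a subset of parameters with networks, which are a subset
    of parameters with ROIs or (in ROI-supplied mode) direct network
    discovery.
    """

    config: PipelineConfig
    outcomes: list[dict] = field(default_factory=list)
    roiset: RoiSet | None = None
    roiset_prededup: RoiSet | None = None
    connectivity: ConnectivityStack | None = None
    networks: dict = field(default_factory=dict)  # parameter -> NetworkComponent
    models: dict = field(default_factory=dict)  # parameter -> OaaSvmModel
    reports: dict = field(default_factory=dict)  # parameter -> ClassifierReport

    @property
    def counts(self) -> dict:
        out = {
            "n_parameters": len(self.outcomes),
            "params_with_rois": sum(1 for o in self.outcomes if o.get("n_rois", 0) > 0),
            "n_rois": len(self.roiset) if self.roiset is not None else 0,
            "params_with_networks": sum(1 for o in self.outcomes if o.get("network_found")),
            "n_networks": len(self.networks),
            "params_with_classifiers": sum(1 for o in self.outcomes if o.get("classifier_trained")),
            "significant_classifiers": sum(
                1 for o in self.outcomes if o.get("classifier_significant")
            ),
        }
        return out

    def validate(self) -> None:
        with_cls = {o["parameter"] for o in self.outcomes if o.get("classifier_trained")}
        with_net = {o["parameter"] for o in self.outcomes if o.get("network_found")}
        if not with_cls <= with_net:
            raise AlignmentError("classifier exists for a parameter without a network")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.outcomes)

    def to_json(self, path: str | Path) -> None:
        payload = {"config": asdict(self.config), "counts": self.counts, "outcomes": self.outcomes}
        Path(path).write_text(json.dumps(payload, indent=1, default=float))


def run_training(
    config: PipelineConfig,
    cohort: CohortData | None = None,
    parameters: Sequence[str] | None = None,
) -> RunManifest:
    """Execute the full training flow and return its manifest.

    Stages: simulate/ingest, morphometry ROI discovery (when GM maps and a
    parcellation are present and ``config.run_morphometry``), connectivity,
    per-parameter network inference with edge-count targeting, and
    classification of each discovered network.  Deterministic under
    ``config.seed``.
    """
    if cohort is None:
        cohort = simulate_cohort(config)
    manifest = RunManifest(config=config)
    params = list(parameters) if parameters is not None else cohort.table.parameters

    if config.run_morphometry and cohort.gm is not None and cohort.parcellation is not None:
        roiset, prededup = discover_rois(
            cohort.gm,
            cohort.table.scores,
            cohort.parcellation,
            parameters=params,
            n_perm=config.n_perm_vbm,
            alpha_fwe=config.alpha_fwe,
            alpha_unc=config.alpha_unc,
            diameter_mm=config.diameter_mm,
            seed=config.child_seed(10),
        )
        manifest.roiset = roiset
        manifest.roiset_prededup = prededup
    rois_per_param = {}
    if manifest.roiset is not None:
        for r in manifest.roiset:
            rois_per_param[r.parameter] = rois_per_param.get(r.parameter, 0) + 1

    stack = compute_connectivity(
        cohort.series, cohort.confounds, low_hz=config.low_hz, high_hz=config.high_hz
    )
    manifest.connectivity = stack

    for param in params:
        outcome = {"parameter": param, "n_rois": rois_per_param.get(param, 0)}
        scores = cohort.table.scores[param]
        component = nb.target_edge_count(
            stack,
            scores,
            target=config.target_edges,
            p_ceiling=config.primary_p,
            n_perm=config.n_perm,
            seed=config.child_seed(20),
            parameter=param,
            alpha=config.alpha,
        )
        outcome["network_found"] = component is not None
        if component is None:
            outcome.update(classifier_trained=False, classifier_significant=False)
            manifest.outcomes.append(outcome)
            continue
        manifest.networks[param] = component
        outcome["n_edges"] = component.n_edges
        outcome["fwe_p"] = component.fwe_p

        observed = scores.dropna()
        labels = cl.discretize(observed, n_classes=config.n_classes, parameter=param)
        feats_all = cl.component_features(stack, component)
        keep = [i for i, sid in enumerate(feats_all.subject_ids) if sid in observed.index]
        feats = cl.FeatureMatrix(
            values=feats_all.values[keep],
            edge_ids=feats_all.edge_ids,
            subject_ids=[feats_all.subject_ids[i] for i in keep],
        )
        model = cl.train_oaa_svm(
            feats, labels, c_grid=config.c_grid, gamma_grid=config.gamma_grid,
            seed=config.child_seed(30),
        )
        report = cl.loocv_evaluate(feats, labels, model.C, model.gamma)
        significant, p = cl.significance_vs_chance(report, alpha=config.alpha)
        manifest.models[param] = model
        manifest.reports[param] = report
        outcome.update(
            classifier_trained=True,
            classifier_significant=significant,
            accuracy_pct=report.accuracy_pct,
            sensitivity_pct=report.sensitivity_pct,
            specificity_pct=report.specificity_pct,
            p_vs_chance=p,
            best_c=model.C,
            best_gamma=model.gamma,
        )
        manifest.outcomes.append(outcome)
    manifest.validate()
    return manifest


def run_apply(
    config: PipelineConfig,
    models: dict,
    cohort: CohortData,
) -> RunManifest:
    """Apply trained classifiers to a new cohort (no regression or NBS).

    Connectivity is computed with the training preprocessing, the stored
    network edges are extracted as features, and each model predicts the
    new subjects' classes; supplied true scores are discretized with the
    stored training min/max for evaluation.
    """
    manifest = RunManifest(config=config)
    stack = compute_connectivity(
        cohort.series, cohort.confounds, low_hz=config.low_hz, high_hz=config.high_hz
    )
    manifest.connectivity = stack
    for param, model in models.items():
        pseudo = nb.NetworkComponent(parameter=param, edges=list(model.edge_ids), edge_t=np.array([]))
        feats = cl.component_features(stack, pseudo)
        scores = (
            cohort.table.scores[param] if param in cohort.table.parameters else None
        )
        if scores is not None:
            observed = scores.dropna()
            keep = [i for i, sid in enumerate(feats.subject_ids) if sid in observed.index]
            feats = cl.FeatureMatrix(
                values=feats.values[keep],
                edge_ids=feats.edge_ids,
                subject_ids=[feats.subject_ids[i] for i in keep],
            )
            preds, report = cl.apply_classifiers(feats, model, true_scores=observed)
        else:
            preds, report = cl.apply_classifiers(feats, model)
        outcome = {"parameter": param, "network_found": True, "classifier_trained": True}
        if report is not None:
            significant, p = cl.significance_vs_chance(report, alpha=config.alpha)
            manifest.reports[param] = report
            outcome.update(
                classifier_significant=significant,
                accuracy_pct=report.accuracy_pct,
                sensitivity_pct=report.sensitivity_pct,
                specificity_pct=report.specificity_pct,
                p_vs_chance=p,
            )
        manifest.outcomes.append(outcome)
    return manifest
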