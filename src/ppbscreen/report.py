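"""End-to-end orchestration and QC summaries.

``run_pipeline`` chains the stages in their canonical order:

    impurity correction -> low-intensity filter -> loading factors
    (cross-species peptides) -> apply factors -> mean-centering ->
    protein summarization (shared peptides only) -> absolute scaling ->
    null-model fit -> candidate calling

``qc_summary`` produces the standard sanity views of the protein table:
per-channel intensity distributions, a PCA of log2 relative profiles with
channels as observations, and average-linkage hierarchical clustering of
channels — replicate channels of a cell line with distinct binding should
co-cluster.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .call import call_candidates, estimate_null_model
from .io import (CandidateTable, ChannelLayout, ImpurityMatrix,
                 LoadingFactors, PPBScreenError, PSMTable,
                 ProteinQuantTable)
from .quantify import (correct_impurity, filter_psms, mean_center,
                       scale_absolute, summarize_proteins)
from .species_norm import apply_loading_factors, compute_loading_factors

logger = logging.getLogger("ppbscreen")

__all__ = ["PipelineParams", "PipelineResult", "run_pipeline",
           "qc_summary", "QCReport"]


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable of the end-to-end run, with study defaults."""

    min_intensity: float = 1000.0
    median_intensity: float = 5000.0
    impurity_mode: str = "invert"
    species_normalize: bool = True
    min_support: int = 10
    abundance_rank: str = "mean"
    scale_scope: str = "protein"
    null_estimator: str = "mle"
    fdr_threshold: float = 0.01
    z_threshold: float = 3.0
    fc_rule: str = "max"


@dataclass
class PipelineResult:
    proteins: ProteinQuantTable
    candidates: CandidateTable
    loading_factors: LoadingFactors | None
    log: list[str] = field(default_factory=list)


def run_pipeline(psms: PSMTable, layout: ChannelLayout,
                 impurity: ImpurityMatrix | None = None,
                 params: PipelineParams | None = None) -> PipelineResult:
    """Run quantification, normalization and candidate calling.

    Deterministic given fixed inputs.  Any stage failure is re-raised with
    the stage name prepended.
    """
    params = params or PipelineParams()
    log: list[str] = [f"params: {params}"]

    def stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except PPBScreenError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc
        log.append(f"{name}: ok")
        return out

    if impurity is not None:
        psms = stage("impurity_correction", correct_impurity, psms, impurity,
                     params.impurity_mode)
    else:
        log.append("impurity_correction: skipped (identity)")
    psms = stage("low_intensity_filter", filter_psms, psms,
                 params.min_intensity, params.median_intensity)
    log.append(f"low_intensity_filter: {len(psms)} PSMs retained")

    factors = None
    if params.species_normalize:
        factors = stage("loading_factors", compute_loading_factors, psms,
                        layout, params.min_support)
        psms = stage("apply_loading_factors", apply_loading_factors, psms,
                     factors)
    raw_for_scale = psms
    psms = stage("mean_center", mean_center, psms)
    proteins = stage("summarize_proteins", summarize_proteins, psms, layout)
    proteins = stage("scale_absolute", scale_absolute, proteins,
                     raw_for_scale, True, params.abundance_rank,
                     params.scale_scope)
    null = stage("null_model", estimate_null_model, proteins, layout,
                 params.null_estimator)
    log.append(f"null_model: mu0={null.mu0:.4g} sigma0={null.sigma0:.4g} "
               f"n={null.n_ratios}")
    candidates = stage("call_candidates", call_candidates, proteins, layout,
                       null, params.fdr_threshold, params.z_threshold,
                       params.fc_rule)
    log.append(f"call_candidates: {int(candidates.data['is_candidate'].sum())}"
               f" candidates / {len(candidates)} proteins")
    return PipelineResult(proteins, candidates, factors, log)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    channel_stats: pd.DataFrame            # per-channel summary of absolutes
    pca_coordinates: pd.DataFrame | None   # channels x PC1/PC2
    pca_variance_fractions: np.ndarray | None
    linkage: np.ndarray                    # scipy linkage matrix of channels
    channel_order: tuple[str, ...]
    composition: pd.Series | None = None   # compartment -> fraction


def _table_digest(table: ProteinQuantTable) -> str:
    h = hashlib.sha256()
    h.update(table.relative.to_csv().encode())
    if table.absolute is not None:
        h.update(table.absolute.to_csv().encode())
    return h.hexdigest()


def qc_summary(table: ProteinQuantTable, layout: ChannelLayout,
               out_dir: str | Path | None = None,
               compartments: pd.Series | None = None) -> QCReport:
    """Summaries of a protein table: distributions, PCA, clustering.

    PCA treats channels as observations and log2 relative profiles as
    features; the first two component coordinates and the variance
    fractions are reported, with each component's sign fixed so its
    largest-magnitude loading is positive.  Hierarchical clustering is
    average-linkage on Euclidean distances of the same profiles.  The input
    table is never mutated.  Plots and machine-readable TSVs are written to
    ``out_dir`` when given.
    """
    if len(table) < 2:
        raise PPBScreenError("qc_summary needs at least 2 proteins")
    digest = _table_digest(table)
    channels = list(table.channels)

    source = table.absolute if table.absolute is not None else table.relative
    channel_stats = source.describe().T
    channel_stats.index.name = "channel"

    log2rel = np.log2(table.relative.to_numpy(dtype=float)).T  # channels x prot
    centered = log2rel - log2rel.mean(axis=0, keepdims=True)

    pca_coords = None
    var_frac = None
    if np.ptp(centered) > 0:
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        scores = u * s                      # channel coordinates
        for comp in range(vt.shape[0]):     # sign convention
            j = int(np.argmax(np.abs(vt[comp])))
            if vt[comp, j] < 0:
                vt[comp] *= -1.0
                scores[:, comp] *= -1.0
        total = float((s ** 2).sum())
        var_frac = (s ** 2) / total
        n_keep = min(2, scores.shape[1])
        pca_coords = pd.DataFrame(
            scores[:, :n_keep], index=pd.Index(channels, name="channel"),
            columns=[f"PC{i + 1}" for i in range(n_keep)])
        var_frac = var_frac[:n_keep]
    else:
        logger.warning("qc_summary: constant relative matrix; PCA skipped")

    dist = scipy.spatial.distance.pdist(log2rel, metric="euclidean")
    linkage = scipy.cluster.hierarchy.linkage(dist, method="average")

    composition = None
    if compartments is not None:
        matched = compartments.reindex(table.proteins).dropna()
        if len(matched):
            composition = matched.value_counts(normalize=True)

    if _table_digest(table) != digest:      # pragma: no cover - invariant
        raise PPBScreenError("qc_summary mutated its input table")

    report = QCReport(channel_stats, pca_coords, var_frac, linkage,
                      tuple(channels), composition)
    if out_dir is not None:
        _write_qc(report, table, Path(out_dir))
    return report


def _write_qc(report: QCReport, table: ProteinQuantTable,
              out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    report.channel_stats.to_csv(out_dir / "channel_stats.tsv", sep="\t")
    if report.pca_coordinates is not None:
        report.pca_coordinates.to_csv(out_dir / "pca_coordinates.tsv",
                                      sep="\t")
        fig, ax = plt.subplots(figsize=(5, 4))
        pcs = report.pca_coordinates
        ax.scatter(pcs.iloc[:, 0], pcs.iloc[:, 1])
        for ch, row in pcs.iterrows():
            ax.annotate(ch, (row.iloc[0], row.iloc[1]), fontsize=8)
        vf = report.pca_variance_fractions
        ax.set_xlabel(f"PC1 ({vf[0]:.1%})")
        if len(vf) > 1:
            ax.set_ylabel(f"PC2 ({vf[1]:.1%})")
        fig.tight_layout()
        fig.savefig(out_dir / "pca.png", dpi=120)
        plt.close(fig)
    if report.composition is not None:
        report.composition.rename("fraction").to_csv(
            out_dir / "composition.tsv", sep="\t")

    fig, ax = plt.subplots(figsize=(6, 4))
    scipy.cluster.hierarchy.dendrogram(report.linkage,
                                       labels=list(report.channel_order),
                                       ax=ax)
    ax.set_ylabel("Euclidean distance (log2 profiles)")
    fig.tight_layout()
    fig.savefig(out_dir / "clustering.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    source = table.absolute if table.absolute is not None else table.relative
    ax.boxplot([np.log2(source[c][source[c] > 0]) for c in table.channels],
               tick_labels=list(table.channels))
    ax.set_ylabel("log2 intensity")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(out_dir / "channel_intensity.png", dpi=120)
    plt.close(fig)
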