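"""Reporter-ion quantification: impurity correction, low-intensity
filtering, mean-centering, protein summarization and absolute scaling.

The stage order follows the standard isobaric-tag workflow: raw reporter
intensities are first corrected for isotopologue spill-over by solving the
mixing system, PSMs of very low intensity are excluded, each PSM is
mean-centered across channels to a relative profile, protein relative
intensities are the unweighted mean of their shared-specificity PSMs, and
an absolute scale — the grand mean of the protein's three most abundant
PSMs — converts relative profiles back to intensity units.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .io import (ChannelLayout, ConsistencyError, ContractError,
                 DegeneracyError, ImpurityMatrix, NumericalError, PSMTable,
                 ProteinQuantTable)

logger = logging.getLogger("ppbscreen")

__all__ = ["correct_impurity", "filter_psms", "mean_center",
           "summarize_proteins", "scale_absolute", "greedy_parsimony"]


def correct_impurity(psms: PSMTable, matrix: ImpurityMatrix,
                     mode: str = "invert") -> PSMTable:
    """Undo reporter isotopologue spill-over.

    Solves ``observed = M @ true`` for each PSM's channel vector.  In
    ``invert`` mode the linear solution is used and negative components are
    clamped to 0 (flagged in an ``impurity_clamped`` column); ``nnls`` mode
    solves under a non-negativity constraint instead.
    """
    if matrix.k != len(psms.channels):
        raise ContractError(
            f"impurity matrix is {matrix.k}x{matrix.k} but table has "
            f"{len(psms.channels)} channels")
    observed = psms.intensities
    m = matrix.matrix
    if mode == "invert":
        if matrix.is_singular:
            raise NumericalError(
                "impurity matrix is singular; use mode='nnls'")
        try:
            true = scipy.linalg.solve(m, observed.T).T
        except scipy.linalg.LinAlgError as exc:
            raise NumericalError(
                f"impurity matrix could not be inverted ({exc}); "
                "use mode='nnls'") from exc
        clamped = (true < 0).any(axis=1)
        np.clip(true, 0.0, None, out=true)
    elif mode == "nnls":
        true = np.empty_like(observed)
        for i in range(observed.shape[0]):
            true[i], _ = scipy.optimize.nnls(m, observed[i])
        clamped = np.zeros(observed.shape[0], dtype=bool)
    else:
        raise ContractError(f"unknown impurity mode {mode!r}")
    if clamped.any():
        logger.info("impurity correction clamped negatives in %d/%d PSMs",
                    int(clamped.sum()), len(clamped))
    return psms.with_intensities(true, extra_meta={"impurity_clamped": clamped})


def filter_psms(psms: PSMTable, min_intensity: float = 1000.0,
                median_intensity: float = 5000.0) -> PSMTable:
    """Exclude PSMs of very low intensity.

    A PSM is retained iff its minimum intensity across channels is at least
    ``min_intensity`` and its median is at least ``median_intensity``
    (inclusive thresholds).
    """
    inten = psms.intensities
    keep = (inten.min(axis=1) >= min_intensity) & \
           (np.median(inten, axis=1) >= median_intensity)
    logger.info("low-intensity filter: retained %d, excluded %d PSMs",
                int(keep.sum()), int((~keep).sum()))
    return PSMTable(psms.data.loc[keep].reset_index(drop=True), psms.channels)


def mean_center(psms: PSMTable) -> PSMTable:
    """Divide each PSM's intensities by its across-channel mean.

    Output rows are relative profiles averaging exactly 1.  Rows with a
    non-positive mean cannot occur after filtering with a positive
    ``min_intensity`` and indicate a pipeline-order bug.
    """
    inten = psms.intensities
    means = inten.mean(axis=1)
    if (means <= 0).any():
        raise DegeneracyError(
            "PSM with non-positive mean intensity reached mean_center; "
            "filter_psms must run first")
    return psms.with_intensities(inten / means[:, None])


def summarize_proteins(psms: PSMTable, layout: ChannelLayout,
                       use_only_shared: bool = True) -> ProteinQuantTable:
    """Average mean-centered PSM profiles into protein relative profiles.

    To avoid quantification bias from species-specific peptides, only PSMs
    of shared (cross-species homologous) peptides contribute when
    ``use_only_shared`` is set; proteins left without eligible PSMs are
    omitted (and logged).  Grouping is by ``canonical_protein`` — the
    parsimony assignment is accepted as input.
    """
    data = psms.data
    if use_only_shared:
        eligible = data[data["species_specificity"] == "shared"]
        omitted = data.loc[
            ~data["canonical_protein"].isin(eligible["canonical_protein"]),
            "canonical_protein"].unique()
        if len(omitted):
            logger.info("summarize_proteins: %d proteins without shared-"
                        "specificity PSMs omitted", len(omitted))
    else:
        eligible = data
    grouped = eligible.groupby("canonical_protein", sort=True)
    relative = grouped[list(psms.channels)].mean()
    relative.index.name = "protein"
    # PSM rows average 1, so their mean does too; renormalize the residual
    # float error away so the table invariant holds to 1e-12
    relative = relative.div(relative.mean(axis=1), axis=0)
    n_psms = grouped.size()
    n_psms.index.name = "protein"
    return ProteinQuantTable(relative, n_psms.astype(int))


def scale_absolute(table: ProteinQuantTable, psms_raw: PSMTable,
                   use_only_shared: bool = True, abundance_rank: str = "mean",
                   scope: str = "protein") -> ProteinQuantTable:
    """Attach absolute intensities: relative x grand mean of top-3 PSMs.

    ``psms_raw`` must be the post-filter, pre-centering table of the same
    run.  A PSM's abundance is its across-channel ``mean`` (or ``sum`` or
    ``max``); each protein's scale is the mean of its top min(3, n) PSM
    abundances.  ``scope='global'`` instead uses one table-wide scale.
    """
    data = psms_raw.data
    if use_only_shared:
        data = data[data["species_specificity"] == "shared"]
    inten = data[list(psms_raw.channels)].to_numpy(dtype=float)
    if abundance_rank == "mean":
        abundance = inten.mean(axis=1)
    elif abundance_rank == "sum":
        abundance = inten.sum(axis=1)
    elif abundance_rank == "max":
        abundance = inten.max(axis=1)
    else:
        raise ContractError(f"unknown abundance_rank {abundance_rank!r}")
    ab = pd.Series(abundance, index=data["canonical_protein"].to_numpy())

    if scope == "global":
        top = np.sort(ab.to_numpy())[::-1][:3]
        scale = pd.Series(float(top.mean()), index=table.proteins)
    elif scope == "protein":
        missing = table.proteins.difference(pd.Index(ab.index).unique())
        if len(missing):
            raise ConsistencyError(
                f"proteins absent from raw PSM table: {list(missing)[:5]}")
        scale = (ab.groupby(level=0)
                   .apply(lambda v: float(np.sort(v.to_numpy())[::-1][:3].mean()))
                   .reindex(table.proteins))
    else:
        raise ContractError(f"unknown scope {scope!r}")
    absolute = table.relative.mul(scale, axis=0)
    return ProteinQuantTable(table.relative, table.n_psms, absolute)


def greedy_parsimony(peptide_to_proteins: dict[str, set[str] | list[str]]
                     ) -> dict[str, str]:
    """Collapse a peptide -> candidate-protein multimap to one canonical
    protein per peptide by greedy maximal coverage.

    Repeatedly picks the protein explaining the most unassigned peptides
    (ties broken lexicographically for determinism) and assigns those
    peptides to it.  Optional helper: pipelines normally receive the
    ``canonical_protein`` assignment precomputed by the search engine.
    """
    remaining = {p: set(prots) for p, prots in peptide_to_proteins.items()}
    for pep, prots in remaining.items():
        if not prots:
            raise ContractError(f"peptide {pep!r} has no candidate proteins")
    assignment: dict[str, str] = {}
    while remaining:
        coverage: dict[str, int] = {}
        for prots in remaining.values():
            for prot in prots:
                coverage[prot] = coverage.get(prot, 0) + 1
        best = max(sorted(coverage), key=coverage.get)
        for pep in [p for p, prots in remaining.items() if best in prots]:
            assignment[pep] = best
            del remaining[pep]
    return assignment
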