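"""Loading-bias correction via cross-species-specific peptides.

Pulldown experiments violate the equal-input assumption behind ordinary
loading normalization: channels legitimately differ in total captured
material.  Pooling human and mouse cell lines into one multiplexed run
provides internal blanks — a mouse-specific peptide carries only background
signal in a human cell line, so its median signal there, relative to the
first blank channel, measures that channel's loading bias independent of
biology.

For a human-line channel c the factor is

    f_c = median_i(x_i[c]) / median_i(x_i[ref])

over the mouse-specific PSMs i, with ``ref`` the first blank channel;
symmetrically with human-specific peptides for mouse-line channels.
Non-reference blank channels — where the original definition is silent —
use the pooled union of both species-specific PSM sets, since every
species-specific peptide is background in every blank.  The reference
blank's factor is exactly 1.  Factors are computed on post-filter,
pre-centering intensities and applied at the PSM level before
mean-centering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import (ChannelLayout, LayoutError, LoadingFactors,
                 NormalizationError, NumericalError, PSMTable)

logger = logging.getLogger("ppbscreen")

__all__ = ["compute_loading_factors", "apply_loading_factors"]

# which peptide-specificity class acts as internal blank for each species
_OPPOSITE = {"human": "mouse", "mouse": "human"}


def compute_loading_factors(psms: PSMTable, layout: ChannelLayout,
                            min_support: int = 10) -> LoadingFactors:
    """Per-channel median-ratio loading factors from cross-species PSMs.

    ``psms`` must be post-filter, pre-centering intensities.  Channels
    supported by fewer than ``min_support`` PSMs are flagged (warning), not
    rejected — medians of tiny sets are unstable.
    """
    layout.validate_for_species_norm()
    ref = layout.blank_reference
    data = psms.data
    spec = data["species_specificity"]

    sets = {cls: data.loc[spec == cls, list(psms.channels)]
            for cls in ("human", "mouse")}
    pooled = data.loc[spec != "shared", list(psms.channels)]

    factors, n_used, cls_used = {}, {}, {}

    def _factor(subset: pd.DataFrame, channel: str, label: str) -> float:
        if len(subset) == 0:
            raise NormalizationError(
                f"no {label} PSMs available to normalize channel {channel!r}")
        num = float(np.median(subset[channel].to_numpy()))
        den = float(np.median(subset[ref].to_numpy()))
        if den <= 0:
            raise NumericalError(
                f"zero median in reference blank {ref!r} for the {label} "
                f"PSM set of channel {channel!r}")
        return num / den

    for ch in psms.channels:
        role = layout.roles[ch]
        if role.kind == "sample":
            cls = _OPPOSITE[layout.species[role.cell_line]]
            subset = sets[cls]
            factors[ch] = _factor(subset, ch, f"{cls}-specific")
            n_used[ch], cls_used[ch] = len(subset), cls
        elif ch == ref:
            factors[ch] = 1.0
            n_used[ch], cls_used[ch] = len(pooled), "pooled"
        else:
            factors[ch] = _factor(pooled, ch, "species-specific (pooled)")
            n_used[ch], cls_used[ch] = len(pooled), "pooled"

    idx = pd.Index(psms.channels, name="channel")
    result = LoadingFactors(
        factors=pd.Series(factors, index=idx, dtype=float),
        reference=ref,
        n_psms=pd.Series(n_used, index=idx, dtype=int),
        specificity_class=pd.Series(cls_used, index=idx),
        min_support=min_support)
    logger.info("loading factors: %s",
                ", ".join(f"{c}={f:.3f}" for c, f in result.factors.items()))
    return result


def apply_loading_factors(psms: PSMTable,
                          factors: LoadingFactors) -> PSMTable:
    """Divide every intensity in channel c by its loading factor f_c.

    Re-computing factors on the output yields 1 for every channel (to float
    precision) on noise-free data — the correction is a fixed point.
    """
    if set(factors.factors.index) != set(psms.channels):
        raise LayoutError("loading factors do not cover the table's channels")
    f = factors.factors.reindex(list(psms.channels)).to_numpy()
    return psms.with_intensities(psms.intensities / f[None, :])
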