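"""Synthetic two-species multiplexed pulldown experiments with ground truth.

The generator reproduces the statistical structure the downstream analysis
assumes: a two-species (human + mouse) pulldown multiplexed into one
isobaric-tag run, with sample channels in duplicate per cell line and blank
negative controls.  Peptides fall into three classes — human-specific,
mouse-specific and shared — and a species-specific peptide measured in a
wrong-species cell line (or a blank) carries only blank-like background
signal, which is exactly the property the loading-bias normalization
exploits.

Signal model, on the log2 scale, for a PSM of protein P in channel c:

* shared peptide, sample channel of line l:
  ``base + effect(P, l) + log2(bias_c) + noise``
* shared peptide, blank channel: ``base + log2(bias_c) + noise``
* species-specific peptide, same-species sample channel:
  ``base + effect(P, l) + log2(bias_c) + noise``
* species-specific peptide elsewhere (wrong species or blank):
  ``background + log2(bias_c) + noise``

Intensities are exponentiated, optionally mixed through a reporter
impurity matrix, and finally censored to 0 below ``censor_threshold``.
Noise is Gaussian on log2 intensities (log-normal on the raw scale), which
makes the pooled-t normality assumption of the caller exactly satisfiable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (ChannelLayout, ConfigError, ImpurityMatrix, PSMTable,
                 SimulationTruth)

__all__ = ["SimConfig", "simulate_experiment"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.  Defaults are the reference study conditions:
    1000 proteins, 5% binders per cell line at log2 fold change 3, log2
    noise SD 0.15, per-channel loading biases drawn uniformly in [0.5, 2].

    ``effect_size`` is either a scalar log2 fold change or a
    ``(mean, sd)`` pair for Gaussian per-(protein, line) effects.
    ``loading_bias`` is ``None`` (all 1), a ``(low, high)`` sampling range,
    or an explicit channel -> multiplier mapping.
    ``base_intensity`` and ``blank_background`` are (location, scale) of
    log2-normal PSM abundances; the defaults put full signal around 2^16
    and background around 2^13.5, both clearing the downstream low-intensity
    filter under typical biases.
    """

    n_proteins: int = 1000
    fraction_shared_peptide_proteins: float = 1.0
    shared_peptide_fraction: float = 0.5
    peptides_per_protein: tuple[int, int] = (3, 6)
    psms_per_peptide: tuple[int, int] = (1, 3)
    human_fraction: float = 0.5
    binder_fraction: float = 0.05
    effect_size: float | tuple[float, float] = 3.0
    noise_sd: float = 0.15
    loading_bias: Mapping[str, float] | tuple[float, float] | None = (0.5, 2.0)
    base_intensity: tuple[float, float] = (16.0, 1.0)
    blank_background: tuple[float, float] = (13.5, 0.75)
    censor_threshold: float = 0.0
    impurity: ImpurityMatrix | None = None
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("fraction_shared_peptide_proteins",
                     "shared_peptide_fraction", "human_fraction",
                     "binder_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        lo, hi = self.peptides_per_protein
        if not 1 <= lo <= hi:
            raise ConfigError("peptides_per_protein range invalid")
        lo, hi = self.psms_per_peptide
        if not 1 <= lo <= hi:
            raise ConfigError("psms_per_peptide range invalid")

    def echo(self) -> dict:
        d = asdict(self)
        if isinstance(self.impurity, ImpurityMatrix):
            d["impurity"] = self.impurity.matrix.tolist()
        if isinstance(self.loading_bias, Mapping):
            d["loading_bias"] = dict(self.loading_bias)
        return d


def _draw_bias(config: SimConfig, channels: Sequence[str],
               rng: np.random.Generator) -> pd.Series:
    lb = config.loading_bias
    if lb is None:
        vals = np.ones(len(channels))
    elif isinstance(lb, Mapping):
        missing = [c for c in channels if c not in lb]
        if missing:
            raise ConfigError(f"loading_bias missing channels {missing}")
        vals = np.array([float(lb[c]) for c in channels])
        if (vals <= 0).any():
            raise ConfigError("loading-bias multipliers must be positive")
    else:
        lo, hi = lb
        if not 0 < lo <= hi:
            raise ConfigError("loading_bias range must satisfy 0 < low <= high")
        vals = rng.uniform(lo, hi, size=len(channels))
    return pd.Series(vals, index=list(channels), name="loading_bias")


def simulate_experiment(config: SimConfig, layout: ChannelLayout
                        ) -> tuple[PSMTable, SimulationTruth]:
    """Generate one synthetic experiment and its ground truth.

    Deterministic given ``config.seed``; all draws flow from one seeded
    generator, so identical configs produce byte-identical tables.
    """
    species_present = set(layout.species.values())
    if config.fraction_shared_peptide_proteins < 1.0 or \
            config.shared_peptide_fraction < 1.0:
        # species-specific peptides will be generated; they are only
        # meaningful (and usable by normalization) with both species present
        if len(species_present) < 2:
            raise ConfigError(
                "layout has a single species; species-specific peptides and "
                "loading normalization require cell lines of both species")

    rng = np.random.default_rng(config.seed)
    channels = list(layout.channels)
    k = len(channels)
    lines = list(layout.cell_lines)

    # --- protein-level truth ------------------------------------------------
    n = config.n_proteins
    prot_ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])
    prot_species = np.where(rng.random(n) < config.human_fraction,
                            "human", "mouse")
    shared_class = rng.random(n) < config.fraction_shared_peptide_proteins

    binders = rng.random((n, len(lines))) < config.binder_fraction
    if np.isscalar(config.effect_size):
        effects = np.where(binders, float(config.effect_size), 0.0)
    else:
        mean, sd = config.effect_size
        effects = np.where(binders,
                           rng.normal(mean, sd, size=binders.shape), 0.0)

    bias = _draw_bias(config, channels, rng)
    log2_bias = np.log2(bias.to_numpy())

    # --- peptide and PSM structure -------------------------------------------
    pep_lo, pep_hi = config.peptides_per_protein
    n_pep = rng.integers(pep_lo, pep_hi + 1, size=n)
    pep_protein = np.repeat(np.arange(n), n_pep)
    pep_rank = np.concatenate([np.arange(m) for m in n_pep])
    # peptide class: within shared-class proteins each peptide is shared with
    # probability shared_peptide_fraction, first peptide forced shared so the
    # protein is quantifiable; other proteins carry only specific peptides
    pep_shared = rng.random(len(pep_protein)) < config.shared_peptide_fraction
    pep_shared[pep_rank == 0] = True
    pep_shared &= shared_class[pep_protein]

    psm_lo, psm_hi = config.psms_per_peptide
    n_psm_per_pep = rng.integers(psm_lo, psm_hi + 1, size=len(pep_protein))
    psm_pep = np.repeat(np.arange(len(pep_protein)), n_psm_per_pep)
    psm_protein = pep_protein[psm_pep]
    psm_shared = pep_shared[psm_pep]
    psm_species = prot_species[psm_protein]
    n_psms = len(psm_pep)

    base_loc, base_scale = config.base_intensity
    bg_loc, bg_scale = config.blank_background
    base = rng.normal(base_loc, base_scale, size=n_psms)
    background = rng.normal(bg_loc, bg_scale, size=n_psms)

    # --- assemble log2 intensity matrix --------------------------------------
    # full[i, c]: signal a PSM would carry if its peptide is observable in c
    full = np.tile(base[:, None], (1, k))
    for j, line in enumerate(lines):
        cols = [channels.index(c) for c in layout.sample_channels(line)]
        full[:, cols] += effects[psm_protein, j][:, None]

    # observable[i, c]: shared peptides everywhere; specific peptides only in
    # same-species sample channels
    observable = np.zeros((n_psms, k), dtype=bool)
    observable[psm_shared, :] = True
    for sp in ("human", "mouse"):
        cols = [channels.index(c) for c in layout.channels_of_species(sp)]
        if cols:
            rows = (~psm_shared) & (psm_species == sp)
            observable[np.ix_(rows, cols)] = True

    log2_int = np.where(observable, full, background[:, None])
    log2_int = log2_int + log2_bias[None, :]
    if config.noise_sd > 0:
        log2_int = log2_int + rng.normal(0.0, config.noise_sd,
                                         size=log2_int.shape)

    raw = np.exp2(log2_int)
    if config.impurity is not None:
        if config.impurity.k != k:
            raise ConfigError("impurity matrix dimension != channel count")
        raw = raw @ config.impurity.matrix.T
    if config.censor_threshold > 0:
        raw[raw < config.censor_threshold] = 0.0

    # --- tables ---------------------------------------------------------------
    specificity = np.where(psm_shared, "shared", psm_species)
    data = pd.DataFrame({
        "psm_id": [f"PSM{i:06d}" for i in range(1, n_psms + 1)],
        "peptide": [f"pep_{p:05d}" for p in psm_pep + 1],
        "protein": prot_ids[psm_protein],
        "canonical_protein": prot_ids[psm_protein],
        "species_specificity": specificity,
    })
    data[channels] = raw
    psms = PSMTable(data, tuple(channels))

    idx = pd.Index(prot_ids, name="protein")
    truth = SimulationTruth(
        protein_species=pd.Series(prot_species, index=idx, name="species"),
        binders=pd.DataFrame(binders, index=idx, columns=lines),
        effects=pd.DataFrame(effects, index=idx, columns=lines),
        loading_bias=bias,
        seed=config.seed,
        config=config.echo(),
    )
    return psms, truth
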