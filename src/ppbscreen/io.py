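"""Domain types, validation, and plain-text readers/writers.

Every on-disk artifact of the pipeline is plain text: PSM tables and truth
tables are TSV, impurity matrices are headerless CSV, channel layouts are
JSON.  The pipeline begins *after* peptide-spectrum matching — no raw
mass-spec formats are touched.

The central objects are:

* :class:`ChannelLayout` — which multiplex channel holds which cell line /
  replicate / blank, and each cell line's species.
* :class:`PSMTable` — one row per peptide-spectrum match with a reporter
  intensity per channel plus peptide/protein/species-specificity metadata.
* :class:`ImpurityMatrix` — the reporter isotopologue mixing matrix.
* :class:`ProteinQuantTable`, :class:`CandidateTable`, :class:`NullModel`,
  :class:`LoadingFactors`, :class:`SimulationTruth` — downstream results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("ppbscreen")

SPECIES = ("human", "mouse")
SPECIFICITY_CLASSES = ("human", "mouse", "shared")

#: Required metadata columns of a PSM table, in canonical order.
META_COLUMNS = ("psm_id", "peptide", "protein", "canonical_protein",
                "species_specificity")
#: Optional metadata columns that are preserved on round trip.
OPTIONAL_META_COLUMNS = ("impurity_clamped",)

#: Reporter labels of the TMT 11-plex, in mass order.
TMT11_LABELS = ("126", "127N", "127C", "128N", "128C", "129N", "129C",
                "130N", "130C", "131N", "131C")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PPBScreenError(Exception):
    """Base class for all typed pipeline errors."""


class FormatError(PPBScreenError):
    """A file does not conform to its documented plain-text format."""


class LayoutError(PPBScreenError):
    """Channel layout is invalid or inconsistent with a table."""


class ConfigError(PPBScreenError):
    """A configuration object violates its contract."""


class NumericalError(PPBScreenError):
    """A numerical degeneracy (singular matrix, zero median, ...)."""


class NormalizationError(PPBScreenError):
    """Species normalization cannot be computed for a channel."""


class ConsistencyError(PPBScreenError):
    """Two artifacts that must describe the same run do not."""


class DegeneracyError(PPBScreenError):
    """Input data are degenerate for the requested estimator."""


class ContractError(PPBScreenError):
    """An operation was called with arguments outside its contract."""


# ---------------------------------------------------------------------------
# ChannelLayout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelRole:
    """Role of one multiplex channel: a cell-line replicate or a blank."""

    kind: str                     # "sample" | "blank"
    cell_line: str | None = None
    replicate: int | None = None
    blank_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "sample":
            if not self.cell_line or not self.replicate:
                raise LayoutError("sample channel needs cell_line and replicate")
        elif self.kind == "blank":
            if not self.blank_index:
                raise LayoutError("blank channel needs blank_index")
        else:
            raise LayoutError(f"unknown channel role kind {self.kind!r}")


@dataclass(frozen=True)
class ChannelLayout:
    """Maps multiplex channels to experimental roles.

    The reference design is the 11-plex pulldown: four cell lines (two human,
    two mouse) in duplicate plus three blank negative controls.  Any layout
    with >= 5 channels, >= 2 cell lines, >= 2 replicates per line and
    >= 2 blanks validates.
    """

    channels: tuple[str, ...]
    roles: Mapping[str, ChannelRole]
    species: Mapping[str, str]           # cell line -> "human" | "mouse"
    blank_reference: str

    def __post_init__(self) -> None:
        if len(self.channels) != len(set(self.channels)):
            raise LayoutError("duplicate channel labels")
        if len(self.channels) < 5:
            raise LayoutError("layout needs at least 5 channels")
        if set(self.roles) != set(self.channels):
            raise LayoutError("roles must cover exactly the layout channels")

        lines: dict[str, list[int]] = {}
        blanks: list[int] = []
        for ch in self.channels:
            role = self.roles[ch]
            if role.kind == "sample":
                lines.setdefault(role.cell_line, []).append(role.replicate)
            else:
                blanks.append(role.blank_index)
        if len(lines) < 2:
            raise LayoutError("layout needs at least 2 cell lines")
        rep_counts = {line: len(reps) for line, reps in lines.items()}
        if len(set(rep_counts.values())) != 1:
            raise LayoutError(f"unequal replicate counts per cell line: {rep_counts}")
        n_rep = next(iter(rep_counts.values()))
        if n_rep < 2:
            raise LayoutError("layout needs at least 2 replicates per cell line")
        for line, reps in lines.items():
            if sorted(reps) != list(range(1, n_rep + 1)):
                raise LayoutError(f"replicate indices of {line} must be 1..{n_rep}")
        if len(blanks) < 2:
            raise LayoutError("layout needs at least 2 blank channels")
        if sorted(blanks) != list(range(1, len(blanks) + 1)):
            raise LayoutError("blank indices must be 1..n_blanks")
        if set(self.species) != set(lines):
            raise LayoutError("species map must cover exactly the cell lines")
        for line, sp in self.species.items():
            if sp not in SPECIES:
                raise LayoutError(f"unknown species {sp!r} for cell line {line}")
        ref_role = self.roles.get(self.blank_reference)
        if ref_role is None or ref_role.kind != "blank" or ref_role.blank_index != 1:
            raise LayoutError("blank_reference must be the channel of blank 1")

    # -- convenience accessors ------------------------------------------------

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def cell_lines(self) -> tuple[str, ...]:
        seen: list[str] = []
        for ch in self.channels:
            role = self.roles[ch]
            if role.kind == "sample" and role.cell_line not in seen:
                seen.append(role.cell_line)
        return tuple(seen)

    def sample_channels(self, cell_line: str) -> list[str]:
        chs = [(self.roles[c].replicate, c) for c in self.channels
               if self.roles[c].kind == "sample"
               and self.roles[c].cell_line == cell_line]
        if not chs:
            raise LayoutError(f"unknown cell line {cell_line!r}")
        return [c for _, c in sorted(chs)]

    def blank_channels(self) -> list[str]:
        chs = [(self.roles[c].blank_index, c) for c in self.channels
               if self.roles[c].kind == "blank"]
        return [c for _, c in sorted(chs)]

    def channels_of_species(self, species: str) -> list[str]:
        return [c for c in self.channels
                if self.roles[c].kind == "sample"
                and self.species[self.roles[c].cell_line] == species]

    def validate_for_species_norm(self) -> None:
        """Species normalization needs at least one cell line of each species."""
        present = set(self.species.values())
        if present != set(SPECIES):
            raise ConfigError(
                "species normalization requires cell lines of both species; "
                f"layout has only {sorted(present)}")

    # -- JSON (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        chans = []
        for ch in self.channels:
            role = self.roles[ch]
            if role.kind == "sample":
                chans.append({"label": ch, "role": "sample",
                              "cell_line": role.cell_line,
                              "replicate": role.replicate})
            else:
                chans.append({"label": ch, "role": "blank",
                              "blank_index": role.blank_index})
        return {"channels": chans,
                "cell_lines": {line: {"species": sp}
                               for line, sp in self.species.items()},
                "blank_reference": self.blank_reference}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChannelLayout":
        try:
            channels = tuple(c["label"] for c in d["channels"])
            roles = {}
            for c in d["channels"]:
                if c["role"] == "sample":
                    roles[c["label"]] = ChannelRole(
                        "sample", cell_line=c["cell_line"],
                        replicate=int(c["replicate"]))
                else:
                    roles[c["label"]] = ChannelRole(
                        "blank", blank_index=int(c["blank_index"]))
            species = {line: v["species"]
                       for line, v in d["cell_lines"].items()}
            blank_reference = d["blank_reference"]
        except (KeyError, TypeError) as exc:
            raise FormatError(f"malformed layout descriptor: {exc}") from exc
        return cls(channels, roles, species, blank_reference)


def default_layout() -> ChannelLayout:
    """The study's 11-plex design: HepG2/U251 (human) and NIH3T3/MEL (mouse)
    in duplicate, three blanks, blank 1 as normalization reference."""
    lines = [("HepG2", "human"), ("U251", "human"),
             ("NIH3T3", "mouse"), ("MEL", "mouse")]
    roles: dict[str, ChannelRole] = {}
    i = 0
    for line, _sp in lines:
        for rep in (1, 2):
            roles[TMT11_LABELS[i]] = ChannelRole("sample", cell_line=line,
                                                 replicate=rep)
            i += 1
    for b in (1, 2, 3):
        roles[TMT11_LABELS[i]] = ChannelRole("blank", blank_index=b)
        i += 1
    return ChannelLayout(TMT11_LABELS, roles,
                         dict(lines), blank_reference=TMT11_LABELS[8])


def read_layout(path) -> ChannelLayout:
    with open(path) as fh:
        return ChannelLayout.from_dict(json.load(fh))


def write_layout(layout: ChannelLayout, path) -> None:
    with open(path, "w") as fh:
        json.dump(layout.to_dict(), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# PSMTable
# ---------------------------------------------------------------------------

@dataclass
class PSMTable:
    """Per-PSM reporter intensities plus identification metadata.

    ``data`` holds the required metadata columns, any recognised optional
    columns, then one float column per layout channel — in that order.
    """

    data: pd.DataFrame
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        for col in META_COLUMNS:
            if col not in cols:
                raise FormatError(f"PSM table missing required column {col!r}")
        for ch in self.channels:
            if ch not in cols:
                raise LayoutError(f"PSM table missing intensity column {ch!r}")
        optional = [c for c in OPTIONAL_META_COLUMNS if c in cols]
        ordered = list(META_COLUMNS) + optional + list(self.channels)
        if cols != ordered:
            self.data = self.data[ordered]
        bad = ~self.data["species_specificity"].isin(SPECIFICITY_CLASSES)
        if bad.any():
            val = self.data.loc[bad, "species_specificity"].iloc[0]
            raise FormatError(f"invalid species_specificity value {val!r}")
        inten = self.data[list(self.channels)].to_numpy()
        if not np.issubdtype(inten.dtype, np.number):
            raise FormatError("intensity columns must be numeric")
        if not np.isfinite(inten).all():
            raise FormatError("intensities must be finite")
        if (inten < 0).any():
            raise FormatError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def intensities(self) -> np.ndarray:
        """(n_psms, n_channels) float array, layout channel order."""
        return self.data[list(self.channels)].to_numpy(dtype=float)

    @property
    def meta(self) -> pd.DataFrame:
        extra = [c for c in OPTIONAL_META_COLUMNS if c in self.data.columns]
        return self.data[list(META_COLUMNS) + extra]

    def with_intensities(self, values: np.ndarray,
                         extra_meta: Mapping[str, Iterable] | None = None
                         ) -> "PSMTable":
        """Return a new table with the same metadata and new intensities."""
        if values.shape != (len(self.data), len(self.channels)):
            raise ContractError("intensity array shape mismatch")
        data = self.meta.copy()
        if extra_meta:
            for name, col in extra_meta.items():
                data[name] = np.asarray(col)
        data[list(self.channels)] = values
        return PSMTable(data.reset_index(drop=True), self.channels)


def read_psm_table(path, layout: ChannelLayout) -> PSMTable:
    """Read a tab-separated PSM table, matching channels to ``layout`` by label.

    Column order in the file is irrelevant: channel identity is by label, and
    a file whose intensity columns are permuted is re-ordered to layout order.
    Unknown extra columns are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for ch in layout.channels:
        if ch not in df.columns:
            raise LayoutError(
                f"{path}: layout channel {ch!r} has no intensity column")
    known = set(META_COLUMNS) | set(OPTIONAL_META_COLUMNS) | set(layout.channels)
    extras = [c for c in df.columns if c not in known]
    if extras:
        logger.warning("%s: ignoring unknown columns %s", path, extras)
        df = df.drop(columns=extras)
    for ch in layout.channels:
        raw = df[ch]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() | ~np.isfinite(num) | (num < 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"{path}: line {i + 2}, column {ch!r}: "
                f"{raw.iloc[i]!r} is not a non-negative finite number")
        # numpy's string parser round-trips shortest-repr floats exactly;
        # pd.to_numeric above is only used to localize bad cells
        df[ch] = raw.to_numpy(dtype=float)
    if "impurity_clamped" in df.columns:
        df["impurity_clamped"] = df["impurity_clamped"].map(
            {"True": True, "False": False}).astype(bool)
    return PSMTable(df, tuple(layout.channels))


def write_psm_table(table: PSMTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ImpurityMatrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImpurityMatrix:
    """Reporter isotopologue mixing matrix.

    ``matrix[i, j]`` is the fraction of label j's reporter ions detected in
    channel i.  Columns may sum to < 1 (isotopologues falling outside the
    plex are undetected).  For the TMT126 reagent, for instance, 91.8% of the
    signal lands in its own channel, 7.9% one channel up and 0.3% two up.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise FormatError(f"impurity matrix must be square, got {m.shape}")
        if (m < 0).any() or (m > 1).any():
            raise FormatError("impurity fractions must lie in [0, 1]")
        colsums = m.sum(axis=0)
        if (colsums > 1 + 1e-9).any():
            j = int(np.argmax(colsums))
            raise FormatError(
                f"column {j} of impurity matrix sums to {colsums[j]:.6f} > 1")
        if (np.diag(m) <= 0.5).any():
            raise FormatError("impurity matrix diagonal entries must exceed 0.5")
        logger.info("impurity matrix condition number: %.3g",
                    self.condition_number)

    @property
    def k(self) -> int:
        return self.matrix.shape[0]

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    @property
    def is_singular(self) -> bool:
        # determinant test on the column-normalized matrix
        scaled = self.matrix / np.maximum(self.matrix.sum(axis=0), 1e-30)
        return abs(float(np.linalg.det(scaled))) < 1e-12

    @classmethod
    def identity(cls, k: int) -> "ImpurityMatrix":
        return cls(np.eye(k))


def read_impurity_matrix(path) -> ImpurityMatrix:
    """Read a headerless k x k CSV of fractions (column j = label j)."""
    try:
        m = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse impurity CSV: {exc}") from exc
    if m.shape[0] != m.shape[1]:
        raise FormatError(
            f"{path}: impurity matrix must be square, got {m.shape[0]}x{m.shape[1]}")
    matrix = ImpurityMatrix(m)
    if matrix.is_singular:
        raise NumericalError(
            f"{path}: impurity matrix is numerically singular; "
            "consider nnls correction mode")
    return matrix


def write_impurity_matrix(matrix: ImpurityMatrix, path) -> None:
    np.savetxt(path, matrix.matrix, delimiter=",", fmt="%.17g")


# ---------------------------------------------------------------------------
# ProteinQuantTable
# ---------------------------------------------------------------------------

@dataclass
class ProteinQuantTable:
    """Protein x channel relative (mean ~ 1) and absolute intensities.

    Only proteins with at least one eligible (shared-specificity) PSM appear.
    ``absolute`` is ``None`` until :func:`ppbscreen.quantify.scale_absolute`
    attaches the grand-mean-of-top-3-PSMs scale.
    """

    relative: pd.DataFrame          # index protein, columns channels
    n_psms: pd.Series               # index protein
    absolute: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        rel = self.relative
        if len(rel):
            row_means = rel.to_numpy(dtype=float).mean(axis=1)
            if not np.allclose(row_means, 1.0, atol=1e-9):
                raise ConsistencyError(
                    "relative intensities must average 1 per protein")
        if not self.n_psms.index.equals(rel.index):
            raise ConsistencyError("n_psms index must match protein index")
        if self.absolute is not None:
            if not self.absolute.index.equals(rel.index) or \
                    list(self.absolute.columns) != list(rel.columns):
                raise ConsistencyError("absolute table shape mismatch")

    @property
    def proteins(self) -> pd.Index:
        return self.relative.index

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.relative.columns)

    def __len__(self) -> int:
        return len(self.relative)


def write_protein_table(table: ProteinQuantTable, path) -> None:
    out = pd.DataFrame({"protein": table.proteins,
                        "n_psms_used": table.n_psms.to_numpy()})
    for ch in table.channels:
        out[f"rel_{ch}"] = table.relative[ch].to_numpy()
    if table.absolute is not None:
        for ch in table.channels:
            out[f"abs_{ch}"] = table.absolute[ch].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_protein_table(path) -> ProteinQuantTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("protein", "n_psms_used"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    rel_cols = [c for c in df.columns if c.startswith("rel_")]
    abs_cols = [c for c in df.columns if c.startswith("abs_")]
    if not rel_cols:
        raise FormatError(f"{path}: no rel_<channel> columns found")
    idx = pd.Index(df["protein"], name="protein")
    relative = pd.DataFrame(df[rel_cols].to_numpy(dtype=float), index=idx,
                            columns=[c[4:] for c in rel_cols])
    absolute = None
    if abs_cols:
        absolute = pd.DataFrame(df[abs_cols].to_numpy(dtype=float), index=idx,
                                columns=[c[4:] for c in abs_cols])
    return ProteinQuantTable(relative,
                             pd.Series(df["n_psms_used"].to_numpy(dtype=int),
                                       index=idx),
                             absolute)


# ---------------------------------------------------------------------------
# LoadingFactors
# ---------------------------------------------------------------------------

@dataclass
class LoadingFactors:
    """Per-channel loading-bias normalization factors.

    Each factor is a ratio of medians of cross-species-specific PSM signals
    in that channel versus the first blank channel; the reference blank's
    factor is exactly 1.
    """

    factors: pd.Series              # channel -> factor
    reference: str
    n_psms: pd.Series               # channel -> PSMs supporting the median
    specificity_class: pd.Series    # channel -> "human" | "mouse" | "pooled"
    min_support: int = 10

    def __post_init__(self) -> None:
        if self.factors[self.reference] != 1.0:
            raise ConsistencyError("reference blank factor must be exactly 1")
        if (self.factors <= 0).any():
            raise NumericalError("loading factors must be positive")
        low = self.n_psms[self.n_psms < self.min_support]
        for ch, n in low.items():
            logger.warning("channel %s loading factor supported by only %d "
                           "PSMs (< %d): treat with caution", ch, n,
                           self.min_support)

    @property
    def low_support(self) -> tuple[str, ...]:
        return tuple(self.n_psms.index[self.n_psms < self.min_support])


def write_loading_factors(factors: LoadingFactors, path) -> None:
    out = pd.DataFrame({"channel": factors.factors.index,
                        "factor": factors.factors.to_numpy(),
                        "n_psms": factors.n_psms.to_numpy(),
                        "class": factors.specificity_class.to_numpy()})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# NullModel & CandidateTable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullModel:
    """Gaussian fit of log2 replicate ratios pooled across proteins.

    ``sigma0`` (the null SD) is the unit of the fold-change z-score gate.
    """

    mu0: float
    sigma0: float
    n_ratios: int
    estimator: str                  # "mle" | "mad"

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise DegeneracyError("null SD must be positive")
        if self.n_ratios < 30:
            logger.warning("null model fitted on only %d replicate ratios "
                           "(< 30): unstable", self.n_ratios)

    @property
    def low_support(self) -> bool:
        return self.n_ratios < 30


@dataclass
class CandidateTable:
    """Per-protein interaction-candidate statistics.

    Columns: ``protein``, then per cell line ``p_<line>`` and
    ``log2fc_<line>``, then ``fisher_x2``, ``combined_p``, ``q_value``,
    ``z_score``, ``is_candidate``.
    """

    data: pd.DataFrame
    null_model: NullModel
    lines: tuple[str, ...]
    fdr_threshold: float = 0.01
    z_threshold: float = 3.0

    def __post_init__(self) -> None:
        d = self.data
        pcols = [f"p_{l}" for l in self.lines]
        for col in pcols + ["combined_p", "q_value"]:
            v = d[col].to_numpy(dtype=float)
            if ((v < 0) | (v > 1)).any():
                raise ConsistencyError(f"{col} outside [0, 1]")
        if (d["fisher_x2"].to_numpy(dtype=float) < 0).any():
            raise ConsistencyError("Fisher statistic must be non-negative")
        if (d["q_value"].to_numpy() + 1e-12 < d["combined_p"].to_numpy()).any():
            raise ConsistencyError("q-values cannot be below combined p")
        rule = (d["q_value"] < self.fdr_threshold) & \
               (d["z_score"] > self.z_threshold)
        if (d["is_candidate"].astype(bool) != rule).any():
            raise ConsistencyError("is_candidate inconsistent with thresholds")

    @property
    def candidates(self) -> pd.Index:
        return pd.Index(self.data.loc[self.data["is_candidate"], "protein"])

    def __len__(self) -> int:
        return len(self.data)


def write_candidate_table(table: CandidateTable, path) -> None:
    nm = table.null_model
    with open(path, "w") as fh:
        fh.write(f"# null_model\tmu0={nm.mu0!r}\tsigma0={nm.sigma0!r}"
                 f"\tn_ratios={nm.n_ratios}\testimator={nm.estimator}\n")
        fh.write(f"# thresholds\tfdr={table.fdr_threshold!r}"
                 f"\tz={table.z_threshold!r}\n")
        table.data.to_csv(fh, sep="\t", index=False)


def read_candidate_table(path) -> CandidateTable:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            for tok in line[1:].split("\t")[1:]:
                key, _, val = tok.strip().partition("=")
                meta[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    try:
        nm = NullModel(float(meta["mu0"]), float(meta["sigma0"]),
                       int(meta["n_ratios"]), meta["estimator"])
        fdr, z = float(meta["fdr"]), float(meta["z"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing candidate-table metadata {exc}")
    lines = tuple(c[2:] for c in df.columns if c.startswith("p_"))
    return CandidateTable(df, nm, lines, fdr, z)


# ---------------------------------------------------------------------------
# SimulationTruth
# ---------------------------------------------------------------------------

@dataclass
class SimulationTruth:
    """Ground truth of a simulated experiment.

    ``binders``/``effects`` are protein x cell-line tables; ``loading_bias``
    is the per-channel multiplier actually applied (normalization recovers
    these relative to the blank-reference channel).
    """

    protein_species: pd.Series          # protein -> species
    binders: pd.DataFrame               # protein x line, bool
    effects: pd.DataFrame               # protein x line, log2 effect
    loading_bias: pd.Series             # channel -> multiplier
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.binders.index.equals(self.effects.index) or \
                list(self.binders.columns) != list(self.effects.columns):
            raise ConsistencyError("binders and effects tables must align")
        if self.binders.index.has_duplicates:
            raise ConsistencyError("each simulated protein appears exactly once")

    @property
    def binder_proteins(self) -> pd.Index:
        return self.binders.index[self.binders.any(axis=1)]


def write_truth(truth: SimulationTruth, path) -> None:
    long = []
    for line in truth.binders.columns:
        long.append(pd.DataFrame({
            "protein": truth.binders.index,
            "species": truth.protein_species.reindex(truth.binders.index),
            "cell_line": line,
            "is_binder": truth.binders[line].to_numpy(),
            "true_log2fc": truth.effects[line].to_numpy()}))
    df = pd.concat(long, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# seed\t{truth.seed}\n")
        for ch, b in truth.loading_bias.items():
            fh.write(f"# bias\t{ch}\t{b!r}\n")
        fh.write(f"# config\t{json.dumps(truth.config, sort_keys=True)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_truth(path) -> SimulationTruth:
    seed, bias, config = 0, {}, {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if parts[0] == "seed":
                seed = int(parts[1])
            elif parts[0] == "bias":
                bias[parts[1]] = float(parts[2])
            elif parts[0] == "config":
                config = json.loads(parts[1])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    line_order = list(df["cell_line"].drop_duplicates())
    binders = df.pivot(index="protein", columns="cell_line",
                       values="is_binder").astype(bool)[line_order]
    effects = df.pivot(index="protein", columns="cell_line",
                       values="true_log2fc")[line_order]
    binders.columns.name = effects.columns.name = None
    species = df.drop_duplicates("protein").set_index("protein")["species"]
    order = pd.Index(df["protein"].drop_duplicates(), name="protein")
    return SimulationTruth(species.reindex(order),
                           binders.reindex(order), effects.reindex(order),
                           pd.Series(bias), seed, config)


# ---------------------------------------------------------------------------
# Generic writer
# ---------------------------------------------------------------------------

def write_table(obj, path) -> None:
    """Write any pipeline table to ``path`` in its canonical text format."""
    if isinstance(obj, PSMTable):
        write_psm_table(obj, path)
    elif isinstance(obj, ProteinQuantTable):
        write_protein_table(obj, path)
    elif isinstance(obj, CandidateTable):
        write_candidate_table(obj, path)
    elif isinstance(obj, LoadingFactors):
        write_loading_factors(obj, path)
    elif isinstance(obj, SimulationTruth):
        write_truth(obj, path)
    elif isinstance(obj, ImpurityMatrix):
        write_impurity_matrix(obj, path)
    elif isinstance(obj, ChannelLayout):
        write_layout(obj, path)
    else:
        raise ContractError(f"cannot write object of type {type(obj).__name__}")
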