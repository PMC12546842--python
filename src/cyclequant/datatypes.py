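"""Core containers shared by every pipeline stage.

The pipeline transforms a single object — an :class:`AbundanceMatrix`
(proteins x TMT channels) — through a fixed sequence of stages::

    raw -> pooled -> sl -> irs -> tmm -> log2 -> averaged

Each normalization step checks the stage tag of its input and advances it,
so stages cannot be applied out of order or twice.  A
:class:`ChannelDesign` maps every ``plex.channel`` column to its plex
(= one multiplexed MS run = one biological repeat), condition label,
replicate index and reference flag; it drives baseline pooling, internal
reference scaling and the linear model design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered pipeline stages for an AbundanceMatrix.
STAGES = ("raw", "pooled", "sl", "irs", "tmm", "log2", "averaged")

#: Condition labels of the predatory-life-cycle design: free-swimming
#: attack phase (AP), prey-only control (Ec), ten post-mixing timepoints,
#: the golden-standard reference mixture (GS) and the in-silico pooled
#: baseline (AP_Ec).
TIMEPOINT_CONDITIONS = (
    "T15", "T30", "T45", "T1h", "T2h", "T3h", "T4h", "T5h", "T6h", "T7h",
)
KNOWN_CONDITIONS = ("AP", "Ec") + TIMEPOINT_CONDITIONS + ("GS", "AP_Ec")

#: Baseline used for all pairwise contrasts.
BASELINE_CONDITION = "AP_Ec"

SPECIES_TAGS = ("predator", "prey", "contaminant", "unknown")


class StageError(RuntimeError):
    """A pipeline stage was applied to a matrix in the wrong stage."""


class ValidationError(ValueError):
    """An input table violates its contract; message names the offender."""


def _check_unique(values, what: str) -> None:
    counts = pd.Index(values).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValidationError(
            f"duplicate {what}: {', '.join(map(str, dups.index[:5]))}"
        )


@dataclass
class AbundanceMatrix:
    """Protein x channel reporter-abundance matrix with a stage tag.

    Parameters
    ----------
    data
        DataFrame indexed by unique protein ids with one column per
        ``plexId.channelLabel`` channel id.  Missing values are NaN;
        zeros are valid measurements, not missing.
    stage
        One of :data:`STAGES`.  Values must be non-negative before the
        ``log2`` stage.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        _check_unique(self.data.index, "protein ids")
        _check_unique(self.data.columns, "channel ids")
        if STAGES.index(self.stage) < STAGES.index("log2"):
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                rows, cols = np.where(vals < 0)
                pid = self.data.index[rows[0]]
                cid = self.data.columns[cols[0]]
                raise ValidationError(
                    f"negative abundance for protein {pid!r} in channel {cid!r}"
                )

    # -- convenience -------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.data.index

    @property
    def channel_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"expected matrix at stage {' or '.join(allowed)}, "
                f"got {self.stage!r}"
            )

    def advanced(self, data: pd.DataFrame, stage: str) -> "AbundanceMatrix":
        """Return a new matrix at `stage`, enforcing monotone progression."""
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise StageError(f"stage cannot go back from {self.stage!r} to {stage!r}")
        return AbundanceMatrix(data, stage)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.stage)

    def subset(self, protein_ids) -> "AbundanceMatrix":
        """Row subset preserving the stage tag (filters never mutate values)."""
        return AbundanceMatrix(self.data.loc[protein_ids], self.stage)


def channel_id(plex_id, channel_label) -> str:
    """Canonical ``plexId.channelLabel`` channel identifier."""
    return f"{plex_id}.{channel_label}"


@dataclass
class ChannelDesign:
    """Maps each plex x channel to condition, replicate and reference flag.

    `table` has columns ``plex_id, channel_label, condition, replicate,
    is_reference`` and is indexed by channel id (``plex.channel``).
    """

    table: pd.DataFrame
    require_reference: bool = True

    REQUIRED = ("plex_id", "channel_label", "condition", "replicate", "is_reference")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design missing column(s): {', '.join(missing)}")
        t = self.table.copy()
        t["is_reference"] = t["is_reference"].astype(bool)
        t.index = pd.Index(
            [channel_id(p, c) for p, c in zip(t["plex_id"], t["channel_label"])],
            name="channel_id",
        )
        _check_unique(t.index, "design channels")
        combos = t.loc[~t["is_reference"], ["condition", "replicate", "plex_id"]]
        _check_unique(
            [tuple(r) for r in combos.itertuples(index=False)],
            "(condition, replicate, plex) combinations",
        )
        if self.require_reference:
            for plex, grp in t.groupby("plex_id"):
                if not grp["is_reference"].any():
                    raise ValidationError(
                        f"plex {plex!r} has no reference channel: IRS impossible"
                    )
        self.table = t

    # -- accessors ---------------------------------------------------
    @property
    def channel_ids(self) -> pd.Index:
        return self.table.index

    @property
    def plexes(self) -> list:
        return list(dict.fromkeys(self.table["plex_id"]))

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(self.table["condition"]))

    def channels_of_plex(self, plex_id) -> pd.Index:
        return self.table.index[self.table["plex_id"] == plex_id]

    def reference_channels(self, plex_id=None) -> pd.Index:
        mask = self.table["is_reference"]
        if plex_id is not None:
            mask = mask & (self.table["plex_id"] == plex_id)
        return self.table.index[mask]

    def sample_channels(self, plex_id=None) -> pd.Index:
        mask = ~self.table["is_reference"]
        if plex_id is not None:
            mask = mask & (self.table["plex_id"] == plex_id)
        return self.table.index[mask]

    def channels_of_condition(self, condition) -> pd.Index:
        return self.table.index[self.table["condition"] == condition]

    def with_rows(self, extra: pd.DataFrame) -> "ChannelDesign":
        return ChannelDesign(
            pd.concat([self.table.reset_index(drop=True), extra], ignore_index=True),
            require_reference=self.require_reference,
        )

    def subset(self, channel_ids) -> "ChannelDesign":
        return ChannelDesign(
            self.table.loc[channel_ids].reset_index(drop=True),
            require_reference=False,
        )


@dataclass
class ProteinMeta:
    """Per-protein annotation table.

    Columns: ``protein_id`` (index), ``species`` (predator / prey /
    contaminant / unknown), ``length`` (aa), ``is_membrane``, ``cog``
    (concatenated COG letters, may be empty), ``evalue``, ``description``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.name != "protein_id":
            if "protein_id" in t.columns:
                t = t.set_index("protein_id")
            else:
                raise ValidationError("protein meta requires a protein_id column")
        _check_unique(t.index, "protein ids in meta")
        if "species" not in t.columns:
            raise ValidationError("protein meta requires a species column")
        bad = set(t["species"].dropna()) - set(SPECIES_TAGS)
        if bad:
            raise ValidationError(f"unknown species tag(s): {sorted(bad)}")
        if "length" in t.columns:
            lengths = pd.to_numeric(t["length"], errors="coerce")
            if (lengths.dropna() < 1).any():
                pid = t.index[lengths < 1][0]
                raise ValidationError(f"protein {pid!r} has length < 1")
        self.table = t

    @property
    def protein_ids(self) -> pd.Index:
        return self.table.index

    def species_of(self, protein_ids) -> pd.Series:
        return self.table["species"].reindex(protein_ids).fillna("unknown")


@dataclass
class NormalizationFactors:
    """Factors produced by the SL / IRS / TMM chain (all dimensionless)."""

    sl_factor: pd.Series | None = None          # per channel
    irs_factor: pd.DataFrame | None = None      # protein x plex
    tmm_factor: pd.Series | None = None         # per channel
    reference_summary: pd.DataFrame | None = None  # protein x plex geometric means


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator for recovery tests."""

    archetype_id: pd.Series                 # per protein; -1 = flat
    baseline: pd.Series                     # true baseline abundance per protein
    log2fc: pd.DataFrame                    # protein x timepoint true log2 fold change
    plex_factor: pd.Series                  # per plex multiplicative batch factor
    loading_factor: pd.Series               # per channel loading factor
    missing_mask: pd.DataFrame = field(default=None)  # protein x channel bool
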