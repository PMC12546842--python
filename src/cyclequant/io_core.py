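"""Readers, writers, validators and filters for the tabular inputs.

All tables are UTF-8 TSV with a header row; the missing marker is the
literal string ``NA``.  Zeros are valid measurements and are never
treated as missing.  FASTA is read with Biopython.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import (
    AbundanceMatrix,
    ChannelDesign,
    KNOWN_CONDITIONS,
    ProteinMeta,
    SPECIES_TAGS,
    ValidationError,
)

log = logging.getLogger(__name__)

NA = "NA"

#: Default id-pattern rules for inferring species when meta lacks it.
DEFAULT_SPECIES_PATTERNS = (
    (re.compile(r"^Bd"), "predator"),
    (re.compile(r"^(b\d|Ec|ECK)"), "prey"),
    (re.compile(r"^(CON|cont)", re.IGNORECASE), "contaminant"),
)


# ---------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------

def read_abundance_table(path, stage: str = "raw") -> AbundanceMatrix:
    """Read a protein x channel abundance TSV.

    First column must be ``protein_id``; every other column is a channel.
    Raises :class:`ValidationError` naming the offending protein/channel
    on malformed numerics or negative values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "protein_id":
        raise ValidationError(
            f"{path}: first column must be 'protein_id', got {df.columns[0]!r}"
        )
    df = df.set_index("protein_id")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        missing = raw == NA
        vals = pd.to_numeric(raw.where(~missing, other="0"), errors="coerce")
        bad = vals.isna() & ~missing
        if bad.any():
            pid = df.index[bad][0]
            raise ValidationError(
                f"{path}: malformed value {raw[bad].iloc[0]!r} for protein "
                f"{pid!r} in channel {col!r}"
            )
        allow_negative = stage in ("log2", "averaged")
        if not allow_negative and (vals[~missing] < 0).any():
            neg = vals.lt(0) & ~missing
            pid = df.index[neg][0]
            raise ValidationError(
                f"{path}: negative abundance {vals[neg].iloc[0]} for protein "
                f"{pid!r} in channel {col!r}"
            )
        out[col] = vals.where(~missing, other=np.nan)
    return AbundanceMatrix(out, stage=stage)


def write_abundance_table(matrix: AbundanceMatrix, path) -> Path:
    """Write an AbundanceMatrix as TSV (``NA`` for missing); round-trip safe."""
    path = Path(path)
    df = matrix.data.copy()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", na_rep=NA, float_format="%.10g")
    return path


# ---------------------------------------------------------------------
# design
# ---------------------------------------------------------------------

def read_design(path, known_conditions=KNOWN_CONDITIONS) -> ChannelDesign:
    """Read and validate the plex/channel design table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ChannelDesign.REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: design missing column(s) {missing}")
    unknown = set(df["condition"]) - set(known_conditions)
    if unknown:
        raise ValidationError(f"{path}: unknown condition label(s) {sorted(unknown)}")
    df["replicate"] = df["replicate"].astype(int)
    df["is_reference"] = df["is_reference"].str.lower().isin(("1", "true", "yes"))
    design = ChannelDesign(df)
    for plex in design.plexes:
        n_ref = len(design.reference_channels(plex))
        log.info("plex %s: %d reference channel(s)", plex, n_ref)
    return design


def write_design(design: ChannelDesign, path) -> Path:
    path = Path(path)
    out = design.table.copy()
    out["is_reference"] = out["is_reference"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------
# protein metadata / FASTA
# ---------------------------------------------------------------------

def read_protein_meta(
    path,
    species_patterns=DEFAULT_SPECIES_PATTERNS,
) -> ProteinMeta:
    """Read the per-protein annotation table.

    Rows lacking a species tag get one inferred from `species_patterns`
    on the protein id; unmatched ids become ``unknown`` with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "protein_id" not in df.columns:
        raise ValidationError(f"{path}: meta requires a protein_id column")
    df = df.set_index("protein_id")
    if "species" not in df.columns:
        df["species"] = ""
    blank = ~df["species"].isin(SPECIES_TAGS)
    if blank.any():
        inferred = []
        for pid in df.index[blank]:
            for pat, tag in species_patterns:
                if pat.search(pid):
                    inferred.append(tag)
                    break
            else:
                inferred.append("unknown")
        df.loc[blank, "species"] = inferred
        n_unknown = sum(1 for s in inferred if s == "unknown")
        if n_unknown:
            log.warning("%d proteins without species tag set to 'unknown'", n_unknown)
    if "length" in df.columns:
        df["length"] = pd.to_numeric(df["length"].replace("", np.nan), errors="coerce")
    if "is_membrane" in df.columns:
        df["is_membrane"] = df["is_membrane"].str.lower().isin(("1", "true", "yes"))
    if "evalue" in df.columns:
        df["evalue"] = pd.to_numeric(df["evalue"].replace("", np.nan), errors="coerce")
    if "cog" not in df.columns:
        df["cog"] = ""
    return ProteinMeta(df)


def write_protein_meta(meta: ProteinMeta, path) -> Path:
    path = Path(path)
    out = meta.table.copy()
    if "is_membrane" in out.columns:
        out["is_membrane"] = out["is_membrane"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", na_rep="")
    return path


def read_fasta_lengths(path) -> pd.Series:
    """Map FASTA record id -> sequence length (aa)."""
    lengths = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in lengths:
            raise ValidationError(f"{path}: duplicate FASTA header {rec.id!r}")
        if len(rec.seq) == 0:
            raise ValidationError(f"{path}: empty sequence for {rec.id!r}")
        lengths[rec.id] = len(rec.seq)
    return pd.Series(lengths, name="length")


def merge_fasta_lengths(meta: ProteinMeta, lengths: pd.Series) -> ProteinMeta:
    """FASTA lengths override / fill the metadata lengths."""
    table = meta.table.copy()
    if "length" not in table.columns:
        table["length"] = np.nan
    shared = table.index.intersection(lengths.index)
    table.loc[shared, "length"] = lengths.loc[shared].astype(float)
    return ProteinMeta(table)


# ---------------------------------------------------------------------
# filters & partitions (row-only, idempotent)
# ---------------------------------------------------------------------

def filter_contaminants(matrix: AbundanceMatrix, meta: ProteinMeta) -> AbundanceMatrix:
    """Drop rows tagged ``contaminant``; proteins without meta are kept."""
    species = meta.species_of(matrix.protein_ids)
    uncovered = int((~matrix.protein_ids.isin(meta.protein_ids)).sum())
    if uncovered:
        log.warning("%d proteins lack metadata; kept", uncovered)
    keep = matrix.protein_ids[species != "contaminant"]
    removed = matrix.shape[0] - len(keep)
    if removed:
        log.info("removed %d contaminant protein(s)", removed)
    return matrix.subset(keep)


def filter_complete_cases(matrix: AbundanceMatrix, design: ChannelDesign) -> AbundanceMatrix:
    """Keep only proteins observed in every sample AND reference channel.

    A protein missing in any one channel of any plex is removed; reference
    channel completeness is required because IRS needs a present reference
    value in every plex.
    """
    cols = [c for c in design.channel_ids if c in matrix.channel_ids]
    complete = matrix.data[cols].notna().all(axis=1)
    kept = matrix.protein_ids[complete]
    log.info(
        "complete-case filter: kept %d / %d proteins", len(kept), matrix.shape[0]
    )
    return matrix.subset(kept)


def split_by_species(matrix: AbundanceMatrix, meta: ProteinMeta) -> dict:
    """Row-disjoint partition of the matrix by species tag."""
    species = meta.species_of(matrix.protein_ids)
    if (species == "unknown").any():
        log.warning(
            "%d proteins of unknown species placed in their own partition",
            int((species == "unknown").sum()),
        )
    return {
        tag: matrix.subset(matrix.protein_ids[species == tag])
        for tag in dict.fromkeys(species)
    }
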