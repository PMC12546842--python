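"""Synthetic multi-plex TMT time-course generator with known ground truth.

The simulator emulates the predatory-life-cycle study geometry: five
multiplexed TMT experiments (one per biological repeat), each carrying a
free-swimming attack-phase channel (AP), a prey-only channel (Ec), ten
post-mixing timepoints (T15 ... T7h) and two golden-standard reference
channels (GS1, GS2) made of an equal mixture of every sample in the study.

The measured reporter value of a sample channel is

    baseline * 2**(effect_scale * archetype(condition))
             * plex_factor * loading_factor * noise

and a reference channel carries the equal-weight mean of all true sample
signals for that protein, times the batch factor of the plex it is
measured in, its own loading factor and noise.  Multiplicative plex batch
factors are geometric-mean-centered to one, so internal reference scaling
can recover them exactly in the zero-noise limit.

Protein trajectories are drawn from a deterministic library of temporal
archetypes (early peak, mid peaks, late rise, declines); a configurable
fraction of proteins is flat (no temporal change).  Prey proteins follow
their own declining family, mirroring prey consumption.  Missingness is
injected with a logistic model enriched in low-abundance and short
proteins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import (
    AbundanceMatrix,
    ChannelDesign,
    ProteinMeta,
    SimTruth,
    TIMEPOINT_CONDITIONS,
    channel_id,
)
from . import io_core

log = logging.getLogger(__name__)

DEFAULT_CONDITIONS = ("AP", "Ec") + TIMEPOINT_CONDITIONS

#: Hours after predator-prey mixing for each timepoint label.
CONDITION_HOURS = {
    "T15": 0.25, "T30": 0.5, "T45": 0.75, "T1h": 1.0, "T2h": 2.0,
    "T3h": 3.0, "T4h": 4.0, "T5h": 5.0, "T6h": 6.0, "T7h": 7.0,
}

#: COG one-letter functional categories used for annotation sampling.
COG_LETTERS = "JKLMNOPQRSTUVWCEFGHID"


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment.

    Defaults encode the study geometry: 5 plexes (biological repeats),
    12 sample conditions per plex plus 2 golden-standard channels, nine
    temporal archetypes with log2 amplitudes of ~2, 10% multiplicative
    reporter noise (CV), modest plex batch and channel loading effects,
    and sparse missingness enriched in low-abundance / short proteins.
    """

    n_predator_proteins: int = 2000
    n_prey_proteins: int = 800
    timepoints: tuple = DEFAULT_CONDITIONS
    n_plexes: int = 5
    n_reference_channels_per_plex: int = 2
    archetype_count: int = 9
    fraction_flat: float = 0.4
    effect_scale: float = 2.0
    plex_effect_sd: float = 0.25
    loading_effect_sd: float = 0.1
    noise_cv: float = 0.1
    missing_base_rate: float = 0.004
    missing_abundance_slope: float = 1.0
    missing_length_slope: float = 0.5
    cross_condition_background: float = 1e-3
    baseline_meanlog: float = 9.9      # natural-log median reporter abundance (~2e4)
    baseline_sdlog: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_predator_proteins, self.n_prey_proteins, self.n_plexes,
            self.n_reference_channels_per_plex, self.archetype_count,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        for name in ("fraction_flat", "missing_base_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("plex_effect_sd", "loading_effect_sd", "noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoints must be unique")
        self.timepoints = tuple(self.timepoints)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints"] = list(self.timepoints)
        return d


# ---------------------------------------------------------------------
# archetype library
# ---------------------------------------------------------------------

def _bump(hours: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((hours - center) ** 2) / (2.0 * width**2))


#: (name, callable hours -> trajectory).  The first nine form the default
#: repertoire: entry peak (T45), growth/division/exit peaks (T2h-T4h),
#: late rise of progeny attack-phase proteins, early and mid declines, a
#: monotone decline and a T5h peak.  All bump shapes return toward the
#: baseline by T7h, reproducing the cyclic character of the life cycle.
_SHAPE_LIBRARY = (
    ("entry_peak_T45", lambda h: _bump(h, 0.75, 0.45)),
    ("exit_peak_T4h", lambda h: _bump(h, 4.0, 1.0)),
    ("growth_peak_T2h", lambda h: _bump(h, 2.0, 0.8)),
    ("late_rise_T6h", lambda h: _bump(h, 6.0, 1.4)),
    ("early_dip_T45", lambda h: -_bump(h, 0.75, 0.45)),
    ("mid_decline", lambda h: -_bump(h, 3.0, 1.5)),
    ("division_peak_T3h", lambda h: _bump(h, 3.0, 0.7)),
    ("monotone_decline", lambda h: -((h / 7.0) ** 0.7)),
    ("release_peak_T5h", lambda h: _bump(h, 5.0, 0.8)),
    ("entry_peak_T1h", lambda h: _bump(h, 1.3, 0.45)),
    ("late_dip_T5h", lambda h: -_bump(h, 5.0, 1.2)),
    ("immediate_peak_T15", lambda h: _bump(h, 0.3, 0.25)),
)

#: Declining family for prey proteins (consumed over the cycle).
_PREY_SHAPES = (
    ("prey_fast_decline", lambda h: -((h / 7.0) ** 0.5)),
    ("prey_linear_decline", lambda h: -(h / 7.0)),
    ("prey_late_decline", lambda h: -((h / 7.0) ** 2.0)),
)


def generate_archetypes(
    k: int, timepoints=DEFAULT_CONDITIONS, balance: bool = True
) -> pd.DataFrame:
    """Deterministic k x condition matrix of temporal archetypes (log2 units).

    Rows are anchored at 0 for the baseline conditions (AP, and Ec when
    present); entries at the timepoint labels follow the shape library.
    With `balance` (default, k >= 2) the repertoire is mean-centered
    across shapes at every timepoint, so a uniform assignment of shapes
    yields a composition-neutral population: phase-specific synthesis is
    offset by decline of other proteins, as expected under a fixed
    per-cell protein budget.  Raises ``ValueError`` when `k` exceeds the
    number of representable distinct shapes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(_SHAPE_LIBRARY):
        raise ValueError(
            f"k={k} exceeds the {len(_SHAPE_LIBRARY)} representable distinct shapes"
        )
    if "AP" not in timepoints and "Ec" not in timepoints:
        raise ValueError("baseline label (AP or Ec) missing from timepoints")
    rows = []
    names = []
    for name, fn in _SHAPE_LIBRARY[:k]:
        row = []
        for cond in timepoints:
            if cond in ("AP", "Ec"):
                row.append(0.0)
            else:
                row.append(float(fn(np.asarray(CONDITION_HOURS[cond]))))
        rows.append(row)
        names.append(name)
    out = pd.DataFrame(rows, index=names, columns=list(timepoints))
    if balance and k >= 2:
        centered = out - out.mean(axis=0)
        centered[[c for c in timepoints if c in ("AP", "Ec")]] = 0.0
        out = centered
    return out


def _prey_archetypes(timepoints) -> pd.DataFrame:
    rows, names = [], []
    for name, fn in _PREY_SHAPES:
        row = [
            0.0 if cond in ("AP", "Ec") else float(fn(np.asarray(CONDITION_HOURS[cond])))
            for cond in timepoints
        ]
        rows.append(row)
        names.append(name)
    return pd.DataFrame(rows, index=names, columns=list(timepoints))


# ---------------------------------------------------------------------
# study container
# ---------------------------------------------------------------------

@dataclass
class SimStudy:
    """A simulated study: abundances, design, metadata and ground truth."""

    abundance: AbundanceMatrix
    design: ChannelDesign
    meta: ProteinMeta
    truth: SimTruth
    config: SimConfig = field(default=None)

    def plex_table(self, plex_id) -> pd.DataFrame:
        cols = self.design.channels_of_plex(plex_id)
        return self.abundance.data[cols]


# ---------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------

def _lognormal_noise(rng, cv: float, size) -> np.ndarray:
    """Multiplicative mean-1 log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def _make_meta(rng, protein_ids, species: np.ndarray) -> ProteinMeta:
    n = len(protein_ids)
    lengths = np.maximum(30, np.round(rng.lognormal(5.5, 0.45, n))).astype(int)
    membrane = rng.random(n) < 0.25
    n_letters = rng.choice([0, 1, 2], size=n, p=[0.35, 0.5, 0.15])
    cogs = [
        "".join(sorted(rng.choice(list(COG_LETTERS), size=m, replace=False)))
        for m in n_letters
    ]
    table = pd.DataFrame(
        {
            "species": species,
            "length": lengths,
            "is_membrane": membrane,
            "cog": cogs,
            "evalue": np.where(n_letters > 0, 1e-10, np.nan),
            "description": "",
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    return ProteinMeta(table)


def simulate_experiment(config: SimConfig) -> SimStudy:
    """Generate a full multi-plex study with ground truth.

    Deterministic: the same (config, seed) yields byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    conds = list(config.timepoints)
    n_pred, n_prey = config.n_predator_proteins, config.n_prey_proteins
    n = n_pred + n_prey
    pids = [f"Bd{i:04d}" for i in range(1, n_pred + 1)] + [
        f"b{i:04d}" for i in range(1, n_prey + 1)
    ]
    species = np.array(["predator"] * n_pred + ["prey"] * n_prey)

    # archetype assignment: -1 = flat
    pred_arch = generate_archetypes(config.archetype_count, conds)
    prey_arch = _prey_archetypes(conds)
    arch_id = np.full(n, -1, dtype=int)
    changing = rng.random(n) >= config.fraction_flat
    arch_id[changing[:n_pred].nonzero()[0]] = rng.integers(
        0, config.archetype_count, size=int(changing[:n_pred].sum())
    )
    prey_changing = n_pred + changing[n_pred:].nonzero()[0]
    arch_id[prey_changing] = rng.integers(0, len(prey_arch), size=len(prey_changing))

    # per-protein true trajectory over conditions (log2 units)
    traj = np.zeros((n, len(conds)))
    for i in range(n):
        if arch_id[i] < 0:
            continue
        bank = pred_arch if species[i] == "predator" else prey_arch
        traj[i] = config.effect_scale * bank.iloc[arch_id[i]].to_numpy()

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, n)

    # species-exclusivity background: predator barely present in the
    # prey-only channel and vice versa
    bg = np.ones((n, len(conds)))
    eps = config.cross_condition_background
    if "Ec" in conds:
        bg[species == "predator", conds.index("Ec")] = eps
    if "AP" in conds:
        bg[species == "prey", conds.index("AP")] = eps

    signal = baseline[:, None] * np.exp2(traj) * bg  # protein x condition
    mixture = signal.mean(axis=1)  # golden-standard pool (equal-weight)

    # batch structure
    plex_ids = [f"P{p+1}" for p in range(config.n_plexes)]
    plex_factor = rng.lognormal(0.0, config.plex_effect_sd, config.n_plexes)
    plex_factor /= np.exp(np.mean(np.log(plex_factor)))  # geometric mean 1
    plex_factor = pd.Series(plex_factor, index=plex_ids, name="plex_factor")

    ref_labels = [f"GS{j+1}" for j in range(config.n_reference_channels_per_plex)]
    design_rows = []
    for p, plex in enumerate(plex_ids):
        for cond in conds:
            design_rows.append((plex, cond, cond, p + 1, False))
        for lab in ref_labels:
            design_rows.append((plex, lab, "GS", p + 1, True))
    design = ChannelDesign(
        pd.DataFrame(
            design_rows,
            columns=["plex_id", "channel_label", "condition", "replicate", "is_reference"],
        )
    )

    loading = pd.Series(
        np.exp(rng.normal(0.0, config.loading_effect_sd, len(design.channel_ids))),
        index=design.channel_ids,
        name="loading_factor",
    )

    values = np.empty((n, len(design.channel_ids)))
    for j, cid in enumerate(design.channel_ids):
        row = design.table.loc[cid]
        base = mixture if row["is_reference"] else signal[:, conds.index(row["condition"])]
        noise = _lognormal_noise(rng, config.noise_cv, n)
        values[:, j] = base * plex_factor[row["plex_id"]] * loading[cid] * noise

    abundance = AbundanceMatrix(
        pd.DataFrame(values, index=pd.Index(pids, name="protein_id"),
                     columns=design.channel_ids),
        stage="raw",
    )
    meta = _make_meta(rng, pids, species)

    timecols = [c for c in conds if c not in ("AP", "Ec")]
    true_fc = pd.DataFrame(
        traj[:, [conds.index(c) for c in timecols]],
        index=abundance.protein_ids, columns=timecols,
    )
    truth = SimTruth(
        archetype_id=pd.Series(arch_id, index=abundance.protein_ids, name="archetype_id"),
        baseline=pd.Series(baseline, index=abundance.protein_ids, name="baseline"),
        log2fc=true_fc,
        plex_factor=plex_factor,
        loading_factor=loading,
        missing_mask=pd.DataFrame(
            False, index=abundance.protein_ids, columns=design.channel_ids
        ),
    )
    study = SimStudy(abundance, design, meta, truth, config)

    if config.missing_base_rate > 0:
        masked = inject_missingness(
            abundance,
            meta,
            base_rate=config.missing_base_rate,
            abundance_slope=config.missing_abundance_slope,
            length_slope=config.missing_length_slope,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth.missing_mask = masked.data.isna() & abundance.data.notna()
        study.abundance = masked
    return study


def inject_missingness(
    matrix: AbundanceMatrix,
    meta: ProteinMeta,
    base_rate: float,
    abundance_slope: float = 0.0,
    length_slope: float = 0.0,
    seed: int = 0,
) -> AbundanceMatrix:
    """Replace entries by the missing marker with a logistic model.

    The per-cell missingness probability is a logistic function centred
    at `base_rate`, decreasing in standardized log abundance
    (`abundance_slope` >= 0) and in standardized log protein length
    (`length_slope` >= 0); probabilities are clamped to [0, 1] by the
    logistic link itself.  ``base_rate`` 0 and 1 are honoured exactly.
    """
    if not 0.0 <= base_rate <= 1.0:
        raise ValueError("base_rate must be in [0, 1]")
    if base_rate == 0.0:
        return matrix.copy()
    if base_rate == 1.0:
        out = matrix.data.copy()
        out[:] = np.nan
        return AbundanceMatrix(out, matrix.stage)
    if abundance_slope < 0 or length_slope < 0:
        log.warning("negative missingness slope(s) invert the intended bias; clamped by the logistic link")

    rng = np.random.default_rng(seed)
    vals = matrix.data.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        la = np.log(np.where(vals > 0, vals, np.nan))
    mu, sd = np.nanmean(la), np.nanstd(la)
    z_a = np.where(np.isfinite(la), (la - mu) / (sd if sd > 0 else 1.0), -3.0)

    lengths = pd.to_numeric(
        meta.table["length"].reindex(matrix.protein_ids), errors="coerce"
    ).to_numpy(dtype=float)
    ll = np.log(np.where(lengths > 0, lengths, np.nan))
    lmu, lsd = np.nanmean(ll), np.nanstd(ll)
    z_l = np.where(np.isfinite(ll), (ll - lmu) / (lsd if lsd > 0 else 1.0), 0.0)

    eta = logit(base_rate) - abundance_slope * z_a - length_slope * z_l[:, None]
    p_missing = expit(eta)
    mask = rng.random(vals.shape) < p_missing
    out = matrix.data.copy()
    out.values[mask] = np.nan
    return AbundanceMatrix(out, matrix.stage)


# ---------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------

def write_fixture(study: SimStudy, directory) -> dict:
    """Write abundance/design/meta/truth TSVs that round-trip via io_core."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": io_core.write_abundance_table(
            study.abundance, directory / "abundance.tsv"
        ),
        "design": io_core.write_design(study.design, directory / "design.tsv"),
        "meta": io_core.write_protein_meta(study.meta, directory / "meta.tsv"),
    }
    truth = pd.concat(
        [study.truth.archetype_id, study.truth.baseline, study.truth.log2fc], axis=1
    )
    truth.index.name = "protein_id"
    tpath = directory / "truth.tsv"
    truth.to_csv(tpath, sep="\t", float_format="%.10g")
    paths["truth"] = tpath
    fpath = directory / "factors.tsv"
    pd.DataFrame(
        {
            "plex_id": study.truth.plex_factor.index,
            "plex_factor": study.truth.plex_factor.to_numpy(),
        }
    ).to_csv(fpath, sep="\t", index=False, float_format="%.10g")
    paths["factors"] = fpath
    return paths
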