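"""End-to-end orchestration of the analysis chain.

Order of operations (mirroring the study's analysis): contaminant
removal -> complete-case filter (sample and reference channels of every
plex) -> in-silico baseline pooling -> SL -> IRS -> TMM on the combined
two-species matrix -> split by species -> per-species >1 filter, log2,
channel median-centering -> imputation -> condition + plex moderated
linear model with contrasts vs AP_Ec -> replicate averaging ->
baseline-relative profiles -> significance prefilter -> hierarchical
clustering with merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import clusterprof, diffexp, io_core, normalize, report
from .datatypes import AbundanceMatrix, ChannelDesign, ProteinMeta
from .tmt_sim import SimStudy

log = logging.getLogger(__name__)


@dataclass
class SpeciesResult:
    """Per-species results of the analysis chain."""

    log2_matrix: AbundanceMatrix          # imputed log2-stage matrix
    imputed_mask: pd.DataFrame
    model: diffexp.ModeratedConditionModel
    de: pd.DataFrame                      # protein x contrast table
    averaged: AbundanceMatrix             # condition-level means
    profiles: pd.DataFrame                # baseline-relative trajectories
    significant_ids: pd.Index
    clusters: clusterprof.ClusterAssignment | None


@dataclass
class PipelineResult:
    design: ChannelDesign                 # design incl. pooled AP_Ec channels
    normalized: AbundanceMatrix           # TMM-stage combined matrix
    factors: dict                         # stage -> NormalizationFactors
    species: dict = field(default_factory=dict)  # tag -> SpeciesResult
    counts: dict = field(default_factory=dict)   # stage -> protein count

    @property
    def predator(self) -> SpeciesResult:
        return self.species["predator"]


def run_pipeline(
    abundance: AbundanceMatrix,
    design: ChannelDesign,
    meta: ProteinMeta,
    pool_mode: str = "sum",
    mad_scale: bool = False,
    fc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    cluster_k: int = 18,
    merge_r: float = 0.9,
    prefilter_p: float = 0.001,
    prefilter_q: float = 0.01,
    analyze_species: tuple = ("predator",),
    do_cluster: bool = True,
) -> PipelineResult:
    """Run the full chain on in-memory tables; see the module docstring."""
    counts = {"input": abundance.shape[0]}
    m = io_core.filter_contaminants(abundance, meta)
    counts["after_contaminant_filter"] = m.shape[0]
    m = io_core.filter_complete_cases(m, design)
    counts["after_complete_case_filter"] = m.shape[0]

    pooled, design2 = normalize.pool_baseline(m, design, mode=pool_mode)
    sl, f_sl = normalize.sl_normalize(pooled, design2)
    irs, f_irs = normalize.irs_normalize(sl, design2)
    tmm, f_tmm = normalize.apply_tmm(irs, design2)
    factors = {"sl": f_sl, "irs": f_irs, "tmm": f_tmm}

    result = PipelineResult(
        design=design2, normalized=tmm, factors=factors, counts=counts
    )
    by_species = io_core.split_by_species(tmm, meta)
    for tag in analyze_species:
        if tag not in by_species or by_species[tag].shape[0] == 0:
            log.warning("no proteins for species %r; skipped", tag)
            continue
        sub = by_species[tag]
        counts[f"{tag}_split"] = sub.shape[0]
        logm = normalize.finalize_transform(sub, mad_scale=mad_scale)
        counts[f"{tag}_log2"] = logm.shape[0]
        imputed, mask = diffexp.impute_missing(logm, design2)
        model = diffexp.ModeratedConditionModel(design2).fit(imputed)
        de = diffexp.de_table(
            model, fc_threshold=fc_threshold, q_threshold=q_threshold
        )
        averaged = normalize.average_replicates(imputed, design2)
        profiles = clusterprof.baseline_relative_profiles(averaged)
        sig = diffexp.moderated_f_filter(
            model, p_threshold=prefilter_p, q_threshold=prefilter_q
        )
        sig = profiles.index.intersection(sig)
        clusters = None
        if do_cluster and len(sig) >= cluster_k:
            est = clusterprof.ProfileClusterer(k=cluster_k, merge_r=merge_r)
            est.fit(profiles, sig)
            clusters = est.assignment_
        counts[f"{tag}_significant"] = len(sig)
        result.species[tag] = SpeciesResult(
            log2_matrix=imputed,
            imputed_mask=mask,
            model=model,
            de=de,
            averaged=averaged,
            profiles=profiles,
            significant_ids=sig,
            clusters=clusters,
        )
    return result


def run_on_study(study: SimStudy, **kwargs) -> PipelineResult:
    """Convenience wrapper for simulated studies."""
    return run_pipeline(study.abundance, study.design, study.meta, **kwargs)


def estimated_log2fc(result: PipelineResult, species: str = "predator") -> pd.DataFrame:
    """Per-protein estimated log2FC vs AP_Ec, one column per timepoint."""
    sp = result.species[species]
    fit = sp.model.fit_
    return fit.effects.copy()
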