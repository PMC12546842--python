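"""The normalization chain: pooling -> SL -> IRS -> TMM -> log2 -> averaging.

Each step is a scikit-learn-style transformer operating on an
:class:`~cyclequant.datatypes.AbundanceMatrix`; the channel design is a
constructor argument because every step needs it.  Fitted scale factors
are exposed as trailing-underscore attributes.  Module-level functions
wrap the transformers for one-shot use.

Stages and their guarantees
---------------------------
* **pooling** adds a per-plex pseudo-channel ``AP_Ec`` combining the
  attack-phase and prey-only channels (sum by default, mimicking a
  physical mixture of both lysates).
* **SL** (sample loading) equalizes total signal per channel within each
  plex: afterwards every channel total equals the pre-normalization plex
  mean exactly.
* **IRS** (internal reference scaling) anchors plexes on the
  golden-standard channels: per protein, each plex is scaled so the
  geometric mean of its reference-channel values equals the geometric
  mean across plexes; afterwards the per-protein reference summaries are
  identical across plexes.
* **TMM** (trimmed mean of M-values) removes residual compositional
  shifts with a doubly trimmed, precision-weighted mean of log ratios
  against an automatically chosen reference channel.
* **finalize** sets values <= 1 to missing, log2-transforms, and
  median-centers each channel (robust scaling; MAD division optional).
* **averaging** collapses the five plexes to one value per condition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    AbundanceMatrix,
    ChannelDesign,
    NormalizationFactors,
    StageError,
    ValidationError,
    channel_id,
)

log = logging.getLogger(__name__)


def _geomean(x: np.ndarray, axis=None) -> np.ndarray:
    return np.exp(np.nanmean(np.log(x), axis=axis))


# ---------------------------------------------------------------------
# baseline pooling
# ---------------------------------------------------------------------

class BaselinePooler(BaseEstimator, TransformerMixin):
    """Add the in-silico pooled ``AP_Ec`` baseline channel to every plex.

    Parameters
    ----------
    design : ChannelDesign
    mode : {"sum", "mean"}
        ``sum`` (default) adds the raw AP and Ec abundances, mimicking a
        physical mixture of both lysates; ``mean`` averages them.
    """

    def __init__(self, design: ChannelDesign, mode: str = "sum"):
        self.design = design
        self.mode = mode

    def fit(self, X: AbundanceMatrix, y=None):
        if self.mode not in ("sum", "mean"):
            raise ValueError(f"mode must be 'sum' or 'mean', got {self.mode!r}")
        X.require_stage("raw")
        for plex in self.design.plexes:
            tbl = self.design.table
            sub = tbl[(tbl["plex_id"] == plex) & ~tbl["is_reference"]]
            for cond in ("AP", "Ec"):
                if not (sub["condition"] == cond).any():
                    raise ValidationError(f"plex {plex!r} lacks an {cond} channel")
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        X.require_stage("raw")
        data = X.data.copy()
        rows = []
        tbl = self.design.table
        for plex in self.design.plexes:
            sub = tbl[(tbl["plex_id"] == plex) & ~tbl["is_reference"]]
            ap = sub.index[sub["condition"] == "AP"][0]
            ec = sub.index[sub["condition"] == "Ec"][0]
            pooled = data[ap] + data[ec]  # NaN propagates
            if self.mode == "mean":
                pooled = pooled / 2.0
            data[channel_id(plex, "AP_Ec")] = pooled
            rows.append(
                (plex, "AP_Ec", "AP_Ec", int(sub.loc[ap, "replicate"]), False)
            )
        self.design_ = self.design.with_rows(
            pd.DataFrame(
                rows,
                columns=["plex_id", "channel_label", "condition", "replicate",
                         "is_reference"],
            )
        )
        return X.advanced(data, "pooled")


def pool_baseline(matrix, design, mode="sum"):
    """One-shot baseline pooling; returns (matrix, updated design)."""
    pooler = BaselinePooler(design, mode=mode).fit(matrix)
    out = pooler.transform(matrix)
    return out, pooler.design_


# ---------------------------------------------------------------------
# sample loading
# ---------------------------------------------------------------------

class SampleLoadingNormalizer(BaseEstimator, TransformerMixin):
    """Equalize per-channel totals within each plex (SL normalization).

    ``factor(channel) = mean(plex channel totals) / channel total``;
    totals are computed over present values only.
    """

    def __init__(self, design: ChannelDesign):
        self.design = design

    def fit(self, X: AbundanceMatrix, y=None):
        X.require_stage("pooled", "raw")
        totals = X.data.sum(axis=0, skipna=True)
        factors = {}
        for plex in self.design.plexes:
            chans = [c for c in self.design.channels_of_plex(plex) if c in X.channel_ids]
            t = totals[chans]
            if (t <= 0).any():
                bad = t.index[t <= 0][0]
                raise ValidationError(f"channel {bad!r} has zero total signal")
            for c in chans:
                factors[c] = t.mean() / t[c]
        self.sl_factors_ = pd.Series(factors, name="sl_factor")
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        X.require_stage("pooled", "raw")
        data = X.data.mul(self.sl_factors_.reindex(X.channel_ids), axis=1)
        return X.advanced(data, "sl")


def sl_normalize(matrix, design):
    norm = SampleLoadingNormalizer(design).fit(matrix)
    out = norm.transform(matrix)
    return out, NormalizationFactors(sl_factor=norm.sl_factors_)


# ---------------------------------------------------------------------
# internal reference scaling
# ---------------------------------------------------------------------

class InternalReferenceScaler(BaseEstimator, TransformerMixin):
    """Anchor plexes on the golden-standard channels, per protein (IRS).

    For each protein: the plex reference summary is the geometric mean of
    that plex's present reference-channel values; the global anchor is
    the geometric mean of the plex summaries; every channel of a plex is
    multiplied by ``anchor / summary``.
    """

    def __init__(self, design: ChannelDesign):
        self.design = design

    def fit(self, X: AbundanceMatrix, y=None):
        X.require_stage("sl")
        plexes = self.design.plexes
        summaries = pd.DataFrame(index=X.protein_ids, columns=plexes, dtype=float)
        for plex in plexes:
            refs = [c for c in self.design.reference_channels(plex) if c in X.channel_ids]
            if not refs:
                raise ValidationError(f"plex {plex!r} has no reference channel in matrix")
            vals = X.data[refs].to_numpy(dtype=float)
            bad = np.all(~(vals > 0), axis=1)  # no positive present value
            if bad.any():
                pid = X.protein_ids[bad][0]
                raise ValidationError(
                    f"protein {pid!r} has no positive reference value in plex {plex!r}"
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                logs = np.log(np.where(vals > 0, vals, np.nan))
            summaries[plex] = np.exp(np.nanmean(logs, axis=1))
        anchor = _geomean(summaries.to_numpy(), axis=1)
        self.reference_summary_ = summaries
        self.irs_factors_ = summaries.rdiv(anchor, axis=0)
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        X.require_stage("sl")
        data = X.data.copy()
        for plex in self.design.plexes:
            chans = [c for c in self.design.channels_of_plex(plex) if c in X.channel_ids]
            data[chans] = data[chans].mul(
                self.irs_factors_[plex].reindex(X.protein_ids), axis=0
            )
        return X.advanced(data, "irs")


def irs_normalize(matrix, design):
    norm = InternalReferenceScaler(design).fit(matrix)
    out = norm.transform(matrix)
    return out, NormalizationFactors(
        irs_factor=norm.irs_factors_, reference_summary=norm.reference_summary_
    )


# ---------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------

def tmm_factor(
    sample,
    reference,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_kept: int = 10,
) -> float:
    """Pairwise TMM scale factor of `sample` relative to `reference`.

    Per protein, ``M = log2(sample/reference)`` and
    ``A = (log2 sample + log2 reference)/2`` are computed on
    total-normalized proportions; proteins in the outer `trim_m` tails of
    M and `trim_a` tails of A (rank-based, two-sided) are discarded; the
    factor is ``(N_s/N_r) * 2**w``, where ``w`` is the precision-weighted
    mean of the surviving M values with weights ``1/(1/p_s + 1/p_r)``
    (inverse delta-method variance of a log ratio, up to a constant).
    Zeros and missing values are excluded pairwise.  If fewer than
    `min_kept` proteins survive the trims, an untrimmed weighted mean is
    used with a warning.
    """
    obs = np.asarray(sample, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if obs.shape != ref.shape:
        raise ValueError("sample and reference must have equal length")
    ok = np.isfinite(obs) & np.isfinite(ref) & (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        raise ValidationError("no pairwise-positive proteins for TMM")
    n_obs, n_ref = obs.sum(), ref.sum()
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
    w = 1.0 / (1.0 / p_obs + 1.0 / p_ref)

    if np.max(np.abs(m)) < 1e-10:
        return float(n_obs / n_ref)

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep.sum() < min_kept:
        log.warning(
            "only %d proteins survive TMM trims; falling back to untrimmed mean",
            int(keep.sum()),
        )
        keep = np.ones(n, dtype=bool)
    f = np.sum(m[keep] * w[keep]) / np.sum(w[keep])
    return float(n_obs / n_ref * 2.0**f)


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """Per-channel TMM factors against an automatically chosen reference.

    The reference is the channel whose upper-quartile proportion is
    closest to the mean upper-quartile proportion over all channels.
    Factors are geometric-mean-centered to 1 and channels are divided by
    their factor.
    """

    def __init__(self, design: ChannelDesign | None = None,
                 trim_m: float = 0.30, trim_a: float = 0.05):
        self.design = design
        self.trim_m = trim_m
        self.trim_a = trim_a

    def fit(self, X: AbundanceMatrix, y=None):
        X.require_stage("irs")
        data = X.data
        # The golden-standard mixture has the study-average composition,
        # so condition-specific proteins sit in the tails of every M
        # distribution against it and are trimmed away; prefer it as the
        # TMM reference when the design provides one.
        refs = (
            [c for c in self.design.reference_channels() if c in X.channel_ids]
            if self.design is not None
            else []
        )
        if refs:
            candidates = pd.Index(refs)
        else:
            candidates = X.channel_ids
        totals = data.sum(axis=0, skipna=True)
        q75 = pd.Series(
            {
                c: np.nanquantile(data[c].to_numpy(dtype=float) / totals[c], 0.75)
                for c in candidates
            }
        )
        self.reference_channel_ = (q75 - q75.mean()).abs().idxmin()
        ref_vals = data[self.reference_channel_]
        factors = pd.Series(
            {
                c: tmm_factor(data[c], ref_vals, self.trim_m, self.trim_a)
                for c in X.channel_ids
            },
            name="tmm_factor",
        )
        factors = factors / _geomean(factors.to_numpy())
        self.tmm_factors_ = factors
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        X.require_stage("irs")
        data = X.data.div(self.tmm_factors_.reindex(X.channel_ids), axis=1)
        return X.advanced(data, "tmm")


def apply_tmm(matrix, design=None, trim_m=0.30, trim_a=0.05):
    norm = TMMNormalizer(design, trim_m=trim_m, trim_a=trim_a).fit(matrix)
    out = norm.transform(matrix)
    return out, NormalizationFactors(tmm_factor=norm.tmm_factors_)


# ---------------------------------------------------------------------
# finalize (>1 filter, robust scaling, log2)
# ---------------------------------------------------------------------

class Log2Finalizer(BaseEstimator, TransformerMixin):
    """Filter values <= 1 to missing, log2, median-center each channel.

    `mad_scale` additionally divides each channel by 1.4826 x the median
    absolute deviation of its log2 values (off by default: it would
    destroy the fold-change interpretation of the log2 differences).
    """

    FILTER_THRESHOLD = 1.0

    def __init__(self, mad_scale: bool = False):
        self.mad_scale = mad_scale

    def fit(self, X: AbundanceMatrix, y=None):
        X.require_stage("tmm")
        vals = X.data.where(X.data > self.FILTER_THRESHOLD)
        dead = vals.notna().sum(axis=0) == 0
        if dead.any():
            raise ValidationError(
                f"channel {vals.columns[dead][0]!r} has all values <= "
                f"{self.FILTER_THRESHOLD}"
            )
        logs = np.log2(vals)
        self.channel_median_ = logs.median(axis=0, skipna=True)
        if self.mad_scale:
            mad = (logs - self.channel_median_).abs().median(axis=0, skipna=True)
            self.channel_scale_ = 1.4826 * mad
        else:
            self.channel_scale_ = pd.Series(1.0, index=X.channel_ids)
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        X.require_stage("tmm")
        vals = X.data.where(X.data > self.FILTER_THRESHOLD)
        surviving = vals.notna().any(axis=1)
        if (~surviving).any():
            log.info("dropping %d rows with no values > 1", int((~surviving).sum()))
        logs = np.log2(vals.loc[surviving])
        logs = logs.sub(self.channel_median_, axis=1).div(self.channel_scale_, axis=1)
        return X.advanced(logs, "log2")


def finalize_transform(matrix, mad_scale=False):
    return Log2Finalizer(mad_scale=mad_scale).fit(matrix).transform(matrix)


# ---------------------------------------------------------------------
# replicate averaging
# ---------------------------------------------------------------------

class ReplicateAverager(BaseEstimator, TransformerMixin):
    """Average log2 values of each condition over the plexes."""

    def __init__(self, design: ChannelDesign):
        self.design = design

    def fit(self, X: AbundanceMatrix, y=None):
        X.require_stage("log2")
        return self

    def transform(self, X: AbundanceMatrix) -> AbundanceMatrix:
        X.require_stage("log2")
        conds = [c for c in self.design.conditions if c != "GS"]
        out = pd.DataFrame(index=X.protein_ids, columns=conds, dtype=float)
        counts = pd.DataFrame(0, index=X.protein_ids, columns=conds, dtype=int)
        for cond in conds:
            chans = [
                c for c in self.design.channels_of_condition(cond)
                if c in X.channel_ids
            ]
            block = X.data[chans]
            n_obs = block.notna().sum(axis=1)
            out[cond] = block.mean(axis=1, skipna=True)
            counts[cond] = n_obs
        empty = int((counts == 0).to_numpy().sum())
        if empty:
            log.warning("%d (protein, condition) cells have zero observations", empty)
        self.n_observed_ = counts
        return X.advanced(out, "averaged")


def average_replicates(matrix, design):
    return ReplicateAverager(design).fit(matrix).transform(matrix)
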