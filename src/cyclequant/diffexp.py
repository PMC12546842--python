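"""Linear modelling and empirical-Bayes moderated-t differential expression.

The per-protein model is additive in condition and plex (the biological
repeat / TMT experiment):

    y_gpc = mu_g + condition_gc + plex_gp + e_gpc ,   e ~ N(0, s2_g)

fit by least squares for all proteins at once (the design matrix is
shared once missing values have been imputed).  Residual variances are
shrunk toward an empirical-Bayes prior estimated by trigamma
moment-matching on log s2 (the "pooled variance" of the moderated
t-test): the posterior variance is

    s2_tilde_g = (d0 * s02 + d_g * s2_g) / (d0 + d_g)

and contrasts against the pooled attack-phase baseline (AP_Ec) are
tested with t = log2FC / (s_tilde_g * m_c) on d0 + d_g degrees of
freedom, where m_c is the contrast standard-error multiplier.  P-values
are adjusted per contrast with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    AbundanceMatrix,
    BASELINE_CONDITION,
    ChannelDesign,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Conditions reported but never modelled against the pooled baseline.
REPORT_ONLY_CONDITIONS = ("AP", "Ec", "GS")


# ---------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------

def impute_missing(matrix: AbundanceMatrix, design: ChannelDesign):
    """Deterministic group-difference imputation of log2 abundances.

    A missing cell becomes the mean of the observed replicates of the
    same (protein, condition); a condition with no observation at all
    falls back to the protein's minimum observed value across conditions
    (a deterministic abundance floor).  Proteins observed nowhere are
    dropped with a warning.

    Returns
    -------
    (AbundanceMatrix, DataFrame)
        The completed matrix and a boolean mask of imputed cells.
    """
    matrix.require_stage("log2")
    data = matrix.data.copy()
    observed_any = data.notna().any(axis=1)
    if (~observed_any).any():
        log.warning(
            "dropping %d protein(s) with no observations", int((~observed_any).sum())
        )
        data = data.loc[observed_any]
    cond_of = design.table["condition"]
    row_min = data.min(axis=1, skipna=True)
    filled = data.copy()
    for cond in dict.fromkeys(cond_of):
        chans = [c for c in design.channels_of_condition(cond) if c in data.columns]
        if not chans:
            continue
        block = data[chans]
        group_mean = block.mean(axis=1, skipna=True)
        fallback = group_mean.fillna(row_min)
        for c in chans:
            filled[c] = filled[c].fillna(fallback)
    mask = filled.notna() & data.isna()
    n_imputed = int(mask.to_numpy().sum())
    if n_imputed:
        log.info("imputed %d missing cell(s)", n_imputed)
    return AbundanceMatrix(filled, "log2"), mask


# ---------------------------------------------------------------------
# variance moderation
# ---------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def moderate_variances(s2, df):
    """Estimate the empirical-Bayes prior (d0, s02) and posterior variances.

    Moment-matching on ``log s2`` using digamma/trigamma identities for
    the distribution of a scaled chi-square on `df` degrees of freedom.
    When the moment equation implies infinite prior df (observed spread
    of log s2 no larger than expected under equal true variances), all
    posterior variances collapse to s02.

    Returns ``(d0, s02, posterior)`` with posterior aligned to `s2`.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        # degenerate input (e.g. constant data): no spread to moderate
        s02 = float(np.nanmean(np.where(np.isfinite(s2), s2, np.nan)))
        return np.inf, s02, np.full_like(s2, s02)
    z = np.log(s2[ok])
    e = z - digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    ebar = float(np.mean(e))
    n = e.size
    evar = float(np.sum((e - ebar) ** 2) / (n - 1))
    t2 = evar - float(np.mean(polygamma(1, df[ok] / 2.0)))
    if t2 > 0:
        d0 = 2.0 * _trigamma_inverse(t2)
        s02 = float(np.exp(ebar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(ebar))
    posterior = posterior_variance(s2, df, d0, s02)
    return d0, s02, posterior


def posterior_variance(s2, df, d0, s02):
    """Shrinkage formula ``(d0*s02 + df*s2) / (d0 + df)`` (d0 may be 0 or inf)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.isinf(d0):
        return np.full_like(s2, s02)
    return (d0 * s02 + df * s2) / (d0 + df)


# ---------------------------------------------------------------------
# model
# ---------------------------------------------------------------------

@dataclass
class ModelFit:
    """Least-squares fit of the additive condition + plex model."""

    effects: pd.DataFrame        # protein x condition (relative to baseline)
    s2: pd.Series                # residual variance per protein
    df_resid: float              # residual degrees of freedom
    se_mult: pd.Series           # contrast SE multiplier per condition
    f_se_matrix: np.ndarray      # (C (X'X)^-1 C')^-1 for the omnibus F
    conditions: list             # modelled non-baseline conditions
    baseline: str


class ModeratedConditionModel(BaseEstimator):
    """Condition + plex linear model with empirical-Bayes moderated tests.

    Parameters
    ----------
    design : ChannelDesign
    baseline : str
        Reference condition for all contrasts (default ``AP_Ec``).
    exclude_conditions : tuple
        Conditions kept out of the model (reported separately).

    Fitted attributes: ``effects_`` (protein x condition log2 effects vs
    baseline), ``s2_``, ``df_resid_``, ``d0_``, ``s02_``,
    ``posterior_var_``.
    """

    def __init__(self, design: ChannelDesign, baseline: str = BASELINE_CONDITION,
                 exclude_conditions: tuple = REPORT_ONLY_CONDITIONS):
        self.design = design
        self.baseline = baseline
        self.exclude_conditions = exclude_conditions

    # -- design matrix ----------------------------------------------
    def _design_matrix(self, channels):
        tbl = self.design.table.loc[channels]
        conds = [c for c in dict.fromkeys(tbl["condition"]) if c != self.baseline]
        plexes = list(dict.fromkeys(tbl["plex_id"]))
        if self.baseline not in set(tbl["condition"]):
            raise ValidationError(f"baseline condition {self.baseline!r} absent")
        cols = {"intercept": np.ones(len(tbl))}
        for c in conds:
            cols[f"cond:{c}"] = (tbl["condition"] == c).to_numpy(dtype=float)
        for p in plexes[1:]:
            cols[f"plex:{p}"] = (tbl["plex_id"] == p).to_numpy(dtype=float)
        X = pd.DataFrame(cols, index=channels)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ValidationError(
                f"rank-deficient design: {X.shape[1] - rank} aliased term(s) "
                f"among {list(X.columns)}"
            )
        return X, conds

    def fit(self, X: AbundanceMatrix, y=None):
        X.require_stage("log2")
        tbl = self.design.table
        use = [
            c for c in X.channel_ids
            if c in tbl.index
            and not tbl.loc[c, "is_reference"]
            and tbl.loc[c, "condition"] not in self.exclude_conditions
        ]
        if len({tbl.loc[c, "condition"] for c in use}) < 2:
            raise ValidationError("need >= 2 modelled conditions")
        Y = X.data[use].to_numpy(dtype=float).T  # channels x proteins
        if np.isnan(Y).any():
            raise ValidationError("matrix has missing values; impute first")
        D, conds = self._design_matrix(use)
        Dm = D.to_numpy()
        n, p = Dm.shape
        beta, *_ = np.linalg.lstsq(Dm, Y, rcond=None)
        resid = Y - Dm @ beta
        df = n - p
        if df < 1:
            raise ValidationError("non-positive residual degrees of freedom")
        s2 = (resid**2).sum(axis=0) / df

        xtx_inv = np.linalg.inv(Dm.T @ Dm)
        cond_rows = [list(D.columns).index(f"cond:{c}") for c in conds]
        se_mult = pd.Series(
            {c: float(np.sqrt(xtx_inv[r, r])) for c, r in zip(conds, cond_rows)},
            name="se_mult",
        )
        C = np.zeros((len(conds), p))
        for i, r in enumerate(cond_rows):
            C[i, r] = 1.0
        f_se = np.linalg.inv(C @ xtx_inv @ C.T)

        self.fit_ = ModelFit(
            effects=pd.DataFrame(
                beta[cond_rows].T, index=X.protein_ids, columns=conds
            ),
            s2=pd.Series(s2, index=X.protein_ids, name="s2"),
            df_resid=float(df),
            se_mult=se_mult,
            f_se_matrix=f_se,
            conditions=conds,
            baseline=self.baseline,
        )
        self.effects_ = self.fit_.effects
        self.s2_ = self.fit_.s2
        self.df_resid_ = self.fit_.df_resid
        self.d0_, self.s02_, post = moderate_variances(s2, df)
        self.posterior_var_ = pd.Series(post, index=X.protein_ids, name="s2_tilde")
        return self

    # -- tests --------------------------------------------------------
    def contrast(self, condition: str, d0: float | None = None) -> pd.DataFrame:
        """Moderated-t contrast of `condition` against the baseline."""
        fit = self.fit_
        if condition not in fit.conditions:
            raise ValidationError(f"condition {condition!r} not in the model")
        d0 = self.d0_ if d0 is None else d0
        post = posterior_variance(fit.s2.to_numpy(), fit.df_resid, d0, self.s02_)
        log2fc = fit.effects[condition].to_numpy()
        se = np.sqrt(post) * fit.se_mult[condition]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, log2fc / se, 0.0)
        df_total = d0 + fit.df_resid
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        return pd.DataFrame(
            {"log2fc": log2fc, "t": t, "p": p}, index=fit.effects.index
        )

    def f_test(self, d0: float | None = None) -> pd.DataFrame:
        """Moderated omnibus F for any condition effect, with BH q-values."""
        fit = self.fit_
        m = len(fit.conditions)
        if m < 2:
            raise ValidationError("omnibus F needs >= 2 non-baseline conditions")
        d0 = self.d0_ if d0 is None else d0
        post = posterior_variance(fit.s2.to_numpy(), fit.df_resid, d0, self.s02_)
        B = fit.effects.to_numpy()  # proteins x m
        quad = np.einsum("gi,ij,gj->g", B, fit.f_se_matrix, B)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(post > 0, quad / (m * post), np.inf)
        df2 = d0 + fit.df_resid
        if np.isinf(df2):
            p = stats.chi2.sf(m * F, m)
        else:
            p = stats.f.sf(F, m, df2)
        q = bh_adjust(p)
        return pd.DataFrame({"F": F, "p": p, "q": q}, index=fit.effects.index)


def fit_condition_model(matrix, design, baseline=BASELINE_CONDITION) -> ModelFit:
    """Least-squares fit only (no moderation); returns the ModelFit."""
    model = ModeratedConditionModel(design, baseline=baseline).fit(matrix)
    return model.fit_


# ---------------------------------------------------------------------
# multiple testing, calls, folds
# ---------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, per contrast)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_regulation(log2fc, q, fc_threshold: float = 1.0,
                        q_threshold: float = 0.05) -> np.ndarray:
    """Regulation calls: up / down / ns at |log2FC| and FDR thresholds."""
    log2fc = np.asarray(log2fc, dtype=float)
    q = np.asarray(q, dtype=float)
    call = np.full(log2fc.shape, "ns", dtype=object)
    call[(log2fc >= fc_threshold) & (q < q_threshold)] = "up"
    call[(log2fc <= -fc_threshold) & (q < q_threshold)] = "down"
    return call


def fold_change_linear(log2fc) -> np.ndarray:
    """Linear fold change ``2**log2FC`` rounded half-up to one decimal."""
    arr = np.atleast_1d(np.asarray(log2fc, dtype=float))
    lin = np.exp2(arr)
    rounded = np.floor(lin * 10.0 + 0.5) / 10.0
    return rounded if np.ndim(log2fc) else float(rounded[0])


def de_table(model: ModeratedConditionModel, conditions=None,
             fc_threshold: float = 1.0, q_threshold: float = 0.05) -> pd.DataFrame:
    """Full differential-expression table, one row per protein x contrast.

    BH adjustment is applied within each contrast separately.
    """
    conditions = conditions or model.fit_.conditions
    frames = []
    for cond in conditions:
        res = model.contrast(cond)
        res["q"] = bh_adjust(res["p"].to_numpy())
        res["fold"] = fold_change_linear(res["log2fc"].to_numpy())
        res["call"] = classify_regulation(
            res["log2fc"], res["q"], fc_threshold, q_threshold
        )
        res.insert(0, "contrast", f"{cond}_vs_{model.fit_.baseline}")
        res.insert(0, "condition", cond)
        res.index.name = "protein_id"
        frames.append(res.reset_index())
    return pd.concat(frames, ignore_index=True)


def moderated_f_filter(model: ModeratedConditionModel,
                       p_threshold: float = 0.001,
                       q_threshold: float = 0.01) -> pd.Index:
    """Protein ids passing the clustering prefilter (omnibus moderated F)."""
    res = model.f_test()
    keep = (res["p"] < p_threshold) & (res["q"] < q_threshold)
    return res.index[keep]


# ---------------------------------------------------------------------
# power
# ---------------------------------------------------------------------

@dataclass
class PowerSpec:
    """Replicate-power design: detect a linear `fold` change with a
    two-sample t-test at level `alpha`, `n` replicates per group, given
    per-protein log2-scale SDs."""

    fold: float = 1.5
    alpha: float = 0.05
    n: int = 5
    sd: np.ndarray = None
    target: float = 0.8

    def __post_init__(self):
        if self.fold <= 1:
            raise ValueError("fold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def t_test_power(sd, n: int, fold: float, alpha: float):
    """Analytic two-sided two-sample t-test power (noncentral t)."""
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be >= 0")
    df = 2 * n - 2
    tcrit = stats.t.ppf(1 - alpha / 2.0, df)
    with np.errstate(divide="ignore"):
        ncp = np.where(sd > 0, np.log2(fold) / (sd * np.sqrt(2.0 / n)), np.inf)
    power = np.where(
        np.isinf(ncp),
        1.0,
        stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp),
    )
    return power


def detection_power_fraction(spec: PowerSpec) -> float:
    """Fraction of proteins whose analytic power meets the target.

    The comparison is boundary-inclusive (power == target counts), with
    a 1e-9 numeric grace.
    """
    power = t_test_power(spec.sd, spec.n, spec.fold, spec.alpha)
    return float(np.mean(power >= spec.target - 1e-9))
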