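"""QC and summary outputs: PCA of normalized samples, proteome coverage,
protein-length/membrane bias diagnostics, volcano tables and heatmap
leaf ordering."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .datatypes import AbundanceMatrix, ProteinMeta, ValidationError
from .diffexp import classify_regulation

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame                 # samples x PCs
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame               # proteins x PCs

    def __post_init__(self):
        evr = self.explained_variance_ratio
        assert np.all((evr >= -1e-12) & (evr <= 1 + 1e-12))
        assert np.all(np.diff(evr) <= 1e-12)


def pca_scores(matrix: AbundanceMatrix, scale: bool = False,
               n_components: int | None = None) -> PcaResult:
    """PCA of samples (channels as observations, proteins as variables).

    Per-protein centering; no unit-variance scaling unless `scale`.  The
    sign of each component is fixed so its largest-magnitude loading is
    positive.  Requires a complete matrix and >= 3 samples.
    """
    matrix.require_stage("log2", "averaged")
    data = matrix.data
    if data.shape[1] < 3:
        raise ValidationError("PCA needs at least 3 samples")
    if data.isna().to_numpy().any():
        raise ValidationError("PCA needs a complete matrix; impute first")
    X = data.to_numpy(dtype=float).T  # samples x proteins
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    m = min(X.shape[0] - 1, X.shape[1])
    if n_components is not None:
        m = min(m, n_components)
    U, S, Vt = U[:, :m], S[:m], Vt[:m]
    # deterministic sign: largest-|loading| entry positive per component
    for i in range(m):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * S
    var = S**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    pcs = [f"PC{i+1}" for i in range(m)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=data.columns, columns=pcs),
        explained_variance_ratio=evr,
        loadings=pd.DataFrame(Vt.T, index=data.index, columns=pcs),
    )


# ---------------------------------------------------------------------
# coverage / length bias
# ---------------------------------------------------------------------

def coverage_fraction(n_quantified: int, n_database: int) -> int:
    """Percentage of the proteome quantified, rounded to nearest integer."""
    if n_database <= 0:
        raise ValueError("n_database must be > 0")
    if not 0 <= n_quantified <= n_database:
        raise ValueError("need 0 <= n_quantified <= n_database")
    return int(np.floor(100.0 * n_quantified / n_database + 0.5))


def length_bias_table(meta: ProteinMeta, quantified_ids,
                      bin_width: int = 50) -> pd.DataFrame:
    """Identified/database ratios per length bin and membrane class.

    Bins are half-open ``[low, high)`` of `bin_width` amino acids.
    """
    quantified_ids = pd.Index(quantified_ids)
    missing = quantified_ids.difference(meta.protein_ids)
    if len(missing):
        raise ValidationError(
            f"quantified protein(s) absent from database meta: {list(missing[:5])}"
        )
    tbl = meta.table
    lengths = pd.to_numeric(tbl["length"], errors="coerce")
    if lengths.isna().any():
        raise ValidationError("lengths required for all database proteins")
    membrane = tbl.get("is_membrane", pd.Series(False, index=tbl.index)).astype(bool)
    quantified = tbl.index.isin(quantified_ids)
    lo_bins = (lengths // bin_width * bin_width).astype(int)
    df = pd.DataFrame(
        {
            "bin_low": lo_bins,
            "class": np.where(membrane, "membrane", "non-membrane"),
            "quantified": quantified,
        }
    )
    rows = []
    for (lo, cls), grp in df.groupby(["bin_low", "class"]):
        n_db = len(grp)
        n_q = int(grp["quantified"].sum())
        rows.append((lo, lo + bin_width, cls, n_db, n_q, n_q / n_db))
    return pd.DataFrame(
        rows,
        columns=["bin_low", "bin_high", "class", "n_database", "n_quantified", "ratio"],
    ).sort_values(["class", "bin_low"], ignore_index=True)


# ---------------------------------------------------------------------
# volcano
# ---------------------------------------------------------------------

def volcano_table(de_results: pd.DataFrame, q_ceiling: float = 16.0) -> pd.DataFrame:
    """One row per protein x contrast: log2FC, -log10(q), regulation call.

    ``-log10(0)`` is reported as `q_ceiling` with the ``capped`` flag set.
    """
    q = de_results["q"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(q)
    capped = ~np.isfinite(neglog) | (neglog > q_ceiling)
    neglog = np.where(capped, q_ceiling, neglog)
    out = de_results[["protein_id", "contrast", "log2fc"]].copy()
    out["neg_log10_q"] = neglog
    out["capped"] = capped
    out["call"] = classify_regulation(
        de_results["log2fc"].to_numpy(), q
    )
    return out


# ---------------------------------------------------------------------
# heatmap ordering
# ---------------------------------------------------------------------

def heatmap_order(data: pd.DataFrame, axis: str = "rows",
                  linkage_method: str = "average") -> list:
    """Leaf order of the hierarchical tree over rows or columns.

    Same metric/linkage as the profile clustering; input rows are
    id-sorted first so the order is permutation-invariant.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    mat = data if axis == "rows" else data.T
    mat = mat.sort_index()
    if mat.isna().to_numpy().any():
        raise ValidationError("heatmap ordering needs a complete matrix")
    if len(mat) < 2:
        return list(mat.index)
    Z = linkage(mat.to_numpy(dtype=float), method=linkage_method, metric="euclidean")
    return [mat.index[i] for i in leaves_list(Z)]
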