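"""Control-fitted PCA of half-cell profiles and anterior/posterior separation.

The control half-samples define a principal-component space (center-only PCA
on adjusted log abundance). Knockdown half-samples are *projected* into that
space — centered by the control gene means, never re-centered — so that a
loss of anterior/posterior separation under the knockdown is measured against
the axes the unperturbed cells define. Because the component carrying the
anterior-posterior (AP) signal is an empirical fact of each experiment (it
can land on PC1 or PC2), the AP axis is detected, not assumed: it is the
component on which anterior and posterior scores differ most by Welch t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import ValidationError

__all__ = [
    "PCAModel",
    "InsufficientDataError",
    "fit_control_pca",
    "project",
    "identify_ap_axis",
    "separation_loss",
    "welch_t",
    "standardized_mean_difference",
]


class InsufficientDataError(ValueError):
    """Too few samples (or labels) to compute the requested statistic."""


@dataclass
class PCAModel:
    """Center-only PCA fitted on control half-samples.

    ``loadings`` is components x genes with mutually orthonormal rows; the
    sign of each component is fixed so its largest-magnitude loading is
    positive, making results deterministic across runs and platforms.
    """

    gene_ids: pd.Index
    gene_means: pd.Series
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def component_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_components)]


def _fix_signs(loadings: np.ndarray, scores: np.ndarray | None = None):
    """Flip each component so its largest-|loading| entry is positive."""
    flip = np.sign(loadings[np.arange(loadings.shape[0]),
                            np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    if scores is not None:
        scores = scores * flip[None, :]
    return loadings, scores


def fit_control_pca(values: pd.DataFrame, n_components: int | None = None) -> PCAModel:
    """Fit center-only PCA on a genes x samples block of control half-cells.

    Genes are centered by their control mean; no unit-variance scaling is
    applied (adjusted log values already share a scale). Components come from
    the SVD of the centered samples x genes matrix. Default
    ``n_components = min(5, n_samples - 1)``.
    """
    n_samples = values.shape[1]
    if n_samples < 3:
        raise InsufficientDataError("need at least 3 control half-samples for PCA")
    limit = min(n_samples - 1, values.shape[0])
    if n_components is None:
        n_components = min(5, limit)
    if n_components < 1 or n_components > limit:
        raise ValueError(
            f"n_components must be in [1, {limit}] for {n_samples} samples "
            f"and {values.shape[0]} genes"
        )
    X = values.to_numpy().T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    loadings, _ = _fix_signs(pca.components_.copy())
    return PCAModel(
        gene_ids=values.index,
        gene_means=pd.Series(pca.mean_, index=values.index, name="gene_mean"),
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
    )


def project(model: PCAModel, values: pd.DataFrame) -> pd.DataFrame:
    """Project any samples into the control PC space.

    ``score = (x - control gene means) @ loadings.T`` — no re-centering on
    the projected set, so control samples reproduce their fitted scores
    exactly and knockdown samples are measured against the control origin.
    The gene set must match the model's exactly.
    """
    if set(values.index) != set(model.gene_ids):
        raise ValidationError(
            f"gene set mismatch: model has {len(model.gene_ids)} genes, "
            f"input has {len(values.index)}"
        )
    aligned = values.reindex(model.gene_ids)
    centered = aligned.to_numpy().T - model.gene_means.to_numpy()[None, :]
    scores = centered @ model.loadings.T
    return pd.DataFrame(scores, index=values.columns, columns=model.component_names())


def welch_t(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Welch t statistic (x minus y); 0 when both groups are constant
    and equal."""
    res = stats.ttest_ind(x, y, equal_var=False)
    t = float(res.statistic)
    if np.isnan(t) and np.isclose(np.mean(x), np.mean(y)):
        return 0.0
    return t


def standardized_mean_difference(x: np.ndarray, y: np.ndarray) -> float:
    """|mean(x) - mean(y)| divided by the pooled standard deviation."""
    nx, ny = len(x), len(y)
    diff = abs(float(np.mean(x) - np.mean(y)))
    pooled_var = (
        (nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)
    ) / (nx + ny - 2)
    pooled = float(np.sqrt(pooled_var))
    if pooled == 0:
        return 0.0 if diff == 0 else np.inf
    return diff / pooled


def identify_ap_axis(scores: pd.DataFrame, halves: pd.Series) -> pd.DataFrame:
    """Find the component that best separates anterior from posterior scores.

    For each component, the Welch t between anterior (A) and posterior (P)
    scores and the standardized mean difference are computed; the AP axis is
    the component with maximal |t| (ties to the lower index). Returns a
    per-component report with columns ``t, smd, is_ap_axis`` indexed by
    component name.
    """
    halves = halves.reindex(scores.index)
    a_mask = (halves == "A").to_numpy()
    p_mask = (halves == "P").to_numpy()
    if a_mask.sum() < 2 or p_mask.sum() < 2:
        raise InsufficientDataError("need at least 2 samples per half (A and P)")
    rows = []
    for name in scores.columns:
        a = scores.loc[a_mask, name].to_numpy()
        p = scores.loc[p_mask, name].to_numpy()
        rows.append({"component": name, "t": welch_t(a, p),
                     "smd": standardized_mean_difference(a, p)})
    report = pd.DataFrame(rows).set_index("component")
    best = int(np.argmax(np.abs(report["t"].to_numpy())))
    report["is_ap_axis"] = False
    report.iloc[best, report.columns.get_loc("is_ap_axis")] = True
    return report


def separation_loss(control_report: pd.DataFrame, other_report: pd.DataFrame) -> dict:
    """Compare AP separation of a projected condition against the control.

    Both reports must come from :func:`identify_ap_axis` on scores in the
    same model space; the comparison is made on the component the *control*
    identifies as the AP axis. Returns the two standardized mean differences
    and their ratio (other / control).
    """
    ap = control_report.index[control_report["is_ap_axis"]][0]
    smd_control = float(control_report.loc[ap, "smd"])
    smd_other = float(other_report.loc[ap, "smd"])
    ratio = smd_other / smd_control if smd_control > 0 else np.nan
    return {
        "ap_component": ap,
        "smd_control": smd_control,
        "smd_other": smd_other,
        "ratio": ratio,
    }
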