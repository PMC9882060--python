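"""Detection of genes whose anterior-posterior skew flips, vanishes or persists
under a knockdown.

Candidate genes are chosen by an unbiased PCA feature selection over the
pairs x genes skew matrix: genes act as variables, pairs (cells) as
observations, and the component whose pair scores best separate control from
knockdown (max |Welch t|) supplies the ranking — genes with the largest
absolute loadings on that component are the ones driving the
condition-dependent variation in skew. Each candidate is then tested with an
unpaired two-sided Welch t comparing its control skews against its knockdown
skews, with Benjamini-Hochberg adjustment across candidates, and classified:

``anti_correlated``
    significant, both condition means at least ``min_effect`` in magnitude,
    opposite in sign — the gene's enrichment side flips under the knockdown.
``lost``
    significant, control mean at least ``min_effect`` but knockdown mean
    below it — regionalization collapses.
``retained``
    significant change that keeps the original side (or gains one).
``not_significant`` / ``untestable``
    everything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .axis import InsufficientDataError
from .skew import SkewMatrix
from ._selection_pca import condition_separating_component

__all__ = [
    "CandidateSet",
    "select_candidates",
    "test_candidates",
    "classify",
    "overlap_with_reference",
    "zscore_rows",
]

#: minimal |mean skew| for a condition to count as genuinely regionalized when
#: classifying; on the adjusted-log skew scale real effects are a few times
#: 0.01, so 0.02 sits above null noise but below genuine regionalization.
DEFAULT_MIN_EFFECT = 0.02


@dataclass
class CandidateSet:
    """Genes selected for testing, ranked by |loading| on the selection PC."""

    genes: list[str]
    component: int  # 1-based index of the selection component
    loadings: pd.Series  # |loading| per selected gene, non-increasing
    condition_t: float  # Welch t of the selection component's pair scores
    k_requested: int


def select_candidates(
    skew: SkewMatrix,
    k: int = 500,
    control_label: str = "control",
    n_components: int | None = None,
) -> CandidateSet:
    """Rank genes by PCA over the pairs x genes skew matrix and keep the top k.

    Missing skews are imputed with the gene's grand-mean skew *for selection
    only* (testing later uses observed values). Genes are centered by their
    grand mean; the selection component is the one whose pair scores maximize
    |Welch t| between control and knockdown pairs. Ties in |loading| break by
    gene id order.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    labels = skew.pair_condition
    is_control = (labels == control_label).to_numpy()
    if is_control.sum() < 2 or (~is_control).sum() < 2:
        raise InsufficientDataError("need at least 2 pairs per condition")
    values = skew.values.copy()
    values = values.fillna(values.mean(axis=0)).fillna(0.0)
    component, loadings_row, t_value = condition_separating_component(
        values.to_numpy(), is_control, n_components=n_components
    )
    abs_loading = pd.Series(np.abs(loadings_row), index=values.columns)
    order = sorted(
        values.columns, key=lambda g: (-abs_loading[g], g)
    )
    selected = order[: min(k, len(order))]
    return CandidateSet(
        genes=list(selected),
        component=component + 1,
        loadings=abs_loading[selected],
        condition_t=t_value,
        k_requested=k,
    )


def classify(
    mean_control: float,
    mean_kd: float,
    significant: bool,
    min_effect: float = DEFAULT_MIN_EFFECT,
) -> str:
    """Classify a gene's skew change between control and knockdown."""
    if not significant:
        return "not_significant"
    if (
        abs(mean_control) >= min_effect
        and abs(mean_kd) >= min_effect
        and np.sign(mean_control) * np.sign(mean_kd) < 0
    ):
        return "anti_correlated"
    if abs(mean_kd) < min_effect <= abs(mean_control):
        return "lost"
    return "retained"


def test_candidates(
    candidates: CandidateSet,
    skew: SkewMatrix,
    control_label: str = "control",
    alpha: float = 0.05,
    significance_mode: str = "bh",
    min_effect: float = DEFAULT_MIN_EFFECT,
) -> pd.DataFrame:
    """Welch-test each candidate's control vs knockdown skews and classify.

    Two-sided unpaired Welch t per gene on observed (non-missing) skews;
    genes with fewer than 2 observations in either condition are flagged
    ``untestable`` and excluded from the BH adjustment. ``significance_mode``
    is ``"bh"`` (BH q < alpha, default) or ``"raw"`` (unadjusted p < alpha).

    Returns one row per candidate: mean_control, mean_kd, t, p, q, class,
    n_control, n_kd — t is control minus knockdown, so swapping the labels
    negates every statistic.
    """
    if significance_mode not in ("bh", "raw"):
        raise ValueError("significance_mode must be 'bh' or 'raw'")
    labels = skew.pair_condition
    is_control = (labels == control_label).to_numpy()
    rows = []
    for gene in candidates.genes:
        col = skew.values[gene].to_numpy()
        ctrl = col[is_control]
        kd = col[~is_control]
        ctrl = ctrl[~np.isnan(ctrl)]
        kd = kd[~np.isnan(kd)]
        row = {
            "gene_id": gene,
            "n_control": len(ctrl),
            "n_kd": len(kd),
            "mean_control": float(np.mean(ctrl)) if len(ctrl) else np.nan,
            "mean_kd": float(np.mean(kd)) if len(kd) else np.nan,
        }
        if len(ctrl) < 2 or len(kd) < 2:
            row.update(t=np.nan, p=np.nan, testable=False)
        else:
            res = stats.ttest_ind(ctrl, kd, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            if np.isnan(t):
                # both groups constant: identical means -> no evidence
                if np.isclose(row["mean_control"], row["mean_kd"]):
                    t, p = 0.0, 1.0
                else:
                    t = np.inf if row["mean_control"] > row["mean_kd"] else -np.inf
                    p = 0.0
            row.update(t=t, p=p, testable=True)
        rows.append(row)
    results = pd.DataFrame(rows).set_index("gene_id")
    results["q"] = np.nan
    testable = results["testable"]
    if testable.any():
        _, q, _, _ = multipletests(results.loc[testable, "p"], method="fdr_bh")
        results.loc[testable, "q"] = q
    if significance_mode == "bh":
        significant = results["q"] < alpha
    else:
        significant = results["p"] < alpha
    results["class"] = [
        "untestable"
        if not row.testable
        else classify(row.mean_control, row.mean_kd, bool(sig), min_effect)
        for row, sig in zip(results.itertuples(), significant.fillna(False))
    ]
    return results


def zscore_rows(frame: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row (population sd) for heatmap export; constant rows -> 0."""
    arr = frame.to_numpy(dtype=float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, keepdims=True)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return pd.DataFrame((arr - mean) / sd_safe, index=frame.index,
                        columns=frame.columns)


def overlap_with_reference(
    results: pd.DataFrame,
    reference: pd.DataFrame,
    skew: SkewMatrix | None = None,
) -> dict:
    """Intersect anti-correlated calls with an external enrichment gene list.

    ``reference`` needs columns ``gene_id`` and ``side`` ('A' or 'P': the
    half the gene was enriched in, e.g. by bulk sequencing of bisected
    cells). Returns the per-gene overlap table (with a concordance flag:
    does the control-skew sign match the reference side?), the overlap
    count, and — when ``skew`` is given — a genes x pairs z-scored skew
    matrix for the overlapping genes, ready for heatmap rendering.
    """
    flipped = results[results["class"] == "anti_correlated"]
    ref = reference.set_index("gene_id")["side"]
    common = [g for g in flipped.index if g in ref.index]
    table = pd.DataFrame(
        {
            "reference_side": [ref[g] for g in common],
            "mean_control": flipped.loc[common, "mean_control"],
            "mean_kd": flipped.loc[common, "mean_kd"],
        },
        index=pd.Index(common, name="gene_id"),
    )
    table["concordant"] = (
        np.sign(table["mean_control"]) == table["reference_side"].map({"A": 1, "P": -1})
    )
    out = {
        "n_flipped": int(len(flipped)),
        "n_overlap": int(len(common)),
        "table": table,
    }
    if skew is not None and common:
        out["heatmap"] = zscore_rows(skew.values[common].T)
    return out
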