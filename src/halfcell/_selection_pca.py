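"""PCA helper shared by feature selection: pairs are observations, genes are
variables, and one component is singled out for separating two groups."""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA


def condition_separating_component(
    matrix: np.ndarray,
    group_mask: np.ndarray,
    n_components: int | None = None,
) -> tuple[int, np.ndarray, float]:
    """PCA on an observations x variables matrix; pick the component whose
    observation scores best separate the two groups by |Welch t|.

    Returns ``(component_index, loadings_row, t_value)`` with a deterministic
    sign convention (largest-|loading| entry positive). Ties in |t| break to
    the lower component index.
    """
    from .axis import welch_t  # local import avoids a cycle

    n_obs = matrix.shape[0]
    limit = min(n_obs - 1, matrix.shape[1])
    if n_components is None:
        n_components = min(5, limit)
    n_components = max(1, min(n_components, limit))
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(matrix)
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(loadings.shape[0]),
                            np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    t_values = np.array(
        [welch_t(scores[group_mask, j], scores[~group_mask, j])
         for j in range(n_components)]
    )
    best = int(np.argmax(np.abs(t_values)))
    return best, loadings[best], float(t_values[best])
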