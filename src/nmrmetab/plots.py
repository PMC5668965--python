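"""Optional matplotlib renderings of the tabular pipeline artifacts.

The TSV tables are the tested surface; these helpers reproduce the three
classic views: scores scatter, permutation validation plot, and the
colour-coded coefficient loading plot (|r| as colour, covariance as height).
"""

from __future__ import annotations

import numpy as np

__all__ = ["scores_plot", "permutation_plot", "coefficient_loading_plot"]


def scores_plot(model, groups, ax=None, components=(0, 1)):
    """Scatter of two score dimensions, coloured by group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scores = model.scores
    if scores.shape[1] < 2 and model.scores_orth is not None:
        scores = np.column_stack([scores[:, 0], model.scores_orth[:, 0]])
        labels = ("t(predictive)", "t(orthogonal)")
    else:
        labels = tuple(f"t{i + 1}" for i in components)
    groups = np.asarray(groups)
    for g in dict.fromkeys(groups):
        m = groups == g
        ax.scatter(scores[m, components[0]], scores[m, components[1]],
                   label=g, alpha=0.8)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel(labels[0])
    ax.set_ylabel(labels[1])
    ax.legend()
    return ax


def permutation_plot(result, ax=None):
    """R2Y/Q2 against label correlation for the permuted and real models."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.label_correlations, result.permuted_r2y, s=12,
               color="tab:green", label="permuted R2Y")
    ax.scatter(result.label_correlations, result.permuted_q2, s=12,
               color="tab:blue", label="permuted Q2")
    ax.scatter([1.0], [result.observed_r2y], marker="^", color="tab:green")
    ax.scatter([1.0], [result.observed_q2], marker="^", color="tab:blue")
    ax.set_xlabel("|correlation with true labels|")
    ax.set_ylabel("R2Y / Q2")
    ax.legend()
    ax.set_title(f"permutation test (n={result.n_permutations}), "
                 f"p(Q2)={result.p_q2:.3g}")
    return ax


def coefficient_loading_plot(centers, covariance, r, cutoff, ax=None):
    """Covariance trace coloured by |r|; warm = significant discriminator."""
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    centers = np.asarray(centers)
    order = np.argsort(centers)[::-1]
    x, y, c = centers[order], np.asarray(covariance)[order], np.abs(r)[order]
    pts = np.array([x, y]).T.reshape(-1, 1, 2)
    segs = np.concatenate([pts[:-1], pts[1:]], axis=1)
    lc = LineCollection(segs, cmap="jet", array=c[:-1], clim=(0, 1), lw=0.8)
    ax.add_collection(lc)
    ax.set_xlim(x.max(), x.min())  # descending ppm, NMR convention
    pad = 1.1 * max(abs(y.min()), abs(y.max()), 1e-12)
    ax.set_ylim(-pad, pad)
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel("covariance with t(predictive)")
    ax.figure.colorbar(lc, ax=ax, label=f"|r| (cutoff {cutoff:.3f})")
    return ax
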