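"""Quick-look plots: activation heatmaps and dose-response curves."""

from __future__ import annotations

import numpy as np

from .activation import ActivationMatrix
from .assays import DoseResponseResults


def plot_activation_matrix(matrix: ActivationMatrix, threshold: float | None = 30.0, ax=None):
    """Heatmap of an activation matrix (positions x residues).

    Cells above ``threshold`` are outlined when the matrix is normalized,
    mirroring how tolerated substitutions are highlighted in scan figures.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    vals = matrix.values
    im = ax.imshow(vals.to_numpy(), aspect="auto", cmap="Blues", vmin=0)
    ax.set_xticks(range(len(vals.columns)), vals.columns)
    ax.set_yticks(
        range(len(vals.index)),
        [f"p{p}{wt}" for p, wt in matrix.positions_wt()],
    )
    ax.set_xlabel("substituted residue")
    ax.set_ylabel("peptide position")
    if threshold is not None and matrix.normalized:
        ys, xs = np.where(vals.to_numpy() > threshold)
        ax.scatter(xs, ys, marker="s", s=60, facecolors="none", edgecolors="orange")
    ax.figure.colorbar(im, ax=ax, label="% activation")
    return ax


def plot_dose_response(results: DoseResponseResults, ax=None):
    """Measured points and the fitted three-parameter logistic curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    doses = results.model.doses
    ax.semilogx(doses, results.model.responses, "o", label="measured")
    grid = np.geomspace(doses.min() / 10, doses.max() * 10, 200)
    ax.semilogx(grid, results.predict(grid), "-", label="3PL fit")
    ax.axvline(results.ec50, ls="--", lw=0.8, color="gray")
    ax.annotate(f"EC50 = {results.ec50:.3g}", (results.ec50, results.bottom), fontsize=8)
    ax.set_xlabel("dose (M)")
    ax.set_ylabel("response")
    ax.legend()
    return ax
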