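"""Observed / expected / residual spectrum panels."""

from __future__ import annotations

import numpy as np

from .sfs import Spectrum


def plot_sfs_comparison(observed: Spectrum, expected: Spectrum, theta: float,
                        path) -> None:
    """Three-panel heatmap: observed SFS, fitted expectation, Poisson residuals.

    ``expected`` is a unit spectrum; it is scaled by ``theta``.  Residuals
    are ``(obs - theta * exp) / sqrt(theta * exp)``; red marks cells where
    the model predicts too many SNPs, blue too few.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    model = theta * expected.data
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = (model - observed.data) / np.sqrt(np.where(model > 0, model, np.nan))
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.4))
    for ax, (arr, title, cmap) in zip(axes, [
        (np.log10(np.where(observed.data > 0, observed.data, np.nan)),
         "observed (log10)", "viridis"),
        (np.log10(np.where(model > 0, model, np.nan)), "model (log10)", "viridis"),
        (resid, "residuals (model - data)", "RdBu_r"),
    ]):
        masked = np.ma.masked_invalid(np.ma.masked_where(observed.mask, arr))
        vmax = np.nanmax(np.abs(arr)) if "resid" in title else None
        im = ax.imshow(masked, origin="lower", aspect="auto", cmap=cmap,
                       vmin=-vmax if vmax else None, vmax=vmax)
        ax.set_title(title)
        ax.set_xlabel(f"derived copies, {observed.pop_ids[1]}")
        ax.set_ylabel(f"derived copies, {observed.pop_ids[0]}")
        fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
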