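"""Basic figures: profile heatmap, ROC curves and index strip plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def profile_heatmap(profile, path: str | Path) -> None:
    """Tissue x site editing-percent heatmap (masked cells blank)."""
    fig, ax = plt.subplots(figsize=(10, 3 + 0.2 * len(profile.tissues)))
    data = profile.values.to_numpy(dtype=float)
    im = ax.imshow(np.ma.masked_invalid(data), aspect="auto", cmap="viridis",
                   vmin=0, vmax=100)
    ax.set_yticks(range(len(profile.tissues)), profile.tissues)
    ax.set_xlabel(f"{len(profile.sites)} editing sites")
    fig.colorbar(im, ax=ax, label="editing %")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def roc_curves(candidates: dict, labels, positive, path: str | Path) -> None:
    """Empirical ROC curves for several markers over the same samples."""
    labels = np.asarray(list(labels))
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, values in candidates.items():
        v = np.asarray(values, dtype=float)
        ok = ~np.isnan(v)
        v, lab = v[ok], labels[ok]
        thresholds = np.unique(v)[::-1]
        tpr = [np.mean(v[lab == positive] >= t) for t in thresholds]
        fpr = [np.mean(v[lab != positive] >= t) for t in thresholds]
        ax.plot([0] + fpr + [1], [0] + tpr + [1], label=name)
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
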