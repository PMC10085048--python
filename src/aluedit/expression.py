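"""Interferon-signature scoring and marker-gene extraction from TPM matrices.

The ISG score summarizes interferon-pathway activity per sample from a
38-gene interferon-stimulated-gene signature.  Each signature gene is
standardized against a designated reference group (typically the controls):

    z_gs = (log2(TPM_gs + 1) - mean_ref(g)) / sd_ref(g)

and a sample's score is the median z over the signature genes present in
the matrix (mean-z is available as an option).  The log2(TPM+1) transform
stabilizes variance; genes with zero reference variance are excluded and
counted.  The score is invariant to any per-gene rescaling of raw TPM that
is common to all samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import ExpressionMatrix

__all__ = ["ISGSignature", "SampleScore", "isg_score", "scores_to_frame", "marker_expression"]


@dataclass(frozen=True)
class ISGSignature:
    """An interferon-stimulated-gene signature (unique, non-empty symbols)."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene symbols must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_file(cls, path: str | Path) -> "ISGSignature":
        """Load a one-symbol-per-line signature file."""
        genes = []
        with open(path) as fh:
            for line in fh:
                symbol = line.strip()
                if symbol and not symbol.startswith("#"):
                    genes.append(symbol)
        return cls(tuple(genes))

    @classmethod
    def default(cls) -> "ISGSignature":
        """The packaged 38-gene interferon signature (ADAR included)."""
        text = resources.files("aluedit.data").joinpath("isg_signature_38.txt").read_text()
        return cls(tuple(g for g in text.split() if g))


@dataclass
class SampleScore:
    sample: str
    score: float
    n_genes_used: int


def isg_score(
    expr: ExpressionMatrix,
    signature: ISGSignature,
    reference_samples: Sequence[str],
    stat: str = "median",
    log_transform: bool = True,
) -> list[SampleScore]:
    """Per-sample ISG score: ``stat`` of per-gene reference z-scores.

    ``reference_samples`` (typically the control group) define the per-gene
    mean and sd.  Raises if no signature gene is present in the matrix;
    genes constant across the reference are dropped with a warning.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    reference_samples = list(reference_samples)
    if not reference_samples:
        raise ValueError("reference_samples must be non-empty")
    missing_ref = [s for s in reference_samples if s not in expr.samples]
    if missing_ref:
        raise ValueError(f"reference samples absent from matrix: {missing_ref}")
    present = [g for g in signature.genes if g in expr.genes]
    if not present:
        raise ValueError("no signature gene is present in the expression matrix")

    values = expr.data.loc[present]
    if log_transform:
        values = np.log2(values + 1.0)
    ref = values[reference_samples]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    usable = sd > 0
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(
            f"{n_dropped} signature gene(s) constant across the reference group; excluded",
            stacklevel=2,
        )
    if not usable.any():
        return [SampleScore(s, float("nan"), 0) for s in expr.samples]
    z = values.loc[usable].sub(mu[usable], axis=0).div(sd[usable], axis=0)
    agg = z.median(axis=0) if stat == "median" else z.mean(axis=0)
    n_used = int(usable.sum())
    return [SampleScore(s, float(agg[s]), n_used) for s in expr.samples]


def scores_to_frame(scores: Sequence[SampleScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [s.sample for s in scores],
            "isg_score": [s.score for s in scores],
            "n_genes_used": [s.n_genes_used for s in scores],
        }
    )


def marker_expression(expr: ExpressionMatrix, markers: Sequence[str]) -> pd.DataFrame:
    """TPM values of ``markers``, one row per marker; NA rows for absent genes."""
    markers = list(markers)
    present = [m for m in markers if m in expr.genes]
    if not present:
        raise ValueError("none of the requested markers is present in the matrix")
    absent = [m for m in markers if m not in expr.genes]
    if absent:
        warnings.warn(f"markers absent from matrix reported as NA: {absent}", stacklevel=2)
    out = pd.DataFrame(
        np.nan, index=pd.Index(markers, name="gene"), columns=expr.samples
    )
    out.loc[present] = expr.data.loc[present].to_numpy()
    return out
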