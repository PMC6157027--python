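"""Principal-component batch correction of methylation matrices.

Genome-wide methylation arrays frequently carry a dominant latent factor
(plate/batch effects) that is shared across sites.  When batches align with
families, per-site polygenic heritability estimates are inflated because the
batch covariance masquerades as familial covariance.  The correction here
mirrors the standard recipe: take a random subset of sites (default 10%),
estimate the leading principal components with samples as observations
(default 20), and either regress each site on the PC scores
(:func:`residualize`) or carry the scores as fixed-effect covariates in the
per-site model.  Both routes are provided; residualization before kernel
construction is the documented default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .methylation import MethylationMatrix

__all__ = ["PCModel", "fit_pcs", "residualize", "write_scores", "read_scores"]


class AlignmentError(ValueError):
    """Sample sets/orders of two objects do not match."""


@dataclass
class PCModel:
    """Leading principal components of a site-subset methylation matrix.

    ``scores`` is samples x components, columns centered and mutually
    orthogonal; ``explained_variance`` holds the per-component fraction of
    the subset variance, non-increasing.
    """

    sample_ids: list[str]
    scores: np.ndarray
    explained_variance: np.ndarray
    n_components: int
    subset_fraction: float
    seed: int
    subset_site_ids: list[str]


def fit_pcs(
    m: MethylationMatrix,
    subset_fraction: float = 0.10,
    n_components: int = 20,
    seed: int = 0,
) -> PCModel:
    """Fit PCs on a random ``subset_fraction`` of sites.

    Sites are shuffled with ``seed`` and the first ``floor(fraction * S)``
    taken; samples are the observations, subset sites the variables
    (variables centered, no extra scaling — rows are expected to be
    inverse-normalized already).  Deterministic given (matrix, seed).
    """
    if not 0.0 < subset_fraction <= 1.0:
        raise ValueError("subset_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_subset = max(1, int(np.floor(subset_fraction * m.n_sites)))
    order = rng.permutation(m.n_sites)[:n_subset]
    # sort the selected rows so the fit depends only on subset membership,
    # not on the input row order
    subset_ids = sorted(m.site_ids[i] for i in order)
    row_of = {s: i for i, s in enumerate(m.site_ids)}
    X = m.values[[row_of[s] for s in subset_ids]].T  # samples x sites
    if n_components > min(m.n_samples - 1, n_subset):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples - 1, subset size)"
            f" = {min(m.n_samples - 1, n_subset)}"
        )
    col_mean = np.nanmean(X, axis=0)
    X = np.where(np.isfinite(X), X, col_mean)  # mean-impute missing entries
    if n_components == 0:
        scores = np.empty((m.n_samples, 0))
        evr = np.empty(0)
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        scores -= scores.mean(axis=0)
        evr = pca.explained_variance_ratio_
    return PCModel(
        sample_ids=list(m.sample_ids),
        scores=scores,
        explained_variance=evr,
        n_components=n_components,
        subset_fraction=subset_fraction,
        seed=seed,
        subset_site_ids=subset_ids,
    )


def residualize(m: MethylationMatrix, pcs: PCModel) -> MethylationMatrix:
    """Replace each site row by its least-squares residual on [1, PC scores].

    Residual rows are orthogonal to every score column, and the operation is
    idempotent.  With zero components it reduces to row centering.  Missing
    entries are left missing; rows with missing values are regressed on the
    observed subset only.
    """
    if pcs.sample_ids != m.sample_ids:
        raise AlignmentError("PC model and methylation matrix have different samples")
    n = m.n_samples
    X = np.column_stack([np.ones(n), pcs.scores])
    vals = np.array(m.values, dtype=float)
    finite = np.isfinite(vals)
    out = np.full_like(vals, np.nan)
    complete = finite.all(axis=1)
    if complete.any():
        Y = vals[complete].T  # samples x rows
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        out[complete] = (Y - X @ beta).T
    for i in np.flatnonzero(~complete):
        mask = finite[i]
        if mask.sum() <= X.shape[1]:
            continue  # too few observations to residualize; row stays missing
        beta, *_ = np.linalg.lstsq(X[mask], vals[i, mask], rcond=None)
        out[i, mask] = vals[i, mask] - X[mask] @ beta
    return MethylationMatrix(
        list(m.site_ids), list(m.sample_ids), out, transformed=m.transformed
    )


def write_scores(pcs: PCModel, path: str | Path) -> None:
    """Write scores as TSV (sample_id, PC1..PCk) for use as model covariates."""
    cols = [f"PC{i + 1}" for i in range(pcs.scores.shape[1])]
    df = pd.DataFrame(pcs.scores, columns=cols)
    df.insert(0, "sample_id", pcs.sample_ids)
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.8g")


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: expected a sample_id column")
    return df
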