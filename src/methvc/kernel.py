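"""Gene-specific methylation relationship kernels.

For each gene, the inverse-normalized (and optionally PC-corrected) values
of its annotated CpG sites are standardized per site into a samples x sites
matrix Z; the cross-product R = Z @ Z.T is then rescaled to exact unit
diagonal,

    K[i, j] = R[i, j] / sqrt(R[i, i] * R[j, j]),

yielding the gene-specific covariance kernel K: the pairwise sample
correlation of methylation state across the gene's sites.  K is symmetric,
positive semi-definite, has |off-diagonal| <= 1, and — because of the
unit-diagonal scaling — is invariant to whether site standardization used
the population (n) or sample (n - 1) variance convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .methylation import GeneSiteIndex, MethylationMatrix

__all__ = [
    "MethylKernel",
    "KernelError",
    "standardize_sites",
    "build_kernel",
    "kernel_scan",
    "build_all_kernels",
    "save_kernels",
    "load_kernels",
    "write_kernel_tsv",
    "write_grm_pairs",
]


class KernelError(ValueError):
    """Kernel construction failed (e.g. a sample with no usable site data)."""


@dataclass
class MethylKernel:
    """Unit-diagonal methylation kernel for one gene."""

    gene_id: str
    sample_ids: list[str]
    K: np.ndarray
    n_sites: int

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.sample_ids)
        if self.K.shape != (n, n):
            raise ValueError(f"kernel shape {self.K.shape} != ({n}, {n})")

    def reindex(self, sample_ids: list[str]) -> "MethylKernel":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as err:
            raise KeyError(f"sample {err.args[0]!r} not in kernel") from None
        return MethylKernel(self.gene_id, list(sample_ids), self.K[np.ix_(idx, idx)], self.n_sites)


def standardize_sites(
    m: MethylationMatrix,
    site_ids: Iterable[str],
    ddof: int = 1,
    max_missing: float = 0.2,
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Standardize selected site rows into Z (samples x sites).

    Each kept column has mean 0 and variance 1 (``ddof`` convention) over its
    non-missing samples; missing entries are imputed to 0 — the standardized
    column mean — which keeps Z @ Z.T a valid Gram matrix.  Constant sites
    and sites with a missing fraction above ``max_missing`` are dropped.

    Returns ``(Z, kept_site_ids, dropped)`` where ``dropped`` lists
    ``(site_id, reason)`` pairs.
    """
    site_ids = list(site_ids)
    row_of = {s: i for i, s in enumerate(m.site_ids)}
    absent = [s for s in site_ids if s not in row_of]
    if absent:
        raise KeyError(f"site(s) not in matrix: {absent[:5]}")
    cols = []
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    n = m.n_samples
    for s in site_ids:
        row = m.values[row_of[s]]
        mask = np.isfinite(row)
        n_obs = int(mask.sum())
        if n - n_obs > max_missing * n:
            dropped.append((s, "missingness above threshold"))
            continue
        if n_obs < 2 or np.nanstd(row) == 0.0:
            dropped.append((s, "constant or near-empty site"))
            continue
        mu = row[mask].mean()
        sd = row[mask].std(ddof=ddof)
        if sd == 0.0:
            dropped.append((s, "constant or near-empty site"))
            continue
        z = np.zeros(n)
        z[mask] = (row[mask] - mu) / sd
        cols.append(z)
        kept.append(s)
    Z = np.column_stack(cols) if cols else np.empty((n, 0))
    return Z, kept, dropped


def build_kernel(Z: np.ndarray, gene_id: str, sample_ids: list[str]) -> MethylKernel:
    """Form R = Z @ Z.T and rescale to exact unit diagonal."""
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != len(sample_ids):
        raise ValueError("Z must be samples x sites, aligned with sample_ids")
    if Z.shape[1] == 0:
        raise KernelError(f"gene {gene_id}: no usable sites")
    R = Z @ Z.T
    d = np.diag(R).copy()
    bad = np.flatnonzero(d <= 0.0)
    if bad.size:
        names = [sample_ids[i] for i in bad[:5]]
        raise KernelError(
            f"gene {gene_id}: zero kernel diagonal for sample(s) {names} "
            "(no informative site data)"
        )
    K = R / np.sqrt(np.outer(d, d))
    K = 0.5 * (K + K.T)
    return MethylKernel(gene_id, list(sample_ids), K, Z.shape[1])


def kernel_scan(
    m: MethylationMatrix,
    index: GeneSiteIndex,
    min_sites: int | None = None,
    max_missing: float = 0.2,
    ddof: int = 1,
    skipped: list | None = None,
) -> Iterator[MethylKernel]:
    """Yield one kernel per eligible gene in deterministic gene-id order.

    Genes whose usable site count drops below ``min_sites`` (after constant
    or too-missing sites are removed), or whose kernel cannot be built, are
    recorded in ``skipped`` as ``(gene_id, reason)`` and omitted.
    """
    if min_sites is None:
        min_sites = index.min_sites
    for gene_id in index.gene_ids:
        sites = [s for s in index.sites_for(gene_id) if s in set(m.site_ids)]
        if len(sites) < min_sites:
            if skipped is not None:
                skipped.append((gene_id, f"only {len(sites)} sites present in matrix"))
            continue
        Z, kept, _dropped = standardize_sites(m, sites, ddof=ddof, max_missing=max_missing)
        if len(kept) < min_sites:
            if skipped is not None:
                skipped.append((gene_id, f"only {len(kept)} usable sites after filtering"))
            continue
        try:
            yield build_kernel(Z, gene_id, m.sample_ids)
        except KernelError as err:
            if skipped is not None:
                skipped.append((gene_id, str(err)))


def build_all_kernels(
    m: MethylationMatrix, index: GeneSiteIndex, **kwargs
) -> tuple[list[MethylKernel], list[tuple[str, str]]]:
    """Materialize :func:`kernel_scan` into (kernels, skip report)."""
    skipped: list[tuple[str, str]] = []
    kernels = list(kernel_scan(m, index, skipped=skipped, **kwargs))
    return kernels, skipped


def save_kernels(kernels: Iterable[MethylKernel], path: str | Path) -> None:
    """Store many small dense kernels in one indexed .npz container."""
    kernels = list(kernels)
    if not kernels:
        raise ValueError("no kernels to save")
    sample_ids = kernels[0].sample_ids
    for k in kernels:
        if k.sample_ids != sample_ids:
            raise ValueError("all kernels in a container must share sample ordering")
    arrays = {f"K_{k.gene_id}": k.K for k in kernels}
    np.savez_compressed(
        Path(path),
        _gene_ids=np.array([k.gene_id for k in kernels]),
        _n_sites=np.array([k.n_sites for k in kernels]),
        _sample_ids=np.array(sample_ids),
        **arrays,
    )


def load_kernels(path: str | Path) -> list[MethylKernel]:
    with np.load(Path(path), allow_pickle=False) as data:
        sample_ids = [str(s) for s in data["_sample_ids"]]
        gene_ids = [str(g) for g in data["_gene_ids"]]
        n_sites = data["_n_sites"]
        return [
            MethylKernel(g, sample_ids, data[f"K_{g}"], int(ns))
            for g, ns in zip(gene_ids, n_sites)
        ]


def write_kernel_tsv(kernel: MethylKernel, path: str | Path) -> None:
    """Square-matrix TSV export of one kernel (header row of sample ids)."""
    pd.DataFrame(kernel.K, index=kernel.sample_ids, columns=kernel.sample_ids).to_csv(
        Path(path), sep="\t", index_label="sample_id", float_format="%.10g"
    )


def write_grm_pairs(kernel: MethylKernel, path: str | Path) -> None:
    """GRM-text-like pairwise export: id1, id2, n_sites, value (lower triangle)."""
    rows = [
        (kernel.sample_ids[i], kernel.sample_ids[j], kernel.n_sites, kernel.K[i, j])
        for i in range(len(kernel.sample_ids))
        for j in range(i + 1)
    ]
    pd.DataFrame(rows, columns=["id1", "id2", "n_sites", "value"]).to_csv(
        Path(path), sep="\t", index=False, float_format="%.10g"
    )
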