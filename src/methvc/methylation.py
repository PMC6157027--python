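"""Methylation matrices, rank-based inverse-normal transform, gene-site index.

Array methylation is summarized per CpG site as a beta value in [0, 1].
Before any model fitting each site is mapped onto standard-normal quantiles
(rank-based inverse-normal transform), which removes the bounded, often
bimodal beta-scale distribution and makes the Gaussian mixed model
applicable.  Sites are linked to genes through an annotation table; a gene
is kernel-eligible only when at least ``min_sites`` sites map to it, since
kernels built from very few sites produce spuriously high pairwise sample
correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "MethylationMatrix",
    "GeneSiteIndex",
    "read_methylation",
    "write_methylation",
    "inverse_normalize",
    "read_annotation",
    "build_gene_index",
]


@dataclass
class MethylationMatrix:
    """Sites x samples methylation values.

    ``values[i, j]`` is site ``site_ids[i]`` in sample ``sample_ids[j]``;
    missing entries are NaN.  ``transformed`` marks whether rows are raw beta
    values (in [0, 1]) or inverse-normal scores (unbounded).
    """

    site_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.site_ids)} sites x {len(self.sample_ids)} samples"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site ids")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def site_row(self, site_id: str) -> np.ndarray:
        return self.values[self.site_ids.index(site_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.sample_ids)


def read_methylation(path: str | Path) -> MethylationMatrix:
    """Read a sites x samples TSV (first column site ids, header sample ids)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = sorted({s for s in header if header.count(s) > 1})
    if dups:
        raise ValueError(f"{path}: duplicate sample id(s) in header: {dups}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as err:
        raise ValueError(f"{path}: could not parse methylation TSV: {err}") from None
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric values in column(s) {non_numeric}")
    return MethylationMatrix(
        [str(s) for s in df.index], [str(c) for c in df.columns], df.to_numpy(float)
    )


def write_methylation(m: MethylationMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(Path(path), sep="\t", index_label="site_id", float_format="%.6g")


def inverse_normalize(
    m: MethylationMatrix, c: float = 0.375, min_obs: int = 3
) -> MethylationMatrix:
    """Rank-based inverse-normal transform of every site row.

    Each non-missing value is replaced by ``ndtri((rank - c) / (n - 2c + 1))``
    with the Blom offset ``c = 3/8`` and average ranks for ties; missing
    values are excluded from ranking and remain missing.  Sites with fewer
    than ``min_obs`` non-missing values carry no usable rank information and
    are dropped with a warning.

    The transform is monotone within each row, and each transformed row has
    mean approximately 0 and variance approximately 1.
    """
    if m.transformed:
        raise ValueError("matrix already inverse-normalized")
    vals = np.array(m.values, dtype=float)
    finite = np.isfinite(vals)
    nobs = finite.sum(axis=1)
    keep = nobs >= min_obs
    if not keep.all():
        dropped = [m.site_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping {len(dropped)} site(s) with < {min_obs} observed values: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    vals = vals[keep]
    nobs = nobs[keep]
    ranks = rankdata(vals, method="average", axis=1, nan_policy="omit")
    quant = (ranks - c) / (nobs[:, None] - 2.0 * c + 1.0)
    out = ndtri(quant)
    out[~np.isfinite(vals)] = np.nan
    return MethylationMatrix(
        [s for s, k in zip(m.site_ids, keep) if k],
        list(m.sample_ids),
        out,
        transformed=True,
    )


def read_annotation(path: str | Path, zero_based: bool = False) -> pd.DataFrame:
    """Read a site-to-gene annotation TSV.

    Expects columns ``site_id`` and ``gene_id`` (one row per site-gene link)
    plus optional ``chromosome`` and ``position``.  BED-like half-open
    coordinates can be declared with ``zero_based=True``, which shifts
    positions to 1-based.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"site_id", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    df["site_id"] = df["site_id"].astype(str)
    df["gene_id"] = df["gene_id"].astype(str)
    if zero_based and "position" in df.columns:
        df = df.assign(position=df["position"] + 1)
    return df


@dataclass
class GeneSiteIndex:
    """Mapping gene id -> ordered site ids, restricted to kernel-eligible genes."""

    genes: dict[str, list[str]]
    min_sites: int = 5
    n_excluded: int = 0
    #: per-gene (chromosome, representative position) for plotting, when known
    gene_meta: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "chromosome", "position"])
    )

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def sites_for(self, gene_id: str) -> list[str]:
        return self.genes[gene_id]

    def __len__(self) -> int:
        return len(self.genes)


def build_gene_index(annotation: pd.DataFrame, min_sites: int = 5) -> GeneSiteIndex:
    """Group annotated sites by gene and apply the >= ``min_sites`` filter.

    A site annotated to several genes contributes to every one of them.  The
    result is independent of annotation row order: sites are ordered by
    (position, site_id) when positions are present, by site_id otherwise.
    """
    if len(annotation) == 0:
        warnings.warn("empty annotation: gene index is empty", stacklevel=2)
        return GeneSiteIndex({}, min_sites=min_sites)
    ann = annotation.drop_duplicates(subset=["site_id", "gene_id"])
    has_pos = "position" in ann.columns
    sort_cols = ["position", "site_id"] if has_pos else ["site_id"]
    genes: dict[str, list[str]] = {}
    meta_rows = []
    for gene_id, grp in ann.groupby("gene_id", sort=True):
        sites = grp.sort_values(sort_cols, kind="stable")["site_id"].tolist()
        genes[str(gene_id)] = sites
        chrom = grp["chromosome"].iloc[0] if "chromosome" in grp.columns else None
        pos = int(grp["position"].median()) if has_pos else None
        meta_rows.append((str(gene_id), chrom, pos))
    eligible = {g: s for g, s in genes.items() if len(s) >= min_sites}
    n_excluded = len(genes) - len(eligible)
    meta = pd.DataFrame(meta_rows, columns=["gene_id", "chromosome", "position"])
    meta = meta[meta["gene_id"].isin(eligible)].reset_index(drop=True)
    return GeneSiteIndex(eligible, min_sites=min_sites, n_excluded=n_excluded, gene_meta=meta)
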