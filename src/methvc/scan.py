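"""Gene-level LRT association scan, per-site heritability scan, plot exports.

Each gene's methylation kernel is tested by a likelihood-ratio test of
h_meth^2 = 0 against the polygenic null.  Because the variance fraction is
tested on the boundary of its parameter space, the LRT statistic is
asymptotically distributed as a 50:50 mixture of a point mass at zero and a
chi-square with 1 degree of freedom; this reference is slightly
conservative.  An observed statistic of exactly zero falls in the point
mass and is reported with p = 1 (configurable), so boundary genes can never
appear significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .kernel import MethylKernel
from .lmm import PolygenicScanner, fit_ml, fit_null_and_full, VarCompModel
from .methylation import MethylationMatrix

__all__ = [
    "AssocResult",
    "SiteH2Result",
    "mixture_pvalue",
    "bonferroni_threshold",
    "gene_scan",
    "site_h2_scan",
    "results_frame",
    "export_plots",
]

#: default multi-start points for per-gene full-model fits; the null warm
#: start is always added, so a lighter set keeps genome-wide scans fast
SCAN_STARTS = [[0.25, 0.25], [0.0, 0.5]]


@dataclass
class AssocResult:
    gene_id: str
    n_sites: int
    lrt: float
    p_value: float
    h_meth2: float
    h_r2_full: float
    loglik_null: float
    loglik_full: float
    converged: bool


@dataclass
class SiteH2Result:
    site_id: str
    h2: float
    loglik_poly: float
    loglik_sporadic: float
    p_value: float


def mixture_pvalue(lrt: float, p_at_zero: float = 1.0) -> float:
    """P-value under the 50:50 point-mass/chi2(1) boundary mixture.

    For lrt > 0, p = 0.5 * P(chi2_1 >= lrt).  A statistic of exactly zero
    lies in the point mass; by default it is reported as p = 1 (never
    significant).  Small negative inputs within -1e-6 are rounding from the
    nested fits and are clamped to zero; anything more negative indicates a
    nesting violation and raises.
    """
    if lrt < -1e-6:
        raise ValueError(f"negative LRT {lrt}: full model fit below null (nesting violation)")
    lrt = max(lrt, 0.0)
    if lrt == 0.0:
        return p_at_zero
    return float(0.5 * chi2.sf(lrt, df=1))


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide significance bar alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def gene_scan(
    y: np.ndarray,
    X: np.ndarray,
    phi2: np.ndarray,
    kernels: Iterable[MethylKernel],
    sample_ids: Sequence[str] | None = None,
    strict_omega: bool = False,
    p_at_zero: float = 1.0,
    starts: list | None = None,
    **fit_kwargs,
) -> list[AssocResult]:
    """LRT every methylation kernel against the shared polygenic null.

    The null model is fitted once and reused; each full fit is warm-started
    at the null solution.  Kernels are re-ordered to ``sample_ids`` by id
    when they carry their own ordering; a kernel over a different sample set
    is skipped with a warning.  Results come back sorted by gene id, so the
    scan is invariant to kernel stream order.
    """
    y = np.asarray(y, float).ravel()
    phi2 = np.asarray(phi2, float)
    null_fit = fit_ml(VarCompModel(y, X, [("polygenic", phi2)]), **fit_kwargs)
    warm = np.array([null_fit.fraction("polygenic"), 0.0])
    start_pts = [np.asarray(s, float) for s in (starts or SCAN_STARTS)] + [warm]
    results: list[AssocResult] = []
    for kern in kernels:
        if sample_ids is not None and kern.sample_ids != list(sample_ids):
            if set(kern.sample_ids) == set(sample_ids):
                kern = kern.reindex(list(sample_ids))
            else:
                warnings.warn(
                    f"kernel {kern.gene_id}: sample set differs from trait; skipped",
                    stacklevel=2,
                )
                continue
        Emat = 2.0 * kern.K if strict_omega else kern.K
        full_fit = fit_ml(
            VarCompModel(y, X, [("polygenic", phi2), ("methylation", Emat)]),
            starts=start_pts,
            **fit_kwargs,
        )
        ll_full = max(full_fit.loglik, null_fit.loglik)
        lrt = max(0.0, 2.0 * (ll_full - null_fit.loglik))
        results.append(
            AssocResult(
                gene_id=kern.gene_id,
                n_sites=kern.n_sites,
                lrt=lrt,
                p_value=mixture_pvalue(lrt, p_at_zero=p_at_zero),
                h_meth2=full_fit.fraction("methylation"),
                h_r2_full=full_fit.fraction("polygenic"),
                loglik_null=null_fit.loglik,
                loglik_full=ll_full,
                converged=full_fit.converged,
            )
        )
    results.sort(key=lambda r: r.gene_id)
    return results


def site_h2_scan(
    m: MethylationMatrix,
    phi2: np.ndarray,
    covariates: np.ndarray | None = None,
    pc_scores: np.ndarray | None = None,
) -> list[SiteH2Result]:
    """Per-site polygenic heritability of methylation levels.

    Each (inverse-normalized) site row is treated as the trait in a
    single-kernel polygenic model against 2*Phi, compared with a sporadic
    (no-kernel) model; h2 and the boundary-mixture p-value are reported.
    ``pc_scores`` (samples x k) adds the leading methylation PCs as fixed
    covariates — the batch correction route.  Sites whose fit fails are
    reported with NaN h2.
    """
    n = m.n_samples
    parts = [np.ones((n, 1))]
    if covariates is not None:
        parts.append(np.atleast_2d(np.asarray(covariates, float)).reshape(n, -1))
    if pc_scores is not None:
        parts.append(np.asarray(pc_scores, float).reshape(n, -1))
    X = np.column_stack(parts)
    scanner = PolygenicScanner(np.asarray(phi2, float), X)
    out: list[SiteH2Result] = []
    for i, site in enumerate(m.site_ids):
        y = m.values[i]
        if not np.isfinite(y).all():
            mask = np.isfinite(y)
            if mask.sum() < X.shape[1] + 3:
                out.append(SiteH2Result(site, np.nan, np.nan, np.nan, np.nan))
                continue
            sub = PolygenicScanner(phi2[np.ix_(mask, mask)], X[mask])
            poly, spor = sub.fit(y[mask])
        else:
            try:
                poly, spor = scanner.fit(y)
            except Exception as err:  # pragma: no cover - defensive
                warnings.warn(f"site {site}: fit failed ({err})", stacklevel=2)
                out.append(SiteH2Result(site, np.nan, np.nan, np.nan, np.nan))
                continue
        lrt = max(0.0, 2.0 * (poly.loglik - spor.loglik))
        out.append(
            SiteH2Result(site, poly.fraction("polygenic"), poly.loglik,
                         spor.loglik, mixture_pvalue(lrt))
        )
    return out


def results_frame(results: Sequence[AssocResult],
                  gene_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tabulate association results, joining chromosome/position when known."""
    df = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id, "n_sites": r.n_sites, "lrt": r.lrt,
                "p": r.p_value, "h_meth2": r.h_meth2, "h_r2": r.h_r2_full,
                "loglik_null": r.loglik_null, "loglik_full": r.loglik_full,
                "converged": r.converged,
            }
            for r in results
        ]
    )
    if gene_meta is not None and len(df):
        df = df.merge(gene_meta, on="gene_id", how="left")
    else:
        df["chromosome"] = pd.NA
        df["position"] = pd.NA
    return df


def _mixture_expected_pvalues(n: int) -> np.ndarray:
    # null p-value law: uniform on (0, 0.5) with mass 0.5, plus mass 0.5 at 1
    q = (np.arange(1, n + 1) - 0.5) / n
    return np.where(q <= 0.5, q, 1.0)


def export_plots(
    results: Sequence[AssocResult],
    out_dir: str | Path,
    gene_meta: pd.DataFrame | None = None,
    prefix: str = "assoc",
    render: bool = False,
) -> dict[str, Path]:
    """Write Manhattan and Q-Q plot data (TSV), optionally rendered PNGs.

    The Q-Q expected quantiles are taken from the 50:50 boundary-mixture
    null rather than the uniform: half the null statistics are exactly
    zero, and a uniform reference would fake deflation.  Genes without
    chromosome/position are placed in an "unplaced" track.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = results_frame(results, gene_meta)
    man = df.copy()
    man["chromosome"] = man["chromosome"].fillna("unplaced").astype(str)
    man["neglog10_p"] = -np.log10(man["p"].clip(lower=1e-300))
    man = man.sort_values(["chromosome", "position", "gene_id"],
                          na_position="last", kind="stable")
    man_path = out_dir / f"{prefix}.manhattan.tsv"
    man[["gene_id", "chromosome", "position", "n_sites", "lrt", "p", "neglog10_p"]].to_csv(
        man_path, sep="\t", index=False, float_format="%.6g"
    )
    obs = np.sort(df["p"].to_numpy(float))
    exp = _mixture_expected_pvalues(obs.size)
    qq = pd.DataFrame(
        {
            "rank": np.arange(1, obs.size + 1),
            "expected_p": exp,
            "observed_p": obs,
            "expected_neglog10": -np.log10(np.clip(exp, 1e-300, None)),
            "observed_neglog10": -np.log10(np.clip(obs, 1e-300, None)),
        }
    )
    qq_path = out_dir / f"{prefix}.qq.tsv"
    qq.to_csv(qq_path, sep="\t", index=False, float_format="%.6g")
    paths = {"manhattan": man_path, "qq": qq_path}
    if render:
        paths.update(_render(man, qq, out_dir, prefix))
    return paths


def _render(man: pd.DataFrame, qq: pd.DataFrame, out_dir: Path, prefix: str) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    chroms = list(dict.fromkeys(man["chromosome"]))
    offset, ticks = 0.0, []
    for ci, chrom in enumerate(chroms):
        sub = man[man["chromosome"] == chrom]
        pos = pd.to_numeric(sub["position"], errors="coerce").fillna(0.0).to_numpy(float)
        span = max(pos.max() - pos.min(), 1.0) if len(pos) else 1.0
        x = offset + (pos - (pos.min() if len(pos) else 0)) / span
        ax.scatter(x, sub["neglog10_p"], s=8, c=f"C{ci % 2}")
        ticks.append((offset + 0.5, str(chrom)))
        offset += 1.2
    ax.set_xticks([t for t, _ in ticks], [l for _, l in ticks], fontsize=7)
    ax.set_ylabel(r"$-\log_{10} p$")
    man_png = out_dir / f"{prefix}.manhattan.png"
    fig.tight_layout()
    fig.savefig(man_png, dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(qq["expected_neglog10"], qq["observed_neglog10"], s=8)
    lim = max(qq["expected_neglog10"].max(), qq["observed_neglog10"].max(), 1.0)
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} p$ (mixture null)")
    ax.set_ylabel("observed $-\\log_{10} p$")
    qq_png = out_dir / f"{prefix}.qq.png"
    fig.tight_layout()
    fig.savefig(qq_png, dpi=150)
    plt.close(fig)
    return {"manhattan_png": man_png, "qq_png": qq_png}
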