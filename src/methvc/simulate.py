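"""Family-structured synthetic methylation + phenotype datasets.

Everything downstream of the readers can be exercised on data with known
ground truth.  The generator emulates the structure the analyses assume:

* a pedigree of unrelated nuclear (or three-generation) families;
* per-site methylation with an additive polygenic component structured by
  2*Phi (``site_h2``), an i.i.d. environmental remainder, and optionally a
  shared latent batch factor.  Batches are assigned at the family level —
  samples from one family are processed together — which is precisely the
  confounding that inflates naive per-site heritability and that PC
  correction removes.  Gaussian site scores are mapped to the [0, 1] beta
  scale through the standard normal CDF, so the rank-based inverse-normal
  transform recovers the Gaussian scale and the simulated pipeline is
  self-consistent;
* a quantitative trait with specified polygenic (``trait_h_r2``) and
  gene-methylation (``trait_h_meth2``) variance fractions, sex and age
  fixed effects with beta = (0.5, 0.01), and unit total variance.

All draws are reproducible from (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kernel import MethylKernel, build_all_kernels
from .methylation import (GeneSiteIndex, MethylationMatrix, build_gene_index,
                          inverse_normalize, write_methylation)
from .pedigree import Individual, Pedigree, additive_matrix, kinship_matrix

__all__ = ["SimConfig", "SimTruth", "SimDataset", "desk_preset",
           "simulate_pedigree", "simulate_methylation", "simulate_trait",
           "simulate_dataset", "write_dataset"]


@dataclass
class SimConfig:
    """Study-condition knobs for the generator (defaults: desk preset)."""

    n_families: int = 40
    offspring_per_family: int = 3
    family_shape: str = "nuclear"  # or "three_gen"
    n_sites: int = 1000
    n_genes: int = 50
    sites_per_gene: tuple[int, int] = (5, 30)
    site_h2: float = 0.2
    batch_sd: float = 0.0
    n_batches: int = 8
    trait_h_r2: float = 0.3
    trait_h_meth2: float = 0.0
    causal_genes: tuple[str, ...] = ()
    beta_sex: float = 0.5
    beta_age: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.trait_h_r2 <= 1.0 and 0.0 <= self.trait_h_meth2 <= 1.0):
            raise ValueError("variance fractions must lie in [0, 1]")
        if self.trait_h_r2 + self.trait_h_meth2 > 1.0:
            raise ValueError("trait_h_r2 + trait_h_meth2 must be <= 1")
        if not 0.0 <= float(self.site_h2) <= 1.0:
            raise ValueError("site_h2 must lie in [0, 1]")


def desk_preset(seed: int = 0, **overrides) -> SimConfig:
    """40 nuclear families of 5 (200 samples), 1000 sites, 50 genes."""
    return SimConfig(seed=seed, **overrides)


@dataclass
class SimTruth:
    """Ground truth stored alongside simulated data for recovery testing."""

    site_h2: np.ndarray | None = None
    batch: np.ndarray | None = None
    batch_loadings: np.ndarray | None = None
    causal_genes: tuple[str, ...] = ()
    u_poly: np.ndarray | None = None
    u_meth: dict[str, np.ndarray] = field(default_factory=dict)
    trait_h_r2: float | None = None
    trait_h_meth2: float | None = None


def _rng(config: SimConfig, stage: int, rng: np.random.Generator | None):
    return rng if rng is not None else np.random.default_rng([stage, config.seed])


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Unrelated families; founders unrelated across families."""
    rng = np.random.default_rng([0, config.seed])
    inds: list[Individual] = []
    for f in range(1, config.n_families + 1):
        fam = f"F{f:03d}"
        if config.family_shape == "nuclear":
            pa, ma = f"{fam}_P1", f"{fam}_P2"
            inds.append(Individual(pa, None, None, "male", fam))
            inds.append(Individual(ma, None, None, "female", fam))
            for k in range(1, config.offspring_per_family + 1):
                sex = "male" if rng.random() < 0.5 else "female"
                inds.append(Individual(f"{fam}_O{k}", pa, ma, sex, fam))
        elif config.family_shape == "three_gen":
            gp1, gp2 = f"{fam}_GP1", f"{fam}_GP2"
            par, spouse = f"{fam}_C1", f"{fam}_S1"
            inds.extend([
                Individual(gp1, None, None, "male", fam),
                Individual(gp2, None, None, "female", fam),
                Individual(par, gp1, gp2, "male", fam),
                Individual(spouse, None, None, "female", fam),
            ])
            for k in range(1, config.offspring_per_family + 1):
                sex = "male" if rng.random() < 0.5 else "female"
                inds.append(Individual(f"{fam}_G{k}", par, spouse, sex, fam))
        else:
            raise ValueError(f"unknown family_shape {config.family_shape!r}")
    return Pedigree(inds)


def _gene_annotation(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = config.sites_per_gene
    if lo * config.n_genes > config.n_sites:
        raise ValueError(
            f"{config.n_genes} genes with >= {lo} sites each need more than "
            f"the {config.n_sites} sites simulated"
        )
    counts = rng.integers(lo, hi + 1, size=config.n_genes)
    # shrink the largest genes until the draw fits in the simulated sites
    while counts.sum() > config.n_sites:
        counts[int(np.argmax(counts))] -= 1
    rows = []
    cursor = 0
    for g, cnt in enumerate(counts):
        gene = f"GENE{g + 1:04d}"
        chrom = str(1 + g % 22)
        start = 1_000_000 * (g + 1)
        for k in range(cnt):
            rows.append((f"cg{cursor:06d}", gene, chrom, start + 500 * k))
            cursor += 1
    return pd.DataFrame(rows, columns=["site_id", "gene_id", "chromosome", "position"])


def simulate_methylation(
    ped: Pedigree, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[MethylationMatrix, pd.DataFrame, SimTruth]:
    """Heritable methylation on the beta scale, plus annotation and truth.

    Gaussian-scale site score for sample j at site s:

        z[s, j] = g[s, j] + lam[s] * b[j] + eps[s, j]

    with g ~ MVN(0, site_h2 * 2*Phi) per site, eps ~ N(0, 1 - site_h2),
    per-site batch loadings lam ~ U(0.5, 1) and a family-level batch value
    b with standard deviation ``batch_sd``.  Beta values are ndtr(z).
    """
    from scipy.special import ndtr

    rng = _rng(config, 1, rng)
    phi2 = additive_matrix(kinship_matrix(ped))
    n = len(ped)
    L = np.linalg.cholesky(phi2 + 1e-10 * np.eye(n))
    S = config.n_sites
    h2 = np.full(S, float(config.site_h2))
    G = (L @ rng.standard_normal((n, S))) * np.sqrt(h2)  # n x S
    eps = rng.standard_normal((n, S)) * np.sqrt(1.0 - h2)
    lam = rng.uniform(0.5, 1.0, size=S)
    families = [ind.family or ind.iid for ind in ped.individuals]
    fam_order = list(dict.fromkeys(families))
    batch_of_family = {
        fam: i * config.n_batches // len(fam_order) for i, fam in enumerate(fam_order)
    }
    b_batch = rng.normal(0.0, config.batch_sd, size=config.n_batches)
    b = np.array([b_batch[batch_of_family[f]] for f in families])
    Z = G + np.outer(b, lam) + eps  # n x S
    beta_vals = ndtr(Z.T)  # sites x samples
    annotation = _gene_annotation(config, rng)
    m = MethylationMatrix(
        [f"cg{i:06d}" for i in range(S)], ped.ids, beta_vals, transformed=False
    )
    truth = SimTruth(site_h2=h2, batch=b, batch_loadings=lam)
    return m, annotation, truth


def _sex_age(ped: Pedigree, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for ind in ped.individuals:
        age = rng.integers(40, 66) if ind.is_founder else rng.integers(18, 41)
        rows.append((ind.iid, 2 if ind.sex == "female" else 1, int(age)))
    return pd.DataFrame(rows, columns=["sample_id", "sex", "age"])


def simulate_trait(
    ped: Pedigree,
    kernels: dict[str, MethylKernel] | list[MethylKernel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Quantitative trait with polygenic + gene-methylation components.

    trait = 0.5 * I(female) + 0.01 * age + u_poly + sum_g u_g + eps, with
    u_poly ~ MVN(0, h_r2 * 2*Phi), u_g ~ MVN(0, h_meth2/|causal| * K_g) for
    each causal gene, eps ~ MVN(0, e2 * I); total variance 1.
    """
    rng = _rng(config, 2, rng)
    if isinstance(kernels, list):
        kernels = {k.gene_id: k for k in kernels}
    causal = list(config.causal_genes)
    if config.trait_h_meth2 > 0 and not causal:
        raise ValueError("trait_h_meth2 > 0 requires causal_genes")
    missing = [g for g in causal if g not in kernels]
    if missing:
        raise ValueError(f"causal gene(s) without kernels: {missing}")
    phi2 = additive_matrix(kinship_matrix(ped))
    n = len(ped)
    pheno = _sex_age(ped, rng)
    u_poly = np.sqrt(config.trait_h_r2) * (
        np.linalg.cholesky(phi2 + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
    )
    u_meth: dict[str, np.ndarray] = {}
    total_meth = np.zeros(n)
    for g in causal:
        K = kernels[g].K
        if kernels[g].sample_ids != ped.ids:
            K = kernels[g].reindex(ped.ids).K
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-8:
            raise ValueError(f"kernel {g} is not PSD (min eigenvalue {w.min():.2e})")
        Lk = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        u = np.sqrt(config.trait_h_meth2 / len(causal)) * (Lk @ rng.standard_normal(n))
        u_meth[g] = u
        total_meth += u
    e2 = 1.0 - config.trait_h_r2 - config.trait_h_meth2
    eps = np.sqrt(e2) * rng.standard_normal(n)
    female = (pheno["sex"] == 2).to_numpy(float)
    trait = (config.beta_sex * female + config.beta_age * pheno["age"].to_numpy(float)
             + u_poly + total_meth + eps)
    pheno.insert(1, "trait", trait)
    truth = SimTruth(
        causal_genes=tuple(causal), u_poly=u_poly, u_meth=u_meth,
        trait_h_r2=config.trait_h_r2, trait_h_meth2=config.trait_h_meth2,
    )
    return pheno, truth


@dataclass
class SimDataset:
    """A complete simulated study: inputs plus ground truth."""

    config: SimConfig
    pedigree: Pedigree
    methylation: MethylationMatrix  # beta scale
    annotation: pd.DataFrame
    index: GeneSiteIndex
    kernels: list[MethylKernel]  # from inverse-normalized methylation
    phenotype: pd.DataFrame
    meth_truth: SimTruth
    trait_truth: SimTruth


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Run the full generative pipeline for one study.

    Kernels used to generate the trait are built from the inverse-normalized
    simulated methylation, so a correct analysis pipeline sees exactly the
    covariance structure that produced the trait.
    """
    ped = simulate_pedigree(config)
    m_beta, annotation, meth_truth = simulate_methylation(ped, config)
    m_norm = inverse_normalize(m_beta)
    index = build_gene_index(annotation, min_sites=min(config.sites_per_gene[0], 5))
    kernels, _skipped = build_all_kernels(m_norm, index)
    pheno, trait_truth = simulate_trait(ped, kernels, config)
    return SimDataset(config, ped, m_beta, annotation, index, kernels, pheno,
                      meth_truth, trait_truth)


def write_dataset(ds: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the TSV formats the readers consume, plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.ped",
        "methylation": outdir / "methylation.tsv",
        "annotation": outdir / "annotation.tsv",
        "phenotype": outdir / "phenotype.tsv",
        "truth": outdir / "truth.json",
    }
    with paths["pedigree"].open("w") as fh:
        for ind in ds.pedigree.individuals:
            sex = {"male": "1", "female": "2"}.get(ind.sex, "0")
            fh.write(f"{ind.family or '0'}\t{ind.iid}\t{ind.father or '0'}"
                     f"\t{ind.mother or '0'}\t{sex}\n")
    write_methylation(ds.methylation, paths["methylation"])
    ds.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    ds.phenotype.to_csv(paths["phenotype"], sep="\t", index=False, float_format="%.8g")
    truth = {
        "config": asdict(ds.config),
        "site_h2": np.asarray(ds.meth_truth.site_h2).tolist(),
        "batch": np.asarray(ds.meth_truth.batch).tolist(),
        "causal_genes": list(ds.trait_truth.causal_genes),
        "trait_h_r2": ds.trait_truth.trait_h_r2,
        "trait_h_meth2": ds.trait_truth.trait_h_meth2,
        "u_poly": np.asarray(ds.trait_truth.u_poly).tolist(),
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
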