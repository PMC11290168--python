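"""Synthetic genotype/mask/phenotype generators with known ground truth.

Stands in for real heterogeneous-stock genotype data at reduced scale:
LD blocks with a tunable adjacent-pair genotype correlation, balanced
family structure with family-specific allele-frequency jitter, contiguous
SNP-to-gene annotation with an intergenic fraction, and an additive sparse
phenotype with exact in-sample variance partitioning.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import UsageError
from .io import AnnotationMask, GenotypeDataset


@dataclass
class SimulationTruth:
    """Ground truth of a simulated phenotype draw."""

    causal_snp_ids: list[str]
    effect_sizes: list[float]
    causal_gene_ids: list[str]
    target_h2: float
    realized_h2: float
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "causal_snp_ids": self.causal_snp_ids,
            "effect_sizes": self.effect_sizes,
            "causal_gene_ids": self.causal_gene_ids,
            "target_h2": self.target_h2,
            "realized_h2": self.realized_h2,
            "seed": self.seed,
            "params": self.params,
        }


def simulate_genotypes(
    n: int,
    J: int,
    maf_range: tuple[float, float] = (0.1, 0.4),
    n_families: int = 1,
    ld_block_size: int = 1,
    within_block_r: float = 0.0,
    seed: int = 0,
    family_maf_jitter: float = 0.03,
) -> GenotypeDataset:
    """Genotypes in {0, 1, 2} with LD blocks and family structure.

    Within an LD block every SNP shares a base allele frequency and each
    allele copy is, with probability ``within_block_r``, copied from the
    previous SNP's copy — giving adjacent genotype correlation equal to
    ``within_block_r`` in expectation. Families are balanced round-robin
    groups whose block allele frequencies are jittered independently.
    """
    lo, hi = maf_range
    if not 0.0 < lo <= hi < 0.5:
        raise UsageError(f"maf_range must satisfy 0 < lo <= hi < 0.5, got {maf_range}")
    if ld_block_size < 1:
        raise UsageError("ld_block_size must be >= 1")
    if not 0.0 <= within_block_r < 1.0:
        raise UsageError("within_block_r must lie in [0, 1)")
    if n_families < 1 or n_families > n:
        raise UsageError("n_families must lie in [1, n]")

    rng = np.random.default_rng(seed)
    n_blocks = (J + ld_block_size - 1) // ld_block_size
    block_of = np.repeat(np.arange(n_blocks), ld_block_size)[:J]
    base_maf = rng.uniform(lo, hi, size=n_blocks)

    family = [f"fam{(i % n_families) + 1}" for i in range(n)]
    fam_arr = np.asarray(family)
    # per (family, block) allele frequency
    jitter = rng.normal(0.0, family_maf_jitter, size=(n_families, n_blocks))
    fam_maf = np.clip(base_maf[np.newaxis, :] + jitter, 0.02, 0.48)
    fam_index = {f"fam{k + 1}": k for k in range(n_families)}

    p = np.empty((n, J))
    for i, f in enumerate(family):
        p[i] = fam_maf[fam_index[f]][block_of]

    X = np.zeros((n, J), dtype=float)
    for copy in range(2):
        alleles = np.zeros((n, J))
        fresh = (rng.random((n, J)) < p).astype(float)
        copy_prev = rng.random((n, J)) < within_block_r
        alleles[:, 0] = fresh[:, 0]
        for j in range(1, J):
            same_block = block_of[j] == block_of[j - 1]
            if same_block and within_block_r > 0:
                take = copy_prev[:, j]
                alleles[:, j] = np.where(take, alleles[:, j - 1], fresh[:, j])
            else:
                alleles[:, j] = fresh[:, j]
        X += alleles

    return GenotypeDataset(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        variable_ids=[f"snp{j + 1}" for j in range(J)],
        X=X,
        family=family,
    )


def simulate_mask(
    J: int,
    G: int,
    snps_per_gene_range: tuple[int, int] = (2, 8),
    intergenic_fraction: float = 0.0,
    seed: int = 0,
) -> AnnotationMask:
    """Contiguous block annotation of J SNPs into G genes.

    ``round(J * intergenic_fraction)`` SNPs are left unannotated (all-zero
    rows), scattered as gaps between gene blocks to exercise intergenic
    grouping. Every gene receives between ``lo`` and ``hi`` SNPs.
    """
    lo, hi = snps_per_gene_range
    if lo < 1 or hi < lo:
        raise UsageError(f"invalid snps_per_gene_range {snps_per_gene_range}")
    if not 0.0 <= intergenic_fraction < 1.0:
        raise UsageError("intergenic_fraction must lie in [0, 1)")
    n_inter = int(round(J * intergenic_fraction))
    n_annot = J - n_inter
    if n_annot < G * lo:
        raise UsageError(
            f"infeasible: {n_annot} annotatable SNPs < G*lo = {G * lo}"
        )
    if n_annot > G * hi:
        raise UsageError(
            f"infeasible: {n_annot} annotatable SNPs > G*hi = {G * hi}"
        )
    rng = np.random.default_rng(seed)
    sizes = np.full(G, lo)
    surplus = n_annot - G * lo
    while surplus > 0:
        g = int(rng.integers(G))
        if sizes[g] < hi:
            sizes[g] += 1
            surplus -= 1
    # scatter the intergenic SNPs into the G+1 gaps around gene blocks
    gaps = np.zeros(G + 1, dtype=int)
    for _ in range(n_inter):
        gaps[int(rng.integers(G + 1))] += 1

    values = np.zeros((J, G), dtype=int)
    row = gaps[0]
    for g in range(G):
        values[row : row + sizes[g], g] = 1
        row += sizes[g] + gaps[g + 1]
    assert row == J
    return AnnotationMask(
        row_ids=[f"snp{j + 1}" for j in range(J)],
        col_ids=[f"gene{g + 1}" for g in range(G)],
        values=values,
    )


def simulate_phenotype(
    X: np.ndarray | GenotypeDataset,
    causal_k: int,
    h2: float,
    effect_distribution: str = "normal",
    seed: int = 0,
    mask: Optional[AnnotationMask] = None,
    causal_ids: Optional[list[str]] = None,
) -> tuple[np.ndarray, SimulationTruth]:
    """Additive sparse phenotype with exact in-sample heritability.

    y = X beta + eps with beta nonzero on ``causal_k`` uniformly chosen
    SNPs; the noise is orthogonalized against the genetic component and
    scaled so that var(X beta) / var(y) equals ``h2`` exactly in-sample.
    Passing ``causal_ids`` pins the causal set instead of sampling it.
    """
    if isinstance(X, GenotypeDataset):
        data, Xm = X, X.X
        var_ids = data.variable_ids
    else:
        Xm = np.asarray(X, dtype=float)
        var_ids = [f"snp{j + 1}" for j in range(Xm.shape[1])]
    n, J = Xm.shape
    if causal_k > J:
        raise UsageError(f"causal_k={causal_k} > J={J}")
    if not 0.0 <= h2 < 1.0:
        raise UsageError(f"h2 must lie in [0, 1), got {h2}")
    if effect_distribution not in ("normal", "constant"):
        raise UsageError("effect_distribution must be 'normal' or 'constant'")

    rng = np.random.default_rng(seed)
    if causal_ids is not None:
        unknown = [c for c in causal_ids if c not in var_ids]
        if unknown:
            raise UsageError(f"unknown causal ids: {unknown}")
        causal = np.array([var_ids.index(c) for c in causal_ids])
    else:
        causal = rng.choice(J, size=causal_k, replace=False)
        causal.sort()
    if effect_distribution == "normal":
        beta_c = rng.standard_normal(len(causal))
    else:
        beta_c = np.ones(len(causal))
    eps = rng.standard_normal(n)

    if h2 == 0.0:
        beta_c = np.zeros(len(causal))
        y = eps - eps.mean()
        realized = 0.0
    else:
        g = Xm[:, causal] @ beta_c
        g = g - g.mean()
        var_g = float(g @ g) / n
        if var_g == 0.0:
            raise UsageError("causal genotypes are constant; cannot scale to h2")
        eps = eps - eps.mean()
        # orthogonalize the noise so the variance partition is exact
        eps = eps - (float(eps @ g) / float(g @ g)) * g
        var_e_target = var_g * (1.0 - h2) / h2
        eps *= np.sqrt(var_e_target / (float(eps @ eps) / n))
        y = g + eps
        realized = var_g / (float(y @ y) / n)

    causal_snps = [var_ids[j] for j in causal]
    causal_genes: list[str] = []
    if mask is not None:
        rows = {r: j for j, r in enumerate(mask.row_ids)}
        hit = set()
        for c in causal_snps:
            if c in rows:
                hit.update(
                    g for g, v in zip(mask.col_ids, mask.values[rows[c]]) if v == 1
                )
        causal_genes = [g for g in mask.col_ids if g in hit]
    truth = SimulationTruth(
        causal_snp_ids=causal_snps,
        effect_sizes=[float(b) for b in beta_c],
        causal_gene_ids=causal_genes,
        target_h2=h2,
        realized_h2=float(realized),
        seed=seed,
        params={
            "causal_k": causal_k,
            "effect_distribution": effect_distribution,
            "n": n,
            "J": J,
        },
    )
    return y, truth


def inject_missingness(
    data: GenotypeDataset, rate: float, seed: int = 0
) -> GenotypeDataset:
    """Set a uniform random fraction of genotype entries to missing (NaN)."""
    if not 0.0 <= rate < 1.0:
        raise UsageError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    X = data.X.copy()
    drop = rng.random(X.shape) < rate
    # never blank out an entire SNP column
    for j in range(X.shape[1]):
        if drop[:, j].all():
            drop[int(rng.integers(X.shape[0])), j] = False
    X[drop] = np.nan
    return GenotypeDataset(
        sample_ids=list(data.sample_ids),
        variable_ids=list(data.variable_ids),
        X=X,
        y=None if data.y is None else data.y.copy(),
        covariates=None if data.covariates is None else data.covariates.copy(),
        covariate_names=(
            None if data.covariate_names is None else list(data.covariate_names)
        ),
        family=None if data.family is None else list(data.family),
    )
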