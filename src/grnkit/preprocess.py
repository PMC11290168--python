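"""Dataset preparation operators applied before variable selection.

All operators are deterministic (no randomness anywhere in this module) and
return a :class:`PreprocessReport` documenting exactly what was changed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError, ValidationError
from .io import AnnotationMask, GenotypeDataset

INTERGENIC_PREFIX = "intergenic_"


@dataclass
class PreprocessReport:
    """Audit trail of a preprocessing step."""

    n_imputed: int = 0
    imputed_with_global_fallback: list[str] = field(default_factory=list)
    snps_removed_maf: list[str] = field(default_factory=list)
    snps_removed_monomorphic: list[str] = field(default_factory=list)
    covariates_used: list[str] = field(default_factory=list)
    intergenic_groups_created: list[str] = field(default_factory=list)
    constant_group_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_imputed": self.n_imputed,
            "imputed_with_global_fallback": self.imputed_with_global_fallback,
            "snps_removed_maf": self.snps_removed_maf,
            "snps_removed_monomorphic": self.snps_removed_monomorphic,
            "covariates_used": self.covariates_used,
            "intergenic_groups_created": self.intergenic_groups_created,
            "constant_group_columns": self.constant_group_columns,
        }


def impute_family_mean(
    data: GenotypeDataset, global_mean: bool = False
) -> tuple[GenotypeDataset, PreprocessReport]:
    """Replace missing genotypes by the SNP's mean within the sample's family.

    Imputed values are real-valued means (dosages), not re-rounded to
    {0, 1, 2}. A SNP missing in an entire family falls back to its
    across-family mean (recorded in the report). With ``global_mean=True``
    (for datasets without family labels) the across-family mean is used for
    every imputation.
    """
    report = PreprocessReport()
    X = data.X.copy()
    missing = np.isnan(X)
    if not missing.any():
        return _with_X(data, X), report

    fully_missing = [
        data.variable_ids[j] for j in range(data.J) if missing[:, j].all()
    ]
    if fully_missing:
        raise ValidationError(
            f"SNP(s) missing in every sample, cannot impute: {fully_missing}"
        )
    if data.family is None and not global_mean:
        raise UsageError(
            "family labels absent: pass global_mean=True to impute with the "
            "across-family (global) mean of each SNP"
        )

    global_means = np.nanmean(data.X, axis=0)
    if data.family is None or global_mean:
        rows, cols = np.where(missing)
        X[rows, cols] = global_means[cols]
        report.n_imputed = int(missing.sum())
        return _with_X(data, X), report

    fam = np.asarray(data.family)
    fallback: set[str] = set()
    for f in np.unique(fam):
        rows = fam == f
        block = data.X[rows]
        blk_missing = np.isnan(block)
        if not blk_missing.any():
            continue
        counts = (~blk_missing).sum(axis=0)
        sums = np.where(blk_missing, 0.0, block).sum(axis=0)
        fam_means = np.divide(
            sums, counts, out=np.full(block.shape[1], np.nan), where=counts > 0
        )
        for j in np.where(blk_missing.any(axis=0))[0]:
            if counts[j] == 0:  # SNP missing in the whole family
                fam_means[j] = global_means[j]
                fallback.add(data.variable_ids[j])
        filled = np.where(blk_missing, fam_means[np.newaxis, :], block)
        X[rows] = filled
    report.n_imputed = int(missing.sum())
    report.imputed_with_global_fallback = sorted(fallback)
    return _with_X(data, X), report


def filter_maf(
    data: GenotypeDataset, min_maf: float = 0.05
) -> tuple[GenotypeDataset, PreprocessReport]:
    """Keep SNP j iff min(f_j, 1 - f_j) > min_maf, f_j = mean(X[:, j]) / 2.

    The inequality is strict, and monomorphic SNPs (f in {0, 1}) are always
    removed regardless of ``min_maf``.
    """
    if not 0.0 <= min_maf < 0.5:
        raise UsageError(f"min_maf must be in [0, 0.5), got {min_maf}")
    if np.isnan(data.X).any():
        raise UsageError("X has missing entries; impute before MAF filtering")
    f = data.X.mean(axis=0) / 2.0
    mono = (f == 0.0) | (f == 1.0)
    low = np.minimum(f, 1.0 - f) <= min_maf
    keep = ~(mono | low)
    report = PreprocessReport(
        snps_removed_maf=[
            data.variable_ids[j] for j in np.where(low & ~mono)[0]
        ],
        snps_removed_monomorphic=[
            data.variable_ids[j] for j in np.where(mono)[0]
        ],
    )
    if not keep.any():
        raise ValidationError("MAF filter removed every SNP (empty design)")
    kept_ids = [v for v, k in zip(data.variable_ids, keep) if k]
    out = GenotypeDataset(
        sample_ids=list(data.sample_ids),
        variable_ids=kept_ids,
        X=data.X[:, keep].copy(),
        y=None if data.y is None else data.y.copy(),
        covariates=None if data.covariates is None else data.covariates.copy(),
        covariate_names=(
            None if data.covariate_names is None else list(data.covariate_names)
        ),
        family=None if data.family is None else list(data.family),
    )
    return out, report


def residualize_phenotype(data: GenotypeDataset) -> GenotypeDataset:
    """Replace y with OLS residuals of y on [intercept | covariates].

    With no covariates this centers y. Raises when the covariate design is
    rank deficient, naming the collinear columns.
    """
    if data.y is None:
        raise UsageError("dataset has no phenotype to residualize")
    n = data.N
    if data.covariates is None:
        design = np.ones((n, 1))
        names = ["intercept"]
    else:
        design = np.column_stack([np.ones(n), data.covariates])
        names = ["intercept"] + (
            data.covariate_names
            or [f"c{k + 1}" for k in range(data.covariates.shape[1])]
        )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # pivoted QR identifies which columns are in the span of earlier ones
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        collinear = [names[k] for k in range(design.shape[1]) if diag[k] < tol]
        raise ValidationError(
            f"covariate design is rank deficient; collinear columns: {collinear}"
        )
    beta, *_ = np.linalg.lstsq(design, data.y, rcond=None)
    resid = data.y - design @ beta
    out = GenotypeDataset(
        sample_ids=list(data.sample_ids),
        variable_ids=list(data.variable_ids),
        X=data.X.copy(),
        y=resid,
        covariates=None if data.covariates is None else data.covariates.copy(),
        covariate_names=(
            None if data.covariate_names is None else list(data.covariate_names)
        ),
        family=None if data.family is None else list(data.family),
    )
    return out


def _next_intergenic_index(col_ids: list[str]) -> int:
    idx = 0
    for c in col_ids:
        if c.startswith(INTERGENIC_PREFIX):
            suffix = c[len(INTERGENIC_PREFIX):]
            if suffix.isdigit():
                idx = max(idx, int(suffix))
    return idx + 1


def assign_intergenic(
    mask: AnnotationMask,
) -> tuple[AnnotationMask, PreprocessReport]:
    """Group unannotated level-1 variables into synthetic intergenic groups.

    Each maximal run of consecutive all-zero mask rows (row order standing in
    for genomic order) becomes one new group ``intergenic_<k>``; numbering
    continues past any intergenic groups already present. Idempotent when no
    all-zero rows exist.
    """
    report = PreprocessReport()
    zero_rows = np.where(mask.values.sum(axis=1) == 0)[0]
    if zero_rows.size == 0:
        return mask, report

    runs: list[list[int]] = []
    for j in zero_rows:
        if runs and runs[-1][-1] == j - 1:
            runs[-1].append(int(j))
        else:
            runs.append([int(j)])

    k0 = _next_intergenic_index(mask.col_ids)
    new_cols = [f"{INTERGENIC_PREFIX}{k0 + i}" for i in range(len(runs))]
    values = np.concatenate(
        [mask.values, np.zeros((mask.J, len(runs)), dtype=int)], axis=1
    )
    for i, run in enumerate(runs):
        for j in run:
            values[j, mask.G + i] = 1
    report.intergenic_groups_created = list(new_cols)
    out = AnnotationMask(
        row_ids=list(mask.row_ids),
        col_ids=list(mask.col_ids) + new_cols,
        values=values,
    )
    return out, report


def build_group_features(
    data: GenotypeDataset, mask: AnnotationMask
) -> tuple[np.ndarray, list[str], PreprocessReport]:
    """Level-2 design: standardized mask-weighted sums of standardized SNPs.

    H[:, g] = standardize( sum_j M[j, g] * X_std[:, j] ). Groups whose
    aggregate is constant yield an all-zero column and are flagged in the
    report.
    """
    if data.variable_ids != mask.row_ids:
        for a, b in zip(data.variable_ids, mask.row_ids):
            if a != b:
                raise ValidationError(
                    f"variable ids do not match mask row ids: {a!r} != {b!r}"
                )
        raise ValidationError(
            f"variable id count {len(data.variable_ids)} != mask rows {mask.J}"
        )
    if np.isnan(data.X).any():
        raise UsageError("X has missing entries; impute before building features")
    Xs = standardize_columns(data.X)
    H_raw = Xs @ mask.values.astype(float)
    report = PreprocessReport()
    sd = H_raw.std(axis=0)
    const = sd == 0.0
    report.constant_group_columns = [
        mask.col_ids[g] for g in np.where(const)[0]
    ]
    H = np.zeros_like(H_raw)
    nz = ~const
    H[:, nz] = (H_raw[:, nz] - H_raw[:, nz].mean(axis=0)) / sd[nz]
    return H, list(mask.col_ids), report


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Column-standardize (mean 0, sd 1); constant columns become zeros."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = np.zeros_like(X, dtype=float)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    return out


def _with_X(data: GenotypeDataset, X: np.ndarray) -> GenotypeDataset:
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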