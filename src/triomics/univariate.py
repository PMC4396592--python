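"""Per-pair power-law regression screen with a conservative FDR estimator.

For every (protein i, miRNA k) pair the log-linear model

    log P_i = alpha + beta * log M_k + gamma * log E_i + eps

is fitted by ordinary least squares, where E_i is the in-cis mRNA of
protein i. Significance of the miRNA exponents is assessed jointly over
all pairs with the estimator FDR = N * P_star / S (expected false positives
under a global null divided by observed positives), choosing the largest
P_star whose estimate stays within the target bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrixio import ExpressionMatrix

__all__ = [
    "UnivariateFit",
    "UnivariateFitTable",
    "FdrResult",
    "AssociationMatrix",
    "fit_univariate",
    "fit_all_pairs",
    "estimate_fdr",
    "choose_threshold",
    "call_significant",
]

# rank-deficiency guard for the 3x3 normal equations
_COND_MAX = 1e12
_MIN_SAMPLES = 4  # 3 coefficients + 1 residual df


@dataclass
class UnivariateFit:
    """OLS estimates for one (protein, miRNA) pair."""

    protein_id: str
    mirna_id: str
    alpha_hat: float
    beta_hat: float
    gamma_hat: float
    p_beta: float
    p_gamma: float
    n_used: int
    degenerate: bool = False


@dataclass
class UnivariateFitTable:
    """All pairwise fits, one row per (protein, miRNA)."""

    frame: pd.DataFrame  # columns: protein, mirna, alpha, beta, gamma, p_beta, p_gamma, n_used, degenerate
    protein_ids: list[str]
    mirna_ids: list[str]

    COLUMNS = (
        "protein", "mirna", "alpha", "beta", "gamma",
        "p_beta", "p_gamma", "n_used", "degenerate",
    )

    def __post_init__(self) -> None:
        expected = len(self.protein_ids) * len(self.mirna_ids)
        if len(self.frame) != expected:
            raise ValueError(
                f"table has {len(self.frame)} rows, expected "
                f"{len(self.protein_ids)} x {len(self.mirna_ids)} = {expected}"
            )

    @property
    def n_tests(self) -> int:
        return len(self.frame)

    def get(self, protein_id: str, mirna_id: str) -> UnivariateFit:
        rows = self.frame[
            (self.frame["protein"] == protein_id) & (self.frame["mirna"] == mirna_id)
        ]
        if rows.empty:
            raise KeyError(f"no fit for ({protein_id}, {mirna_id})")
        r = rows.iloc[0]
        return UnivariateFit(
            r["protein"], r["mirna"], r["alpha"], r["beta"], r["gamma"],
            r["p_beta"], r["p_gamma"], int(r["n_used"]), bool(r["degenerate"]),
        )

    def pivot(self, column: str) -> pd.DataFrame:
        wide = self.frame.pivot(index="protein", columns="mirna", values=column)
        return wide.loc[self.protein_ids, self.mirna_ids]

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, path) -> "UnivariateFitTable":
        frame = pd.read_csv(path, sep="\t")
        proteins = list(dict.fromkeys(frame["protein"]))
        mirnas = list(dict.fromkeys(frame["mirna"]))
        return cls(frame, proteins, mirnas)


@dataclass
class FdrResult:
    """Outcome of the conservative FDR calculation at one threshold."""

    n_tests: int
    p_star: float
    n_significant: int
    fdr_hat: float
    target_fdr: float | None = None

    @property
    def expected_false_positives(self) -> float:
        return self.n_tests * self.p_star


@dataclass
class AssociationMatrix:
    """Proteins x miRNAs coefficient table with a significance mask."""

    protein_ids: list[str]
    mirna_ids: list[str]
    beta: np.ndarray         # (n_proteins, n_mirnas)
    significant: np.ndarray  # bool mask, same shape
    sign: np.ndarray         # int in {-1, 0, +1}; nonzero exactly on the mask
    fdr: FdrResult | None = None

    def __post_init__(self) -> None:
        shape = (len(self.protein_ids), len(self.mirna_ids))
        for name in ("beta", "significant", "sign"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if ((self.sign != 0) != self.significant).any():
            raise ValueError("sign must be nonzero exactly where significant")

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def counts_by_sign(self) -> tuple[int, int]:
        """(negative, positive) significant association counts."""
        return int((self.sign < 0).sum()), int((self.sign > 0).sum())


def _finite_mask(*vectors: np.ndarray) -> np.ndarray:
    mask = np.ones(vectors[0].shape[0], dtype=bool)
    for v in vectors:
        mask &= np.isfinite(v)
    return mask


def _ols_three(y: np.ndarray, e: np.ndarray, m: np.ndarray):
    """OLS of y on [1, m, e]; returns (alpha, beta, gamma, p_beta, p_gamma, ok)."""
    n = y.shape[0]
    X = np.column_stack([np.ones(n), m, e])
    xtx = X.T @ X
    if np.linalg.cond(xtx) > _COND_MAX:
        return np.nan, np.nan, np.nan, 1.0, 1.0, False
    xty = X.T @ y
    coef = np.linalg.solve(xtx, xty)
    resid = y - X @ coef
    dof = n - 3
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(xtx)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = np.empty(3)
    for i in range(3):
        if se[i] == 0:
            pvals[i] = 0.0 if coef[i] != 0 else 1.0
        else:
            pvals[i] = 2.0 * stats.t.sf(abs(tvals[i]), dof)
    return coef[0], coef[1], coef[2], pvals[1], pvals[2], True


def fit_univariate(
    log_protein,
    log_mrna,
    log_mirna,
    protein_id: str = "",
    mirna_id: str = "",
) -> UnivariateFit:
    """Fit log P = alpha + beta log M + gamma log E by OLS.

    Samples with a missing value in any of the three vectors are excluded
    pairwise. Collinear designs and fits with fewer than four usable
    samples are flagged degenerate with p-values of 1.
    """
    y = np.asarray(log_protein, dtype=float)
    e = np.asarray(log_mrna, dtype=float)
    m = np.asarray(log_mirna, dtype=float)
    if not (y.shape == e.shape == m.shape) or y.ndim != 1:
        raise ValueError("the three vectors must be 1-D and equal length")
    mask = _finite_mask(y, e, m)
    n_used = int(mask.sum())
    if n_used < _MIN_SAMPLES:
        warnings.warn(
            f"fit ({protein_id}, {mirna_id}) skipped: only {n_used} usable samples",
            UserWarning,
            stacklevel=2,
        )
        return UnivariateFit(
            protein_id, mirna_id, np.nan, np.nan, np.nan, 1.0, 1.0, n_used, True
        )
    a, b, g, pb, pg, ok = _ols_three(y[mask], e[mask], m[mask])
    return UnivariateFit(protein_id, mirna_id, a, b, g, pb, pg, n_used, not ok)


def _batched_fits(y: np.ndarray, e: np.ndarray, M: np.ndarray):
    """Vectorized OLS of y on [1, M_j, e] for every row j of M (complete data).

    Returns arrays (alpha, beta, gamma, p_beta, p_gamma, degenerate) of
    length M.shape[0]. Uses the 3x3 normal equations assembled from
    sufficient statistics; mathematically identical to lstsq for
    well-conditioned designs.
    """
    n = y.shape[0]
    n_mir = M.shape[0]
    sy, se_, syy = y.sum(), e.sum(), float(y @ y)
    see, sey = float(e @ e), float(e @ y)
    sm = M.sum(axis=1)
    smm = (M * M).sum(axis=1)
    sme = M @ e
    smy = M @ y

    xtx = np.empty((n_mir, 3, 3))
    xtx[:, 0, 0] = n
    xtx[:, 0, 1] = xtx[:, 1, 0] = sm
    xtx[:, 0, 2] = xtx[:, 2, 0] = se_
    xtx[:, 1, 1] = smm
    xtx[:, 1, 2] = xtx[:, 2, 1] = sme
    xtx[:, 2, 2] = see
    xty = np.stack([np.full(n_mir, sy), smy, np.full(n_mir, sey)], axis=1)

    cond = np.linalg.cond(xtx)
    good = np.isfinite(cond) & (cond <= _COND_MAX)
    coef = np.full((n_mir, 3), np.nan)
    p_beta = np.ones(n_mir)
    p_gamma = np.ones(n_mir)
    if good.any():
        inv = np.linalg.inv(xtx[good])
        c = np.einsum("ijk,ik->ij", inv, xty[good])
        rss = syy - np.einsum("ij,ij->i", c, xty[good])
        rss = np.maximum(rss, 0.0)
        dof = n - 3
        s2 = rss / dof
        var = np.einsum("ijj->ij", inv) * s2[:, None]
        se = np.sqrt(np.maximum(var, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.abs(c) / se
        pv = 2.0 * stats.t.sf(tval, dof)
        # exact fits: zero residual variance -> p = 0 for nonzero coefficients
        zero_se = se == 0
        pv[zero_se] = np.where(c[zero_se] != 0, 0.0, 1.0)
        coef[good] = c
        p_beta[good] = pv[:, 1]
        p_gamma[good] = pv[:, 2]
    return coef[:, 0], coef[:, 1], coef[:, 2], p_beta, p_gamma, ~good


def fit_all_pairs(
    log_protein: ExpressionMatrix,
    log_mrna: ExpressionMatrix,
    log_mirna: ExpressionMatrix,
    gene_map: dict[str, str],
) -> UnivariateFitTable:
    """Run the full protein x miRNA univariate screen.

    All three matrices must already be on the log scale and share their
    sample sets; the intersection of sample ids (in the protein matrix's
    order) is used. ``gene_map`` pairs every protein with its in-cis mRNA.
    """
    shared = [
        s
        for s in log_protein.sample_ids
        if s in set(log_mrna.sample_ids) and s in set(log_mirna.sample_ids)
    ]
    if not shared:
        raise ValueError("no shared samples across the three matrices")
    prot = log_protein.subset_samples(shared)
    mrna = log_mrna.subset_samples(shared)
    mirna = log_mirna.subset_samples(shared)

    missing = [p for p in prot.feature_ids if p not in gene_map]
    if missing:
        raise ValueError(f"proteins without a mapped mRNA: {missing[:5]}")
    unknown = [
        g for g in (gene_map[p] for p in prot.feature_ids)
        if g not in set(mrna.feature_ids)
    ]
    if unknown:
        raise ValueError(f"mapped mRNAs absent from the mRNA matrix: {unknown[:5]}")

    M = mirna.values
    mirna_complete = np.isfinite(M).all()
    records: dict[str, list] = {c: [] for c in UnivariateFitTable.COLUMNS}

    for i, protein_id in enumerate(prot.feature_ids):
        y = prot.values[i]
        e = mrna.row(gene_map[protein_id])
        if mirna_complete and np.isfinite(y).all() and np.isfinite(e).all():
            a, b, g, pb, pg, bad = _batched_fits(y, e, M)
            n_used = np.full(M.shape[0], y.shape[0], dtype=int)
        else:
            fits = [
                fit_univariate(y, e, M[j], protein_id, mid)
                for j, mid in enumerate(mirna.feature_ids)
            ]
            a = np.array([f.alpha_hat for f in fits])
            b = np.array([f.beta_hat for f in fits])
            g = np.array([f.gamma_hat for f in fits])
            pb = np.array([f.p_beta for f in fits])
            pg = np.array([f.p_gamma for f in fits])
            bad = np.array([f.degenerate for f in fits])
            n_used = np.array([f.n_used for f in fits])
        records["protein"].extend([protein_id] * M.shape[0])
        records["mirna"].extend(mirna.feature_ids)
        records["alpha"].extend(a)
        records["beta"].extend(b)
        records["gamma"].extend(g)
        records["p_beta"].extend(pb)
        records["p_gamma"].extend(pg)
        records["n_used"].extend(n_used)
        records["degenerate"].extend(bad)

    frame = pd.DataFrame(records)
    return UnivariateFitTable(frame, list(prot.feature_ids), list(mirna.feature_ids))


def estimate_fdr(p_values, p_star: float, target_fdr: float | None = None) -> FdrResult:
    """Conservative estimate FDR = N * p_star / S with S = #{p <= p_star}."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values given")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    s = int((p <= p_star).sum())
    fdr_hat = (n * p_star / s) if s > 0 else float("inf")
    return FdrResult(n, float(p_star), s, fdr_hat, target_fdr)


def choose_threshold(p_values, target_fdr: float) -> FdrResult:
    """Largest significant-call count S over observed-p-value thresholds
    subject to the estimated FDR staying within ``target_fdr``.

    Only observed p-values are scanned: any threshold between consecutive
    order statistics yields the same S, so observed values are canonical.
    If no threshold qualifies the result has S = 0 and p_star = 0.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values given")
    if not 0 < target_fdr < 1:
        raise ValueError(f"target_fdr must be in (0, 1), got {target_fdr}")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    candidates, counts = np.unique(p, return_counts=True)
    s_at = np.cumsum(counts)  # S at each candidate threshold
    with np.errstate(divide="ignore"):
        fdr_at = n * candidates / s_at
    ok = fdr_at <= target_fdr
    if not ok.any():
        return FdrResult(n, 0.0, 0, float("inf"), target_fdr)
    best = np.nonzero(ok)[0][np.argmax(s_at[ok])]
    return FdrResult(
        n, float(candidates[best]), int(s_at[best]), float(fdr_at[best]), target_fdr
    )


def call_significant(table: UnivariateFitTable, target_fdr: float) -> AssociationMatrix:
    """Threshold the pooled miRNA-exponent p-values and build the
    coefficient table with its significance mask."""
    beta = table.pivot("beta").to_numpy()
    p_beta = table.pivot("p_beta").to_numpy()
    if target_fdr <= 0:
        fdr = FdrResult(table.n_tests, 0.0, 0, float("inf"), target_fdr)
    else:
        fdr = choose_threshold(table.frame["p_beta"].to_numpy(), target_fdr)
    if fdr.n_significant == 0:
        mask = np.zeros_like(p_beta, dtype=bool)
    else:
        mask = p_beta <= fdr.p_star
    sign = np.zeros(beta.shape, dtype=int)
    sign[mask] = np.sign(beta[mask]).astype(int)
    # a zero estimated coefficient cannot carry a significant sign
    mask &= sign != 0
    sign[~mask] = 0
    return AssociationMatrix(
        list(table.protein_ids), list(table.mirna_ids), beta, mask, sign, fdr
    )
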