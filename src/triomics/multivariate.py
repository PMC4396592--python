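"""Per-protein multivariate fit: all prescreened miRNAs at once.

The model log P = alpha + sum_j beta_j log M_j + gamma log E + eps is
fitted with an L1 penalty on the miRNA coefficients. miRNAs that were not
nominally significant in the univariate screen (p > prescreen alpha) are
constrained to zero by exclusion from the design. The penalty is chosen by
k-fold cross-validation on a geometric lambda path; the intercept and the
in-cis mRNA coefficient gamma are unpenalized by default.

The solver is cyclic coordinate descent on the standardized design using
covariance updates, with warm starts along the path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix
from .univariate import UnivariateFitTable

__all__ = [
    "MultivariateFit",
    "prescreen",
    "fit_multivariate",
    "fit_all_multivariate",
    "lasso_path",
    "write_multivariate_fits",
    "read_multivariate_fits",
]

DEFAULT_FOLDS = 10
DEFAULT_PRESCREEN_ALPHA = 0.01
_N_LAMBDAS = 100
_LAMBDA_EPS = 1e-4
_TOL = 1e-7
_MAX_ITER = 100_000


@dataclass
class MultivariateFit:
    """One protein's penalized multivariate fit."""

    protein_id: str
    alpha_hat: float
    gamma_hat: float
    beta_hats: dict[str, float]       # nonzero miRNA coefficients only
    lambda_: float
    cv_folds: int
    cv_seed: int
    allowed_set: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        allowed = set(self.allowed_set)
        outside = [k for k in self.beta_hats if k not in allowed]
        if outside:
            raise ValueError(f"nonzero coefficients outside the prescreen set: {outside}")
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")

    def beta_vector(self, mirna_ids: list[str]) -> np.ndarray:
        return np.array([self.beta_hats.get(m, 0.0) for m in mirna_ids])


def prescreen(
    table: UnivariateFitTable, protein_id: str, alpha_level: float = DEFAULT_PRESCREEN_ALPHA
) -> list[str]:
    """miRNAs whose univariate exponent is nominally significant
    (p <= alpha_level) for this protein, in the table's miRNA order."""
    if protein_id not in set(table.protein_ids):
        raise KeyError(f"unknown protein {protein_id!r}")
    sub = table.frame[table.frame["protein"] == protein_id]
    keep = sub[sub["p_beta"] <= alpha_level]["mirna"].tolist()
    order = {m: i for i, m in enumerate(table.mirna_ids)}
    return sorted(keep, key=order.__getitem__)


# ---------------------------------------------------------------------------
# Coordinate-descent core (covariance updates)
# ---------------------------------------------------------------------------

def _cd_solve(G, c, lam, weights, beta, tol, max_iter):
    """Minimize (1/2) b'Gb - c'b + lam * sum_j w_j |b_j| by cyclic CD.

    G = X'X/n and c = X'y/n for the centered/standardized design; beta is
    modified in place (warm start) and returned.
    """
    p = beta.shape[0]
    q = G @ beta
    diag = np.diag(G).copy()
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            z = c[j] - q[j] + diag[j] * bj
            t = lam * weights[j]
            if z > t:
                bnew = (z - t) / diag[j]
            elif z < -t:
                bnew = (z + t) / diag[j]
            else:
                bnew = 0.0
            if bnew != bj:
                q += G[:, j] * (bnew - bj)
                beta[j] = bnew
                d = abs(bnew - bj)
                if d > max_delta:
                    max_delta = d
        if max_delta < tol:
            break
    return beta


def lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    weights: np.ndarray,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> np.ndarray:
    """Coefficients (p, L) on the given (descending) lambda path.

    X columns must be centered; y centered. Penalty is
    (1/(2n))||y - Xb||^2 + lam * sum_j w_j |b_j|. Warm starts across the path.
    """
    n, p = X.shape
    G = (X.T @ X) / n
    c = (X.T @ y) / n
    out = np.zeros((p, len(lambdas)))
    beta = np.zeros(p)
    for k, lam in enumerate(lambdas):
        beta = _cd_solve(G, c, lam, weights, beta, tol, max_iter)
        out[:, k] = beta
    return out


def _standardize_design(X: np.ndarray):
    """Center columns and scale to unit population SD; constant columns get
    scale 1 (their centered values are all zero, so the coefficient is 0)."""
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = np.sqrt((Xc * Xc).mean(axis=0))
    sd_safe = np.where(sd > 0, sd, 1.0)
    return Xc / sd_safe, mean, sd_safe


def _fold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, n, k]))
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def _lambda_grid(X: np.ndarray, y: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Geometric path from the smallest lambda killing all penalized
    coefficients (after partialling out unpenalized columns by OLS)."""
    n = X.shape[0]
    free = weights == 0
    if free.any():
        Xf = X[:, free]
        coef, *_ = np.linalg.lstsq(Xf, y, rcond=None)
        r = y - Xf @ coef
    else:
        r = y
    pen = ~free
    if not pen.any():
        return np.array([0.0])
    lam_max = np.max(np.abs(X[:, pen].T @ r)) / n
    if lam_max <= 0:
        return np.array([0.0])
    return np.geomspace(lam_max, lam_max * _LAMBDA_EPS, _N_LAMBDAS)


def fit_multivariate(
    log_protein,
    log_mrna,
    log_mirna_allowed: np.ndarray,
    allowed_ids: list[str],
    protein_id: str = "",
    cv_folds: int = DEFAULT_FOLDS,
    cv_seed: int = 0,
    penalize_gamma: bool = False,
    lambda_rule: str = "min",
    lambda_: float | None = None,
    tol: float = _TOL,
) -> MultivariateFit:
    """Penalized fit for one protein.

    Parameters
    ----------
    log_protein, log_mrna : 1-D sample vectors on the log scale.
    log_mirna_allowed : array (n_allowed, n_samples) of log miRNA expression
        for the prescreened miRNAs (possibly empty).
    allowed_ids : miRNA identifiers matching the rows of the design.
    lambda_ : fix the penalty instead of cross-validating (None = CV).
    lambda_rule : "min" (CV-minimal) or "1se".
    """
    y = np.asarray(log_protein, dtype=float)
    e = np.asarray(log_mrna, dtype=float)
    Ma = np.asarray(log_mirna_allowed, dtype=float)
    if Ma.size == 0:
        Ma = Ma.reshape(0, y.shape[0])
    if Ma.shape[1] != y.shape[0] or e.shape[0] != y.shape[0]:
        raise ValueError("sample dimensions disagree")
    if Ma.shape[0] != len(allowed_ids):
        raise ValueError("allowed_ids length must match the design rows")
    n = y.shape[0]
    if lambda_ is None:
        if cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if n <= cv_folds:
            raise ValueError(f"need more samples ({n}) than folds ({cv_folds})")
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")

    # design: [mRNA | allowed miRNAs]; intercept handled by centering
    X = np.column_stack([e, Ma.T]) if Ma.shape[0] else e[:, None]
    p = X.shape[1]
    weights = np.ones(p)
    if not penalize_gamma:
        weights[0] = 0.0

    if Ma.shape[0] == 0 and not penalize_gamma:
        # pure OLS of y on [1, e]
        A = np.column_stack([np.ones(n), e])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return MultivariateFit(
            protein_id, float(coef[0]), float(coef[1]), {}, 0.0,
            cv_folds, cv_seed, [],
        )

    if lambda_ is not None:
        lambdas = np.array([float(lambda_)])
        chosen_idx = 0
    else:
        Xs_full, _, _ = _standardize_design(X)
        yc_full = y - y.mean()
        lambdas = _lambda_grid(Xs_full, yc_full, weights)
        folds = _fold_assignment(n, cv_folds, cv_seed)
        mse = np.zeros((cv_folds, len(lambdas)))
        for f in range(cv_folds):
            tr, va = folds != f, folds == f
            Xtr, mean_tr, sd_tr = _standardize_design(X[tr])
            ytr_mean = y[tr].mean()
            path = lasso_path(Xtr, y[tr] - ytr_mean, lambdas, weights, tol=tol)
            Xva = (X[va] - mean_tr) / sd_tr
            pred = ytr_mean + Xva @ path
            mse[f] = ((y[va][:, None] - pred) ** 2).mean(axis=0)
        mean_mse = mse.mean(axis=0)
        if lambda_rule == "min":
            chosen_idx = int(np.argmin(mean_mse))
        else:
            se = mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
            bound = mean_mse.min() + se[int(np.argmin(mean_mse))]
            chosen_idx = int(np.nonzero(mean_mse <= bound)[0][0])

    Xs, mean_x, sd_x = _standardize_design(X)
    yc = y - y.mean()
    beta_std = lasso_path(Xs, yc, lambdas[: chosen_idx + 1], weights, tol=tol)[:, -1]
    beta_orig = beta_std / sd_x
    intercept = float(y.mean() - mean_x @ beta_orig)
    gamma_hat = float(beta_orig[0])
    beta_hats = {
        allowed_ids[j]: float(beta_orig[j + 1])
        for j in range(len(allowed_ids))
        if beta_orig[j + 1] != 0.0
    }
    return MultivariateFit(
        protein_id, intercept, gamma_hat, beta_hats, float(lambdas[chosen_idx]),
        cv_folds if lambda_ is None else 0, cv_seed, list(allowed_ids),
    )


def fit_all_multivariate(
    log_protein: ExpressionMatrix,
    log_mrna: ExpressionMatrix,
    log_mirna: ExpressionMatrix,
    gene_map: dict[str, str],
    table: UnivariateFitTable,
    alpha_level: float = DEFAULT_PRESCREEN_ALPHA,
    cv_folds: int = DEFAULT_FOLDS,
    cv_seed: int = 0,
    penalize_gamma: bool = False,
    lambda_rule: str = "min",
) -> list[MultivariateFit]:
    """Prescreen + penalized fit for every protein in the table's order."""
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
    mirna_index = {m: i for i, m in enumerate(mirna.feature_ids)}

    fits = []
    for protein_id in table.protein_ids:
        allowed = prescreen(table, protein_id, alpha_level)
        allowed = [m for m in allowed if m in mirna_index]
        design = mirna.values[[mirna_index[m] for m in allowed], :]
        fits.append(
            fit_multivariate(
                prot.row(protein_id),
                mrna.row(gene_map[protein_id]),
                design,
                allowed,
                protein_id=protein_id,
                cv_folds=cv_folds,
                cv_seed=cv_seed,
                penalize_gamma=penalize_gamma,
                lambda_rule=lambda_rule,
            )
        )
    return fits


def write_multivariate_fits(fits: list[MultivariateFit], coef_path, summary_path) -> None:
    """Nonzero coefficients as (protein, mirna, beta) TSV plus a per-protein
    summary (alpha, gamma, lambda, counts)."""
    rows = [
        {"protein": f.protein_id, "mirna": m, "beta": b}
        for f in fits
        for m, b in sorted(f.beta_hats.items())
    ]
    pd.DataFrame(rows, columns=["protein", "mirna", "beta"]).to_csv(
        coef_path, sep="\t", index=False, float_format="%.17g"
    )
    summary = pd.DataFrame(
        {
            "protein": [f.protein_id for f in fits],
            "alpha": [f.alpha_hat for f in fits],
            "gamma": [f.gamma_hat for f in fits],
            "lambda": [f.lambda_ for f in fits],
            "n_allowed": [len(f.allowed_set) for f in fits],
            "n_selected": [len(f.beta_hats) for f in fits],
        }
    )
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.17g")


def read_multivariate_fits(coef_path, summary_path) -> list[MultivariateFit]:
    """Rebuild fits from the TSV pair written by ``write_multivariate_fits``.

    The prescreen set is not serialized; the reconstructed ``allowed_set``
    is the selected set, which is sufficient for scoring and prediction.
    """
    coef = pd.read_csv(coef_path, sep="\t")
    summary = pd.read_csv(summary_path, sep="\t")
    by_protein: dict[str, dict[str, float]] = {}
    for _, row in coef.iterrows():
        by_protein.setdefault(str(row["protein"]), {})[str(row["mirna"])] = float(row["beta"])
    fits = []
    for _, row in summary.iterrows():
        protein_id = str(row["protein"])
        betas = by_protein.get(protein_id, {})
        fits.append(
            MultivariateFit(
                protein_id,
                float(row["alpha"]),
                float(row["gamma"]),
                betas,
                float(row["lambda"]),
                0,
                0,
                sorted(betas),
            )
        )
    return fits
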