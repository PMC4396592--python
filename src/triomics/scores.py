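"""Patient-specific miRNA-effect scores and downstream validation.

score(protein, patient) = sum_j beta_j * logM(j, patient) summed over the
protein's multivariate coefficients, i.e. the modeled total miRNA
contribution to that patient's log protein level. Scores feed patient
clustering and clinical-association testing; the same coefficients drive
cross-cohort protein prediction, and overexpression-screen z-scores give an
orthogonal functional consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .matrixio import ExpressionMatrix
from .multivariate import MultivariateFit
from .univariate import AssociationMatrix
from .interactome import ClusterTree, hierarchical_cluster, extract_clusters

__all__ = [
    "PatientScoreMatrix",
    "PredictionResult",
    "ScreenZScores",
    "ClinicalAssociation",
    "compute_scores",
    "cluster_patients",
    "cluster_vs_clinical",
    "predict_protein",
    "screen_zscore",
    "screen_consistency",
]

DEFAULT_SCREEN_THRESHOLD = 1.96


@dataclass
class PatientScoreMatrix:
    """Proteins x patients score table."""

    values: np.ndarray
    protein_ids: list[str]
    sample_ids: list[str]

    def to_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(
            self.values, list(self.protein_ids), list(self.sample_ids), "score"
        )


@dataclass
class PredictionResult:
    """Cross-cohort prediction quality for one protein."""

    protein_id: str
    r: float
    p: float
    n: int
    n_mirnas_used: int
    n_mirnas_missing: int
    degenerate: bool = False


@dataclass
class ScreenZScores:
    """Overexpression-screen standard scores, proteins x perturbations."""

    values: np.ndarray
    protein_ids: list[str]
    mirna_ids: list[str]
    threshold: float = DEFAULT_SCREEN_THRESHOLD

    def significant_mask(self) -> np.ndarray:
        return np.abs(self.values) >= self.threshold


@dataclass
class ClinicalAssociation:
    """Association between a cluster assignment and a clinical factor."""

    table: pd.DataFrame
    statistic: float
    p_value: float
    test: str


def compute_scores(
    fits: list[MultivariateFit], log_mirna: ExpressionMatrix
) -> PatientScoreMatrix:
    """Per-patient weighted sums of log miRNA expression.

    A protein with no selected miRNAs gets an all-zero score row. Missing
    miRNAs raise with the full list of absent features.
    """
    index = {m: i for i, m in enumerate(log_mirna.feature_ids)}
    missing = sorted(
        {m for f in fits for m in f.beta_hats if m not in index}
    )
    if missing:
        raise KeyError(f"miRNAs absent from the expression matrix: {missing}")
    n = log_mirna.n_samples
    values = np.zeros((len(fits), n))
    for i, fit in enumerate(fits):
        for mirna_id, beta in fit.beta_hats.items():
            values[i] += beta * log_mirna.values[index[mirna_id]]
    return PatientScoreMatrix(
        values, [f.protein_id for f in fits], list(log_mirna.sample_ids)
    )


def cluster_patients(
    scores: PatientScoreMatrix, k: int | None = None
) -> tuple[ClusterTree, dict[str, int] | None]:
    """Cluster patients (columns) by Euclidean distance, complete linkage.

    Returns the tree and, if ``k`` is given, the flat assignment.
    """
    if len(scores.sample_ids) < 2:
        raise ValueError("need at least two patients to cluster")
    D = squareform(pdist(scores.values.T, metric="euclidean"))
    tree = hierarchical_cluster(D, scores.sample_ids)
    labels = extract_clusters(tree, k) if k is not None else None
    return tree, labels


def cluster_vs_clinical(labels: dict[str, int], clinical: dict[str, str]) -> ClinicalAssociation:
    """Contingency-table test of cluster assignment against a categorical
    clinical variable; chi-square, with Fisher's exact test for 2x2 tables
    whose expected counts fall below 5."""
    shared = [s for s in labels if s in clinical]
    if not shared:
        raise ValueError("no shared sample ids between labels and clinical data")
    frame = pd.DataFrame(
        {
            "cluster": [labels[s] for s in shared],
            "clinical": [clinical[s] for s in shared],
        }
    )
    table = pd.crosstab(frame["cluster"], frame["clinical"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("both factors need at least two categories")
    counts = table.to_numpy()
    chi2, p, _, expected = stats.chi2_contingency(counts)
    test = "chi-square"
    if counts.shape == (2, 2) and (expected < 5).any():
        _, p = stats.fisher_exact(counts)
        chi2 = float("nan")
        test = "fisher-exact"
    return ClinicalAssociation(table, float(chi2), float(p), test)


def predict_protein(
    fit: MultivariateFit,
    log_mrna_target: np.ndarray,
    log_mirna_target: ExpressionMatrix,
    observed_log_protein: np.ndarray | None = None,
) -> tuple[np.ndarray, PredictionResult | None]:
    """Predict log protein in a target cohort from a fitted model.

    prediction = alpha + gamma * logE + sum over coefficient miRNAs present
    in the target cohort; absent miRNAs are dropped and counted. Returns
    the prediction and, when observations are supplied, a Pearson
    correlation result.
    """
    e = np.asarray(log_mrna_target, dtype=float)
    index = {m: i for i, m in enumerate(log_mirna_target.feature_ids)}
    pred = fit.alpha_hat + fit.gamma_hat * e
    used = missing = 0
    for mirna_id, beta in fit.beta_hats.items():
        if mirna_id in index:
            pred = pred + beta * log_mirna_target.values[index[mirna_id]]
            used += 1
        else:
            missing += 1
    degenerate = used == 0 and fit.gamma_hat == 0
    if observed_log_protein is None:
        return pred, None
    obs = np.asarray(observed_log_protein, dtype=float)
    mask = np.isfinite(obs) & np.isfinite(pred)
    n = int(mask.sum())
    if n < 3 or degenerate or np.std(pred[mask]) == 0 or np.std(obs[mask]) == 0:
        result = PredictionResult(fit.protein_id, float("nan"), float("nan"), n, used, missing, True)
    else:
        r, p = stats.pearsonr(pred[mask], obs[mask])
        result = PredictionResult(fit.protein_id, float(r), float(p), n, used, missing, False)
    return pred, result


def screen_zscore(
    raw: ExpressionMatrix, threshold: float = DEFAULT_SCREEN_THRESHOLD
) -> ScreenZScores:
    """Standardize each protein across the whole screen: subtract the
    screen mean and divide by the screen SD (per protein row)."""
    values = raw.values
    if values.shape[1] < 3:
        raise ValueError("need at least three perturbations per protein")
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, ddof=0, keepdims=True)
    zero = (sd == 0).ravel()
    if zero.any():
        bad = [raw.feature_ids[i] for i in np.nonzero(zero)[0]]
        raise ValueError(f"zero screen SD for protein(s): {bad[:5]}")
    z = (values - mean) / sd
    return ScreenZScores(
        z, list(raw.feature_ids), list(raw.sample_ids), float(threshold)
    )


def screen_consistency(
    assoc: AssociationMatrix, z: ScreenZScores
) -> list[tuple[str, str]]:
    """(mirna, protein) pairs that are significant in the cohort screen AND
    pass the perturbation-screen threshold with a consistent sign."""
    prot_idx = {p: i for i, p in enumerate(z.protein_ids)}
    mir_idx = {m: j for j, m in enumerate(z.mirna_ids)}
    validated = []
    for i, protein_id in enumerate(assoc.protein_ids):
        if protein_id not in prot_idx:
            continue
        zi = prot_idx[protein_id]
        for j, mirna_id in enumerate(assoc.mirna_ids):
            if not assoc.significant[i, j] or mirna_id not in mir_idx:
                continue
            zval = z.values[zi, mir_idx[mirna_id]]
            if abs(zval) >= z.threshold and np.sign(zval) == assoc.sign[i, j]:
                validated.append((mirna_id, protein_id))
    return validated
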