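"""Genotype PCA and the Evanno Δk statistic.

The PCA follows the EIGENSOFT/smartpca convention: per-locus centring by the
mean dosage and scaling by sqrt(p̂(1−p̂)) with p̂ = mean/2 (Patterson
scaling); missing calls are mean-imputed per locus before scaling;
eigendecomposition of the accession × accession cross-product gives scores
identical to an SVD of the standardised matrix.

Evanno Δk consumes a table of replicate admixture log-likelihoods per K
(e.g. real STRUCTURE runs or synthetic fixtures); the admixture MCMC itself
is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geno_io import MISSING, GenotypeMatrix


@dataclass
class PcaResult:
    accession_ids: list[str]
    scores: np.ndarray  # accession × component (U·S of the standardised matrix)
    eigenvalues: np.ndarray  # descending, all components
    variance_explained: np.ndarray  # λ_i / Σλ, sums to 1

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.accession_ids, columns=cols)


@dataclass
class EvannoResult:
    k_values: list[int]
    mean_logl: dict[int, float]
    sd_logl: dict[int, float]
    delta_k: dict[int, float]  # interior K only
    best_k: int


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Patterson-scaled genotype PCA.

    Monomorphic loci are dropped; missing cells are replaced by the locus
    mean dosage.  Component signs follow a fixed convention: the locus
    loading of largest magnitude is made positive.
    """
    X = gm.calls.astype(np.float64)
    valid = gm.calls != MISSING
    if not valid.any(axis=0).all():
        raise ValidationError("some loci have no non-missing calls")
    mean = np.where(valid, X, 0.0).sum(axis=0) / valid.sum(axis=0)
    X = np.where(valid, X, mean[None, :])
    p_hat = mean / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    # also drop loci constant after imputation (p̂ in (0,1) but zero spread)
    poly &= X.std(axis=0) > 0
    if not poly.any():
        raise ValidationError("all loci are monomorphic; PCA undefined")
    Z = (X[:, poly] - mean[poly]) / np.sqrt(p_hat[poly] * (1.0 - p_hat[poly]))
    C = Z @ Z.T
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if (eigval < -1e-9 * max(1.0, eigval.max())).any():
        raise ValidationError("cross-product matrix not PSD (numerical failure)")
    eigval = np.clip(eigval, 0.0, None)
    total = eigval.sum()
    var_exp = eigval / total if total > 0 else eigval
    n_components = min(n_components, eigval.size)
    sv = np.sqrt(eigval[:n_components])
    scores = eigvec[:, :n_components] * sv[None, :]
    # sign convention via locus loadings V = Zᵀ U / s
    for j in range(n_components):
        if sv[j] == 0:
            continue
        loading = Z.T @ eigvec[:, j]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, j] *= -1.0
    return PcaResult(list(gm.accession_ids), scores, eigval, var_exp)


def evanno_delta_k(likelihoods: pd.DataFrame) -> EvannoResult:
    """Evanno second-difference statistic over replicate log-likelihoods.

    ``likelihoods`` needs columns ``K`` and ``logL`` (one row per replicate).
    ΔK(K) = |mean L(K+1) − 2 mean L(K) + mean L(K−1)| / sd(L(K)) with the
    sample standard deviation, defined for interior K only.
    """
    if not {"K", "logL"}.issubset(likelihoods.columns):
        raise ValidationError("likelihood table needs columns 'K' and 'logL'")
    grouped = likelihoods.groupby("K")["logL"]
    ks = sorted(int(k) for k in grouped.groups)
    if len(ks) < 3:
        raise ValidationError("need >= 3 K values for Δk")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValidationError(f"K values must be consecutive, got {ks}")
    counts = grouped.count()
    if (counts < 2).any():
        bad = int(counts[counts < 2].index[0])
        raise ValidationError(f"K={bad} has fewer than 2 replicates")
    mean_l = {int(k): float(v) for k, v in grouped.mean().items()}
    sd_l = {int(k): float(v) for k, v in grouped.std(ddof=1).items()}
    delta: dict[int, float] = {}
    for k in ks[1:-1]:
        if sd_l[k] == 0:
            raise ValidationError(f"sd of logL at interior K={k} is 0; Δk undefined")
        delta[k] = abs(mean_l[k + 1] - 2.0 * mean_l[k] + mean_l[k - 1]) / sd_l[k]
    best_k = max(delta, key=lambda k: (delta[k], -k))
    return EvannoResult(ks, mean_l, sd_l, delta, best_k)
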