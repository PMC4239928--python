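"""PCA score-space Mahalanobis screening of calibration spectra.

The screen works on the normalized distance MD^2/k (k = number of retained
principal components), the convention of filter-instrument calibration
software: a sample is flagged when MD^2 > limit * k.  With ``limit`` 3 and
3 retained PCs this reproduces the chi-square(3) > 9 tail.  The 95%
chi-square quantile is reported alongside as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["PCModel", "pca_mahalanobis_screen"]


@dataclass
class PCModel:
    mean: np.ndarray
    components: np.ndarray  # (k, p) row-orthonormal loadings
    score_sd: np.ndarray  # (k,) standard deviation per retained PC
    explained_fraction: float
    md_limit: float
    chi2_95: float  # 95% quantile of chi-square(k): diagnostic only

    @property
    def n_components(self) -> int:
        return len(self.score_sd)

    def normalized_md2(self, X: np.ndarray) -> np.ndarray:
        """MD^2 / k of each row in the retained score space."""
        t = (np.atleast_2d(X) - self.mean) @ self.components.T
        return np.sum((t / self.score_sd) ** 2, axis=1) / self.n_components


def pca_mahalanobis_screen(
    X: np.ndarray,
    md_limit: float = 3.0,
    retained_variance: float = 0.99,
) -> tuple[np.ndarray, np.ndarray, PCModel]:
    """Single-pass outlier screen; returns (inlier idx, outlier idx, model)."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 samples to screen")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (n - 1)
    total = var.sum()
    if total <= 0:
        raise ValueError("degenerate spectra matrix: zero variance")
    frac = np.cumsum(var) / total
    k = int(np.searchsorted(frac, retained_variance) + 1)
    k = min(k, len(s))
    model = PCModel(
        mean=mean,
        components=Vt[:k],
        score_sd=s[:k] / np.sqrt(n - 1),
        explained_fraction=float(frac[k - 1]),
        md_limit=md_limit,
        chi2_95=float(sps.chi2.ppf(0.95, k)),
    )
    gh = model.normalized_md2(X)
    outliers = np.flatnonzero(gh > md_limit)
    inliers = np.flatnonzero(gh <= md_limit)
    return inliers, outliers, model
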