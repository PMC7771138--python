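"""Environmental-gradient characterization by correlation-matrix PCA.

The ten plot-level environmental variables are centered and scaled to
unit variance, the eigendecomposition of their correlation matrix gives
axis loadings and eigenvalues (which sum to the number of variables),
and plot scores are the standardized data projected on the loadings, so
loadings are interpretable as variable-axis correlations up to the axis
scale.  Axes with eigenvalue > 1 (Kaiser criterion) are marked retained;
all axes are reported.  Signs are fixed by making the largest-magnitude
loading on each axis positive, so repeated runs are bit-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ENV_VARS, EnvironmentTable
from .errors import InsufficientDataError, ValidationError


@dataclass(frozen=True)
class GradientAxes:
    """Loadings, plot scores and eigenvalues of the environment PCA."""

    loadings: pd.DataFrame = field(repr=False)   # variable x axis
    scores: pd.DataFrame = field(repr=False)     # plot x axis
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    retained_axes: int

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def environment_pca(env: EnvironmentTable) -> GradientAxes:
    """PCA of the plot x environment matrix on its correlation matrix."""
    X = env.matrix()
    if len(X) < 3:
        raise InsufficientDataError("environment PCA needs >=3 plots")
    sd = X.std(axis=0, ddof=1)
    constant = sd.index[sd == 0.0]
    if len(constant):
        raise ValidationError(
            f"constant environmental variable {constant[0]!r}: zero variance "
            "breaks standardization")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # Deterministic sign: largest-|loading| entry of each axis positive.
    for k in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[i, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    axes = [f"PC{k + 1}" for k in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=list(ENV_VARS), columns=axes)
    scores = pd.DataFrame(Z.to_numpy() @ eigvec, index=X.index, columns=axes)
    var_exp = eigval / eigval.sum()
    return GradientAxes(
        loadings=loadings, scores=scores, eigenvalues=eigval,
        variance_explained=var_exp,
        retained_axes=int((eigval > 1.0).sum()),
    )
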