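"""Expression binarization via per-gene two-component Gaussian mixtures.

Each gene's expression values across samples are modeled as a mixture of an
OFF and an ON Gaussian (the ON component is the one with the larger mean).
The binarized value of a sample is the posterior probability of the ON
component at that sample's expression level, so downstream rule fitting
works on soft ON-probabilities rather than hard calls.

The two components share a tied variance, which makes the ON posterior a
monotone (logistic) function of expression.  Genes whose mixture fit cannot
separate two components (near-zero variance, or fitted means closer than a
small fraction of the sample standard deviation) are flagged degenerate and
mapped to a flat 0.5 everywhere: no evidence either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.mixture import GaussianMixture

from .io import ExpressionMatrix

__all__ = ["GeneMixture", "BinarizedMatrix", "fit_binarizer", "transform_value"]

#: |mu_on - mu_off| below this multiple of the sample SD counts as unseparated
SEPARATION_TOL = 1e-3
#: total variance below this counts as constant expression
VARIANCE_TOL = 1e-12


@dataclass(frozen=True)
class GeneMixture:
    """Fitted 1-D two-component mixture for one gene (tied variance)."""

    means: tuple[float, float]
    variance: float
    weights: tuple[float, float]
    on_component: int
    degenerate: bool


@dataclass(frozen=True)
class BinarizedMatrix:
    """ON-probabilities with the same gene/sample index as the input matrix,
    plus the per-gene mixture records used to produce them."""

    probabilities: pd.DataFrame
    mixtures: Mapping[str, GeneMixture]

    def __post_init__(self) -> None:
        arr = self.probabilities.to_numpy(dtype=float)
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("binarized probabilities must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.probabilities.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.probabilities.columns]

    def mixture_table(self) -> pd.DataFrame:
        """Per-gene mixture parameters, exportable as CSV."""
        rows = []
        for gene, mix in self.mixtures.items():
            rows.append(
                {
                    "gene": gene,
                    "mu_off": mix.means[1 - mix.on_component],
                    "mu_on": mix.means[mix.on_component],
                    "variance": mix.variance,
                    "weight_off": mix.weights[1 - mix.on_component],
                    "weight_on": mix.weights[mix.on_component],
                    "degenerate": mix.degenerate,
                }
            )
        return pd.DataFrame(rows).set_index("gene")


def _fit_gene(values: np.ndarray, seed: int) -> GeneMixture:
    sd = float(np.std(values))
    if float(np.var(values)) < VARIANCE_TOL:
        return GeneMixture((0.0, 0.0), 0.0, (0.5, 0.5), 0, True)
    q25, q75 = np.percentile(values, [25, 75])
    gm = GaussianMixture(
        n_components=2,
        covariance_type="tied",
        tol=1e-6,
        max_iter=500,
        n_init=1,
        means_init=np.array([[q25], [q75]]),
        weights_init=np.array([0.5, 0.5]),
        random_state=seed,
    )
    gm.fit(values.reshape(-1, 1))
    means = (float(gm.means_[0, 0]), float(gm.means_[1, 0]))
    variance = float(gm.covariances_[0, 0])
    weights = (float(gm.weights_[0]), float(gm.weights_[1]))
    if abs(means[0] - means[1]) < SEPARATION_TOL * sd or variance < VARIANCE_TOL:
        return GeneMixture(means, variance, weights, 0, True)
    on = int(np.argmax(means))
    return GeneMixture(means, variance, weights, on, False)


def transform_value(mixture: GeneMixture, value: float) -> float:
    """Posterior probability of the ON component at ``value``.

    Degenerate mixtures return 0.5 for every input.  With tied variances
    the posterior is a logistic function of ``value``, hence monotone
    non-decreasing in expression.
    """
    if not np.isfinite(value):
        raise ValueError("expression value must be finite")
    return float(_transform_values(mixture, np.asarray([value], dtype=float))[0])


def _transform_values(mixture: GeneMixture, values: np.ndarray) -> np.ndarray:
    if mixture.degenerate:
        return np.full(values.shape, 0.5)
    on = mixture.on_component
    off = 1 - on
    var = mixture.variance
    # log-odds of ON vs OFF; the quadratic terms cancel under tied variance
    log_odds = (
        np.log(mixture.weights[on])
        - np.log(mixture.weights[off])
        - 0.5 * ((values - mixture.means[on]) ** 2) / var
        + 0.5 * ((values - mixture.means[off]) ** 2) / var
    )
    return expit(log_odds)


def fit_binarizer(matrix: ExpressionMatrix, seed: int = 0) -> BinarizedMatrix:
    """Fit a two-component mixture per gene and return ON-probabilities.

    Every gene is fitted independently across samples.  ``seed`` fixes the
    EM initialisation so refits are bit-reproducible.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples to fit a mixture")
    probs = pd.DataFrame(
        index=matrix.values.index, columns=matrix.values.columns, dtype=float
    )
    mixtures: dict[str, GeneMixture] = {}
    for gene in matrix.values.index:
        values = matrix.values.loc[gene].to_numpy(dtype=float)
        mix = _fit_gene(values, seed)
        mixtures[str(gene)] = mix
        probs.loc[gene] = _transform_values(mix, values)
    return BinarizedMatrix(probabilities=probs, mixtures=mixtures)
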