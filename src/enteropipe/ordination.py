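"""Principal coordinates analysis and envfit-style vector fitting.

PCoA is classical metric scaling: Gower double-centering of -1/2 squared
distances followed by an eigendecomposition.  Semi-metric dissimilarities
(Bray-Curtis, sqrt-JSD) can produce negative eigenvalues; those axes are
dropped and their magnitudes reported — no Cailliez/Lingoes correction is
applied.  Axis signs are fixed by forcing the largest-magnitude loading of
each axis positive, so biplots are reproducible.

envfit regresses an external continuous variable (typically a driver
genus's relative abundance) on the ordination axes; the fitted direction is
the vector along which the variable changes fastest, r^2 its squared
multiple correlation, and significance comes from row permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from skbio import DistanceMatrix


@dataclass
class OrdinationResult:
    """Sample coordinates on PCoA axes ordered by decreasing eigenvalue."""

    sample_ids: list[str]
    coordinates: np.ndarray  # (n, m) axes scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray  # magnitudes of dropped negative axes
    truncated: bool = False

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates,
            index=self.sample_ids,
            columns=[f"PCo{i + 1}" for i in range(self.n_axes)],
        )

    def to_report_dict(self) -> dict:
        return {
            "eigenvalues": self.eigenvalues,
            "proportion_explained": self.proportion_explained,
            "negative_eigenvalues": self.negative_eigenvalues,
            "coordinates": {
                s: self.coordinates[i] for i, s in enumerate(self.sample_ids)
            },
        }


@dataclass
class EnvfitResult:
    """Fitted direction, squared correlation and permutation p per variable."""

    variable: str
    direction: np.ndarray  # unit vector in ordination space
    r_squared: float
    p_value: float
    n_perm: int

    def to_report_dict(self) -> dict:
        return {
            "variable": self.variable,
            "direction": self.direction,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
        }


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    For distances realizable in Euclidean space the coordinates reproduce
    the input distances exactly; requesting more axes than there are
    positive eigenvalues truncates with a warning flag.
    """
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("pcoa needs at least 3 samples")
    a = -0.5 * d**2
    # Gower double-centering
    row = a.mean(axis=1, keepdims=True)
    g = a - row - row.T + a.mean()
    evals, evecs = linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-10
    pos = evals > tol
    neg_mags = np.abs(evals[evals < -tol])
    evals_pos = evals[pos]
    coords = evecs[:, pos] * np.sqrt(evals_pos)
    # deterministic axis signs: largest-|loading| positive
    for j in range(coords.shape[1]):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    truncated = False
    if n_axes is not None:
        if n_axes > coords.shape[1]:
            truncated = True
            n_axes = coords.shape[1]
        coords = coords[:, :n_axes]
        prop = evals_pos[:n_axes] / evals_pos.sum()
        evals_out = evals_pos[:n_axes]
    else:
        prop = evals_pos / evals_pos.sum()
        evals_out = evals_pos
    return OrdinationResult(
        list(dist.ids), coords, evals_out, prop, neg_mags, truncated
    )


def envfit(
    ord_result: OrdinationResult,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = 0,
) -> list[EnvfitResult]:
    """Fit continuous variables onto ordination axes with permutation tests.

    Per variable: least-squares regression on the (centered) axes gives the
    direction of steepest increase and r^2; the p-value is
    (1 + #{permuted r^2 >= observed}) / (n_perm + 1) under row permutation.
    Zero-variance variables are excluded (flagged with r^2 = NaN, p = NaN).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = ord_result.coordinates
    variables = variables.loc[ord_result.sample_ids]
    rng = np.random.default_rng(seed)
    # hat projection reused across variables and permutations
    q, _ = np.linalg.qr(x - x.mean(axis=0))
    results = []
    for name in variables.columns:
        y = variables[name].to_numpy(dtype=float)
        yc = y - y.mean()
        sst = float(yc @ yc)
        if sst <= 0:
            results.append(EnvfitResult(name, np.full(x.shape[1], np.nan), np.nan, np.nan, n_perm))
            continue
        coef, *_ = np.linalg.lstsq(x - x.mean(axis=0), yc, rcond=None)
        fitted = q @ (q.T @ yc)
        r2 = float(fitted @ fitted) / sst
        direction = coef / np.linalg.norm(coef)
        perms = np.array([rng.permutation(len(yc)) for _ in range(n_perm)])
        proj = yc[perms] @ q  # (n_perm, m) projections onto the axis span
        r2p = (proj**2).sum(axis=1) / sst
        p = (1 + int((r2p >= r2 - 1e-12).sum())) / (n_perm + 1)
        results.append(EnvfitResult(name, direction, r2, p, n_perm))
    return results
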