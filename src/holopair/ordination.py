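"""Bray-Curtis distances, classical PCoA, and one-factor PERMANOVA.

The completeness profiles (genomes x modules, zero-variance modules
removed) are compared with the Bray-Curtis dissimilarity
``d(u, v) = sum|u - v| / sum(u + v)``, embedded with classical
(Torgerson) principal-coordinate analysis, and tested for group effects
with the permutational MANOVA pseudo-F of Anderson (2001),

    F = (SS_total - SS_within) / (a - 1) / (SS_within / (n - a)),

where sums of squared interpoint distances are computed within groups
and in total. The permutation p-value uses the add-one convention
``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DesignError, InputError
from .modules import CompletenessMatrix


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise InputError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise InputError("distance matrix must be symmetric with zero diagonal")


@dataclass(frozen=True)
class PCoAResult:
    coordinates: pd.DataFrame  # ids x retained axes (positive eigenvalues only)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    r_squared: float


def bray_curtis_matrix(cm: CompletenessMatrix | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between genome profiles."""
    df = cm.df if isinstance(cm, CompletenessMatrix) else cm
    profile = df.to_numpy(dtype=float)
    if (profile.sum(axis=1) == 0).any():
        zero = df.index[profile.sum(axis=1) == 0].tolist()
        raise InputError(
            f"Bray-Curtis undefined for all-zero profile(s): {', '.join(map(str, zero))}"
        )
    d = squareform(pdist(profile, metric="braycurtis"))
    return DistanceMatrix(ids=tuple(df.index), values=d)


def pcoa(dm: DistanceMatrix, k: int | None = None) -> PCoAResult:
    """Classical (Torgerson) principal-coordinate analysis.

    Double-centers the squared distance matrix, eigendecomposes it and
    returns coordinates on the axes with positive eigenvalues (at most
    ``k``), ordered by descending eigenvalue. Negative eigenvalues are
    reported unchanged; no Lingoes/Cailliez correction is applied.
    """
    n = len(dm.ids)
    if k is not None and k > n - 1:
        raise InputError("k must be at most n - 1")
    d2 = dm.values**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ d2 @ centerer
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-12, 1e-9 * max(abs(eigval[0]), 1.0))
    positive = np.flatnonzero(eigval > tol)
    if k is not None:
        positive = positive[:k]
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    coordinates = pd.DataFrame(
        coords,
        index=pd.Index(dm.ids, name="genome_id"),
        columns=[f"PCo{i + 1}" for i in range(len(positive))],
    )
    return PCoAResult(coordinates=coordinates, eigenvalues=eigval)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        members = codes == g
        n_g = int(members.sum())
        ss_within += d2[np.ix_(members, members)].sum() / (2 * n_g)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    dm: DistanceMatrix,
    labels: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA with seeded label permutations.

    Requires at least two groups with at least two members each.
    ``r_squared`` is the between-group fraction of the total sum of
    squared distances.
    """
    labels = np.asarray(labels)
    if len(labels) != len(dm.ids):
        raise InputError("labels length does not match distance matrix")
    groups, codes = np.unique(labels, return_inverse=True)
    counts = np.bincount(codes)
    if len(groups) < 2 or (counts < 2).any():
        raise DesignError("PERMANOVA requires >= 2 groups with >= 2 members each")
    d2 = dm.values**2
    n = d2.shape[0]
    a = len(groups)
    f_obs = _pseudo_f(d2, codes, a)

    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_perm):
        perm_codes = codes[rng.permutation(n)]
        if _pseudo_f(d2, perm_codes, a) >= f_obs:
            n_extreme += 1
    p = (1 + n_extreme) / (1 + n_perm)

    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(a):
        members = codes == g
        ss_within += d2[np.ix_(members, members)].sum() / (2 * int(members.sum()))
    r2 = (ss_total - ss_within) / ss_total
    return PermanovaResult(
        pseudo_F=float(f_obs), p_value=float(p), n_permutations=n_perm, r_squared=float(r2)
    )
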