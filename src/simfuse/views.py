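"""Per-view compound similarity matrices and their stochastic normal form.

A *view* is one independent representation of the same compound set.  The
two views built here are

* bioactivity: the Pearson correlation of two activity profiles, with
  negative correlations clipped to zero (a weak negative correlation
  carries no more information about molecular similarity than noise);
* structure: the Tanimoto index of two binary fingerprints,
  ``N_AB / (N_A + N_B - N_AB)``.

Both similarities live in [0, 1] with a unit diagonal.  Before fusion
each similarity matrix S is standardized to z-scores over all entries,
shifted so its minimum is zero (the factorization requires a nonnegative
matrix), and renormalized to sum to one.  The result P is the stochastic
form consumed by the fusion objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CompoundProfileSet, FingerprintSet

MIN_COMPLETE_FEATURES = 3

__all__ = [
    "SimilarityView",
    "pearson_similarity",
    "tanimoto_similarity",
    "euclidean_similarity",
    "standardize_normalize",
]


@dataclass
class SimilarityView:
    """A named symmetric similarity matrix plus its normalized form.

    Attributes
    ----------
    name : str
        View label, e.g. ``"bioactivity"`` or ``"structure"``.
    compound_ids : list of str
        Row/column labels of ``S`` in order.
    S : ndarray
        Symmetric similarity matrix in [0, 1].
    P : ndarray
        ``standardize_normalize(S)``: nonnegative, sums to 1.  Computed
        on first access (a constant S has no stochastic form and only
        errors if fusion actually asks for it).
    """

    name: str
    compound_ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.compound_ids)
        if self.S.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.S.shape} != ({n}, {n})")
        if not np.allclose(self.S, self.S.T, atol=1e-12, rtol=0):
            raise ValueError("similarity matrix is not symmetric within 1e-12")
        if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
            raise ValueError("similarity entries must lie in [0, 1]")
        self._P: np.ndarray | None = None

    @property
    def P(self) -> np.ndarray:
        if self._P is None:
            self._P = standardize_normalize(self.S)
        return self._P

    @classmethod
    def from_similarity(cls, name: str, compound_ids, S: np.ndarray) -> "SimilarityView":
        S = np.asarray(S, dtype=float)
        return cls(name, [str(c) for c in compound_ids], S)

    @property
    def n(self) -> int:
        return len(self.compound_ids)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.compound_ids, columns=self.compound_ids)

    def p_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.compound_ids, columns=self.compound_ids)

    def restrict(self, indices) -> "SimilarityView":
        """Sub-view on a compound subset; P is recomputed on the submatrix."""
        indices = np.asarray(indices, dtype=int)
        ids = [self.compound_ids[i] for i in indices]
        S = self.S[np.ix_(indices, indices)]
        return SimilarityView.from_similarity(self.name, ids, S)


def pearson_similarity(profiles: CompoundProfileSet, name: str = "bioactivity") -> SimilarityView:
    """Bioactivity-profile similarity: clipped Pearson correlation.

    Correlation is computed on pairwise-complete features (a feature
    missing in either compound is dropped for that pair).  Pairs left
    with fewer than three complete features, or with a constant profile
    on the complete subset, get similarity 0 and a warning.  Negative
    correlations are clipped to 0; the diagonal is 1 by definition.

    Raises
    ------
    ValueError
        If a compound's observed profile has zero variance (its
        correlation with anything is undefined), or fewer than two
        compounds / three features are supplied.
    """
    X = profiles.values
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 compounds for a similarity matrix")
    if m < MIN_COMPLETE_FEATURES:
        raise ValueError(f"need at least {MIN_COMPLETE_FEATURES} features for correlation")
    for i, cid in enumerate(profiles.compound_ids):
        row = X[i][~np.isnan(X[i])]
        if row.size >= 2 and np.ptp(row) == 0:
            raise ValueError(f"compound {cid!r} has a constant profile; correlation undefined")

    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(X[i]) | np.isnan(X[j]))
            if ok.sum() < MIN_COMPLETE_FEATURES:
                warnings.warn(
                    f"compounds {profiles.compound_ids[i]!r} and "
                    f"{profiles.compound_ids[j]!r} share only {int(ok.sum())} complete "
                    f"features; similarity set to 0",
                    stacklevel=2,
                )
                continue
            a, b = X[i, ok], X[j, ok]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn(
                    f"constant profile on the complete-feature subset for pair "
                    f"({profiles.compound_ids[i]!r}, {profiles.compound_ids[j]!r}); "
                    f"similarity set to 0",
                    stacklevel=2,
                )
                continue
            r = np.corrcoef(a, b)[0, 1]
            S[i, j] = S[j, i] = max(0.0, float(r))
    np.clip(S, 0.0, 1.0, out=S)
    return SimilarityView.from_similarity(name, profiles.compound_ids, S)


def tanimoto_similarity(fps: FingerprintSet, name: str = "structure") -> SimilarityView:
    """Structural similarity: Tanimoto index of binary fingerprints."""
    B = fps.bits.astype(np.int64)
    if B.shape[0] < 2:
        raise ValueError("need at least 2 compounds for a similarity matrix")
    counts = B.sum(axis=1)
    for cid, c in zip(fps.compound_ids, counts):
        if c == 0:
            raise ValueError(f"compound {cid!r} has an all-zero fingerprint")
    common = B @ B.T
    union = counts[:, None] + counts[None, :] - common
    S = common / union
    np.fill_diagonal(S, 1.0)
    return SimilarityView.from_similarity(name, fps.compound_ids, S)


def euclidean_similarity(profiles: CompoundProfileSet, name: str = "euclidean") -> SimilarityView:
    """Distance-based profile similarity 1/(1 + euclidean distance).

    Provided only for side-by-side comparison curves against the
    correlation view; the convention for mapping a distance to [0, 1]
    is this package's own choice and the resulting curve should be read
    as illustrative.  Missing features are dropped pairwise and the
    distance rescaled to the full feature count.
    """
    X = profiles.values
    n, m = X.shape
    if n < 2:
        raise ValueError("need at least 2 compounds for a similarity matrix")
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(X[i]) | np.isnan(X[j]))
            if ok.sum() == 0:
                continue
            d = np.linalg.norm(X[i, ok] - X[j, ok]) * np.sqrt(m / ok.sum())
            S[i, j] = S[j, i] = 1.0 / (1.0 + d)
    return SimilarityView.from_similarity(name, profiles.compound_ids, S)


def standardize_normalize(S: np.ndarray) -> np.ndarray:
    """Map a similarity matrix to the stochastic form used by fusion.

    z-scores are taken over all n^2 entries (diagonal included), shifted
    by the global minimum so the smallest entry becomes 0, and divided
    by the total so the result sums to 1.  The output is invariant to
    any positive affine rescaling a*S + b of the input.

    Raises
    ------
    ValueError
        If S is not symmetric/finite or all entries are equal (sd = 0).
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.isfinite(S).all():
        raise ValueError("similarity matrix contains non-finite entries")
    if not np.allclose(S, S.T, atol=1e-12, rtol=0):
        raise ValueError("similarity matrix is not symmetric within 1e-12")
    sd = S.std()
    if sd == 0:
        raise ValueError("constant similarity matrix: standardization undefined (sd = 0)")
    Z = (S - S.mean()) / sd
    Z -= Z.min()
    P = Z / Z.sum()
    # exact symmetry can drift by 1 ulp through the reductions; restore it
    return (P + P.T) / 2.0
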