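"""User grouping: residential status and compositional photo-content axes.

Residential status (local vs tourist) comes from the profile country
when listed, otherwise from the modal country of the user's geotagged
public photographs.  Per-user photo-category profiles are compositional
data: counts are converted to percentages, a fixed value of one is added
to every component to avoid zeros, and the result is closed to the unit
simplex.  User axes are principal components of the isometric log-ratio
(ilr) coordinates — robust (MCD scatter) by default — with loadings
back-transformed to centred log-ratio (clr) space, where each
component's loadings sum to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import MinCovDet

from .exceptions import ValidationError

__all__ = ["CompositionTable", "CompositionalPCAResult", "assign_status",
           "assign_status_frame", "user_composition", "ilr_contrast_matrix",
           "ilr", "robust_pca"]


@dataclass
class CompositionTable:
    user_ids: list
    categories: list
    proportions: np.ndarray  # rows close to 1, strictly positive

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=self.user_ids,
                            columns=self.categories)


@dataclass
class CompositionalPCAResult:
    scores: np.ndarray            # user x component
    loadings_clr: np.ndarray      # category x component; columns sum to 0
    explained_variance: np.ndarray
    robust: bool
    categories: list
    user_ids: list


def assign_status(profile_country: str | None,
                  photo_countries: list[str],
                  home_country: str,
                  seed: int = 0,
                  subsample_cap: int = 50) -> str:
    """'local', 'tourist' or 'unresolved' for one user.

    The profile country decides when present; otherwise the modal
    country of the user's geotagged public photographs (subsampled to
    ``subsample_cap`` with the seed when larger).  Users with neither a
    profile country nor geotags are 'unresolved' and excluded downstream.
    """
    if profile_country:
        return "local" if profile_country == home_country else "tourist"
    countries = [c for c in photo_countries if c]
    if not countries:
        return "unresolved"
    if len(countries) > subsample_cap:
        rng = np.random.default_rng(seed)
        countries = list(rng.choice(countries, size=subsample_cap,
                                    replace=False))
    vc = pd.Series(countries).value_counts()
    top = vc.max()
    modal = sorted(vc.index[vc == top])[0]  # ties: lexicographic, deterministic
    return "local" if modal == home_country else "tourist"


def assign_status_frame(users: pd.DataFrame, photos: pd.DataFrame,
                        home_country: str, seed: int = 0,
                        subsample_cap: int = 50) -> pd.Series:
    """Vectorized :func:`assign_status` over a user table.

    ``photos`` should be the public channel with a ``country`` column.
    """
    pub = photos[photos["channel"] == "public"]
    by_user = pub.groupby("user_id")["country"].agg(list)
    out = {}
    for i, row in enumerate(users.itertuples(index=False)):
        countries = by_user.get(row.user_id, [])
        out[row.user_id] = assign_status(
            row.profile_country if isinstance(row.profile_country, str) else None,
            countries, home_country, seed=seed + i, subsample_cap=subsample_cap)
    return pd.Series(out, name="status")


def user_composition(photos: pd.DataFrame, categories: list,
                     category_col: str = "category") -> CompositionTable:
    """Per-user closed compositions over photo categories.

    Counts -> percentages -> +1 to every component -> closure to sum 1.
    The +1 zero replacement happens on the 0-100 percentage scale, so
    every part is strictly positive.  Users with zero photos are
    excluded with a warning.
    """
    if category_col not in photos.columns:
        raise ValidationError(f"photo table lacks a {category_col!r} column")
    counts = (photos.groupby(["user_id", category_col]).size()
              .unstack(fill_value=0)
              .reindex(columns=categories, fill_value=0))
    empty = counts.index[counts.sum(axis=1) == 0]
    if len(empty):
        warnings.warn(f"excluding {len(empty)} users with zero photos",
                      stacklevel=2)
        counts = counts.drop(index=empty)
    pct = counts.to_numpy(dtype=float)
    pct = 100.0 * pct / pct.sum(axis=1, keepdims=True)
    plus = pct + 1.0
    closed = plus / plus.sum(axis=1, keepdims=True)
    return CompositionTable(list(counts.index), list(categories), closed)


def ilr_contrast_matrix(n_parts: int) -> np.ndarray:
    """Pivot-coordinate ilr contrast matrix V (n_parts x n_parts-1).

    Column j contrasts part j against the geometric mean of the later
    parts; ilr coordinates are z = ln(x) @ V and clr vectors are
    recovered as V @ z (V has orthonormal, zero-sum columns).
    """
    C = n_parts
    V = np.zeros((C, C - 1))
    for j in range(C - 1):
        r = C - j - 1  # number of later parts
        norm = np.sqrt(r / (r + 1.0))
        V[j, j] = norm
        V[j + 1:, j] = -norm / r
    return V


def ilr(comp: CompositionTable | np.ndarray) -> np.ndarray:
    """Pivot-coordinate ilr transform of strictly positive compositions.

    z_j = sqrt((C-j)/(C-j+1)) * ln(x_j / gm(x_{j+1..C})), j = 1..C-1.
    Scale-invariant: closure (or any rescaling) does not change z.
    """
    x = comp.proportions if isinstance(comp, CompositionTable) else np.asarray(comp, dtype=float)
    one_d = x.ndim == 1
    x = np.atleast_2d(x)
    if np.any(x <= 0):
        raise ValidationError(
            "compositions must be strictly positive; apply zero replacement first")
    z = np.log(x) @ ilr_contrast_matrix(x.shape[1])
    return z[0] if one_d else z


def robust_pca(comp: CompositionTable, n_components: int = 2,
               robust: bool = True, support_fraction: float = 0.75,
               seed: int = 0) -> CompositionalPCAResult:
    """Principal components of ilr coordinates, reported in clr space.

    With ``robust=True`` the location/scatter come from a high-breakdown
    minimum-covariance-determinant estimate (support fraction 0.75);
    otherwise the classical mean/covariance.  Scores are centred at the
    (robust) location; clr loadings are V @ ilr-loadings and each sum to
    zero.  Component signs are fixed so the largest-magnitude clr
    loading of each component is positive.
    """
    Z = ilr(comp)
    n, D = Z.shape
    if n < D + 1:
        raise ValidationError(
            f"need at least {D + 1} observations for {D}-dimensional ilr PCA")
    if n_components > D:
        raise ValidationError("n_components must be <= n_parts - 1")
    used_robust = robust
    if robust:
        try:
            mcd = MinCovDet(support_fraction=support_fraction,
                            random_state=seed).fit(Z)
            loc, cov = mcd.location_, mcd.covariance_
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"robust scatter failed ({exc}); falling back to "
                          "classical covariance", stacklevel=2)
            used_robust = False
    if not used_robust:
        loc = Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    idx = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[idx], 0.0), evecs[:, idx]
    W = evecs[:, :n_components]
    V = ilr_contrast_matrix(len(comp.categories))
    loadings_clr = V @ W
    # Sign convention: largest-|loading| clr entry of each component positive.
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings_clr[:, j])))
        if loadings_clr[i, j] < 0:
            loadings_clr[:, j] *= -1
            W[:, j] *= -1
    scores = (Z - loc) @ W
    explained = evals[:n_components] / evals.sum() if evals.sum() > 0 else \
        np.zeros(n_components)
    return CompositionalPCAResult(
        scores=scores, loadings_clr=loadings_clr,
        explained_variance=explained, robust=used_robust,
        categories=list(comp.categories), user_ids=list(comp.user_ids))
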