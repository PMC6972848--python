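"""Group comparison of park-photo category frequencies.

Users differ wildly in how many park photographs they take, so raw
category frequencies over-weight prolific users.  The estimator here
samples exactly one park photograph per user, tabulates category
fractions per user group (e.g. local vs tourist), and averages the
fractions over repeated samples (50 by default).  Group differences per
category use the pooled two-proportion z test (z^2 equals the Pearson
chi-square of the 2x2 table), with a standardized mean-difference
effect size d derived from the chi-square -> r -> d conversion:
r = sqrt(chi2 / N), d = 2 r / sqrt(1 - r^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ValidationError

__all__ = ["FrequencyTable", "ProportionTestResult", "resample_frequencies",
           "group_test", "sensitivity"]


@dataclass
class FrequencyTable:
    groups: list
    categories: list
    mean_freq: pd.DataFrame  # group x category, rows sum to 1
    reps: int
    seed: int


@dataclass
class ProportionTestResult:
    category: object
    z: float
    p: float
    chi2: float
    r: float
    d: float
    n1: int
    n2: int


def _user_groups(photos: pd.DataFrame, users: pd.DataFrame,
                 group_col: str = "status",
                 groups: list | None = None):
    merged = photos.merge(users[["user_id", group_col]], on="user_id",
                          how="left")
    if groups is None:
        groups = sorted(g for g in merged[group_col].dropna().unique()
                        if g != "unresolved")
    merged = merged[merged[group_col].isin(groups)]
    return merged, list(groups)


def resample_frequencies(photos: pd.DataFrame, users: pd.DataFrame,
                         reps: int = 50, seed: int = 0,
                         group_col: str = "status",
                         groups: list | None = None,
                         categories: list | None = None) -> FrequencyTable:
    """Mean category frequencies per group over one-photo-per-user samples.

    ``photos`` must carry ``user_id`` and ``category`` columns (park
    channel); ``users`` maps users to groups.  Users without any
    categorized park photo are simply absent; users in no requested
    group are excluded with a warning when unresolved.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    merged, groups = _user_groups(photos, users, group_col, groups)
    if categories is None:
        categories = sorted(merged["category"].unique())
    n_unresolved = users[group_col].eq("unresolved").sum() \
        if group_col in users else 0
    if n_unresolved:
        warnings.warn(f"excluding {n_unresolved} unresolved users",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    cat_index = {c: i for i, c in enumerate(categories)}
    # per-user photo category arrays, stable order
    by_user = merged.groupby("user_id", sort=True)
    user_cats = {uid: g["category"].to_numpy() for uid, g in by_user}
    user_group = merged.drop_duplicates("user_id").set_index("user_id")[group_col]
    freq_sum = {g: np.zeros(len(categories)) for g in groups}
    g_users = {g: [u for u in user_cats if user_group[u] == g] for g in groups}
    for g in groups:
        if not g_users[g]:
            raise ValidationError(f"group {g!r} has no users with park photos")
    for _ in range(reps):
        for g in groups:
            counts = np.zeros(len(categories))
            for u in g_users[g]:
                cats = user_cats[u]
                pick = cats[rng.integers(len(cats))]
                counts[cat_index[pick]] += 1
            freq_sum[g] += counts / counts.sum()
    mean_freq = pd.DataFrame(
        {g: freq_sum[g] / reps for g in groups}, index=categories).T
    return FrequencyTable(groups, list(categories), mean_freq, reps, seed)


def group_test(x1: int, n1: int, x2: int, n2: int,
               category=None) -> ProportionTestResult:
    """Pooled two-proportion z test with chi-square and effect size d."""
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValidationError("successes must lie in [0, n]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if denom == 0:
        z = 0.0
    else:
        z = (p1 - p2) / np.sqrt(denom)
    p = float(2 * norm.sf(abs(z)))
    chi2 = z * z
    r = float(np.sqrt(chi2 / (n1 + n2)))
    d = 2 * r / np.sqrt(1 - r * r) if r < 1 else np.inf
    return ProportionTestResult(category, float(z), p, float(chi2), r,
                                float(d), int(n1), int(n2))


def frequency_tests(photos: pd.DataFrame, users: pd.DataFrame,
                    reps: int = 50, seed: int = 0,
                    groups: list | None = None) -> pd.DataFrame:
    """Per-category two-group tests on mean resampled counts.

    Uses the rounded mean one-photo-per-user counts per group as the
    2x2 table entries (each user contributes one 'trial' per sample).
    Returns a frame with z, chi2, p, r, d per category.
    """
    table = resample_frequencies(photos, users, reps=reps, seed=seed,
                                 groups=groups)
    if len(table.groups) != 2:
        raise ValidationError("frequency_tests compares exactly 2 groups")
    g1, g2 = table.groups
    merged, _ = _user_groups(photos, users, groups=table.groups)
    n = merged.drop_duplicates("user_id").groupby("status").size()
    n1, n2 = int(n[g1]), int(n[g2])
    rows = []
    for cat in table.categories:
        x1 = int(round(table.mean_freq.loc[g1, cat] * n1))
        x2 = int(round(table.mean_freq.loc[g2, cat] * n2))
        t = group_test(x1, n1, x2, n2, category=cat)
        rows.append({"category": cat, "z": t.z, "chi2": t.chi2, "p": t.p,
                     "r": t.r, "d": t.d, "n1": t.n1, "n2": t.n2})
    return pd.DataFrame(rows)


def sensitivity(photos: pd.DataFrame, users: pd.DataFrame,
                reps_grid: list[int], seed: int = 0,
                meta_replicates: int = 20,
                groups: list | None = None) -> pd.DataFrame:
    """Stability of the mean-frequency estimate vs repetition count.

    For each value in ``reps_grid`` the mean-frequency table is
    recomputed ``meta_replicates`` times with independent sub-seeds; the
    reported dispersion is the SD across those tables, averaged over
    group x category cells.  In expectation it decreases with reps.
    """
    if not reps_grid:
        raise ValidationError("reps_grid must be non-empty")
    rows = []
    for gi, reps in enumerate(reps_grid):
        tables = []
        for m in range(meta_replicates):
            t = resample_frequencies(photos, users, reps=reps,
                                     seed=seed + 10_000 * gi + m,
                                     groups=groups)
            tables.append(t.mean_freq.to_numpy())
        stack = np.stack(tables)
        rows.append({"reps": reps,
                     "sd": float(stack.std(axis=0, ddof=1).mean())})
    return pd.DataFrame(rows)
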