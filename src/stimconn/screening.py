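"""Discriminative-fibre screening, rank correlations and R-maps.

The whole-brain screen treats every fibre of the connectome as a
two-group contrast: subjects whose stimulation volume touches the fibre
("connected") versus those whose volume does not. A two-sample t-test on
the behavioural change score yields a signed t-score per fibre —
positive when connected subjects show a larger change — and the 20% of
scored fibres with the highest discriminative power (|t|) are retained.

No multiple-comparison correction is applied anywhere in this module:
the screen is descriptive/exploratory and p-values are reported
uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import ceil, factorial

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "mass_t",
    "retain_top",
    "spearman",
    "roi_correlations",
    "rmap",
    "StatResult",
    "RMap",
    "DegenerateInputError",
    "DEFAULT_RETAIN_FRACTION",
    "DEFAULT_MIN_GROUP",
    "ALPHA",
]

DEFAULT_RETAIN_FRACTION = 0.20
DEFAULT_MIN_GROUP = 2
ALPHA = 0.05  # significance level used throughout (uncorrected)

# Below this n the Spearman p-value is computed by exhaustive permutation.
EXACT_PERMUTATION_N = 10


class DegenerateInputError(ValueError):
    """Zero-variance input: the requested statistic is undefined."""


def _membership_matrix(
    subjects: list, connected_sets: dict, fiber_ids: np.ndarray
) -> np.ndarray:
    """Bool matrix (n_subjects, n_fibers): does subject s touch fibre f?"""
    m = np.zeros((len(subjects), len(fiber_ids)), dtype=bool)
    col = {int(f): j for j, f in enumerate(fiber_ids)}
    for i, s in enumerate(subjects):
        for f in connected_sets.get(s, ()):
            j = col.get(int(f))
            if j is not None:
                m[i, j] = True
    return m


def mass_t(
    change_scores: pd.Series,
    connected_sets: dict,
    fiber_ids,
    min_group: int = DEFAULT_MIN_GROUP,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-fibre two-sample t of change scores, connected − unconnected.

    Parameters
    ----------
    change_scores : Series indexed by subject id.
    connected_sets : subject id -> iterable of fibre ids touched.
    fiber_ids : universe of fibre ids to score.
    min_group : a fibre is scored only if both groups hold at least this
        many subjects; others are excluded (not set to zero).
    welch : use Welch's unequal-variance t instead of the pooled-variance
        Student t (the default used by connectome fibre screens).

    Returns a FiberProfile DataFrame indexed by fiber_id with columns
    t, n_connected, n_unconnected, retained (all False; see
    :func:`retain_top`).
    """
    subjects = list(change_scores.index)
    y = change_scores.to_numpy(dtype=float)
    fiber_ids = np.asarray(list(fiber_ids), dtype=int)
    m = _membership_matrix(subjects, connected_sets, fiber_ids)

    n1 = m.sum(axis=0).astype(float)  # connected
    n0 = (~m).sum(axis=0).astype(float)
    sum1 = m.T @ y
    sum0 = y.sum() - sum1
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = sum1 / n1
        mean0 = sum0 / n0
        sq1 = m.T @ (y * y)
        sq0 = (y * y).sum() - sq1
        ss1 = sq1 - n1 * mean1**2
        ss0 = sq0 - n0 * mean0**2
        if welch:
            v1 = ss1 / (n1 - 1) / n1
            v0 = ss0 / (n0 - 1) / n0
            se = np.sqrt(v1 + v0)
        else:
            pooled = (ss1 + ss0) / (n1 + n0 - 2)
            se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n0))
        t = (mean1 - mean0) / se
    # Zero pooled variance: identical group values carry no discrimination
    # (t = 0); separated constant groups are infinitely discriminative.
    with np.errstate(invalid="ignore"):
        t = np.where(
            se == 0, np.where(mean1 == mean0, 0.0, np.sign(mean1 - mean0) * np.inf), t
        )

    scorable = (n1 >= min_group) & (n0 >= min_group)
    profile = pd.DataFrame(
        {
            "t": t[scorable],
            "n_connected": n1[scorable].astype(int),
            "n_unconnected": n0[scorable].astype(int),
            "retained": False,
        },
        index=pd.Index(fiber_ids[scorable], name="fiber_id"),
    )
    return profile


def retain_top(
    profile: pd.DataFrame,
    fraction: float = DEFAULT_RETAIN_FRACTION,
    by_abs: bool = True,
) -> pd.DataFrame:
    """Flag the ceil(fraction x scored) most discriminative fibres.

    Ranking is by |t| descending (signs are preserved in the output);
    ties are broken by fibre id ascending. ``by_abs=False`` ranks by the
    signed t instead (sensitivity variant).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    profile = profile.copy()
    profile["retained"] = False
    n = len(profile)
    if n == 0:
        return profile
    k = ceil(fraction * n)
    key = profile["t"].abs() if by_abs else profile["t"]
    order = sorted(profile.index, key=lambda f: (-key.loc[f], f))
    profile.loc[order[:k], "retained"] = True
    return profile


@dataclass(frozen=True)
class StatResult:
    rho: float
    p: float
    n: int


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x, y) -> StatResult:
    """Spearman rank correlation with two-sided p.

    Ties receive average ranks. For n < 10 the p-value is exact
    (exhaustive permutation of one rank vector); for larger n the usual
    t-approximation on the rank correlation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance: Spearman rho undefined")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n < EXACT_PERMUTATION_N:
        # Exhaustive two-sided permutation p over all n! orderings.
        perms = np.array(list(permutations(range(n))))
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        stats_all = (ry_c[perms] @ rx_c) / denom
        p = float((np.abs(stats_all) >= abs(rho) - 1e-12).sum() / factorial(n))
    else:
        if abs(rho) >= 1.0:
            p = 2.0 / factorial(n) if n < 20 else np.finfo(float).tiny
        else:
            tstat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
    return StatResult(rho=rho, p=min(max(p, np.finfo(float).tiny), 1.0), n=n)


def roi_correlations(
    change_table: pd.DataFrame, roi_counts: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of each change score with each ROI fibre count.

    ``change_table``: subjects x outcomes; ``roi_counts``: subjects x ROIs.
    Returns a tidy table (roi, outcome, rho, p, n, defined); cells with a
    constant count or outcome are flagged undefined rather than dropped.
    No multiple-testing correction is applied.
    """
    subjects = change_table.index.intersection(roi_counts.index)
    if len(subjects) < 3:
        raise ValueError("need >= 3 subjects with both outcomes and counts")
    rows = []
    for roi in roi_counts.columns:
        for outcome in change_table.columns:
            x = roi_counts.loc[subjects, roi].to_numpy(dtype=float)
            y = change_table.loc[subjects, outcome].to_numpy(dtype=float)
            try:
                res = spearman(x, y)
                rows.append(
                    {"roi": roi, "outcome": outcome, "rho": res.rho, "p": res.p,
                     "n": res.n, "defined": True}
                )
            except DegenerateInputError:
                rows.append(
                    {"roi": roi, "outcome": outcome, "rho": np.nan, "p": np.nan,
                     "n": len(subjects), "defined": False}
                )
    return pd.DataFrame(rows)


@dataclass
class RMap:
    """Voxel-wise Spearman coefficients; NaN marks undefined voxels."""

    data: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.data)


def rmap(change_scores: pd.Series, density_volumes: np.ndarray) -> RMap:
    """Voxel-wise Spearman correlation of fibre density with change score.

    ``density_volumes``: array (n_subjects, *shape) of per-subject
    VAT-seeded fibre-density volumes aligned to ``change_scores``'s
    order. Voxels where the density does not vary across subjects are
    undefined (NaN). Positive rho marks voxels where stronger VAT
    connectivity accompanies a larger behavioural change.
    """
    dens = np.asarray(density_volumes, dtype=float)
    y = change_scores.to_numpy(dtype=float)
    n = len(y)
    if dens.shape[0] != n:
        raise ValueError("density_volumes first axis must index subjects")
    if n < 3:
        raise ValueError("rmap needs >= 3 subjects")
    shape = dens.shape[1:]
    flat = dens.reshape(n, -1)
    ranks = stats.rankdata(flat, axis=0, method="average")
    ry = _rank(y)
    ry_c = ry - ry.mean()
    r_c = ranks - ranks.mean(axis=0)
    denom = np.sqrt((r_c**2).sum(axis=0) * (ry_c**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ry_c @ r_c) / denom
    rho[denom == 0] = np.nan
    if np.ptp(ry) == 0:
        rho[:] = np.nan
    return RMap(data=rho.reshape(shape))
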