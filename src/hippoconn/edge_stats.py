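"""Per-edge inference across participants.

An "edge" is one (hippocampal seed, target ROI) pair; its datum is the
per-participant Fisher-z connectivity value.  The binary design compares
SMD+ vs SMD- with a two-tailed two-sample t-test per edge; the continuous
design correlates edge strength with a severity score (CCI) per edge, with
an optional first-order partial correlation controlling a covariate.
Directional significance counts per seed feed the permutation procedures.
No edge-level multiple-testing correction is applied — correction happens
at the network level downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import SEEDS, TargetAtlas
from .connectivity import FcMatrix, stack_fc
from .simulate import GROUP_MINUS, GROUP_PLUS

WEAKER = "weaker_in_plus"
STRONGER = "stronger_in_plus"
NEGATIVE = "negative"
POSITIVE = "positive"


@dataclass(frozen=True)
class EdgeResultSet:
    """Per-edge statistics for all 4 x N edges of one design.

    ``table`` columns: seed, roi_id, statistic, p, direction, degenerate.
    Degenerate edges (zero variance) carry NaN statistics and are excluded
    from all counts.
    """

    design: str  # "binary" | "continuous"
    table: pd.DataFrame
    n_participants: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        n_seeds = self.table["seed"].nunique()
        if n_seeds != len(SEEDS):
            raise ValueError(f"expected {len(SEEDS)} seeds, found {n_seeds}")
        ok = self.table["degenerate"].to_numpy()
        p = self.table["p"].to_numpy()
        if np.any((p[~ok] < 0) | (p[~ok] > 1)):
            raise ValueError("p-values outside [0, 1]")

    @property
    def n_targets(self) -> int:
        return self.table["roi_id"].nunique()

    def attach_networks(self, atlas: TargetAtlas) -> pd.DataFrame:
        net = dict(zip(atlas.roi_ids, atlas.network_labels))
        out = self.table.copy()
        out.insert(2, "network", out["roi_id"].map(net))
        return out


def group_indicator(groups) -> np.ndarray:
    """Boolean SMD+ indicator from a group-label vector."""
    g = np.asarray(groups)
    bad = set(g) - {GROUP_PLUS, GROUP_MINUS}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return g == GROUP_PLUS


def group_tstats(z: np.ndarray, is_plus: np.ndarray, welch: bool = False):
    """Vectorised two-sample t statistics over the trailing edge axes.

    ``z`` has shape (n_participants, ...); returns (t, df, diff) where
    ``diff = mean(SMD+) - mean(SMD-)`` so negative t means weaker in SMD+.
    Zero-pooled-variance edges yield NaN.
    """
    z1 = z[is_plus]
    z0 = z[~is_plus]
    n1, n0 = len(z1), len(z0)
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs at least 2 participants")
    m1, m0 = z1.mean(0), z0.mean(0)
    v1 = z1.var(0, ddof=1)
    v0 = z0.var(0, ddof=1)
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = v1 / n1 + v0 / n0
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        else:
            sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
            se2 = sp2 * (1 / n1 + 1 / n0)
            df = np.full_like(se2, float(n1 + n0 - 2))
        t = diff / np.sqrt(se2)
    t = np.where(se2 > 0, t, np.nan)
    return t, df, diff


def corr_stats(z: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Vectorised Pearson r of each edge (trailing axes) with ``scores``."""
    s = np.asarray(scores, dtype=float)
    if np.std(s) == 0:
        raise ValueError("scores are constant: correlation undefined")
    zc = z - z.mean(0)
    sc = (s - s.mean()) / s.std(ddof=0)
    sd = z.std(0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.tensordot(sc, zc, axes=(0, 0)) / (len(s) * sd)
    return np.where(sd > 0, r, np.nan)


def _build_table(stat, p, direction, roi_ids) -> pd.DataFrame:
    n_targets = len(roi_ids)
    return pd.DataFrame({
        "seed": np.repeat(SEEDS, n_targets),
        "roi_id": np.tile(roi_ids, len(SEEDS)),
        "statistic": stat.ravel(),
        "p": p.ravel(),
        "direction": direction.ravel(),
        "degenerate": ~np.isfinite(stat.ravel()),
    })


def edge_group_ttests(
    fcs: list[FcMatrix], groups, alpha: float = 0.05, welch: bool = False
) -> EdgeResultSet:
    """Two-tailed two-sample t-test at every edge (pooled variance default).

    Direction records the sign of ``mean z(SMD+) - mean z(SMD-)``: weaker
    in SMD+ means the difference is negative, regardless of the sign of z
    itself.
    """
    z, _ = stack_fc(fcs)
    is_plus = group_indicator(groups)
    if len(is_plus) != len(z):
        raise ValueError("groups length does not match number of matrices")
    t, df, diff = group_tstats(z, is_plus, welch=welch)
    with np.errstate(invalid="ignore"):
        p = 2 * stats.t.sf(np.abs(t), df)
    direction = np.where(diff < 0, WEAKER, STRONGER)
    roi_ids = fcs[0].z.columns.to_numpy()
    return EdgeResultSet("binary", _build_table(t, p, direction, roi_ids),
                         n_participants=len(z), alpha=alpha)


def edge_score_correlations(
    fcs: list[FcMatrix], scores, alpha: float = 0.05
) -> EdgeResultSet:
    """Two-tailed Pearson correlation of every edge with a score (no
    predicted direction); direction records the sign of r."""
    z, _ = stack_fc(fcs)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(z):
        raise ValueError("scores length does not match number of matrices")
    if len(s) < 4:
        raise ValueError("need at least 4 participants")
    r = corr_stats(z, s)
    n = len(s)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1, 0.0, p)
    direction = np.where(r < 0, NEGATIVE, POSITIVE)
    roi_ids = fcs[0].z.columns.to_numpy()
    return EdgeResultSet("continuous", _build_table(r, p, direction, roi_ids),
                         n_participants=n, alpha=alpha)


def partial_corr(x: np.ndarray, y: np.ndarray, covar: np.ndarray) -> float:
    """First-order partial correlation of x and y controlling covar.

    Closed form ``(r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))``.
    """
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, covar)[0, 1]
    r_yz = np.corrcoef(y, covar)[0, 1]
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        raise ValueError("covariate perfectly collinear with an input")
    return float((r_xy - r_xz * r_yz) / denom)


def edge_partial_correlations(
    fcs: list[FcMatrix], scores, covariate, alpha: float = 0.05
) -> EdgeResultSet:
    """Per-edge partial correlation with a score, controlling one covariate.

    Two-tailed p with df = n - 3.  Used for the sensitivity re-runs that
    control depression score (GDS) or right hippocampal volume.
    """
    z, _ = stack_fc(fcs)
    s = np.asarray(scores, dtype=float)
    c = np.asarray(covariate, dtype=float)
    n = len(s)
    if n < 5:
        raise ValueError("need at least 5 participants for a partial correlation")
    if np.std(c) == 0:
        raise ValueError("covariate is constant")
    r_sc = np.corrcoef(s, c)[0, 1]
    if abs(r_sc) >= 1 - 1e-12:
        raise ValueError("covariate collinear with scores (|r| = 1)")
    r_zs = corr_stats(z, s)
    r_zc = corr_stats(z, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        rp = (r_zs - r_zc * r_sc) / np.sqrt((1 - r_zc**2) * (1 - r_sc**2))
        rp = np.clip(rp, -1.0, 1.0)
        df = n - 3
        t = rp * np.sqrt(df / (1 - rp**2))
        p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(rp) >= 1, 0.0, p)
    direction = np.where(rp < 0, NEGATIVE, POSITIVE)
    roi_ids = fcs[0].z.columns.to_numpy()
    return EdgeResultSet("continuous", _build_table(rp, p, direction, roi_ids),
                         n_participants=n, alpha=alpha)


def count_significant(
    edges: EdgeResultSet, alpha: float | None = None,
    direction_filter: str | None = WEAKER,
) -> dict[str, int]:
    """Per-seed count of edges with p < alpha matching the direction filter.

    Strict inequality; degenerate edges never count.  ``direction_filter``
    of None counts both directions.
    """
    a = edges.alpha if alpha is None else alpha
    t = edges.table
    mask = (t["p"] < a) & ~t["degenerate"]
    if direction_filter is not None:
        mask &= t["direction"] == direction_filter
    counts = t.loc[mask, "seed"].value_counts()
    return {s: int(counts.get(s, 0)) for s in SEEDS}
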