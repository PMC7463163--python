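"""Permutation inference for patterns of differential connectivity.

Two procedures assess whether differential edges cluster more than chance
would allow, given the 4 x 264 edge battery:

* **Seed-wise difference-score test.**  The statistic is
  ``count(focal seed) - sum(counts of the other three seeds)``, where each
  count is the number of edges significant at ``alpha_edge`` in the
  direction of interest (weaker in SMD+, or inversely score-correlated).
  Group labels (binary design) or severity scores (continuous design) are
  permuted across participants; the full per-edge test battery is
  recomputed for every permutation — not merely the significance flags
  reshuffled — and the score re-derived, giving a one-sided p-value for
  "greater than chance".

* **Network contingency test.**  For the focal seed, directional
  significant-edge counts are tallied per resting-state network; each
  network's count gets a one-sided permutation p from the same full
  recomputation null, and the 13 network tests are corrected with
  Benjamini-Hochberg FDR.

The Monte-Carlo p convention is ``(1 + #{null >= observed}) / (B + 1)``:
one-sided, never zero, with the identity permutation entering via the +1.
Permutations preserve group sizes (binary) and the score multiset
(continuous) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import NETWORKS, SEEDS, TargetAtlas
from .connectivity import FcMatrix, stack_fc
from .edge_stats import NEGATIVE, WEAKER, group_indicator
from .volumetrics import bh_fdr


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation procedures.

    ``fdr_family`` controls which networks enter the FDR correction of the
    contingency test: ``"all"`` (all 13, including zero-count networks) or
    ``"nonzero"`` (only networks with a nonzero observed count).
    """

    n_permutations: int = 10_000
    alpha_edge: float = 0.05
    rng_seed: int = 0
    fdr_family: str = "all"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0 < self.alpha_edge < 1):
            raise ValueError("alpha_edge must lie in (0, 1)")
        if self.fdr_family not in ("all", "nonzero"):
            raise ValueError("fdr_family must be 'all' or 'nonzero'")


@dataclass(frozen=True)
class DifferenceScoreResult:
    """Outcome of the seed-wise difference-score permutation test."""

    design: str
    focal_seed: str
    observed_counts: dict[str, int]
    observed_score: int
    null_scores: np.ndarray
    p: float
    config: PermutationConfig

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "focal_seed": self.focal_seed,
            "observed_counts": self.observed_counts,
            "observed_score": self.observed_score,
            "n_permutations": self.config.n_permutations,
            "alpha_edge": self.config.alpha_edge,
            "rng_seed": self.config.rng_seed,
            "p": self.p,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass(frozen=True)
class NetworkContingencyResult:
    """Per-network differential-edge counts with permutation p and FDR."""

    design: str
    focal_seed: str
    table: pd.DataFrame  # network, observed_count, p, p_fdr, significant, absent
    config: PermutationConfig

    @property
    def significant_networks(self) -> list[str]:
        return self.table.loc[self.table["significant"], "network"].tolist()

    @property
    def total_count(self) -> int:
        return int(self.table["observed_count"].sum())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def difference_score(counts: dict[str, int], focal_seed: str) -> int:
    """``counts[focal] - sum(counts of the other three seeds)``."""
    missing = [s for s in SEEDS if s not in counts]
    if missing:
        raise ValueError(f"missing seed counts: {missing}")
    if focal_seed not in SEEDS:
        raise ValueError(f"unknown focal seed: {focal_seed}")
    return int(counts[focal_seed]
               - sum(counts[s] for s in SEEDS if s != focal_seed))


def _binary_sig(z2, labels_bool, t_crit, n1, n0):
    """Directional significance (weaker in the '+' relabelling) for a batch
    of label vectors.  ``z2`` is (n, E); ``labels_bool`` is (B, n) boolean;
    returns (B, E) boolean."""
    lb = labels_bool.astype(float)
    s1 = lb @ z2
    s0 = z2.sum(0) - s1
    q1 = lb @ (z2**2)
    q0 = (z2**2).sum(0) - q1
    m1, m0 = s1 / n1, s0 / n0
    v1 = (q1 - n1 * m1**2) / (n1 - 1)
    v0 = (q0 - n0 * m0**2) / (n0 - 1)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(sp2 * (1 / n1 + 1 / n0))
    return (t < -t_crit) & np.isfinite(t)


def _continuous_sig(z2, scores_mat, r_crit):
    """Directional significance (negative correlation) for a batch of score
    vectors.  ``scores_mat`` is (B, n); returns (B, E) boolean."""
    n = z2.shape[0]
    zc = z2 - z2.mean(0)
    zsd = z2.std(0, ddof=0)
    sc = scores_mat - scores_mat.mean(1, keepdims=True)
    sc = sc / sc.std(1, ddof=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (sc @ zc) / (n * zsd)
    return (r < -r_crit) & np.isfinite(r)


def _edge_thresholds(design: str, n: int, alpha: float) -> float:
    """Critical |t| (binary) or |r| (continuous) for two-tailed p < alpha."""
    if design == "binary":
        return stats.t.isf(alpha / 2, n - 2)
    t_crit = stats.t.isf(alpha / 2, n - 2)
    return t_crit / np.sqrt(n - 2 + t_crit**2)


def _permutation_counts(
    z: np.ndarray,
    design: str,
    labels_or_scores: np.ndarray,
    config: PermutationConfig,
    net_onehot: np.ndarray | None = None,
    focal_idx: int | None = None,
    chunk: int = 512,
):
    """Observed and null directional significant-edge counts.

    Returns ``(observed_seed_counts (4,), null_seed_counts (B, 4),
    observed_net_counts (K,) | None, null_net_counts (B, K) | None)``.
    The per-edge battery is fully recomputed for every permutation.
    """
    n, n_seeds, n_targets = z.shape
    z2 = z.reshape(n, n_seeds * n_targets)
    B = config.n_permutations
    rng = np.random.default_rng(config.rng_seed)

    if design == "binary":
        is_plus = group_indicator(labels_or_scores)
        n1 = int(is_plus.sum())
        n0 = n - n1
        if n1 < 2 or n0 < 2:
            raise ValueError("each group needs at least 2 participants")
        t_crit = _edge_thresholds("binary", n, config.alpha_edge)
        sig_obs = _binary_sig(z2, is_plus[None, :], t_crit, n1, n0)[0]
    elif design == "continuous":
        scores = np.asarray(labels_or_scores, dtype=float)
        if np.std(scores) == 0:
            raise ValueError("scores are constant")
        r_crit = _edge_thresholds("continuous", n, config.alpha_edge)
        sig_obs = _continuous_sig(z2, scores[None, :], r_crit)[0]
    else:
        raise ValueError(f"unknown design: {design}")

    def tally(sig):  # (B, E) -> per-seed and per-network counts
        per_edge = sig.reshape(-1, n_seeds, n_targets)
        seed_counts = per_edge.sum(axis=2)
        net_counts = None
        if net_onehot is not None:
            net_counts = per_edge[:, focal_idx, :].astype(float) @ net_onehot
        return seed_counts, net_counts

    obs_seed, obs_net = tally(sig_obs[None, :])
    null_seed = np.empty((B, n_seeds), dtype=np.int64)
    null_net = (np.empty((B, net_onehot.shape[1]))
                if net_onehot is not None else None)
    for start in range(0, B, chunk):
        b = min(chunk, B - start)
        # each row an independent shuffle across participants
        idx = np.argsort(rng.random((b, n)), axis=1)
        if design == "binary":
            sig = _binary_sig(z2, is_plus[idx], t_crit, n1, n0)
        else:
            sig = _continuous_sig(z2, scores[idx], r_crit)
        sc, nc = tally(sig)
        null_seed[start:start + b] = sc
        if null_net is not None:
            null_net[start:start + b] = nc
    return (obs_seed[0], null_seed,
            None if obs_net is None else obs_net[0],
            null_net)


def _mc_pvalue(null: np.ndarray, observed: float) -> float:
    return float((1 + np.sum(null >= observed)) / (len(null) + 1))


def perm_test_difference_score(
    fcs: list[FcMatrix],
    labels_or_scores,
    design: str,
    focal_seed: str,
    config: PermutationConfig = PermutationConfig(),
) -> DifferenceScoreResult:
    """Permutation test of the seed-wise difference score.

    Shuffles group labels (binary) or scores (continuous) across
    participants, recomputes every per-edge test and the directional counts
    at ``alpha_edge``, and compares the observed difference score with the
    null distribution; one-sided p for "greater than chance".
    """
    if focal_seed not in SEEDS:
        raise ValueError(f"unknown focal seed: {focal_seed}")
    z, _ = stack_fc(fcs)
    obs_seed, null_seed, _, _ = _permutation_counts(
        z, design, np.asarray(labels_or_scores), config)
    focal_idx = SEEDS.index(focal_seed)
    others = [i for i in range(len(SEEDS)) if i != focal_idx]
    observed_counts = {s: int(c) for s, c in zip(SEEDS, obs_seed)}
    observed = int(obs_seed[focal_idx] - obs_seed[others].sum())
    null_scores = null_seed[:, focal_idx] - null_seed[:, others].sum(axis=1)
    return DifferenceScoreResult(
        design=design,
        focal_seed=focal_seed,
        observed_counts=observed_counts,
        observed_score=observed,
        null_scores=null_scores,
        p=_mc_pvalue(null_scores, observed),
        config=config,
    )


def network_contingency(
    fcs: list[FcMatrix],
    labels_or_scores,
    design: str,
    focal_seed: str,
    atlas: TargetAtlas,
    config: PermutationConfig = PermutationConfig(),
) -> NetworkContingencyResult:
    """Per-network contingency permutation test for the focal seed.

    For each of the 13 networks, tests whether the number of directional
    significant edges between the focal seed and that network exceeds
    chance, with the same full-recomputation null as the difference-score
    test; Benjamini-Hochberg FDR across the network family.
    """
    if focal_seed not in SEEDS:
        raise ValueError(f"unknown focal seed: {focal_seed}")
    z, _ = stack_fc(fcs)
    if z.shape[2] != atlas.n_targets:
        raise ValueError("atlas size does not match connectivity matrices")
    net_labels = atlas.network_labels
    onehot = np.column_stack([
        (net_labels == net).astype(float) for net in NETWORKS
    ])
    focal_idx = SEEDS.index(focal_seed)
    _, _, obs_net, null_net = _permutation_counts(
        z, design, np.asarray(labels_or_scores), config,
        net_onehot=onehot, focal_idx=focal_idx)

    absent = onehot.sum(axis=0) == 0
    pvals = np.array([
        1.0 if absent[k] else _mc_pvalue(null_net[:, k], obs_net[k])
        for k in range(len(NETWORKS))
    ])
    counts = obs_net.astype(int)
    if config.fdr_family == "all":
        in_family = np.ones(len(NETWORKS), dtype=bool)
    else:
        in_family = counts > 0
    p_fdr = np.ones(len(NETWORKS))
    if in_family.any():
        p_fdr[in_family] = bh_fdr(pvals[in_family])
    table = pd.DataFrame({
        "network": NETWORKS,
        "observed_count": counts,
        "p": pvals,
        "p_fdr": p_fdr,
        "significant": p_fdr < 0.05,
        "absent": absent,
    })
    return NetworkContingencyResult(design=design, focal_seed=focal_seed,
                                    table=table, config=config)
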