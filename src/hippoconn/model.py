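"""Model/Results interface over the connectivity and volumetric analyses.

Two model classes follow the fit-then-inspect idiom: a model object is
built from data, ``fit()`` runs the estimation and inference, and the
returned Results object carries the estimates, their uncertainties and a
``summary()`` table.  Plotting hangs off the Results objects.

``SeedConnectivityModel`` covers the connectivity arm: per-edge statistics,
per-seed directional counts, the seed-wise difference-score permutation
test and the per-network contingency permutation analysis, for a binary
group design or a continuous severity design.

``VolumeModel`` covers the volumetric arm: age/eTIV adjustment, the
one-tailed group tests with FDR over the subfield family, and the
one-tailed severity correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import SEEDS, TargetAtlas
from .connectivity import FcMatrix, bandpass, fc_matrix, RoiTimeseries
from .edge_stats import (
    NEGATIVE, WEAKER, EdgeResultSet, count_significant,
    edge_group_ttests, edge_partial_correlations, edge_score_correlations,
)
from .permutation import (
    DifferenceScoreResult, NetworkContingencyResult, PermutationConfig,
    network_contingency, perm_test_difference_score,
)
from .volumetrics import adjust_volumes, bh_fdr, ttest_onetailed, volume_cci_correlation


class SeedConnectivityModel:
    """Seed-based connectivity inference for one cohort.

    Parameters
    ----------
    fcs :
        One Fisher-z connectivity matrix per participant.
    atlas :
        Target atlas; its row order must match the matrix columns.
    groups :
        Per-participant SMD+/SMD- labels (binary design).
    scores :
        Per-participant severity scores (continuous design).

    Exactly one of ``groups`` / ``scores`` selects the design.
    """

    def __init__(self, fcs: list[FcMatrix], atlas: TargetAtlas,
                 groups=None, scores=None):
        if (groups is None) == (scores is None):
            raise ValueError("give exactly one of groups= or scores=")
        self.fcs = list(fcs)
        self.atlas = atlas
        self.groups = None if groups is None else np.asarray(groups)
        self.scores = None if scores is None else np.asarray(scores, dtype=float)
        self.design = "binary" if scores is None else "continuous"
        n = len(self.fcs)
        vec = self.groups if self.groups is not None else self.scores
        if len(vec) != n:
            raise ValueError("design vector length does not match matrices")

    @classmethod
    def from_timeseries(cls, timeseries: list[RoiTimeseries], atlas: TargetAtlas,
                        groups=None, scores=None,
                        band: tuple[float, float] = (0.01, 0.1)):
        """Band-pass each participant's signals and build the z matrices."""
        fcs = [fc_matrix(bandpass(ts, *band), atlas) for ts in timeseries]
        return cls(fcs, atlas, groups=groups, scores=scores)

    def fit(self, alpha_edge: float = 0.05, n_permutations: int = 10_000,
            seed: int = 0, focal_seed: str | None = None,
            welch: bool = False, fdr_family: str = "all",
            run_permutations: bool = True) -> "SeedConnectivityResults":
        """Run the per-edge battery and the permutation procedures.

        ``focal_seed=None`` selects the seed with the maximum observed
        directional count, the rule the original analysis applied after
        inspecting the counts.
        """
        if self.design == "binary":
            edges = edge_group_ttests(self.fcs, self.groups,
                                      alpha=alpha_edge, welch=welch)
            direction = WEAKER
            design_vec = self.groups
        else:
            edges = edge_score_correlations(self.fcs, self.scores,
                                            alpha=alpha_edge)
            direction = NEGATIVE
            design_vec = self.scores
        counts = count_significant(edges, alpha_edge, direction)
        if focal_seed is None:
            focal_seed = max(SEEDS, key=lambda s: counts[s])
        cfg = PermutationConfig(n_permutations=n_permutations,
                                alpha_edge=alpha_edge, rng_seed=seed,
                                fdr_family=fdr_family)
        diff_res = net_res = None
        if run_permutations:
            diff_res = perm_test_difference_score(
                self.fcs, design_vec, self.design, focal_seed, cfg)
            net_res = network_contingency(
                self.fcs, design_vec, self.design, focal_seed, self.atlas, cfg)
        return SeedConnectivityResults(
            model=self, edges=edges, direction=direction,
            seed_counts=counts, focal_seed=focal_seed,
            difference_score=diff_res, contingency=net_res, config=cfg,
        )


@dataclass(frozen=True)
class SeedConnectivityResults:
    """Fitted connectivity inference: edge table, counts, permutation tests."""

    model: SeedConnectivityModel
    edges: EdgeResultSet
    direction: str
    seed_counts: dict[str, int]
    focal_seed: str
    difference_score: DifferenceScoreResult | None
    contingency: NetworkContingencyResult | None
    config: PermutationConfig

    @property
    def edge_table(self) -> pd.DataFrame:
        """Per-edge results with network labels attached."""
        t = self.edges.attach_networks(self.model.atlas)
        t["significant"] = ((t["p"] < self.config.alpha_edge)
                            & ~t["degenerate"])
        return t

    def sensitivity_partial(self, covariate) -> EdgeResultSet:
        """Re-run the continuous design partialling out a covariate."""
        if self.model.design != "continuous":
            raise ValueError("partial-correlation sensitivity needs the "
                             "continuous design")
        return edge_partial_correlations(self.model.fcs, self.model.scores,
                                         covariate,
                                         alpha=self.config.alpha_edge)

    def summary(self) -> str:
        lines = [
            "Seed connectivity analysis",
            "=" * 58,
            f"design:            {self.model.design}",
            f"participants:      {self.edges.n_participants}",
            f"targets:           {self.model.atlas.n_targets}",
            f"edge alpha:        {self.config.alpha_edge}"
            f"  (expected false positives/seed: "
            f"{self.config.alpha_edge * self.model.atlas.n_targets:.1f})",
            f"direction counted: {self.direction}",
            "",
            "directional significant edges per seed:",
        ]
        for s in SEEDS:
            marker = "  <- focal" if s == self.focal_seed else ""
            lines.append(f"  {s:<11} {self.seed_counts[s]:>4}{marker}")
        if self.difference_score is not None:
            d = self.difference_score
            lines += [
                "",
                f"difference score ({d.focal_seed} vs rest): "
                f"{d.observed_score}",
                f"permutation p (B={d.config.n_permutations}): {d.p:.4f}",
            ]
        if self.contingency is not None:
            lines += ["", "network contingency (focal seed):",
                      self.contingency.table.to_string(index=False)]
        return "\n".join(lines)

    def plot_null_distribution(self, ax=None):
        """Histogram of the permutation null with the observed score marked."""
        if self.difference_score is None:
            raise ValueError("permutations were not run")
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        d = self.difference_score
        ax.hist(d.null_scores, bins=40, color="steelblue", alpha=0.8)
        ax.axvline(d.observed_score, color="crimson",
                   label=f"observed = {d.observed_score} (p = {d.p:.4f})")
        ax.set_xlabel("difference score under permuted labels/scores")
        ax.set_ylabel("permutations")
        ax.legend()
        return ax

    def plot_network_counts(self, ax=None):
        """Observed per-network counts for the focal seed."""
        if self.contingency is None:
            raise ValueError("permutations were not run")
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        t = self.contingency.table
        colors = ["crimson" if s else "gray" for s in t["significant"]]
        ax.bar(t["network"], t["observed_count"], color=colors)
        ax.set_ylabel(f"{self.focal_seed} differential edges")
        ax.tick_params(axis="x", rotation=60)
        return ax


class VolumeModel:
    """Volumetric inference: adjustment, group tests, severity correlations.

    Parameters
    ----------
    volumes :
        Table ``participant_id, age, etiv, <measure columns>``.
    groups, cci :
        Per-participant labels and/or severity scores; either enables the
        corresponding arm of the analysis.
    """

    def __init__(self, volumes: pd.DataFrame, groups=None, cci=None):
        self.volumes = volumes
        self.groups = None if groups is None else np.asarray(groups)
        self.cci = None if cci is None else np.asarray(cci, dtype=float)
        self.measures = [c for c in volumes.columns
                         if c not in ("participant_id", "age", "etiv")]

    def fit(self, welch: bool = False,
            direction: str = "plus_smaller") -> "VolumeResults":
        adjusted = adjust_volumes(self.volumes, self.measures)
        group_tests = cci_tests = None
        if self.groups is not None:
            group_tests = ttest_onetailed(adjusted, self.groups, self.measures,
                                          direction=direction, welch=welch)
            group_tests = _with_subfield_fdr(group_tests)
        if self.cci is not None:
            cci_tests = volume_cci_correlation(adjusted, self.cci, self.measures)
            cci_tests = _with_subfield_fdr(cci_tests)
        return VolumeResults(model=self, adjusted=adjusted,
                             group_tests=group_tests, cci_tests=cci_tests)


def _with_subfield_fdr(tests: pd.DataFrame) -> pd.DataFrame:
    """FDR over the subfield family only; whole-hippocampus measures are
    tested on their own at 0.05 (their p_fdr is left NaN)."""
    out = tests.copy()
    subfield = ~out["measure"].str.contains("whole")
    out["p_fdr"] = np.nan
    if subfield.any():
        out.loc[subfield, "p_fdr"] = bh_fdr(out.loc[subfield, "p"].to_numpy())
    out["significant"] = np.where(
        subfield, out["p_fdr"] < 0.05, out["p"] < 0.05)
    return out


@dataclass(frozen=True)
class VolumeResults:
    """Fitted volumetric analysis."""

    model: VolumeModel
    adjusted: pd.DataFrame
    group_tests: pd.DataFrame | None
    cci_tests: pd.DataFrame | None

    def group_means(self) -> pd.DataFrame:
        """Adjusted-volume group means and SDs per measure."""
        if self.model.groups is None:
            raise ValueError("no group labels were given")
        g = pd.Series(self.model.groups, index=self.adjusted.index)
        rows = []
        for m in self.model.measures:
            by = self.adjusted.groupby(g)[m]
            rows.append({
                "measure": m,
                **{f"mean_{k}": v for k, v in by.mean().items()},
                **{f"sd_{k}": v for k, v in by.std().items()},
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Hippocampal volumetrics", "=" * 58,
                 f"participants: {len(self.adjusted)}",
                 f"measures:     {len(self.model.measures)} "
                 "(age- and eTIV-adjusted residuals)"]
        if self.group_tests is not None:
            sig = self.group_tests[self.group_tests["significant"]]
            lines += ["", "one-tailed group tests (SMD+ smaller):",
                      self.group_tests.round(4).to_string(index=False),
                      f"significant measures: {sig['measure'].tolist()}"]
        if self.cci_tests is not None:
            lines += ["", "one-tailed severity correlations (inverse):",
                      self.cci_tests.round(4).to_string(index=False)]
        return "\n".join(lines)
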