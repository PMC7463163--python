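"""End-to-end orchestration of the binary, continuous and exploratory runs.

A run consumes four inputs in plain-text formats — a phenotype CSV, a
directory of per-participant time-series TSVs, a volume CSV and an atlas
TSV — and writes per-stage result files plus a ``report.json`` whose every
p-value is traceable to one of those files.  Simulated and real cohorts are
interchangeable: the synthetic generator writes exactly these formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .atlas import SEEDS, TargetAtlas, load_atlas
from .connectivity import bandpass, fc_matrix, read_timeseries_tsv
from .edge_stats import NEGATIVE, POSITIVE, WEAKER, count_significant, edge_score_correlations
from .model import SeedConnectivityModel, VolumeModel
from .simulate import CCI_MIN, GROUP_MINUS, GROUP_PLUS

log = logging.getLogger("hippoconn")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for one pipeline run."""

    phenotypes: str
    timeseries_dir: str
    volumes: str
    atlas: str
    out_dir: str
    mode: str = "all"  # binary | continuous | gds | all
    alpha_edge: float = 0.05
    n_permutations: int = 10_000
    rng_seed: int = 0
    t_variant: str = "pooled"  # pooled | welch
    smd_threshold: int = 16
    band: tuple[float, float] = (0.01, 0.1)

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "continuous", "gds", "all"):
            raise ValueError(f"invalid mode: {self.mode}")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError(f"invalid t_variant: {self.t_variant}")
        for p in (self.phenotypes, self.volumes, self.atlas):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if not Path(self.timeseries_dir).is_dir():
            raise FileNotFoundError(self.timeseries_dir)


def classify_smd(cci12: int, threshold: int = 16) -> str:
    """SMD+ iff the 12-item memory CCI score is at or above the threshold."""
    if cci12 < CCI_MIN:
        raise ValueError(f"cci12={cci12} below the scale minimum {CCI_MIN}")
    return GROUP_PLUS if cci12 >= threshold else GROUP_MINUS


def _load_inputs(config: RunConfig):
    phen = pd.read_csv(config.phenotypes)
    atlas = load_atlas(config.atlas)
    vols = pd.read_csv(config.volumes)
    ts_dir = Path(config.timeseries_dir)
    timeseries = []
    for pid in phen["participant_id"]:
        path = ts_dir / f"{pid}.tsv"
        if not path.exists():
            raise PipelineError(f"[load] missing time series for {pid}: {path}")
        timeseries.append(read_timeseries_tsv(path, participant_id=pid))
    vols = vols.set_index("participant_id").loc[phen["participant_id"]].reset_index()
    # group labels re-derived from the configured threshold
    phen = phen.copy()
    phen["group"] = [classify_smd(c, config.smd_threshold) for c in phen["cci12"]]
    return phen, timeseries, vols, atlas


def _fit_connectivity(config: RunConfig, timeseries, atlas, *,
                      groups=None, scores=None):
    model = SeedConnectivityModel.from_timeseries(
        timeseries, atlas, groups=groups, scores=scores, band=config.band)
    return model.fit(alpha_edge=config.alpha_edge,
                     n_permutations=config.n_permutations,
                     seed=config.rng_seed,
                     welch=config.t_variant == "welch")


def _demographics_report(phen: pd.DataFrame) -> dict:
    """Simple group comparisons of the phenotype table (screening only)."""
    is_plus = phen["group"] == GROUP_PLUS
    out = {}
    a, b = phen.loc[~is_plus, "age"], phen.loc[is_plus, "age"]
    out["age_ttest_p"] = float(stats.ttest_ind(a, b).pvalue)
    for col in ("education", "cci12", "gds"):
        u = stats.mannwhitneyu(phen.loc[~is_plus, col], phen.loc[is_plus, col])
        out[f"{col}_ranksum_p"] = float(u.pvalue)
    ct = pd.crosstab(phen["group"], phen["sex"])
    if ct.shape == (2, 2):
        out["sex_chi2_p"] = float(stats.chi2_contingency(ct).pvalue)
    return out


def _edge_outputs(results, outdir: Path, prefix: str) -> dict:
    table = results.edge_table
    table.to_csv(outdir / f"{prefix}_edge_tests.csv", index=False)
    block = {
        "seed_counts": results.seed_counts,
        "focal_seed": results.focal_seed,
    }
    if results.difference_score is not None:
        results.difference_score.to_json(outdir / f"{prefix}_difference_score.json")
        block["difference_score"] = results.difference_score.to_dict()
        del block["difference_score"]["design"]
    if results.contingency is not None:
        results.contingency.to_csv(outdir / f"{prefix}_network_contingency.csv")
        block["significant_networks"] = results.contingency.significant_networks
        block["network_p_fdr"] = dict(zip(
            results.contingency.table["network"],
            results.contingency.table["p_fdr"].round(6)))
    return block


def run_binary_analysis(config: RunConfig) -> dict:
    """Group analysis: volume tests, edge t-tests, both permutation tests."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    phen, timeseries, vols, atlas = _load_inputs(config)
    log.info("binary analysis: %d participants (%d SMD+), %d targets",
             len(phen), int((phen["group"] == GROUP_PLUS).sum()), atlas.n_targets)

    vres = VolumeModel(vols, groups=phen["group"]).fit(
        welch=config.t_variant == "welch")
    vres.adjusted.to_csv(outdir / "adjusted_volumes.csv", index=False)
    vres.group_tests.to_csv(outdir / "volume_tests.csv", index=False)

    cres = _fit_connectivity(config, timeseries, atlas, groups=phen["group"])
    report = {
        "mode": "binary",
        "demographics": _demographics_report(phen),
        "volumes": {
            "significant_measures":
                vres.group_tests.loc[vres.group_tests["significant"],
                                     "measure"].tolist(),
        },
        "connectivity": _edge_outputs(cres, outdir, "binary"),
    }
    return report


def run_continuous_analysis(config: RunConfig) -> dict:
    """Severity analysis: CCI correlations at edges and volumes, permutation
    tests, and partial-correlation sensitivity re-runs."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    phen, timeseries, vols, atlas = _load_inputs(config)
    cci = phen["cci12"].to_numpy(dtype=float)
    log.info("continuous analysis: %d participants, CCI range %d-%d",
             len(phen), int(cci.min()), int(cci.max()))

    vres = VolumeModel(vols, cci=cci).fit()
    vres.adjusted.to_csv(outdir / "adjusted_volumes.csv", index=False)
    vres.cci_tests.to_csv(outdir / "volume_cci_tests.csv", index=False)

    cres = _fit_connectivity(config, timeseries, atlas, scores=cci)

    # Sensitivity: which flagged edges survive controlling GDS and right
    # whole-hippocampal volume (raw and adjusted)?
    flagged = cres.edge_table.query("significant and direction == @NEGATIVE")
    sensitivity = {}
    covars = {"gds": phen["gds"].to_numpy(dtype=float)}
    if "right_whole_hippocampus" in vols.columns:
        covars["right_volume_raw"] = vols["right_whole_hippocampus"].to_numpy()
        covars["right_volume_adjusted"] = \
            vres.adjusted["right_whole_hippocampus"].to_numpy()
    for name, cov in covars.items():
        part = cres.sensitivity_partial(cov)
        pt = part.attach_networks(atlas)
        pt["significant"] = (pt["p"] < config.alpha_edge) & ~pt["degenerate"]
        pt.to_csv(outdir / f"continuous_partial_{name}.csv", index=False)
        merged = flagged.merge(pt, on=["seed", "roi_id"], suffixes=("", "_part"))
        surviving = int((merged["significant_part"]
                         & (merged["direction_part"] == NEGATIVE)).sum())
        sensitivity[name] = {"flagged": int(len(flagged)),
                             "surviving": surviving}

    report = {
        "mode": "continuous",
        "volumes": {
            "significant_measures":
                vres.cci_tests.loc[vres.cci_tests["significant"],
                                   "measure"].tolist(),
        },
        "connectivity": _edge_outputs(cres, outdir, "continuous"),
        "sensitivity": sensitivity,
    }
    return report


def run_gds_exploratory(config: RunConfig) -> dict:
    """Exploratory arm: edge correlations with the depression score (GDS),
    positive-direction counts, and the overlap with CCI-flagged edges."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    phen, timeseries, vols, atlas = _load_inputs(config)
    gds = phen["gds"].to_numpy(dtype=float)
    if np.std(gds) == 0:
        raise PipelineError("[gds] covariate 'gds' is constant: "
                            "correlations undefined")
    cci = phen["cci12"].to_numpy(dtype=float)

    model = SeedConnectivityModel.from_timeseries(
        timeseries, atlas, scores=gds, band=config.band)
    gres = model.fit(alpha_edge=config.alpha_edge,
                     n_permutations=config.n_permutations,
                     seed=config.rng_seed, run_permutations=False)
    gtable = gres.edge_table
    gtable.to_csv(outdir / "gds_edge_tests.csv", index=False)
    pos_counts = count_significant(gres.edges, config.alpha_edge, POSITIVE)

    # overlap of GDS-significant and CCI-significant (inverse) edge sets
    cci_edges = edge_score_correlations(model.fcs, cci,
                                        alpha=config.alpha_edge)
    ct = cci_edges.table
    cci_sig = ct[(ct["p"] < config.alpha_edge) & ~ct["degenerate"]
                 & (ct["direction"] == NEGATIVE)][["seed", "roi_id"]]
    gds_sig = gtable[gtable["significant"]][["seed", "roi_id"]]
    overlap = gds_sig.merge(cci_sig, on=["seed", "roi_id"])

    report = {
        "mode": "gds",
        "gds_positive_counts": pos_counts,
        "gds_significant_edges": int(len(gds_sig)),
        "cci_significant_inverse_edges": int(len(cci_sig)),
        "overlap_edges": int(len(overlap)),
    }
    return report


def run(config: RunConfig) -> dict:
    """Run the configured mode(s); write ``report.json`` and return it."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        modes = ["binary", "continuous", "gds"] if config.mode == "all" \
            else [config.mode]
        runners = {"binary": run_binary_analysis,
                   "continuous": run_continuous_analysis,
                   "gds": run_gds_exploratory}
        report = {
            "provenance": {
                "version": __version__,
                "rng_seed": config.rng_seed,
                # out_dir excluded so identical runs yield identical reports
                "config": {k: v for k, v in asdict(config).items()
                           if k != "out_dir"},
            },
        }
        for m in modes:
            log.info("stage: %s", m)
            try:
                report[m] = runners[m](config)
            except Exception as exc:  # tag the failing stage
                raise PipelineError(f"[{m}] {exc}") from exc
        (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                       default=str))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
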