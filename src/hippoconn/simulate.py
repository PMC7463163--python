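"""Synthetic cohort generation for the hippocampal connectivity pipeline.

The pipeline was designed around a cohort of cognitively normal older adults
split into subjective-memory-decline groups (SMD+ / SMD-) by a 12-item
memory questionnaire score (CCI, range 12-60, threshold 16).  Real
participant data are not redistributable, so this module generates cohorts
with the statistical structure the downstream analyses consume:

* phenotypes — age, sex, education, intracranial volume (eTIV), CCI and a
  depression score (GDS), with the group label deterministically implied by
  the CCI threshold;
* ROI time series — a latent-factor (block covariance) model: one Gaussian
  factor per resting-state network, targets loading on their network's
  factor, and the four hippocampal seeds coupling to every network factor.
  Seed-network coupling can be attenuated in SMD+ (a group effect) or
  linearly in CCI (a severity effect), which is exactly the alternative the
  edge statistics and permutation tests are built to detect;
* volumes — 26 hippocampal measures with additive age/eTIV/group structure,
  matching what the covariate-adjustment regression assumes.

Under the factor model the population edge correlation is known in closed
form (``coupling * target_loading`` for a target in the coupled network),
which makes every downstream stage testable against an analytic oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import NETWORKS, SEEDS, TargetAtlas, _CANONICAL_SIZES, synthetic_power264_atlas
from .connectivity import RoiTimeseries

GROUP_PLUS = "SMD+"
GROUP_MINUS = "SMD-"

CCI_MIN = 12
CCI_MAX = 60


class ConfigError(ValueError):
    """Raised for infeasible cohort configurations."""


@dataclass(frozen=True)
class Effect:
    """Attenuation of one (seed, network) coupling.

    ``group_delta`` is subtracted from the coupling for SMD+ participants;
    ``cci_slope`` is subtracted per CCI point above the scale minimum.
    """

    group_delta: float = 0.0
    cci_slope: float = 0.0


@dataclass(frozen=True)
class VolumeParams:
    """Generative model for one volumetric measure (mm^3)."""

    intercept: float
    beta_age: float
    beta_etiv: float
    group_delta: float = 0.0
    sd_noise: float = 0.0


def _default_partition() -> dict[str, int]:
    return dict(_CANONICAL_SIZES)


#: Canonical measure names (13 per hemisphere: whole + 12 subfields).
def measure_names() -> list[str]:
    subfields = [
        "whole_hippocampus", "hippocampal_tail", "subiculum", "ca1",
        "hippocampal_fissure", "presubiculum", "parasubiculum",
        "molecular_layer", "gc_ml_dg", "ca3", "ca4", "fimbria", "hata",
    ]
    return [f"{side}_{m}" for side in ("left", "right") for m in subfields]


def default_volume_model(group_delta_whole: float = 0.0) -> dict[str, VolumeParams]:
    """Plausible per-measure generative parameters.

    Intercepts track typical automated-segmentation magnitudes; the age slope
    and eTIV slope scale with the measure's size; residual noise is ~7% of
    the intercept.  ``group_delta_whole`` plants a group effect on the two
    whole-hippocampus measures (subfields get a proportional share).
    """
    base = {
        "whole_hippocampus": 3400.0, "hippocampal_tail": 580.0,
        "subiculum": 420.0, "ca1": 620.0, "hippocampal_fissure": 160.0,
        "presubiculum": 300.0, "parasubiculum": 60.0, "molecular_layer": 550.0,
        "gc_ml_dg": 290.0, "ca3": 200.0, "ca4": 250.0, "fimbria": 90.0,
        "hata": 60.0,
    }
    model: dict[str, VolumeParams] = {}
    for side in ("left", "right"):
        for m, v in base.items():
            model[f"{side}_{m}"] = VolumeParams(
                intercept=v,
                beta_age=-0.004 * v,          # mm^3 per year
                beta_etiv=v / 1.45e6,         # mm^3 per mm^3 eTIV
                group_delta=group_delta_whole * v / base["whole_hippocampus"],
                sd_noise=0.07 * v,
            )
    return model


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the study conditions the pipeline was designed for:
    24 SMD- and 29 SMD+ participants, 264 targets in the canonical
    13-network partition, 190 timepoints at TR = 3 s (a 10-minute resting
    scan with 10 volumes discarded upstream), and a base seed-network
    coupling of 0.25 with target loading 0.7.
    """

    n_minus: int = 24
    n_plus: int = 29
    n_targets: int = 264
    partition_spec: dict[str, int] = field(default_factory=_default_partition)
    n_timepoints: int = 190
    tr_seconds: float = 3.0
    base_coupling: float = 0.25
    target_loading: float = 0.7
    effect_map: dict[tuple[str, str], Effect] = field(default_factory=dict)
    noise_sd: float = 0.0
    volume_model: dict[str, VolumeParams] = field(default_factory=default_volume_model)
    smd_threshold: int = 16
    cci_max: int = 41
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_minus < 0 or self.n_plus < 0 or self.n_minus + self.n_plus == 0:
            raise ConfigError("group sizes must be nonnegative and not both zero")
        if sum(self.partition_spec.values()) != self.n_targets:
            raise ConfigError(
                f"partition sizes sum to {sum(self.partition_spec.values())}, "
                f"expected n_targets={self.n_targets}"
            )
        unknown = set(self.partition_spec) - set(NETWORKS)
        if unknown:
            raise ConfigError(f"unknown networks in partition_spec: {sorted(unknown)}")
        if self.n_timepoints < 20:
            raise ConfigError("n_timepoints must be >= 20")
        if self.tr_seconds <= 0:
            raise ConfigError("tr_seconds must be positive")
        if not (0 <= self.base_coupling < 1):
            raise ConfigError("base_coupling must lie in [0, 1)")
        if not (0 < self.target_loading < 1):
            raise ConfigError("target_loading must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if self.smd_threshold <= CCI_MIN:
            raise ConfigError(
                f"smd_threshold must exceed the CCI scale minimum {CCI_MIN}"
            )
        if not (self.smd_threshold < self.cci_max <= CCI_MAX):
            raise ConfigError(
                f"cci_max must lie in ({self.smd_threshold}, {CCI_MAX}]"
            )
        for (seed, net), eff in self.effect_map.items():
            if seed not in SEEDS:
                raise ConfigError(f"unknown seed in effect_map: {seed}")
            if net not in self.partition_spec:
                raise ConfigError(f"effect_map network {net} not in partition")
            max_att = eff.group_delta + eff.cci_slope * (self.cci_max - CCI_MIN)
            if not (0 <= self.base_coupling - max_att < 1):
                raise ConfigError(
                    f"coupling for {(seed, net)} leaves [0, 1) under maximal "
                    f"attenuation ({self.base_coupling} - {max_att:.3f})"
                )
        # Seed signals are normalised to unit variance, which requires the
        # couplings' sum of squares to stay below 1.
        k = len(self.partition_spec)
        if k * self.base_coupling**2 >= 1:
            raise ConfigError(
                f"base_coupling={self.base_coupling} too large for "
                f"{k} networks (sum of squared couplings must be < 1)"
            )

    @property
    def n_total(self) -> int:
        return self.n_minus + self.n_plus

    def coupling(self, seed: str, network: str, is_plus: bool, cci12: int) -> float:
        """Effective seed-network factor coupling for one participant."""
        c = self.base_coupling
        eff = self.effect_map.get((seed, network))
        if eff is not None:
            c -= eff.group_delta * bool(is_plus)
            c -= eff.cci_slope * (cci12 - CCI_MIN)
        return c

    def expected_edge_r(self, seed: str, network: str, is_plus: bool, cci12: int) -> float:
        """Closed-form population correlation for an edge under the factor model."""
        c = self.coupling(seed, network, is_plus, cci12)
        scale = np.sqrt((1 + self.noise_sd**2))
        return c * self.target_loading / scale**2


def generate_phenotypes(config: CohortConfig) -> pd.DataFrame:
    """Generate the phenotype table.

    Ages, education, eTIV and GDS are drawn independently of group; CCI is
    drawn per group so the classification invariant (SMD+ iff CCI >= the
    threshold) holds by construction: SMD- scores uniform on
    ``[12, threshold-1]``, SMD+ scores shifted-geometric above the threshold
    (right-skewed, clipped at 60).
    """
    ss = np.random.SeedSequence(config.rng_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n = config.n_total
    groups = np.array([GROUP_MINUS] * config.n_minus + [GROUP_PLUS] * config.n_plus)
    thr = config.smd_threshold

    cci = np.empty(n, dtype=int)
    is_plus = groups == GROUP_PLUS
    cci[~is_plus] = rng.integers(CCI_MIN, thr, size=(~is_plus).sum())
    # Shifted geometric with mean offset ~7.4 above threshold mimics the
    # right-skewed severity distribution seen in such cohorts.
    cci[is_plus] = np.minimum(thr + rng.geometric(p=0.135, size=is_plus.sum()) - 1,
                              config.cci_max)
    table = pd.DataFrame({
        "participant_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "age": np.clip(rng.normal(71.9, 8.5, n), 55, 95).round(1),
        "sex": rng.choice(["M", "F"], size=n, p=[0.36, 0.64]),
        "education": np.clip(rng.normal(16.1, 2.3, n), 8, 22).round(0),
        "etiv": rng.normal(1.45e6, 1.4e5, n).round(0),
        "cci12": cci,
        "gds": rng.choice([0, 1, 2, 3, 4], size=n,
                          p=np.array([32, 10, 5, 5, 1]) / 53),
        "group": groups,
    })
    return table


def generate_timeseries(
    config: CohortConfig, phenotypes: pd.DataFrame
) -> list[RoiTimeseries]:
    """Generate one ROI time-series table per participant.

    Latent-factor construction per participant: one standard-normal factor
    per network; a target in network j is
    ``loading * F_j + sqrt(1 - loading^2) * eps`` (unit variance); a seed is
    ``sum_j c_j F_j + sqrt(1 - sum_j c_j^2) * eps`` with couplings c_j
    attenuated per the effect map.  The population seed-target correlation
    is therefore ``c_j * loading`` exactly.  ``noise_sd`` optionally adds
    white measurement noise to every channel afterwards, scaling all
    correlations by ``1 / (1 + noise_sd^2)``.
    """
    ss = np.random.SeedSequence(config.rng_seed)
    ts_children = ss.spawn(3)[2].spawn(len(phenotypes))
    networks = list(config.partition_spec)
    sizes = [config.partition_spec[k] for k in networks]
    loading = config.target_loading
    T = config.n_timepoints

    out: list[RoiTimeseries] = []
    roi_cols = [f"roi_{i + 1}" for i in range(config.n_targets)]
    target_net_idx = np.repeat(np.arange(len(networks)), sizes)
    for row, child in zip(phenotypes.itertuples(index=False), ts_children):
        rng = np.random.default_rng(child)
        factors = rng.standard_normal((T, len(networks)))
        targets = (loading * factors[:, target_net_idx]
                   + np.sqrt(1 - loading**2) * rng.standard_normal((T, config.n_targets)))
        is_plus = row.group == GROUP_PLUS
        seeds = np.empty((T, len(SEEDS)))
        for si, seed in enumerate(SEEDS):
            c = np.array([config.coupling(seed, net, is_plus, row.cci12)
                          for net in networks])
            ssq = float(c @ c)
            if ssq >= 1 or np.any(c < 0) or np.any(c >= 1):
                raise ConfigError(
                    f"couplings for seed {seed}, participant "
                    f"{row.participant_id} leave the feasible region"
                )
            seeds[:, si] = factors @ c + np.sqrt(1 - ssq) * rng.standard_normal(T)
        data = np.hstack([seeds, targets])
        if config.noise_sd > 0:
            data = data + config.noise_sd * rng.standard_normal(data.shape)
        df = pd.DataFrame(data, columns=list(SEEDS) + roi_cols)
        out.append(RoiTimeseries(participant_id=row.participant_id,
                                 tr_seconds=config.tr_seconds, data=df))
    return out


def generate_volumes(config: CohortConfig, phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Generate the 26-measure volume table.

    Each measure is ``intercept + beta_age*age + beta_etiv*etiv +
    group_delta*1[SMD+] + N(0, sd_noise)``.
    """
    for name, p in config.volume_model.items():
        if p.sd_noise < 0:
            raise ConfigError(f"negative sd_noise for measure {name}")
    ss = np.random.SeedSequence(config.rng_seed)
    rng = np.random.default_rng(ss.spawn(2)[1])
    n = len(phenotypes)
    is_plus = (phenotypes["group"] == GROUP_PLUS).to_numpy().astype(float)
    age = phenotypes["age"].to_numpy()
    etiv = phenotypes["etiv"].to_numpy()
    out = pd.DataFrame({
        "participant_id": phenotypes["participant_id"],
        "age": age,
        "etiv": etiv,
    })
    for name, p in config.volume_model.items():
        out[name] = (p.intercept + p.beta_age * age + p.beta_etiv * etiv
                     + p.group_delta * is_plus
                     + (rng.normal(0, p.sd_noise, n) if p.sd_noise > 0 else 0.0))
    return out


def cohort_atlas(config: CohortConfig) -> TargetAtlas:
    """Atlas matching the cohort's partition, in generation order."""
    if config.partition_spec == _CANONICAL_SIZES:
        atlas = synthetic_power264_atlas(seed=config.rng_seed)
        return atlas
    labels = np.concatenate([
        np.repeat(net, size) for net, size in config.partition_spec.items()
    ])
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed))
    table = pd.DataFrame({
        "roi_id": np.arange(1, config.n_targets + 1),
        "x": rng.uniform(-70, 70, config.n_targets).round(1),
        "y": rng.uniform(-105, 70, config.n_targets).round(1),
        "z": rng.uniform(-45, 75, config.n_targets).round(1),
        "network": labels,
    })
    return TargetAtlas(table=table)


def simulate_cohort(config: CohortConfig):
    """Generate phenotypes, time series, volumes and the matching atlas."""
    phen = generate_phenotypes(config)
    ts = generate_timeseries(config, phen)
    vols = generate_volumes(config, phen)
    atlas = cohort_atlas(config)
    return phen, ts, vols, atlas


def write_cohort(config: CohortConfig, outdir: str | Path) -> Path:
    """Write a simulated cohort in the pipeline's input formats.

    Produces ``phenotypes.csv``, ``volumes.csv``, ``atlas.tsv`` and a
    ``timeseries/`` directory with one TSV per participant, so simulated and
    real cohorts are interchangeable inputs.
    """
    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    phen, ts, vols, atlas = simulate_cohort(config)
    phen.to_csv(outdir / "phenotypes.csv", index=False)
    vols.to_csv(outdir / "volumes.csv", index=False)
    atlas.to_tsv(outdir / "atlas.tsv")
    for t in ts:
        t.to_tsv(outdir / "timeseries" / f"{t.participant_id}.tsv")
    return outdir
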