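"""From ROI time series to per-participant seed x target Fisher-z matrices.

Each participant contributes a table of band-limited BOLD signals: four
hippocampal seed channels plus one channel per atlas target.  Connectivity
strength for an edge (seed, target) is the Pearson correlation of the two
filtered channels, variance-stabilised with the Fisher r-to-z transform,
yielding a 4 x N matrix per participant (4 x 264 for the canonical atlas).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .atlas import SEEDS, TargetAtlas

MIN_TIMEPOINTS = 20


class TimeseriesError(ValueError):
    """Raised for schema or invariant violations in an ROI time-series table."""


@dataclass(frozen=True)
class RoiTimeseries:
    """Per-participant time x channel signal table.

    ``data`` columns are the four seed labels followed by ``roi_<id>`` target
    channels; values are arbitrary-unit BOLD signal sampled every
    ``tr_seconds``.
    """

    participant_id: str
    tr_seconds: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise TimeseriesError("tr_seconds must be positive")
        if len(self.data) < MIN_TIMEPOINTS:
            raise TimeseriesError(
                f"need >= {MIN_TIMEPOINTS} timepoints, got {len(self.data)}"
            )
        if self.data.isna().any().any():
            raise TimeseriesError("time series contains missing values")
        variances = self.data.var(axis=0, ddof=1)
        dead = variances[variances == 0].index.tolist()
        if dead:
            raise TimeseriesError(f"constant channels: {dead}")

    @property
    def n_timepoints(self) -> int:
        return len(self.data)

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "t", np.arange(len(out)))
        out.to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(
    path: str | Path, participant_id: str | None = None, tr_seconds: float = 3.0
) -> RoiTimeseries:
    """Read one participant's time-series TSV (first column ``t``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "t" in df.columns:
        df = df.drop(columns="t")
    pid = participant_id if participant_id is not None else path.stem
    return RoiTimeseries(participant_id=pid, tr_seconds=tr_seconds, data=df)


@dataclass(frozen=True)
class FcMatrix:
    """Per-participant Fisher-z connectivity matrix, seeds x targets."""

    participant_id: str
    z: pd.DataFrame  # index: seed labels; columns: roi ids

    def __post_init__(self) -> None:
        if list(self.z.index) != list(SEEDS):
            raise ValueError(f"rows must be the seeds {list(SEEDS)} in order")
        if not np.isfinite(self.z.to_numpy()).all():
            raise ValueError("non-finite connectivity values")

    def to_csv(self, path: str | Path) -> None:
        self.z.to_csv(path, index_label="seed")


def bandpass(ts: RoiTimeseries, low_hz: float = 0.01, high_hz: float = 0.1) -> RoiTimeseries:
    """Zero-phase band-pass filter of every channel.

    A 4th-order Butterworth band-pass applied forward-backward (``filtfilt``),
    so the effective magnitude response is the square of the single-pass
    response and the phase is zero.  Output length equals input length.
    Passband frequencies are retained at >= 0.9 amplitude and frequencies an
    octave beyond the band edges are attenuated to <= 0.1.
    """
    nyq = ts.nyquist_hz
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyq:.4f} Hz "
            f"for TR={ts.tr_seconds}s"
        )
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds,
                        output="sos")
    arr = ts.data.to_numpy(dtype=float)
    # Gustafsson's method avoids the padlen > n constraint on short series.
    filtered = signal.sosfiltfilt(sos, arr, axis=0)
    out = pd.DataFrame(filtered, columns=ts.data.columns)
    return RoiTimeseries(ts.participant_id, ts.tr_seconds, out)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length signals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher r-to-z transform, z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError(
            "|r| >= 1: perfectly collinear channels have no finite z-score"
        )
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def fc_matrix(ts: RoiTimeseries, atlas: TargetAtlas) -> FcMatrix:
    """Build the seed x target Fisher-z connectivity matrix for one participant.

    ``z[s, t] = atanh(corr(seed s, target t))`` over all 4 x N pairs; target
    columns follow the atlas row order.
    """
    cols = list(ts.data.columns)
    missing_seeds = [s for s in SEEDS if s not in cols]
    if missing_seeds:
        raise TimeseriesError(f"missing seed channels: {missing_seeds}")
    target_cols = [f"roi_{i}" for i in atlas.roi_ids]
    missing_targets = [c for c in target_cols if c not in cols]
    if missing_targets:
        raise TimeseriesError(f"missing target channels: {missing_targets[:5]}"
                              + ("..." if len(missing_targets) > 5 else ""))
    seed_arr = ts.data[list(SEEDS)].to_numpy(dtype=float)
    targ_arr = ts.data[target_cols].to_numpy(dtype=float)

    # Correlate all seed/target pairs in one pass.
    s = (seed_arr - seed_arr.mean(0)) / seed_arr.std(0, ddof=0)
    t = (targ_arr - targ_arr.mean(0)) / targ_arr.std(0, ddof=0)
    r = s.T @ t / len(s)
    r = np.clip(r, -1.0, 1.0)  # guard rounding just past +/-1 for exact copies
    if np.any(np.abs(r) >= 1.0):
        bad = np.argwhere(np.abs(r) >= 1.0)[0]
        raise ValueError(
            f"|r| = 1 between seed '{SEEDS[bad[0]]}' and target "
            f"'{target_cols[bad[1]]}': collinear channels"
        )
    z = pd.DataFrame(np.arctanh(r), index=list(SEEDS), columns=atlas.roi_ids)
    return FcMatrix(participant_id=ts.participant_id, z=z)


def stack_fc(fcs: list[FcMatrix]) -> tuple[np.ndarray, list[str]]:
    """Stack matrices into an (n_participants, 4, N) array plus the id order."""
    if not fcs:
        raise ValueError("no connectivity matrices given")
    shapes = {fc.z.shape for fc in fcs}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent matrix shapes: {shapes}")
    arr = np.stack([fc.z.to_numpy() for fc in fcs])
    return arr, [fc.participant_id for fc in fcs]
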