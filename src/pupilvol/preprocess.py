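"""Pupillometry preprocessing: blink removal, nuisance regression,
low-pass filtering with down-sampling, and z-scored averaging.

The pipeline transforms raw 1000 Hz pupil-area traces into the 10 Hz
z-scored series the convolution GLMs are fitted to:

1. blinks (runs of zero samples) are padded by 150 ms on each side and
   linearly interpolated;
2. a linear temporal drift and the pupillary responses to violation,
   likelihood-violation and target events are regressed out;
3. the trace is mean-centred, low-pass filtered below 10 Hz (zero-phase
   Butterworth) and decimated to 10 Hz;
4. each block is z-scored, blocks are averaged within participant over the
   identical stimulus schedule, and participants are averaged for the grand
   mean — an event-related average.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.signal import butter, fftconvolve, filtfilt

from .evidence import gamma_kernel, rasterize_boxcar

logger = logging.getLogger(__name__)

__all__ = [
    "RAW_RATE",
    "ANALYSIS_RATE",
    "PupilTimeSeries",
    "remove_blinks",
    "regress_nuisance",
    "filter_downsample",
    "zscore",
    "zscore_and_average",
    "preprocess_block",
    "preprocess_participants",
    "nuisance_projector",
]

RAW_RATE = 1000.0
ANALYSIS_RATE = 10.0
BLINK_PAD_MS = 150.0


@dataclass
class PupilTimeSeries:
    """A pupil trace with its sampling rate and processing provenance.

    ``samples`` are raw area units up to the z-scoring stage, after which
    they are standard-deviation units.  ``stage`` is one of raw, deblinked,
    denuisanced, filtered, zscored, averaged.
    """

    samples: np.ndarray
    rate: float
    stage: str = "raw"
    block_id: int = 0
    participant_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate

    def to_csv(self, path, metadata_path=None) -> None:
        pd.DataFrame({"time_s": self.time_s, "pupil": self.samples}).to_csv(path, index=False)
        if metadata_path is not None:
            meta = {
                "rate": self.rate,
                "stage": self.stage,
                "block_id": self.block_id,
                "participant_id": self.participant_id,
                "n_samples": len(self.samples),
            }
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @staticmethod
    def from_csv(path, rate: float | None = None, **kwargs) -> "PupilTimeSeries":
        df = pd.read_csv(path)
        if rate is None:
            dt = np.diff(df["time_s"].to_numpy())
            rate = float(round(1.0 / np.median(dt)))
        return PupilTimeSeries(samples=df["pupil"].to_numpy(float), rate=rate, **kwargs)


def _zero_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of exactly-zero samples as half-open (start, stop)."""
    is_zero = np.concatenate(([False], x == 0.0, [False]))
    edges = np.flatnonzero(np.diff(is_zero.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def remove_blinks(ts: PupilTimeSeries, pad_ms: float = BLINK_PAD_MS) -> PupilTimeSeries:
    """Remove blink artifacts (zero samples) by padded linear interpolation.

    Every maximal run of zero samples, extended ``pad_ms`` on both sides, is
    replaced by the straight line between the flanking valid samples;
    overlapping padded runs merge into one span.  Runs touching the edge of
    the series are filled with the nearest valid value.
    """
    x = ts.samples.copy()
    runs = _zero_runs(x)
    if not runs:
        return replace(ts, samples=x, stage="deblinked")
    pad = int(round(pad_ms * ts.rate / 1000.0))
    bad = np.zeros(len(x), dtype=bool)
    for start, stop in runs:
        bad[max(0, start - pad) : min(len(x), stop + pad)] = True
    if bad.all():
        raise ValueError("series contains no valid samples to anchor interpolation")
    good = np.flatnonzero(~bad)
    x[bad] = np.interp(np.flatnonzero(bad), good, x[good])
    return replace(ts, samples=x, stage="deblinked")


def _nuisance_design(ts: PupilTimeSeries, events, kernel: np.ndarray | None) -> pd.DataFrame:
    n = len(ts)
    cols = {"const": np.ones(n), "drift": np.linspace(0.0, 1.0, n)}
    if kernel is None:
        kernel = gamma_kernel(peak_time=8.0, shape=3.0, rate=ts.rate)

    def smoothed(mask: np.ndarray) -> np.ndarray:
        box = rasterize_boxcar(events, ts.rate, mask, n_samples=n)
        return fftconvolve(box, kernel)[:n]

    cols["violation"] = smoothed(events.is_violation)
    if events.is_likelihood_violation.any():
        # Only combination blocks carry likelihood violations.
        cols["likelihood_violation"] = smoothed(events.is_likelihood_violation)
    cols["target"] = smoothed(events.is_target)
    return pd.DataFrame(cols)


def regress_nuisance(
    ts: PupilTimeSeries, events, kernel: np.ndarray | None = None
) -> PupilTimeSeries:
    """Regress out temporal drift and event-locked nuisance responses.

    Ordinary least squares of the trace on a constant, a linear drift, and
    violation / likelihood-violation / target event regressors (250 ms
    boxcars at the flagged digit steps, smoothed by a slow gamma kernel
    standing in for the pupillary response).  Returns the residuals plus the
    fitted constant, so the signal keeps its baseline.  Collinear columns
    are dropped with a logged warning.
    """
    X = _nuisance_design(ts, events, kernel)
    # Drop degenerate/collinear columns (keep the constant).
    keep = ["const"]
    for name in X.columns[1:]:
        trial = X[keep + [name]].to_numpy()
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(name)
        else:
            logger.warning("dropping collinear nuisance regressor %r", name)
    X = X[keep]
    fit = sm.OLS(ts.samples, X).fit()
    cleaned = fit.resid + fit.params["const"]
    return replace(ts, samples=np.asarray(cleaned), stage="denuisanced")


def filter_downsample(
    ts: PupilTimeSeries, cutoff_hz: float = 10.0, out_rate: float = ANALYSIS_RATE, order: int = 4
) -> PupilTimeSeries:
    """Mean-centre, zero-phase low-pass below ``cutoff_hz``, decimate to 10 Hz.

    The filter is a 4th-order Butterworth applied forward-backward; the
    decimation keeps every ``rate / out_rate``-th sample.
    """
    factor = ts.rate / out_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"rate {ts.rate} is not an integer multiple of {out_rate}")
    factor = int(round(factor))
    x = ts.samples - ts.samples.mean()
    b, a = butter(order, cutoff_hz, fs=ts.rate, btype="low")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(x) <= padlen:
        raise ValueError(f"series of {len(x)} samples is shorter than the filter warm-up")
    y = filtfilt(b, a, x)[::factor]
    return replace(ts, samples=y, rate=out_rate, stage="filtered")


def zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def zscore_and_average(
    blocks_by_participant: list[list[PupilTimeSeries]],
) -> tuple[list[PupilTimeSeries], PupilTimeSeries]:
    """Z-score each block, average within participants, then across them.

    All blocks share the identical stimulus schedule, so averaging over
    blocks is an event-related average.  Returns the per-participant
    averages and the grand mean, both in standard-deviation units.
    """
    lengths = {len(b) for blocks in blocks_by_participant for b in blocks}
    if len(lengths) != 1:
        raise ValueError(f"all blocks must have the same length, got {sorted(lengths)}")
    participant_means = []
    for p, blocks in enumerate(blocks_by_participant):
        z = np.stack([zscore(b.samples) for b in blocks])
        participant_means.append(
            PupilTimeSeries(
                samples=z.mean(axis=0),
                rate=blocks[0].rate,
                stage="averaged",
                participant_id=blocks[0].participant_id,
            )
        )
    grand = PupilTimeSeries(
        samples=np.stack([p.samples for p in participant_means]).mean(axis=0),
        rate=participant_means[0].rate,
        stage="averaged",
        participant_id=-1,
    )
    return participant_means, grand


def nuisance_projector(events, rate: float = ANALYSIS_RATE, kernel: np.ndarray | None = None):
    """Residualiser matching the nuisance regression at the analysis rate.

    The preprocessing removes drift and event-locked nuisance responses from
    the data, so design-matrix columns fitted to the cleaned series must be
    passed through the same projection (a Frisch-Waugh residualisation) to
    keep the regression consistent.  Returns a callable that residualises
    the columns of a matrix against [constant, drift, violation,
    likelihood-violation, target] built at ``rate``.

    A list of block trains yields the union of the per-block nuisance
    columns: each block's regression removed that block's own directions
    (notably its block-specific target regressor), so a series averaged over
    such blocks lacks signal along every one of them.
    """
    events_list = events if isinstance(events, (list, tuple)) else [events]
    if kernel is None:
        kernel = gamma_kernel(peak_time=8.0, shape=3.0, rate=rate)
    ref = events_list[0]
    n = int(round(len(ref.outcome) * ref.step_duration * rate))

    def smoothed(ev, mask: np.ndarray) -> np.ndarray:
        box = rasterize_boxcar(ev, rate, mask, n_samples=n)
        return fftconvolve(box, kernel)[:n]

    cols = [np.ones(n), np.linspace(0.0, 1.0, n)]
    seen: set[bytes] = set()
    for ev in events_list:
        flags = [ev.is_violation, ev.is_target]
        if ev.is_likelihood_violation.any():
            flags.insert(1, ev.is_likelihood_violation)
        for mask in flags:
            key = np.packbits(mask).tobytes()
            if key not in seen:  # identical flags recur across frozen blocks
                seen.add(key)
                cols.append(smoothed(ev, mask))
    N = np.column_stack(cols)

    def residualize(X: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(N, X, rcond=None)
        return X - N @ coef

    return residualize


def preprocess_block(ts: PupilTimeSeries, events) -> PupilTimeSeries:
    """Run one block through blink removal, nuisance regression and filtering."""
    return filter_downsample(regress_nuisance(remove_blinks(ts), events))


def preprocess_participants(
    raw: list[list[PupilTimeSeries]], events: list[list]
) -> tuple[list[PupilTimeSeries], PupilTimeSeries]:
    """Full pipeline from raw 1000 Hz blocks to participant and grand means."""
    cleaned = [
        [preprocess_block(ts, ev) for ts, ev in zip(blocks, evs)]
        for blocks, evs in zip(raw, events)
    ]
    return zscore_and_average(cleaned)
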