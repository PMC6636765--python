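"""Forward generation of realistic raw pupillometry from a known model.

The generator inverts the analysis chain: it simulates the ideal observer at
a ground-truth prior precision, composes a pupil signal from the same
convolution regressors the GLMs use (model 3 — photic plus inferred
precision — by default, since that is the winning model structure), and then
degrades it the way real recordings are degraded: slow drift, additive
Gaussian noise, and blink dropouts recorded as runs of zero samples at
1000 Hz.  Because the ground truth under the blink gaps and the generating
parameters are known, every downstream preprocessing and model-recovery
stage can be tested without any external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evidence import GammaBasis, make_gamma_basis, rasterize_boxcar
from .markov import TransitionModel, build_source_model
from .observer import ObserverSettings, PriorBelief, run_observer, upsample_trace
from .preprocess import RAW_RATE, PupilTimeSeries
from .schedule import BlockSchedule, build_block, build_experiment, expand_to_events

__all__ = ["SyntheticConfig", "SyntheticParticipant", "generate_participant", "make_fixture_suite"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of one synthetic participant.

    Amplitudes are in z-units of the final series; the precision weight is
    negative because pupil diameter is taken to rise with inferred
    volatility (dilation under uncertainty), and the photic weight is a
    signed free parameter.  Blink statistics (15 per minute, ~200 ms) are
    conventional resting values.
    """

    beta_inv_true: float = 2.25
    weight_photic: float = 0.5
    weight_precision: float = -1.0
    weight_interaction: float = 0.5
    noise_sd: float = 0.5
    blink_rate: float = 15.0            # blinks per minute
    blink_duration_ms: float = 200.0    # median duration
    blink_duration_sigma: float = 0.3   # lognormal shape
    drift_slope: float = 0.2            # z-units per minute
    baseline: float = 10.0              # raw offset keeping valid samples > 0
    n_participants: int = 9
    n_blocks: int = 16
    generating_model: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.blink_rate < 0 or self.blink_duration_ms < 0:
            raise ValueError("rates and durations must be non-negative")
        if self.generating_model not in (1, 2, 3, 4):
            raise ValueError("generating_model must be one of 1-4")


@dataclass
class SyntheticParticipant:
    """Raw synthetic blocks with their event trains and ground truth."""

    blocks: list                      # PupilTimeSeries at 1000 Hz
    events: list                      # EventTrain per block
    schedules: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)
    clean: list = field(default_factory=list)   # noise/blink-free 1000 Hz signal

    def write(self, out_dir) -> list:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for b, (ts, ev) in enumerate(zip(self.blocks, self.events)):
            raw = out_dir / f"block{b:02d}_raw.csv"
            evp = out_dir / f"block{b:02d}_events.tsv"
            ts.to_csv(raw)
            ev.to_tsv(evp)
            paths += [raw, evp]
        manifest = out_dir / "manifest.json"
        with open(manifest, "w") as fh:
            json.dump(self.truth, fh, indent=2)
        return paths + [manifest]


def _signal_10hz(
    cfg: SyntheticConfig, events, model: TransitionModel, basis: GammaBasis, settings
) -> np.ndarray:
    trace = run_observer(events, model, PriorBelief.from_precision(cfg.beta_inv_true), settings)
    om10 = upsample_trace(trace.omega_inferred)
    photic = rasterize_boxcar(events, basis.rate)
    kernel = basis.widest
    conv = lambda x: np.convolve(x, kernel)[: len(x)]

    signal = cfg.weight_photic * conv(photic)
    if cfg.generating_model in (3, 4):
        signal = signal + cfg.weight_precision * conv(om10 - om10.mean())
    if cfg.generating_model in (2, 4):
        inter = (om10 - om10.mean()) * photic
        signal = signal + cfg.weight_interaction * conv(inter - inter.mean())
    return signal


def generate_participant(
    cfg: SyntheticConfig,
    schedules: list[BlockSchedule] | None = None,
    model: TransitionModel | None = None,
    basis: GammaBasis | None = None,
    settings: ObserverSettings = ObserverSettings(),
    participant_id: int = 0,
) -> SyntheticParticipant:
    """Generate one participant's raw 1000 Hz blocks from the ground truth.

    Per block: the observer is run at the true prior precision, the 10 Hz
    signal is composed from the generating model's regressors (convolved
    with the widest pupillary kernel), linearly up-sampled to 1000 Hz, and
    degraded with drift, Gaussian noise and zero-valued blink gaps (Poisson
    onsets, lognormal durations).  Everything is driven by ``cfg.seed``, so
    a fixed seed reproduces the output exactly.
    """
    model = build_source_model() if model is None else model
    basis = make_gamma_basis() if basis is None else basis
    rng = np.random.default_rng(cfg.seed)
    if schedules is None:
        if cfg.n_blocks % 2 == 0:
            schedules = build_experiment(model, n_blocks=cfg.n_blocks, rng=rng)
        else:  # odd block counts: basic condition only
            basic = build_block(model, rng=rng)
            schedules = [basic.with_target(b % 8 + 1) for b in range(cfg.n_blocks)]
    events = [expand_to_events(b) for b in schedules]

    blocks, clean = [], []
    for b, ev in enumerate(events):
        sig10 = _signal_10hz(cfg, ev, model, basis, settings)
        t10 = np.arange(len(sig10)) / 10.0
        n_raw = int(round(ev.duration_s * RAW_RATE))
        t_raw = np.arange(n_raw) / RAW_RATE
        sig = np.interp(t_raw, t10, sig10)
        sig = sig + cfg.baseline + cfg.drift_slope * t_raw / 60.0
        clean.append(sig.copy())
        x = sig + rng.normal(0.0, cfg.noise_sd, n_raw) if cfg.noise_sd > 0 else sig.copy()
        if cfg.blink_rate > 0:
            n_blinks = rng.poisson(cfg.blink_rate * ev.duration_s / 60.0)
            onsets = rng.uniform(0.0, ev.duration_s, n_blinks)
            durations = rng.lognormal(
                np.log(cfg.blink_duration_ms / 1000.0), cfg.blink_duration_sigma, n_blinks
            )
            for t0, d in zip(onsets, durations):
                i0 = int(t0 * RAW_RATE)
                i1 = min(n_raw, i0 + max(1, int(d * RAW_RATE)))
                x[i0:i1] = 0.0
        blocks.append(
            PupilTimeSeries(
                samples=x, rate=RAW_RATE, stage="raw", block_id=b, participant_id=participant_id
            )
        )

    truth = {
        "participant_id": participant_id,
        "beta_inv_true": cfg.beta_inv_true,
        "generating_model": cfg.generating_model,
        "weights": {
            "photic": cfg.weight_photic,
            "precision": cfg.weight_precision,
            "interaction": cfg.weight_interaction,
        },
        "noise_sd": cfg.noise_sd,
        "blink_rate": cfg.blink_rate,
        "drift_slope": cfg.drift_slope,
        "seed": cfg.seed,
    }
    return SyntheticParticipant(
        blocks=blocks, events=events, schedules=list(schedules), truth=truth, clean=clean
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def make_fixture_suite(out_dir, seed: int = 1234) -> dict:
    """Write a small canonical fixture set for regression testing.

    Emits a two-state hidden Markov problem with exact (enumeration)
    smoothing posteriors, one 25-sequence block schedule as an event TSV,
    and one noiseless plus one noisy single-block participant, together with
    a manifest of SHA-256 checksums.  With a pinned seed the files are
    byte-identical across runs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    # -- tiny two-state HMM with exact posteriors by path enumeration
    A2 = np.array([[0.9, 0.2], [0.1, 0.8]])
    B2 = np.array([[0.7, 0.3], [0.3, 0.7]])
    outcomes = [0, 0, 1, 1]
    post = _enumerate_smoothing(A2, B2, outcomes)
    np.savetxt(out_dir / "two_state_A.csv", A2, delimiter=",")
    np.savetxt(out_dir / "two_state_B.csv", B2, delimiter=",")
    np.savetxt(out_dir / "two_state_posteriors.csv", post, delimiter=",")
    with open(out_dir / "two_state_outcomes.json", "w") as fh:
        json.dump(outcomes, fh)
    written += [
        "two_state_A.csv",
        "two_state_B.csv",
        "two_state_posteriors.csv",
        "two_state_outcomes.json",
    ]

    # -- one block schedule and its event train
    model = build_source_model()
    rng = np.random.default_rng(seed)
    block = build_block(model, rng=rng)
    ev = expand_to_events(block)
    ev.to_tsv(out_dir / "block_events.tsv")
    written.append("block_events.tsv")

    # -- one noiseless and one noisy participant, one block each
    for tag, cfg in {
        "noiseless": SyntheticConfig(
            noise_sd=0.0, blink_rate=0.0, drift_slope=0.0, n_blocks=1, seed=seed
        ),
        "noisy": SyntheticConfig(n_blocks=1, seed=seed),
    }.items():
        participant = generate_participant(cfg, [block], model)
        participant.blocks[0].to_csv(out_dir / f"participant_{tag}_raw.csv")
        written.append(f"participant_{tag}_raw.csv")

    checksums = {name: _sha256(out_dir / name) for name in written}
    with open(out_dir / "checksums.json", "w") as fh:
        json.dump(checksums, fh, indent=2, sort_keys=True)
    return checksums


def _enumerate_smoothing(A: np.ndarray, B: np.ndarray, outcomes) -> np.ndarray:
    """Exact smoothing posteriors by brute-force path enumeration."""
    import itertools

    n = B.shape[0]
    T = len(outcomes)
    post = np.zeros((T, n))
    for path in itertools.product(range(n), repeat=T):
        p = 1.0 / n
        for t, s in enumerate(path):
            if t > 0:
                p *= B[s, path[t - 1]]
            p *= A[outcomes[t], s]
        for t, s in enumerate(path):
            post[t, s] += p
    return post / post.sum(axis=1, keepdims=True)
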