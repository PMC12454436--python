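"""Synthetic serial-reaction-time-task (SRTT) MEG generator.

Emulates the experiment this package targets: a 12-item key sequence
(1 2 1 3 4 2 3 1 4 3 2 4) repeated for 10 cycles in each of 12 blocks
(120 keypresses per block, 1,440 in total), with keys mapped to the left
middle (1), left index (2), right index (3) and right middle (4) fingers.
Sensor data follow the linear generative model

    X_t = A . S_t + eps,

where ``A`` is a known mixing matrix (class-specific focal topographies on
a planar sensor layout), ``S_t`` holds per-class source time courses — a
low-frequency movement-evoked transient plus alpha/beta oscillations with
event-related desynchronization (ERD) around the button press — and
``eps`` is i.i.d. Gaussian sensor noise.  Because the mixing matrix and
the exact source time courses are returned alongside the epochs, every
downstream stage (decoding, pattern reconstruction, phase statistics) can
be tested against ground truth.

Reaction times decay exponentially across blocks toward a floor,
emulating sequence learning; response accuracy is ~97.5%.  An optional
"phase shift" alters the evoked component's latency and amplitude in the
late (learned) blocks so that cross-phase decoding analyses have a known
effect to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import EpochSet, FINGERS, TRIAL_COLUMNS

DEFAULT_SEQUENCE = (1, 2, 1, 3, 4, 2, 3, 1, 4, 3, 2, 4)
DEFAULT_KEY_TO_FINGER = {1: "LM", 2: "LI", 3: "RI", 4: "RM"}

#: seconds of feedback + rest between blocks (bookkeeping only)
BLOCK_GAP_S = 30.0


class ConfigurationError(ValueError):
    """Raised for invalid simulator / pipeline configuration values."""


# ---------------------------------------------------------------------------
# trial table & behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SRTTConfig:
    sequence: tuple[int, ...] = DEFAULT_SEQUENCE
    cycles_per_block: int = 10
    n_blocks: int = 12
    isi: float = 0.338
    key_to_finger: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_KEY_TO_FINGER)
    )
    seed: int = 0

    def validate(self) -> None:
        if len(self.sequence) == 0:
            raise ConfigurationError("sequence must be non-empty")
        if self.cycles_per_block < 1 or self.n_blocks < 1:
            raise ConfigurationError("cycles_per_block and n_blocks must be >= 1")
        keys = set(self.sequence)
        if not keys <= set(self.key_to_finger):
            raise ConfigurationError("sequence contains keys without a finger mapping")
        fingers = list(self.key_to_finger.values())
        if len(set(fingers)) != len(fingers) or not set(fingers) <= set(FINGERS):
            raise ConfigurationError(
                f"key_to_finger must map bijectively into {FINGERS}"
            )


@dataclass(frozen=True)
class BehaviorModel:
    """Block-level exponential RT decay plus Gaussian trial noise.

    Mean RT in block b is ``rt_floor + (rt_start - rt_floor) *
    exp(-learning_rate * (b - 1))``; single-trial RTs add Gaussian noise
    and are truncated at ``rt_floor``.  Correctness is i.i.d. Bernoulli
    with ``accuracy_rate``.
    """

    rt_start: float = 0.55
    rt_floor: float = 0.35
    learning_rate: float = 0.25
    rt_noise_sd: float = 0.05
    accuracy_rate: float = 0.975

    def validate(self) -> None:
        if not self.rt_floor < self.rt_start:
            raise ConfigurationError("rt_floor must be < rt_start")
        if self.rt_noise_sd < 0:
            raise ConfigurationError("rt_noise_sd must be >= 0")
        if not 0 < self.accuracy_rate <= 1:
            raise ConfigurationError("accuracy_rate must be in (0, 1]")

    def block_mean_rt(self, block: np.ndarray) -> np.ndarray:
        block = np.asarray(block, dtype=float)
        return self.rt_floor + (self.rt_start - self.rt_floor) * np.exp(
            -self.learning_rate * (block - 1.0)
        )


def generate_trial_table(cfg: SRTTConfig) -> pd.DataFrame:
    """Deterministic trial table: block/cycle/position/key/finger per press.

    RT, correctness and onset are filled by :func:`simulate_behavior`.
    """
    cfg.validate()
    seq = np.asarray(cfg.sequence, dtype=int)
    n_per_block = seq.size * cfg.cycles_per_block
    block = np.repeat(np.arange(1, cfg.n_blocks + 1), n_per_block)
    cycle = np.tile(np.repeat(np.arange(1, cfg.cycles_per_block + 1), seq.size), cfg.n_blocks)
    position = np.tile(np.arange(1, seq.size + 1), cfg.cycles_per_block * cfg.n_blocks)
    key = np.tile(seq, cfg.cycles_per_block * cfg.n_blocks)
    finger = np.array([cfg.key_to_finger[k] for k in key])
    return pd.DataFrame(
        {
            "block": block,
            "cycle": cycle,
            "position": position,
            "key": key,
            "pressed": key.copy(),
            "finger": finger,
            "rt": np.nan,
            "correct": True,
            "onset": np.nan,
        },
        columns=list(TRIAL_COLUMNS),
    )


def simulate_behavior(
    table: pd.DataFrame,
    bm: BehaviorModel | None = None,
    seed: int = 0,
    key_to_finger: dict[int, str] | None = None,
    isi: float = 0.338,
) -> pd.DataFrame:
    """Fill RT, correctness, pressed key and response onset into a trial table.

    Error trials press one of the three other keys (uniformly at random)
    and carry the *pressed* key's finger label, flagged incorrect, so the
    correct-trials-only filter downstream has something to remove.
    """
    bm = bm or BehaviorModel()
    bm.validate()
    key_to_finger = key_to_finger or dict(DEFAULT_KEY_TO_FINGER)
    if len(table) == 0:
        raise ConfigurationError("trial table is empty")
    rng = np.random.default_rng(seed)
    out = table.copy()

    mean_rt = bm.block_mean_rt(out["block"].to_numpy())
    rt = mean_rt + bm.rt_noise_sd * rng.standard_normal(len(out))
    out["rt"] = np.maximum(rt, bm.rt_floor)

    out["correct"] = rng.random(len(out)) < bm.accuracy_rate
    wrong = ~out["correct"].to_numpy()
    keys = sorted(key_to_finger)
    target = out["key"].to_numpy()
    pressed = target.copy()
    for i in np.flatnonzero(wrong):
        others = [k for k in keys if k != target[i]]
        pressed[i] = others[rng.integers(len(others))]
    out["pressed"] = pressed
    out["finger"] = [key_to_finger[k] for k in pressed]

    # response onsets: stimulus -> rt -> press; isi before next stimulus;
    # feedback + rest between blocks (timing bookkeeping only)
    press = np.empty(len(out))
    t = 0.0
    prev_block = int(out["block"].iloc[0])
    for i, (blk, r) in enumerate(zip(out["block"].to_numpy(), out["rt"].to_numpy())):
        if blk != prev_block:
            t += BLOCK_GAP_S
            prev_block = blk
        press[i] = t + r
        t = press[i] + isi
    out["onset"] = press
    return out


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceSpec:
    """Dynamics of one finger class's sources.

    The evoked component is a low-frequency Gabor (carrier < 5 Hz) centred
    ``evoked_latency`` s after the press; alpha/beta oscillations carry a
    Gaussian-windowed ERD starting ~200 ms before the press and a beta
    rebound after +300 ms.  Amplitudes are in the same arbitrary units as
    the sensor noise SD.
    """

    evoked_amp: float = 1.0
    evoked_freq: float = 3.0
    evoked_latency: float = 0.05
    evoked_width: float = 0.10
    alpha_amp: float = 0.5
    alpha_freq: float = 10.0
    beta_amp: float = 0.5
    beta_freq: float = 20.0
    erd_depth: float = 0.7
    erd_center: float = 0.05
    erd_sigma: float = 0.15
    beta_rebound_gain: float = 0.5
    beta_rebound_center: float = 0.40
    beta_rebound_sigma: float = 0.08

    def scaled(self, factor: float) -> "SourceSpec":
        return replace(
            self,
            evoked_amp=self.evoked_amp * factor,
            alpha_amp=self.alpha_amp * factor,
            beta_amp=self.beta_amp * factor,
        )


@dataclass(frozen=True)
class PhaseShift:
    """Source-dynamics change in the learned blocks (default 10-12):
    the evoked component arrives ``latency_s`` later, scaled by
    ``amp_scale``."""

    latency_s: float = 0.05
    amp_scale: float = 1.2
    learned_blocks: frozenset[int] = frozenset({10, 11, 12})


# class -> topography centre on the unit disk (x < 0 is LEFT); left-hand
# fingers project contralaterally, i.e. to x > 0
TOPO_CENTERS = {
    "LI": (0.35, 0.10),
    "LM": (0.50, 0.25),
    "RI": (-0.35, 0.10),
    "RM": (-0.50, 0.25),
}
TOPO_SIGMA = 0.22


@dataclass
class ForwardModel:
    layout: np.ndarray                      # (n_channels, 2), x<0 = left
    A_true: np.ndarray                      # (n_channels, 4 * m), unit-norm columns
    source_classes: np.ndarray              # class label of each source column
    source_spec: dict[str, SourceSpec]
    noise_sd: float = 0.1
    phase_shift: PhaseShift | None = None

    @property
    def n_channels(self) -> int:
        return self.A_true.shape[0]

    @property
    def n_sources(self) -> int:
        return self.A_true.shape[1]

    def scaled(self, amplitude: float) -> "ForwardModel":
        """Copy with every source amplitude multiplied by ``amplitude``."""
        spec = {c: s.scaled(amplitude) for c, s in self.source_spec.items()}
        return replace(self, source_spec=spec)


def sensor_layout(n_channels: int) -> np.ndarray:
    """Deterministic sunflower-spiral layout filling the unit disk."""
    i = np.arange(n_channels)
    r = np.sqrt((i + 0.5) / n_channels)
    theta = i * np.pi * (3.0 - np.sqrt(5.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def build_forward_model(
    n_channels: int = 204,
    n_sources_per_class: int = 1,
    seed: int = 0,
    noise_sd: float = 0.1,
    phase_shift: PhaseShift | None = None,
    source_spec: dict[str, SourceSpec] | None = None,
) -> ForwardModel:
    """Mixing matrix with focal Gaussian topographies over central sensors,
    contralateral to each finger's hand; columns normalized to unit norm."""
    if n_channels < 4:
        raise ConfigurationError("n_channels must be >= 4")
    if n_sources_per_class < 1:
        raise ConfigurationError("n_sources_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    layout = sensor_layout(n_channels)
    cols, classes = [], []
    for finger in FINGERS:
        cx, cy = TOPO_CENTERS[finger]
        for j in range(n_sources_per_class):
            jitter = rng.normal(0.0, 0.08, size=2) if j > 0 else np.zeros(2)
            d2 = (layout[:, 0] - cx - jitter[0]) ** 2 + (layout[:, 1] - cy - jitter[1]) ** 2
            g = np.exp(-d2 / (2.0 * TOPO_SIGMA**2))
            cols.append(g / np.linalg.norm(g))
            classes.append(finger)
    spec = source_spec or {f: SourceSpec() for f in FINGERS}
    return ForwardModel(
        layout=layout,
        A_true=np.column_stack(cols),
        source_classes=np.array(classes),
        source_spec=spec,
        noise_sd=noise_sd,
        phase_shift=phase_shift,
    )


# ---------------------------------------------------------------------------
# epoch synthesis
# ---------------------------------------------------------------------------

def _erd_envelope(t: np.ndarray, spec: SourceSpec, rebound: bool) -> np.ndarray:
    env = 1.0 - spec.erd_depth * np.exp(
        -((t - spec.erd_center) ** 2) / (2.0 * spec.erd_sigma**2)
    )
    if rebound:
        env = env + spec.beta_rebound_gain * np.exp(
            -((t - spec.beta_rebound_center) ** 2) / (2.0 * spec.beta_rebound_sigma**2)
        )
    return env


def _source_timecourse(
    t: np.ndarray, spec: SourceSpec, active: bool, rng: np.random.Generator
) -> np.ndarray:
    """One trial of one source: evoked (if this source's class was pressed)
    plus alpha/beta oscillations with random phase; ERD only when active."""
    s = np.zeros_like(t)
    if active and spec.evoked_amp != 0.0:
        s += spec.evoked_amp * np.exp(
            -((t - spec.evoked_latency) ** 2) / (2.0 * spec.evoked_width**2)
        ) * np.cos(2.0 * np.pi * spec.evoked_freq * (t - spec.evoked_latency))
    alpha_env = _erd_envelope(t, spec, rebound=False) if active else np.ones_like(t)
    beta_env = _erd_envelope(t, spec, rebound=True) if active else np.ones_like(t)
    s += spec.alpha_amp * alpha_env * np.cos(
        2.0 * np.pi * spec.alpha_freq * t + rng.uniform(0, 2 * np.pi)
    )
    s += spec.beta_amp * beta_env * np.cos(
        2.0 * np.pi * spec.beta_freq * t + rng.uniform(0, 2 * np.pi)
    )
    return s


def simulate_epochs(
    table: pd.DataFrame,
    fm: ForwardModel,
    sfreq: float = 200.0,
    window: tuple[float, float] = (-0.5, 0.5),
    seed: int = 0,
    subject_id: str = "sim",
) -> tuple[EpochSet, dict]:
    """Response-locked epochs ``X = A_true . S + eps`` for every trial.

    Returns the epoch set and a ground-truth record with the mixing
    matrix and the exact per-trial source time courses, for oracle tests.
    When the forward model carries a phase shift, trials in the learned
    blocks use the shifted evoked latency/amplitude.
    """
    if not (window[0] < 0.0 <= window[1]):
        raise ConfigurationError("epoch window must contain the lock point t=0")
    if not table["correct"].any():
        raise ConfigurationError("no correct trials to simulate")
    rng = np.random.default_rng(seed)
    n_times = int(round((window[1] - window[0]) * sfreq))
    t = window[0] + np.arange(n_times) / sfreq
    n_trials = len(table)
    fingers = table["finger"].to_numpy()
    blocks = table["block"].to_numpy()

    S = np.zeros((n_trials, fm.n_sources, n_times))
    ps = fm.phase_shift
    for i in range(n_trials):
        shifted = ps is not None and int(blocks[i]) in ps.learned_blocks
        for j, src_class in enumerate(fm.source_classes):
            spec = fm.source_spec[src_class]
            active = src_class == fingers[i]
            if active and shifted:
                spec = replace(
                    spec,
                    evoked_latency=spec.evoked_latency + ps.latency_s,
                    evoked_amp=spec.evoked_amp * ps.amp_scale,
                )
            S[i, j] = _source_timecourse(t, spec, active, rng)

    noise = fm.noise_sd * rng.standard_normal((n_trials, fm.n_channels, n_times))
    X = np.einsum("nk,ikt->int", fm.A_true, S) + noise
    epochs = EpochSet(
        data=X,
        times=t,
        sfreq=sfreq,
        labels=fingers.copy(),
        block=blocks.copy(),
        lock="response",
        subject_id=subject_id,
        provenance=[f"simulate_epochs(seed={seed}, sfreq={sfreq}, window={window})"],
    )
    truth = {
        "A_true": fm.A_true,
        "source_classes": fm.source_classes,
        "sources": S,
        "noise_sd": fm.noise_sd,
        "layout": fm.layout,
    }
    return epochs, truth


def save_ground_truth_h5(path, truth: dict) -> None:
    """Sidecar HDF5 with the exact mixing matrix and source time courses."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("A_true", data=truth["A_true"])
        f.create_dataset("sources", data=truth["sources"])
        f.create_dataset("layout", data=truth["layout"])
        f.create_dataset("source_classes",
                         data=np.asarray(truth["source_classes"], dtype="S8"))
        f.attrs["noise_sd"] = truth["noise_sd"]


def load_ground_truth_h5(path) -> dict:
    import h5py

    with h5py.File(path, "r") as f:
        return {
            "A_true": f["A_true"][()],
            "sources": f["sources"][()],
            "layout": f["layout"][()],
            "source_classes": f["source_classes"][()].astype(str),
            "noise_sd": float(f.attrs["noise_sd"]),
        }


def simulate_subject(
    seed: int,
    cfg: SRTTConfig | None = None,
    bm: BehaviorModel | None = None,
    fm: ForwardModel | None = None,
    sfreq: float = 200.0,
    window: tuple[float, float] = (-0.5, 0.5),
    subject_id: str | None = None,
) -> tuple[pd.DataFrame, EpochSet, dict]:
    """Convenience wrapper: trial table -> behavior -> epochs for one subject."""
    cfg = cfg or SRTTConfig()
    table = generate_trial_table(cfg)
    table = simulate_behavior(table, bm, seed=seed, key_to_finger=cfg.key_to_finger)
    fm = fm or build_forward_model(seed=seed + 1)
    epochs, truth = simulate_epochs(
        table, fm, sfreq=sfreq, window=window, seed=seed + 2,
        subject_id=subject_id or f"sub-{seed:03d}",
    )
    return table, epochs, truth
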