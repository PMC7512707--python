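"""Synthetic inputs with known ground truth.

Two generators cover the pipeline's two entry points:

* :func:`synth_feature_table` — a labeled feature table whose columns
  have *known* roles: marginally predictive Gaussians, redundant copies,
  XOR-synergistic pairs that carry class information only jointly, and
  pure noise.  It exists to test that the coalition game recovers
  synergy that univariate relevance rankings miss.
* :func:`synth_vital_records` — quasi-periodic 3-channel records shaped
  like the ICU monitor data the method targets (5-minute ECG II / ABP /
  PLETH traces at 250 Hz with binary alarm labels).  Realism is
  deliberately minimal — template pulse trains plus Gaussian noise — its
  job is exercising the pipeline's shape, not physiological fidelity.

Both are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .wavelets import ALARM_TYPES, VitalRecord

__all__ = [
    "TabularSpec",
    "WaveformSpec",
    "synth_feature_table",
    "synth_vital_records",
    "write_records",
    "read_records",
]

#: class separation of marginal features (Cohen's d)
MARGINAL_EFFECT_SIZE = 1.0
#: component spread of the +-1 Gaussian mixture behind each XOR feature
XOR_COMPONENT_SD = 0.4
#: jitter added to redundant copies
REDUNDANT_JITTER_SD = 0.15
#: alarm-type mix of the target cohort (Asystole, ExtBrady, ExtTachy, VT, VF/VFib)
ALARM_TYPE_WEIGHTS = np.array([34, 30, 15, 124, 17]) / 220.0


@dataclass(frozen=True)
class TabularSpec:
    """Composition of a synthetic labeled feature table.

    Defaults define the synergy benchmark: 16 features of which exactly
    four (the XOR pair and two noise columns) carry no univariate signal,
    and the twelve informative columns are copies of only two independent
    sources so univariate rankings pile onto redundant features.
    """

    n_samples: int = 3000
    n_marginal: int = 2
    n_redundant: int = 10
    n_xor_pairs: int = 1
    n_noise: int = 2
    noise_flip_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_marginal", "n_redundant", "n_xor_pairs", "n_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.noise_flip_prob < 0.5:
            raise ValueError("noise_flip_prob must be in [0, 0.5)")
        if self.n_xor_pairs > 0 and self.n_samples < 10:
            raise ValueError("XOR pairs need n_samples >= 10")
        if self.n_redundant > 0 and self.n_marginal == 0:
            raise ValueError("redundant copies need at least one marginal feature")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")

    @property
    def n_features(self) -> int:
        return self.n_marginal + self.n_redundant + 2 * self.n_xor_pairs + self.n_noise


def synth_feature_table(spec: TabularSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a labeled table plus the ground-truth role of each column.

    The binary target ``C`` is exactly balanced.  Marginal features are
    class-conditional Gaussians separated by ``MARGINAL_EFFECT_SIZE``
    standard deviations; each XOR pair ``(A, B)`` is built from two
    independent balanced +-1 sign variables whose XOR equals ``C`` except
    on a ``noise_flip_prob`` fraction of samples, rendered as Gaussian
    mixtures so each member is marginally uninformative; redundant
    features are jittered copies of marginal features (cyclically);
    noise features are independent standard normals.

    Returns ``(table, roles)`` — the table carries a final ``label``
    column; ``roles`` maps column name to one of ``marginal``,
    ``redundant``, ``xor``, ``noise``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    c = np.zeros(n, dtype=np.int64)
    c[: n // 2] = 1
    rng.shuffle(c)

    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}

    marg_names = []
    for k in range(spec.n_marginal):
        name = f"marginal_{k}"
        cols[name] = c * MARGINAL_EFFECT_SIZE + rng.normal(0.0, 1.0, n)
        roles[name] = "marginal"
        marg_names.append(name)

    for k in range(spec.n_redundant):
        src = marg_names[k % spec.n_marginal]
        name = f"redundant_{k}"
        cols[name] = cols[src] + rng.normal(0.0, REDUNDANT_JITTER_SD, n)
        roles[name] = "redundant"

    for k in range(spec.n_xor_pairs):
        target = np.where(rng.random(n) < spec.noise_flip_prob, 1 - c, c)
        bit_a = rng.integers(0, 2, n)
        bit_b = bit_a ^ target
        for suffix, bits in (("a", bit_a), ("b", bit_b)):
            name = f"xor{k}_{suffix}"
            cols[name] = (2.0 * bits - 1.0) + rng.normal(0.0, XOR_COMPONENT_SD, n)
            roles[name] = "xor"

    for k in range(spec.n_noise):
        name = f"noise_{k}"
        cols[name] = rng.normal(0.0, 1.0, n)
        roles[name] = "noise"

    table = pd.DataFrame(cols)
    table["label"] = c
    return table, pd.Series(roles, name="role")


@dataclass(frozen=True)
class WaveformSpec:
    """Shape of a synthetic monitor-record cohort: 5-minute 3-channel
    records at 250 Hz by default, with the target cohort's true-alarm
    fraction (170 of 220)."""

    n_records: int = 8
    duration_s: float = 300.0
    fs: float = 250.0
    true_alarm_fraction: float = 170.0 / 220.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if not 0.0 <= self.true_alarm_fraction <= 1.0:
            raise ValueError("true_alarm_fraction must be in [0, 1]")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _pulse_trains(phase: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Template waveforms as functions of beat phase in [0, 1)."""
    frac = phase % 1.0
    # ECG: narrow R spike plus a broad low T-like bump
    ecg = np.exp(-0.5 * ((frac - 0.15) / 0.015) ** 2) + 0.25 * np.exp(
        -0.5 * ((frac - 0.45) / 0.08) ** 2
    )
    # ABP: systolic upstroke with a dicrotic-notch-ish secondary bump
    abp = 0.8 * np.exp(-0.5 * ((frac - 0.3) / 0.1) ** 2) + 0.3 * np.exp(
        -0.5 * ((frac - 0.6) / 0.07) ** 2
    )
    # PLETH: smooth pulse lagging the pressure wave
    pleth = np.sin(np.pi * ((frac - 0.35) % 1.0)) ** 3
    return ecg, abp, pleth


def synth_vital_records(spec: WaveformSpec) -> list[VitalRecord]:
    """Generate quasi-periodic 3-channel records with binary labels.

    Each record runs at its own baseline heart rate (~75 bpm).  True-alarm
    records get an event in the final 10 s — the beat rate jumps by 80%
    and the waveform amplitude drops — mimicking an arrhythmia onset just
    before the alarm fires; false-alarm records stay stationary.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_records)
    n_samp = int(round(spec.duration_s * spec.fs))
    records = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        label = int(rng.random() < spec.true_alarm_fraction)
        alarm_type = str(rng.choice(ALARM_TYPES, p=ALARM_TYPE_WEIGHTS))
        hr = rng.normal(75.0, 5.0)  # bpm
        rate = np.full(n_samp, hr / 60.0)  # beats per second
        amp = np.ones(n_samp)
        if label == 1:
            onset = max(n_samp - int(round(10.0 * spec.fs)), 0)
            rate[onset:] *= 1.8
            amp[onset:] *= 0.6
        phase = np.cumsum(rate) / spec.fs
        # slow respiratory-like phase wobble
        t = np.arange(n_samp) / spec.fs
        phase = phase + 0.02 * np.sin(2.0 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
        ecg, abp, pleth = _pulse_trains(phase)
        noise = rng.normal(0.0, spec.noise_sd, (3, n_samp))
        records.append(
            VitalRecord(
                record_id=f"synth{r:04d}",
                channels={
                    "ECGII": amp * ecg + noise[0],
                    # ABP lives on a mmHg scale; noise scaled to match
                    "ABP": 80.0 + 40.0 * (amp * abp + noise[1]),
                    "PLETH": amp * pleth + noise[2],
                },
                fs=spec.fs,
                alarm_type=alarm_type,
                label=label,
            )
        )
    return records


# ---------------------------------------------------------------------------
# delimited-text record I/O
# ---------------------------------------------------------------------------

def write_records(records: list[VitalRecord], directory) -> Path:
    """Write each record as ``<record_id>.csv`` (one channel per column)
    plus a ``records.csv`` manifest (record_id, fs, alarm_type, label)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in records:
        pd.DataFrame(rec.channels).to_csv(directory / f"{rec.record_id}.csv", index=False)
        manifest.append(
            {"record_id": rec.record_id, "fs": rec.fs, "alarm_type": rec.alarm_type, "label": rec.label}
        )
    pd.DataFrame(manifest).to_csv(directory / "records.csv", index=False)
    return directory


def read_records(directory) -> list[VitalRecord]:
    """Read a directory written by :func:`write_records`."""
    directory = Path(directory)
    manifest_path = directory / "records.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no records.csv manifest in {directory}")
    manifest = pd.read_csv(manifest_path)
    records = []
    for row in manifest.itertuples(index=False):
        frame = pd.read_csv(directory / f"{row.record_id}.csv")
        records.append(
            VitalRecord(
                record_id=str(row.record_id),
                channels={c: frame[c].to_numpy() for c in frame.columns},
                fs=float(row.fs),
                alarm_type=str(row.alarm_type),
                label=int(row.label),
            )
        )
    return records
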