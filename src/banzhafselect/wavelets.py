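"""Discrete wavelet decomposition of ICU vital signs and the 20
statistical / information-theoretic features computed per coefficient
vector.

Each channel of a 5-minute record (ECG lead II, arterial blood pressure,
photoplethysmogram at 250 Hz) is decomposed with a multi-level DWT —
Daubechies-8 for ECG, Daubechies-4 for ABP/PLETH, six levels by default.
Per channel the cascade yields detail coefficients d1..dl plus
approximations a1..al; a configurable grouping mode picks the l vectors
that represent the channel (3 channels x 6 levels = 18 vectors).  From
each vector 20 order-invariant features are extracted, giving 360 named
columns per record for the default configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pywt

__all__ = [
    "ALARM_TYPES",
    "FEATURE_NAMES",
    "VitalRecord",
    "WaveletConfig",
    "CoefficientVector",
    "CoefficientSet",
    "decompose",
    "decompose_record",
    "standardized_moment",
    "threshold_count",
    "extract_features",
    "build_feature_table",
]

ALARM_TYPES = (
    "Asystole",
    "ExtremeBradycardia",
    "ExtremeTachycardia",
    "VentricularTachycardia",
    "VentricularFlutterFib",
)

GROUPING_MODES = ("details_only", "details_plus_final_approx", "approx_plus_final_detail")

#: the 20 per-vector features, in fixed output order
FEATURE_NAMES = (
    "mean",
    "mode",
    "median",
    "max",
    "min",
    "range",
    "variance",
    "std",
    "moment3",
    "moment4",
    "coef_var",
    "kurtosis",
    "skewness",
    "harmonic_mean",
    "iqr",
    "shannon_energy_entropy",
    "log_energy",
    "n_above_half_max",
    "n_above_energy",
    "n_above_5x_energy",
)


@dataclass
class VitalRecord:
    """One patient record: named channels sampled at ``fs`` Hz, the alarm
    type that triggered the record, and the binary label (1 = true alarm,
    0 = false alarm)."""

    record_id: str
    channels: dict[str, np.ndarray]
    fs: float
    alarm_type: str
    label: int

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {v.size for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"record {self.record_id}: channels differ in length {lengths}")
        if self.fs <= 0:
            raise ValueError(f"record {self.record_id}: fs must be positive")
        if self.label not in (0, 1):
            raise ValueError(f"record {self.record_id}: label must be 0 or 1")
        if self.alarm_type not in ALARM_TYPES:
            raise ValueError(f"record {self.record_id}: unknown alarm type {self.alarm_type!r}")


@dataclass(frozen=True)
class WaveletConfig:
    """Per-channel wavelet family, decomposition depth, and how the
    cascade's ``levels + 1`` outputs are grouped into ``levels`` vectors
    per channel (see ``GROUPING_MODES``)."""

    wavelet_by_channel: Mapping[str, str] = field(
        default_factory=lambda: {"ECGII": "db8", "ABP": "db4", "PLETH": "db4"}
    )
    levels: int = 6
    grouping_mode: str = "details_plus_final_approx"
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.grouping_mode not in GROUPING_MODES:
            raise ValueError(f"unknown grouping_mode {self.grouping_mode!r}")

    def wavelet_for(self, channel: str) -> str:
        try:
            return self.wavelet_by_channel[channel]
        except KeyError:
            raise KeyError(f"no wavelet assigned to channel {channel!r}") from None


@dataclass(frozen=True)
class CoefficientVector:
    channel: str
    level: int
    kind: str  # "detail" or "approx"
    coeffs: np.ndarray

    @property
    def name(self) -> str:
        return f"{self.channel}_{self.level}_{self.kind}"


@dataclass
class CoefficientSet:
    """Ordered per-channel, per-level coefficient vectors for one record
    (18 vectors in the 3-channel, 6-level configuration)."""

    record_id: str
    vectors: list[CoefficientVector]


def _dwt_cascade(signal: np.ndarray, wavelet: str, levels: int, mode: str):
    """Run the analysis filter bank, returning (a1..al, d1..dl)."""
    approxs, details = [], []
    a = signal
    for _ in range(levels):
        a, d = pywt.dwt(a, wavelet, mode=mode)
        approxs.append(a)
        details.append(d)
    return approxs, details


def decompose(signal, config: WaveletConfig, channel: str) -> list[CoefficientVector]:
    """Decompose one channel and group the outputs per
    ``config.grouping_mode`` into ``config.levels`` coefficient vectors."""
    x = np.asarray(signal, dtype=float).ravel()
    if x.size == 0:
        raise ValueError(f"channel {channel!r}: empty signal")
    wavelet = config.wavelet_for(channel)
    if wavelet not in pywt.wavelist():
        raise ValueError(f"unknown wavelet name {wavelet!r}")
    approxs, details = _dwt_cascade(x, wavelet, config.levels, config.boundary_mode)
    l = config.levels
    if config.grouping_mode == "details_only":
        picked = [("detail", i + 1, details[i]) for i in range(l)]
    elif config.grouping_mode == "details_plus_final_approx":
        picked = [("detail", i + 1, details[i]) for i in range(l - 1)]
        picked.append(("approx", l, approxs[-1]))
    else:  # approx_plus_final_detail
        picked = [("approx", i + 1, approxs[i]) for i in range(l - 1)]
        picked.append(("detail", l, details[-1]))
    return [CoefficientVector(channel, lev, kind, c) for kind, lev, c in picked]


def decompose_record(record: VitalRecord, config: WaveletConfig) -> CoefficientSet:
    """Decompose every channel of a record; vectors are ordered by the
    channel order of ``config.wavelet_by_channel`` then by level."""
    vectors: list[CoefficientVector] = []
    for channel in config.wavelet_by_channel:
        if channel not in record.channels:
            raise ValueError(
                f"record {record.record_id}: missing channel {channel!r} "
                f"(has {sorted(record.channels)})"
            )
        vectors.extend(decompose(record.channels[channel], config, channel))
    return CoefficientSet(record_id=record.record_id, vectors=vectors)


def standardized_moment(X, n: int) -> float:
    """Central sample moment ``sum((Xi - mean)^n) / N``."""
    x = np.asarray(X, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty input")
    if n < 1:
        raise ValueError("moment order must be >= 1")
    return float(np.mean((x - x.mean()) ** n))


def threshold_count(X, alpha: float) -> int:
    """Number of coefficients with magnitude strictly above ``alpha``."""
    x = np.asarray(X, dtype=float).ravel()
    return int(np.count_nonzero(np.abs(x) > alpha))


def _histogram_mode(x: np.ndarray, bins: int = 100) -> float:
    # "mode" of continuous data: midpoint of the fullest equal-width bin
    lo, hi = x.min(), x.max()
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(x, bins=bins, range=(lo, hi))
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def extract_features(coeffs, normalized_entropy: bool = False) -> dict[str, float]:
    """The 20 per-vector features, keyed by ``FEATURE_NAMES`` in order.

    Degenerate cases are mapped to finite values so downstream MI
    estimation never sees NaN/inf: zero variance forces kurtosis,
    skewness and the coefficient of variation to 0 (likewise a zero
    mean for the coefficient of variation); a zero coefficient sends the
    harmonic mean to 0 (the limit as one term of ``sum(1/Xi)`` diverges);
    log-energy floors ``Xi^2`` at the smallest positive float.
    """
    x = np.asarray(coeffs, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty coefficient vector")
    n = x.size
    mean = float(x.mean())
    var = standardized_moment(x, 2)
    std = float(np.sqrt(var))
    mu3 = standardized_moment(x, 3)
    mu4 = standardized_moment(x, 4)
    energy = x * x
    total_energy = float(energy.sum())

    if std > 0.0:
        kurtosis = mu4 / std**4
        skewness = mu3 / std**3
        coef_var = std / mean if mean != 0.0 else 0.0
    else:
        kurtosis = skewness = coef_var = 0.0

    if np.any(x == 0.0):
        hmean = 0.0
    else:
        inv_sum = float(np.sum(1.0 / x))
        hmean = n / inv_sum if inv_sum != 0.0 else 0.0

    if normalized_entropy:
        p = energy / total_energy if total_energy > 0 else np.full(n, 1.0 / n)
        nz = p[p > 0]
        shannon = float(-(nz * np.log2(nz)).sum())
    else:
        nz = energy[energy > 0]
        shannon = float(-(nz * np.log2(nz)).sum())

    log_energy = float(np.sum(np.log(np.maximum(energy, np.finfo(float).tiny))))
    q25, q75 = np.percentile(x, [25.0, 75.0])
    max_abs = float(np.abs(x).max())

    return {
        "mean": mean,
        "mode": _histogram_mode(x),
        "median": float(np.median(x)),
        "max": float(x.max()),
        "min": float(x.min()),
        "range": float(x.max() - x.min()),
        "variance": var,
        "std": std,
        "moment3": mu3,
        "moment4": mu4,
        "coef_var": coef_var,
        "kurtosis": kurtosis,
        "skewness": skewness,
        "harmonic_mean": hmean,
        "iqr": float(q75 - q25),
        "shannon_energy_entropy": shannon,
        "log_energy": log_energy,
        "n_above_half_max": threshold_count(x, max_abs / 2.0),
        "n_above_energy": threshold_count(x, total_energy),
        "n_above_5x_energy": threshold_count(x, 5.0 * total_energy),
    }


def build_feature_table(
    records: Iterable[VitalRecord],
    config: WaveletConfig | None = None,
    normalized_entropy: bool = False,
) -> pd.DataFrame:
    """One row per record, one column per (channel, level, kind, feature)
    named ``{channel}_{level}_{kind}_{feature}``, plus a binary ``label``
    column.  Column order is deterministic: channels in config order,
    vectors by level, features in ``FEATURE_NAMES`` order."""
    config = config or WaveletConfig()
    rows = []
    index = []
    labels = []
    columns: list[str] | None = None
    for record in records:
        cset = decompose_record(record, config)
        row: dict[str, float] = {}
        for vec in cset.vectors:
            feats = extract_features(vec.coeffs, normalized_entropy=normalized_entropy)
            for fname, value in feats.items():
                row[f"{vec.name}_{fname}"] = value
        if columns is None:
            columns = list(row)
        rows.append(row)
        index.append(record.record_id)
        labels.append(record.label)
    if not rows:
        raise ValueError("no records given")
    table = pd.DataFrame(rows, index=pd.Index(index, name="record_id"), columns=columns)
    table["label"] = np.asarray(labels, dtype=np.int64)
    return table
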