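"""Labeled synthetic action-potential datasets.

A dataset holds noisy, periodized membrane-potential records from the three
signal classes defined in :mod:`vmdecg.hh`.  Spatial heterogeneity across
"representative points" of a whole-heart simulation is emulated at the
single-membrane level by giving every record a random amplitude scale
(uniform on [0.8, 1.2], applied to the deflection about the resting level)
and a random circular phase shift (uniform over one beat period).  The
default configuration is 200 representative points per class with 5 noise
replicates each: 3000 records total, 1000 per class, split 90/10 into
train/test stratified by label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hh import ARRHYTHMIA_MODELS, HHParameters, StimulusProtocol, simulate_membrane

__all__ = ["SyntheticSignal", "SignalDataset", "make_dataset", "save_dataset", "load_dataset"]

LABEL_TO_INT = {m: i for i, m in enumerate(ARRHYTHMIA_MODELS)}


@dataclass
class SyntheticSignal:
    """One labeled record: samples (mV) at rate fs (Hz)."""

    samples: np.ndarray
    fs: float
    label: str
    point_id: int
    noise_sigma: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("signal must be non-empty")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not self.label:
            raise ValueError("label must be a non-empty string")


@dataclass
class SignalDataset:
    """A list of signals with a per-signal train/test split flag."""

    signals: list
    split: np.ndarray  # "train"/"test" per signal
    seed: int
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.signals)

    @property
    def X(self) -> np.ndarray:
        return np.stack([s.samples for s in self.signals])

    @property
    def label_map(self) -> dict:
        labels = {s.label for s in self.signals}
        if labels <= set(ARRHYTHMIA_MODELS):
            return LABEL_TO_INT
        return {lab: i for i, lab in enumerate(sorted(labels))}

    @property
    def y(self) -> np.ndarray:
        lm = self.label_map
        return np.array([lm[s.label] for s in self.signals])

    @property
    def train_idx(self) -> np.ndarray:
        return np.flatnonzero(self.split == "train")

    @property
    def test_idx(self) -> np.ndarray:
        return np.flatnonzero(self.split == "test")


def _prototype(model: str, stim: StimulusProtocol, params: HHParameters, fs: float,
               dt: float = 0.01) -> np.ndarray:
    """Noise-free single-beat prototype at rate fs (one stimulus period)."""
    _, v = simulate_membrane(
        params=params, model=model, stim=stim, duration=stim.period, dt=dt, fs=fs
    )
    return v


def _stratified_split(labels: np.ndarray, test_frac: float, rng: np.random.Generator):
    split = np.full(labels.shape, "train", dtype=object)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        idx = rng.permutation(idx)
        n_test = int(round(test_frac * idx.size))
        split[idx[:n_test]] = "test"
    return split.astype(str)


def make_dataset(
    n_points: int = 200,
    noise_sigma: float = 5.0,
    snr_db=None,
    record_length: int = 512,
    fs: float = 300.0,
    seed: int = 0,
    n_replicates: int = 5,
    test_frac: float = 0.10,
    stim: StimulusProtocol | None = None,
    params: HHParameters | None = None,
) -> SignalDataset:
    """Build the default three-class dataset.

    Each class contributes ``n_points * n_replicates`` records (defaults:
    200 x 5 = 1000, hence 3000 in total).  Noise is zero-mean i.i.d.
    Gaussian with standard deviation ``noise_sigma`` mV; alternatively
    ``snr_db`` may give a list of per-replicate SNR targets (dB) from which
    the noise level is derived per record.  Fully reproducible from
    ``seed``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    stim = stim or StimulusProtocol()
    params = params or HHParameters()
    period_samples = int(round(stim.period * fs / 1000.0))
    if record_length < period_samples:
        raise ValueError(
            f"record_length {record_length} shorter than one beat period "
            f"({period_samples} samples)"
        )

    rng = np.random.default_rng(seed)
    protos = {m: _prototype(m, stim, params, fs) for m in ARRHYTHMIA_MODELS}

    signals, labels = [], []
    n_tiles = int(np.ceil(record_length / period_samples)) + 1
    for model in ARRHYTHMIA_MODELS:
        proto = protos[model]
        rest = proto[0]
        for p in range(n_points):
            scale = rng.uniform(0.8, 1.2)
            shift = rng.integers(0, period_samples)
            base = np.tile(rest + scale * (proto - rest), n_tiles)
            base = np.roll(base, int(shift))[:record_length]
            for r in range(n_replicates):
                if snr_db is not None:
                    target = snr_db[r % len(snr_db)]
                    p_sig = np.var(base)
                    sigma = float(np.sqrt(p_sig / (10.0 ** (target / 10.0))))
                else:
                    sigma = float(noise_sigma)
                # always consume the stream so scale/shift draws stay aligned
                # across different noise settings of the same seed
                noise = sigma * rng.standard_normal(record_length)
                signals.append(
                    SyntheticSignal(
                        samples=base + noise,
                        fs=fs,
                        label=model,
                        point_id=p,
                        noise_sigma=sigma,
                    )
                )
                labels.append(LABEL_TO_INT[model])

    labels = np.array(labels)
    split = _stratified_split(labels, test_frac, rng)
    meta = {
        "n_points": n_points,
        "n_replicates": n_replicates,
        "record_length": record_length,
        "fs": fs,
        "noise_sigma": None if snr_db is not None else float(noise_sigma),
        "snr_db": list(snr_db) if snr_db is not None else None,
        "period_samples": period_samples,
    }
    return SignalDataset(signals=signals, split=split, seed=seed, meta=meta)


def save_dataset(ds: SignalDataset, prefix) -> None:
    """Write ``<prefix>.csv`` (manifest) and ``<prefix>.npz`` (traces)."""
    prefix = str(prefix)
    df = pd.DataFrame(
        {
            "point_id": [s.point_id for s in ds.signals],
            "label": [s.label for s in ds.signals],
            "split": ds.split,
            "noise_sigma": [s.noise_sigma for s in ds.signals],
            "fs": [s.fs for s in ds.signals],
            "seed": ds.seed,
        }
    )
    df.to_csv(prefix + ".csv", index=False)
    np.savez(prefix + ".npz", traces=ds.X, meta=json.dumps(ds.meta))


def load_dataset(prefix) -> SignalDataset:
    """Inverse of :func:`save_dataset`; round-trip is lossless."""
    prefix = str(prefix)
    df = pd.read_csv(prefix + ".csv")
    with np.load(prefix + ".npz", allow_pickle=False) as npz:
        traces = npz["traces"]
        meta = json.loads(str(npz["meta"]))
    signals = [
        SyntheticSignal(
            samples=traces[i],
            fs=float(df.fs[i]),
            label=str(df.label[i]),
            point_id=int(df.point_id[i]),
            noise_sigma=float(df.noise_sigma[i]),
        )
        for i in range(len(df))
    ]
    return SignalDataset(
        signals=signals,
        split=df.split.to_numpy().astype(str),
        seed=int(df.seed[0]) if len(df) else 0,
        meta=meta,
    )
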