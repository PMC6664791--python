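"""Sliding-window scans of long sequences: Q_MFE profiles and model
probability profiles with threshold calling.

Coordinates are 1-based with inclusive ends everywhere except BED export
(0-based half-open, per the format).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .classifier import TrainedModel, assemble_features, predict
from .errors import ConfigError, DegenerateInputError, EngineError
from .kmer import KmerSpace, LocalWindowConfig, parse_local_name
from .sequence_io import RnaSequence
from .structure import FoldingEngine, qmfe


@dataclass(frozen=True)
class ScanWindow:
    start: int  # 1-based
    end: int  # inclusive
    value: float


@dataclass(frozen=True)
class ScanProfile:
    windows: tuple[ScanWindow, ...]
    value_kind: Literal["qmfe", "probability"]
    window_length: int
    step: int

    def values(self) -> np.ndarray:
        return np.array([w.value for w in self.windows])

    def argmin(self) -> ScanWindow:
        return min(self.windows, key=lambda w: w.value)

    def argmax(self) -> ScanWindow:
        return max(self.windows, key=lambda w: w.value)


@dataclass(frozen=True)
class CallSet:
    calls: tuple[ScanWindow, ...]
    threshold: float
    polarity: Literal["above", "below"] = "above"


def _window_coords(
    seq_len: int, window: int, step: int, include_truncated: bool = False
) -> list[tuple[int, int]]:
    if window < 1 or step < 1:
        raise ConfigError("window and step must be >= 1")
    if seq_len < window:
        raise DegenerateInputError(
            f"sequence length {seq_len} shorter than window {window}"
        )
    coords = []
    start = 1
    while start + window - 1 <= seq_len:
        coords.append((start, start + window - 1))
        start += step
    if include_truncated and start <= seq_len:
        coords.append((start, seq_len))
    return coords


def scan_qmfe(
    seq: RnaSequence,
    window: int = 200,
    step: int | None = None,
    N: int = 100,
    engine: FoldingEngine = None,
    rng_seed: int = 0,
    include_truncated: bool = False,
) -> ScanProfile:
    """Per-window Q_MFE profile along a long sequence.

    Step defaults to window // 2. Engine errors are re-raised annotated
    with the window coordinates where they occurred.
    """
    if engine is None:
        raise ConfigError("scan_qmfe requires a folding engine")
    step = step or max(window // 2, 1)
    out = []
    for i, (start, end) in enumerate(
        _window_coords(seq.length, window, step, include_truncated)
    ):
        sub = RnaSequence(f"{seq.id}:{start}-{end}", seq.residues[start - 1 : end])
        try:
            result = qmfe(sub, N, engine, rng_seed=rng_seed + i)
        except EngineError as err:
            raise EngineError(
                f"engine failed in window {start}-{end}: {err}",
                raw_output=getattr(err, "raw_output", None),
            ) from err
        out.append(ScanWindow(start, end, result.qmfe))
    return ScanProfile(tuple(out), "qmfe", window, step)


def merge_calls(calls: Sequence[ScanWindow], polarity: str) -> list[ScanWindow]:
    """Merge overlapping/adjacent calls, keeping the extremal value."""
    merged: list[ScanWindow] = []
    pick = max if polarity == "above" else min
    for call in sorted(calls, key=lambda w: w.start):
        if merged and call.start <= merged[-1].end + 1:
            prev = merged[-1]
            merged[-1] = ScanWindow(
                prev.start, max(prev.end, call.end), pick(prev.value, call.value)
            )
        else:
            merged.append(call)
    return merged


def scan_predict(
    seq: RnaSequence,
    model: TrainedModel,
    window: int = 173,
    step: int = 10,
    threshold: float = 0.1,
    engine: FoldingEngine | None = None,
    n_shuffles: int = 100,
    rng_seed: int = 0,
) -> tuple[ScanProfile, CallSet]:
    """Model probability per window plus merged above-threshold calls.

    Features are assembled per window exactly as at training time (the
    model's metadata records the feature selection and window config).
    """
    selection = model.metadata.get("feature_selection", ["global-kmer"])
    window_cfg = None
    if "local-kmer" in selection:
        starts = sorted(
            {parse_local_name(n)[1] for n in model.feature_names if "_" in n}
        )
        if len(starts) >= 2:
            window_cfg = LocalWindowConfig(
                window=model.metadata.get("local_window", 20),
                step=starts[1] - starts[0],
            )
    min_len = model.metadata.get("min_sequence_length", 1)
    if window < min_len:
        raise ConfigError(
            f"window {window} shorter than model minimum {min_len}"
        )
    coords = _window_coords(seq.length, window, step)
    subs = [
        RnaSequence(f"{seq.id}:{s}-{e}", seq.residues[s - 1 : e])
        for s, e in coords
    ]
    matrix = assemble_features(
        subs,
        selection=selection,
        engine=engine,
        n_shuffles=n_shuffles,
        rng_seed=rng_seed,
        window_cfg=window_cfg,
        space=KmerSpace(),
    )
    probs = predict(model, matrix)
    windows = tuple(
        ScanWindow(s, e, float(p)) for (s, e), p in zip(coords, probs)
    )
    profile = ScanProfile(windows, "probability", window, step)
    hits = [w for w in windows if w.value > threshold]
    calls = CallSet(tuple(merge_calls(hits, "above")), threshold, "above")
    return profile, calls


def profile_to_tsv(profile: ScanProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tvalue\n")
        for w in profile.windows:
            fh.write(f"{w.start}\t{w.end}\t{w.value:.6g}\n")


def calls_to_bed(
    calls: CallSet, chrom: str, path: str | Path, name_prefix: str = "call"
) -> None:
    """Export calls as BED: 0-based half-open, score scaled to 0-1000."""
    with open(path, "w") as fh:
        for i, call in enumerate(calls.calls, start=1):
            score = int(round(min(max(call.value, 0.0), 1.0) * 1000))
            fh.write(
                f"{chrom}\t{call.start - 1}\t{call.end}\t"
                f"{name_prefix}{i}\t{score}\t+\n"
            )
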