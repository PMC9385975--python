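"""The fixed 286-dimensional per-recording feature vector.

Each LLD track is summarized by six functionals — mean, standard
deviation, and the percentile ranges left after trimming the lower and
upper 1, 5, 15 and 25% of the ordered values — over a fixed set of region
scopes:

    F0                        voiced parts               6
    intensity                 vowels, whole speech      12
    jitter                    E, O, vowels              18
    shimmer                   E, O, vowels              18
    F1, F2, BW1, BW2          E, O, vowels              72
    13 MFCC                   vowels, whole speech     156
                                        LLD subtotal   282
    articulation rate         whole speech               1
    pause ratio               whole sample               1
    ratio of transients       whole speech, sample       2
                                        total          286

The layout and names are canonical (``<lld>_<scope>_<functional>``); an
empty scope flags its features missing but never changes the length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_io import (AnnotatedRecording, RegionScope, build_scopes,
                       peak_normalize)
from .llds import FrameSpec, LLDTrackSet, extract_tracks

__all__ = [
    "FUNCTIONAL_NAMES",
    "FEATURE_NAMES",
    "TIMING_FEATURE_NAMES",
    "N_FEATURES",
    "N_LLD_FEATURES",
    "FeatureVector",
    "apply_functionals",
    "articulation_rate",
    "pause_ratio",
    "ratio_of_transients",
    "assemble_vector",
    "extract_features",
    "features_to_frame",
]

FUNCTIONAL_NAMES = ("mean", "std", "pr1", "pr5", "pr15", "pr25")

_LLD_LAYOUT: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("f0", ("voiced",)),
    ("intensity", ("all_vowels", "whole_speech")),
    ("jitter", ("vowel_E", "vowel_O", "all_vowels")),
    ("shimmer", ("vowel_E", "vowel_O", "all_vowels")),
    ("f1", ("vowel_E", "vowel_O", "all_vowels")),
    ("f2", ("vowel_E", "vowel_O", "all_vowels")),
    ("bw1", ("vowel_E", "vowel_O", "all_vowels")),
    ("bw2", ("vowel_E", "vowel_O", "all_vowels")),
) + tuple(
    (f"mfcc{c:02d}", ("all_vowels", "whole_speech")) for c in range(13)
)

TIMING_FEATURE_NAMES = (
    "articulation_rate_whole_speech",
    "pause_ratio_whole_sample",
    "transients_whole_speech",
    "transients_whole_sample",
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{lld}_{scope}_{func}"
    for lld, scopes in _LLD_LAYOUT
    for scope in scopes
    for func in FUNCTIONAL_NAMES
) + TIMING_FEATURE_NAMES

N_LLD_FEATURES = len(FEATURE_NAMES) - len(TIMING_FEATURE_NAMES)  # 282
N_FEATURES = len(FEATURE_NAMES)                                  # 286


@dataclass
class FeatureVector:
    """Ordered named feature values with a per-feature missing flag."""

    values: np.ndarray
    names: tuple[str, ...]
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.names)
                == len(self.missing_mask) == N_FEATURES):
            raise ValueError(f"feature vector must have length {N_FEATURES}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


def apply_functionals(track: np.ndarray, scope_mask: np.ndarray
                      ) -> tuple[np.ndarray, bool]:
    """The six functionals of a track restricted to a scope.

    NaN entries (undefined frames) are dropped before aggregation.
    Returns (six values, missing flag); fewer than two defined values in
    scope flag the whole block missing.  Percentiles use linear
    interpolation between order statistics; std is the population SD.
    """
    track = np.asarray(track, dtype=float)
    mask = np.asarray(scope_mask, dtype=bool)
    if len(track) != len(mask):
        raise ValueError("track and scope mask must share frame count")
    vals = track[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        return np.full(6, np.nan), True
    p = np.percentile(vals, [1, 5, 15, 25, 75, 85, 95, 99])
    out = np.array([vals.mean(), vals.std(),
                    p[7] - p[0], p[6] - p[1], p[5] - p[2], p[4] - p[3]])
    return out, False


def articulation_rate(phoneme_tier, segment_tier) -> tuple[float, bool]:
    """Phoneme segments per second of speech (pauses excluded).

    Returns (rate, flag); zero phonemes give (0.0, flagged).
    """
    speech_dur = sum(e - s for s, e, l in segment_tier if l == "speech")
    if speech_dur <= 0:
        raise ValueError("no speech: articulation rate undefined")
    n_ph = len(phoneme_tier)
    return (n_ph / speech_dur, n_ph == 0)


def pause_ratio(segment_tier, total_duration_s: float | None = None
                ) -> tuple[float, bool]:
    """Silence duration over total sample duration, in [0, 1].

    Returns (ratio, empty-speech flag).  When ``total_duration_s`` is not
    given, the tier extent is used.
    """
    silence = sum(e - s for s, e, l in segment_tier if l == "silence")
    speech = sum(e - s for s, e, l in segment_tier if l == "speech")
    total = total_duration_s if total_duration_s is not None else \
        max((e for _, e, _ in segment_tier), default=0.0)
    if total <= 0:
        raise ValueError("total duration must be positive")
    return min(silence / total, 1.0), speech == 0


def ratio_of_transients(phoneme_tier, segment_tier, frame_times,
                        transient_halfwidth_ms: float = 20.0
                        ) -> tuple[float, float]:
    """Fraction of frames near phoneme boundaries (transition density).

    A frame is transient when its centre time lies within +-halfwidth of
    any phoneme segment boundary (starts and ends).  Returns the transient
    fraction over speech frames and over all frames; the second never
    exceeds the first.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    n = len(frame_times)
    if n == 0:
        return 0.0, 0.0
    hw = transient_halfwidth_ms / 1000.0
    boundaries = sorted({b for s, e, _ in phoneme_tier for b in (s, e)})
    transient = np.zeros(n, dtype=bool)
    if hw > 0:
        for b in boundaries:
            transient |= np.abs(frame_times - b) <= hw
    speech = np.zeros(n, dtype=bool)
    for s, e, l in segment_tier:
        if l == "speech":
            speech |= (frame_times >= s) & (frame_times < e)
    n_speech = int(speech.sum())
    over_speech = (transient & speech).sum() / n_speech if n_speech else 0.0
    over_sample = (transient & speech).sum() / n
    return float(over_speech), float(over_sample)


def assemble_vector(tracks: LLDTrackSet, scopes: dict[str, RegionScope],
                    segment_tier, phoneme_tier,
                    transient_halfwidth_ms: float = 20.0,
                    total_duration_s: float | None = None) -> FeatureVector:
    """Assemble the canonical 286-dimensional vector.

    Missing flags propagate from empty scopes and degenerate timing
    features; the length and ordering never change.
    """
    named = tracks.named_tracks()
    values = np.empty(N_FEATURES)
    missing = np.zeros(N_FEATURES, dtype=bool)
    i = 0
    for lld, scope_names in _LLD_LAYOUT:
        for scope in scope_names:
            block, flag = apply_functionals(named[lld],
                                            scopes[scope].frame_mask)
            values[i:i + 6] = block
            missing[i:i + 6] = flag
            i += 6
    assert i == N_LLD_FEATURES

    ar, ar_flag = articulation_rate(phoneme_tier, segment_tier)
    pr, pr_flag = pause_ratio(segment_tier, total_duration_s)
    tr_speech, tr_sample = ratio_of_transients(
        phoneme_tier, segment_tier, tracks.frame_times,
        transient_halfwidth_ms)
    values[i:i + 4] = (ar, pr, tr_speech, tr_sample)
    missing[i:i + 4] = (ar_flag, pr_flag, False, False)
    return FeatureVector(values=values, names=FEATURE_NAMES,
                         missing_mask=missing)


def extract_features(recording: AnnotatedRecording,
                     frame_spec: FrameSpec = FrameSpec(),
                     transient_halfwidth_ms: float = 20.0) -> FeatureVector:
    """End-to-end: peak-normalize, extract LLDs, aggregate to 286 features."""
    rec = AnnotatedRecording(
        samples=peak_normalize(recording.samples),
        sample_rate_hz=recording.sample_rate_hz,
        segment_tier=list(recording.segment_tier),
        phoneme_tier=list(recording.phoneme_tier))
    tracks = extract_tracks(rec, frame_spec)
    scopes = build_scopes(rec, tracks.frame_times, tracks.voiced_mask)
    return assemble_vector(tracks, scopes, rec.segment_tier,
                           rec.phoneme_tier, transient_halfwidth_ms,
                           total_duration_s=rec.duration_s)


def features_to_frame(vectors: dict[str, FeatureVector]) -> pd.DataFrame:
    """Stack per-recording vectors into a subject-keyed feature table."""
    df = pd.DataFrame({sid: fv.as_series() for sid, fv in vectors.items()}).T
    df.index.name = "subject_id"
    return df.reset_index()
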