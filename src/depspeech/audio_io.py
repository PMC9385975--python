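"""Recording + annotation I/O and region scoping.

A recording arrives as mono PCM WAV plus a two-tier annotation: a
speech/silence tier and a phoneme tier (SAMPA labels) nested inside the
speech parts.  Features downstream are computed over six region scopes:
the vowel E, the vowel O, all vowels, the whole speech part, the whole
sample, and the voiced frames.  Intervals are half-open [start, end) in
seconds; a frame belongs to a segment iff its centre time falls inside.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "Interval",
    "AnnotatedRecording",
    "RegionScope",
    "SCOPE_NAMES",
    "HUNGARIAN_SAMPA_VOWELS",
    "peak_normalize",
    "load_wav",
    "save_wav",
    "load_annotation",
    "save_annotation",
    "build_scopes",
]

#: Hungarian SAMPA vowel inventory (short and long); configurable in
#: :func:`build_scopes`.  Only E and O are singled out by name downstream.
HUNGARIAN_SAMPA_VOWELS = (
    "A:", "E", "O", "e:", "i", "i:", "o", "o:",
    "2", "2:", "u", "u:", "y", "y:",
)

SCOPE_NAMES = ("vowel_E", "vowel_O", "all_vowels",
               "whole_speech", "whole_sample", "voiced")

Interval = tuple[float, float, str]


def _validate_tier(tier: Sequence[Interval], name: str,
                   duration: float | None = None) -> None:
    prev_end = -np.inf
    for iv in tier:
        start, end, label = iv
        if not start < end:
            raise ValueError(f"{name} tier: empty/reversed interval {iv}")
        if start < prev_end:
            raise ValueError(f"{name} tier: overlapping/unordered interval {iv}")
        if start < 0 or (duration is not None and end > duration + 1e-9):
            raise ValueError(f"{name} tier: interval {iv} outside [0, duration]")
        prev_end = end


@dataclass
class AnnotatedRecording:
    """Waveform plus its two-tier segmentation.

    samples: amplitude sequence (float, full-scale units)
    sample_rate_hz: samples per second
    segment_tier: (start_s, end_s, label) with label in {"speech", "silence"}
    phoneme_tier: (start_s, end_s, SAMPA label), inside speech segments
    """

    samples: np.ndarray
    sample_rate_hz: int
    segment_tier: list[Interval] = field(default_factory=list)
    phoneme_tier: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("expected a mono (1-D) waveform")
        self.validate()

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def validate(self) -> None:
        dur = self.duration_s
        _validate_tier(self.segment_tier, "segment", dur)
        _validate_tier(self.phoneme_tier, "phoneme", dur)
        bad = {lbl for _, _, lbl in self.segment_tier} - {"speech", "silence"}
        if bad:
            raise ValueError(f"segment labels must be speech/silence, got {bad}")
        speech = [(s, e) for s, e, lbl in self.segment_tier if lbl == "speech"]
        for iv in self.phoneme_tier:
            s, e, _ = iv
            if not any(ss - 1e-9 <= s and e <= se + 1e-9 for ss, se in speech):
                raise ValueError(
                    f"phoneme interval {iv} not inside any speech segment")


def peak_normalize(samples: np.ndarray) -> np.ndarray:
    """Scale so that max |sample| is 1.0 (digital full scale).

    Removes recording-gain differences; the waveform shape is preserved up
    to a positive scalar.  An all-zero signal has no defined gain.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    peak = np.max(np.abs(x))
    if peak == 0.0:
        raise ValueError("all-zero signal: peak normalization undefined")
    return x / peak


def save_wav(path, samples: np.ndarray, sample_rate_hz: int) -> None:
    """Write 16-bit PCM mono WAV (values clipped to [-1, 1])."""
    x = np.clip(np.asarray(samples, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), int(sample_rate_hz),
                  np.round(x * 32767.0).astype(np.int16))


def load_wav(path, target_rate_hz: int | None = 16000) -> tuple[np.ndarray, int]:
    """Read a PCM WAV as float in [-1, 1]; resample to the working rate."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        raise ValueError("expected mono audio")
    if np.issubdtype(data.dtype, np.integer):
        x = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        x = data.astype(float)
    if target_rate_hz is not None and rate != target_rate_hz:
        from math import gcd
        g = gcd(int(target_rate_hz), int(rate))
        x = resample_poly(x, target_rate_hz // g, rate // g)
        rate = target_rate_hz
    return x, int(rate)


# ---------------------------------------------------------------------------
# Annotation files: Praat TextGrid (long format) and a 3-column TSV dialect.
# The TSV carries both tiers in one file; a line "# tier: <name>" starts a
# tier and data rows are "start_s<TAB>end_s<TAB>label".

def save_annotation(path, segment_tier: Sequence[Interval],
                    phoneme_tier: Sequence[Interval],
                    dialect: str = "tsv", duration_s: float | None = None) -> None:
    path = Path(path)
    if dialect == "tsv":
        lines = []
        for name, tier in (("segments", segment_tier), ("phonemes", phoneme_tier)):
            lines.append(f"# tier: {name}")
            for s, e, lbl in tier:
                lines.append(f"{s:.6f}\t{e:.6f}\t{lbl}")
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "textgrid":
        path.write_text(_format_textgrid(segment_tier, phoneme_tier, duration_s))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _format_textgrid(segment_tier, phoneme_tier, duration_s=None) -> str:
    tiers = [("segments", list(segment_tier)), ("phonemes", list(phoneme_tier))]
    xmax = duration_s
    if xmax is None:
        xmax = max((e for t in tiers for _, e, _ in t[1]), default=0.0)
    out = _stdio.StringIO()
    out.write('File type = "ooTextFile"\nObject class = "TextGrid"\n\n')
    out.write(f"xmin = 0\nxmax = {xmax:.6f}\ntiers? <exists>\n")
    out.write(f"size = {len(tiers)}\nitem []:\n")
    for ti, (name, tier) in enumerate(tiers, start=1):
        out.write(f"    item [{ti}]:\n")
        out.write('        class = "IntervalTier"\n')
        out.write(f'        name = "{name}"\n')
        out.write(f"        xmin = 0\n        xmax = {xmax:.6f}\n")
        out.write(f"        intervals: size = {len(tier)}\n")
        for ii, (s, e, lbl) in enumerate(tier, start=1):
            out.write(f"        intervals [{ii}]:\n")
            out.write(f"            xmin = {s:.6f}\n")
            out.write(f"            xmax = {e:.6f}\n")
            out.write(f'            text = "{lbl}"\n')
    return out.getvalue()


def _parse_textgrid(text: str) -> dict[str, list[Interval]]:
    tiers: dict[str, list[Interval]] = {}
    cur_name = None
    cur: dict[str, float | str] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("name ="):
            cur_name = line.split("=", 1)[1].strip().strip('"')
            tiers[cur_name] = []
            cur = {}
        elif line.startswith("intervals ["):
            cur = {}
        elif line.startswith("xmin =") and cur_name is not None:
            cur["xmin"] = float(line.split("=", 1)[1])
        elif line.startswith("xmax =") and cur_name is not None:
            cur["xmax"] = float(line.split("=", 1)[1])
        elif line.startswith("text =") and cur_name is not None:
            lbl = line.split("=", 1)[1].strip().strip('"')
            if "xmin" in cur and "xmax" in cur:
                tiers[cur_name].append((float(cur["xmin"]),
                                        float(cur["xmax"]), lbl))
            cur = {}
    return tiers


def load_annotation(path, dialect: str = "tsv"
                    ) -> tuple[list[Interval], list[Interval]]:
    """Read a two-tier annotation; labels are preserved verbatim.

    Returns (segment_tier, phoneme_tier).  Overlapping or unordered
    intervals, or a phoneme outside every speech segment, raise a
    validation error naming the offending interval.
    """
    if dialect not in ("tsv", "textgrid"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = Path(path).read_text()
    if dialect == "tsv":
        tiers: dict[str, list[Interval]] = {}
        cur: list[Interval] | None = None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("# tier:"):
                cur = tiers.setdefault(line.split(":", 1)[1].strip(), [])
            elif not line.startswith("#"):
                if cur is None:
                    raise ValueError("TSV row before any '# tier:' header")
                s, e, lbl = line.split("\t")
                cur.append((float(s), float(e), lbl))
    elif dialect == "textgrid":
        tiers = _parse_textgrid(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    segment_tier = tiers.get("segments", [])
    phoneme_tier = tiers.get("phonemes", [])
    # drop empty-label padding intervals a TextGrid may carry
    segment_tier = [iv for iv in segment_tier if iv[2]]
    phoneme_tier = [iv for iv in phoneme_tier if iv[2]]
    _validate_tier(segment_tier, "segment")
    _validate_tier(phoneme_tier, "phoneme")
    speech = [(s, e) for s, e, lbl in segment_tier if lbl == "speech"]
    for iv in phoneme_tier:
        if not any(ss - 1e-9 <= iv[0] and iv[1] <= se + 1e-9 for ss, se in speech):
            raise ValueError(f"phoneme interval {iv} not inside speech")
    return segment_tier, phoneme_tier


# ---------------------------------------------------------------------------
# Region scopes

@dataclass
class RegionScope:
    """A named boolean frame mask over which functionals are computed."""

    name: str
    frame_mask: np.ndarray
    empty: bool = False

    def __post_init__(self) -> None:
        self.frame_mask = np.asarray(self.frame_mask, dtype=bool)
        self.empty = not bool(self.frame_mask.any())


def _mask_for_intervals(frame_times: np.ndarray,
                        intervals: list[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros(len(frame_times), dtype=bool)
    for s, e in intervals:
        mask |= (frame_times >= s) & (frame_times < e)  # half-open [s, e)
    return mask


def build_scopes(recording: AnnotatedRecording, frame_times: np.ndarray,
                 voiced_mask: np.ndarray | None = None,
                 vowel_labels: Sequence[str] = HUNGARIAN_SAMPA_VOWELS,
                 ) -> dict[str, RegionScope]:
    """Build the six region scopes as frame masks over common frame times.

    A frame belongs to a segment iff its centre time lies in [start, end).
    The voiced scope intersects the supplied voicing decision with the
    speech parts (all-false when no voicing mask is given).
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size and np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be strictly increasing")
    vowels = set(vowel_labels)
    seg = {
        "vowel_E": [(s, e) for s, e, l in recording.phoneme_tier if l == "E"],
        "vowel_O": [(s, e) for s, e, l in recording.phoneme_tier if l == "O"],
        "all_vowels": [(s, e) for s, e, l in recording.phoneme_tier
                       if l in vowels],
        "whole_speech": [(s, e) for s, e, l in recording.segment_tier
                         if l == "speech"],
    }
    scopes = {name: RegionScope(name, _mask_for_intervals(frame_times, ivs))
              for name, ivs in seg.items()}
    scopes["whole_sample"] = RegionScope(
        "whole_sample", np.ones(len(frame_times), dtype=bool))
    speech_mask = scopes["whole_speech"].frame_mask
    if voiced_mask is None:
        vmask = np.zeros(len(frame_times), dtype=bool)
    else:
        vmask = np.asarray(voiced_mask, dtype=bool) & speech_mask
    scopes["voiced"] = RegionScope("voiced", vmask)
    return scopes
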