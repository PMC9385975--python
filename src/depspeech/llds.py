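"""Frame-level low-level descriptors (LLDs).

Per 30 ms Hamming frame with 10 ms step: intensity (dB), fundamental
frequency with a voicing decision, local jitter and shimmer (from
F0-guided pulse marks), the first two formant frequencies and bandwidths
(LPC root-finding), and 13 MFCCs.  F0, jitter, shimmer and formants are
defined only on voiced frames (NaN elsewhere); intensity and MFCCs are
defined on every frame.

Algorithm choices (the source names none): F0 by normalized
autocorrelation with parabolic peak interpolation over 60-400 Hz;
jitter/shimmer in the "local" variant (mean absolute cycle-to-cycle
difference over the cycle mean); LPC by the autocorrelation method
(Levinson-Durbin) after 0.97 pre-emphasis, formants from polynomial roots
with a 700 Hz bandwidth admissibility ceiling; MFCC from a 26-filter mel
bank spanning 20 Hz to min(8 kHz, Nyquist), coefficients c0-c12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft
from scipy.signal import lfilter

from .audio_io import AnnotatedRecording

__all__ = [
    "FrameSpec",
    "LLDTrackSet",
    "frame_signal",
    "intensity_db",
    "f0_autocorr",
    "jitter_shimmer",
    "extract_pulses",
    "jitter_shimmer_tracks",
    "formants_lpc",
    "mfcc_13",
    "extract_tracks",
]

INTENSITY_FLOOR = 1e-10  # mean-square floor so silence stays finite


@dataclass(frozen=True)
class FrameSpec:
    """Analysis framing: 30 ms Hamming window, 10 ms step."""

    window_ms: float = 30.0
    step_ms: float = 10.0
    window_shape: str = "hamming"

    def validate(self) -> None:
        if not (0 < self.step_ms <= self.window_ms):
            raise ValueError("need 0 < step <= window")
        if self.window_shape != "hamming":
            raise ValueError("only the Hamming window is supported")

    def sizes(self, rate: int) -> tuple[int, int]:
        return (int(round(self.window_ms * rate / 1000.0)),
                int(round(self.step_ms * rate / 1000.0)))


@dataclass
class LLDTrackSet:
    """All LLD tracks on a common frame grid (NaN where undefined)."""

    frame_times: np.ndarray
    intensity_db: np.ndarray
    f0_hz: np.ndarray
    voiced_mask: np.ndarray
    jitter_local: np.ndarray
    shimmer_local: np.ndarray
    f1_hz: np.ndarray
    f2_hz: np.ndarray
    bw1_hz: np.ndarray
    bw2_hz: np.ndarray
    mfcc: np.ndarray  # (n_frames, 13)

    def __post_init__(self) -> None:
        n = len(self.frame_times)
        for name in ("intensity_db", "f0_hz", "voiced_mask", "jitter_local",
                     "shimmer_local", "f1_hz", "f2_hz", "bw1_hz", "bw2_hz"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"track {name} length != frame count")
        if self.mfcc.shape != (n, 13):
            raise ValueError("mfcc must be (n_frames, 13)")

    def named_tracks(self) -> dict[str, np.ndarray]:
        out = {
            "f0": self.f0_hz, "intensity": self.intensity_db,
            "jitter": self.jitter_local, "shimmer": self.shimmer_local,
            "f1": self.f1_hz, "f2": self.f2_hz,
            "bw1": self.bw1_hz, "bw2": self.bw2_hz,
        }
        for c in range(13):
            out[f"mfcc{c:02d}"] = self.mfcc[:, c]
        return out


def frame_signal(samples: np.ndarray, rate: int,
                 spec: FrameSpec = FrameSpec(), window: bool = True
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Slice into overlapping frames; frame count floor((N-W)/H) + 1.

    Returns (frames, frame_times); times are frame centres in seconds.
    With ``window`` the frames are Hamming-weighted.
    """
    spec.validate()
    x = np.asarray(samples, dtype=float)
    w, h = spec.sizes(rate)
    if len(x) < w:
        raise ValueError(
            f"signal ({len(x)} samples) shorter than one window ({w})")
    n_frames = (len(x) - w) // h + 1
    idx = np.arange(w)[None, :] + h * np.arange(n_frames)[:, None]
    frames = x[idx]
    if window:
        frames = frames * np.hamming(w)[None, :]
    frame_times = (h * np.arange(n_frames) + w / 2.0) / rate
    return frames, frame_times


def intensity_db(frames: np.ndarray) -> np.ndarray:
    """10 log10 of the mean squared (windowed) amplitude, floored."""
    ms = np.mean(frames ** 2, axis=1)
    return 10.0 * np.log10(np.maximum(ms, INTENSITY_FLOOR))


def f0_autocorr(samples: np.ndarray, rate: int,
                spec: FrameSpec = FrameSpec(),
                f0_min: float = 60.0, f0_max: float = 400.0,
                voicing_threshold: float = 0.45,
                silence_db: float = -45.0
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Autocorrelation F0 with parabolic interpolation.

    Returns (f0_hz, voiced_mask, frame_times).  A frame is voiced when its
    peak normalized autocorrelation within the F0 lag range exceeds the
    voicing threshold and the frame is not near-silent; unvoiced frames
    get NaN.
    """
    if not (0 < f0_min < f0_max < rate / 2):
        raise ValueError("need 0 < f0_min < f0_max < Nyquist")
    frames, frame_times = frame_signal(samples, rate, spec, window=False)
    frames = frames - frames.mean(axis=1, keepdims=True)
    w = frames.shape[1]
    lag_min = max(2, int(np.floor(rate / f0_max)))
    lag_max = min(w - 2, int(np.ceil(rate / f0_min)))
    if lag_max <= lag_min:
        raise ValueError("window too short for the requested F0 range")

    # full autocorrelation via FFT, all frames at once
    nfft = int(2 ** np.ceil(np.log2(2 * w)))
    spec_f = np.fft.rfft(frames, nfft, axis=1)
    ac = np.fft.irfft(spec_f * np.conj(spec_f), nfft, axis=1)[:, :w]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = np.inf
    norm = ac / r0[:, None]

    loud = intensity_db(frames * np.hamming(w)[None, :]) > silence_db
    band = norm[:, lag_min:lag_max + 1]
    peak_rel = np.argmax(band, axis=1)
    peak_lag = peak_rel + lag_min
    peak_val = band[np.arange(len(band)), peak_rel]
    voiced = (peak_val >= voicing_threshold) & loud

    f0 = np.full(len(frames), np.nan)
    for i in np.where(voiced)[0]:
        lag = peak_lag[i]
        # parabolic refinement around the autocorrelation peak
        if 1 <= lag < w - 1:
            ym, y0, yp = norm[i, lag - 1], norm[i, lag], norm[i, lag + 1]
            denom = ym - 2 * y0 + yp
            delta = 0.5 * (ym - yp) / denom if denom != 0 else 0.0
            lag = lag + np.clip(delta, -1, 1)
        f0[i] = rate / lag
    return f0, voiced, frame_times


def jitter_shimmer(period_sequence: np.ndarray,
                   amplitude_sequence: np.ndarray
                   ) -> tuple[float, float]:
    """Local jitter and shimmer of a cycle sequence (dimensionless ratios).

    jitter  = mean |T_i - T_{i-1}| / mean T_i
    shimmer = mean |A_i - A_{i-1}| / mean A_i

    Needs at least two periods; amplitudes may have one more entry than
    periods (one per pulse) — the trailing entries are used as given.
    """
    T = np.asarray(period_sequence, dtype=float)
    A = np.asarray(amplitude_sequence, dtype=float)
    if len(T) < 2:
        raise ValueError("need at least 2 consecutive periods")
    jit = float(np.mean(np.abs(np.diff(T))) / np.mean(T))
    if len(A) >= 2:
        shim = float(np.mean(np.abs(np.diff(A))) / np.mean(A))
    else:
        shim = np.nan
    return jit, shim


def _lpc_residual(x: np.ndarray, order: int = 12,
                  preemphasis: float = 0.97) -> np.ndarray:
    """Inverse-filter a voiced stretch: LPC whitening leaves sharp spikes
    at the glottal pulse instants, free of formant ringing."""
    xe = np.append(x[0], x[1:] - preemphasis * x[:-1])
    r = np.correlate(xe, xe, "full")[len(xe) - 1:len(xe) + order]
    if r[0] <= 0:
        return np.abs(xe)
    a = _levinson(r, order)
    return np.abs(lfilter(a, [1.0], xe))


def extract_pulses(samples: np.ndarray, rate: int, f0_hz: np.ndarray,
                   voiced_mask: np.ndarray, frame_times: np.ndarray,
                   region_ids: np.ndarray | None = None
                   ) -> list[tuple[np.ndarray, np.ndarray, float, float]]:
    """F0-guided pulse marking on each contiguous voiced stretch.

    Each maximal run of voiced frames is inverse-filtered (LPC residual),
    and pulse marks are successive residual-magnitude peaks constrained to
    [0.7, 1.3] median-F0 periods apart; the residual is used because
    formant ringing in the raw waveform shifts peak positions and
    amplitudes, biasing jitter and shimmer.  ``region_ids`` (e.g. the
    phoneme index per frame) additionally splits stretches at region
    changes, since the constant-expected-period search is only valid
    while F0 is locally stable.  Returns a list of
    (pulse_times_s, pulse_amplitudes, stretch_start_s, stretch_end_s).
    """
    x = np.asarray(samples, dtype=float)
    out = []
    vm = np.asarray(voiced_mask, dtype=bool)
    if region_ids is None:
        run_key = vm.view(np.int8).copy()
    else:
        rid = np.asarray(region_ids)
        run_key = np.where(vm, rid + 2, 0).astype(np.int64)  # 0 = unvoiced
    change = np.flatnonzero(np.diff(run_key) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(vm)]))
    voiced_runs = [(a, b) for a, b in zip(starts, ends) if run_key[a] != 0]
    for a, b in voiced_runs:  # frames [a, b) voiced, same region
        t_start, t_end = frame_times[a], frame_times[b - 1]
        f0_med = np.nanmedian(f0_hz[a:b])
        if not np.isfinite(f0_med):
            continue
        period = rate / f0_med  # samples
        i0 = max(0, int(round(t_start * rate - period)))
        i1 = min(len(x), int(round(t_end * rate + period)))
        if i1 - i0 < 2 * period:
            continue
        mag = _lpc_residual(x[i0:i1])
        mag[:14] = 0.0  # inverse-filter startup transient is not a pulse
        # first mark: global max of the first two expected periods
        seg_end = min(len(mag), int(round(2 * period)))
        pos = [int(np.argmax(mag[:seg_end]))]
        while True:
            lo = pos[-1] + int(round(0.7 * period))
            hi = pos[-1] + int(round(1.3 * period))
            if hi >= len(mag):
                break
            nxt = lo + int(np.argmax(mag[lo:hi]))
            pos.append(nxt)
        if len(pos) < 3:
            continue
        pos_arr = np.asarray(pos)
        amps = mag[pos_arr]
        # trim anomalous edge marks: phoneme/segment boundary transients
        # produce residual spikes (or shadows) far from the stretch median
        med = np.median(amps)
        keep = (amps >= 0.5 * med) & (amps <= 2.0 * med)
        first = int(np.argmax(keep))
        last = len(keep) - int(np.argmax(keep[::-1]))
        pos_arr, amps = pos_arr[first:last], amps[first:last]
        if len(pos_arr) < 3:
            continue
        out.append(((i0 + pos_arr) / rate, amps,
                    float(t_start), float(t_end)))
    return out


def jitter_shimmer_tracks(samples: np.ndarray, rate: int,
                          f0_hz: np.ndarray, voiced_mask: np.ndarray,
                          frame_times: np.ndarray,
                          region_ids: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame local jitter/shimmer, constant over each voiced stretch.

    Each voiced stretch (split at region changes, see
    :func:`extract_pulses`) gets the scalar local jitter/shimmer of its
    pulse sequence; frames outside voiced stretches (or stretches with
    fewer than three pulses) stay NaN.
    """
    n = len(frame_times)
    jit = np.full(n, np.nan)
    shim = np.full(n, np.nan)
    for times, amps, t0, t1 in extract_pulses(samples, rate, f0_hz,
                                              voiced_mask, frame_times,
                                              region_ids):
        periods = np.diff(times)
        if len(periods) < 2:
            continue
        j, s = jitter_shimmer(periods, amps)
        sel = (frame_times >= t0) & (frame_times <= t1) & voiced_mask
        jit[sel] = j
        shim[sel] = s
    return jit, shim


def _levinson(r: np.ndarray, order: int) -> np.ndarray:
    """LPC coefficients a[1..p] (prediction polynomial 1 - sum a_k z^-k)."""
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    if err <= 0:
        return a
    for i in range(1, order + 1):
        acc = r[i] + np.dot(a[1:i], r[i - 1:0:-1])
        k = -acc / err
        a[1:i + 1] = a[1:i + 1] + k * a[i - 1::-1][:i]
        a[i] = k
        err *= (1.0 - k * k)
        if err <= 0:
            break
    return a


def formants_lpc(frames: np.ndarray, rate: int, order: int | None = None,
                 preemphasis: float = 0.97, bw_ceiling_hz: float = 700.0,
                 f_floor_hz: float = 90.0
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """First two formant frequencies and bandwidths per frame via LPC.

    Autocorrelation-method LPC on pre-emphasized Hamming frames; formant
    candidates are polynomial roots inside the unit circle with angle in
    (0, pi), frequency above ``f_floor_hz`` and bandwidth below
    ``bw_ceiling_hz``; the two lowest admissible frequencies become F1/F2.
    Frames with fewer than two admissible roots get NaN.  The default
    order (12 at 16 kHz) is deliberately moderate: higher orders start
    modelling individual harmonics of high-pitched voices as spurious
    narrow resonances.
    """
    if order is None:
        order = max(8, int(round(rate / 1600.0)) + 2)
    n, w = frames.shape
    f1 = np.full(n, np.nan)
    f2 = np.full(n, np.nan)
    b1 = np.full(n, np.nan)
    b2 = np.full(n, np.nan)
    win = np.hamming(w)
    for i in range(n):
        fr = frames[i]
        fr = np.append(fr[0], fr[1:] - preemphasis * fr[:-1]) * win
        r = np.correlate(fr, fr, "full")[w - 1:w + order]
        if r[0] <= 0:
            continue
        a = _levinson(r, order)
        roots = np.roots(a)
        roots = roots[(np.abs(roots) < 1.0) & (roots.imag > 0)]
        if roots.size == 0:
            continue
        freqs = np.angle(roots) * rate / (2 * np.pi)
        bws = -np.log(np.abs(roots)) * rate / np.pi
        ok = (freqs > f_floor_hz) & (freqs < rate / 2 - 50) & \
             (bws < bw_ceiling_hz) & (bws > 0)
        freqs, bws = freqs[ok], bws[ok]
        if len(freqs) < 2:
            continue
        order_idx = np.argsort(freqs)
        f1[i], f2[i] = freqs[order_idx[0]], freqs[order_idx[1]]
        b1[i], b2[i] = bws[order_idx[0]], bws[order_idx[1]]
    return f1, f2, b1, b2


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(rate: int, nfft: int, n_filters: int = 26,
                    f_lo: float = 20.0, f_hi: float = 8000.0) -> np.ndarray:
    f_hi = min(f_hi, rate / 2.0)
    mels = np.linspace(_mel(f_lo), _mel(f_hi), n_filters + 2)
    bins = np.floor((nfft + 1) * _mel_inv(mels) / rate).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for j in range(n_filters):
        a, b, c = bins[j], bins[j + 1], bins[j + 2]
        if b > a:
            fb[j, a:b] = (np.arange(a, b) - a) / (b - a)
        if c > b:
            fb[j, b:c] = (c - np.arange(b, c)) / (c - b)
    return fb


def mfcc_13(frames: np.ndarray, rate: int, n_filters: int = 26,
            f_lo: float = 20.0, f_hi: float = 8000.0) -> np.ndarray:
    """13 mel-frequency cepstral coefficients (c0..c12) per frame.

    Power spectrum of the (already windowed) frame, triangular mel bank,
    log with floor, orthonormal DCT-II.  Deterministic for a fixed
    filterbank configuration; silence maps to finite values.
    """
    w = frames.shape[1]
    nfft = int(2 ** np.ceil(np.log2(w)))
    power = np.abs(rfft(frames, nfft, axis=1)) ** 2 / nfft
    fb = _mel_filterbank(rate, nfft, n_filters, f_lo, f_hi)
    energies = np.log(np.maximum(power @ fb.T, 1e-12))
    return dct(energies, type=2, norm="ortho", axis=1)[:, :13]


def extract_tracks(recording: AnnotatedRecording,
                   spec: FrameSpec = FrameSpec(),
                   f0_min: float = 60.0, f0_max: float = 400.0
                   ) -> LLDTrackSet:
    """Run every LLD on one recording, on a common frame grid.

    Voicing is additionally restricted to annotated speech segments, so
    resonant silence or breath noise outside speech never contributes to
    the voiced-scope features.
    """
    x = recording.samples
    rate = recording.sample_rate_hz
    frames, frame_times = frame_signal(x, rate, spec, window=True)
    f0, voiced, _ = f0_autocorr(x, rate, spec, f0_min, f0_max)

    in_speech = np.zeros(len(frame_times), dtype=bool)
    for s, e, lbl in recording.segment_tier:
        if lbl == "speech":
            in_speech |= (frame_times >= s) & (frame_times < e)
    if recording.segment_tier:
        voiced = voiced & in_speech
    # close single-frame voicing dropouts so pulse stretches stay whole
    gaps = np.flatnonzero(~voiced[1:-1] & voiced[:-2] & voiced[2:]) + 1
    if gaps.size:
        voiced[gaps] = True
        f0[gaps] = 0.5 * (f0[gaps - 1] + f0[gaps + 1])
    f0 = np.where(voiced, f0, np.nan)

    # phoneme identity per frame: pulse stretches split at boundaries,
    # where the expected-period assumption breaks
    region = np.full(len(frame_times), -1)
    for pi, (s, e, _) in enumerate(recording.phoneme_tier):
        region[(frame_times >= s) & (frame_times < e)] = pi
    jit, shim = jitter_shimmer_tracks(x, rate, f0, voiced, frame_times,
                                      region_ids=region)
    raw_frames, _ = frame_signal(x, rate, spec, window=False)
    f1, f2, b1, b2 = formants_lpc(raw_frames, rate)
    for tr in (f1, f2, b1, b2):
        tr[~voiced] = np.nan
    return LLDTrackSet(
        frame_times=frame_times,
        intensity_db=intensity_db(frames),
        f0_hz=f0, voiced_mask=voiced,
        jitter_local=jit, shimmer_local=shim,
        f1_hz=f1, f2_hz=f2, bw1_hz=b1, bw2_hz=b2,
        mfcc=mfcc_13(frames, rate),
    )
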