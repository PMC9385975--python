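"""Synthetic speech and cohort generation with known ground truth.

The study database (read speech from depressed and healthy Hungarian
adults, BDI for everyone, HAMD for a depression-skewed ~20% subset) is not
public, so this module provides controllable stand-ins:

* :func:`synthesize_phonation` — a source-filter vowel: an impulse train
  with exponential glottal decay excites a cascade of second-order formant
  resonators.  Per-cycle periods and amplitudes are perturbed to produce
  jitter and shimmer, and the *realized* sequences are returned, so the
  acoustic ground truth is exact rather than nominal.
* :func:`synthesize_reading` — concatenates labelled phonations and pauses
  into an annotated recording whose tier boundaries are exact by
  construction.
* :func:`generate_cohort` — a subject table (gender, age, BDI, HAMD for a
  severity-skewed subset) plus a feature matrix linearly loaded on a latent
  severity, emulating the population structure of the study cohort
  (n = 218, 66% female, near-uniform severity among the depressed, about
  half healthy, BDI–HAMD correlation configurable in the literature range
  0.4–0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .audio_io import AnnotatedRecording, Interval
from .scales import assign_h2b

__all__ = [
    "PhonationSpec",
    "PhonationTruth",
    "CohortSpec",
    "synthesize_phonation",
    "synthesize_reading",
    "generate_cohort",
    "VOWEL_FORMANTS",
]

#: Reference (centre Hz, bandwidth Hz) pairs for the SAMPA vowels used in
#: synthetic readings.  Values are generic adult targets, not speaker data.
VOWEL_FORMANTS: dict[str, tuple[tuple[float, float], ...]] = {
    "E": ((550.0, 80.0), (1750.0, 120.0)),
    "O": ((600.0, 90.0), (1000.0, 120.0)),
    "i": ((300.0, 70.0), (2200.0, 150.0)),
    "o": ((450.0, 80.0), (900.0, 110.0)),
    "u": ((350.0, 70.0), (800.0, 100.0)),
    "A:": ((700.0, 110.0), (1200.0, 130.0)),
}


@dataclass(frozen=True)
class PhonationSpec:
    """Ground-truth parameters of one synthetic sustained phonation.

    jitter_pct / shimmer_pct target the *local* perturbation measure
    (mean absolute cycle-to-cycle difference over the mean), in percent.
    """

    f0_hz: float = 120.0
    jitter_pct: float = 0.0
    shimmer_pct: float = 0.0
    formants_hz: tuple[tuple[float, float], ...] = VOWEL_FORMANTS["E"]
    duration_s: float = 1.0
    sample_rate_hz: int = 16000
    seed: int = 0

    def validate(self) -> None:
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if not (0 <= self.jitter_pct < 50 and 0 <= self.shimmer_pct < 50):
            raise ValueError("jitter/shimmer must be in [0, 50)%")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        nyq = self.sample_rate_hz / 2
        if any(f >= nyq for f, _ in self.formants_hz):
            raise ValueError("formant centres must lie below Nyquist")
        if any(b <= 0 for _, b in self.formants_hz):
            raise ValueError("formant bandwidths must be positive")


@dataclass(frozen=True)
class PhonationTruth:
    """Realized per-cycle ground truth of a synthesized phonation."""

    spec: PhonationSpec
    pulse_times_s: np.ndarray      # glottal pulse instants (sample-exact)
    periods_s: np.ndarray          # diffs of pulse times
    amplitudes: np.ndarray         # per-pulse excitation amplitude


def _resonator_coeffs(f_hz: float, bw_hz: float, rate: int):
    # second-order all-pole resonator (Klatt-style), unity DC-ish gain
    r = np.exp(-np.pi * bw_hz / rate)
    theta = 2.0 * np.pi * f_hz / rate
    a1, a2 = 2.0 * r * np.cos(theta), -r * r
    b0 = 1.0 - a1 - a2
    return [b0], [1.0, -a1, -a2]


def synthesize_phonation(spec: PhonationSpec
                         ) -> tuple[np.ndarray, PhonationTruth]:
    """Render one phonation; return (waveform, realized ground truth).

    Pulse instants are quantized to the sample grid, and the returned
    period sequence is the diff of the quantized instants — the measurement
    oracle downstream is therefore exact, not subject to rounding of the
    nominal f0.  For i.i.d. Gaussian period perturbations of SD sigma the
    expected local jitter is (2 sigma / sqrt(pi)) / T0, so sigma is chosen
    as jitter_pct/100 * T0 * sqrt(pi)/2 (same construction for shimmer).
    Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rate = spec.sample_rate_hz
    n = int(round(spec.duration_s * rate))
    # base period quantized to the sample grid so that zero perturbation
    # yields exactly constant realized periods at any f0
    t0s = max(2.0, round(rate / spec.f0_hz))

    sigma_t = (spec.jitter_pct / 100.0) * t0s * np.sqrt(np.pi) / 2.0
    sigma_a = (spec.shimmer_pct / 100.0) * np.sqrt(np.pi) / 2.0
    positions = []
    pos = t0s / 2.0  # first pulse half a period in
    while pos < n - t0s / 4.0:
        # round half up: banker's rounding would alternate on odd periods
        positions.append(int(np.floor(pos + 0.5)))
        dt = t0s + (rng.normal(0.0, sigma_t) if sigma_t > 0 else 0.0)
        pos += max(dt, 0.2 * t0s)
    pulse_idx = np.unique(np.asarray(positions, dtype=int))
    pulse_idx = pulse_idx[(pulse_idx >= 0) & (pulse_idx < n)]
    if len(pulse_idx) < 2:
        raise ValueError("duration too short for two glottal cycles")
    pulse_times = pulse_idx / rate

    amps = np.ones(len(pulse_idx))
    if sigma_a > 0:
        amps = np.clip(1.0 + rng.normal(0.0, sigma_a, len(pulse_idx)),
                       0.05, None)

    excitation = np.zeros(n)
    excitation[pulse_idx] = amps
    # glottal decay: one-pole lowpass softens the impulse train
    x = lfilter([1.0], [1.0, -0.9], excitation)
    for f_hz, bw_hz in spec.formants_hz:
        b, a = _resonator_coeffs(f_hz, bw_hz, rate)
        x = lfilter(b, a, x)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = 0.8 * x / peak

    truth = PhonationTruth(spec=spec, pulse_times_s=pulse_times,
                           periods_s=np.diff(pulse_idx) / rate,
                           amplitudes=amps)
    return x, truth


def synthesize_reading(phonations: Sequence[tuple[str, PhonationSpec]],
                       pause_plan: Sequence[float] = (),
                       seed: int = 0) -> AnnotatedRecording:
    """Concatenate labelled phonations and pauses into a read "sentence".

    ``phonations`` is a list of (SAMPA label, PhonationSpec); formants are
    looked up from :data:`VOWEL_FORMANTS` when the PhonationSpec carries the default
    inventory entry for its label.  ``pause_plan[i]`` is the silence (s)
    inserted after phonation i (missing entries mean no pause).  Adjacent
    phonations without an intervening pause merge into one speech segment.
    Tier boundaries are exact by construction; the waveform is
    byte-identical for a fixed seed.
    """
    if not phonations:
        raise ValueError("need at least one phonation")
    pauses = list(pause_plan) + [0.0] * (len(phonations) - len(pause_plan))
    if any(p < 0 for p in pauses):
        raise ValueError("pauses must be non-negative")
    rate = phonations[0][1].sample_rate_hz
    if any(sp.sample_rate_hz != rate for _, sp in phonations):
        raise ValueError("all phonations must share one sample rate")

    chunks: list[np.ndarray] = []
    segment_tier: list[Interval] = []
    phoneme_tier: list[Interval] = []
    t = 0.0
    speech_start: float | None = None
    rng = np.random.default_rng(seed)
    for i, (label, sp) in enumerate(phonations):
        formants = VOWEL_FORMANTS.get(label, sp.formants_hz)
        sp_i = PhonationSpec(
            f0_hz=sp.f0_hz, jitter_pct=sp.jitter_pct,
            shimmer_pct=sp.shimmer_pct, formants_hz=formants,
            duration_s=sp.duration_s, sample_rate_hz=rate,
            seed=int(rng.integers(0, 2**31 - 1)))
        wave, _ = synthesize_phonation(sp_i)
        dur = len(wave) / rate
        if speech_start is None:
            speech_start = t
        phoneme_tier.append((t, t + dur, label))
        chunks.append(wave)
        t += dur
        if pauses[i] > 0 and i < len(phonations) - 1:
            segment_tier.append((speech_start, t, "speech"))
            speech_start = None
            n_sil = int(round(pauses[i] * rate))
            chunks.append(np.zeros(n_sil))
            segment_tier.append((t, t + n_sil / rate, "silence"))
            t += n_sil / rate
    if speech_start is not None:
        segment_tier.append((speech_start, t, "speech"))
    samples = np.concatenate(chunks)
    return AnnotatedRecording(samples=samples, sample_rate_hz=rate,
                              segment_tier=segment_tier,
                              phoneme_tier=phoneme_tier)


# ---------------------------------------------------------------------------
# Cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Population structure of a synthetic cohort.

    The latent severity s in [0, 1] drives both rating scales and the
    acoustic features:

    * BDI  = clip(round(63 s + N(0, bdi_noise_sd)), 0, 63)   (self-report)
    * HAMD = clip(round(48 s + N(0, hamd_noise_sd)), 0, 48)  (clinician),
      recorded for floor(n * hamd_subset_fraction) subjects sampled with
      severity-proportional weights (the HAMD subset of the study skews
      depressed).
    * feature_j = effect_vector[j] * standardize(s) + N(0, 1); effect
      entries are therefore per-feature signal SDs in noise-SD units.

    When ``target_bdi_hamd_r`` is set, both noise SDs are solved from the
    latent-severity variance assuming equal relative noise on both scales
    (r = 1 / (1 + k^2) with k the noise-to-signal SD ratio), overriding the
    explicit SDs.  Defaults mirror the study population: 218 subjects, 66%
    female, ~half healthy with the depressed half covering severity almost
    evenly, HAMD for 20%.
    """

    n_subjects: int = 218
    female_fraction: float = 144 / 218
    severity_distribution: str = "study_mixture"  # or "uniform"
    bdi_noise_sd: float = 6.0
    hamd_noise_sd: float = 3.0
    target_bdi_hamd_r: float | None = None
    hamd_subset_fraction: float = 0.2
    effect_vector: tuple[float, ...] = ()
    n_noise_features: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for name in ("female_fraction", "hamd_subset_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.target_bdi_hamd_r is not None and not (
                0.0 < self.target_bdi_hamd_r <= 1.0):
            raise ValueError(
                "target_bdi_hamd_r must be in (0, 1]: both scales load "
                "positively on severity, so the target is unsatisfiable "
                "otherwise")
        if self.bdi_noise_sd < 0 or self.hamd_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.severity_distribution not in ("study_mixture", "uniform"):
            raise ValueError("unknown severity_distribution")
        if self.n_noise_features < 0:
            raise ValueError("n_noise_features must be >= 0")


def _draw_severity(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_subjects
    if spec.severity_distribution == "uniform":
        return rng.uniform(0.0, 1.0, n)
    # study mixture: ~half healthy near zero, depressed spread almost
    # evenly over the rest of the scale (BDI >= 14 <=> s >= 14/63)
    healthy = rng.random(n) < 0.5
    s = np.where(healthy,
                 rng.uniform(0.0, 0.18, n),
                 rng.uniform(14.0 / 63.0, 1.0, n))
    return s


def generate_cohort(spec: CohortSpec
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (features, subjects) tables; deterministic per seed.

    The subjects table has columns subject_id, gender, age, bdi, hamd,
    set, h2b, and the ground-truth column ``severity`` (the latent s).
    Features are named f000, f001, ...: first the loaded features (one per
    effect_vector entry), then ``n_noise_features`` pure-noise columns.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    cols = ["subject_id", "gender", "age", "bdi", "hamd", "set"]
    p = len(spec.effect_vector) + spec.n_noise_features
    fnames = [f"f{j:03d}" for j in range(p)]
    if n == 0:
        feats = pd.DataFrame(columns=["subject_id"] + fnames)
        subs = pd.DataFrame(columns=cols + ["h2b", "severity"])
        return feats, subs

    s = _draw_severity(spec, rng)
    sd_s = float(np.std(s)) if n > 1 else 1.0
    eb = rng.normal(0.0, 1.0, n)  # unit score noises, scaled below
    eh = rng.normal(0.0, 1.0, n)

    n_hamd = int(np.floor(n * spec.hamd_subset_fraction))
    idx = np.array([], dtype=int)
    if n_hamd > 0:
        weights = 0.1 + s
        idx = rng.choice(n, size=n_hamd, replace=False,
                         p=weights / weights.sum())

    def scores(bdi_sd: float, hamd_sd: float):
        b = np.clip(np.round(63.0 * s + bdi_sd * eb), 0, 63).astype(int)
        h = np.clip(np.round(48.0 * s + hamd_sd * eh), 0, 48).astype(int)
        return b, h

    bdi_sd, hamd_sd = spec.bdi_noise_sd, spec.hamd_noise_sd
    if spec.target_bdi_hamd_r is not None:
        if sd_s == 0:
            raise ValueError("degenerate severity: correlation target "
                             "unsatisfiable")
        if len(idx) >= 3:
            # clipping and rounding censor the noise, so the closed form
            # r = 1/(1+k^2) is biased; calibrate the equal-relative-noise
            # ratio k by bisection on the realized (clipped, rounded)
            # scores of the HAMD subset — deterministic given the seed
            def subset_r(k: float) -> float:
                b, h = scores(63.0 * sd_s * k, 48.0 * sd_s * k)
                bs, hs = b[idx].astype(float), h[idx].astype(float)
                if bs.std() == 0 or hs.std() == 0:
                    return 0.0
                return float(np.corrcoef(bs, hs)[0, 1])

            lo, hi = 0.0, 8.0
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                if subset_r(mid) > spec.target_bdi_hamd_r:
                    lo = mid
                else:
                    hi = mid
            k = 0.5 * (lo + hi)
        else:
            k = np.sqrt(1.0 / spec.target_bdi_hamd_r - 1.0)
        bdi_sd, hamd_sd = 63.0 * sd_s * k, 48.0 * sd_s * k

    bdi, hamd_full = scores(bdi_sd, hamd_sd)
    hamd = np.full(n, np.nan)
    if n_hamd > 0:
        hamd[idx] = hamd_full[idx]

    gender = np.where(rng.random(n) < spec.female_fraction,
                      "female", "male")
    age = np.clip(np.round(rng.normal(42.0, 16.0, n)), 18, 85).astype(int)

    subs = pd.DataFrame({
        "subject_id": [f"s{i:04d}" for i in range(n)],
        "gender": gender,
        "age": age,
        "bdi": bdi,
        "hamd": hamd,
    })
    subs = assign_h2b(subs)
    subs["severity"] = s
    subs = subs[cols + ["h2b", "severity"]]

    z = (s - s.mean()) / sd_s if sd_s > 0 else np.zeros(n)
    effect = np.concatenate([np.asarray(spec.effect_vector, dtype=float),
                             np.zeros(spec.n_noise_features)])
    X = np.outer(z, effect) + rng.normal(0.0, 1.0, (n, p))
    feats = pd.DataFrame(X, columns=fnames)
    feats.insert(0, "subject_id", subs["subject_id"].to_numpy())
    return feats, subs
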