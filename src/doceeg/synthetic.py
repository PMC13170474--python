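"""Seeded synthetic EEG and clinical cohorts with the structure the analysis assumes.

EEG model
---------
Each recording is built per canonical band from (a) a shared band-limited
Gaussian oscillator injected into every channel with a fixed per-channel
phase lag, plus (b) independent per-channel band-limited noise, all riding
on a 1/f^k background. The coupling parameter c of a band splits the band's
power between shared (c) and independent (1-c) components; lags are drawn
with magnitude in [pi/8, 3pi/8] and random sign, bounded away from 0 and pi
because the weighted phase lag index is blind to zero-lag coupling. Volume
conduction is emulated separately as an instantaneous (zero-lag) mixture of
all channels.

State profiles encode the qualitative physiology the analysis targets:
gamma-dominant coupling and power while awake; broadband suppression with
relative slow-wave dominance under anesthesia (more pronounced, and more
beta/gamma-suppressed, under the GABAergic propofol profile than the NMDA-
antagonist esketamine profile); a slow-band-led rebound during recovery.

Cohort model
------------
Per-subject clinical rows are drawn from group-wise Gaussians (truncated
where the scale demands), categorical probabilities, and a logistic model
for the binary 3-month improvement flag. Defaults mirror the two-group
(n=17 each) cohort the analysis is designed around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .bands import CANONICAL_BANDS, BAND_NAMES
from .errors import ConfigurationError, InvalidParameterError
from .recording import EEGRecording, default_labels

STATE_LADDER = ("UWS", "MCS-", "MCS+", "EMCS")
DEFAULT_FS = 250.0
DEFAULT_RMS_UV = 30.0


# ---------------------------------------------------------------------------
# state profiles

@dataclass(frozen=True)
class StateProfile:
    """Pure parameter object describing one anesthesia state.

    band_power_weights: relative linear power per band (any positive scale);
    coupling: target shared-oscillator fraction per band, in [0, 1];
    noise_exponent: slope k of the 1/f^k background;
    background_weight: background power relative to the summed band power.
    """

    name: str
    band_power_weights: dict[str, float]
    coupling: dict[str, float]
    noise_exponent: float = 1.0
    background_weight: float = 0.2

    def __post_init__(self) -> None:
        weights = [self.band_power_weights.get(b, 0.0) for b in BAND_NAMES]
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise InvalidParameterError(
                "band power weights must be nonnegative with at least one positive"
            )
        for b, c in self.coupling.items():
            if not 0.0 <= c <= 1.0:
                raise InvalidParameterError(
                    f"coupling for band {b!r} must be in [0, 1], got {c}"
                )
        if self.background_weight < 0:
            raise InvalidParameterError("background_weight must be nonnegative")


def default_profiles() -> dict[str, StateProfile]:
    """The four study states with their qualitative band structure.

    Awake: high-frequency dominant coupling (gamma strongest, ~0.5) and a
    flat-ish spectrum. Maintenance: global connectivity suppression with
    slow-wave power dominance; the propofol profile suppresses beta/gamma
    power and coupling harder than the esketamine profile (which keeps more
    beta power and broadband irregularity, hence higher permutation
    entropy). Recovery: slow bands rebound first (delta > theta > alpha >
    gamma > beta).
    """
    return {
        "awake": StateProfile(
            name="awake",
            band_power_weights={"delta": 1.0, "theta": 1.0, "alpha": 1.2,
                                "beta": 1.2, "gamma": 1.5},
            coupling={"delta": 0.15, "theta": 0.2, "alpha": 0.3,
                      "beta": 0.4, "gamma": 0.55},
            noise_exponent=1.0,
        ),
        "esketamine_maintenance": StateProfile(
            name="esketamine_maintenance",
            band_power_weights={"delta": 4.0, "theta": 2.0, "alpha": 1.2,
                                "beta": 1.5, "gamma": 0.8},
            coupling={"delta": 0.27, "theta": 0.25, "alpha": 0.15,
                      "beta": 0.15, "gamma": 0.22},
            noise_exponent=1.2,
        ),
        "propofol_maintenance": StateProfile(
            name="propofol_maintenance",
            band_power_weights={"delta": 8.0, "theta": 2.0, "alpha": 1.0,
                                "beta": 0.5, "gamma": 0.3},
            coupling={"delta": 0.27, "theta": 0.25, "alpha": 0.12,
                      "beta": 0.08, "gamma": 0.08},
            noise_exponent=1.8,
        ),
        "recovery": StateProfile(
            name="recovery",
            band_power_weights={"delta": 3.0, "theta": 1.5, "alpha": 1.2,
                                "beta": 0.8, "gamma": 0.8},
            coupling={"delta": 0.38, "theta": 0.32, "alpha": 0.28,
                      "beta": 0.18, "gamma": 0.24},
            noise_exponent=1.2,
        ),
    }


def profile_for(group: str, phase: str) -> StateProfile:
    """Map a (group, phase) pair onto its generator profile."""
    profiles = default_profiles()
    if phase == "preoperative":
        return profiles["awake"]
    if phase == "recovery":
        return profiles["recovery"]
    if phase == "maintenance":
        return profiles[f"{group}_maintenance"]
    raise InvalidParameterError(f"unknown phase {phase!r}")


# ---------------------------------------------------------------------------
# EEG generation

def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        f_low: float, f_high: float,
                        shape: tuple[int, ...] = ()) -> np.ndarray:
    """Unit-variance Gaussian noise with spectrum confined to [f_low, f_high)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= f_low) & (freqs < f_high)
    spec = np.zeros(shape + (freqs.size,), dtype=complex)
    k = int(sel.sum())
    spec[..., sel] = rng.standard_normal(shape + (k,)) \
        + 1j * rng.standard_normal(shape + (k,))
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _one_over_f(rng: np.random.Generator, n: int, fs: float, exponent: float,
                shape: tuple[int, ...] = ()) -> np.ndarray:
    """Unit-variance 1/f^k background noise."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2)
    spec = amp * (rng.standard_normal(shape + (freqs.size,))
                  + 1j * rng.standard_normal(shape + (freqs.size,)))
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _phase_shift(x: np.ndarray, phi: np.ndarray, n: int) -> np.ndarray:
    """Apply a constant phase shift phi (per leading axis entry) to signal x."""
    spec = np.fft.rfft(x, axis=-1)
    return np.fft.irfft(spec[None, :] * np.exp(-1j * phi)[:, None], n=n, axis=-1)


def generate_eeg(profile: StateProfile, n_channels: int = 64,
                 duration: float = 60.0, fs: float = DEFAULT_FS,
                 seed: int = 0, rms_uv: float = DEFAULT_RMS_UV) -> EEGRecording:
    """Generate one multichannel recording for a state profile.

    Per band: a shared band-limited oscillator reaches each channel with a
    fixed nonzero per-channel phase lag (magnitude uniform in
    [pi/8, 3pi/8], random sign), mixed with independent band noise in
    proportion coupling : (1 - coupling); bands are weighted by the
    profile's relative power weights over a 1/f^k background. Identical
    seeds give identical output.
    """
    if duration <= 0 or fs <= 0:
        raise InvalidParameterError("duration and fs must be positive")
    if n_channels < 2:
        raise InvalidParameterError("need at least 2 channels")
    n = int(round(duration * fs))
    if n < 4 * fs:
        raise InvalidParameterError(
            "recording must span at least two 2-s epochs (duration >= 4 s)"
        )
    for band in CANONICAL_BANDS:
        if profile.band_power_weights.get(band.name, 0.0) > 0 \
                and band.f_high >= fs / 2:
            raise ConfigurationError(
                f"band {band.name!r} edge {band.f_high} Hz >= Nyquist {fs / 2} Hz"
            )
    rng = np.random.default_rng(seed)
    weights = np.array([profile.band_power_weights.get(b, 0.0) for b in BAND_NAMES])
    total_w = weights.sum()
    data = np.zeros((n_channels, n))
    for band, w in zip(CANONICAL_BANDS, weights):
        if w == 0:
            continue
        c = float(profile.coupling.get(band.name, 0.0))
        shared = _band_limited_noise(rng, n, fs, band.f_low, band.f_high)
        lags = rng.uniform(np.pi / 8, 3 * np.pi / 8, size=n_channels) \
            * rng.choice([-1.0, 1.0], size=n_channels)
        shifted = _phase_shift(shared, lags, n)
        indep = _band_limited_noise(rng, n, fs, band.f_low, band.f_high,
                                    shape=(n_channels,))
        data += np.sqrt(w) * (np.sqrt(c) * shifted + np.sqrt(1 - c) * indep)
    if profile.background_weight > 0:
        bg = _one_over_f(rng, n, fs, profile.noise_exponent, shape=(n_channels,))
        data += np.sqrt(profile.background_weight * total_w) * bg
    data *= rms_uv / max(data.std(), 1e-12)
    return EEGRecording(data=data, fs=fs,
                        channel_labels=default_labels(n_channels))


def mix_volume_conduction(rec: EEGRecording, leakage: float) -> EEGRecording:
    """Zero-lag leakage: each channel becomes (1-l)*self + l*channel-mean."""
    if not 0.0 <= leakage < 1.0:
        raise InvalidParameterError(f"leakage must be in [0, 1), got {leakage}")
    common = rec.data.mean(axis=0, keepdims=True)
    return rec.with_data((1 - leakage) * rec.data + leakage * common)


def inject_artifacts(rec: EEGRecording, rate: float, amplitude: float,
                     seed: int = 0
                     ) -> tuple[EEGRecording, list[tuple[float, float]]]:
    """Add Poisson-timed transient deflections; returns ground-truth events.

    Events are flat-topped pulses of 0.2-0.5 s at the given amplitude
    (microvolts), added to every channel, so every sample of an event sits
    at the full deflection and any epoch overlapping it is detectable.
    ``rate`` is events per minute; the returned list holds (onset_s,
    duration_s) pairs sorted by onset.
    """
    if amplitude <= 0:
        raise InvalidParameterError(f"amplitude must be positive, got {amplitude}")
    if rate < 0:
        raise InvalidParameterError(f"rate must be nonnegative, got {rate}")
    if rate == 0:
        return rec.with_data(rec.data.copy()), []
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate * rec.duration / 60.0)
    data = rec.data.copy()
    events: list[tuple[float, float]] = []
    for _ in range(n_events):
        t0 = rng.uniform(0, rec.duration)
        width = rng.uniform(0.2, 0.5)
        i0 = int(t0 * rec.fs)
        i1 = min(int((t0 + width) * rec.fs), rec.n_samples)
        if i1 - i0 < 2:
            continue
        data[:, i0:i1] += amplitude
        events.append((t0, (i1 - i0) / rec.fs))
    return rec.with_data(data), sorted(events)


# ---------------------------------------------------------------------------
# clinical cohorts

@dataclass(frozen=True)
class GroupClinicalParams:
    """Per-group marginal distributions for the clinical table."""

    age_mean: float
    age_sd: float
    crsr_mean: float
    crsr_sd: float
    surgical_mean: float
    surgical_sd: float
    recovery_mean: float
    recovery_sd: float
    duration_median: float  # months; durations are lognormal
    duration_log_sd: float
    p_male: float
    p_tbi: float
    state_probs: dict[str, float] | None  # over UWS / MCS- / MCS+ (None -> defaults)
    p_norepinephrine: float

    def __post_init__(self) -> None:
        for sd in (self.age_sd, self.crsr_sd, self.surgical_sd,
                   self.recovery_sd, self.duration_log_sd):
            if sd <= 0:
                raise InvalidParameterError("all SDs must be positive")
        probs = [self.p_male, self.p_tbi, self.p_norepinephrine]
        if self.state_probs is not None:
            probs += list(self.state_probs.values())
            if abs(sum(self.state_probs.values()) - 1.0) > 1e-9:
                raise InvalidParameterError(
                    "baseline state probabilities must sum to 1"
                )
        if any(not 0 <= p <= 1 for p in probs):
            raise InvalidParameterError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CohortParams:
    """Full cohort specification, including the improvement logistic model.

    The binary 3-month improvement flag is Bernoulli with log-odds
    ``intercept + group_effect*[esketamine] + age_effect*age +
    tbi_effect*[TBI] + crsr_effect*crsr_baseline``.
    """

    n_per_group: int = 17
    esketamine: GroupClinicalParams = field(default_factory=lambda: GroupClinicalParams(
        age_mean=46.92, age_sd=15.18, crsr_mean=7.65, crsr_sd=1.84,
        surgical_mean=51.92, surgical_sd=10.9,
        recovery_mean=12.02, recovery_sd=3.88,
        duration_median=4.0, duration_log_sd=0.5,
        p_male=12 / 17, p_tbi=9 / 17,
        state_probs=None, p_norepinephrine=3 / 17))
    propofol: GroupClinicalParams = field(default_factory=lambda: GroupClinicalParams(
        age_mean=50.29, age_sd=14.00, crsr_mean=6.47, crsr_sd=2.10,
        surgical_mean=54.17, surgical_sd=6.28,
        recovery_mean=17.42, recovery_sd=4.62,
        duration_median=3.0, duration_log_sd=0.5,
        p_male=10 / 17, p_tbi=10 / 17,
        state_probs=None, p_norepinephrine=9 / 17))
    improvement_intercept: float = -2.36
    improvement_group_effect: float = log(6.84)
    improvement_age_effect: float = log(0.99)
    improvement_tbi_effect: float = log(1.32)
    improvement_crsr_effect: float = log(1.28)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise InvalidParameterError("n_per_group must be at least 2")


# dataclass default factories cannot easily carry dict literals above;
# patch the state probabilities here once.
def _default_group(params: GroupClinicalParams, probs: dict[str, float]
                   ) -> GroupClinicalParams:
    if params.state_probs is not None:
        return params
    from dataclasses import replace
    return replace(params, state_probs=probs)


_ESK_STATE_PROBS = {"UWS": 10 / 17, "MCS-": 6 / 17, "MCS+": 1 / 17}
_PRO_STATE_PROBS = {"UWS": 13 / 17, "MCS-": 4 / 17, "MCS+": 0.0}


def default_cohort_params(n_per_group: int = 17) -> CohortParams:
    """Cohort defaults mirroring the two-group study population."""
    base = CohortParams(n_per_group=n_per_group)
    from dataclasses import replace
    return replace(base,
                   esketamine=_default_group(base.esketamine, _ESK_STATE_PROBS),
                   propofol=_default_group(base.propofol, _PRO_STATE_PROBS))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(params: CohortParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw a per-subject clinical table; identical seed, identical table.

    Columns: subject_id, group, age, sex, etiology, duration_months,
    baseline_state, crsr_baseline, surgical_time, recovery_time,
    norepinephrine, improved, state_3mo.
    """
    if params is None:
        params = default_cohort_params()
    rng = np.random.default_rng(seed)
    rows = []
    for group, gp in (("esketamine", params.esketamine),
                      ("propofol", params.propofol)):
        gp = _default_group(gp, _ESK_STATE_PROBS if group == "esketamine"
                            else _PRO_STATE_PROBS)
        n = params.n_per_group
        age = rng.normal(gp.age_mean, gp.age_sd, n).clip(18, 90)
        crsr = np.rint(rng.normal(gp.crsr_mean, gp.crsr_sd, n)).clip(0, 23)
        surgical = rng.normal(gp.surgical_mean, gp.surgical_sd, n).clip(min=5.0)
        recovery = rng.normal(gp.recovery_mean, gp.recovery_sd, n).clip(min=1.0)
        duration = np.exp(rng.normal(np.log(gp.duration_median),
                                     gp.duration_log_sd, n))
        sex = np.where(rng.random(n) < gp.p_male, "M", "F")
        etiology = np.where(rng.random(n) < gp.p_tbi, "TBI", "CVD")
        states = list(gp.state_probs)
        state = rng.choice(states, size=n, p=[gp.state_probs[s] for s in states])
        norepi = np.where(rng.random(n) < gp.p_norepinephrine, "yes", "no")
        lp = (params.improvement_intercept
              + params.improvement_group_effect * (group == "esketamine")
              + params.improvement_age_effect * age
              + params.improvement_tbi_effect * (etiology == "TBI")
              + params.improvement_crsr_effect * crsr)
        improved = rng.random(n) < _sigmoid(lp)
        for i in range(n):
            base_idx = STATE_LADDER.index(state[i])
            final_idx = min(base_idx + 1, len(STATE_LADDER) - 1) \
                if improved[i] else base_idx
            rows.append({
                "subject_id": f"{group[:3]}{i + 1:02d}",
                "group": group,
                "age": float(age[i]),
                "sex": sex[i],
                "etiology": etiology[i],
                "duration_months": float(duration[i]),
                "baseline_state": state[i],
                "crsr_baseline": int(crsr[i]),
                "surgical_time": float(surgical[i]),
                "recovery_time": float(recovery[i]),
                "norepinephrine": norepi[i],
                "improved": bool(improved[i] and final_idx > base_idx),
                "state_3mo": STATE_LADDER[final_idx],
            })
    return pd.DataFrame(rows)
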