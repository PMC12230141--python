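"""Synthetic epoched EEG with embedded ACC responses.

Emulates the study design end to end: per-condition sets of sweeps at
2048 Hz with a biphasic N1-P2 deflection after the tone onset, riding on
1/f-shaped background EEG with an optional alpha component, per-epoch
latency jitter, occasional artifact epochs, amplitude growth with SNR,
reduced amplitude at 4 kHz and on the second repetition (habituation),
a smaller contralateral projection, and optional "dead-region"
participants whose response is suppressed below a configurable SNR.

Everything is seeded: a fixed seed reproduces every array bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .design import ConfigurationError, StimulusDesign
from .staircase import simulate_staircase

__all__ = [
    "ParticipantProfile",
    "EpochSet",
    "acc_template",
    "simulate_epochs",
    "Cohort",
    "simulate_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ParticipantProfile:
    """Generator parameters for one simulated participant.

    ``acc_amp_at_max_snr_uv`` maps tone frequency (Hz) to the N1-P2
    peak-to-peak amplitude in microvolts at the top of the SNR grid; the
    amplitude shrinks by ``amp_growth_slope_uv_per_db`` for every dB the
    SNR drops (clamped at zero), is multiplied by ``habituation_factor``
    on the second repetition and by ``contra_scale`` on the contralateral
    channel.  ``dr_suppression_snr_db``, when set, forces the response to
    zero below that SNR — a caricature of a cochlear dead region, where
    the tone is only detected by off-frequency listening at high SNR.
    """

    participant_id: str = "p00"
    acc_amp_at_max_snr_uv: Mapping[float, float] = field(
        default_factory=lambda: {1000.0: 6.0, 4000.0: 4.0}
    )
    amp_growth_slope_uv_per_db: float = 0.35
    latency_jitter_ms: float = 5.0
    noise_rms_uv: float = 8.0
    habituation_factor: float = 0.8
    artifact_rate: float = 0.05
    contra_scale: float = 0.6
    dr_suppression_snr_db: Optional[float] = None
    behavioural_str_db: float = -2.0
    absolute_threshold_dbhl: float = 5.0
    alpha_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.artifact_rate < 1.0):
            raise ConfigurationError(f"artifact_rate must be in [0, 1), got {self.artifact_rate}")
        if not (0.0 < self.habituation_factor <= 1.0):
            raise ConfigurationError(
                f"habituation_factor must be in (0, 1], got {self.habituation_factor}"
            )
        if not (0.0 < self.contra_scale <= 1.0):
            raise ConfigurationError(f"contra_scale must be in (0, 1], got {self.contra_scale}")
        if any(a < 0 for a in self.acc_amp_at_max_snr_uv.values()) or self.noise_rms_uv < 0:
            raise ConfigurationError("amplitudes must be non-negative")

    def n1p2_amplitude_uv(self, frequency_hz: float, snr_db: float, repetition: int,
                          snr_max_db: float = 15.0) -> float:
        """Embedded N1-P2 amplitude for one condition (ipsilateral channel)."""
        try:
            amp_max = self.acc_amp_at_max_snr_uv[float(frequency_hz)]
        except KeyError as err:
            raise ConfigurationError(
                f"no template amplitude for frequency {frequency_hz} Hz"
            ) from err
        amp = max(amp_max - self.amp_growth_slope_uv_per_db * (snr_max_db - snr_db), 0.0)
        if repetition >= 2:
            amp *= self.habituation_factor
        if self.dr_suppression_snr_db is not None and snr_db < self.dr_suppression_snr_db:
            amp = 0.0
        return amp


@dataclass
class EpochSet:
    """One condition's epoched EEG: ``data`` is n_epochs x n_samples in microvolts.

    ``condition`` is (frequency_hz, snr_db, repetition); ``accepted`` flags
    epochs surviving artifact rejection (all True straight out of the
    generator).  The time axis follows the design: sample 0 at
    ``epoch_start_s`` re noise onset.
    """

    data: np.ndarray
    design: StimulusDesign
    channel_role: str = "ipsi"
    condition: Optional[tuple] = None
    accepted: np.ndarray = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ConfigurationError("EpochSet data must be 2-D (n_epochs x n_samples)")
        if self.data.shape[1] != self.design.n_samples:
            raise ConfigurationError(
                f"epoch length {self.data.shape[1]} != design n_samples {self.design.n_samples}"
            )
        if self.channel_role not in ("ipsi", "contra"):
            raise ConfigurationError(f"channel_role must be ipsi|contra, got {self.channel_role}")
        if self.accepted is None:
            self.accepted = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.accepted = np.asarray(self.accepted, dtype=bool)
            if self.accepted.shape != (self.data.shape[0],):
                raise ConfigurationError("accepted flags must match n_epochs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    def accepted_data(self) -> np.ndarray:
        return self.data[self.accepted]


def acc_template(
    design: StimulusDesign,
    n1_amp_uv: float,
    p2_amp_uv: float,
    n1_lat_s: float = 1.100,
    p2_lat_s: float = 1.200,
    n1_fwhm_s: float = 0.030,
    p2_fwhm_s: float = 0.050,
    p1_amp_uv: float = 0.0,
    p1_lat_s: float = 1.050,
    p1_fwhm_s: float = 0.025,
) -> np.ndarray:
    """Deterministic ACC morphology: Gaussian-windowed biphasic deflection.

    A negative lobe of depth ``n1_amp_uv`` at ``n1_lat_s`` and a positive
    lobe of height ``p2_amp_uv`` at ``p2_lat_s`` (optionally preceded by a
    small P1).  The waveform is zero outside [tone_onset, tone_onset+0.4 s]
    and its peak-to-peak amplitude equals n1 + p2 to well within 1 % for
    the default widths (the lobes barely overlap at 100 ms separation).
    """
    if n1_amp_uv < 0 or p2_amp_uv < 0 or p1_amp_uv < 0:
        raise ConfigurationError("template amplitudes are magnitudes and must be >= 0")
    lo1, hi1 = design.n1_window_s
    lo2, hi2 = design.p2_window_s
    if not (lo1 <= n1_lat_s <= hi1):
        raise ConfigurationError(f"n1_lat_s={n1_lat_s} outside N1 window ({lo1}, {hi1})")
    if not (lo2 <= p2_lat_s <= hi2):
        raise ConfigurationError(f"p2_lat_s={p2_lat_s} outside P2 window ({lo2}, {hi2})")
    t = design.times
    w = np.zeros_like(t)
    for amp, lat, fwhm, sign in (
        (p1_amp_uv, p1_lat_s, p1_fwhm_s, +1.0),
        (n1_amp_uv, n1_lat_s, n1_fwhm_s, -1.0),
        (p2_amp_uv, p2_lat_s, p2_fwhm_s, +1.0),
    ):
        if amp > 0:
            sigma = fwhm * _FWHM_TO_SIGMA
            w += sign * amp * np.exp(-0.5 * ((t - lat) / sigma) ** 2)
    support = (t >= design.tone_onset_s) & (t <= design.tone_onset_s + 0.4)
    w[~support] = 0.0
    return w


def _shaped_noise(rng: np.random.Generator, n_epochs: int, design: StimulusDesign,
                  alpha_fraction: float) -> np.ndarray:
    """Unit-RMS background EEG: 1/f power over ~0.5-35 Hz plus an alpha bump."""
    n = design.n_samples
    white = rng.standard_normal((n_epochs, n))
    f = np.fft.rfftfreq(n, d=1.0 / design.fs)
    shape = np.zeros_like(f)
    band = (f >= 0.5) & (f <= 35.0)
    shape[band] = 1.0 / np.sqrt(np.maximum(f[band], 1.0))
    shape = shape + alpha_fraction * np.exp(-0.5 * ((f - 10.0) / 1.5) ** 2)
    x = np.fft.irfft(np.fft.rfft(white, axis=1) * shape, n=n, axis=1)
    scale = x.std()
    if scale > 0:
        x /= scale
    return x


def simulate_epochs(
    design: StimulusDesign,
    profile: ParticipantProfile,
    condition: tuple,
    channel_role: str = "ipsi",
    seed: int = 0,
) -> EpochSet:
    """Generate one condition's sweeps: embedded ACC template + shaped noise.

    ``condition`` is (frequency_hz, snr_db, repetition) and must lie on the
    design grid.  Artifact epochs (probability ``profile.artifact_rate``)
    have their background scaled tenfold, which the downstream 2-SD RMS
    rule is meant to catch.  Fixed seed => bit-identical output.
    """
    frequency_hz, snr_db, repetition = condition
    if float(frequency_hz) not in design.frequencies_hz:
        raise ConfigurationError(f"frequency {frequency_hz} not in design grid")
    if float(snr_db) not in design.snr_levels_db:
        raise ConfigurationError(f"SNR {snr_db} not in design grid")
    if not (1 <= int(repetition) <= design.repetitions):
        raise ConfigurationError(f"repetition {repetition} not in 1..{design.repetitions}")

    rng = np.random.default_rng(seed)
    snr_max = max(design.snr_levels_db)
    amp = profile.n1p2_amplitude_uv(frequency_hz, snr_db, int(repetition), snr_max_db=snr_max)
    if channel_role == "contra":
        amp *= profile.contra_scale

    n_epochs = design.sweeps
    jitter_s = rng.normal(0.0, profile.latency_jitter_ms / 1000.0, size=n_epochs)
    artifact = rng.random(n_epochs) < profile.artifact_rate
    noise = _shaped_noise(rng, n_epochs, design, profile.alpha_fraction) * profile.noise_rms_uv
    noise[artifact] *= 10.0

    data = noise
    if amp > 0:
        # 60/40 split of the peak-to-peak between the N1 and P2 lobes
        t = design.times
        n1_amp, p2_amp = 0.6 * amp, 0.4 * amp
        s1 = 0.030 * _FWHM_TO_SIGMA
        s2 = 0.050 * _FWHM_TO_SIGMA
        lat1 = 1.100 + jitter_s[:, None]
        lat2 = 1.200 + jitter_s[:, None]
        sig = -n1_amp * np.exp(-0.5 * ((t[None, :] - lat1) / s1) ** 2)
        sig += p2_amp * np.exp(-0.5 * ((t[None, :] - lat2) / s2) ** 2)
        support = (t >= design.tone_onset_s) & (t <= design.tone_onset_s + 0.4)
        sig[:, ~support] = 0.0
        data = data + sig

    return EpochSet(
        data=data,
        design=design,
        channel_role=channel_role,
        condition=(float(frequency_hz), float(snr_db), int(repetition)),
        seed=int(seed),
    )


@dataclass
class Cohort:
    """A simulated cohort: profiles, a recording manifest, and lazy epoch access.

    Epoch data are regenerated on demand from the per-cell seeds recorded in
    the manifest (memory-light and exactly reproducible), so a cohort of any
    size is just bookkeeping until epochs are requested.
    """

    design: StimulusDesign
    profiles: list
    manifest: pd.DataFrame
    behavioural: pd.DataFrame
    seed: int

    def profile(self, participant_id: str) -> ParticipantProfile:
        for p in self.profiles:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    def epochs(self, participant_id: str, frequency_hz: float, snr_db: float,
               repetition: int, channel_role: str = "ipsi") -> EpochSet:
        row = self.manifest[
            (self.manifest.participant == participant_id)
            & (self.manifest.frequency_hz == float(frequency_hz))
            & (self.manifest.snr_db == float(snr_db))
            & (self.manifest.repetition == int(repetition))
        ]
        if row.empty:
            raise KeyError((participant_id, frequency_hz, snr_db, repetition))
        row = row.iloc[0]
        if row.status != "ok":
            raise KeyError(f"recording marked {row.status}")
        seed = int(row.seed_ipsi if channel_role == "ipsi" else row.seed_contra)
        return simulate_epochs(
            self.design, self.profile(participant_id),
            (frequency_hz, snr_db, repetition), channel_role, seed,
        )


def _draw_profile(rng: np.random.Generator, idx: int, base: ParticipantProfile,
                  variability: float) -> ParticipantProfile:
    """Lognormal between-participant spread around the base profile."""
    amps = {
        f: a * rng.lognormal(0.0, variability)
        for f, a in base.acc_amp_at_max_snr_uv.items()
    }
    return dataclasses.replace(
        base,
        participant_id=f"p{idx:02d}",
        acc_amp_at_max_snr_uv=amps,
        noise_rms_uv=base.noise_rms_uv * rng.lognormal(0.0, variability / 2),
        behavioural_str_db=float(rng.uniform(-6.0, 2.0)),
    )


def simulate_cohort(
    design: StimulusDesign,
    n_participants: int,
    dr_spec: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    base_profile: Optional[ParticipantProfile] = None,
    variability: float = 0.25,
    attrition: int = 0,
    ten_level_dbhl: float = 60.0,
) -> Cohort:
    """Simulate a whole cohort's design grid plus behavioural TEN thresholds.

    ``dr_spec`` maps participant id (``"p03"``) to the SNR below which that
    participant's ACC is suppressed.  ``attrition`` marks that many randomly
    chosen recordings (participant x frequency x SNR x repetition cells) as
    missing — opt-in, never applied silently.  Behavioural masked thresholds
    are measured with the 2-down/1-up staircase (4 dB down, 2 dB up, start
    70 dB HL) against each participant's true signal-to-TEN ratio.
    """
    if n_participants < 1:
        raise ConfigurationError("n_participants must be >= 1")
    base = base_profile if base_profile is not None else ParticipantProfile()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    profiles = []
    for i in range(n_participants):
        prof = _draw_profile(rng, i, base, variability)
        if dr_spec and prof.participant_id in dr_spec:
            prof = dataclasses.replace(
                prof, dr_suppression_snr_db=float(dr_spec[prof.participant_id])
            )
        profiles.append(prof)

    rows = []
    for prof in profiles:
        for f in design.frequencies_hz:
            for s in design.snr_levels_db:
                for rep in range(1, design.repetitions + 1):
                    rows.append(
                        {
                            "participant": prof.participant_id,
                            "frequency_hz": f,
                            "snr_db": s,
                            "repetition": rep,
                            "status": "ok",
                            "seed_ipsi": int(rng.integers(2**31)),
                            "seed_contra": int(rng.integers(2**31)),
                        }
                    )
    manifest = pd.DataFrame(rows)

    if attrition:
        if attrition >= len(manifest):
            raise ConfigurationError("attrition would remove every recording")
        drop = rng.choice(len(manifest), size=int(attrition), replace=False)
        manifest.loc[drop, "status"] = "missing"

    beh_rows = []
    for prof in profiles:
        for f in design.frequencies_hz:
            true_thr = ten_level_dbhl + prof.behavioural_str_db
            res = simulate_staircase(
                true_threshold_db=true_thr,
                start_db=70.0,
                psychometric_slope=2.0,
                seed=int(rng.integers(2**31)),
            )
            beh_rows.append(
                {
                    "participant": prof.participant_id,
                    "frequency_hz": f,
                    "ten_level_dbhl": ten_level_dbhl,
                    "true_str_db": prof.behavioural_str_db,
                    "masked_threshold_dbhl": res.threshold_db,
                    "str_db": res.threshold_db - ten_level_dbhl,
                    "absolute_threshold_dbhl": prof.absolute_threshold_dbhl,
                    "converged": res.converged,
                }
            )
    behavioural = pd.DataFrame(beh_rows)

    return Cohort(design=design, profiles=profiles, manifest=manifest,
                  behavioural=behavioural, seed=int(seed))
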