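"""Stimulus/recording design shared by every stage of the ACC pipeline.

The experiment presents a tone in ongoing threshold-equalizing noise (TEN):
the noise starts at t = 0 s, the tone appears at 1 s for 0.5 s, the whole
stimulus ends at 1.5 s, and epochs run from -0.1 to 2.5 s re noise onset.
Six tone-to-noise SNRs (0-15 dB in 3-dB steps) x two tone frequencies
(1 and 4 kHz) x two repetitions are recorded per participant, 120 sweeps
each, from ipsi- and contralateral mastoids referenced to Cz.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["ConfigurationError", "StimulusDesign", "make_design"]


class ConfigurationError(ValueError):
    """A stimulus design or pipeline configuration violates its invariants."""


@dataclass(frozen=True)
class StimulusDesign:
    """Timing and condition grid of one ACC recording session.

    All times are seconds relative to the TEN (noise) onset.  Analysis
    windows are half-open ``[start, stop)`` sample intervals; the absolute
    N1/P2 windows correspond to 80-120 ms and 170-230 ms after the tone
    onset at 1 s, and the RMS noise-floor window to 80-230 ms after the
    stimulus offset at 1.5 s.
    """

    fs: float = 2048.0
    ten_onset_s: float = 0.0
    tone_onset_s: float = 1.0
    tone_dur_s: float = 0.5
    stim_offset_s: float = 1.5
    epoch_start_s: float = -0.1
    epoch_end_s: float = 2.5
    isi_s: float = 1.5
    snr_levels_db: tuple[float, ...] = (15.0, 12.0, 9.0, 6.0, 3.0, 0.0)
    frequencies_hz: tuple[float, ...] = (1000.0, 4000.0)
    sweeps: int = 120
    repetitions: int = 2
    n1_window_s: tuple[float, float] = (1.080, 1.120)
    p2_window_s: tuple[float, float] = (1.170, 1.230)
    rms_signal_window_s: tuple[float, float] = (1.080, 1.230)
    rms_noise_window_s: tuple[float, float] = (1.580, 1.730)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if self.sweeps < 1 or self.repetitions < 1:
            raise ConfigurationError("sweeps and repetitions must be >= 1")
        if self.epoch_end_s <= self.stim_offset_s + 0.23:
            raise ConfigurationError(
                "epoch must extend at least 0.23 s past the stimulus offset so the "
                f"noise-floor window fits (epoch_end_s={self.epoch_end_s}, "
                f"stim_offset_s={self.stim_offset_s})"
            )
        for name in ("n1_window_s", "p2_window_s", "rms_signal_window_s", "rms_noise_window_s"):
            lo, hi = getattr(self, name)
            if not (lo < hi):
                raise ConfigurationError(f"{name} must be increasing, got ({lo}, {hi})")
            if lo < self.epoch_start_s or hi > self.epoch_end_s:
                raise ConfigurationError(
                    f"{name}=({lo}, {hi}) lies outside the epoch "
                    f"[{self.epoch_start_s}, {self.epoch_end_s}]"
                )
        snrs = np.asarray(self.snr_levels_db, dtype=float)
        if snrs.size < 2:
            raise ConfigurationError("need at least two SNR levels")
        steps = np.diff(np.sort(snrs))
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ConfigurationError(
                f"SNR levels must be distinct and uniformly spaced, got {self.snr_levels_db}"
            )
        # normalise sequence fields so designs hash/compare predictably
        object.__setattr__(self, "snr_levels_db", tuple(float(s) for s in self.snr_levels_db))
        object.__setattr__(self, "frequencies_hz", tuple(float(f) for f in self.frequencies_hz))

    # ---- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        """Epoch length in samples, half-open convention [start, end)."""
        return int(round((self.epoch_end_s - self.epoch_start_s) * self.fs))

    @property
    def times(self) -> np.ndarray:
        """Time axis in s re noise onset; sample 0 sits at ``epoch_start_s``."""
        return self.epoch_start_s + np.arange(self.n_samples) / self.fs

    @property
    def snr_step_db(self) -> float:
        grid = np.sort(np.asarray(self.snr_levels_db))
        return float(grid[1] - grid[0])

    @property
    def snr_grid_ascending(self) -> tuple[float, ...]:
        return tuple(sorted(self.snr_levels_db))

    @property
    def trial_duration_s(self) -> float:
        """One sweep: stimulus plus inter-stimulus interval (3 s by default)."""
        return self.stim_offset_s + self.isi_s

    @property
    def n_conditions_per_participant(self) -> int:
        return len(self.snr_levels_db) * len(self.frequencies_hz) * self.repetitions

    def planned_recordings(self, n_participants: int) -> int:
        """Number of recordings for a cohort: one per participant x frequency x SNR x repetition."""
        return n_participants * self.n_conditions_per_participant

    @property
    def stimulus_time_per_frequency_s(self) -> float:
        """Presentation time for one frequency block (all SNRs, one repetition)."""
        return self.trial_duration_s * self.sweeps * len(self.snr_levels_db)

    # ---- sample bookkeeping -------------------------------------------------

    def sample_index(self, t_s: float) -> int:
        return int(round((t_s - self.epoch_start_s) * self.fs))

    def window_indices(self, window_s: Sequence[float]) -> tuple[int, int]:
        """Half-open sample range [i0, i1) for a window in absolute seconds."""
        i0 = self.sample_index(window_s[0])
        i1 = self.sample_index(window_s[1])
        i0 = max(i0, 0)
        i1 = min(i1, self.n_samples)
        if i1 <= i0:
            raise ConfigurationError(f"window {tuple(window_s)} maps to an empty sample range")
        return i0, i1

    @property
    def baseline_window_s(self) -> tuple[float, float]:
        return (self.epoch_start_s, self.ten_onset_s)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def make_design(**overrides) -> StimulusDesign:
    """Build a :class:`StimulusDesign`, applying field overrides to the defaults.

    Raises :class:`ConfigurationError` if an override breaks a design
    invariant (e.g. an epoch too short to contain the noise-floor window).
    """
    unknown = set(overrides) - {f.name for f in dataclasses.fields(StimulusDesign)}
    if unknown:
        raise ConfigurationError(f"unknown design field(s): {sorted(unknown)}")
    for key in ("snr_levels_db", "frequencies_hz"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    for key in ("n1_window_s", "p2_window_s", "rms_signal_window_s", "rms_noise_window_s"):
        if key in overrides:
            overrides[key] = tuple(overrides[key])
    return StimulusDesign(**overrides)
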