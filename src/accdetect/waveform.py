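"""N1/P2 peak measurement and windowed RMS on averaged responses.

N1 is the most negative sample in the 1.080-1.120 s window (80-120 ms
after the tone onset) and P2 the most positive sample in 1.170-1.230 s;
the N1-P2 amplitude is their signed difference (peak-to-peak).  Peaks
are raw extrema with ties broken by the earliest sample; parabolic
interpolation is available behind a flag but off by default, matching
automatic-pick-then-visual-check practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .design import ConfigurationError, StimulusDesign
from .preprocess import AveragedResponse

__all__ = ["PeakMeasurement", "find_peaks", "segment_rms"]

Waveform = Union[AveragedResponse, np.ndarray]


@dataclass(frozen=True)
class PeakMeasurement:
    """Signed N1/P2 peak amplitudes (microvolts), latencies (s) and peak-to-peak."""

    n1_latency_s: float
    n1_amp_uv: float
    p2_latency_s: float
    p2_amp_uv: float

    @property
    def n1p2_amp_uv(self) -> float:
        return self.p2_amp_uv - self.n1_amp_uv


def _waveform_of(avg: Waveform) -> np.ndarray:
    w = getattr(avg, "waveform", avg)
    if w is None:
        raise ConfigurationError("averaged response has no waveform (all epochs rejected)")
    return np.asarray(w, dtype=float)


def _refine_parabolic(w: np.ndarray, i: int, lo: int, hi: int, fs: float) -> float:
    """Sub-sample latency offset from a parabola through three samples."""
    if i <= lo or i >= hi - 1:
        return 0.0
    y0, y1, y2 = w[i - 1], w[i], w[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return 0.0
    return 0.5 * (y0 - y2) / denom / fs


def find_peaks(avg: Waveform, design: StimulusDesign,
               interpolate: bool = False) -> PeakMeasurement:
    """Locate N1 (window minimum) and P2 (window maximum) on an average.

    Latencies are reported at sample centres; with ``interpolate`` a
    parabolic refinement of the latency is added (amplitudes stay the
    raw extrema).
    """
    w = _waveform_of(avg)
    if w.size != design.n_samples:
        raise ConfigurationError(
            f"waveform length {w.size} != design n_samples {design.n_samples}"
        )
    out = {}
    for name, window, pick in (("n1", design.n1_window_s, np.argmin),
                               ("p2", design.p2_window_s, np.argmax)):
        i0, i1 = design.window_indices(window)
        i = i0 + int(pick(w[i0:i1]))  # argmin/argmax take the earliest tie
        lat = design.epoch_start_s + i / design.fs
        if interpolate:
            lat += _refine_parabolic(w, i, i0, i1, design.fs)
        out[name] = (lat, float(w[i]))
    return PeakMeasurement(
        n1_latency_s=out["n1"][0], n1_amp_uv=out["n1"][1],
        p2_latency_s=out["p2"][0], p2_amp_uv=out["p2"][1],
    )


def segment_rms(avg: Waveform, window_s: Sequence[float],
                design: StimulusDesign) -> float:
    """Root-mean-square over a half-open window of the averaged waveform."""
    w = _waveform_of(avg)
    i0, i1 = design.window_indices(window_s)
    if i1 > w.size:
        raise ConfigurationError("window extends past the end of the waveform")
    seg = w[i0:i1]
    return float(np.sqrt(np.mean(seg**2)))
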