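"""Three objective detectors for the acoustic change complex.

* RMS method: present when the RMS over the response window (1.080-1.230 s)
  is at least 1.5x the RMS of the post-offset noise floor (1.580-1.730 s).
* BSA repetition-SNR method: the mean N1-P2 amplitude of two repetitions
  divided by the sample SD of those two amplitudes, expressed in dB;
  present when > 3 dB.
* Bootstrap method: epochs from both mastoids are pooled; a null
  distribution of the (N1-P2 amplitude / noise-floor RMS) statistic is
  built by repeatedly drawing 240 epochs with replacement, flipping each
  drawn epoch's polarity at random (which destroys the phase-locked
  response while preserving the noise spectrum), and averaging; the
  response is present when the observed statistic exceeds the upper
  bound of the null's 95 % interval.

Any recording flagged invalid by preprocessing yields "inconclusive" —
never a guess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .design import ConfigurationError, StimulusDesign
from .preprocess import AveragedResponse
from .synth import EpochSet
from .waveform import find_peaks, segment_rms

__all__ = [
    "DetectionResult",
    "detect_rms",
    "bsa_statistic_db",
    "detect_bsa",
    "detect_bootstrap",
]

logger = logging.getLogger(__name__)

PRESENT, ABSENT, INCONCLUSIVE = "present", "absent", "inconclusive"


@dataclass
class DetectionResult:
    """Outcome of one detector on one recording (or recording pair)."""

    method: str
    statistic: float
    criterion: float
    outcome: str
    n_boot: Optional[int] = None
    ci: Optional[tuple] = None
    seed: Optional[int] = None
    info: dict = field(default_factory=dict)

    @property
    def present(self) -> Optional[bool]:
        if self.outcome == INCONCLUSIVE:
            return None
        return self.outcome == PRESENT


def _inconclusive(method: str, criterion: float, **info) -> DetectionResult:
    return DetectionResult(method=method, statistic=float("nan"),
                           criterion=criterion, outcome=INCONCLUSIVE, info=info)


# ---- RMS method -------------------------------------------------------------


def detect_rms(avg: AveragedResponse, design: StimulusDesign,
               criterion: float = 1.5, numerator: str = "window") -> DetectionResult:
    """Response-window RMS over noise-floor RMS, present when >= 1.5.

    ``numerator="window"`` (default) uses the RMS of the waveform over the
    response window; ``numerator="peaks"`` uses ``|N1-P2| / sqrt(2)``, the
    RMS of a two-point peak pair, for labs reading the rule that way.
    """
    if avg is None or not avg.is_valid:
        return _inconclusive("rms", criterion)
    if numerator == "window":
        sig = segment_rms(avg, design.rms_signal_window_s, design)
    elif numerator == "peaks":
        sig = abs(find_peaks(avg, design).n1p2_amp_uv) / np.sqrt(2.0)
    else:
        raise ConfigurationError(f"unknown numerator mode {numerator!r}")
    noise = segment_rms(avg, design.rms_noise_window_s, design)
    if noise == 0.0:
        logger.warning("zero noise-floor RMS; RMS statistic is infinite")
        stat = float("inf")
    else:
        stat = sig / noise
    outcome = PRESENT if stat >= criterion else ABSENT
    return DetectionResult(method="rms", statistic=stat, criterion=criterion,
                           outcome=outcome, info={"numerator": numerator})


# ---- BSA repetition-SNR method ---------------------------------------------


def bsa_statistic_db(a1: float, a2: float) -> float:
    """20*log10(mean / sample SD) of the two repetitions' N1-P2 amplitudes.

    The sample SD of two values is |a1 - a2| / sqrt(2).  Identical
    amplitudes give +inf; a non-positive mean gives -inf (no coherent
    response).
    """
    m = 0.5 * (a1 + a2)
    sd = abs(a1 - a2) / np.sqrt(2.0)
    if sd == 0.0:
        return float("inf") if m > 0 else float("-inf")
    if m <= 0.0:
        return float("-inf")
    return float(20.0 * np.log10(m / sd))


def detect_bsa(avg_rep1: AveragedResponse, avg_rep2: AveragedResponse,
               design: StimulusDesign, criterion_db: float = 3.0,
               scale: str = "db") -> DetectionResult:
    """Repetition-consistency SNR of the N1-P2 amplitude, present when > 3 dB.

    ``scale="db"`` follows the printed rule (20*log10 amplitude ratio
    > 3 dB); ``scale="linear"`` offers the linear-ratio >= 3 reading of
    the same guidance.
    """
    if any(a is None or not a.is_valid for a in (avg_rep1, avg_rep2)):
        return _inconclusive("bsa", criterion_db)
    a1 = find_peaks(avg_rep1, design).n1p2_amp_uv
    a2 = find_peaks(avg_rep2, design).n1p2_amp_uv
    stat_db = bsa_statistic_db(a1, a2)
    if np.isinf(stat_db) and stat_db > 0:
        logger.warning("identical repetition amplitudes; BSA statistic is infinite")
    if scale == "db":
        stat, crit = stat_db, criterion_db
        outcome = PRESENT if stat > crit else ABSENT
    elif scale == "linear":
        stat = 10.0 ** (stat_db / 20.0) if np.isfinite(stat_db) else np.copysign(np.inf, stat_db)
        crit = 3.0
        outcome = PRESENT if stat >= crit else ABSENT
    else:
        raise ConfigurationError(f"unknown scale {scale!r}")
    return DetectionResult(method="bsa", statistic=float(stat), criterion=crit,
                           outcome=outcome, info={"a1": a1, "a2": a2, "scale": scale})


# ---- bootstrap method -------------------------------------------------------


def _bootstrap_columns(design: StimulusDesign) -> tuple[np.ndarray, slice, slice, slice]:
    """Column subset (and slices into it) needed by the bootstrap statistic.

    By linearity of the mean, averaging restricted to the analysis windows
    equals the windows of the full average, so null averages are computed
    only over the N1, P2 and noise-floor columns.
    """
    n1 = design.window_indices(design.n1_window_s)
    p2 = design.window_indices(design.p2_window_s)
    nz = design.window_indices(design.rms_noise_window_s)
    cols = np.concatenate([np.arange(*n1), np.arange(*p2), np.arange(*nz)])
    k1 = n1[1] - n1[0]
    k2 = p2[1] - p2[0]
    return cols, slice(0, k1), slice(k1, k1 + k2), slice(k1 + k2, cols.size)


def _statistic_from_windows(avgs: np.ndarray, s_n1: slice, s_p2: slice,
                            s_nz: slice) -> np.ndarray:
    """(N1-P2 peak-to-peak) / noise-floor RMS, vectorised over rows."""
    n1 = avgs[:, s_n1].min(axis=1)
    p2 = avgs[:, s_p2].max(axis=1)
    noise = np.sqrt(np.mean(avgs[:, s_nz] ** 2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(noise > 0, (p2 - n1) / noise, np.inf)


def detect_bootstrap(
    epochs_ipsi: EpochSet,
    epochs_contra: Optional[EpochSet],
    design: StimulusDesign,
    n_boot: int = 499,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    resample_size: int = 240,
    mode: str = "polarity",
) -> DetectionResult:
    """Bootstrap significance of the N1-P2 / noise-floor ratio.

    Accepted epochs from both channels are concatenated into one pool
    (pass ``epochs_contra=None`` for a per-ear decision).  ``mode``:

    * ``"polarity"`` (default): each resampled epoch gets an independent
      random sign flip, building a response-free null; present iff the
      observed statistic exceeds the null's upper ``1 - alpha/2``
      quantile (one-sided — only response-larger-than-noise is
      meaningful).
    * ``"plain"``: plain with-replacement resampling; the interval then
      describes the observed statistic's own uncertainty and the response
      is present iff its lower quantile exceeds 1.
    """
    if n_boot < 99:
        logger.warning("n_boot=%d is small; the null quantiles will be coarse", n_boot)
    pools = [e for e in (epochs_ipsi, epochs_contra) if e is not None]
    data = [e.accepted_data() for e in pools]
    pool = np.vstack(data) if data else np.empty((0, design.n_samples))
    if pool.shape[0] < 2:
        return _inconclusive("bootstrap", 1.0, reason="fewer than 2 accepted epochs")

    cols, s_n1, s_p2, s_nz = _bootstrap_columns(design)
    pool_w = pool[:, cols]
    observed = float(_statistic_from_windows(pool_w.mean(axis=0, keepdims=True),
                                             s_n1, s_p2, s_nz)[0])

    rng = np.random.default_rng(seed)
    n_pool = pool_w.shape[0]
    idx = rng.integers(0, n_pool, size=(n_boot, resample_size))
    if mode == "polarity":
        signs = rng.choice(np.array([-1.0, 1.0]), size=(n_boot, resample_size))
    elif mode == "plain":
        signs = np.ones((n_boot, resample_size))
    else:
        raise ConfigurationError(f"unknown bootstrap mode {mode!r}")

    # accumulate per-iteration epoch weights, then one matmul per recording
    flat = (idx + np.arange(n_boot)[:, None] * n_pool).ravel()
    weights = np.bincount(flat, weights=signs.ravel(), minlength=n_boot * n_pool)
    weights = weights.reshape(n_boot, n_pool) / resample_size
    null_avgs = weights @ pool_w
    null_stats = _statistic_from_windows(null_avgs, s_n1, s_p2, s_nz)
    lo, hi = np.quantile(null_stats, [alpha / 2.0, 1.0 - alpha / 2.0])

    if mode == "polarity":
        outcome = PRESENT if observed > hi else ABSENT
    else:
        outcome = PRESENT if lo > 1.0 else ABSENT
    return DetectionResult(
        method="bootstrap", statistic=observed, criterion=float(hi),
        outcome=outcome, n_boot=n_boot, ci=(float(lo), float(hi)),
        seed=seed, info={"mode": mode, "n_pool": int(n_pool),
                         "resample_size": resample_size, "alpha": alpha},
    )
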