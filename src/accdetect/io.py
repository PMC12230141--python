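"""File I/O: epoch containers, event tables, and the EDF/BDF entry point."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .design import ConfigurationError, StimulusDesign, make_design
from .synth import EpochSet

__all__ = ["write_epochs", "read_epochs", "read_events_csv", "read_recording"]


def write_epochs(path: Union[str, Path], epochs: EpochSet) -> Path:
    """Write one condition's :class:`EpochSet` to a ``.npz`` array container."""
    path = Path(path)
    cond = epochs.condition if epochs.condition is not None else (np.nan, np.nan, -1)
    np.savez(
        path,
        data=epochs.data,
        accepted=epochs.accepted,
        condition=np.asarray(cond, dtype=float),
        channel_role=np.array(epochs.channel_role),
        seed=np.array(-1 if epochs.seed is None else epochs.seed),
        design_json=np.array(json.dumps(epochs.design.to_dict())),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_epochs(path: Union[str, Path]) -> EpochSet:
    """Read an :class:`EpochSet` written by :func:`write_epochs` (bit-exact)."""
    with np.load(path, allow_pickle=False) as z:
        design = make_design(**_design_from_json(str(z["design_json"])))
        cond = tuple(z["condition"])
        condition = None if cond[2] < 0 else (float(cond[0]), float(cond[1]), int(cond[2]))
        seed = int(z["seed"])
        return EpochSet(
            data=z["data"],
            design=design,
            channel_role=str(z["channel_role"]),
            condition=condition,
            accepted=z["accepted"],
            seed=None if seed < 0 else seed,
        )


def _design_from_json(text: str) -> dict:
    d = json.loads(text)
    for key in ("snr_levels_db", "frequencies_hz", "n1_window_s", "p2_window_s",
                "rms_signal_window_s", "rms_noise_window_s"):
        if key in d:
            d[key] = tuple(d[key])
    return d


def read_events_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Event table: one row per sweep with an ``onset_s`` column (+ condition columns)."""
    df = pd.read_csv(path)
    if "onset_s" not in df.columns:
        raise ConfigurationError(f"event table {path} lacks an 'onset_s' column")
    return df


def read_recording(
    path: Union[str, Path],
    design: Optional[StimulusDesign] = None,
    fmt: Optional[str] = None,
    channel_map: Optional[Mapping[str, str]] = None,
) -> Union[EpochSet, dict]:
    """Read a recording: ``.npz`` epoch container, or continuous EDF/BDF.

    EDF/BDF files are read through :mod:`mne` (lazy import) and returned as
    ``{"fs": float, "channels": {label: series_in_uV}}`` with labels
    remapped via ``channel_map`` (file label -> pipeline label).  When a
    design is given, a sampling-rate mismatch raises an error naming both
    rates.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such recording: {path}")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "npz":
        epochs = read_epochs(path)
        if design is not None and epochs.design.fs != design.fs:
            raise ConfigurationError(
                f"recording sampled at {epochs.design.fs} Hz but design expects {design.fs} Hz"
            )
        return epochs
    if fmt in ("edf", "bdf"):
        try:
            import mne
        except ImportError as err:  # pragma: no cover - mne is an optional extra
            raise ConfigurationError("reading EDF/BDF requires the 'mne' package") from err
        reader = mne.io.read_raw_edf if fmt == "edf" else mne.io.read_raw_bdf
        raw = reader(path, preload=True, verbose="error")
        fs = float(raw.info["sfreq"])
        if design is not None and fs != design.fs:
            raise ConfigurationError(
                f"recording sampled at {fs} Hz but design expects {design.fs} Hz"
            )
        data = raw.get_data() * 1e6  # mne uses volts internally
        channels = dict(zip(raw.ch_names, data))
        if channel_map:
            missing = [src for src in channel_map if src not in channels]
            if missing:
                raise ConfigurationError(f"channel(s) {missing} not in {raw.ch_names}")
            channels = {dst: channels[src] for src, dst in channel_map.items()}
        return {"fs": fs, "channels": channels}
    raise ConfigurationError(f"unknown recording format {fmt!r} (expected npz, edf or bdf)")
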