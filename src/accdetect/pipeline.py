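"""End-to-end orchestration: simulate -> preprocess -> detect -> threshold -> agree.

A single master seed fans out to per-stage seeds through a CRC32-based
splitting scheme, so a config plus one integer reproduces every table
bit for bit.  All tables are plain CSV with a header row; missing values
are empty cells.
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import bland_altman, ccc, repeatability
from .design import ConfigurationError, StimulusDesign, make_design
from .detect import detect_bootstrap, detect_bsa, detect_rms
from .preprocess import average, reject_artifacts
from .synth import Cohort, ParticipantProfile, simulate_cohort
from .threshold import classify_dead_region, estimate_threshold
from .waveform import find_peaks

__all__ = ["DEFAULT_CONFIG", "load_config", "stage_seed", "run_pipeline", "RunManifest"]

DEFAULT_CONFIG: dict = {
    "design": {},
    "cohort": {
        "n_participants": 4,
        "variability": 0.25,
        "attrition": 0,
        "dr_spec": {},
        "ten_level_dbhl": 60.0,
        "profile": {},
    },
    "detect": {
        "n_boot": 499,
        "alpha": 0.05,
        "bootstrap_mode": "polarity",
        "bootstrap_per_ear": True,
        "resample_size": 240,
        "rms_criterion": 1.5,
        "rms_numerator": "window",
        "bsa_criterion_db": 3.0,
        "bsa_scale": "db",
    },
    "threshold": {
        "acc_cutoff_db": 12.0,
        "dr_method": "bootstrap",
    },
    "output": {
        "plots": False,
    },
}


def _merge_validate(user: dict, defaults: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (user or {}).items():
        if key not in defaults and path not in ("design", "cohort.profile",
                                                "cohort.dr_spec"):
            raise ConfigurationError(f"unknown config key {path + '.' + key if path else key!r}")
        if isinstance(val, dict) and isinstance(defaults.get(key), dict):
            out[key] = _merge_validate(val, defaults[key], f"{path}.{key}".lstrip("."))
        else:
            out[key] = val
    return out


def load_config(source: Union[str, Path, dict, None]) -> dict:
    """Load + validate a pipeline config (YAML path or dict); defaults fill gaps.

    Unknown keys raise :class:`ConfigurationError` before any computation.
    """
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    return _merge_validate(user, DEFAULT_CONFIG)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master hashed with the stage name (< 2^31)."""
    return (int(master_seed) * 2654435761 ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunManifest:
    """Everything needed to replay a run: config snapshot, seeds, outputs, statuses."""

    config: dict
    master_seed: int
    stage_seeds: dict
    version: str
    recordings: pd.DataFrame
    tables: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "version": self.version,
                "master_seed": self.master_seed,
                "stage_seeds": self.stage_seeds,
                "config": self.config,
                "files": {k: str(v) for k, v in self.files.items()},
                "n_recordings": int(len(self.recordings)),
                "status_counts": self.recordings["status"].value_counts().to_dict(),
            },
            sort_keys=True,
        )


def _method_thresholds(outcome_map: dict, design: StimulusDesign) -> object:
    outcomes = [outcome_map.get(s) for s in design.snr_levels_db]
    return estimate_threshold(outcomes, design)


def run_pipeline(config: Union[str, Path, dict, None] = None, seed: int = 0,
                 out_dir: Union[str, Path, None] = None) -> RunManifest:
    """Run the full synthetic pipeline and (optionally) write all tables.

    Returns a :class:`RunManifest` whose ``tables`` hold the peak,
    detection, threshold, dead-region and agreement DataFrames.
    """
    cfg = load_config(config)
    design = make_design(**cfg["design"])
    seeds = {name: stage_seed(seed, name) for name in ("simulate", "bootstrap")}

    base_profile = ParticipantProfile(**cfg["cohort"]["profile"])
    cohort = simulate_cohort(
        design,
        n_participants=int(cfg["cohort"]["n_participants"]),
        dr_spec={str(k): float(v) for k, v in (cfg["cohort"]["dr_spec"] or {}).items()},
        seed=seeds["simulate"],
        base_profile=base_profile,
        variability=float(cfg["cohort"]["variability"]),
        attrition=int(cfg["cohort"]["attrition"]),
        ten_level_dbhl=float(cfg["cohort"]["ten_level_dbhl"]),
    )

    det_cfg = cfg["detect"]
    channels = ("ipsi", "contra")
    peak_rows, det_rows = [], []
    averaged: dict = {}
    status_rows = []

    boot_counter = 0
    for row in cohort.manifest.itertuples():
        if row.status != "ok":
            status_rows.append({"participant": row.participant, "frequency_hz": row.frequency_hz,
                                "snr_db": row.snr_db, "repetition": row.repetition,
                                "status": "missing"})
            continue
        per_ch = {}
        for ch in channels:
            epochs = cohort.epochs(row.participant, row.frequency_hz, row.snr_db,
                                   row.repetition, ch)
            epochs, _ = reject_artifacts(epochs)
            avg = average(epochs)
            key = (row.participant, row.frequency_hz, row.snr_db, row.repetition, ch)
            averaged[key] = avg
            per_ch[ch] = epochs
            if avg.is_valid:
                pk = find_peaks(avg, design)
                peak_rows.append({
                    "participant": row.participant, "frequency_hz": row.frequency_hz,
                    "snr_db": row.snr_db, "repetition": row.repetition, "channel": ch,
                    "n1_latency_s": pk.n1_latency_s, "n1_amp_uv": pk.n1_amp_uv,
                    "p2_latency_s": pk.p2_latency_s, "p2_amp_uv": pk.p2_amp_uv,
                    "n1p2_amp_uv": pk.n1p2_amp_uv,
                    "n_accepted": avg.n_accepted, "n_rejected": avg.n_rejected,
                })
            res = detect_rms(avg, design, criterion=float(det_cfg["rms_criterion"]),
                             numerator=det_cfg["rms_numerator"])
            det_rows.append({
                "participant": row.participant, "frequency_hz": row.frequency_hz,
                "snr_db": row.snr_db, "repetition": row.repetition, "channel": ch,
                "method": "rms", "statistic": res.statistic,
                "criterion": res.criterion, "outcome": res.outcome, "seed": "",
            })
        # bootstrap: per-ear (default) or pooled across mastoids
        boot_targets = (
            [("ipsi", per_ch["ipsi"], None), ("contra", per_ch["contra"], None)]
            if det_cfg["bootstrap_per_ear"]
            else [("pooled", per_ch["ipsi"], per_ch["contra"])]
        )
        for ch, e1, e2 in boot_targets:
            bseed = stage_seed(seeds["bootstrap"], f"boot-{boot_counter}")
            boot_counter += 1
            res = detect_bootstrap(
                e1, e2, design, n_boot=int(det_cfg["n_boot"]),
                alpha=float(det_cfg["alpha"]), seed=bseed,
                resample_size=int(det_cfg["resample_size"]),
                mode=det_cfg["bootstrap_mode"],
            )
            det_rows.append({
                "participant": row.participant, "frequency_hz": row.frequency_hz,
                "snr_db": row.snr_db, "repetition": row.repetition, "channel": ch,
                "method": "bootstrap", "statistic": res.statistic,
                "criterion": res.criterion, "outcome": res.outcome, "seed": bseed,
            })
        status_rows.append({"participant": row.participant, "frequency_hz": row.frequency_hz,
                            "snr_db": row.snr_db, "repetition": row.repetition, "status": "ok"})

    # BSA: compares the two repetitions of the same condition and channel
    for row in cohort.manifest[cohort.manifest.repetition == 1].itertuples():
        for ch in channels:
            k1 = (row.participant, row.frequency_hz, row.snr_db, 1, ch)
            k2 = (row.participant, row.frequency_hz, row.snr_db, 2, ch)
            res = detect_bsa(averaged.get(k1), averaged.get(k2), design,
                             criterion_db=float(det_cfg["bsa_criterion_db"]),
                             scale=det_cfg["bsa_scale"])
            det_rows.append({
                "participant": row.participant, "frequency_hz": row.frequency_hz,
                "snr_db": row.snr_db, "repetition": "1+2", "channel": ch,
                "method": "bsa", "statistic": res.statistic,
                "criterion": res.criterion, "outcome": res.outcome, "seed": "",
            })

    detections = pd.DataFrame(det_rows)
    peaks = pd.DataFrame(peak_rows)

    # thresholds per participant/frequency/method/repetition/channel
    thr_rows = []
    participants = [p.participant_id for p in cohort.profiles]
    boot_channels = channels if det_cfg["bootstrap_per_ear"] else ("pooled",)
    for pid in participants:
        for f in design.frequencies_hz:
            for method, reps, chans in (("rms", (1, 2), channels),
                                        ("bootstrap", (1, 2), boot_channels),
                                        ("bsa", ("1+2",), channels)):
                for rep in reps:
                    for ch in chans:
                        sel = detections[
                            (detections.participant == pid)
                            & (detections.frequency_hz == f)
                            & (detections.method == method)
                            & (detections.repetition == rep)
                            & (detections.channel == ch)
                        ]
                        omap = dict(zip(sel.snr_db, sel.outcome))
                        tr = _method_thresholds(omap, design)
                        thr_rows.append({
                            "participant": pid, "frequency_hz": f, "method": method,
                            "repetition": rep, "channel": ch,
                            "threshold_db_snr": tr.threshold_db_snr,
                            "pattern": tr.pattern, "reason": tr.reason,
                        })
    thresholds = pd.DataFrame(thr_rows)

    # dead-region classification
    dr_method = cfg["threshold"]["dr_method"]
    dr_rep = "1+2" if dr_method == "bsa" else 1
    dr_ch = "pooled" if (dr_method == "bootstrap" and not det_cfg["bootstrap_per_ear"]) else "ipsi"
    dr_rows = []
    for beh in cohort.behavioural.itertuples():
        sel = thresholds[
            (thresholds.participant == beh.participant)
            & (thresholds.frequency_hz == beh.frequency_hz)
            & (thresholds.method == dr_method)
            & (thresholds.repetition == dr_rep)
            & (thresholds.channel == dr_ch)
        ]
        acc_thr = None
        if len(sel) and pd.notna(sel.iloc[0].threshold_db_snr):
            acc_thr = float(sel.iloc[0].threshold_db_snr)
        cls = classify_dead_region(
            acc_thr, beh.masked_threshold_dbhl, beh.ten_level_dbhl,
            beh.absolute_threshold_dbhl,
            acc_cutoff_db=float(cfg["threshold"]["acc_cutoff_db"]),
        )
        dr_rows.append({
            "participant": beh.participant, "frequency_hz": beh.frequency_hz,
            "method": dr_method,
            "acc_threshold_db_snr": cls.acc_threshold_db_snr,
            "acc_rule_positive": cls.acc_rule_positive,
            "masked_threshold_dbhl": cls.masked_threshold_dbhl,
            "ten_level_dbhl": cls.ten_level_dbhl,
            "absolute_threshold_dbhl": cls.absolute_threshold_dbhl,
            "ten_rule_positive": cls.ten_rule_positive,
        })
    dr_table = pd.DataFrame(dr_rows)

    agreement = _agreement_tables(thresholds, design, det_cfg)

    manifest = RunManifest(
        config=cfg, master_seed=int(seed), stage_seeds=seeds, version=__version__,
        recordings=pd.DataFrame(status_rows),
        tables={
            "peaks": peaks, "detections": detections, "thresholds": thresholds,
            "dr_classification": dr_table, "agreement": agreement,
            "cohort_manifest": cohort.manifest, "behavioural": cohort.behavioural,
        },
    )
    if out_dir is not None:
        _write_outputs(manifest, Path(out_dir), cfg)
    return manifest


def _threshold_series(thresholds: pd.DataFrame, f: float, method: str, rep, ch: str,
                      index: pd.MultiIndex) -> pd.Series:
    sel = thresholds[
        (thresholds.frequency_hz == f) & (thresholds.method == method)
        & (thresholds.repetition == rep)
        & (thresholds.channel.isin([ch] if ch != "any" else ["ipsi", "contra", "pooled"]))
    ]
    s = sel.set_index(["participant", "channel"]).threshold_db_snr
    return s.reindex(index).astype(float)


def _agreement_tables(thresholds: pd.DataFrame, design: StimulusDesign,
                      det_cfg: dict) -> pd.DataFrame:
    """Pairwise method agreement and test-retest repeatability per frequency.

    Pairing key is (participant, channel); ipsi/contra thresholds enter as
    repeated measurements of the same participant (the replicate label for
    the variance correction).  Method comparisons use the first repetition
    of the RMS and bootstrap thresholds and the overall BSA threshold.
    """
    rows = []
    channels = ["ipsi", "contra"]
    boot_ch = channels if det_cfg["bootstrap_per_ear"] else ["pooled"]
    participants = sorted(thresholds.participant.unique())
    for f in design.frequencies_hz:
        idx = pd.MultiIndex.from_product([participants, channels],
                                         names=["participant", "channel"])
        idx_boot = pd.MultiIndex.from_product([participants, boot_ch],
                                              names=["participant", "channel"])
        series = {
            "bsa": _threshold_series(thresholds, f, "bsa", "1+2", "any", idx),
            "rms1": _threshold_series(thresholds, f, "rms", 1, "any", idx),
            "rms2": _threshold_series(thresholds, f, "rms", 2, "any", idx),
            "boot1": _threshold_series(thresholds, f, "bootstrap", 1, "any", idx_boot),
            "boot2": _threshold_series(thresholds, f, "bootstrap", 2, "any", idx_boot),
        }
        def _on_boot_index(s: pd.Series) -> pd.Series:
            if boot_ch == channels:
                return s
            # pooled bootstrap decisions: pair against the ipsilateral threshold
            vals = s.xs("ipsi", level="channel")
            return pd.Series([vals.get(p, np.nan) for p, _ in idx_boot], index=idx_boot)

        comparisons = [
            ("bsa_vs_rms", series["bsa"], series["rms1"], False),
            ("bsa_vs_bootstrap", _on_boot_index(series["bsa"]), series["boot1"], False),
            ("rms_vs_bootstrap", _on_boot_index(series["rms1"]), series["boot1"], False),
            ("rms_repeatability", series["rms1"], series["rms2"], True),
            ("bootstrap_repeatability", series["boot1"], series["boot2"], True),
        ]
        for name, x, y, is_rep in comparisons:
            pair_mask = x.notna() & y.notna()
            n_pairs = int(pair_mask.sum())
            base = {"comparison": name, "frequency_hz": f, "n": n_pairs}
            if n_pairs < 3:
                rows.append(base)
                continue
            subj = x.index.get_level_values("participant")[pair_mask.to_numpy()]
            if is_rep:
                ba = repeatability(x[pair_mask], y[pair_mask], subjects=subj)
            else:
                ba = bland_altman(x[pair_mask], y[pair_mask], repeated=True, subjects=subj)
            try:
                cc = ccc(x[pair_mask], y[pair_mask])
                ccc_est, ccc_lo, ccc_hi = cc.estimate, cc.ci[0], cc.ci[1]
            except ValueError:
                ccc_est = ccc_lo = ccc_hi = np.nan
            rows.append({
                **base, "bias": ba.bias, "sd_diff": ba.sd_diff,
                "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
                "bias_ci_lower": ba.ci_bias[0], "bias_ci_upper": ba.ci_bias[1],
                "loa_lower_ci_lower": ba.ci_loa_lower[0],
                "loa_lower_ci_upper": ba.ci_loa_lower[1],
                "loa_upper_ci_lower": ba.ci_loa_upper[0],
                "loa_upper_ci_upper": ba.ci_loa_upper[1],
                "cor": ba.cor, "ccc": ccc_est,
                "ccc_ci_lower": ccc_lo, "ccc_ci_upper": ccc_hi,
            })
    return pd.DataFrame(rows)


def _write_outputs(manifest: RunManifest, out_dir: Path, cfg: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, table in manifest.tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, na_rep="")
        manifest.files[name] = path
    if cfg["output"]["plots"]:
        from .plotting import bland_altman_panels

        fig_path = out_dir / "agreement_bland_altman.png"
        bland_altman_panels(manifest.tables["thresholds"],
                            manifest.tables["agreement"], fig_path)
        manifest.files["agreement_plot"] = fig_path
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(manifest.to_yaml())
    manifest.files["manifest"] = manifest_path
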