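"""Plain-text I/O for cohorts, beat tables and results.

Beat tables are columnar CSV (``beat_time_s``, ``rri_s``, ``ppga``); the
roster is one CSV row per subject; the planted-event truth log and the
detected-event/metric tables are CSV; configurations round-trip through
YAML. EDF ingestion (raw polysomnogram exports) is an extension point: a
caller can construct a :class:`~vocrisk.preprocessing.BeatSeries` from any
beat-level source and enter the pipeline at
:func:`~vocrisk.preprocessing.preprocess_night`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocessing import BeatSeries
from .synthetic_data import CohortBundle, CohortConfig, EventTruth

__all__ = [
    "read_beats_csv",
    "write_beats_csv",
    "write_cohort",
    "read_config_yaml",
    "write_config_yaml",
]


def read_beats_csv(path: str | Path) -> BeatSeries:
    """Read a per-beat table (columns beat_time_s, rri_s, ppga)."""
    df = pd.read_csv(path)
    missing = {"beat_time_s", "rri_s", "ppga"} - set(df.columns)
    if missing:
        raise ValueError(f"beat CSV missing columns: {sorted(missing)}")
    return BeatSeries(
        beat_times=df["beat_time_s"].to_numpy(float),
        rri=df["rri_s"].to_numpy(float),
        ppga=df["ppga"].to_numpy(float),
    )


def write_beats_csv(beats: BeatSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"beat_time_s": beats.beat_times, "rri_s": beats.rri, "ppga": beats.ppga}
    ).to_csv(path, index=False)


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write a cohort as roster CSV, per-subject beat CSVs, truth CSV, YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(bundle.roster).to_csv(out / "roster.csv", index=False)
    beats_dir = out / "beats"
    beats_dir.mkdir(exist_ok=True)
    for sid, beats in bundle.signals.items():
        write_beats_csv(beats, beats_dir / f"{sid}.csv")
    pd.DataFrame([dataclasses.asdict(t) for t in bundle.truth]).to_csv(
        out / "truth.csv", index=False
    )
    rows = [
        {"subject_id": sid, "start_s": a, "end_s": b}
        for sid, ivs in bundle.artifact_intervals.items()
        for a, b in ivs
    ]
    pd.DataFrame(rows, columns=["subject_id", "start_s", "end_s"]).to_csv(
        out / "artifacts.csv", index=False
    )
    if bundle.config is not None:
        write_config_yaml(bundle.config, out / "config.yaml")


def read_cohort(indir: str | Path) -> CohortBundle:
    """Read a cohort previously written by :func:`write_cohort`."""
    src = Path(indir)
    roster = pd.read_csv(src / "roster.csv").to_dict("records")
    signals = {
        rec["id"]: read_beats_csv(src / "beats" / f"{rec['id']}.csv")
        for rec in roster
    }
    truth_df = pd.read_csv(src / "truth.csv")
    truth = [
        EventTruth(r.subject_id, r.onset_time, r.duration, r.depth)
        for r in truth_df.itertuples()
    ]
    art = pd.read_csv(src / "artifacts.csv")
    intervals: dict[str, list[tuple[float, float]]] = {rec["id"]: [] for rec in roster}
    for r in art.itertuples():
        intervals[r.subject_id].append((r.start_s, r.end_s))
    cfg_path = src / "config.yaml"
    config = read_config_yaml(cfg_path) if cfg_path.exists() else None
    return CohortBundle(roster, signals, intervals, truth, config)


def write_config_yaml(config: CohortConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["pain_link"] = list(d["pain_link"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config_yaml(path: str | Path) -> CohortConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "pain_link" in d:
        d["pain_link"] = tuple(d["pain_link"])
    return CohortConfig(**d)
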