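"""Reading and writing the bout-table interchange format.

A bout table is a flat CSV with fixed columns
``trial_id,fly_id,action,start_frame,end_frame[,target]`` plus a JSON or
YAML *sidecar* carrying trial metadata (frame rate, duration, roster,
optional copulation onset and photostimulation protocol reference). The
pair is diff-able, language-neutral, and round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .catalog import ActionCatalog, DEFAULT_CATALOG
from .core import Bout, BoutTable, FlyInfo, Trial

log = logging.getLogger("dyadica")

BOUT_COLUMNS = ["trial_id", "fly_id", "action", "start_frame", "end_frame"]
_SIDECAR_SUFFIXES = (".json", ".yaml", ".yml")


def _sidecar_path(csv_path: Path) -> Path:
    for suffix in _SIDECAR_SUFFIXES:
        cand = csv_path.with_suffix(suffix)
        if cand.exists():
            return cand
    raise FileNotFoundError(
        f"no trial sidecar ({'/'.join(_SIDECAR_SUFFIXES)}) next to {csv_path}"
    )


def _load_sidecar(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def trial_from_dict(meta: dict) -> Trial:
    if "frame_rate" not in meta or meta["frame_rate"] is None:
        raise ValueError("trial sidecar is missing 'frame_rate'")
    roster = tuple(
        FlyInfo(
            fly_id=str(f["fly_id"]),
            sex=f.get("sex", "male"),
            strain=f.get("strain", "wildtype"),
            housing=f.get("housing", "single"),
            genotype=f.get("genotype", "wildtype"),
            wing_clipped=bool(f.get("wing_clipped", False)),
        )
        for f in meta.get("roster", [])
    )
    return Trial(
        trial_id=str(meta["trial_id"]),
        assay=meta.get("assay", "dyad"),
        frame_rate=float(meta["frame_rate"]),
        duration=int(meta["duration_frames"]),
        roster=roster,
        copulation_onset=(
            None
            if meta.get("copulation_onset") is None
            else int(meta["copulation_onset"])
        ),
        protocol_ref=meta.get("protocol_ref"),
    )


def trial_to_dict(trial: Trial) -> dict:
    return {
        "trial_id": trial.trial_id,
        "assay": trial.assay,
        "frame_rate": trial.frame_rate,
        "duration_frames": trial.duration,
        "copulation_onset": trial.copulation_onset,
        "protocol_ref": trial.protocol_ref,
        "roster": [
            {
                "fly_id": f.fly_id,
                "sex": f.sex,
                "strain": f.strain,
                "housing": f.housing,
                "genotype": f.genotype,
                "wing_clipped": f.wing_clipped,
            }
            for f in trial.roster
        ],
    }


def read_bout_table(
    path: Union[str, Path],
    catalog: Optional[ActionCatalog] = None,
    sidecar: Union[str, Path, None] = None,
) -> tuple[Trial, BoutTable]:
    """Read a bout CSV plus its trial sidecar and validate both.

    Raises ``ValueError`` naming the offending row for unknown action
    labels, non-positive-length bouts, or overlapping same-fly same-action
    bouts; a missing frame rate in the sidecar is also an error.
    """
    path = Path(path)
    catalog = catalog or DEFAULT_CATALOG
    meta = _load_sidecar(Path(sidecar) if sidecar else _sidecar_path(path))
    trial = trial_from_dict(meta)

    df = pd.read_csv(path, dtype={"trial_id": str, "fly_id": str, "action": str})
    missing = [c for c in BOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bout CSV missing columns {missing}")
    bouts = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.action not in catalog:
            raise ValueError(
                f"row {i}: unknown action label {row.action!r}"
            )
        start, end = int(row.start_frame), int(row.end_frame)
        if end <= start:
            raise ValueError(
                f"row {i}: end_frame {end} <= start_frame {start}"
            )
        target = getattr(row, "target", None)
        if target is not None and (pd.isna(target) or target == ""):
            target = None
        bouts.append(
            Bout(
                fly_id=str(row.fly_id),
                action=row.action,
                start=start,
                end=end,
                target=target,
            )
        )
    table = BoutTable(trial.trial_id, tuple(bouts))
    table.validate_against(trial, catalog)
    log.info(
        "read %s: trial %s, %d bouts, %d flies, %.1f s at %g Hz",
        path,
        trial.trial_id,
        len(table),
        len(trial.roster),
        trial.duration_s,
        trial.frame_rate,
    )
    return trial, table


def write_bout_table(
    trial: Trial,
    bouts: BoutTable,
    path: Union[str, Path],
    sidecar_format: str = "json",
) -> Path:
    """Write the CSV + sidecar pair; round-trips bit-exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    has_target = any(b.target is not None for b in bouts)
    cols = BOUT_COLUMNS + (["target"] if has_target else [])
    records = [
        {
            "trial_id": trial.trial_id,
            "fly_id": b.fly_id,
            "action": b.action,
            "start_frame": b.start,
            "end_frame": b.end,
            **({"target": b.target or ""} if has_target else {}),
        }
        for b in bouts
    ]
    pd.DataFrame.from_records(records, columns=cols).to_csv(path, index=False)
    meta = trial_to_dict(trial)
    if sidecar_format == "json":
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    elif sidecar_format in ("yaml", "yml"):
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    else:
        raise ValueError(f"sidecar_format must be json or yaml, got {sidecar_format!r}")
    return path
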