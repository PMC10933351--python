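"""Dataset readers and writers.

Interchange layout (all plain text, diffable):

* ``manifest.json`` — lists mice with their group and per-mouse files, plus
  optional assay CSVs and the simulator ground truth.
* per mouse, a trace CSV with columns ``day, trial_index, time_ms, value``
  (``time_ms`` relative to CS onset) and a JSON sidecar holding the trial
  metadata records.
* tidy assay/outcome CSVs with one row per record, headers equal to the
  field names of the corresponding record type.

``load_deposited_dataset`` maps a user-downloaded copy of a deposited study
dataset into the same types through an explicit column-mapping config; it
never downloads anything.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import RawTrial, TrialMeta


__all__ = [
    "write_dataset",
    "read_dataset",
    "load_deposited_dataset",
]


def write_dataset(
    trials: Sequence[RawTrial],
    out_dir: str | Path,
    ground_truth: Optional[pd.DataFrame] = None,
    assays: Optional[dict[str, pd.DataFrame]] = None,
) -> Path:
    """Write trials (and optional tables) to an interchange directory.

    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_mouse: dict[str, list[RawTrial]] = {}
    for t in trials:
        by_mouse.setdefault(t.meta.mouse_id, []).append(t)

    manifest: dict = {"mice": [], "assays": {}}
    for mouse_id in sorted(by_mouse):
        ts = by_mouse[mouse_id]
        frames = []
        metas = []
        for t in ts:
            frames.append(
                pd.DataFrame(
                    {
                        "day": t.meta.day,
                        "trial_index": t.meta.trial_index,
                        "time_ms": t.times_ms(),
                        "value": t.samples,
                    }
                )
            )
            m = t.meta.to_dict()
            m["sample_rate_hz"] = t.sample_rate_hz
            metas.append(m)
        trace_file = f"{mouse_id}_traces.csv"
        meta_file = f"{mouse_id}_meta.json"
        # full repr precision so write -> read round-trips exactly
        pd.concat(frames, ignore_index=True).to_csv(out / trace_file, index=False)
        (out / meta_file).write_text(json.dumps(metas))
        manifest["mice"].append(
            {
                "mouse_id": mouse_id,
                "group": ts[0].meta.group.value,
                "trace_file": trace_file,
                "meta_file": meta_file,
            }
        )
    if ground_truth is not None:
        ground_truth.to_csv(out / "ground_truth.csv", index=False)
        manifest["ground_truth"] = "ground_truth.csv"
    for name, frame in (assays or {}).items():
        fn = f"assay_{name}.csv"
        frame.to_csv(out / fn, index=False)
        manifest["assays"][name] = fn
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_dataset(
    manifest_path: str | Path,
) -> tuple[list[RawTrial], dict[str, pd.DataFrame]]:
    """Read an interchange dataset back into typed objects.

    Invariants are re-validated on load; malformed trials are reported with
    the file and trial they came from.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())

    trials: list[RawTrial] = []
    for entry in manifest.get("mice", []):
        trace_path = root / entry["trace_file"]
        meta_path = root / entry["meta_file"]
        for p in (trace_path, meta_path):
            if not p.exists():
                raise FileNotFoundError(
                    f"manifest references missing file: {p}"
                )
        metas = {
            (m["day"], m["trial_index"]): m
            for m in json.loads(meta_path.read_text())
        }
        traces = pd.read_csv(trace_path)
        for (day, trial_index), sub in traces.groupby(
            ["day", "trial_index"], sort=True
        ):
            key = (int(day), int(trial_index))
            if key not in metas:
                raise ValueError(
                    f"{trace_path}: trial day={day} index={trial_index} "
                    f"has no metadata record in {meta_path.name}"
                )
            m = dict(metas[key])
            rate = float(m.pop("sample_rate_hz"))
            time_ms = sub["time_ms"].to_numpy(dtype=float)
            order = np.argsort(time_ms)
            time_ms = time_ms[order]
            values = sub["value"].to_numpy(dtype=float)[order]
            cs_onset_index = int(np.searchsorted(time_ms, 0.0))
            try:
                trials.append(
                    RawTrial(
                        meta=TrialMeta.from_dict(m),
                        samples=values,
                        sample_rate_hz=rate,
                        cs_onset_index=cs_onset_index,
                        pre_cs_ms=-float(time_ms[0]),
                    )
                )
            except ValueError as exc:
                raise ValueError(
                    f"{trace_path}: trial day={day} index={trial_index} "
                    f"violates a trial invariant: {exc}"
                ) from exc

    assays = {
        name: pd.read_csv(root / fn)
        for name, fn in manifest.get("assays", {}).items()
    }
    return trials, assays


# ---------------------------------------------------------------------------
# deposited-dataset loader

_EYEBLINK_FIELDS = {
    "mouse_id",
    "group",
    "day",
    "trial_index",
    "trial_type",
    "time_ms",
    "value",
}
_ASSAY_FIELDS = {"mouse_id", "group", "day", "trial_or_run", "value", "beam_width_mm"}


def load_deposited_dataset(
    path: str | Path, mapping_path: str | Path
) -> dict:
    """Best-effort loader for a user-downloaded copy of a deposited dataset.

    ``mapping_path`` is a YAML file the user writes for the deposited
    layout, e.g.::

        eyeblink:
          file: eyeblink_traces.csv
          columns: {mouse: mouse_id, session: day, ...}
        assays:
          rotarod:
            file: rotarod.csv
            columns: {animal: mouse_id, housing: group, latency: value, ...}

    Keys of ``columns`` are the deposited column names, values the package's
    logical field names. Unknown logical fields and columns absent from the
    file are reported explicitly. Returns a dict with the mapped eyeblink
    long table (if any), per-assay tidy tables, and per-mouse-day trial
    counts for manual cross-checking. Never downloads anything.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"deposited dataset not found at {path}; download the study's "
            "data repository manually and point this loader at your local copy"
        )
    mapping = yaml.safe_load(Path(mapping_path).read_text()) or {}
    unknown_sections = set(mapping) - {"eyeblink", "assays"}
    if unknown_sections:
        raise ValueError(
            f"unknown mapping sections: {sorted(unknown_sections)}"
        )

    out: dict = {"assays": {}, "counts": None, "eyeblink": None}

    def _apply(section: dict, allowed: set[str], label: str) -> pd.DataFrame:
        fn = path / section["file"]
        if not fn.exists():
            raise FileNotFoundError(f"{label}: mapped file missing: {fn}")
        columns = section.get("columns", {})
        bad_targets = set(columns.values()) - allowed
        if bad_targets:
            raise ValueError(
                f"{label}: unknown logical fields in mapping: "
                f"{sorted(bad_targets)} (allowed: {sorted(allowed)})"
            )
        frame = pd.read_csv(fn)
        missing_src = set(columns) - set(frame.columns)
        if missing_src:
            raise ValueError(
                f"{label}: mapped columns absent from {fn.name}: "
                f"{sorted(missing_src)}; file has {list(frame.columns)}"
            )
        frame = frame.rename(columns=columns)
        unmapped = [c for c in frame.columns if c not in allowed]
        if unmapped:
            frame.attrs["unmapped_columns"] = unmapped
        return frame

    if "eyeblink" in mapping:
        frame = _apply(mapping["eyeblink"], _EYEBLINK_FIELDS, "eyeblink")
        out["eyeblink"] = frame
        key_cols = [c for c in ("mouse_id", "day") if c in frame.columns]
        if key_cols:
            if "trial_index" in frame.columns:
                counts = frame.groupby(key_cols)["trial_index"].nunique()
            else:
                counts = frame.groupby(key_cols).size()
            out["counts"] = counts.rename("n_trials").reset_index()

    for assay, section in mapping.get("assays", {}).items():
        frame = _apply(section, _ASSAY_FIELDS, f"assay {assay}")
        out["assays"][assay] = frame
    return out


def write_outcomes(
    outcomes: pd.DataFrame, detections: pd.DataFrame, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outcomes.to_csv(out / "outcomes.csv", index=False)
    detections.to_csv(out / "detections.csv", index=False)
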