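"""On-disk recording format: one CSV per channel plus a YAML manifest.

Layout of a recording directory::

    manifest.yaml       # subject_id, channels: {modality: [{file, fs}]},
                        # baseline_spans (optional)
    ecg.csv             # columns time_s,value
    emg1.csv .. emg5.csv
    eda.csv
    ppg.csv
    annotations.csv     # columns time_s,nrs  (may be empty apart from header)

The write→read round trip is the identity on :class:`Recording` objects to
numeric tolerance 1e-9.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (DEFAULT_CHANNEL_SCHEMA, FormatError, PainAnnotation,
                    Recording, Signal, ValidationError)

MANIFEST = "manifest.yaml"
ANNOTATIONS = "annotations.csv"


def write_recording(rec: Recording, path: str | Path,
                    schema: dict[str, int] | None = None) -> Path:
    """Serialize a Recording to a directory of CSV files + manifest."""
    rec.validate_schema(schema)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"subject_id": rec.subject_id, "channels": {}}
    for mod, sigs in rec.channels.items():
        entries = []
        for i, sig in enumerate(sigs):
            fname = f"{mod.lower()}{i + 1 if len(sigs) > 1 else ''}.csv"
            df = pd.DataFrame({"time_s": sig.times(), "value": sig.samples})
            df.to_csv(path / fname, index=False, float_format="%.10g")
            entries.append({"file": fname, "fs": float(sig.fs),
                            "t0": float(sig.t0), "name": sig.name})
        manifest["channels"][mod] = entries
    if rec.baseline_spans:
        manifest["baseline_spans"] = [[float(a), float(b)]
                                      for a, b in rec.baseline_spans]

    ann = pd.DataFrame({"time_s": [a.t for a in rec.annotations],
                        "nrs": [a.nrs for a in rec.annotations]})
    ann.to_csv(path / ANNOTATIONS, index=False, float_format="%.10g")
    (path / MANIFEST).write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_recording(path: str | Path,
                   schema: dict[str, int] | None = None) -> Recording:
    """Load a recording directory written by :func:`write_recording`."""
    path = Path(path)
    mpath = path / MANIFEST
    if not mpath.exists():
        raise FormatError(f"no {MANIFEST} in {path}")
    manifest = yaml.safe_load(mpath.read_text())

    channels: dict[str, list[Signal]] = {}
    for mod, entries in manifest.get("channels", {}).items():
        sigs = []
        for entry in entries:
            fpath = path / entry["file"]
            if not fpath.exists():
                raise FormatError(f"missing channel file {entry['file']}")
            df = pd.read_csv(fpath)
            t = df["time_s"].to_numpy(float)
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValidationError(f"non-monotone time column in {entry['file']}")
            sigs.append(Signal(samples=df["value"].to_numpy(float),
                               fs=float(entry["fs"]),
                               t0=float(entry.get("t0", t[0] if t.size else 0.0)),
                               name=entry.get("name", "")))
        channels[mod] = sigs

    annotations: list[PainAnnotation] = []
    apath = path / ANNOTATIONS
    if apath.exists():
        adf = pd.read_csv(apath)
        if len(adf):
            t = adf["time_s"].to_numpy(float)
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValidationError("non-monotone time column in annotations.csv")
            for ts, nrs in zip(t, adf["nrs"].to_numpy()):
                annotations.append(PainAnnotation(t=float(ts), nrs=int(nrs)))

    spans = [tuple(s) for s in manifest.get("baseline_spans", [])]
    rec = Recording(subject_id=str(manifest["subject_id"]), channels=channels,
                    annotations=annotations, baseline_spans=spans)
    rec.validate_schema(schema)
    return rec


def features_to_frame(windows) -> pd.DataFrame:
    """Flatten FeatureWindow objects into a long-format table.

    Columns: subject_id, modality, t_start, window_len, feature_source,
    then one column per named feature.  Windows of different modalities
    produce NaN in each other's feature columns.
    """
    rows = []
    for w in windows:
        row = {"subject_id": w.subject_id, "modality": w.modality,
               "t_start": w.t_start, "t_end": w.t_end,
               "window_len": w.window_len, "feature_source": w.feature_source}
        row.update({f"{w.modality}_{n}": v for n, v in zip(w.names, w.values)})
        rows.append(row)
    return pd.DataFrame(rows)
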