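"""Reading and writing virtual-subject populations and result tables.

Two on-disk layouts are supported:

``synthetic_csv``
    The package's own directory format: one ``manifest.json`` describing
    geometry, demographics and ground truth, plus one CSV per waveform
    (columns ``t,value``, with ``# site=... modality=... fs=...`` header
    comments).  Written by :func:`write_population`; round-trips exactly.

``zenodo_matlab``
    A MATLAB-container layout for externally deposited populations.  The
    container schema is isolated behind a single field-name mapping
    (:data:`DEFAULT_MATLAB_MAPPING`), so a layout change requires editing
    only the mapping, not the loader.

Pressures are converted to Pa on load; loading never mutates on-disk data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .core import (INDEX_NAMES, ArterialSegment, IndexPanel, PulseWave,
                   VirtualSubject, convert_pressure)
from .synthetic import GroundTruth

_FMT = "%.17g"  # lossless float round-trip


# ---------------------------------------------------------------------------
# synthetic_csv writer

def _wave_filename(subject_id: str, site: str, modality: str) -> str:
    return f"{subject_id}__{site}__{modality}.csv"


def write_population(population, path) -> Path:
    """Write ``[(VirtualSubject, GroundTruth), ...]`` as a directory.

    Returns the directory path.  Waveforms go to per-signal CSV files and
    everything else (geometry, demographics, ground truth) to
    ``manifest.json``; floats are serialised losslessly.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {"format": "synthetic_csv", "subjects": []}
    for subject, truth in population:
        entry = {
            "id": subject.id,
            "age": subject.age,
            "height": subject.height,
            "rho": subject.rho,
            "aortic_path": [
                {"length": s.length, "r_in": s.r_in, "r_out": s.r_out,
                 "k1": s.k1, "k2": s.k2, "k3": s.k3,
                 "h_over_r": s.h_over_r}
                for s in subject.aortic_path
            ],
            "path_lengths": dict(subject.path_lengths),
            "waves": [],
            "truth": None,
        }
        for (site, modality), wave in sorted(subject.waves.items()):
            fname = _wave_filename(subject.id, site, modality)
            with open(root / fname, "w") as fh:
                fh.write(f"# site={site}\n# modality={modality}\n"
                         f"# fs={wave.fs!r}\n")
                fh.write("t,value\n")
                for t, v in zip(wave.t, wave.samples):
                    fh.write(f"{float(t)!r},{float(v)!r}\n")
            entry["waves"].append({"site": site, "modality": modality,
                                   "fs": wave.fs, "file": fname})
        if truth is not None:
            entry["truth"] = {
                "e_ao": truth.e_ao,
                "ao_pwv_t": truth.ao_pwv_t,
                "dc_true": truth.dc_true,
                "onset_time": truth.onset_time,
                "upstroke_start": truth.upstroke_start,
                "reflection_gain": truth.reflection_gain,
                "reflection_delay": truth.reflection_delay,
                "transit_delays": dict(truth.transit_delays),
                "site_delays": dict(truth.site_delays),
            }
        manifest["subjects"].append(entry)
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return root


# ---------------------------------------------------------------------------
# population handle and loaders

@dataclass
class PopulationHandle:
    """Lazy access to a population on disk.

    ``subject_ids`` lists every advertised subject; :meth:`subject` builds
    the full :class:`VirtualSubject` (with ground truth when available).
    Subjects with missing signals load with the signal absent — downstream
    indices flag themselves rather than the subject being dropped.
    """

    source: Path
    format: str
    subject_ids: List[str]
    _manifest: Optional[dict] = None

    def subject(self, subject_id: str):
        if self.format == "synthetic_csv":
            return _load_synthetic_subject(self.source, self._manifest,
                                           subject_id)
        return _load_matlab_subject(self.source, subject_id)

    def subjects(self):
        for sid in self.subject_ids:
            yield self.subject(sid)


def load_population(path, format: str = "synthetic_csv") -> PopulationHandle:
    """Open a population directory/container for reading.

    ``format`` is ``synthetic_csv`` or ``zenodo_matlab``.  Raises for an
    unreadable path or unknown format.
    """
    path = Path(path)
    if format == "synthetic_csv":
        manifest_path = path / "manifest.json"
        if not manifest_path.exists():
            raise FileNotFoundError(f"no manifest.json under {path}")
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        ids = [s["id"] for s in manifest["subjects"]]
        return PopulationHandle(path, format, ids, manifest)
    if format == "zenodo_matlab":
        if not path.exists():
            raise FileNotFoundError(str(path))
        ids = _matlab_subject_ids(path)
        return PopulationHandle(path, format, ids)
    raise ValueError(f"unknown population format {format!r}")


def _load_synthetic_subject(root: Path, manifest: dict, subject_id: str):
    entry = next((s for s in manifest["subjects"] if s["id"] == subject_id),
                 None)
    if entry is None:
        raise KeyError(f"unknown subject {subject_id!r}")
    waves = {}
    for w in entry["waves"]:
        fpath = root / w["file"]
        if not fpath.exists():
            continue  # degraded subject: indices needing it will flag
        df = pd.read_csv(fpath, comment="#")
        waves[(w["site"], w["modality"])] = PulseWave(
            df["value"].to_numpy(), w["fs"], w["site"], w["modality"])
    segments = [ArterialSegment(**d) for d in entry["aortic_path"]]
    subject = VirtualSubject(
        id=entry["id"], age=entry["age"], height=entry["height"],
        aortic_path=segments, path_lengths=entry["path_lengths"],
        waves=waves, rho=entry["rho"])
    truth = None
    if entry.get("truth"):
        t = entry["truth"]
        truth = GroundTruth(
            ao_pwv_t=t["ao_pwv_t"], onset_time=t["onset_time"],
            upstroke_start=t.get("upstroke_start", t["onset_time"]),
            reflection_gain=t["reflection_gain"],
            reflection_delay=t["reflection_delay"],
            e_ao=t["e_ao"], dc_true=t["dc_true"],
            transit_delays=t["transit_delays"],
            site_delays=t["site_delays"])
    return subject, truth


# ---------------------------------------------------------------------------
# zenodo_matlab adapter

#: Field-name mapping for the MATLAB container: edit here if the deposited
#: layout differs.  Keys are the package's names, values the names expected
#: inside the container.
DEFAULT_MATLAB_MAPPING = {
    "subjects_var": "subjects",
    "id": "id",
    "age": "age",
    "height": "height",
    "rho": "rho",
    "fs": "fs",
    "pressure_unit": "mmHg",
    "sites": {
        "aortic_root": "AorticRoot", "carotid": "Carotid",
        "brachial": "Brachial", "radial": "Radial", "digital": "Digital",
        "femoral": "Femoral", "ankle": "Ankle", "desc_aorta": "DescAorta",
    },
    "modalities": {
        "pressure": "P", "flow_velocity": "U", "area": "A", "ppg": "PPG",
    },
    "geometry": {
        "lengths": "L", "r_in": "Rin", "r_out": "Rout",
        "k1": "k1", "k2": "k2", "k3": "k3",
    },
    "path_lengths": "path_lengths",
}


def _matlab_subject_ids(path: Path) -> List[str]:
    data = _read_matlab(path)
    subjects = data[DEFAULT_MATLAB_MAPPING["subjects_var"]]
    return [str(s[DEFAULT_MATLAB_MAPPING["id"]]) for s in subjects]


def _read_matlab(path: Path) -> dict:
    """Read a MATLAB container (v7 via scipy, v7.3 via h5py)."""
    from scipy.io import loadmat
    try:
        raw = loadmat(path, squeeze_me=True, simplify_cells=True)
        return {k: v for k, v in raw.items() if not k.startswith("__")}
    except NotImplementedError:
        import h5py
        out = {}
        with h5py.File(path, "r") as fh:
            for key in fh:
                out[key] = fh[key][()]
        return out


def _load_matlab_subject(path: Path, subject_id: str):
    m = DEFAULT_MATLAB_MAPPING
    data = _read_matlab(path)
    subjects = data[m["subjects_var"]]
    entry = next((s for s in subjects if str(s[m["id"]]) == subject_id), None)
    if entry is None:
        raise KeyError(f"unknown subject {subject_id!r}")
    fs = float(entry[m["fs"]])
    waves = {}
    for site, site_key in m["sites"].items():
        if site_key not in entry:
            continue
        rec = entry[site_key]
        for modality, mod_key in m["modalities"].items():
            if mod_key not in rec:
                continue
            samples = np.asarray(rec[mod_key], dtype=float).ravel()
            if modality == "pressure":
                samples = np.array([
                    convert_pressure(v, m["pressure_unit"], "Pa")
                    for v in samples])
            waves[(site, modality)] = PulseWave(samples, fs, site, modality)
    geo = entry[m["geometry"]["lengths"]], entry[m["geometry"]["r_in"]], \
        entry[m["geometry"]["r_out"]], entry[m["geometry"]["k1"]], \
        entry[m["geometry"]["k2"]], entry[m["geometry"]["k3"]]
    segments = [ArterialSegment(float(L), float(ri), float(ro),
                                float(k1), float(k2), float(k3))
                for L, ri, ro, k1, k2, k3 in zip(*map(np.atleast_1d, geo))]
    subject = VirtualSubject(
        id=subject_id, age=float(entry[m["age"]]),
        height=float(entry[m["height"]]), aortic_path=segments,
        path_lengths={k: float(v)
                      for k, v in dict(entry[m["path_lengths"]]).items()},
        waves=waves, rho=float(entry.get(m["rho"], 1060.0)))
    return subject, None


# ---------------------------------------------------------------------------
# result tables

def export_panel_table(panels: List[IndexPanel], path,
                       truths=None, ages=None) -> Path:
    """Write one row per subject, one column per index (+ age, E_Ao).

    Comma-separated with a header row and '.' decimals; missing index
    values become empty cells, never zero.  Raises on a length mismatch
    between panels and truths/ages.
    """
    if not panels:
        raise ValueError("panels must be non-empty")
    for extra, name in ((truths, "truths"), (ages, "ages")):
        if extra is not None and len(extra) != len(panels):
            raise ValueError(f"{name} length does not match panels")
    rows = []
    for i, panel in enumerate(panels):
        row = dict(panel.as_dict())
        if ages is not None:
            row["age"] = ages[i]
        if truths is not None:
            row["E_Ao"] = truths[i]
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = list(INDEX_NAMES) + [c for c in ("age", "E_Ao") if c in df]
    df = df[cols]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FMT)
    return path


def read_panel_table(path) -> pd.DataFrame:
    """Re-import a table written by :func:`export_panel_table`."""
    return pd.read_csv(path)
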