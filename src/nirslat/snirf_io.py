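"""SNIRF (HDF5) reading and writing.

Files follow the published SNIRF layout: ``/formatVersion``, one ``/nirs``
group with ``metaDataTags``, ``data1`` (``dataTimeSeries`` time × measurement
columns, ``time``, one ``measurementList<m>`` group per column), ``probe``
(wavelengths and optode positions) and one ``stim<k>`` group per condition
holding (onset, duration, value) rows. Continuous-wave amplitude
(dataType 1) with two wavelengths per source–detector pair is the only
supported measurement type.

Montage structure that SNIRF has no standard slot for (channel ids,
hemispheres, homolog pairs, ROI definitions) is carried in a JSON string
under ``metaDataTags/MontageJSON`` and recovered on read when present.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import TimeSeriesBundle
from .design import Block, BlockDesign
from .montage import ChannelDef, Montage

__all__ = ["SnirfFormatError", "read_snirf", "write_snirf", "validate_snirf"]

_STR = h5py.string_dtype(encoding="utf-8")


class SnirfFormatError(ValueError):
    """The file does not follow the required SNIRF layout."""


def _montage_json(montage: Montage) -> str:
    return json.dumps({
        "sources": montage.sources,
        "detectors": montage.detectors,
        "channels": [
            [c.channel_id, c.source_id, c.detector_id, c.hemisphere]
            for c in montage.channels
        ],
        "homolog_map": {str(k): v for k, v in montage.homolog_map.items()},
        "roi_defs": {
            name: {side: sorted(ids) for side, ids in sides.items()}
            for name, sides in montage.roi_defs.items()
        },
        "separation_cm": montage.separation_cm,
    })


def _montage_from_json(text: str) -> Montage:
    d = json.loads(text)
    return Montage(
        sources=list(d["sources"]),
        detectors=list(d["detectors"]),
        channels=[ChannelDef(*row) for row in d["channels"]],
        homolog_map={int(k): int(v) for k, v in d["homolog_map"].items()},
        roi_defs={
            name: {side: set(ids) for side, ids in sides.items()}
            for name, sides in d["roi_defs"].items()
        },
        separation_cm=float(d["separation_cm"]),
    )


def write_snirf(
    bundle: TimeSeriesBundle,
    montage: Montage,
    design: BlockDesign | None,
    path: str | Path,
) -> Path:
    """Write a raw-intensity bundle (plus montage and stimulus blocks)."""
    if bundle.kind != "intensity":
        raise ValueError("SNIRF export is defined for raw intensity bundles")
    if bundle.n_channels == 0:
        raise ValueError("cannot write a zero-channel bundle")
    if not (bundle.data > 0).all():
        raise ValueError("raw intensities must be positive")
    path = Path(path)
    chan_by_id = {c.channel_id: c for c in montage.channels}
    missing = [c for c in bundle.channel_ids if c not in chan_by_id]
    if missing:
        raise ValueError(f"bundle channels not in montage: {missing}")

    n_t, n_c = bundle.n_times, bundle.n_channels
    flat = bundle.data.reshape(n_t, n_c * 2)  # columns: (c0,wl0),(c0,wl1),...
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.1", dtype=_STR)
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        for key, val in (("SubjectID", "sim"), ("MeasurementDate", "unknown"),
                         ("MeasurementTime", "unknown"), ("LengthUnit", "cm"),
                         ("TimeUnit", "s"), ("FrequencyUnit", "Hz")):
            meta.create_dataset(key, data=val, dtype=_STR)
        meta.create_dataset("MontageJSON", data=_montage_json(montage), dtype=_STR)

        data1 = nirs.create_group("data1")
        data1.create_dataset("dataTimeSeries", data=flat)
        data1.create_dataset("time", data=np.arange(n_t) / bundle.sfreq)
        for j, cid in enumerate(bundle.channel_ids):
            ch = chan_by_id[cid]
            for w in range(2):
                ml = data1.create_group(f"measurementList{2 * j + w + 1}")
                ml.create_dataset("sourceIndex", data=ch.source_id, dtype="i4")
                ml.create_dataset("detectorIndex", data=ch.detector_id, dtype="i4")
                ml.create_dataset("wavelengthIndex", data=w + 1, dtype="i4")
                ml.create_dataset("dataType", data=1, dtype="i4")
                ml.create_dataset("dataTypeIndex", data=1, dtype="i4")

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(bundle.wavelengths_nm))
        pos = montage.optode_positions
        src = np.array([pos.get(f"S{s}", np.zeros(3)) for s in montage.sources])
        det = np.array([pos.get(f"D{d}", np.zeros(3)) for d in montage.detectors])
        probe.create_dataset("sourcePos3D", data=src.reshape(-1, 3))
        probe.create_dataset("detectorPos3D", data=det.reshape(-1, 3))

        if design is not None:
            meta.create_dataset("Task", data=design.task, dtype=_STR)
            for k, cond in enumerate(design.conditions):
                stim = nirs.create_group(f"stim{k + 1}")
                stim.create_dataset("name", data=cond, dtype=_STR)
                rows = np.array(
                    [[b.onset_s, b.duration_s, 1.0] for b in design.blocks_of(cond)]
                )
                stim.create_dataset("data", data=rows.reshape(-1, 3))
    return path


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(
    path: str | Path,
    time_rtol: float = 1e-6,
) -> tuple[Montage, TimeSeriesBundle, BlockDesign | None]:
    """Read a SNIRF file into (montage, raw-intensity bundle, design)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "nirs" not in f or "data1" not in f["nirs"]:
            raise SnirfFormatError("missing required /nirs/data1 group")
        data1 = f["nirs/data1"]
        for req in ("dataTimeSeries", "time"):
            if req not in data1:
                raise SnirfFormatError(f"missing /nirs/data1/{req}")
        flat = np.asarray(data1["dataTimeSeries"], dtype=float)
        time = np.asarray(data1["time"], dtype=float)
        if flat.ndim != 2 or len(time) != flat.shape[0]:
            raise SnirfFormatError("dataTimeSeries/time shape mismatch")
        dt = np.diff(time)
        if len(dt) == 0 or dt.min() <= 0:
            raise SnirfFormatError("time vector must be strictly increasing")
        if (dt.max() - dt.min()) > time_rtol * np.median(dt):
            raise SnirfFormatError("non-uniform time vector beyond tolerance")
        sfreq = 1.0 / float(np.median(dt))

        ml_names = sorted(
            (k for k in data1 if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        if len(ml_names) != flat.shape[1]:
            raise SnirfFormatError(
                "number of measurementList groups does not match columns"
            )
        meas = []
        for k in ml_names:
            g = data1[k]
            try:
                meas.append((int(g["sourceIndex"][()]),
                             int(g["detectorIndex"][()]),
                             int(g["wavelengthIndex"][()])))
            except KeyError as e:
                raise SnirfFormatError(f"{k} missing {e}") from e
        pairs: dict[tuple[int, int], dict[int, int]] = {}
        for col, (s, d, w) in enumerate(meas):
            pairs.setdefault((s, d), {})[w] = col
        for (s, d), cols in pairs.items():
            if sorted(cols) != [1, 2]:
                raise SnirfFormatError(
                    f"source {s} / detector {d} lacks two wavelengths"
                )

        meta = f["nirs"].get("metaDataTags")
        montage = None
        if meta is not None and "MontageJSON" in meta:
            montage = _montage_from_json(_read_str(meta["MontageJSON"]))
        if montage is None:
            montage = _montage_from_probe(f["nirs"], pairs)

        order = {(c.source_id, c.detector_id): c.channel_id for c in montage.channels}
        channel_ids, cube_cols = [], []
        for (s, d), cols in pairs.items():
            cid = order.get((s, d))
            if cid is None:
                raise SnirfFormatError(
                    f"measurement ({s},{d}) not present in montage"
                )
            channel_ids.append(cid)
            cube_cols.append((cols[1], cols[2]))
        sort = np.argsort(channel_ids)
        channel_ids = [channel_ids[i] for i in sort]
        cube = np.stack(
            [flat[:, [cube_cols[i][0], cube_cols[i][1]]] for i in sort], axis=1
        )

        wavelengths = (740.0, 850.0)
        if "probe" in f["nirs"] and "wavelengths" in f["nirs/probe"]:
            wl = np.asarray(f["nirs/probe/wavelengths"], dtype=float).ravel()
            if len(wl) >= 2:
                wavelengths = (float(wl[0]), float(wl[1]))

        design = None
        stim_names = sorted(
            (k for k in f["nirs"] if k.startswith("stim")),
            key=lambda k: int(k[len("stim"):]),
        )
        if stim_names:
            task = "unknown"
            if meta is not None and "Task" in meta:
                task = _read_str(meta["Task"])
            blocks, conditions = [], []
            for k in stim_names:
                g = f["nirs"][k]
                cond = _read_str(g["name"]) if "name" in g else k
                conditions.append(cond)
                for onset, dur, _amp in np.asarray(g["data"]).reshape(-1, 3):
                    blocks.append(Block(0, cond, float(onset), float(dur)))
            blocks.sort(key=lambda b: b.onset_s)
            blocks = tuple(
                Block(i, b.condition, b.onset_s, b.duration_s)
                for i, b in enumerate(blocks)
            )
            total = max(len(time) / sfreq, blocks[-1].end_s if blocks else 0.0)
            design = BlockDesign(task, tuple(conditions), blocks, total)

    bundle = TimeSeriesBundle(cube, sfreq, channel_ids, kind="intensity",
                              wavelengths_nm=wavelengths)
    return montage, bundle, design


def _montage_from_probe(nirs, pairs) -> Montage:
    """Fallback montage for files without the MontageJSON tag: hemisphere
    from the sign of the optode x coordinate; no homology or ROIs."""
    src_pos = det_pos = None
    if "probe" in nirs:
        p = nirs["probe"]
        if "sourcePos3D" in p:
            src_pos = np.asarray(p["sourcePos3D"], dtype=float)
        if "detectorPos3D" in p:
            det_pos = np.asarray(p["detectorPos3D"], dtype=float)
    channels = []
    for cid, (s, d) in enumerate(sorted(pairs), start=1):
        hemi = "midline"
        if src_pos is not None and s - 1 < len(src_pos):
            x = src_pos[s - 1][0]
            hemi = "left" if x < 0 else ("right" if x > 0 else "midline")
        channels.append(ChannelDef(cid, s, d, hemi))
    sources = sorted({s for s, _ in pairs})
    detectors = sorted({d for _, d in pairs})
    return Montage(sources, detectors, channels, {}, {}, 3.0)


# required dataset paths per the published format (CW amplitude subset)
_REQUIRED = (
    "formatVersion",
    "nirs/data1/dataTimeSeries",
    "nirs/data1/time",
    "nirs/probe/wavelengths",
)


def validate_snirf(path: str | Path) -> list[str]:
    """Structural validation against the published SNIRF requirements.

    Returns a list of problems (empty = valid): required datasets present,
    one measurementList group per data column with mandatory fields, optode
    indices within the probe arrays, and a monotone time vector.
    """
    problems: list[str] = []
    with h5py.File(path, "r") as f:
        for req in _REQUIRED:
            if req not in f:
                problems.append(f"missing {req}")
        if problems:
            return problems
        data1 = f["nirs/data1"]
        flat = data1["dataTimeSeries"]
        time = np.asarray(data1["time"])
        if flat.ndim != 2:
            problems.append("dataTimeSeries is not 2-D")
        elif flat.shape[0] != len(time):
            problems.append("time length does not match dataTimeSeries rows")
        if len(time) > 1 and np.any(np.diff(time) <= 0):
            problems.append("time vector not strictly increasing")
        n_src = n_det = None
        probe = f["nirs/probe"]
        if "sourcePos3D" in probe:
            n_src = probe["sourcePos3D"].shape[0]
        if "detectorPos3D" in probe:
            n_det = probe["detectorPos3D"].shape[0]
        n_wl = len(np.asarray(probe["wavelengths"]).ravel())
        ml = [k for k in data1 if k.startswith("measurementList")]
        if flat.ndim == 2 and len(ml) != flat.shape[1]:
            problems.append(
                f"{len(ml)} measurementList groups for {flat.shape[1]} columns"
            )
        for k in ml:
            g = data1[k]
            for fieldname in ("sourceIndex", "detectorIndex",
                              "wavelengthIndex", "dataType"):
                if fieldname not in g:
                    problems.append(f"{k} missing {fieldname}")
                    continue
            if "wavelengthIndex" in g:
                w = int(g["wavelengthIndex"][()])
                if not 1 <= w <= n_wl:
                    problems.append(f"{k} wavelengthIndex {w} out of range")
            if n_src is not None and "sourceIndex" in g:
                if not 1 <= int(g["sourceIndex"][()]) <= n_src:
                    problems.append(f"{k} sourceIndex out of range")
            if n_det is not None and "detectorIndex" in g:
                if not 1 <= int(g["detectorIndex"][()]) <= n_det:
                    problems.append(f"{k} detectorIndex out of range")
        for k in f["nirs"]:
            if k.startswith("stim"):
                g = f["nirs"][k]
                if "data" in g and np.asarray(g["data"]).reshape(-1, 3).shape[1] != 3:
                    problems.append(f"{k} data is not (onset,duration,value) rows")
    return problems
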