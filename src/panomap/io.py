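"""File formats: layouts, trace containers, frame stacks, metrics, maps.

Conventions: JSON for structured metadata (layouts, sidecars, reports), CSV
via pandas for tabular exports, ``.npz`` as the array container for traces,
and ``.npy``/TIFF for frame stacks with a JSON sidecar carrying the sampling
rate and saturation value.  Every writer has a lossless reader counterpart.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig  # noqa: F401  (re-exported for CLI convenience)
from .electrical import ElectrogramMetrics, ElectrogramTrace
from .errors import IOFormatError
from .geometry import EllipsoidSpec, Modality, SensorLayout, SensorSite
from .mapping import ActivationMap, ConcordanceReport
from .optical import ExtractionMask, FiberTrace, FrameStack, OpticalAPMetrics

# ---------------------------------------------------------------------------
# layouts
# ---------------------------------------------------------------------------


def write_layout_json(layout: SensorLayout, path: str | Path) -> None:
    ell = layout.ellipsoid
    doc = {
        "ellipsoid": {
            "a": ell.semi_axis_a,
            "b": ell.semi_axis_b,
            "c": ell.semi_axis_c,
            "truncation": ell.truncation_fraction,
        },
        "pitch": layout.nominal_pitch,
        "sites": [
            {
                "id": s.site_id,
                "x": s.position[0], "y": s.position[1], "z": s.position[2],
                "nx": s.surface_normal[0], "ny": s.surface_normal[1], "nz": s.surface_normal[2],
                "modality": s.modality.value,
            }
            for s in layout.sites
        ],
        "petal_map": {str(k): v for k, v in layout.petal_map.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_layout_json(path: str | Path) -> SensorLayout:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise IOFormatError(f"{path}: invalid JSON at byte {exc.pos}: {exc.msg}") from exc
    try:
        e = doc["ellipsoid"]
        ell = EllipsoidSpec(e["a"], e["b"], e["c"], e["truncation"])
        sites = [
            SensorSite(
                site_id=int(s["id"]),
                position=np.array([s["x"], s["y"], s["z"]], dtype=float),
                surface_normal=np.array([s["nx"], s["ny"], s["nz"]], dtype=float),
                modality=Modality(s["modality"]),
            )
            for s in doc["sites"]
        ]
        petal = {int(k): [int(x) for x in v] for k, v in doc["petal_map"].items()}
        return SensorLayout(ellipsoid=ell, sites=sites, nominal_pitch=float(doc["pitch"]),
                            petal_map=petal)
    except (KeyError, TypeError, ValueError) as exc:
        raise IOFormatError(f"{path}: layout schema violation: {exc!r}") from exc


def write_layout_csv(layout: SensorLayout, path: str | Path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "x_mm": s.position[0], "y_mm": s.position[1], "z_mm": s.position[2],
            "nx": s.surface_normal[0], "ny": s.surface_normal[1], "nz": s.surface_normal[2],
            "modality": s.modality.value,
        }
        for s in layout.sites
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trace containers (npz + sidecar JSON)
# ---------------------------------------------------------------------------


def write_traces(
    path: str | Path,
    traces: list[FiberTrace] | list[ElectrogramTrace],
    kind: str,
    stimulus_times: list[float] | None = None,
) -> None:
    """Channels x time array container with a ``<path>.json`` sidecar."""
    if kind not in ("optical", "electrical"):
        raise IOFormatError("kind must be 'optical' or 'electrical'")
    path = Path(path)
    if not traces:
        raise IOFormatError("no traces to write")
    ids = np.array([t.fiber_id if kind == "optical" else t.electrode_id for t in traces])
    data = np.stack([t.samples for t in traces])
    np.savez_compressed(path, samples=data, channel_ids=ids)
    sidecar = {
        "kind": kind,
        "sampling_rate": traces[0].sampling_rate,
        "stimulus_times": stimulus_times or [],
        "channel_ids": [int(i) for i in ids],
    }
    if kind == "optical":
        sv = traces[0].saturation_value
        sidecar["saturation_value"] = sv
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1) + "\n")


def read_traces(path: str | Path) -> list[FiberTrace] | list[ElectrogramTrace]:
    path = Path(path)
    side_path = Path(str(path) + ".json")
    if not side_path.exists():
        raise IOFormatError(f"missing sidecar {side_path}")
    sidecar = json.loads(side_path.read_text())
    try:
        with np.load(path) as z:
            data = z["samples"]
            ids = z["channel_ids"]
    except (OSError, KeyError) as exc:
        raise IOFormatError(f"{path}: unreadable trace container: {exc!r}") from exc
    fs = float(sidecar["sampling_rate"])
    if sidecar["kind"] == "optical":
        return [
            FiberTrace(fiber_id=int(i), samples=row, sampling_rate=fs,
                       saturation_value=sidecar.get("saturation_value"))
            for i, row in zip(ids, data)
        ]
    return [
        ElectrogramTrace(electrode_id=int(i), samples=row, sampling_rate=fs,
                         stimulus_times=list(sidecar.get("stimulus_times", [])))
        for i, row in zip(ids, data)
    ]


# ---------------------------------------------------------------------------
# frame stacks
# ---------------------------------------------------------------------------


def write_frames(path: str | Path, stack: FrameStack) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, stack.intensities, photometric="minisblack")
    else:
        np.save(path, stack.intensities)
        if path.suffix != ".npy":
            path = path.with_suffix(path.suffix + ".npy")
    Path(str(path) + ".json").write_text(
        json.dumps({"sampling_rate": stack.sampling_rate,
                    "saturation_value": stack.saturation_value}) + "\n"
    )


def read_frames(path: str | Path) -> FrameStack:
    path = Path(path)
    side = Path(str(path) + ".json")
    if not side.exists():
        raise IOFormatError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
    else:
        data = np.load(path)
    return FrameStack(intensities=data, sampling_rate=float(meta["sampling_rate"]),
                      saturation_value=meta.get("saturation_value"))


def write_mask(mask: ExtractionMask, path: str | Path) -> None:
    doc = {
        "spatial_filter": mask.spatial_filter.value,
        "blocks": {str(k): {"row0": r, "col0": c} for k, (r, c) in mask.blocks.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_mask(path: str | Path) -> ExtractionMask:
    try:
        doc = json.loads(Path(path).read_text())
        blocks = {int(k): (int(v["row0"]), int(v["col0"])) for k, v in doc["blocks"].items()}
        return ExtractionMask(blocks=blocks, spatial_filter=doc.get("spatial_filter", "mean"))
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise IOFormatError(f"{path}: mask schema violation: {exc!r}") from exc


# ---------------------------------------------------------------------------
# metrics / maps / reports
# ---------------------------------------------------------------------------

OPTICAL_METRIC_COLUMNS = [
    "fiber_id", "ap_index", "dFF_percent", "dVdt_max", "apd50", "apd70", "apd90",
    "snr", "olat_50", "olat_sg", "shape_class", "excluded", "exclusion_reason",
]


def optical_metrics_to_csv(metrics: dict[int, list[OpticalAPMetrics]], path: str | Path) -> None:
    rows = []
    for fid in sorted(metrics):
        for k, m in enumerate(metrics[fid]):
            rows.append(
                {
                    "fiber_id": fid,
                    "ap_index": k,
                    "dFF_percent": m.dFF_percent,
                    "dVdt_max": m.dVdt_max,
                    "apd50": m.apd.get(50),
                    "apd70": m.apd.get(70),
                    "apd90": m.apd.get(90),
                    "snr": m.snr,
                    "olat_50": m.olat_50,
                    "olat_sg": m.olat_sg,
                    "shape_class": m.shape_class.value,
                    "excluded": m.excluded,
                    "exclusion_reason": m.exclusion_reason or "",
                }
            )
    pd.DataFrame(rows, columns=OPTICAL_METRIC_COLUMNS).to_csv(path, index=False)


EGM_METRIC_COLUMNS = [
    "electrode_id", "beat_index", "downstroke_amplitude", "downstroke_duration",
    "max_negative_slope", "elat_sg", "excluded", "exclusion_reason",
]


def egm_metrics_to_csv(metrics: dict[int, list[ElectrogramMetrics]], path: str | Path) -> None:
    rows = []
    for eid in sorted(metrics):
        for k, m in enumerate(metrics[eid]):
            rows.append(
                {
                    "electrode_id": eid,
                    "beat_index": k,
                    "downstroke_amplitude": m.downstroke_amplitude,
                    "downstroke_duration": m.downstroke_duration,
                    "max_negative_slope": m.max_negative_slope,
                    "elat_sg": m.elat_sg,
                    "excluded": m.excluded,
                    "exclusion_reason": m.exclusion_reason or "",
                }
            )
    pd.DataFrame(rows, columns=EGM_METRIC_COLUMNS).to_csv(path, index=False)


def write_activation_map_csv(amap: ActivationMap, path: str | Path) -> None:
    rows = [{"site_id": k, "lat_ms": v, "variant": amap.variant, "beat_id": amap.beat_id}
            for k, v in sorted(amap.lat_by_site.items())]
    pd.DataFrame(rows, columns=["site_id", "lat_ms", "variant", "beat_id"]).to_csv(path, index=False)


def read_activation_map_csv(path: str | Path) -> ActivationMap:
    df = pd.read_csv(path)
    required = {"site_id", "lat_ms", "variant", "beat_id"}
    if not required <= set(df.columns):
        raise IOFormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df.empty:
        raise IOFormatError(f"{path}: empty activation map")
    return ActivationMap(
        beat_id=int(df["beat_id"].iloc[0]),
        lat_by_site={int(r.site_id): float(r.lat_ms) for r in df.itertuples()},
        variant=str(df["variant"].iloc[0]),
    )


def write_concordance_json(report: ConcordanceReport, path: str | Path) -> None:
    doc = {
        "mean_ms": report.mean,
        "sd_ms": report.sd,
        "n_electrodes": len(report.differences),
        "differences": {str(k): v for k, v in sorted(report.differences.items())},
        "histogram": {
            "bin_edges_ms": [float(x) for x in report.bin_edges],
            "counts": [int(x) for x in report.counts],
        },
        "by_shape": {k: list(v) for k, v in report.by_shape.items()},
        "excluded_electrodes": report.excluded_electrodes,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
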