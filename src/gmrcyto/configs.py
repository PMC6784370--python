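"""Structured-text (YAML) configuration parsing.

Config files use instrument-friendly units (μm, emu, mT, μT, mL/min); this
module converts them to the SI quantities the library uses internally.
Unknown keys raise, so typos in campaign files fail loudly.
"""

from __future__ import annotations

from typing import Any, Mapping

import yaml

from .detection import DetectorConfig
from .magnetics import BeadMagnetics, SensorGeometry
from .sample import ChannelGeometry, SampleComposition
from .tracesim import AcquisitionConfig

__all__ = [
    "load_config",
    "sensor_from_config",
    "bead_from_config",
    "channel_from_config",
    "acquisition_from_config",
    "detector_from_config",
    "composition_from_config",
]


def _take(d: Mapping[str, Any], allowed: dict[str, Any], section: str) -> dict[str, Any]:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
    out = dict(allowed)
    out.update(d)
    return out


def sensor_from_config(d: Mapping[str, Any]) -> SensorGeometry:
    v = _take(d, {"length_um": 120.0, "width_um": 4.0, "detectivity_uT": 2.2}, "sensor")
    return SensorGeometry(
        length=v["length_um"] * 1e-6,
        width=v["width_um"] * 1e-6,
        detectivity=v["detectivity_uT"] * 1e-6,
    )


def bead_from_config(d: Mapping[str, Any]) -> BeadMagnetics:
    v = _take(
        d,
        {"diameter_um": 1.0, "moment_sat_emu": 2.1e-11, "moment_op_emu": 1.6e-11,
         "magnet_field_mT": 90.0},
        "bead",
    )
    return BeadMagnetics.from_emu(
        diameter=v["diameter_um"] * 1e-6,
        moment_sat_emu=v["moment_sat_emu"],
        moment_op_emu=v["moment_op_emu"],
    )


def channel_from_config(d: Mapping[str, Any]) -> ChannelGeometry:
    v = _take(
        d,
        {"height_um": 25.0, "width_um": 100.0, "spacer_um": 6.0, "flow_mL_per_min": 1.0 / 30.0},
        "channel",
    )
    return ChannelGeometry(
        height=v["height_um"] * 1e-6,
        width=v["width_um"] * 1e-6,
        spacer_thickness=v["spacer_um"] * 1e-6,
        flow_volume_rate=v["flow_mL_per_min"],
    )


def acquisition_from_config(d: Mapping[str, Any]) -> AcquisitionConfig:
    v = _take(
        d,
        {
            "sample_rate_hz": 200_000.0,
            "preamp_gain": 500.0,
            "post_gain": 20.0,
            "filter_cutoff_hz": 15_000.0,
            "filter_order": 4,
            "bias_v": 1.0,
            "sensitivity_pct_per_mT": 2.5,
            "noise_rms_uT": 2.2 / 3.0,
        },
        "acquisition",
    )
    return AcquisitionConfig(
        sample_rate=v["sample_rate_hz"],
        preamp_gain=v["preamp_gain"],
        post_gain=v["post_gain"],
        filter_cutoff=v["filter_cutoff_hz"],
        filter_order=int(v["filter_order"]),
        bias_voltage=v["bias_v"],
        sensitivity_per_mT=v["sensitivity_pct_per_mT"] / 100.0,
        noise_rms_field=v["noise_rms_uT"] * 1e-6,
    )


def detector_from_config(d: Mapping[str, Any]) -> DetectorConfig:
    v = _take(
        d,
        {
            "vthr_v": None,
            "k": 1,
            "width_min_us": 25.0,
            "width_max_ms": 2.5,
            "bipolar_fraction": 1.0 / 3.0,
            "symmetry_max": 0.4,
            "grow_step": 15,
            "edge_margin": 20,
        },
        "detector",
    )
    if v["vthr_v"] is None:
        raise ValueError("detector config requires vthr_v")
    return DetectorConfig(
        v_threshold=float(v["vthr_v"]),
        direction_k=int(v["k"]),
        width_min=v["width_min_us"] * 1e-6,
        width_max=v["width_max_ms"] * 1e-3,
        bipolar_fraction=v["bipolar_fraction"],
        symmetry_max=v["symmetry_max"],
        grow_step=int(v["grow_step"]),
        edge_margin=int(v["edge_margin"]),
    )


def composition_from_config(d: Mapping[str, Any]) -> SampleComposition:
    v = _take(
        d,
        {
            "label": "sample",
            "cells_per_mL": 0.0,
            "beads_per_mL": 2e7,
            "fraction_beads_bound": 0.0,
            "cell_diameter_um": 6.0,
            "nominal_class": "negative",
        },
        "composition",
    )
    return SampleComposition(
        label=str(v["label"]),
        cell_concentration=float(v["cells_per_mL"]),
        bead_concentration=float(v["beads_per_mL"]),
        fraction_beads_bound=float(v["fraction_beads_bound"]),
        cell_diameter=v["cell_diameter_um"] * 1e-6,
        nominal_class=str(v["nominal_class"]),
    )


def load_config(path) -> dict[str, Any]:
    """Parse a YAML campaign/config file into domain objects.

    Recognized sections: sensor, bead, channel, acquisition, detector,
    compositions (list), seed, duration_s, output_dir.  Missing sections
    fall back to the experimental defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, Any] = {
        "sensor": sensor_from_config(raw.get("sensor", {})),
        "bead": bead_from_config(raw.get("bead", {})),
        "channel": channel_from_config(raw.get("channel", {})),
        "acquisition": acquisition_from_config(raw.get("acquisition", {})),
        "seed": int(raw.get("seed", 0)),
        "duration_s": float(raw.get("duration_s", 1.0)),
        "output_dir": raw.get("output_dir", "campaign_out"),
    }
    if "detector" in raw:
        out["detector"] = detector_from_config(raw["detector"])
    out["compositions"] = [
        composition_from_config(c) for c in raw.get("compositions", [])
    ]
    return out
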