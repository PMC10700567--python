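"""Model configuration documents (YAML/JSON, versioned schema).

A configuration file carries everything the solver needs: segments, DOFs,
muscle-tendon parameters with their moment-arm polynomials and insertion
geometry, actuators, Hill-curve parameters, and the reference posture.
Validation is strict and names the offending entry in every message.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from .model import (
    ActuatorParams,
    HillCurves,
    MTUParams,
    MusculoskeletalModel,
    SegmentParams,
)

SCHEMA_VERSION = 1


def model_to_dict(model: MusculoskeletalModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "body_mass": model.body_mass,
        "height": model.height,
        "ref_height": model.ref_height,
        "ref_mass": model.ref_mass,
        "gravity": model.gravity,
        "dofs": list(model.dofs),
        "reference_posture": dict(model.reference_posture),
        "segments": {name: asdict(seg) for name, seg in model.segments.items()},
        "mtus": [asdict(m) for m in model.mtus],
        "actuators": [asdict(a) for a in model.actuators],
        "hill_curves": asdict(model.hill_curves),
    }


class ConfigError(ValueError):
    """Invalid model configuration; the message names the entry at fault."""


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise ConfigError(f"{where}: missing required field {key!r}")
    return d[key]


def model_from_dict(doc: dict) -> MusculoskeletalModel:
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version!r} "
                          f"(this reader supports {SCHEMA_VERSION})")
    segments = {}
    for name, sd in _require(doc, "segments", "document").items():
        try:
            seg = SegmentParams(**sd)
            seg.validate()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"segments/{name}: {exc}") from exc
        segments[name] = seg
    mtus = []
    for i, md in enumerate(_require(doc, "mtus", "document")):
        where = f"mtus[{i}] ({md.get('name', 'unnamed')})"
        try:
            mtu = MTUParams(**md)
            mtu.validate()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{where}: {exc}") from exc
        mtus.append(mtu)
    actuators = []
    for i, ad in enumerate(_require(doc, "actuators", "document")):
        where = f"actuators[{i}] ({ad.get('name', 'unnamed')})"
        try:
            act = ActuatorParams(**ad)
            act.validate()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{where}: {exc}") from exc
        actuators.append(act)
    try:
        curves = HillCurves(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in doc.get("hill_curves", {}).items()})
    except TypeError as exc:
        raise ConfigError(f"hill_curves: {exc}") from exc

    model = MusculoskeletalModel(
        segments=segments,
        dofs=tuple(_require(doc, "dofs", "document")),
        mtus=mtus,
        actuators=actuators,
        hill_curves=curves,
        body_mass=float(_require(doc, "body_mass", "document")),
        gravity=float(doc.get("gravity", 9.80665)),
        ref_height=float(doc.get("ref_height", 1.75)),
        ref_mass=float(doc.get("ref_mass", 75.0)),
        height=float(doc.get("height", 1.75)),
        reference_posture=dict(doc.get("reference_posture", {})),
    )
    try:
        model.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return model


def save_model(model: MusculoskeletalModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_model(path) -> MusculoskeletalModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: not a mapping document")
    return model_from_dict(doc)
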