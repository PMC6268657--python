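"""File formats: spectra and titration CSVs with JSON sidecars, model JSON.

All numeric CSV output is written with 17 significant digits so that
read(write(x)) round-trips to full float precision.  Each CSV carries a
JSON sidecar at ``<path>.json`` holding the metadata that does not fit a
rectangular table (ligand totals, channel, analytical composition,
titrant).  Equilibrium models are plain JSON with a ``schema_version``
field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibria import Component, EquilibriumModel, Species, build_model
from .potentiometry import TitrationDataset
from .rafa import SpectraMatrix

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_titration_csv",
    "write_titration_csv",
    "read_model_json",
    "write_model_json",
]

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.17g"


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_spectra_csv(matrix: SpectraMatrix, path) -> None:
    """CSV: first column wavelength_nm, one sample column per metal total
    (header ``<metal>=<total>``); sidecar JSON with ligand totals and
    channel."""
    path = Path(path)
    totals = matrix.sample_totals
    metal = matrix.metadata.get("metal", "Al")
    if metal not in totals.columns:
        metal = totals.columns[0]
    cols = [f"{metal}={_FLOAT_FMT % v}" for v in totals[metal]]
    df = pd.DataFrame(matrix.intensity, columns=cols)
    df.insert(0, "wavelength_nm", matrix.wavelengths)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    ligand_totals = {
        c: float(totals[c].iloc[0]) for c in totals.columns if c != metal
    }
    meta = {
        "schema_version": SCHEMA_VERSION,
        "channel": matrix.channel,
        "metal": metal,
        "ligand_totals": ligand_totals,
        "n_samples": int(matrix.n_samples),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_spectra_csv(path) -> SpectraMatrix:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    for key in ("channel", "metal", "ligand_totals", "n_samples"):
        if key not in meta:
            raise ValueError(f"sidecar {side} missing field {key!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or incomplete rows")
    if df.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be wavelength_nm")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError(f"{path}: wavelengths not strictly increasing")
    metal = meta["metal"]
    sample_cols = list(df.columns[1:])
    if len(sample_cols) != meta["n_samples"]:
        raise ValueError(
            f"{path}: {len(sample_cols)} sample columns but sidecar "
            f"declares {meta['n_samples']}"
        )
    metal_totals = []
    for c in sample_cols:
        name, _, val = c.partition("=")
        if name != metal or not val:
            raise ValueError(f"{path}: malformed sample header {c!r}")
        metal_totals.append(float(val))
    totals = pd.DataFrame({metal: metal_totals})
    for lig, tot in meta["ligand_totals"].items():
        totals[lig] = float(tot)
    return SpectraMatrix(
        wl,
        df[sample_cols].to_numpy(dtype=float),
        totals,
        channel=meta["channel"],
        metadata={"metal": metal, **meta.get("extra", {})},
    )


def write_titration_csv(dataset: TitrationDataset, path) -> None:
    """CSV with columns volume_L, pH; composition and titrant in the
    sidecar."""
    path = Path(path)
    ph = dataset.ph if dataset.ph is not None else np.full(len(dataset.volumes), np.nan)
    pd.DataFrame({"volume_L": dataset.volumes, "pH": ph}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    meta = {
        "schema_version": SCHEMA_VERSION,
        "initial_volume_L": dataset.initial_volume,
        "totals": dataset.totals,
        "titrant_conc": dataset.titrant_conc,
        "medium": dataset.medium,
        "excluded": [[int(i), reason] for i, reason in dataset.excluded],
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_titration_csv(path) -> TitrationDataset:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df) == 0:
        raise ValueError(f"{path}: empty titration file")
    if list(df.columns[:2]) != ["volume_L", "pH"]:
        raise ValueError(f"{path}: columns must be volume_L, pH")
    ph = df["pH"].to_numpy(dtype=float)
    return TitrationDataset(
        initial_volume=float(meta["initial_volume_L"]),
        totals={k: float(v) for k, v in meta["totals"].items()},
        titrant_conc=float(meta["titrant_conc"]),
        volumes=df["volume_L"].to_numpy(dtype=float),
        ph=None if np.all(np.isnan(ph)) else ph,
        medium=meta.get("medium", ""),
        excluded=[(int(i), r) for i, r in meta.get("excluded", [])],
    )


def write_model_json(model: EquilibriumModel, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "temperature": model.temperature,
        "components": [
            {"name": c.name, "charge": c.charge, "role": c.role}
            for c in model.components
        ],
        "species": [
            {
                "label": s.label,
                "stoichiometry": dict(s.stoichiometry),
                "log_beta": s.log_beta,
                "adjustable": s.adjustable,
            }
            for s in model.species
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model_json(path) -> EquilibriumModel:
    doc = json.loads(Path(path).read_text())
    if "components" not in doc or "species" not in doc:
        raise ValueError(f"{path}: not a model file")
    comps = [
        Component(c["name"], int(c.get("charge", 0)), c.get("role", "ligand"))
        for c in doc["components"]
    ]
    specs = [
        Species(
            s["label"],
            {k: int(v) for k, v in s["stoichiometry"].items()},
            float(s["log_beta"]),
            bool(s.get("adjustable", False)),
        )
        for s in doc["species"]
    ]
    return build_model(comps, specs, float(doc.get("temperature", 298.15)))
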