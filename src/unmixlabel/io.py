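"""File formats: HDF5 hypercubes/models, CSV tables, JSON metrics."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .classifier import KNNModel
from .evaluation import MetricsReport
from .hypercube import CalibrationFrames, Hypercube
from .labeling import InkMark, LabeledSpectrum
from .unmixing import AbundanceMap, EndmemberSet


def save_hypercube(path, cube: Hypercube, refs: CalibrationFrames | None = None) -> None:
    """HDF5 container: /data, /wavelengths, attrs camera + pixel_pitch_mm."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=cube.data, compression="gzip", compression_opts=1)
        f.create_dataset("wavelengths", data=cube.wavelengths)
        f.attrs["camera"] = cube.camera
        f.attrs["pixel_pitch_mm"] = cube.pixel_pitch
        if refs is not None:
            f.create_dataset("white", data=refs.white, compression="gzip", compression_opts=1)
            f.create_dataset("dark", data=refs.dark, compression="gzip", compression_opts=1)


def load_hypercube(path) -> tuple[Hypercube, CalibrationFrames | None]:
    with h5py.File(path, "r") as f:
        cube = Hypercube(
            f["data"][()],
            f["wavelengths"][()],
            str(f.attrs["camera"]),
            float(f.attrs["pixel_pitch_mm"]),
        )
        refs = None
        if "white" in f:
            refs = CalibrationFrames(f["white"][()], f["dark"][()])
    return cube, refs


def save_abundance_map(path, amap: AbundanceMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("abundances", data=amap.abundances)
        f.create_dataset("tumor_map", data=amap.tumor_map)
        f.create_dataset("residual_norms", data=amap.residual_norms)
        f.attrs["classes"] = list(amap.classes)


def endmembers_to_csv(path, E: EndmemberSet) -> None:
    """CSV (wavelength + one column per class) with a JSON provenance sidecar."""
    wl = E.wavelengths if E.wavelengths is not None else np.arange(E.n_bands)
    df = pd.DataFrame({"wavelength": wl})
    for i, name in enumerate(E.classes):
        df[name] = E.spectra[i]
    df.to_csv(path, index=False)
    sidecar = Path(path).with_suffix(".provenance.json")
    sidecar.write_text(json.dumps({k: list(v) for k, v in E.provenance.items()}, indent=2))


def endmembers_from_csv(path) -> EndmemberSet:
    df = pd.read_csv(path)
    classes = tuple(c for c in df.columns if c != "wavelength")
    E = EndmemberSet(df[list(classes)].to_numpy().T, classes, df["wavelength"].to_numpy())
    sidecar = Path(path).with_suffix(".provenance.json")
    if sidecar.exists():
        E.provenance = {k: tuple(v) for k, v in json.loads(sidecar.read_text()).items()}
    return E


def marks_to_csv(path, marks, labels=None) -> None:
    rows = []
    for i, m in enumerate(marks):
        rows.append(
            {
                "mark_id": m.mark_id,
                "row": m.center[0],
                "col": m.center[1],
                "he_label": "" if labels is None else labels[i],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def marks_from_csv(path) -> tuple[list[InkMark], list[int | None]]:
    df = pd.read_csv(path)
    marks = [
        InkMark((int(r.row), int(r.col)), mark_id=str(r.mark_id)) for r in df.itertuples()
    ]
    labels = [
        int(v) if not pd.isna(v) else None for v in df.get("he_label", [None] * len(df))
    ]
    return marks, labels


def labeled_spectra_to_csv(path, labeled: list[LabeledSpectrum], wavelengths=None) -> None:
    """Wide table: mark_id, strategy, label, row, col, then one column per band."""
    rows = []
    for ls in labeled:
        mark_id, row, col, strategy = ls.source
        rec = {"mark_id": mark_id, "strategy": strategy, "label": ls.label,
               "row": row, "col": col}
        rec.update({f"b{i}": v for i, v in enumerate(ls.spectrum)})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, index=False)


def labeled_spectra_from_csv(path) -> list[LabeledSpectrum]:
    df = pd.read_csv(path)
    bands = [c for c in df.columns if c.startswith("b") and c[1:].isdigit()]
    out = []
    for r in df.itertuples():
        spectrum = np.array([getattr(r, b) for b in bands], dtype=float)
        out.append(
            LabeledSpectrum(spectrum, int(r.label),
                            (str(r.mark_id), int(r.row), int(r.col), str(r.strategy)))
        )
    return out


def save_model(path, model: KNNModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("training_spectra", data=model.training_spectra)
        f.create_dataset("training_labels", data=model.training_labels)
        f.attrs["k"] = model.k
        f.attrs["metric"] = "euclidean"
        f.attrs["weight_rule"] = "squared_inverse_distance"


def load_model(path) -> KNNModel:
    with h5py.File(path, "r") as f:
        return KNNModel(f["training_spectra"][()], f["training_labels"][()],
                        k=int(f.attrs["k"]))


def report_to_dict(rep: MetricsReport) -> dict:
    c = rep.confusion
    return {
        "strategy": rep.strategy,
        "TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN,
        "sensitivity": rep.sensitivity,
        "sensitivity_ci": list(rep.sensitivity_ci),
        "specificity": rep.specificity,
        "specificity_ci": list(rep.specificity_ci),
        "accuracy": rep.accuracy,
        "accuracy_ci": list(rep.accuracy_ci),
        "mcc": rep.mcc,
        "auc": rep.auc,
    }


def reports_to_json(path, reports: dict[str, MetricsReport]) -> None:
    payload = {name: report_to_dict(rep) for name, rep in reports.items()}
    Path(path).write_text(json.dumps(payload, indent=2))
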