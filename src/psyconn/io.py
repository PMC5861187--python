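"""On-disk formats: TSV tables, NIfTI volumes, JSON sidecars, model bundles.

All tables are tab-separated with a header row; volumes are NIfTI-1
(via nibabel) with RAS/MNI millimeter affines; the ground truth and run
manifests are JSON sidecars.  Trained classifier bundles are a JSON
metadata file plus pickled SVM weights.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import TimeSeriesMatrix
from .morphometry import GmStack, RoiSet
from .synth import GroundTruth, PlantedEdge, PlantedFocus, PsychometricTable

__all__ = [
    "save_scores",
    "load_scores",
    "save_gm_stack",
    "load_gm_stack",
    "save_parcellation",
    "load_parcellation",
    "save_timeseries",
    "load_timeseries",
    "save_roiset",
    "load_roiset",
    "save_truth",
    "load_truth",
    "save_components",
    "save_model",
    "load_model",
]


def save_scores(table: PsychometricTable, path: str | Path) -> None:
    table.scores.to_csv(path, sep="\t", index_label="subject_id", na_rep="NA")


def load_scores(path: str | Path) -> PsychometricTable:
    df = pd.read_csv(path, sep="\t", index_col="subject_id", na_values=["NA"])
    return PsychometricTable(df)


def save_gm_stack(stack: GmStack, out_dir: str | Path) -> None:
    """One .nii.gz per subject plus a TBV TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, sid in enumerate(stack.subject_ids):
        nib.save(nib.Nifti1Image(stack.data[k], stack.affine), out / f"{sid}_gm.nii.gz")
    pd.DataFrame({"subject_id": stack.subject_ids, "tbv": stack.tbv}).to_csv(
        out / "tbv.tsv", sep="\t", index=False
    )


def load_gm_stack(in_dir: str | Path) -> GmStack:
    in_dir = Path(in_dir)
    tbv = pd.read_csv(in_dir / "tbv.tsv", sep="\t")
    data, affine = [], None
    for sid in tbv["subject_id"]:
        img = nib.load(in_dir / f"{sid}_gm.nii.gz")
        data.append(np.asarray(img.dataobj, dtype=float))
        affine = img.affine
    return GmStack(
        subject_ids=list(tbv["subject_id"]),
        data=np.stack(data),
        affine=affine,
        tbv=tbv["tbv"].to_numpy(),
    )


def save_parcellation(parcellation: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(parcellation.astype(np.int32), affine), str(path))


def load_parcellation(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(int)


def save_timeseries(series: list[TimeSeriesMatrix], out_dir: str | Path) -> None:
    """One T x R TSV per subject, columns named by ROI id."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ts in series:
        pd.DataFrame(ts.data, columns=[f"roi-{r}" for r in ts.roi_ids]).to_csv(
            out / f"{ts.subject_id}_ts.tsv", sep="\t", index=False
        )
    meta = {"tr": series[0].tr, "subject_ids": [ts.subject_id for ts in series]}
    (out / "timeseries.json").write_text(json.dumps(meta))


def load_timeseries(in_dir: str | Path) -> list[TimeSeriesMatrix]:
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "timeseries.json").read_text())
    out = []
    for sid in meta["subject_ids"]:
        path = in_dir / f"{sid}_ts.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing time-series file: {path}")
        df = pd.read_csv(path, sep="\t")
        roi_ids = [int(c.split("-", 1)[1]) for c in df.columns]
        out.append(
            TimeSeriesMatrix(subject_id=sid, data=df.to_numpy(), tr=meta["tr"], roi_ids=roi_ids)
        )
    return out


def save_roiset(rois: RoiSet, path: str | Path) -> None:
    rois.to_dataframe().to_csv(path, sep="\t", index=False)


def load_roiset(path: str | Path) -> RoiSet:
    return RoiSet.from_dataframe(pd.read_csv(path, sep="\t"))


def save_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "seed": truth.seed,
        "score_model": {k: list(v) for k, v in truth.score_model.items()},
        "planted_foci": [
            {"parameter": f.parameter, "parcel": f.parcel, "center": list(f.center), "beta_vbm": f.beta_vbm}
            for f in truth.planted_foci
        ],
        "planted_edges": [
            {"parameter": e.parameter, "i": e.i, "j": e.j, "beta_edge": e.beta_edge}
            for e in truth.planted_edges
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_foci=[
            PlantedFocus(f["parameter"], f["parcel"], tuple(f["center"]), f["beta_vbm"])
            for f in d["planted_foci"]
        ],
        planted_edges=[
            PlantedEdge(e["parameter"], e["i"], e["j"], e["beta_edge"]) for e in d["planted_edges"]
        ],
        score_model={k: tuple(v) for k, v in d["score_model"].items()},
        seed=d["seed"],
    )


def save_components(components, path: str | Path, graphml_path: str | Path | None = None) -> None:
    """Edge-list TSV (roi_i, roi_j, t, parameter, fwe_p); optional GraphML."""
    rows = []
    for c in components:
        for (i, j), t in zip(c.edges, c.edge_t):
            rows.append(
                {"roi_i": i, "roi_j": j, "t": t, "parameter": c.parameter, "fwe_p": c.fwe_p}
            )
    pd.DataFrame(rows, columns=["roi_i", "roi_j", "t", "parameter", "fwe_p"]).to_csv(
        path, sep="\t", index=False
    )
    if graphml_path is not None:
        import networkx as nx

        g = nx.Graph()
        for c in components:
            for (i, j), t in zip(c.edges, c.edge_t):
                g.add_edge(i, j, t=float(t), parameter=c.parameter, fwe_p=float(c.fwe_p or np.nan))
        nx.write_graphml(g, str(graphml_path))


def save_model(model, model_dir: str | Path) -> None:
    """JSON metadata (label map, scaler, edge ids, grid winners) + pickled SVMs."""
    out = Path(model_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "parameter": model.parameter,
        "C": model.C,
        "gamma": model.gamma,
        "edge_ids": [list(e) for e in model.edge_ids],
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_sd": model.scaler_sd.tolist(),
        "label_map": {
            "vmin": model.label_map.vmin,
            "vmax": model.label_map.vmax,
            "n_classes": model.label_map.n_classes,
        },
        "loocv_accuracy_pct": model.loocv_accuracy_pct,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=1))
    with open(out / "weights.pkl", "wb") as fh:
        pickle.dump(model, fh)


def load_model(model_dir: str | Path):
    path = Path(model_dir) / "weights.pkl"
    try:
        with open(path, "rb") as fh:
            return pickle.load(fh)
    except (pickle.UnpicklingError, EOFError) as exc:
        raise ValueError(f"corrupted model file: {path}") from exc
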