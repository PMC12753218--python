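"""CSV / JSON / YAML serialization for waveforms, cohorts and models.

Waveform CSV format: ``#``-prefixed header lines carrying ``kind``,
``assay``, ``sample_id`` and ``units`` metadata, followed by a
``time_s,value`` table.  Cohort manifests are one-row-per-sample CSVs
pointing at per-sample waveform files.  Fitted models serialize to JSON
(weights, standardizer constants, training config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from clotwave.estimators import (
    LinearModel,
    NNModel,
    Standardizer,
    PredictionSet,
)
from clotwave.kinetics import KineticParameters
from clotwave.reference import ReferenceCurve
from clotwave.waveform import SampleRecord, Waveform, WaveformError

_UNITS = {"transparency": "mA", "attenuance": "1", "thrombin": "nM",
          "fluorescence": "au", "derivative": "mixed"}


def write_waveform_csv(wf: Waveform, path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind={wf.kind}\n")
        fh.write(f"# assay={wf.assay}\n")
        fh.write(f"# sample_id={wf.sample_id}\n")
        fh.write(f"# units={_UNITS.get(wf.kind, '1')}\n")
        fh.write("time_s,value\n")
        for t, v in zip(wf.times, wf.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def read_waveform_csv(path: Union[str, Path]) -> Waveform:
    """Read a waveform CSV; malformed rows or headers raise with context."""
    path = Path(path)
    meta = {}
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            if line.lower().startswith("time_s"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise WaveformError(f"{path}:{lineno}: expected 2 columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise WaveformError(f"{path}:{lineno}: {exc}") from None
    if "kind" not in meta:
        raise WaveformError(f"{path}: missing '# kind=' header")
    times = np.array([r[0] for r in rows])
    values = np.array([r[1] for r in rows])
    if times.size > 1:
        bad = np.nonzero(np.diff(times) <= 0)[0]
        if bad.size:
            i = int(bad[0])
            raise WaveformError(
                f"{path}: times not strictly increasing at row {i + 2} "
                f"({times[i]!r} -> {times[i + 1]!r})")
    return Waveform(times=times, values=values, kind=meta["kind"],
                    assay=meta.get("assay", "none"),
                    sample_id=meta.get("sample_id", ""))


_WF_FILES = {"tg_thrombin": "tg_thrombin.csv", "tg_turbidity":
             "tg_turbidity.csv", "pt": "pt.csv", "rt": "rt.csv"}


def write_cohort(records: Sequence[SampleRecord],
                 directory: Union[str, Path]) -> Path:
    """Write a cohort as a manifest CSV plus per-sample waveform CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        row = {"sample_id": rec.sample_id,
               "fibrinogen_ref_g_L": rec.fibrinogen_ref,
               "inr": rec.inr, "anti_xa_U_mL": rec.anti_xa,
               "d_dimer_mg_L": rec.d_dimer}
        for key, fname in _WF_FILES.items():
            wf = rec.waveforms.get(key)
            if wf is None:
                row[key] = ""
                continue
            rel = f"{rec.sample_id}_{fname}"
            write_waveform_csv(wf, directory / rel)
            row[key] = rel
        rows.append(row)
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest: Union[str, Path]) -> list:
    manifest = Path(manifest)
    base = manifest.parent
    df = pd.read_csv(manifest)
    records = []
    for _, row in df.iterrows():
        waveforms = {}
        for key in _WF_FILES:
            rel = row.get(key)
            if isinstance(rel, str) and rel:
                waveforms[key] = read_waveform_csv(base / rel)

        def _opt(name):
            v = row.get(name)
            return None if v is None or (isinstance(v, float)
                                         and np.isnan(v)) else float(v)

        records.append(SampleRecord(
            sample_id=str(row["sample_id"]),
            fibrinogen_ref=_opt("fibrinogen_ref_g_L"),
            inr=_opt("inr"), anti_xa=_opt("anti_xa_U_mL"),
            d_dimer=_opt("d_dimer_mg_L"), waveforms=waveforms))
    return records


def write_trajectory_csv(result, path: Union[str, Path]) -> None:
    """Write a simulation trajectory as a wide CSV (time + named species)."""
    df = pd.DataFrame(result.states, columns=list(result.space.names()))
    df.insert(0, "time_s", result.times)
    df["attenuance"] = result.attenuance.values
    df.to_csv(path, index=False)


def write_predictions_csv(preds: PredictionSet,
                          path: Union[str, Path]) -> None:
    rows = [{"sample_id": p.sample_id, "truth_g_L": p.truth,
             "pred_linear": p.linear, "pred_nn": p.nn,
             "pred_combined": p.combined, "inr_stratum": p.inr_stratum,
             "antixa_pos": p.antixa_positive,
             "ddimer_elevated": p.ddimer_elevated,
             "excluded": p.excluded, "reason": p.reason}
            for p in preds.predictions]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_reference_curve_csv(ref: ReferenceCurve,
                              path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# provenance={ref.provenance}\n")
        fh.write("fib_g_per_L,max_dA\n")
        for f, a in zip(ref.fib_grid, ref.max_dA):
            fh.write(f"{float(f)!r},{float(a)!r}\n")


def read_reference_curve_csv(path: Union[str, Path]) -> ReferenceCurve:
    path = Path(path)
    prov = ""
    with path.open() as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "provenance=" in first:
            prov = first.split("provenance=", 1)[1]
    df = pd.read_csv(path, comment="#")
    return ReferenceCurve(fib_grid=df["fib_g_per_L"].to_numpy(),
                          max_dA=df["max_dA"].to_numpy(), provenance=prov)


def kinetic_parameters_from_file(path: Union[str, Path]) -> KineticParameters:
    """Load kinetic/optical constants from a YAML or JSON mapping."""
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise WaveformError(f"{path}: expected a mapping of parameters")
    return KineticParameters(**data)


def kinetic_parameters_to_file(params: KineticParameters,
                               path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=False)


def save_models_json(lr: Optional[LinearModel], nn: Optional[NNModel],
                     path: Union[str, Path],
                     extra: Optional[dict] = None) -> None:
    payload = {"format": "clotwave-models-v1"}
    if lr is not None:
        payload["linear"] = {"intercept": lr.intercept,
                             "coefficients": lr.coefficients.tolist()}
    if nn is not None:
        payload["nn"] = {
            "W1": nn.W1.tolist(), "b1": nn.b1.tolist(),
            "W2": nn.W2.tolist(), "b2": nn.b2, "seed": nn.seed,
            "standardizer": {"means": nn.standardizer.means.tolist(),
                             "sds": nn.standardizer.sds.tolist()},
        }
    if extra:
        payload["meta"] = extra
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2)


def load_models_json(path: Union[str, Path]):
    """Return ``(LinearModel | None, NNModel | None)`` from a model file."""
    with Path(path).open() as fh:
        payload = json.load(fh)
    lr = nn = None
    if "linear" in payload:
        d = payload["linear"]
        lr = LinearModel(intercept=float(d["intercept"]),
                         coefficients=np.asarray(d["coefficients"]))
    if "nn" in payload:
        d = payload["nn"]
        std = Standardizer(means=np.asarray(d["standardizer"]["means"]),
                           sds=np.asarray(d["standardizer"]["sds"]))
        nn = NNModel(W1=np.asarray(d["W1"]), b1=np.asarray(d["b1"]),
                     W2=np.asarray(d["W2"]), b2=float(d["b2"]),
                     standardizer=std, seed=int(d.get("seed", 0)))
    return lr, nn
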