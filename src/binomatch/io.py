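"""On-disk dataset layout and result tables.

A dataset directory holds ``protocol.yaml`` at its root and one
subdirectory per cell under ``cells/``, with each sweep stored as a
two-column CSV (``sample,value``) plus a YAML sidecar carrying its labels.
Results are written as ``cell_results.tsv`` (one row per cell),
``tuning_curves.tsv`` (one row per cell x eye x input type x direction)
and ``cohort_summary.json``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .protocol import (BLANK, CONTRA, CORTICAL, EYES, INPUT_TYPES, IPSI,
                       THALAMIC, TOTAL, Dataset, ProtocolError,
                       StimulusProtocol, SweepRecord)
from .decompose import CellResult
from .cohort import CohortSummary, TestResult
from .simulate import CellGroundTruth


def write_dataset(dataset: Dataset, path) -> None:
    """Write a Dataset to a directory (see module docstring for layout)."""
    dataset.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    with open(root / "protocol.yaml", "w") as fh:
        yaml.safe_dump({"protocol": dataset.protocol.to_dict(),
                        "provenance": dataset.provenance}, fh,
                       sort_keys=True)
    cells_dir = root / "cells"
    cells_dir.mkdir(exist_ok=True)
    for cell_id, sweeps in dataset.cells.items():
        cdir = cells_dir / str(cell_id)
        cdir.mkdir(exist_ok=True)
        for k, s in enumerate(sweeps):
            stem = cdir / f"sweep_{k:04d}"
            df = pd.DataFrame({"sample": np.arange(s.trace.size),
                               "value": s.trace})
            df.to_csv(f"{stem}.csv", index=False,
                      float_format="%.17g")
            meta = {
                "clamp_mode": s.clamp_mode,
                "eye": s.eye,
                "led": s.led,
                "stimulus": BLANK if s.is_blank else int(round(
                    float(s.stimulus))),
                "trial_index": int(s.trial_index),
                "stimulus_onset_s": float(s.stimulus_onset),
                "sampling_rate_hz": float(s.sampling_rate),
            }
            with open(f"{stem}.meta.yaml", "w") as fh:
                yaml.safe_dump(meta, fh, sort_keys=True)


def read_dataset(path) -> Dataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Malformed sweeps are reported with the offending file name.
    """
    root = Path(path)
    proto_file = root / "protocol.yaml"
    if not proto_file.exists():
        raise ProtocolError(f"missing protocol file {proto_file}")
    with open(proto_file) as fh:
        blob = yaml.safe_load(fh)
    protocol = StimulusProtocol.from_dict(blob["protocol"])
    provenance = blob.get("provenance", {})
    cells = {}
    cells_dir = root / "cells"
    if cells_dir.exists():
        for cdir in sorted(p for p in cells_dir.iterdir() if p.is_dir()):
            sweeps = []
            for csv_file in sorted(cdir.glob("sweep_*.csv")):
                meta_file = csv_file.with_suffix("").with_suffix(
                    ".meta.yaml")
                if not meta_file.exists():
                    raise ProtocolError(
                        f"{csv_file}: missing sidecar {meta_file.name}")
                with open(meta_file) as fh:
                    meta = yaml.safe_load(fh)
                trace = pd.read_csv(
                    csv_file,
                    float_precision="round_trip")["value"].to_numpy()
                stimulus = meta["stimulus"]
                try:
                    sweep = SweepRecord(
                        cell_id=cdir.name,
                        clamp_mode=meta["clamp_mode"],
                        eye=meta["eye"], led=meta["led"],
                        stimulus=(BLANK if stimulus == BLANK
                                  else float(stimulus)),
                        trial_index=int(meta["trial_index"]),
                        trace=trace,
                        stimulus_onset=float(meta["stimulus_onset_s"]),
                        sampling_rate=float(meta["sampling_rate_hz"]))
                    if not sweep.is_blank:
                        protocol.validate_direction(float(stimulus))
                except (ProtocolError, KeyError, ValueError) as err:
                    raise ProtocolError(f"{csv_file}: {err}") from err
                sweeps.append(sweep)
            cells[cdir.name] = sweeps
    ds = Dataset(protocol=protocol, cells=cells, provenance=provenance)
    ds.validate()
    return ds


# --------------------------------------------------------------------------
# result tables

_ANGLE_COLS = [
    ("delta_o_total", lambda r: r.delta_o.get(TOTAL)),
    ("delta_o_thalamic", lambda r: r.delta_o.get(THALAMIC)),
    ("delta_o_cortical", lambda r: r.delta_o.get(CORTICAL)),
    ("thal_total_diff_contra", lambda r: r.thal_total_diff.get(CONTRA)),
    ("thal_total_diff_ipsi", lambda r: r.thal_total_diff.get(IPSI)),
    ("thal_cort_diff_contra", lambda r: r.thal_cort_diff.get(CONTRA)),
    ("thal_cort_diff_ipsi", lambda r: r.thal_cort_diff.get(IPSI)),
]


def cell_results_frame(results: Sequence[CellResult]) -> pd.DataFrame:
    """One row per cell with every scalar metric."""
    rows = []
    for r in results:
        row = {"cell_id": r.cell_id, "clamp_mode": r.clamp_mode,
               "age_group": r.group}
        for eye in EYES:
            for itype in INPUT_TYPES:
                st = r.stats.get((eye, itype))
                row[f"pref_o_{eye}_{itype}"] = (
                    np.nan if st is None or st.pref_o is None else st.pref_o)
                row[f"gosi_{eye}_{itype}"] = (
                    np.nan if st is None else st.gosi)
        for name, getter in _ANGLE_COLS:
            v = getter(r)
            row[name] = np.nan if v is None else v
        row["scale_contra"] = r.scale_factor.get(CONTRA, np.nan)
        row["scale_ipsi"] = r.scale_factor.get(IPSI, np.nan)
        row["ci_ratio_total"] = (np.nan if r.ci_ratio_total is None
                                 else r.ci_ratio_total)
        row["ci_ratio_thalamic"] = (np.nan if r.ci_ratio_thalamic is None
                                    else r.ci_ratio_thalamic)
        row["clipped_fraction_cortical"] = r.qc.get(
            "clipped_fraction_cortical", np.nan)
        row["n_adapted_conditions"] = len(r.qc.get("adapted_conditions",
                                                   []))
        row["undefined_pref"] = ";".join(
            f"{e}:{t}" for e, t in r.qc.get("undefined_pref", []))
        rows.append(row)
    if not rows:
        cols = (["cell_id", "clamp_mode", "age_group"]
                + [f"{stat}_{eye}_{itype}" for eye in EYES
                   for itype in INPUT_TYPES for stat in ("pref_o",
                                                         "gosi")]
                + [name for name, _ in _ANGLE_COLS]
                + ["scale_contra", "scale_ipsi", "ci_ratio_total",
                   "ci_ratio_thalamic", "clipped_fraction_cortical",
                   "n_adapted_conditions", "undefined_pref"])
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def tuning_curves_frame(results: Sequence[CellResult]) -> pd.DataFrame:
    """Long-format tuning curves: one row per direction and condition."""
    rows = []
    for r in results:
        for (eye, itype), curve in sorted(r.curves.items()):
            for d, m in zip(curve.directions, curve.magnitudes):
                rows.append({"cell_id": r.cell_id, "eye": eye,
                             "input_type": itype,
                             "direction_deg": float(d),
                             "magnitude": float(m),
                             "units": curve.units,
                             "n_cycles_used": curve.n_cycles_used})
    if not rows:
        return pd.DataFrame(columns=["cell_id", "eye", "input_type",
                                     "direction_deg", "magnitude",
                                     "units", "n_cycles_used"])
    return pd.DataFrame(rows)


def _summary_to_dict(summary: CohortSummary) -> dict:
    return {
        "label": summary.label,
        "n_cells": summary.n_cells,
        "metrics": {k: {"n": v.n, "mean": v.mean, "sem": v.sem}
                    for k, v in summary.metrics.items()},
        "excluded": dict(summary.excluded),
    }


def write_results(results: Sequence[CellResult],
                  summaries: Sequence[CohortSummary],
                  path,
                  tests: Sequence[TestResult] = ()) -> None:
    """Write cell_results.tsv, tuning_curves.tsv and cohort_summary.json."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    cell_results_frame(results).to_csv(root / "cell_results.tsv",
                                       sep="\t", index=False,
                                       float_format="%.15g")
    tuning_curves_frame(results).to_csv(root / "tuning_curves.tsv",
                                        sep="\t", index=False,
                                        float_format="%.15g")
    payload = {
        "cohorts": [_summary_to_dict(s) for s in summaries],
        "tests": [{"name": t.name, "groups": t.groups,
                   "statistic": t.statistic, "p": t.p_value, "n": t.n}
                  for t in tests],
    }
    with open(root / "cohort_summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=True)


def write_ground_truth(truths: Sequence[CellGroundTruth], path) -> None:
    """Ground-truth table beside a simulated dataset (never read by the
    analysis pipeline)."""
    rows = []
    for t in truths:
        for eye in EYES:
            rows.append({
                "cell_id": t.cell_id, "clamp_mode": t.clamp_mode,
                "eye": eye,
                "pref_thalamic": t.pref_thalamic[eye],
                "pref_cortical": t.pref_cortical[eye],
                "amplitude_pa": t.amplitude_pa[eye],
                "scale_factor": t.scale_factor[eye],
                "delta_o_thalamic": t.delta_o_thalamic,
                "n_injected_spikes": int(sum(
                    v.size for (e, _, _), v in t.spike_times.items()
                    if e == eye)),
            })
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False,
                              float_format="%.15g")
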