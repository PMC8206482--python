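"""CSV / JSON serialization of sample data and fit results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datagen import PopulationSpec, SampleData
from .sem import WordingFactorResults


def sample_to_frame(data: SampleData) -> pd.DataFrame:
    k = data.k
    df = pd.DataFrame(data.responses, columns=[f"item_{i+1}" for i in range(k)])
    df["criterion"] = data.criterion
    df["inconsistent"] = data.inconsistent_flags.astype(int)
    return df

def write_sample(data: SampleData, path: str | Path, spec: PopulationSpec | None = None) -> None:
    """Write a SampleData as CSV plus a JSON sidecar with the generating model."""
    path = Path(path)
    sample_to_frame(data).to_csv(path, index=False)
    if spec is not None:
        sidecar = {
            "loadings": list(map(float, spec.loadings)),
            "thresholds": list(spec.thresholds),
            "factor_corr": spec.factor_corr,
            "criterion_loading": spec.criterion_loading,
            "item_polarity": list(map(str, data.item_polarity)),
            "seed": int(data.seed),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_sample(path: str | Path) -> SampleData:
    path = Path(path)
    df = pd.read_csv(path)
    item_cols = [c for c in df.columns if c.startswith("item_")]
    responses = df[item_cols].to_numpy(dtype=int)
    polarity = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        polarity = np.array(meta.get("item_polarity"))
    if polarity is None:
        polarity = np.array(["PW"] * len(item_cols))
    return SampleData(
        responses=responses,
        criterion=df["criterion"].to_numpy(dtype=float),
        item_polarity=polarity,
        inconsistent_flags=df["inconsistent"].to_numpy(dtype=bool),
    )


def write_fit(fit: WordingFactorResults, path: str | Path) -> None:
    payload = {
        "model": fit.spec.kind,
        "converged": bool(fit.converged),
        "reason": fit.reason,
        "loadings": list(map(float, fit.loadings_hat)),
        "omega": float(fit.omega_hat),
        "beta_sf": float(fit.beta_sf),
        "beta_wf": float(fit.beta_wf),
        "r2": float(fit.r2),
        "chi2": float(fit.chi2),
        "df": int(fit.df),
        "cfi": float(fit.cfi),
        "tli": float(fit.tli),
        "rmsea": float(fit.rmsea),
        "n": int(fit.n),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
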