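"""Serialization of feature tables and cohort artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ComplexionHistogram, LuminanceBinning

__all__ = ["write_features_csv", "read_features_csv"]


def write_features_csv(path, ids, labels, histograms: list[ComplexionHistogram]) -> None:
    """One row per image (id, label, values...) plus a JSON layout sidecar."""
    path = Path(path)
    values = np.vstack([h.values for h in histograms])
    df = pd.DataFrame(values, columns=[f"f{i}" for i in range(values.shape[1])])
    df.insert(0, "label", list(labels))
    df.insert(0, "id", list(ids))
    df.to_csv(path, index=False)
    ref = histograms[0]
    header = {
        "lum_lo": ref.binning.lo,
        "lum_hi": ref.binning.hi,
        "lum_interval": ref.binning.interval,
        "include_base_bins": ref.include_base_bins,
        "n_regions": ref.n_regions,
    }
    path.with_suffix(".layout.json").write_text(json.dumps(header, indent=1))


def read_features_csv(path):
    """Returns (ids, labels, value matrix, layout dict)."""
    path = Path(path)
    df = pd.read_csv(path)
    layout = json.loads(path.with_suffix(".layout.json").read_text())
    values = df.drop(columns=["id", "label"]).to_numpy(dtype=float)
    return list(df["id"]), list(df["label"]), values, layout


def layout_binning(layout: dict) -> LuminanceBinning:
    return LuminanceBinning(layout["lum_lo"], layout["lum_hi"], layout["lum_interval"])
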