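"""Serialization: YAML preset configs, JSON reports, CSV spot tables, PNGs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pattern_analysis import SpotSummary
from .presets import Preset

__all__ = ["save_preset_yaml", "load_preset_yaml", "save_json",
           "spots_to_dataframe", "save_spots_csv", "save_field_csv",
           "save_heatmap_png"]


def save_preset_yaml(preset: Preset, path) -> None:
    Path(path).write_text(yaml.safe_dump(preset.to_dict(), sort_keys=False))


def load_preset_yaml(path) -> Preset:
    return Preset.from_dict(yaml.safe_load(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and obj != obj:  # NaN
        return None
    return obj


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def spots_to_dataframe(spots: list[SpotSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"label": s.label, "x": s.x, "y": s.y, "area_cells": s.area_cells,
          "area_units": s.area_units, "mean_u": s.mean_u,
          "is_initiator": s.is_initiator} for s in spots],
        columns=["label", "x", "y", "area_cells", "area_units", "mean_u",
                 "is_initiator"])


def save_spots_csv(spots: list[SpotSummary], path) -> None:
    spots_to_dataframe(spots).to_csv(path, index=False)


def save_field_csv(field: np.ndarray, path) -> None:
    np.savetxt(path, field, delimiter=",")


def save_heatmap_png(field: np.ndarray, path, L: float,
                     title: str = "") -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(field, origin="lower", extent=(0, L, 0, L),
                   cmap="viridis")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
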