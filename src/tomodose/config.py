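"""YAML experiment configuration loader."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .cgan import TrainConfig
from .msbf import MsbfParams
from .phantom import PhantomSpec
from .pipeline import ExperimentConfig


def load_config(path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file.

    Top-level keys mirror the ExperimentConfig fields; ``phantom``,
    ``train`` and ``msbf`` are nested mappings passed to the corresponding
    dataclasses.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "phantom" in kwargs:
        ph = dict(kwargs["phantom"])
        for key in ("lateral_extent_mm", "mc_sizes_mm", "mass_diameters_mm"):
            if key in ph:
                ph[key] = tuple(ph[key])
        kwargs["phantom"] = PhantomSpec(**ph)
    if "train" in kwargs:
        kwargs["train"] = TrainConfig(**kwargs["train"])
    if "msbf" in kwargs:
        ms = dict(kwargs["msbf"])
        if "w_alpha" in ms:
            ms["w_alpha"] = np.asarray(ms["w_alpha"], dtype=float)
        kwargs["msbf"] = MsbfParams(**ms)
    for key in ("thicknesses_mm", "dose_labels", "arms"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return ExperimentConfig(**kwargs)
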