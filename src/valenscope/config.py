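"""YAML/JSON run configuration.

A configuration file can override band edges, labeling thresholds,
classifier settings and simulation parameters, e.g.::

    bands:
      alpha: [8, 12]
    label:
      mode: binary
      binary_threshold: 5
    classifier:
      kind: svm_rbf
      tuner: grid
      tuner_iters: 9
    simulation:
      n_subjects: 8
      effect_ratio: 2.0

Unknown keys are rejected early so typos surface as errors rather than
silently falling back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import fields
from pathlib import Path

import yaml

from .band_filters import BandDef
from .classify import ClassifierConfig
from .labeling import LabelScheme
from .synthetic import SimSpec

_SECTIONS = {"bands", "label", "classifier", "simulation", "units"}


def load_config(path: str | Path) -> dict:
    """Parse a YAML or JSON run configuration into typed objects.

    Returns a dict with optional keys ``bands`` (list of BandDef),
    ``label`` (LabelScheme), ``classifier`` (ClassifierConfig) and
    ``simulation`` (SimSpec).
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValueError(
            f"{path}: unknown configuration sections {sorted(unknown)}; "
            f"expected a subset of {sorted(_SECTIONS)}"
        )
    out: dict = {}
    if "bands" in raw:
        out["bands"] = [
            BandDef(name, float(lo), float(hi))
            for name, (lo, hi) in raw["bands"].items()
        ]
    for key, cls in (
        ("label", LabelScheme),
        ("classifier", ClassifierConfig),
        ("simulation", SimSpec),
    ):
        if key in raw:
            allowed = {f.name for f in fields(cls)}
            section = dict(raw[key])
            bad = set(section) - allowed
            if bad:
                raise ValueError(
                    f"{path}: unknown {key} options {sorted(bad)}"
                )
            # Tuples arrive as YAML lists.
            for name, value in section.items():
                if isinstance(value, list):
                    section[name] = tuple(value)
            out[key] = cls(**section)
    if "units" in raw:
        out["units"] = str(raw["units"])
    return out
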