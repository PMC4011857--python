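"""Pipeline configuration with YAML/JSON round-tripping.

All tunables of the detect -> classify -> complete -> quantify chain
live here with their defaults; a config file needs to state only the
fields it overrides.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Tunable parameters of the fissure-integrity pipeline.

    Attributes
    ----------
    scales_mm : Gaussian scales of the plate-likeness filter; bracket
        the expected fissure thickness (~1 voxel).
    threshold : plateness cut in (0, 1) for fissure voxel extraction.
    min_component_mm2 : smallest sheet component kept after thinning.
    cone_deg : half-angle of the cranio-caudal cone that admits a
        right-lung component as the horizontal fissure.
    completion_smoothing : thin-plate-spline regularization of the
        complete-boundary fit.
    completion_grid_mm : in-plane evaluation step of the fitted surface.
    rhf_clip_margin_mm : gap kept between the completed horizontal
        boundary and the oblique boundary it terminates against.
    gold_ratio_cutoff : FEV1/FVC % below which a subject is COPD.
    gold_pp_cutoffs : FEV1 %predicted cut-points for stages I/II/III/IV.
    bin_edges : integrity-level edges; first bin closed at 0.
    seed : master seed for everything stochastic (phantom simulation).
    """

    scales_mm: tuple = (0.7, 1.0, 1.4)
    threshold: float = 0.6
    min_component_mm2: float = 20.0
    cone_deg: float = 35.0
    completion_smoothing: float = 1.0
    completion_grid_mm: float = 0.7
    rhf_clip_margin_mm: float = 1.5
    gold_ratio_cutoff: float = 70.0
    gold_pp_cutoffs: tuple = (80.0, 50.0, 30.0)
    bin_edges: tuple = (0.0, 20.0, 40.0, 60.0, 80.0, 90.0, 100.0)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    def save(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})
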