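"""Analysis configuration: one dataclass, loadable from YAML or JSON."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Tunable parameters of the localization analysis pipeline."""

    min_photons: float = 700.0
    precision_percentile: float = 98.0
    density_filter_radius: float = 70.0       # nm
    density_filter_max_neighbors: int = 50
    pixel_size: float = 1.6                   # nm, binarization grid
    roi_area_um2: float = 20.0
    alpha: float = 3.0                        # appearances per label
    max_r: float = 500.0                      # nm, correlation range
    bin_width: float = 5.0                    # nm, radial bin
    deconvolve: bool = True                   # composite fit with resolution kernel
    r_min: float = 0.0                        # nm, exclude small radii from the fit
    max_dark_frames: int = 250
    grouping_factor: float = 4.0              # molecule radius = factor * mean precision

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        path = Path(path)
        payload = asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2))
        else:
            path.write_text(yaml.safe_dump(payload))
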