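"""Pipeline configuration: a TOML file with nested sections, fully validated.

Sections (all optional unless a command needs them):

* ``[synthetic]`` — fields of :class:`~connstab.cohort.SyntheticConfig`
  (``scale_weights`` keys are written ``"i-j"``).
* ``[features]``  — threshold ``c``, ``block_dims``, ``min_fill``, ``absolute``.
* ``[stats]``     — ``alpha``.
* ``[cv]``        — ``k_grid``, ``classifier_families``, ``seed``.
* ``[en]``        — ``target_grid``, ``lambda2_grid``.

Unknown sections or keys are rejected before any stage runs.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .cohort import SyntheticConfig, config_from_dict

_SECTION_KEYS = {
    "synthetic": {f.name for f in dataclasses.fields(SyntheticConfig)},
    "features": {"c", "block_dims", "min_fill", "absolute"},
    "stats": {"alpha"},
    "cv": {"k_grid", "classifier_families", "seed"},
    "en": {"target_grid", "lambda2_grid"},
}


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig | None = None
    c: float = 0.7
    block_dims: tuple[int, int, int] = (4, 4, 3)
    min_fill: float = 0.5
    absolute: bool = False
    alpha: float = 0.05
    k_grid: list[int] = field(default_factory=lambda: [10, 30, 100])
    classifier_families: list[str] = field(default_factory=lambda: ["linear_svm"])
    seed: int = 0
    target_grid: list[int] = field(default_factory=lambda: [50, 100, 300, 500, 700])
    lambda2_grid: list[float] = field(default_factory=lambda: [0.01, 0.1, 1.0])

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        unknown_sections = set(raw) - set(_SECTION_KEYS)
        if unknown_sections:
            raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
        for section, keys in _SECTION_KEYS.items():
            extra = set(raw.get(section, {})) - keys
            if extra:
                raise ValueError(f"unknown keys in [{section}]: {sorted(extra)}")
        cfg = cls()
        if "synthetic" in raw:
            cfg.synthetic = config_from_dict(raw["synthetic"])
        feat = raw.get("features", {})
        cfg.c = float(feat.get("c", cfg.c))
        cfg.block_dims = tuple(feat.get("block_dims", cfg.block_dims))
        cfg.min_fill = float(feat.get("min_fill", cfg.min_fill))
        cfg.absolute = bool(feat.get("absolute", cfg.absolute))
        cfg.alpha = float(raw.get("stats", {}).get("alpha", cfg.alpha))
        cv = raw.get("cv", {})
        cfg.k_grid = [int(k) for k in cv.get("k_grid", cfg.k_grid)]
        cfg.classifier_families = list(cv.get("classifier_families", cfg.classifier_families))
        cfg.seed = int(cv.get("seed", cfg.seed))
        en = raw.get("en", {})
        cfg.target_grid = [int(t) for t in en.get("target_grid", cfg.target_grid)]
        cfg.lambda2_grid = [float(l) for l in en.get("lambda2_grid", cfg.lambda2_grid)]
        return cfg
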