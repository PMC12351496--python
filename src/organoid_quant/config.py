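"""Aggregate analysis configuration with YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from organoid_quant.calcium_activity import CalciumParams
from organoid_quant.expression_stats import ALPHA, FC_DOWN, FC_UP, MIN_AVG_COUNT, REF_GENE
from organoid_quant.marker_quant2d import Preprocess2DParams
from organoid_quant.neurite_morph3d import TubeEnhanceParams


@dataclass
class ExpressionParams:
    """Tunables of normalization, DE selection, and qPCR."""

    min_avg_count: float = MIN_AVG_COUNT
    alpha: float = ALPHA
    fc_up: float = FC_UP
    fc_down: float = FC_DOWN
    log_scale: bool = True
    add_fdr: bool = False
    ref_gene: str = REF_GENE


@dataclass
class AnalysisConfig:
    """Every tunable of the four pipelines, with the protocol defaults.

    Serializes to YAML and round-trips exactly (write → read → identical).
    """

    preprocess2d: Preprocess2DParams = field(default_factory=Preprocess2DParams)
    n_projection_planes: int = 20
    tube_enhance: TubeEnhanceParams = field(default_factory=TubeEnhanceParams)
    deconvolve: bool = False
    deconvolve_psf_sigma_px: float = 2.0
    min_fragment_voxels: int = 0
    calcium: CalciumParams = field(default_factory=CalciumParams)
    expression: ExpressionParams = field(default_factory=ExpressionParams)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            preprocess2d=Preprocess2DParams(**data.get("preprocess2d", {})),
            n_projection_planes=data.get("n_projection_planes", 20),
            tube_enhance=TubeEnhanceParams(**data.get("tube_enhance", {})),
            deconvolve=data.get("deconvolve", False),
            deconvolve_psf_sigma_px=data.get("deconvolve_psf_sigma_px", 2.0),
            min_fragment_voxels=data.get("min_fragment_voxels", 0),
            calcium=CalciumParams(**data.get("calcium", {})),
            expression=ExpressionParams(**data.get("expression", {})),
        )
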