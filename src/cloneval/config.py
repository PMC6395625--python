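"""Schema-validated run configuration (unknown keys rejected, explicit seed
required for every random stage)."""
from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ReferenceConfig(_Strict):
    length: int = 261
    primer_len: int = 20
    seed: int = 20190228
    sequence: Optional[str] = None  # explicit sequence overrides the generator
    primer_mask: Optional[list[tuple[int, int]]] = None


class TemplateConfig(_Strict):
    #: each variant is (pos0, kind, ref, alt)
    variants: Optional[list[tuple[int, str, str, str]]] = None
    fraction: float = 1.0
    label: Optional[str] = None


class PcrConfig(_Strict):
    doublings: float = 43.0
    sub_rate: float = 2.5e-6
    indel_rate: float = 0.0
    mode: Literal["poisson_approx", "lineage_tree"] = "poisson_approx"
    n_molecules: int = 100_000
    composition: Literal["multinomial", "expected"] = "multinomial"


class SequencerConfig(_Strict):
    sub_rate: float = 0.00148
    indel_rate: float = 0.00147
    hp_multipliers: Optional[dict[int, float]] = None
    positional_gain: tuple[float, float] = (0.5, 1.5)
    read_rate_sigma: float = 0.0
    q_jitter_sd: float = 0.0


class SequencingRunConfig(_Strict):
    n_reads: int = 10_000


class LayoutSection(_Strict):
    frame_grid: tuple[int, int] = (2, 2)
    frame_size: tuple[int, int] = (512, 512)
    overlap: float = 48.0
    offset_jitter: float = 1.5
    min_separation: float = 6.0
    spot_sigma: float = 1.4
    #: pixel -> stage truth transform as (scale, rotation, tx, ty)
    transform: tuple[float, float, float, float] = (0.65, 0.03, 1500.0, -900.0)


class SelectionConfig(_Strict):
    mode: Literal["all_variant_reads", "positional"] = "all_variant_reads"
    positions: Optional[list[int]] = None
    band_width: int = 16


class RegistrationConfig(_Strict):
    plate_format: Literal[96, 384] = 96
    laser_radius: float = 3.0
    skip_collisions: bool = False
    render_noise_sd: float = 0.0
    min_intensity: float = 100.0


class ValidationConfig(_Strict):
    depth: int = 20
    error_rate: float = 0.0
    damage_rate: float = 0.0
    consensus_threshold: float = 0.80
    min_depth_fraction: float = 0.02


class StatsConfig(_Strict):
    q_thresholds: list[float] = Field(default_factory=lambda: [0, 10, 20, 30])
    quality_mode: Literal["mean_q", "fraction_above"] = "mean_q"
    p_fraction: float = 0.5


class InputConfig(_Strict):
    """Real-data mode: reads + alignments instead of the simulator."""

    fastq: Optional[str] = None
    sam: Optional[str] = None
    reference_fasta: Optional[str] = None
    layout_tsv: Optional[str] = None


STAGES = ("simulate", "select", "register", "validate", "stats")


class RunConfig(_Strict):
    seed: Optional[int] = None
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    reference: ReferenceConfig = Field(default_factory=ReferenceConfig)
    templates: list[TemplateConfig] = Field(
        default_factory=lambda: [TemplateConfig()]
    )
    pcr: PcrConfig = Field(default_factory=PcrConfig)
    sequencer: SequencerConfig = Field(default_factory=SequencerConfig)
    run: SequencingRunConfig = Field(default_factory=SequencingRunConfig)
    layout: Optional[LayoutSection] = None
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    registration: RegistrationConfig = Field(default_factory=RegistrationConfig)
    validation: ValidationConfig = Field(default_factory=ValidationConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    input: Optional[InputConfig] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        random_stages = {"simulate", "validate"}
        if random_stages & set(self.stages) and self.seed is None:
            raise ValueError(
                "an explicit integer seed is required when random stages "
                f"({sorted(random_stages & set(self.stages))}) are enabled"
            )
        if "register" in self.stages and "simulate" in self.stages and self.layout is None:
            raise ValueError("register stage requires a layout section")
        return self

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
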