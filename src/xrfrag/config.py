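"""Run configuration: one serializable object drives the whole pipeline.

A run's config plus its inputs determine every output bit-for-bit: all
stochastic stages (the simulator) consume only the stated seed.  Schema
violations surface as field-level validation errors.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config"]


class GenomeSpec(BaseModel):
    """One synthetic genome to generate (simulate stage)."""

    id: str
    length: int = Field(ge=100)
    at_fraction: float = Field(ge=0.0, le=1.0, default=0.7)
    topology: str = "circular"
    compartment: str = "mito"


class DuplicationSpec(BaseModel):
    """A planted organellar insertion into a nuclear genome."""

    donor: str
    target: str
    donor_start: int = Field(ge=0)
    donor_end: int = Field(gt=0)
    insertion_site: int = Field(ge=0)
    divergence_rate: float = Field(ge=0.0, le=0.25, default=0.0)


class DamageSpec(BaseModel):
    mechanism: str = "fixed_incision"
    primary_length: int = 26
    trim_step: int = 2
    trim_max_steps: int = 0
    dimer_offset_3p: int = 19

    @field_validator("mechanism")
    @classmethod
    def _mech(cls, v):
        if v not in ("fixed_incision", "five_prime_trim"):
            raise ValueError("mechanism must be fixed_incision or five_prime_trim")
        return v


class SimulateSpec(BaseModel):
    genomes: list[GenomeSpec] = Field(default_factory=list)
    duplications: list[DuplicationSpec] = Field(default_factory=list)
    damage: DamageSpec = Field(default_factory=DamageSpec)
    source_genome: str | None = None
    n_reads: int = Field(ge=1, default=5000)


class EditSpec(BaseModel):
    """A reference edit on 1-based inclusive coordinates."""

    genome: str
    kind: str
    start: int = Field(ge=1)
    end: int = Field(ge=1)
    reason: str = ""

    @field_validator("kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("remove_interval", "halve_count_interval"):
            raise ValueError("kind must be remove_interval or halve_count_interval")
        return v


class FilterSpec(BaseModel):
    mapq_min: int = 30
    max_mismatches: int = 0


class ProfileSpec(BaseModel):
    anchor: str = "five_prime"
    lengths: list[int] | None = None
    dinucs: list[str] = Field(default_factory=lambda: ["TT"])
    min_reads: int = 100
    null_from: str = "genome"  # or a literal float via null_value
    null_value: float | None = None


class CoverageSpec(BaseModel):
    dipyr_set: list[str] = Field(default_factory=lambda: ["TT"])


class PathsSpec(BaseModel):
    outdir: Path = Path("xrfrag_out")
    genomes_fasta: Path | None = None
    gff: Path | None = None
    reads_fastq: Path | None = None
    sam: Path | None = None
    topology: dict[str, str] = Field(default_factory=dict)
    compartment: dict[str, str] = Field(default_factory=dict)


class RunConfig(BaseModel):
    """Top-level configuration for simulate + pipeline runs."""

    paths: PathsSpec = Field(default_factory=PathsSpec)
    simulate: SimulateSpec = Field(default_factory=SimulateSpec)
    edits: list[EditSpec] = Field(default_factory=list)
    adapter: str = "AGATCGGAAGAGC"
    filters: FilterSpec = Field(default_factory=FilterSpec)
    profile: ProfileSpec = Field(default_factory=ProfileSpec)
    coverage: CoverageSpec = Field(default_factory=CoverageSpec)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                self.model_dump(mode="json"), fh, default_flow_style=False
            )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
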