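"""Run configuration: one YAML file with per-stage sections.

Unknown keys are rejected so a typo'd threshold can never silently fall
back to a default.  The chain presets ``maq_transcript_2011`` and
``samtools_genome_2011`` name the two classic parameter sets as
executable documentation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .ngs import CallerConfig
from .sanger import SangerConfig


class ConfigError(ValueError):
    pass


CHAIN_PRESETS = {
    "maq_transcript_2011": CallerConfig.transcript_preset,
    "samtools_genome_2011": CallerConfig.genome_preset,
}


@dataclass
class SimulateSection:
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len: tuple[int, int] = (150, 400)
    intron_len: tuple[int, int] = (80, 300)
    cultivars: list[str] = field(
        default_factory=lambda: ["Atlantic", "PremierRusset", "Snowden"]
    )
    ploidy: int = 4
    snp_rate: float = 0.005
    nonbiallelic_fraction: float = 0.05
    read_length: int = 61
    depth: float = 100.0
    error_rate: float = 0.0
    three_prime_multiplier: float = 5.0
    indel_rate: float = 0.0
    multi_map_fraction: float = 0.0
    space: str = "transcript"


@dataclass
class AnchorSection:
    min_identity: float = 95.0
    min_boundary_distance: int = 50
    flank: int = 60


@dataclass
class PanelSection:
    groups: list = field(
        default_factory=lambda: [
            ["chip_processing", 40],
            ["frenchfry_processing", 40],
            ["round_white", 40],
            ["russet", 40],
        ]
    )
    n_markers: int = 82
    divergence: float = 0.2
    missing_rate: float = 0.02


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "spudsnp_run"
    log_level: str = "INFO"
    chain_preset: str = "maq_transcript_2011"
    simulate: SimulateSection = field(default_factory=SimulateSection)
    anchor: AnchorSection = field(default_factory=AnchorSection)
    panel: PanelSection = field(default_factory=PanelSection)
    sanger: SangerConfig = field(default_factory=SangerConfig)

    def caller_config(self) -> CallerConfig:
        try:
            return CHAIN_PRESETS[self.chain_preset]()
        except KeyError:
            raise ConfigError(
                f"unknown chain preset {self.chain_preset!r}; "
                f"choose from {sorted(CHAIN_PRESETS)}"
            ) from None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_dict(self) -> dict:
        """Config without run-location keys; the provenance hash covers
        only parameters that affect scientific content."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("log_level", None)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        def build(dc_type, payload, path):
            if not isinstance(payload, dict):
                raise ConfigError(f"section {path or 'root'} must be a mapping")
            fields = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(payload) - set(fields)
            if unknown:
                raise ConfigError(
                    f"unknown config keys at {path or 'root'}: {sorted(unknown)}"
                )
            kwargs = {}
            for name, value in payload.items():
                ftype = fields[name].type
                if dataclasses.is_dataclass(_resolve(ftype)):
                    kwargs[name] = build(_resolve(ftype), value, f"{path}{name}.")
                elif isinstance(value, list) and name in (
                    "exons_per_gene",
                    "exon_len",
                    "intron_len",
                ):
                    kwargs[name] = tuple(value)
                else:
                    kwargs[name] = value
            return dc_type(**kwargs)

        def _resolve(ftype):
            return {
                "SimulateSection": SimulateSection,
                "AnchorSection": AnchorSection,
                "PanelSection": PanelSection,
                "SangerConfig": SangerConfig,
            }.get(ftype if isinstance(ftype, str) else ftype.__name__, ftype)

        return build(cls, data or {}, "")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
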