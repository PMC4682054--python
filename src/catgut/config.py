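"""Run configuration: one serialisable object covering every stage knob."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ALL_STAGES"]

ALL_STAGES = ("simulate", "diversity", "ordinate", "associate",
              "pathways", "enrich")


@dataclass
class RunConfig:
    """Everything a reproducible end-to-end run depends on.

    Every field has an explicit default; a run report echoes the full
    config (defaults included) plus its hash, so any number in a stage
    output traces back to a (config, seed) pair.
    """

    seed: int = 0
    outdir: str = "catgut_out"
    #: read inputs from here instead of simulating (design.tsv,
    #: genus_counts.tsv, ko_counts.tsv, hierarchy.tsv, gene_sets.json)
    input_dir: str | None = None
    stages: tuple = ALL_STAGES

    # simulate
    full_scale: bool = False
    n_ko: int = 400
    n_pathway: int = 60
    theta: float = 50.0
    kitten_sd: float = 0.3

    # diversity
    rarefaction_replicates: int = 10

    # ordination
    n_axes: int = 3

    # association
    alpha: float = 0.05
    max_zero_prop: float = 0.75
    working_corr: str = "exchangeable"
    taxa_direction_rule: str = "pairwise-18"
    ko_direction_rule: str = "monotone"

    # pathways
    parsimony_solver: str = "auto"

    # enrichment
    n_perm: int = 1000
    universe_mode: str = "analysed"
    bias_corrected: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("input_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw = dict(raw, stages=tuple(raw["stages"]))
        return cls(**raw)
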