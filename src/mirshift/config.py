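"""Run configuration: paths, analysis constants, seed, and the config hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs.

    Analysis constants default to the stated study values: a 1.2-fold
    upregulation threshold, a wild-type linear-intensity floor of 16, and a
    top-10% conservation cut.
    """

    # inputs
    utr_fasta: str = "utrs.fasta"
    mirna_file: str = "mirna.fasta"
    expr_1: str = "expr_1.tsv"
    design_1: str = "design_1.yaml"
    expr_2: str | None = None
    design_2: str | None = None
    conservation: str | None = None
    gene_sets: str | None = None
    rules: str | None = None
    # output
    outdir: str = "results"
    # analysis constants
    fold: float = 1.2
    floor: float = 16.0
    conserved_fraction: float = 0.10
    alternative: str = "two-sided"
    controls_per_target: int = 1
    wt_label: str = "WT"
    ko_label: str = "KO"
    seed: int = 0

    def validate(self) -> None:
        if not self.fold > 1:
            raise ValueError(f"fold must be > 1, got {self.fold}")
        if self.floor < 0:
            raise ValueError(f"floor must be >= 0, got {self.floor}")
        if not 0 < self.conserved_fraction <= 1:
            raise ValueError("conserved_fraction must be in (0, 1]")
        if self.alternative not in ("two-sided", "less", "greater"):
            raise ValueError(f"unknown alternative {self.alternative!r}")
        if self.controls_per_target < 1:
            raise ValueError("controls_per_target must be >= 1")
        if (self.expr_2 is None) != (self.design_2 is None):
            raise ValueError("expr_2 and design_2 must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so a run is
        relocatable without its provenance changing)."""
        params = {
            k: v
            for k, v in asdict(self).items()
            if k in ("fold", "floor", "conserved_fraction", "alternative",
                     "controls_per_target", "wt_label", "ko_label", "seed")
        }
        payload = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
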