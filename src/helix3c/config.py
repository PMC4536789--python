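"""Run configuration: defaults for every pipeline stage, YAML round trip.

All window parameters default to the analysis geometry the pipeline is
built around (25-kb anchors stepped every 5 kb over a one-sided 400-kb
span at 5-kb bins, 70-kb fit span, in-TAD span equal to the fit span) and
are mirrored completely into each run's manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    model: str = "helix"                 # helix | unconstrained | powerlaw
    l_mode: str = "fixed"                # fixed | free
    fixed_l: float | None = None         # nm/kb; derived from nrl_bp if absent
    nrl_bp: float | None = None
    weight_mode: str = "sem"             # sem | uniform
    domain_scheme: str = "gene_rich_poor"
    star_convention: str = "fig2"
    # virtual-3C window geometry (kb)
    bin_size_kb: float = 5.0
    anchor_width_kb: float = 25.0
    step_kb: float = 5.0
    span_kb: float = 400.0
    fit_span_kb: float = 70.0
    min_in_tad_span_kb: float | None = None   # None -> fit_span_kb
    aggregation: str = "offset_mean"
    exclude_chromosomes: tuple = ()
    seed: int = 0
    output_dir: str = "helix3c_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclude_chromosomes"] = list(self.exclude_chromosomes)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_chromosomes" in data and data["exclude_chromosomes"]:
            data["exclude_chromosomes"] = tuple(data["exclude_chromosomes"])
        return cls(**data)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())
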