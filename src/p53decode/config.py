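"""Pipeline configuration: every analysis constant lives here, none inline.

The defaults encode the study's selection thresholds (mRNA fold change 1.5,
FDR 0.2, replicate PCC 0.5; protein fold change 1.15 with either the strict
FDR 0.05 / PCC 0.7 pair or the looser 0.2 / 0.5 pair via preset), the
clustering setup (fuzzifier 1.3; five mRNA / three protein clusters), and the
fitting options (delay bound 3 h, 0-9 h comparison window).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .clustering import ClusterConfig
from .differential_expression import DECriteria, default_criteria


@dataclass
class SyntheticConfig:
    n_genes: int = 200
    cv: float = 0.1
    n_replicates: int = 2
    mechanism_mix: dict[str, float] | None = None


@dataclass
class FitConfig:
    tdel_max: float = 3.0
    window: tuple[float, float] = (0.0, 9.0)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "p53decode_out"
    preset: str = "paper-defaults"  # or "fig2-protein-thresholds"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    mrna_table: str | None = None       # load instead of simulating
    protein_table: str | None = None
    annotation_table: str | None = None
    de_mrna: DECriteria | None = None
    de_protein: DECriteria | None = None
    cluster_mrna: ClusterConfig = field(default_factory=lambda: ClusterConfig(n_clusters=5))
    cluster_protein: ClusterConfig = field(default_factory=lambda: ClusterConfig(n_clusters=3))
    fit: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if self.de_mrna is None:
            self.de_mrna = default_criteria("mRNA", self.preset)
        if self.de_protein is None:
            self.de_protein = default_criteria("protein", self.preset)
        if (self.mrna_table is None) != (self.protein_table is None):
            raise ValueError("provide both mRNA and protein tables, or neither")
        if self.synthetic.n_genes <= 0 and self.mrna_table is None:
            raise ValueError("synthetic cohort must contain at least one gene")

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}

    def content_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in ("window",) and isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    sub = {}
    if "synthetic" in data:
        sub["synthetic"] = _build(SyntheticConfig, data.pop("synthetic"))
    if "fit" in data:
        sub["fit"] = _build(FitConfig, data.pop("fit"))
    for key, cls in (("de_mrna", DECriteria), ("de_protein", DECriteria),
                     ("cluster_mrna", ClusterConfig), ("cluster_protein", ClusterConfig)):
        if key in data and isinstance(data[key], dict):
            d = data.pop(key)
            if "fc_window" in d and isinstance(d["fc_window"], list):
                d["fc_window"] = tuple(d["fc_window"])
            sub[key] = cls(**d)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data, **sub)
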