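"""Single TOML config file holding every tunable of the pipeline.

Sections (all optional; missing keys fall back to the documented defaults):

```toml
[alignment]
match = 1.0
mismatch = -1.0
gap_open = 2.0
gap_extend = 0.5

[disease]
alpha = 0.5

[snf]
K = 20
t = 20
tol = 1e-6

[features]
n_bins = 10
top_n = 10
kmer_ks = [2, 3, 4]
svd_rank = 5
pca_variance = 0.95
kmer_raw = false

[gbdt]
n_estimators = 60
learning_rate = 0.1
max_depth = 9
min_samples_split = 24
min_samples_leaf = 11
max_features = 9
subsample = 0.8
seed = 0

[evaluate]
threshold = 0.5
use_pca = false

[synthetic]
n_circ = 132
n_disease = 40
n_blocks = 6
...
```
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

from .features import FeatureConfig
from .gbdt import GBDTParams
from .similarity import AlignmentParams, DiseaseSimWeights
from .snf import SNFParams
from .synthetic import SynthConfig

__all__ = ["Config", "load_config"]


@dataclass
class EvalConfig:
    threshold: float = 0.5
    use_pca: bool = False


@dataclass
class Config:
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    disease: DiseaseSimWeights = field(default_factory=DiseaseSimWeights)
    snf: SNFParams = field(default_factory=SNFParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    gbdt: GBDTParams = field(default_factory=GBDTParams)
    evaluate: EvalConfig = field(default_factory=EvalConfig)
    synthetic: SynthConfig = field(default_factory=SynthConfig)


_SECTIONS = {
    "alignment": AlignmentParams,
    "disease": DiseaseSimWeights,
    "snf": SNFParams,
    "features": FeatureConfig,
    "gbdt": GBDTParams,
    "evaluate": EvalConfig,
    "synthetic": SynthConfig,
}

_TUPLE_KEYS = {"kmer_ks", "seq_len"}


def load_config(path: str | Path | None) -> Config:
    """Load a TOML config; unknown sections or keys raise a ValueError."""
    if path is None:
        return Config()
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    out = {}
    for section, payload in raw.items():
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section [{section}]")
        cls = _SECTIONS[section]
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")
        payload = {
            k: tuple(v) if k in _TUPLE_KEYS and isinstance(v, list) else v
            for k, v in payload.items()
        }
        out[section] = cls(**payload)
    return Config(**out)
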