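"""Pipeline configuration: one TOML file covering every stage's thresholds.

Sections map onto the stage configs (``[ssr]``, ``[primer]``, ``[compare]``,
``[filter]``, ``[pipeline]``); unknown sections or keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from .annotation_filter import GENOMIC_BLACKLIST, GENOMIC_MAX_EVALUE
from .cross_compare import CompareConfig
from .primer_select import PrimerConfig
from .ssr_detect import SSRConfig


@dataclass(frozen=True)
class FilterConfig:
    """Keyword-exclusion settings for the homology screen."""

    blacklist: tuple[str, ...] = GENOMIC_BLACKLIST
    max_evalue: float = GENOMIC_MAX_EVALUE


@dataclass(frozen=True)
class PipelineConfig:
    ssr: SSRConfig = field(default_factory=SSRConfig)
    primer: PrimerConfig = field(default_factory=PrimerConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    enrich_strict: bool = True  # strictly greater than N50
    di_tri_only: bool = True  # restrict the final panel to di/tri motifs
    outdir: str = "ssrforge_out"


_SECTION_TYPES = {
    "ssr": SSRConfig,
    "primer": PrimerConfig,
    "compare": CompareConfig,
    "filter": FilterConfig,
}
_TOP_KEYS = {"enrich_strict", "di_tri_only", "outdir"}


def _build(cls, section: str, data: dict):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_pipeline_config(path) -> PipelineConfig:
    """Parse and validate a pipeline TOML file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return pipeline_config_from_dict(data)


def pipeline_config_from_dict(data: dict) -> PipelineConfig:
    unknown = set(data) - set(_SECTION_TYPES) - {"pipeline"}
    if unknown:
        raise ValueError(f"unknown section(s): {sorted(unknown)}")
    kwargs = {
        name: _build(cls, name, data.get(name, {}))
        for name, cls in _SECTION_TYPES.items()
    }
    top = data.get("pipeline", {})
    bad = set(top) - _TOP_KEYS
    if bad:
        raise ValueError(f"unknown key(s) in [pipeline]: {sorted(bad)}")
    kwargs.update(top)
    return PipelineConfig(**kwargs)
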