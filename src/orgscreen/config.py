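"""Pipeline configuration: comparisons, thresholds, Boolean expression.

Defaults encode the study design: six pairwise comparisons of organizer
vs most-similar non-organizer tissue, an absolute log2 fold-change
threshold of 1.2, a Benjamini-Hochberg FDR threshold of 0.05, and the
default combination expression ``(C1 AND (C2 OR C3)) AND C4 AND (C5 OR C6)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from . import boolean
from .errors import ConfigError
from .io import SampleSheet

__all__ = [
    "ComparisonSpec",
    "PipelineConfig",
    "DEFAULT_COMPARISONS",
    "DEFAULT_EXPRESSION",
    "load_config",
    "dump_config",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """One pairwise comparison; ``group_a`` is the putative organizer side."""

    name: str
    group_a: str
    group_b: str

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ConfigError(f"comparison {self.name!r}: group_a equals group_b")


#: The six study comparisons. C1-C3 probe the gastrula organizer (Hensen's
#: node vs posterior primitive streak, early vs late node), C4 the
#: notochord/floor-plate vs dorsal neural tube, C5-C6 the posterior
#: (ZPA-containing) vs anterior wing bud at two stages.
DEFAULT_COMPARISONS: tuple[ComparisonSpec, ...] = (
    ComparisonSpec("C1", "HH4 HN", "HH4 PS"),
    ComparisonSpec("C2", "HH6 HN", "HH4 PS"),
    ComparisonSpec("C3", "HH4 HN", "HH6 HN"),
    ComparisonSpec("C4", "VNT", "DNT"),
    ComparisonSpec("C5", "HH20 PL", "HH20 AL"),
    ComparisonSpec("C6", "HH24 PL", "HH24 AL"),
)

DEFAULT_EXPRESSION = "(C1 AND (C2 OR C3)) AND C4 AND (C5 OR C6)"


@dataclass(frozen=True)
class PipelineConfig:
    comparisons: tuple[ComparisonSpec, ...] = DEFAULT_COMPARISONS
    expression_text: str = DEFAULT_EXPRESSION
    lfc_threshold: float = 1.2
    fdr_threshold: float = 0.05
    fc_scale: str = "log2"  # "log2": |log2FC| >= tau; "linear": |FC| >= tau
    variance_pooling: str = "global"  # "global": full-design residual; "pair"
    patchy_as_positive: bool = False
    already_log2: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lfc_threshold <= 0:
            raise ConfigError("lfc_threshold must be positive")
        if not (0 < self.fdr_threshold <= 1):
            raise ConfigError("fdr_threshold must lie in (0, 1]")
        if self.fc_scale not in ("log2", "linear"):
            raise ConfigError(f"fc_scale must be 'log2' or 'linear', got {self.fc_scale!r}")
        if self.variance_pooling not in ("global", "pair"):
            raise ConfigError(
                f"variance_pooling must be 'global' or 'pair', got {self.variance_pooling!r}"
            )
        names = [c.name for c in self.comparisons]
        if len(set(names)) != len(names):
            raise ConfigError("comparison names must be unique")
        expr = boolean.parse_expression(self.expression_text)
        unknown = boolean.leaves(expr) - set(names)
        if unknown:
            raise ConfigError(
                f"expression names unknown comparisons {sorted(unknown)}; "
                f"valid names: {names}"
            )

    @property
    def expression(self) -> boolean.BooleanExpr:
        return boolean.parse_expression(self.expression_text)

    @property
    def comparison_names(self) -> list[str]:
        return [c.name for c in self.comparisons]

    @property
    def effective_lfc_threshold(self) -> float:
        """The threshold on the log2 scale regardless of ``fc_scale``."""
        if self.fc_scale == "log2":
            return self.lfc_threshold
        return math.log2(self.lfc_threshold)

    def validate_against(self, sheet: SampleSheet) -> None:
        groups = set(sheet.groups)
        for c in self.comparisons:
            for g in (c.group_a, c.group_b):
                if g not in groups:
                    raise ConfigError(
                        f"comparison {c.name!r} references group {g!r} "
                        "absent from the sample sheet"
                    )


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; omitted keys fall back to the study defaults.

    An empty (or absent) file yields the default configuration.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data = loaded
    known = {
        "comparisons",
        "expression_text",
        "lfc_threshold",
        "fdr_threshold",
        "fc_scale",
        "variance_pooling",
        "patchy_as_positive",
        "already_log2",
        "seed",
    }
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "comparisons" in data:
        comps = tuple(
            ComparisonSpec(c["name"], c["group_a"], c["group_b"])
            for c in data["comparisons"]
        )
        data = {**data, "comparisons": comps}
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a config back to YAML; ``load_config`` reproduces it exactly."""
    data = {
        "comparisons": [
            {"name": c.name, "group_a": c.group_a, "group_b": c.group_b}
            for c in config.comparisons
        ],
        "expression_text": config.expression_text,
        "lfc_threshold": config.lfc_threshold,
        "fdr_threshold": config.fdr_threshold,
        "fc_scale": config.fc_scale,
        "variance_pooling": config.variance_pooling,
        "patchy_as_positive": config.patchy_as_positive,
        "already_log2": config.already_log2,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def with_overrides(config: PipelineConfig, **kwargs) -> PipelineConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **kwargs)
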