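"""Configuration profiles and layered parameter resolution.

Every tunable named by the pipeline — clustering thresholds, the similarity
formula, the cluster-cut distance, the class cutoffs, smoothing density, the
scale-bar fraction, colours, page profile — is a field of
:class:`Parameters` and is addressable from a profile file or a CLI
``key=value`` override.  Resolution is layered: built-in defaults <-
profile <- explicit overrides (last wins).

Profile files use a flat ``key = value`` dialect with optional ``[section]``
headers (sections are cosmetic; keys are globally unique).
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

from .layout import PROFILE_WIDTHS, CanvasSpec
from .model import DEFAULT_HYPOTHETICAL_PATTERNS
from .render import StyleConfig

BUILTIN_PROFILES = tuple(PROFILE_WIDTHS)  # A4p1, A4p2, standard


@dataclass
class Parameters:
    """All user-facing knobs of the pipeline with their defaults."""

    profile: str = "standard"
    mode: str = "full"  # full | compact
    # homology clustering
    min_identity: float = 0.35
    min_coverage: float = 0.7
    # proteome analysis
    similarity_formula: str = "mean_directional"  # or jaccard
    cluster_cut_distance: float = 0.75
    conserved_cutoff: float = 0.75
    variable_cutoff: float = 0.25
    # tracks
    points_per_unit: float = 2.0
    gc_window: int = 101
    # layout
    scale_bar_fraction: float = 0.25
    connector_style: str = "straight"
    hypothetical_patterns: tuple[str, ...] = DEFAULT_HYPOTHETICAL_PATTERNS
    # rendering
    highlight_mode: str = "variable"  # variable | conserved
    color_intermediate: bool = True
    palette_seed: int = 0
    conserved_color: tuple[float, float, float] = (0.78, 0.78, 0.78)
    connector_color: tuple[float, float, float] = (0.88, 0.88, 0.88)
    positive_track_color: tuple[float, float, float] = (0.80, 0.30, 0.25)
    negative_track_color: tuple[float, float, float] = (0.30, 0.45, 0.75)
    creation_date: str = "D:20250101000000Z"

    def canvas(self) -> CanvasSpec:
        spec = CanvasSpec.from_profile(self.profile, mode=self.mode)
        spec.scale_bar_fraction = self.scale_bar_fraction
        return spec

    def style(self) -> StyleConfig:
        return StyleConfig(
            conserved_color=self.conserved_color,
            connector_color=self.connector_color,
            positive_track_color=self.positive_track_color,
            negative_track_color=self.negative_track_color,
            highlight_mode=self.highlight_mode,
            color_intermediate=self.color_intermediate,
            palette_seed=self.palette_seed,
            creation_date=self.creation_date,
        )


_VALID_KEYS = {f.name for f in fields(Parameters)}


def _coerce(name: str, value: str):
    proto = getattr(Parameters(), name)
    if isinstance(proto, bool):
        return value.strip().lower() in ("true", "1", "yes")
    if isinstance(proto, int) and not isinstance(proto, bool):
        return int(value)
    if isinstance(proto, float):
        return float(value)
    if isinstance(proto, tuple):
        parts = [p.strip() for p in value.split(",") if p.strip()]
        if name == "hypothetical_patterns":
            return tuple(parts)
        return tuple(float(p) for p in parts)
    return value.strip()


def load_profile(name_or_path: str | Path = "standard") -> Parameters:
    """Resolve a built-in profile name or a profile file into parameters.

    Unknown keys raise an error listing the valid ones.
    """
    name = str(name_or_path)
    if name in BUILTIN_PROFILES:
        return Parameters(profile=name)
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(
            f"unknown profile {name!r}: not a built-in name "
            f"({', '.join(sorted(BUILTIN_PROFILES))}) and not a file"
        )
    parser = configparser.ConfigParser()
    # tolerate section-less files by injecting a default section
    text = path.read_text()
    if not text.lstrip().startswith("["):
        text = "[DEFAULT]\n" + text
    parser.read_string(text)
    params = Parameters()
    seen = {}
    for section in [parser.defaults()] + [
        parser[s] for s in parser.sections()
    ]:
        for key, value in section.items():
            seen[key] = value
    for key, value in seen.items():
        if key not in _VALID_KEYS:
            raise ValueError(
                f"unknown configuration key {key!r}; valid keys: "
                + ", ".join(sorted(_VALID_KEYS))
            )
        params = replace(params, **{key: _coerce(key, value)})
    return params


def apply_overrides(params: Parameters, overrides: dict[str, str]) -> Parameters:
    """Apply CLI ``key=value`` overrides on top of a profile (CLI wins)."""
    for key, value in overrides.items():
        if key not in _VALID_KEYS:
            raise ValueError(
                f"unknown parameter {key!r}; valid keys: "
                + ", ".join(sorted(_VALID_KEYS))
            )
        params = replace(
            params,
            **{key: _coerce(key, value) if isinstance(value, str) else value},
        )
    return params
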