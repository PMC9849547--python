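"""Criteria matrix for the nine recreational nature qualities.

The matrix couples each quality with a noise criterion (a named per-source cap
set), optional strict patch-size and slope thresholds, and the set of biotope
types (or the nature-reserve flag) that admit a component polygon. The default
matrix ships as an editable YAML resource; everything downstream evaluates
whatever matrix was actually loaded.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .types import (
    NOISE_SOURCES,
    BiotopeType,
    ConfigurationError,
    NoiseLevel,
    NoiseProfile,
    RNQ,
)

_NR_STATES = ("ignored", "admitted", "required")


@dataclass(frozen=True)
class NoiseThresholds:
    """Per-source strict caps (dB) for the quiet and moderate criterion levels."""

    quiet: Mapping[str, float]
    moderate: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, caps in (("quiet", self.quiet), ("moderate", self.moderate)):
            missing = [s for s in NOISE_SOURCES if s not in caps]
            if missing:
                raise ConfigurationError(f"{name} thresholds missing sources {missing}")
        for source in NOISE_SOURCES:
            if self.quiet[source] > self.moderate[source]:
                raise ConfigurationError(
                    f"quiet cap for {source!r} ({self.quiet[source]}) exceeds the "
                    f"moderate cap ({self.moderate[source]}); quiet must dominate"
                )

    def caps(self, level: NoiseLevel) -> Mapping[str, float]:
        if level is NoiseLevel.QUIET:
            return self.quiet
        if level is NoiseLevel.MODERATE:
            return self.moderate
        raise ConfigurationError(f"no caps defined for noise level {level!r}")


@dataclass(frozen=True)
class LabelCriteria:
    """Assessment criteria of one recreational nature quality."""

    noise_level: NoiseLevel
    biotopes: frozenset[BiotopeType] = frozenset()
    min_size_ha: float | None = None
    min_slope_deg: float | None = None
    nature_reserve: str = "ignored"

    def __post_init__(self) -> None:
        if self.nature_reserve not in _NR_STATES:
            raise ConfigurationError(
                f"nature_reserve must be one of {_NR_STATES}, "
                f"got {self.nature_reserve!r}"
            )
        if not self.biotopes and self.nature_reserve == "ignored":
            raise ConfigurationError(
                "label admits no biotope type and ignores the nature-reserve flag; "
                "it could never apply"
            )


@dataclass(frozen=True)
class CriteriaMatrix:
    """Full quality-assessment matrix: thresholds plus per-label criteria."""

    thresholds: NoiseThresholds
    labels: Mapping[RNQ, LabelCriteria]

    def __post_init__(self) -> None:
        missing = [label for label in RNQ if label not in self.labels]
        if missing:
            raise ConfigurationError(
                f"criteria matrix missing labels: {[m.value for m in missing]}"
            )

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CriteriaMatrix":
        try:
            thresholds = NoiseThresholds(
                quiet=dict(raw["noise_thresholds"]["quiet"]),
                moderate=dict(raw["noise_thresholds"]["moderate"]),
            )
        except KeyError as exc:
            raise ConfigurationError(f"criteria matrix missing field {exc}") from exc
        labels: dict[RNQ, LabelCriteria] = {}
        for name, spec in raw.get("labels", {}).items():
            try:
                label = RNQ(name)
            except ValueError as exc:
                raise ConfigurationError(f"unknown quality label {name!r}") from exc
            if "noise" not in spec:
                raise ConfigurationError(f"label {name!r} missing required field 'noise'")
            try:
                noise_level = NoiseLevel(spec["noise"])
            except ValueError as exc:
                raise ConfigurationError(
                    f"label {name!r} has unknown noise level {spec['noise']!r}"
                ) from exc
            try:
                biotopes = frozenset(BiotopeType(b) for b in spec.get("biotopes", []))
            except ValueError as exc:
                raise ConfigurationError(f"label {name!r}: {exc}") from exc
            labels[label] = LabelCriteria(
                noise_level=noise_level,
                biotopes=biotopes,
                min_size_ha=spec.get("min_size_ha"),
                min_slope_deg=spec.get("min_slope_deg"),
                nature_reserve=spec.get("nature_reserve", "ignored"),
            )
        return cls(thresholds=thresholds, labels=labels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CriteriaMatrix":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "CriteriaMatrix":
        text = (
            resources.files("urbanros.data")
            .joinpath("default_criteria.yaml")
            .read_text(encoding="utf-8")
        )
        return cls.from_dict(yaml.safe_load(text))


def evaluate_noise(
    profile: NoiseProfile,
    level: NoiseLevel,
    thresholds: NoiseThresholds | None = None,
) -> bool:
    """True iff `profile` satisfies the noise criterion `level`.

    NONE always passes; QUIET/MODERATE pass iff every source immission is
    strictly below its per-source cap.
    """
    if not isinstance(level, NoiseLevel):
        raise ConfigurationError(f"unknown noise level {level!r}")
    if level is NoiseLevel.NONE:
        return True
    if thresholds is None:
        thresholds = CriteriaMatrix.default().thresholds
    caps = thresholds.caps(level)
    return all(getattr(profile, source) < caps[source] for source in NOISE_SOURCES)
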