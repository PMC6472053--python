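"""Spectral assignment library for the milk lipid fraction.

Single source of truth for the 500 MHz ``1H`` assignments of the milk
lipid-fraction spectrum (chemical shift, protons per acyl chain,
first-order couplings, T1) and for the default integration windows of the
ten quantification integrals (I0.88 ... I6.28). Both tables ship as YAML
package data and can be round-tripped through YAML for user overrides.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PeakAssignment",
    "IntegrationWindow",
    "assignment_table",
    "default_windows",
    "lookup",
    "window",
    "windows_from_yaml",
    "windows_to_yaml",
    "INTEGRAL_NAMES",
]

#: The ten integral symbols used by the quantification equations.
INTEGRAL_NAMES = (
    "I0.88", "I0.95", "I2.02", "I2.33", "I2.77",
    "I2.81", "I4.99", "I5.80", "I5.99", "I6.28",
)


@dataclass(frozen=True)
class PeakAssignment:
    """A proton group of one acyl-chain species.

    Parameters
    ----------
    species_id : str
        Acyl-chain species (``butyric``, ``linoleic``, ...) or the special
        ids ``glycerol``, ``dag`` and ``reference``.
    group_label : str
        Human-readable proton-group name, e.g. ``"bis-allylic"``.
    shift_ppm : float
        Chemical shift in ppm (CDCl3, referenced at 0.172 ppm).
    protons_per_chain : int
        Equivalent protons the group contributes per chain (per glycerol
        unit for backbone groups).
    multiplicity : tuple of float
        First-order couplings in Hz; each coupling is to an equivalent CH2
        pair and splits the line 1:2:1. Empty means singlet.
    t1_s : float
        Longitudinal relaxation time in seconds.
    """

    species_id: str
    group_label: str
    shift_ppm: float
    protons_per_chain: int
    multiplicity: tuple = field(default_factory=tuple)
    t1_s: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.shift_ppm <= 7.0:
            raise ValueError(f"shift_ppm {self.shift_ppm} outside 0-7 ppm")
        if self.protons_per_chain < 1:
            raise ValueError("protons_per_chain must be >= 1")
        if self.t1_s <= 0:
            raise ValueError("t1_s must be positive")
        object.__setattr__(self, "multiplicity", tuple(self.multiplicity))


@dataclass(frozen=True)
class IntegrationWindow:
    """Half-open integration window ``[lo_ppm, hi_ppm)`` for one integral."""

    name: str
    lo_ppm: float
    hi_ppm: float

    def __post_init__(self):
        if not self.lo_ppm < self.hi_ppm:
            raise ValueError(f"window {self.name}: lo_ppm must be < hi_ppm")

    def contains(self, ppm: float) -> bool:
        return self.lo_ppm <= ppm < self.hi_ppm

    @property
    def center(self) -> float:
        return 0.5 * (self.lo_ppm + self.hi_ppm)


def _data_text(name: str) -> str:
    return (importlib.resources.files("milknmr") / "data" / name).read_text()


def assignment_table() -> list[PeakAssignment]:
    """Return the fixed assignment table shipped with the package."""
    raw = yaml.safe_load(_data_text("assignments.yaml"))
    return [PeakAssignment(**entry) for entry in raw["assignments"]]


def lookup(group_label: str) -> PeakAssignment:
    """Find an assignment by its proton-group label.

    Raises ``KeyError`` if no group of that name exists.
    """
    for a in assignment_table():
        if a.group_label == group_label:
            return a
    raise KeyError(f"no assignment with group_label {group_label!r}")


def _check_disjoint(windows: list[IntegrationWindow]) -> None:
    ordered = sorted(windows, key=lambda w: w.lo_ppm)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.lo_ppm < prev.hi_ppm:
            raise ValueError(
                f"integration windows {prev.name} and {nxt.name} overlap"
            )


def default_windows() -> list[IntegrationWindow]:
    """Return the ten default, pairwise-disjoint integration windows."""
    raw = yaml.safe_load(_data_text("windows.yaml"))
    wins = [IntegrationWindow(**entry) for entry in raw["windows"]]
    _check_disjoint(wins)
    return wins


def window(name: str, windows: list[IntegrationWindow] | None = None) -> IntegrationWindow:
    """Return the window of a given integral symbol (e.g. ``"I2.77"``)."""
    for w in windows if windows is not None else default_windows():
        if w.name == name:
            return w
    raise KeyError(f"no integration window named {name!r}")


def windows_from_yaml(path: str | Path) -> list[IntegrationWindow]:
    """Load user integration windows from YAML; overlapping windows rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    wins = [IntegrationWindow(**entry) for entry in raw["windows"]]
    names = {w.name for w in wins}
    missing = set(INTEGRAL_NAMES) - names
    if missing:
        raise ValueError(f"missing integration windows: {sorted(missing)}")
    _check_disjoint(wins)
    return wins


def windows_to_yaml(windows: list[IntegrationWindow], path: str | Path) -> None:
    """Serialize integration windows to YAML."""
    payload = {
        "windows": [
            {"name": w.name, "lo_ppm": float(w.lo_ppm), "hi_ppm": float(w.hi_ppm)}
            for w in windows
        ]
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
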