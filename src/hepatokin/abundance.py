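"""Physiological-state scaling of maximal enzyme activities.

Maximal enzyme activity is a linear function of enzyme abundance, so the
Vmax of an enzyme in any physiological state is obtained by scaling the
fed-state (reference) Vmax with the measured abundance ratio
alpha_state = <E>_state / <E>_fed.  The table below holds the reported
mean ratios and, where available, the reported min-max ranges for the
normal, fasted, and diabetic rat liver.  Enzymes absent from the table
keep alpha = 1 in every state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

STATES = ("fed", "normal", "fasted", "diabetic")


@dataclass(frozen=True)
class AbundanceEntry:
    """Relative abundance of one enzyme: mean ratio and optional range."""

    mean: float
    range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("abundance ratio must be > 0")
        if self.range is not None:
            lo, hi = self.range
            if not (0 < lo <= hi):
                raise ValueError("invalid abundance range")
            if not (lo <= self.mean <= hi):
                raise ValueError(
                    f"mean {self.mean} outside reported range [{lo}, {hi}]"
                )


# Relative maximal enzyme activities with respect to the fed reference
# state.  Mean ratios and reported ranges for the normal, fasted, and
# diabetic rat liver; the fed state is the reference (alpha = 1).
_TABLE: dict[str, dict[str, AbundanceEntry]] = {
    "FBP1": {
        "normal": AbundanceEntry(1.00),
        "fasted": AbundanceEntry(1.00),
        "diabetic": AbundanceEntry(4.00),
    },
    "FBP2": {
        "normal": AbundanceEntry(0.66),
        "fasted": AbundanceEntry(0.43, (0.40, 0.475)),
        "diabetic": AbundanceEntry(0.26, (0.20, 0.40)),
    },
    "GK": {
        "normal": AbundanceEntry(0.48),
        "fasted": AbundanceEntry(0.23, (0.12, 0.46)),
        "diabetic": AbundanceEntry(0.24, (0.19, 0.33)),
    },
    "GlcT": {
        "normal": AbundanceEntry(1.00),
        "fasted": AbundanceEntry(1.00),
        "diabetic": AbundanceEntry(1.35, (1.00, 2.00)),
    },
    "GP": {
        "normal": AbundanceEntry(0.89),
        "fasted": AbundanceEntry(0.80, (0.65, 1.00)),
        "diabetic": AbundanceEntry(0.45, (0.40, 0.63)),
    },
    "G6P": {
        "normal": AbundanceEntry(1.41),
        "fasted": AbundanceEntry(2.00),
        "diabetic": AbundanceEntry(3.54, (1.48, 7.07)),
    },
    "GS": {
        "normal": AbundanceEntry(1.00),
        "fasted": AbundanceEntry(1.00),
        "diabetic": AbundanceEntry(1.70, (1.24, 2.25)),
    },
    "PC": {
        "normal": AbundanceEntry(1.25),
        "fasted": AbundanceEntry(1.56),
        "diabetic": AbundanceEntry(3.75, (2.50, 5.00)),
    },
    "PEPCK": {
        "normal": AbundanceEntry(1.41),
        "fasted": AbundanceEntry(2.00),
        "diabetic": AbundanceEntry(4.24, (2.83, 5.66)),
    },
    "PFK1": {
        "normal": AbundanceEntry(0.76),
        "fasted": AbundanceEntry(0.57, (0.30, 0.85)),
        "diabetic": AbundanceEntry(0.30, (0.23, 0.41)),
    },
    "PFK2": {
        "normal": AbundanceEntry(0.66),
        "fasted": AbundanceEntry(0.43, (0.40, 0.475)),
        "diabetic": AbundanceEntry(0.26, (0.20, 0.40)),
    },
    "PK": {
        "normal": AbundanceEntry(0.58),
        "fasted": AbundanceEntry(0.33, (0.25, 0.50)),
        "diabetic": AbundanceEntry(0.29, (0.17, 0.52)),
    },
}

# The mitochondrial PEPCK isoform follows the cytosolic abundance data.
_ALIASES = {"PEPCK_mito": "PEPCK"}


@dataclass
class AbundanceTable:
    """Per-enzyme abundance scaling factors for the physiological states.

    ``entries[enzyme][state]`` gives an :class:`AbundanceEntry`; the fed
    state is implicit with alpha = 1 for every enzyme.
    """

    entries: dict[str, dict[str, AbundanceEntry]] = field(
        default_factory=lambda: dict(_TABLE)
    )
    aliases: dict[str, str] = field(default_factory=lambda: dict(_ALIASES))

    def _resolve(self, enzyme: str) -> str:
        return self.aliases.get(enzyme, enzyme)

    def has_entry(self, enzyme: str) -> bool:
        return self._resolve(enzyme) in self.entries

    def alpha(self, enzyme: str, state: str) -> float:
        """Mean abundance ratio alpha_state for one enzyme.

        Unknown states raise; enzymes without a table entry scale with
        alpha = 1 (logged once per call site at DEBUG level).
        """
        if state not in STATES:
            raise ValueError(f"unknown physiological state {state!r}; "
                             f"expected one of {STATES}")
        if state == "fed":
            return 1.0
        enzyme = self._resolve(enzyme)
        if enzyme not in self.entries:
            logger.debug("enzyme %s has no abundance entry; alpha = 1", enzyme)
            return 1.0
        return self.entries[enzyme][state].mean

    def range(self, enzyme: str, state: str) -> tuple[float, float] | None:
        """Reported [min, max] of the abundance ratio, or None."""
        if state not in STATES:
            raise ValueError(f"unknown physiological state {state!r}")
        if state == "fed":
            return None
        enzyme = self._resolve(enzyme)
        entry = self.entries.get(enzyme, {}).get(state)
        return None if entry is None else entry.range

    def alphas(self, state: str, enzymes) -> dict[str, float]:
        """Mean alpha for every enzyme id in ``enzymes``."""
        return {e: self.alpha(e, state) for e in enzymes}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for enzyme, per_state in self.entries.items():
            row = {"enzyme": enzyme}
            for state, entry in per_state.items():
                row[f"{state}_mean"] = entry.mean
                if entry.range is not None:
                    row[f"{state}_min"], row[f"{state}_max"] = entry.range
            rows.append(row)
        return pd.DataFrame(rows).set_index("enzyme")


DEFAULT_ABUNDANCE = AbundanceTable()


def scale_vmax(vmax_fed: float, enzyme: str, state: str,
               table: AbundanceTable = DEFAULT_ABUNDANCE,
               alpha: float | None = None) -> float:
    """Scale a fed-reference Vmax to another physiological state.

    ``alpha`` allows a caller-supplied sample (e.g. drawn from the
    reported range); otherwise the table mean is used.
    """
    if alpha is None:
        alpha = table.alpha(enzyme, state)
    return alpha * vmax_fed
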