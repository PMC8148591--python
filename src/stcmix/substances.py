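"""Reference single-substance parameters for the six neuroactive test compounds.

These are the published spontaneous-tail-coiling potency parameters for the
six substances the mixture designs are built from.  Each substance carries
two EC50s: the primary fit and the independent-experiment ("modeling") value
actually used as input to mixture prediction; carbamazepine has a single
value serving both roles.  Slopes are the published curve slopes; curves are
on the standardized scale (floor 0, ceiling 100).
"""

from __future__ import annotations

from dataclasses import dataclass

from .dose_response import Direction, LogisticCRC

__all__ = ["SubstanceInfo", "reference_substances"]


@dataclass(frozen=True)
class SubstanceInfo:
    name: str
    ec50_um: float  # primary fit
    ec50_modeling_um: float  # independent-experiment value, used for mixtures
    slope: float
    direction: Direction

    def crc(self, which: str = "modeling") -> LogisticCRC:
        """Standardized LL.4 curve (floor 0, ceiling 100) for this substance."""
        ec50 = self.ec50_modeling_um if which == "modeling" else self.ec50_um
        return LogisticCRC(
            slope_b=self.slope,
            inflection_e=ec50,
            floor_c=0.0,
            ceiling_d=100.0,
            direction=self.direction,
        )


_REFERENCE = (
    SubstanceInfo("chlorpyrifos", 1.85, 1.95, 1.30, Direction.HYPERACTIVITY),
    SubstanceInfo("chlorpyrifos-oxon", 0.32, 0.44, 1.00, Direction.HYPERACTIVITY),
    SubstanceInfo("hexaconazole", 4.03, 3.63, 1.80, Direction.HYPERACTIVITY),
    SubstanceInfo("abamectin", 0.06, 0.09, 1.70, Direction.HYPOACTIVITY),
    SubstanceInfo("carbamazepine", 271.0, 271.0, 2.28, Direction.HYPOACTIVITY),
    SubstanceInfo("propafenone", 32.0, 46.0, 1.94, Direction.HYPOACTIVITY),
)


def reference_substances() -> dict[str, SubstanceInfo]:
    """The six reference substances keyed by name.

    Raises ``KeyError`` on unknown names when the returned mapping is
    indexed, as a plain dict does.
    """
    return {s.name: s for s in _REFERENCE}
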