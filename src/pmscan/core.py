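"""Shared containers for multi-channel fluorescence fields.

Conventions used throughout the package:

* images are 2D float arrays indexed ``(row, col)``, 0-based, with pixel
  centers at integer coordinates;
* intensities are arbitrary units (AU) and must be non-negative after
  background handling;
* channels are identified by *role*, not by fluorophore: ``membrane``
  (a reporter that labels the plasma membrane and renders as a bright
  ring in an equatorial confocal section), ``reporter`` (the translocating
  protein whose PM/cytoplasm partitioning is being measured), ``nuclear``
  (a chromatin marker), and optionally ``reporter2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: channel roles understood by the pipeline
ROLE_MEMBRANE = "membrane"
ROLE_REPORTER = "reporter"
ROLE_NUCLEAR = "nuclear"
ROLE_REPORTER2 = "reporter2"

KNOWN_ROLES = (ROLE_MEMBRANE, ROLE_REPORTER, ROLE_NUCLEAR, ROLE_REPORTER2)


class ChannelMissingError(KeyError):
    """A required channel role is absent from the field."""


@dataclass
class FieldImage:
    """Aligned multi-channel intensity grids for one microscope field.

    Parameters
    ----------
    channels
        Mapping channel-role -> 2D float array (AU).  All arrays must share
        one shape and contain no negative values.
    metadata
        Acquisition metadata (time point, well, field id, ...).  Free-form;
        the pipeline propagates it into output tables.
    """

    channels: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        for role, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {role!r} is not 2D")
            if np.any(arr < 0):
                raise ValueError(f"channel {role!r} contains negative intensities")
            self.channels[role] = arr

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def channel(self, role: str) -> np.ndarray:
        """Return one channel, raising a named error when absent."""
        try:
            return self.channels[role]
        except KeyError:
            raise ChannelMissingError(
                f"field has no {role!r} channel (present: {sorted(self.channels)})"
            ) from None

    def with_channels(self, channels: Mapping[str, np.ndarray]) -> "FieldImage":
        """Copy of this field with some channels replaced."""
        merged = dict(self.channels)
        merged.update({k: np.asarray(v, dtype=float) for k, v in channels.items()})
        return FieldImage(channels=merged, metadata=dict(self.metadata))
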