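"""Geometry of the micro-well array and the central culture channel.

The device holds an array of square micro-wells at the bottom of a wide,
shallow culture channel.  Columns run along the channel axis (x); rows run
across it (y).  Row 1 sits next to the drug-side connecting channels, the
last row next to the medium side, so the concentration gradient develops
across rows while every well in a row sees (nearly) the same dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DeviceLayout", "generate_layout"]


@dataclass(frozen=True)
class DeviceLayout:
    """Well-array geometry and the coordinate frame used downstream.

    All lengths in micrometres.  ``side_margin_um`` is the gap between the
    outermost well rows and the channel walls where the connecting-channel
    arrays join; ``end_margin_um`` is the gap between the outermost columns
    and the channel ends leading to the central reservoirs.
    """

    n_rows: int = 8
    n_cols: int = 30
    well_size_um: float = 150.0
    well_depth_um: float = 180.0
    well_pitch_um: float = 200.0
    side_margin_um: float = 150.0
    end_margin_um: float = 500.0
    channel_depth_um: float = 35.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("layout needs at least one row and one column")
        if self.well_size_um <= 0 or self.well_pitch_um <= 0:
            raise ValueError("well size and pitch must be positive")
        if self.well_size_um > self.well_pitch_um:
            raise ValueError("wells cannot be larger than the array pitch")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def channel_length_um(self) -> float:
        """Extent of the culture channel along the channel axis (x)."""
        return self.n_cols * self.well_pitch_um + 2 * self.end_margin_um

    @property
    def channel_width_um(self) -> float:
        """Extent across the channel (y), spanned by the gradient."""
        return self.n_rows * self.well_pitch_um + 2 * self.side_margin_um

    def well_center_um(self, row: int, col: int) -> tuple[float, float]:
        """Centre (x, y) of well ``(row, col)``; both indices are 1-based.

        Row 1 is the drug-source side (y = 0 wall), column 1 one channel end.
        """
        if not (1 <= row <= self.n_rows and 1 <= col <= self.n_cols):
            raise IndexError(f"well ({row}, {col}) outside layout")
        x = self.end_margin_um + (col - 0.5) * self.well_pitch_um
        y = self.side_margin_um + (row - 0.5) * self.well_pitch_um
        return x, y

    def well_centers_um(self) -> np.ndarray:
        """(n_rows, n_cols, 2) array of well-centre (x, y) positions."""
        cols = self.end_margin_um + (np.arange(self.n_cols) + 0.5) * self.well_pitch_um
        rows = self.side_margin_um + (np.arange(self.n_rows) + 0.5) * self.well_pitch_um
        out = np.empty((self.n_rows, self.n_cols, 2))
        out[..., 0] = cols[None, :]
        out[..., 1] = rows[:, None]
        return out


def generate_layout(
    n_rows: int = 8,
    n_cols: int = 30,
    well_size_um: float = 150.0,
    **kwargs,
) -> DeviceLayout:
    """Build a regular well-array layout.

    Defaults give the standard 8 x 30 array of 150 um wells (240 wells);
    the 5-row variant of 250 um wells is ``generate_layout(n_rows=5,
    well_size_um=250)``.  When only the well size is given, the pitch is
    widened to keep the default 50 um walls between wells.
    """
    if "well_pitch_um" not in kwargs:
        default = DeviceLayout.__dataclass_fields__["well_pitch_um"].default
        kwargs["well_pitch_um"] = max(default, well_size_um + 50.0)
    return DeviceLayout(n_rows=n_rows, n_cols=n_cols, well_size_um=well_size_um, **kwargs)
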