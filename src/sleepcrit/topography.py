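"""2-D head-schematic coordinates for 10-20 electrode labels.

Numeric backing for topographic result maps: Cz sits at the vertex
(0, 0), the nose points toward +y, and homologous left/right pairs have
mirrored x-coordinates on the unit head circle.  Rendering is out of
scope; downstream tools consume the (x, y) table directly.
"""

from __future__ import annotations

import math

import pandas as pd

# (angle from +y axis in degrees, clockwise positive / radius in head units)
_POLAR = {
    "Cz": (0, 0.0),
    "Fz": (0, 0.5), "Pz": (180, 0.5), "Fpz": (0, 1.0), "Oz": (180, 1.0),
    "Fp1": (-18, 1.0), "Fp2": (18, 1.0),
    "F7": (-54, 1.0), "F8": (54, 1.0),
    "F3": (-39, 0.59), "F4": (39, 0.59),
    "T3": (-90, 1.0), "T4": (90, 1.0),
    "T7": (-90, 1.0), "T8": (90, 1.0),
    "C3": (-90, 0.5), "C4": (90, 0.5),
    "T5": (-126, 1.0), "T6": (126, 1.0),
    "P7": (-126, 1.0), "P8": (126, 1.0),
    "P3": (-141, 0.59), "P4": (141, 0.59),
    "O1": (-162, 1.0), "O2": (162, 1.0),
}


def channel_coordinates(label: str) -> tuple[float, float] | None:
    """(x, y) schematic coordinates of a 10-20 label, or None if unknown."""
    if label not in _POLAR:
        return None
    theta, r = _POLAR[label]
    rad = math.radians(theta)
    return (round(r * math.sin(rad), 6), round(r * math.cos(rad), 6))


def report_topography_values(per_channel: pd.DataFrame,
                             channel_column: str = "channel") -> pd.DataFrame:
    """Attach schematic coordinates to a per-channel result table.

    Unknown labels get NaN coordinates and ``unknown_label=True`` so they
    can be reported without aborting the pipeline.
    """
    out = per_channel.copy()
    xs, ys, flags = [], [], []
    for label in out[channel_column]:
        coord = channel_coordinates(str(label))
        if coord is None:
            xs.append(float("nan"))
            ys.append(float("nan"))
            flags.append(True)
        else:
            xs.append(coord[0])
            ys.append(coord[1])
            flags.append(False)
    out["x"] = xs
    out["y"] = ys
    out["unknown_label"] = flags
    return out
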