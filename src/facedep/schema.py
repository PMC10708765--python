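"""Canonical OpenFace 2.x feature-column schema and feature-group layout.

The full per-frame table carries 49 feature columns:

* head pose rotation  (3):  pitch / yaw / roll in radians
* head pose location  (3):  x / y / z in millimetres
* gaze vectors        (6):  per-eye unit-vector components
* gaze angles         (2):  horizontal / vertical radians
* AU intensity       (17):  0-5 scale
* AU presence        (18):  0/1 (the 17 intensity AUs plus AU28)

Feature selection keeps 40 columns: rotation + gaze angles + both AU groups.
"""

from __future__ import annotations

# OpenFace 2.x column names are the canonical internal names.
POSE_ROTATION = ["pose_Rx", "pose_Ry", "pose_Rz"]  # pitch, yaw, roll
POSE_LOCATION = ["pose_Tx", "pose_Ty", "pose_Tz"]
GAZE_VECTOR = [
    "gaze_0_x", "gaze_0_y", "gaze_0_z",
    "gaze_1_x", "gaze_1_y", "gaze_1_z",
]
GAZE_ANGLE = ["gaze_angle_x", "gaze_angle_y"]

# OpenFace's 17 intensity-estimated AUs; presence adds AU28 (lip suck).
AU_INTENSITY_IDS = [
    "01", "02", "04", "05", "06", "07", "09", "10", "12",
    "14", "15", "17", "20", "23", "25", "26", "45",
]
AU_PRESENCE_IDS = [
    "01", "02", "04", "05", "06", "07", "09", "10", "12",
    "14", "15", "17", "20", "23", "25", "26", "28", "45",
]
AU_INTENSITY = [f"AU{i}_r" for i in AU_INTENSITY_IDS]
AU_PRESENCE = [f"AU{i}_c" for i in AU_PRESENCE_IDS]

#: the 49 canonical feature columns, in canonical order
ALL_FEATURES = (
    POSE_ROTATION + POSE_LOCATION + GAZE_VECTOR + GAZE_ANGLE
    + AU_INTENSITY + AU_PRESENCE
)

#: the 40 columns retained by feature selection, in canonical group order
SELECTED_FEATURES = POSE_ROTATION + GAZE_ANGLE + AU_INTENSITY + AU_PRESENCE

#: feature-group partition of the 40 selected columns
GROUP_SLICES = {
    "Pose": slice(0, 3),
    "Gaze": slice(3, 5),
    "AU_r": slice(5, 22),
    "AU_c": slice(22, 40),
}
GROUP_NAMES = list(GROUP_SLICES)

FRAME_COLUMN = "frame"
TIMESTAMP_COLUMN = "timestamp"

# Header dialects seen in the wild: raw OpenFace output pads headers with a
# space; some re-exports lowercase everything.  Keys are lowercased stripped
# header cells, values are canonical names.
_ALIASES = {name.lower(): name for name in ALL_FEATURES}
_ALIASES[FRAME_COLUMN] = FRAME_COLUMN
_ALIASES[TIMESTAMP_COLUMN] = TIMESTAMP_COLUMN


def canonical_name(header_cell: str) -> str | None:
    """Map a raw CSV header cell to its canonical column name, or ``None``."""
    return _ALIASES.get(header_cell.strip().lower())


def group_of(feature: str) -> str:
    """Feature-group name ('Pose'/'Gaze'/'AU_r'/'AU_c') of a selected column."""
    idx = SELECTED_FEATURES.index(feature)
    for name, sl in GROUP_SLICES.items():
        if sl.start <= idx < sl.stop:
            return name
    raise ValueError(feature)  # pragma: no cover


def group_widths() -> dict[str, int]:
    return {name: sl.stop - sl.start for name, sl in GROUP_SLICES.items()}
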