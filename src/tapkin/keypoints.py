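"""Canonical hand-marker layout for the four-finger tapping task.

Seventeen keypoints are tracked on the right hand: 14 on the four tapping
fingers (index and middle carry four joints each — tip, DIP, PIP, MCP; ring
and little carry three — tip, PIP, MCP) plus three anchor points on the
static thumb. Coherence and amplitude analyses use the four fingertips;
pattern decoding uses all 14 tapping-finger points (91 unordered pairs).
"""

from __future__ import annotations

FINGERS: tuple[str, ...] = ("index", "middle", "ring", "little")

CONDITIONS: tuple[str, ...] = (
    "reference",
    "sequence_focused",
    "index_focused",
    "middle_focused",
)

DURATION_CLASSES: tuple[str, ...] = ("short", "long")

#: joints per tapping finger, proximal joints omitted on the ulnar fingers
FINGER_JOINTS: dict[str, tuple[str, ...]] = {
    "index": ("tip", "dip", "pip", "mcp"),
    "middle": ("tip", "dip", "pip", "mcp"),
    "ring": ("tip", "pip", "mcp"),
    "little": ("tip", "pip", "mcp"),
}

THUMB_KEYPOINTS: tuple[str, ...] = ("thumb_tip", "thumb_ip", "thumb_mcp")

TAPPING_KEYPOINTS: tuple[str, ...] = tuple(
    f"{finger}_{joint}" for finger in FINGERS for joint in FINGER_JOINTS[finger]
)

FINGERTIPS: tuple[str, ...] = tuple(f"{finger}_tip" for finger in FINGERS)

#: the full ordered 17-label layout
KEYPOINT_NAMES: tuple[str, ...] = TAPPING_KEYPOINTS + THUMB_KEYPOINTS

assert len(TAPPING_KEYPOINTS) == 14
assert len(KEYPOINT_NAMES) == 17


def finger_of(keypoint: str) -> str:
    """Return the finger a tapping keypoint belongs to."""
    finger = keypoint.split("_", 1)[0]
    if finger not in FINGERS:
        raise ValueError(f"{keypoint!r} is not a tapping-finger keypoint")
    return finger
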