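"""Feature-vector layout: named domain groups over the 424 dimensions.

The patch representation concatenates MPEG-7-style color and texture
descriptors, a gradient-based structure descriptor, and a Gabor filter
bank.  The per-group dimension budget is fixed here; the group map is the
authoritative index layout (0-based, half-open spans) and is exported next
to persisted feature matrices.
"""

from __future__ import annotations

import json

#: (group name, dimension) in concatenation order.
GROUP_SIZES: tuple[tuple[str, int], ...] = (
    ("scalable_color", 64),
    ("color_structure", 64),
    ("color_layout", 18),
    ("dominant_color", 25),
    ("edge_histogram", 80),
    ("structure", 158),
    ("gabor", 15),
)

FEATURE_DIM = sum(d for _, d in GROUP_SIZES)  # 424


def group_map() -> dict[str, tuple[int, int]]:
    """Group name -> ``[start, end)`` span into the 424-vector."""
    spans: dict[str, tuple[int, int]] = {}
    start = 0
    for name, dim in GROUP_SIZES:
        spans[name] = (start, start + dim)
        start += dim
    return spans


def group_slice(name: str) -> slice:
    start, end = group_map()[name]
    return slice(start, end)


def save_group_map(path) -> None:
    """Write the group map as sidecar JSON (spans as [start, end) lists)."""
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in group_map().items()}, fh, indent=2)


def feature_index_array():
    """Per-dimension group name, useful for per-group normalization."""
    import numpy as np

    names = []
    for name, dim in GROUP_SIZES:
        names.extend([name] * dim)
    return np.array(names)
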