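"""Shared labels and layout conventions for the six-node attention network.

The network comprises the bilateral intraparietal sulcus (IPS) and frontal
eye fields (FEF) of the dorsal attention network and the bilateral
temporoparietal junction (TPJ) of the ventral network.  Node order is frozen
so that connectivity matrices, time-series files and beta tables remain
mutually consistent.
"""

from __future__ import annotations

#: Canonical node order for all 6x6 connectivity matrices and TSV headers.
NODES = ("IPS_L", "IPS_R", "FEF_L", "FEF_R", "TPJ_L", "TPJ_R")

NODE_INDEX = {name: i for i, name in enumerate(NODES)}

#: Condition regressor order (invalid/valid x left/right/down/up).
CONDITIONS = ("iL", "iR", "vL", "vR", "iD", "iU", "vD", "vU")

#: Run labels.
HORIZONTAL = "horizontal"
VERTICAL = "vertical"
RUNS = (HORIZONTAL, VERTICAL)

#: Target positions per run.
POSITIONS = {HORIZONTAL: ("L", "R"), VERTICAL: ("D", "U")}

#: Driving-input streams: u1 = invalid-horizontal targets, u2 = valid-horizontal,
#: u3 = invalid-vertical, u4 = valid-vertical.
INPUT_STREAMS = (
    ("invalid", HORIZONTAL),
    ("valid", HORIZONTAL),
    ("invalid", VERTICAL),
    ("valid", VERTICAL),
)

N_INPUTS = len(INPUT_STREAMS)

#: Microtime resolution: integration bins per TR (shared by the generator and
#: the inversion scheme).
BINS_PER_TR = 36


def stream_index(cueing: str, run: str) -> int:
    """Map a (cueing, run) pair to its driving-input stream index (0-based)."""
    return INPUT_STREAMS.index((cueing, run))
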