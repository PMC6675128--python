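"""Display exports: coverage tracks and read down-sampling.

Down-sampling exists only so that read-pile displays (IGV-style plots,
logos) stay legible; quantification never uses down-sampled sets.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from .align import AlignmentRecord
from .modification import _walk_core_columns
from .reference import PaddedReference


def downsample_for_display(
    records: Sequence[AlignmentRecord],
    per_window: int = 100,
    window_nt: int = 50,
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Keep at most ``per_window`` records per (ref, 5'-start window).

    Selection is uniform at random under the run seed, so repeated runs
    retain the identical subset.
    """
    if per_window <= 0 or window_nt <= 0:
        raise ValueError("per_window and window_nt must be positive")
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, int], list[int]] = defaultdict(list)
    for i, r in enumerate(records):
        groups[(r.ref_id, r.core_start // window_nt)].append(i)
    keep: list[int] = []
    for key in sorted(groups):
        idx = groups[key]
        if len(idx) <= per_window:
            keep.extend(idx)
        else:
            keep.extend(sorted(rng.choice(idx, size=per_window, replace=False)))
    return [records[i] for i in sorted(keep)]


def export_coverage(
    records: Sequence[AlignmentRecord], ref: PaddedReference, ref_id: str
) -> pd.DataFrame:
    """Primary-weighted pileup depth per core position (M and D columns),
    identical to the depth seen by the misincorporation pileup."""
    depth = np.zeros(len(ref.core(ref_id)))
    for r in records:
        if r.ref_id != ref_id:
            continue
        for ci, _ in _walk_core_columns(r):
            depth[ci] += r.weight
    return pd.DataFrame({"core_index": np.arange(len(depth)), "depth": depth})
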