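"""Fusion of per-modality subnetwork risk scores.

Subnetwork weights are estimated independently per molecular modality
(e.g., mRNA abundance and copy-number aberration), each yielding its own
patients × subnetworks risk matrix; the element-wise sum is the multi-modal
pathway activation estimate per patient. No rescaling is applied before
summation by default — risk scores are already on the common signed
log2-hazard-ratio-weighted scale — but an optional per-modality z-scaling
is available for heterogeneous platforms.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["fuse"]


def fuse(modalities: dict[str, pd.DataFrame], scale: bool = False
         ) -> pd.DataFrame:
    """Element-wise sum of aligned per-modality risk matrices.

    All matrices must carry identical sample rows and subnetwork columns;
    mismatches are reported explicitly. With ``scale=True`` each modality's
    columns are z-scaled before summation.
    """
    if len(modalities) < 2:
        raise ValueError("fusion needs at least two modalities")
    items = list(modalities.items())
    ref_label, ref = items[0]
    for label, m in items[1:]:
        sample_diff = set(ref.index) ^ set(m.index)
        if sample_diff:
            raise ValueError(
                f"sample mismatch between {ref_label!r} and {label!r}: "
                f"{sorted(sample_diff)[:5]}")
        col_diff = set(ref.columns) ^ set(m.columns)
        if col_diff:
            raise ValueError(
                f"subnetwork mismatch between {ref_label!r} and {label!r}: "
                f"{sorted(col_diff)[:5]}")
    total = None
    for _, m in items:
        block = m.loc[ref.index, ref.columns]
        if scale:
            sd = block.std(axis=0, ddof=1).replace(0.0, 1.0)
            block = (block - block.mean(axis=0)) / sd
        total = block if total is None else total + block
    return total
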