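"""Expression preprocessing: zero replacement, log2 transform, hygiene filters.

RPKM matrices contain exact zeros that break the log2 transform, so zeros are
replaced with the minimum nonzero value before taking logs.  The replacement
is per transcript by default (a global minimum would compress the dynamic
range of low-abundance transcripts); a ``global`` policy is available as a
switch.  All-zero and constant transcripts are dropped, since they admit no
replacement value, no regression fit and no median split.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

ZERO_POLICIES = ("per_transcript", "global")


def replace_zeros(m: ExpressionMatrix, zero_policy: str = "per_transcript") -> ExpressionMatrix:
    """Replace zero entries with the minimum nonzero value.

    ``per_transcript`` uses each transcript's own minimum nonzero value;
    ``global`` uses the matrix-wide minimum nonzero.  Transcripts with no
    nonzero value at all are dropped (and logged): no replacement exists.
    Nonzero entries are never modified; applying the operation twice equals
    applying it once.
    """
    if m.values.empty:
        raise ValueError("empty expression matrix")
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"zero_policy must be one of {ZERO_POLICIES}")
    values = m.values.to_numpy(dtype=float, copy=True)
    if (values < 0).any():
        raise ValueError("negative expression values")

    nonzero_any = (values > 0).any(axis=1)
    n_dropped = int((~nonzero_any).sum())
    if n_dropped:
        dropped = m.transcript_ids[~nonzero_any].tolist()
        logger.warning("dropping %d all-zero transcripts: %s%s", n_dropped,
                       dropped[:10], "..." if n_dropped > 10 else "")
    values = values[nonzero_any]
    index = m.transcript_ids[nonzero_any]
    if values.size == 0:
        raise ValueError("all transcripts are all-zero")

    if zero_policy == "per_transcript":
        masked = np.where(values > 0, values, np.inf)
        fill = masked.min(axis=1)[:, None]
    else:
        fill = values[values > 0].min()
    values = np.where(values == 0, fill, values)
    return ExpressionMatrix(
        pd.DataFrame(values, index=index, columns=m.sample_ids),
        m.biotypes.loc[index],
    )


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2 every entry; requires strictly positive values."""
    values = m.values.to_numpy(dtype=float)
    if m.values.empty:
        raise ValueError("empty expression matrix")
    if (values <= 0).any():
        raise ValueError("non-positive values present: run replace_zeros first")
    return ExpressionMatrix(
        pd.DataFrame(np.log2(values), index=m.transcript_ids, columns=m.sample_ids),
        m.biotypes.copy(),
    )


def drop_constant(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove zero-variance transcripts (they break regression and median splits)."""
    values = m.values.to_numpy(dtype=float)
    keep = values.std(axis=1) > 0 if values.size else np.zeros(0, dtype=bool)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d constant transcripts", n_dropped)
    if keep.size and not keep.any():
        logger.warning("all transcripts are constant; returning empty matrix")
    index = m.transcript_ids[keep]
    return ExpressionMatrix(m.values.loc[index], m.biotypes.loc[index])


def preprocess(m: ExpressionMatrix, zero_policy: str = "per_transcript") -> ExpressionMatrix:
    """The full hygiene chain: replace zeros, log2, drop constants."""
    return drop_constant(log2_transform(replace_zeros(m, zero_policy)))
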