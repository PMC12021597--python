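"""Alpha-diversity statistics: richness, Shannon entropy, Pielou's evenness.

Shannon uses the natural logarithm, so values are in nats and Pielou's
evenness is H / ln(richness), bounded in [0, 1].  No rarefaction is applied;
the statistics operate directly on whatever (typically TPM-normalized)
feature table they are given.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["shannon", "richness", "pielou", "alpha_series"]


def shannon(vector) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats); zeros contribute 0."""
    x = np.asarray(vector, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("zero-sum abundance vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(vector) -> int:
    """Number of features with strictly positive abundance."""
    return int((np.asarray(vector, dtype=float) > 0).sum())


def pielou(vector) -> float:
    """Pielou's evenness J = H / ln(S); NaN when richness < 2 (undefined)."""
    s = richness(vector)
    if s < 2:
        return float("nan")
    return shannon(vector) / np.log(s)


def alpha_series(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample alpha-diversity records for a features-by-samples table.

    Returns a DataFrame indexed by sample id with columns richness, shannon
    and pielou (NaN where evenness is undefined).
    """
    if matrix.shape[1] == 0:
        raise ValueError("empty abundance matrix")
    records = []
    for sample in matrix.columns:
        v = matrix[sample].to_numpy(dtype=float)
        records.append(
            {
                "sample_id": sample,
                "richness": richness(v),
                "shannon": shannon(v),
                "pielou": pielou(v),
            }
        )
    return pd.DataFrame(records).set_index("sample_id")
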