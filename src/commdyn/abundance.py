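"""Normalization and filtering of coverage/abundance tables.

All tables are pandas DataFrames with features as rows and samples as
columns.  The normalization here is the TPM-like convention used for
metagenomic coverage: per-feature counts divided by feature length, then
rescaled so every sample column sums to one million — length- and
depth-normalized at once.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import VALID_DOMAINS

logger = logging.getLogger(__name__)

#: Mean SSU rRNA gene lengths (bp) used for gene-equivalent normalization.
RRNA_GENE_LENGTHS = {"16S": 1408.0, "18S": 1705.0}

#: Default short-read length (bp) when converting read counts to aligned bp.
DEFAULT_READ_LENGTH = 150.0

TPM_SCALE = 1e6


def tpm_normalize(counts: pd.DataFrame, feature_lengths) -> pd.DataFrame:
    """Length- and library-size-normalize a coverage table (TPM-like).

    rate_i = count_i / length_i per sample; values are rates rescaled so each
    sample column sums to 1e6.  The result is invariant to uniform rescaling
    of all lengths and to uniform rescaling of any one sample's counts.

    Parameters
    ----------
    counts : DataFrame, features x samples
        Non-negative counts or coverage values.
    feature_lengths : Series or array
        Strictly positive feature lengths in bp, aligned to ``counts.index``.

    Raises
    ------
    ValueError
        If any sample column is all zero (named in the message) or any
        length is non-positive.
    """
    lengths = _as_lengths(feature_lengths, counts.index)
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    rates = values / lengths[:, None]
    colsums = rates.sum(axis=0)
    zero = colsums <= 0
    if zero.any():
        bad = list(counts.columns[zero])
        raise ValueError(f"all-zero sample column(s): {bad}")
    return pd.DataFrame(
        rates / colsums * TPM_SCALE, index=counts.index, columns=counts.columns
    )


def _as_lengths(feature_lengths, index) -> np.ndarray:
    if isinstance(feature_lengths, pd.Series):
        lengths = feature_lengths.reindex(index).to_numpy(dtype=float)
        if np.isnan(lengths).any():
            missing = [i for i in index if i not in feature_lengths.index]
            raise ValueError(f"missing lengths for features: {missing[:5]}")
    else:
        lengths = np.broadcast_to(
            np.asarray(feature_lengths, dtype=float), (len(index),)
        ).copy()
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be strictly positive")
    return lengths


def filter_multimapped(records: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Resolve multi-mapping reads by their equal-top-score domain pattern.

    A read is assigned to a domain iff *all* of its maximum-score alignments
    fall in that single domain; reads whose top score is shared across two or
    more domains are unclassified (the cross-domain "equally mapped" reads).
    Score ties *within* one domain do not unclassify a read.

    Parameters
    ----------
    records : DataFrame with columns read_id, target_id, domain, alignment_score
        The minimal alignment digest; domain must be one of eukaryote /
        prokaryote / virus.

    Returns
    -------
    assigned : Series
        read_id -> domain for every classifiable read.
    unclassified : list of str
        Read ids whose equal-top alignments span more than one domain.
    """
    required = ["read_id", "target_id", "domain", "alignment_score"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"alignment digest missing column(s): {missing}")
    bad_domain = ~records["domain"].isin(VALID_DOMAINS)
    if bad_domain.any():
        line = int(np.argmax(bad_domain.to_numpy())) + 1
        raise ValueError(
            f"malformed alignment record at line {line}: "
            f"unknown domain {records['domain'].iloc[line - 1]!r}"
        )
    scores = pd.to_numeric(records["alignment_score"], errors="coerce")
    if scores.isna().any():
        line = int(np.argmax(scores.isna().to_numpy())) + 1
        raise ValueError(f"malformed alignment record at line {line}: non-numeric score")

    assigned: dict[str, str] = {}
    unclassified: list[str] = []
    frame = records.assign(alignment_score=scores)
    for read_id, group in frame.groupby("read_id", sort=False):
        top = group["alignment_score"].max()
        domains = set(group.loc[group["alignment_score"] == top, "domain"])
        if len(domains) == 1:
            assigned[read_id] = domains.pop()
        else:
            unclassified.append(read_id)
    return pd.Series(assigned, name="domain", dtype=object), unclassified


def rrna_normalize(
    value: float,
    marker: str,
    unit: str = "bp",
    read_length: float = DEFAULT_READ_LENGTH,
) -> float:
    """Convert aligned rRNA signal to SSU gene-equivalents.

    Divides aligned base pairs by the mean SSU gene length: 1408 bp for 16S,
    1705 bp for 18S.  With ``unit='reads'`` the input is a read count first
    converted to bp via ``read_length`` (default 150 bp short reads).
    """
    if marker not in RRNA_GENE_LENGTHS:
        raise ValueError(f"unknown marker {marker!r}; expected one of {list(RRNA_GENE_LENGTHS)}")
    if value < 0:
        raise ValueError("rRNA signal must be non-negative")
    if unit == "reads":
        value = value * read_length
    elif unit != "bp":
        raise ValueError("unit must be 'bp' or 'reads'")
    return value / RRNA_GENE_LENGTHS[marker]


def occurrence_filter(matrix: pd.DataFrame, min_fraction: float = 0.10) -> pd.DataFrame:
    """Keep features present (value > 0) in strictly more than ``min_fraction``
    of samples.

    Presence is exact positivity — TPM-like zeros are structural, so no
    epsilon threshold is applied.  At the default 10% cutoff on 143 samples,
    a feature seen in 15 samples (10.49%) is retained and one seen in 14
    (9.79%) is dropped.  Idempotent.
    """
    n_samples = matrix.shape[1]
    frac = (matrix.to_numpy() > 0).sum(axis=1) / n_samples
    keep = frac > min_fraction
    if not keep.any():
        logger.warning("occurrence_filter removed every feature (min_fraction=%s)", min_fraction)
    return matrix.loc[keep]


def expression_ratio(rna: pd.DataFrame, dna: pd.DataFrame) -> pd.DataFrame:
    """Elementwise RNA/DNA activity ratio over the shared features/samples.

    Entries with zero DNA are undefined and returned as NaN (flagged, never
    infinity) so downstream summaries can exclude them.
    """
    features = rna.index.intersection(dna.index)
    samples = rna.columns.intersection(dna.columns)
    if len(features) == 0 or len(samples) == 0:
        raise ValueError("rna and dna tables share no features/samples")
    r = rna.loc[features, samples].to_numpy(dtype=float)
    d = dna.loc[features, samples].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, r / np.where(d > 0, d, 1.0), np.nan)
    return pd.DataFrame(ratio, index=features, columns=samples)


def aggregate_taxa(
    matrix: pd.DataFrame, taxonomy: Mapping[str, str], rank_of_unmapped: str = "unassigned"
) -> pd.DataFrame:
    """Sum feature rows within taxonomy groups (e.g. contigs -> phyla).

    Features missing from ``taxonomy`` fall into the ``unassigned`` bucket.
    Column sums are conserved exactly.
    """
    groups = [taxonomy.get(f, rank_of_unmapped) for f in matrix.index]
    out = matrix.groupby(pd.Index(groups, name=matrix.index.name), sort=False).sum()
    return out
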