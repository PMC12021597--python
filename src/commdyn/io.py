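"""Tab-separated table I/O.

Abundance and metadata tables are features/parameters-by-samples with the
feature id in the first column and YYYY-MM sample ids as remaining columns.
A sidecar taxonomy table maps taxon_id -> domain and phylum.  Distance
matrices round-trip as square TSV files; alignment digests are 4-column
TSVs (read_id, target_id, domain, alignment_score).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .ordination import DistanceMatrix


def write_table(frame: pd.DataFrame, path, index_label: str = "taxon_id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_taxonomy(taxon_ids, domains, phyla, path) -> None:
    frame = pd.DataFrame({"domain": domains, "phylum": phyla}, index=pd.Index(taxon_ids, name="taxon_id"))
    write_table(frame, path)


def read_alignment_digest(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    expected = ["read_id", "target_id", "domain", "alignment_score"]
    if list(frame.columns) != expected:
        raise ValueError(f"alignment digest must have columns {expected}, got {list(frame.columns)}")
    return frame


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    write_table(dist.to_frame(), path, index_label="sample_id")


def read_distance_matrix(path) -> DistanceMatrix:
    return DistanceMatrix.from_frame(read_table(path))
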