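"""Per-taxon metadata: clade membership, body-size category, tip age ranges.

Body sizes are order-of-magnitude categories (small <1 kg, medium 1-10 kg,
large 10-100 kg, very large 100-1000 kg), matching the coarse resolution at
which fragmentary fossil taxa can still be scored.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "SIZE_CATEGORIES",
    "MetadataValidationError",
    "read_metadata",
    "read_partition_assignments",
    "normalize_name",
]

SIZE_CATEGORIES = ("small", "medium", "large", "very_large")


class MetadataValidationError(ValueError):
    pass


def normalize_name(name: str) -> str:
    """Spaces and underscores are interchangeable; case is significant."""
    return str(name).strip().replace(" ", "_")


def read_metadata(path, matrix=None, sep=None) -> pd.DataFrame:
    """Read a delimited taxon table with columns taxon, clade, size_category.

    When a ``CharacterMatrix`` is supplied, rows are aligned to its taxa;
    taxa without a row are flagged ``unassigned`` and table rows naming
    unknown taxa are dropped with a warning.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if "taxon" not in df.columns:
        raise MetadataValidationError("metadata table needs a 'taxon' column")
    df["taxon"] = df["taxon"].map(normalize_name)
    if df["taxon"].duplicated().any():
        dupes = sorted(df.loc[df["taxon"].duplicated(), "taxon"])
        raise MetadataValidationError(f"duplicate metadata rows for {dupes}")
    if "size_category" in df.columns:
        present = df["size_category"].dropna()
        bad = sorted(set(present) - set(SIZE_CATEGORIES))
        if bad:
            raise MetadataValidationError(
                f"size categories {bad} outside {SIZE_CATEGORIES}"
            )
    df = df.set_index("taxon")
    if matrix is not None:
        matrix_names = [normalize_name(t) for t in matrix.taxa]
        extra = sorted(set(df.index) - set(matrix_names))
        if extra:
            warnings.warn(
                f"{len(extra)} metadata rows name taxa absent from the matrix "
                f"and were dropped: {extra[:5]}{'...' if len(extra) > 5 else ''}"
            )
        df = df.reindex(matrix_names)
        df["unassigned"] = df.isna().all(axis=1)
    return df


def read_partition_assignments(path, n_chars=None) -> dict:
    """Read a per-character partition CSV (columns: char, partition).

    Characters are 1-based in the file, 0-based in the returned mapping
    ``{char_index: set of labels}``; a character may carry several labels
    (one row each).
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"char", "partition"} <= set(df.columns):
        raise MetadataValidationError(
            "partition table needs 'char' and 'partition' columns"
        )
    out: dict = {}
    for _, row in df.iterrows():
        j = int(row["char"]) - 1
        if j < 0 or (n_chars is not None and j >= n_chars):
            raise MetadataValidationError(f"character number {row['char']} out of range")
        out.setdefault(j, set()).add(str(row["partition"]).strip())
    return out
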