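"""Barcoded fragment sets — the raw single-cell chromatin signal.

A fragments file is the standard 5-column TSV (chrom, start, end, barcode,
count), 0-based half-open, sorted by (chrom, start), optionally gzipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


@dataclass
class FragmentSet:
    """One sample's barcoded genomic fragments."""

    records: pd.DataFrame
    sample: str

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"fragment table missing columns {missing}")
        r = self.records
        if len(r) and not (r["start"] < r["end"]).all():
            raise ValueError("fragments must satisfy start < end")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def barcodes(self) -> np.ndarray:
        return self.records["barcode"].unique()

    def sort(self, chrom_order: dict[str, int] | None = None) -> "FragmentSet":
        r = self.records
        if chrom_order is not None:
            key = r["chrom"].map(chrom_order)
            idx = np.lexsort((r["start"].to_numpy(), key.to_numpy()))
            r = r.iloc[idx]
        else:
            r = r.sort_values(["chrom", "start"], kind="mergesort")
        return FragmentSet(r.reset_index(drop=True), self.sample)

    def write(self, path) -> None:
        """Write as (optionally gzipped, by extension) 5-column TSV.

        Gzip output is written with a zeroed timestamp so identical
        content gives byte-identical files.
        """
        compression = ({"method": "gzip", "mtime": 0}
                       if str(path).endswith(".gz") else None)
        self.records[FRAGMENT_COLUMNS].to_csv(
            path, sep="\t", header=False, index=False, compression=compression)

    @classmethod
    def read(cls, path, sample: str) -> "FragmentSet":
        df = pd.read_csv(path, sep="\t", header=None, names=FRAGMENT_COLUMNS, comment="#")
        return cls(df, sample)
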