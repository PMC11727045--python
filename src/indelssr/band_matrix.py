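"""Binary band-presence matrix: the dominant-marker scoring unit.

Electrophoretic bands are scored 1 (present), 0 (absent) or NA (failed
amplification / missing).  Bands are grouped by the marker (primer pair)
that produced them; an individual is missing for a marker iff all of that
marker's bands are NA for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class BandMatrix:
    """Band presence/absence scores grouped by marker.

    ``scores`` is a DataFrame indexed by a (marker_id, band_id) MultiIndex
    with one column per individual; cells are 0.0, 1.0 or NaN.
    """

    scores: pd.DataFrame
    _marker_order: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.scores.index, pd.MultiIndex):
            raise ValueError("scores must be indexed by (marker_id, band_id)")
        vals = self.scores.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | (vals == 0) | (vals == 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            marker, band = self.scores.index[i]
            raise ValueError(
                f"non-binary band score at marker={marker!r} band={band!r} "
                f"individual={self.scores.columns[j]!r}: {vals[i, j]!r}"
            )
        if not self._marker_order:
            seen: dict[str, None] = {}
            for m, _ in self.scores.index:
                seen.setdefault(m, None)
            self._marker_order = list(seen)

    @property
    def marker_ids(self) -> list[str]:
        return list(self._marker_order)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n_individuals(self) -> int:
        return self.scores.shape[1]

    def bands_for(self, marker_id: str) -> pd.DataFrame:
        """Rows (band_id-indexed) of one marker."""
        sub = self.scores.xs(marker_id, level=0, drop_level=True)
        if sub.empty:
            raise KeyError(marker_id)
        return sub

    def band_ids(self, marker_id: str) -> list[str]:
        return list(self.bands_for(marker_id).index)

    def missing_mask(self, marker_id: str) -> pd.Series:
        """True where an individual is NA for the whole marker."""
        return self.bands_for(marker_id).isna().all(axis=0)

    # ---- I/O -------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.scores.copy()
        out.index.names = ["marker_id", "band_id"]
        with open(path, "w") as fh:
            fh.write("marker_id\tband_id\t" + "\t".join(out.columns) + "\n")
            for (m, b), row in out.iterrows():
                cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
                fh.write(f"{m}\t{b}\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BandMatrix":
        df = pd.read_csv(
            path, sep="\t", dtype={"marker_id": str, "band_id": str},
            na_values=["NA"], keep_default_na=False,
        )
        if df.columns[0] != "marker_id" or df.columns[1] != "band_id":
            raise ValueError(
                f"{path}: band matrix must start with marker_id and band_id columns"
            )
        order = list(dict.fromkeys(df["marker_id"]))
        body = df.set_index(["marker_id", "band_id"])
        for col in body.columns:
            raw = df[col]
            numeric = pd.to_numeric(raw, errors="coerce")
            bad = numeric.notna() & ~numeric.isin([0, 1])
            bad |= raw.notna() & numeric.isna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise ValueError(
                    f"{path}: non-binary band cell at marker="
                    f"{df['marker_id'].iloc[i]!r} band={df['band_id'].iloc[i]!r} "
                    f"individual={col!r}: {raw.iloc[i]!r}"
                )
            body[col] = numeric.to_numpy(dtype=float)
        return cls(scores=body.astype(float), _marker_order=order)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self._marker_order == other._marker_order
            and self.scores.index.equals(other.scores.index)
            and list(self.scores.columns) == list(other.scores.columns)
            and np.array_equal(
                self.scores.to_numpy(), other.scores.to_numpy(), equal_nan=True
            )
        )
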