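"""Genomic probe maps and per-strain ratio profiles.

The probe map is the coordinate backbone of the whole pipeline: an ordered
list of non-overlapping probes per chromosome, each labeled ``arm``,
``center`` or ``X``.  A :class:`RatioProfile` holds one strain's per-probe
fluorescence intensities and log2(test/reference) ratios aligned to a probe
map.  Coordinates are 1-based inclusive internally; on-disk dialects are
handled by :mod:`cghindel.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["ProbeMap", "RatioProfile"]


class ProbeMap:
    """Ordered, non-overlapping genomic probes with arm/center/X labels.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``probe_id``, ``chromosome``, ``start``, ``end``, ``region``
        (region in {"arm", "center", "X"}).  Rows are sorted by
        (chromosome, start) with chromosome order taken from first
        appearance, and validated to be non-overlapping within chromosomes.
    """

    REQUIRED = ("probe_id", "chromosome", "start", "end", "region")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        # stable sort keeps first-appearance chromosome order
        order = {c: i for i, c in enumerate(pd.unique(table["chromosome"]))}
        table = table.assign(_c=table["chromosome"].map(order))
        table = table.sort_values(["_c", "start"], kind="mergesort")
        table = table.drop(columns="_c").reset_index(drop=True)
        if table["probe_id"].duplicated().any():
            dup = table.loc[table["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id: {dup!r}")
        if (table["start"] > table["end"]).any():
            raise ValueError("probe with start > end")
        self.table = table
        self.chromosomes: list[str] = list(order)
        # index span [lo, hi) of each chromosome in the global probe order
        self._spans: dict[str, tuple[int, int]] = {}
        chrom = table["chromosome"].to_numpy()
        for c in self.chromosomes:
            idx = np.flatnonzero(chrom == c)
            lo, hi = int(idx[0]), int(idx[-1]) + 1
            starts = table["start"].to_numpy()[lo:hi]
            ends = table["end"].to_numpy()[lo:hi]
            if np.any(starts[1:] <= ends[:-1]):
                raise ValueError(f"overlapping probes on {c}")
            self._spans[c] = (lo, hi)
        self._id_index = pd.Series(
            np.arange(len(table)), index=table["probe_id"]
        )

    def __len__(self) -> int:
        return len(self.table)

    def span(self, chromosome: str) -> tuple[int, int]:
        """Global index range [lo, hi) of a chromosome's probes."""
        return self._spans[chromosome]

    def chromosome_slice(self, chromosome: str) -> slice:
        lo, hi = self._spans[chromosome]
        return slice(lo, hi)

    @property
    def starts(self) -> np.ndarray:
        return self.table["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.table["end"].to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    @property
    def regions(self) -> np.ndarray:
        return self.table["region"].to_numpy()

    @property
    def probe_ids(self) -> np.ndarray:
        return self.table["probe_id"].to_numpy()

    def index_of(self, probe_id: str) -> int:
        """Global index of a probe id."""
        return int(self._id_index[probe_id])

    def local_index(self, global_index: int) -> tuple[str, int]:
        """Map a global probe index to (chromosome, within-chromosome index)."""
        chrom = self.table["chromosome"].iloc[global_index]
        lo, _ = self._spans[chrom]
        return chrom, global_index - lo

    def overlapping(self, chromosome: str, start: int, end: int) -> np.ndarray:
        """Global indices of probes overlapping [start, end] (1-based incl.)."""
        lo, hi = self._spans[chromosome]
        s = self.starts[lo:hi]
        e = self.ends[lo:hi]
        mask = (s <= end) & (e >= start)
        return np.flatnonzero(mask) + lo

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProbeMap):
            return NotImplemented
        return self.table.equals(other.table)


@dataclass
class RatioProfile:
    """One strain's per-probe intensities and log2 ratios on a probe map.

    ``log2_ratio`` is log2(test/reference); ~0 for copy-neutral probes,
    strongly negative over deletions, positive over amplifications.
    """

    strain: str
    probe_map: ProbeMap
    log2_ratio: np.ndarray
    test_intensity: np.ndarray | None = None
    ref_intensity: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self):
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        if len(self.log2_ratio) != len(self.probe_map):
            raise ValueError("log2_ratio length does not match probe map")
        if not np.all(np.isfinite(self.log2_ratio)):
            raise ValueError("non-finite log2 ratios")
        for name in ("test_intensity", "ref_intensity"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if len(v) != len(self.probe_map):
                    raise ValueError(f"{name} length does not match probe map")
                if np.any(v <= 0):
                    raise ValueError(f"{name} must be strictly positive")
                setattr(self, name, v)

    @property
    def has_intensities(self) -> bool:
        return self.test_intensity is not None and self.ref_intensity is not None

    @property
    def mean_log_intensity(self) -> np.ndarray:
        """A = (log2 test + log2 ref)/2, the two-color MA-plot covariate."""
        if not self.has_intensities:
            raise ValueError("profile has no intensities")
        return 0.5 * (np.log2(self.test_intensity) + np.log2(self.ref_intensity))

    def with_ratios(self, log2_ratio: np.ndarray, *, normalized: bool) -> "RatioProfile":
        return replace(self, log2_ratio=np.asarray(log2_ratio, float), normalized=normalized)

    def chromosome_ratios(self, chromosome: str) -> np.ndarray:
        return self.log2_ratio[self.probe_map.chromosome_slice(chromosome)]

    def rebind(self, probe_map: ProbeMap) -> "RatioProfile":
        """Attach a richer probe map (e.g. one carrying region labels)
        covering the same probes in the same order."""
        if len(probe_map) != len(self.probe_map) or not np.array_equal(
            probe_map.probe_ids, self.probe_map.probe_ids
        ):
            raise ValueError("probe map does not cover the profile's probes")
        return replace(self, probe_map=probe_map)
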