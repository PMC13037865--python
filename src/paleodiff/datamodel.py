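"""Core in-memory containers shared by every analysis stage.

Three types flow through the package:

* :class:`SiteTable` — biallelic SNP genotypes for a set of diploid samples,
  with optional ancestral-allele polarization (1-based positions, VCF
  convention).
* :class:`GeneticMap` — monotone bp ↔ cM interpolation per chromosome.
* :class:`IntervalTrack` — genomic intervals in 0-based half-open (BED)
  coordinates, used for callability masks, HBD tracts and ancestry segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

# ancestral-state codes in SiteTable.anc
ANC_REF = 0
ANC_ALT = 1
ANC_UNKNOWN = -1

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transversion(ref: str, alt: str) -> bool:
    """True if ref→alt is a purine↔pyrimidine change (deamination-immune)."""
    return (ref.upper(), alt.upper()) not in _TRANSITIONS


class SiteTable:
    """Polarized biallelic genotypes for diploid samples.

    Genotypes are stored as ALT-allele dosage in {0, 1, 2} with -1 for
    missing. Polarization (derived-allele dosage) is derived on demand from
    the per-site ancestral-state code, so statistics that do not need
    polarization (e.g. F_ST) can use raw dosages at every site.

    Parameters
    ----------
    chrom, pos : site coordinates; ``pos`` is 1-based and strictly
        increasing within each chromosome.
    ref, alt : single-nucleotide alleles.
    anc : ancestral-state code per site (ANC_REF / ANC_ALT / ANC_UNKNOWN).
    samples : sample names, one per genotype column.
    gt : (n_sites, n_samples) int8 ALT dosages, -1 = missing.
    callable_site : per-site callability flag (default all True).
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        ref: np.ndarray,
        alt: np.ndarray,
        anc: np.ndarray,
        samples: Sequence[str],
        gt: np.ndarray,
        callable_site: Optional[np.ndarray] = None,
    ):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = np.asarray(alt, dtype=object)
        self.anc = np.asarray(anc, dtype=np.int8)
        self.samples = list(samples)
        self.gt = np.asarray(gt, dtype=np.int8)
        if self.gt.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.gt.shape} does not match "
                f"{len(self.pos)} sites x {len(self.samples)} samples"
            )
        if callable_site is None:
            callable_site = np.ones(len(self.pos), dtype=bool)
        self.callable_site = np.asarray(callable_site, dtype=bool)
        self._validate()

    def _validate(self) -> None:
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic properties -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> List[str]:
        seen: Dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def transversion(self) -> np.ndarray:
        return np.array(
            [is_transversion(r, a) for r, a in zip(self.ref, self.alt)], dtype=bool
        )

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(
                f"sample {name!r} not found; available: {', '.join(self.samples)}"
            ) from None

    # -- genotype views ---------------------------------------------------
    def alt_dosage(self, samples: Optional[Sequence[str]] = None) -> np.ndarray:
        """Raw ALT dosages as float, NaN for missing."""
        idx = self._indices(samples)
        g = self.gt[:, idx].astype(float)
        g[g < 0] = np.nan
        return g

    def derived_dosage(self, samples: Optional[Sequence[str]] = None) -> np.ndarray:
        """Derived-allele dosages as float; NaN where missing or ancestral
        state is unknown."""
        g = self.alt_dosage(samples)
        flip = self.anc == ANC_ALT
        g[flip] = 2.0 - g[flip]
        g[self.anc == ANC_UNKNOWN] = np.nan
        return g

    def _indices(self, samples: Optional[Sequence[str]]) -> List[int]:
        if samples is None:
            return list(range(len(self.samples)))
        return [self.sample_index(s) for s in samples]

    # -- subsetting -------------------------------------------------------
    def subset(self, mask: np.ndarray) -> "SiteTable":
        mask = np.asarray(mask)
        return SiteTable(
            self.chrom[mask],
            self.pos[mask],
            self.ref[mask],
            self.alt[mask],
            self.anc[mask],
            self.samples,
            self.gt[mask],
            self.callable_site[mask],
        )

    def restrict_to(self, track: "IntervalTrack") -> "SiteTable":
        """Keep sites whose (0-based) position falls inside the track."""
        return self.subset(track.contains(self.chrom, self.pos - 1))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SiteTable({self.n_sites} sites, {len(self.samples)} samples, "
            f"{len(self.chromosomes)} chromosomes)"
        )


class GeneticMap:
    """Piecewise-linear bp ↔ cM map per chromosome.

    Positions outside the mapped range are clamped to the terminal cM
    values, so genetic lengths never extrapolate beyond the map.
    """

    def __init__(self, maps: Dict[str, Tuple[np.ndarray, np.ndarray]]):
        self._maps: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in maps.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"bp positions not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cM values decreasing on {chrom}")
            self._maps[chrom] = (bp, cm)

    @classmethod
    def uniform(cls, chrom_lengths: Dict[str, int], cm_per_mb: float = 1.0) -> "GeneticMap":
        """Constant-rate map (default 1 cM/Mb, the genome-wide human average)."""
        return cls(
            {
                c: (np.array([0.0, float(L)]), np.array([0.0, L * cm_per_mb / 1e6]))
                for c, L in chrom_lengths.items()
            }
        )

    @property
    def chromosomes(self) -> List[str]:
        return list(self._maps)

    def _get(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        if chrom not in self._maps:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        return self._maps[chrom]

    def interpolate_cm(self, chrom: str, pos) -> np.ndarray:
        """cM position(s) for bp position(s); clamps outside the map range."""
        bp, cm = self._get(chrom)
        return np.interp(np.asarray(pos, dtype=float), bp, cm)

    def interpolate_bp(self, chrom: str, cm_pos) -> np.ndarray:
        """Inverse interpolation cM → bp (clamped)."""
        bp, cm = self._get(chrom)
        # np.interp needs strictly increasing x; collapse flat cM stretches
        keep = np.concatenate([[True], np.diff(cm) > 0])
        return np.interp(np.asarray(cm_pos, dtype=float), cm[keep], bp[keep])

    def span_cm(self, chrom: str) -> Tuple[float, float]:
        bp, cm = self._get(chrom)
        return float(cm[0]), float(cm[-1])

    def length_cm(self, chrom: str, start_bp: float, end_bp: float) -> float:
        a = self.interpolate_cm(chrom, start_bp)
        b = self.interpolate_cm(chrom, end_bp)
        return float(b - a)

    def total_cm(self) -> float:
        return sum(self.span_cm(c)[1] - self.span_cm(c)[0] for c in self._maps)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (bp, cm) in self._maps.items():
            for b, c in zip(bp, cm):
                rows.append((chrom, int(b), float(c)))
        return pd.DataFrame(rows, columns=["chrom", "bp", "cM"])


@dataclass
class IntervalTrack:
    """Sorted genomic intervals, 0-based half-open, with optional score/label.

    Interval set operations (merge, intersect, subtract) operate per
    chromosome on sorted coordinate arrays.
    """

    df: pd.DataFrame = field(default_factory=lambda: _empty_track_frame())

    def __post_init__(self):
        cols = list(self.df.columns)
        for c in ("chrom", "start", "end"):
            if c not in cols:
                raise ValueError(f"IntervalTrack frame missing column {c!r}")
        if "score" not in cols:
            self.df = self.df.assign(score=np.nan)
        if "label" not in cols:
            self.df = self.df.assign(label=".")
        bad = self.df["end"] <= self.df["start"]
        if bad.any():
            raise ValueError(f"{int(bad.sum())} intervals with end <= start")
        self.df = (
            self.df.sort_values(["chrom", "start", "end"])
            .reset_index(drop=True)
            .astype({"start": np.int64, "end": np.int64})
        )

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple], columns=("chrom", "start", "end")
    ) -> "IntervalTrack":
        return cls(pd.DataFrame(list(records), columns=list(columns)))

    @classmethod
    def empty(cls) -> "IntervalTrack":
        return cls(_empty_track_frame())

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> List[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def _per_chrom(self) -> Dict[str, np.ndarray]:
        out = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            out[chrom] = sub[["start", "end"]].to_numpy(dtype=np.int64)
        return out

    def merged(self) -> "IntervalTrack":
        """Union of intervals (scores/labels dropped)."""
        rows = []
        for chrom, iv in self._per_chrom().items():
            if len(iv) == 0:
                continue
            cur_s, cur_e = iv[0]
            for s, e in iv[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        return IntervalTrack.from_records(rows) if rows else IntervalTrack.empty()

    def intersect(self, other: "IntervalTrack") -> "IntervalTrack":
        a = self.merged()._per_chrom()
        b = other.merged()._per_chrom()
        rows = []
        for chrom in a:
            if chrom not in b:
                continue
            rows.extend(
                (chrom, s, e) for s, e in _intersect_sorted(a[chrom], b[chrom])
            )
        return IntervalTrack.from_records(rows) if rows else IntervalTrack.empty()

    def subtract(self, other: "IntervalTrack") -> "IntervalTrack":
        a = self.merged()._per_chrom()
        b = other.merged()._per_chrom()
        rows = []
        for chrom, iv in a.items():
            cut = b.get(chrom, np.empty((0, 2), dtype=np.int64))
            rows.extend((chrom, s, e) for s, e in _subtract_sorted(iv, cut))
        return IntervalTrack.from_records(rows) if rows else IntervalTrack.empty()

    def total_length(self) -> int:
        m = self.merged().df
        return int((m["end"] - m["start"]).sum()) if len(m) else 0

    def total_cm(self, gmap: GeneticMap) -> float:
        tot = 0.0
        for _, row in self.merged().df.iterrows():
            tot += gmap.length_cm(row["chrom"], row["start"], row["end"])
        return tot

    def contains(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Boolean membership for 0-based positions."""
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos0, dtype=np.int64)
        out = np.zeros(len(pos0), dtype=bool)
        per = self.merged()._per_chrom()
        for c, iv in per.items():
            sel = chrom == c
            if not sel.any():
                continue
            starts, ends = iv[:, 0], iv[:, 1]
            k = np.searchsorted(starts, pos0[sel], side="right") - 1
            ok = (k >= 0) & (pos0[sel] < ends[np.clip(k, 0, len(ends) - 1)])
            out[sel] = ok
        return out

    def with_lengths_cm(self, gmap: GeneticMap) -> pd.DataFrame:
        """Frame with start_cM / end_cM / length_cM columns appended."""
        df = self.df.copy()
        start_cm = np.empty(len(df))
        end_cm = np.empty(len(df))
        for chrom, sub in df.groupby("chrom", sort=False):
            start_cm[sub.index] = gmap.interpolate_cm(chrom, sub["start"].to_numpy())
            end_cm[sub.index] = gmap.interpolate_cm(chrom, sub["end"].to_numpy())
        df["start_cM"] = start_cm
        df["end_cM"] = end_cm
        df["length_cM"] = end_cm - start_cm
        return df


def _empty_track_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "score": pd.Series(dtype=float),
            "label": pd.Series(dtype=object),
        }
    )


def _intersect_sorted(a: np.ndarray, b: np.ndarray):
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            yield int(s), int(e)
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1


def _subtract_sorted(a: np.ndarray, b: np.ndarray):
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                yield int(cur), int(b[k, 0])
            cur = max(cur, b[k, 1])
            if cur >= e:
                break
            k += 1
        if cur < e:
            yield int(cur), int(e)
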