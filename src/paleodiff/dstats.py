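"""Derived-allele-sharing statistics between genomes.

Three related measures of how genomes share derived variation:

* :func:`d_statistic` — the ABBA-BABA test of treeness. For
  D(ind1, ind2; ind3, outgroup), sites where ind3 carries a derived allele
  absent from the outgroup are informative; an excess of ind1–ind3 sharing
  over ind2–ind3 sharing (positive D by the sign convention used here)
  rejects a symmetric relationship of ind3 to the pair. |Z| >= 3 from the
  weighted block jackknife is the customary significance rule.
* :func:`f_a_given_b` — F(A|B): the fraction of sites derived in a
  conditioning genome set B at which genome A also carries the derived
  allele; used for lineage assignment of an unknown genome.
* :func:`assign_tracts` — assigns archaic-introgressed tracts in modern
  genomes to the archaic reference genome sharing the most variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import GeneticMap, IntervalTrack, SiteTable
from .jackknife import block_ids, ratio_jackknife

DEFAULT_BLOCK_CM = 5.0
Z_SIGNIFICANT = 3.0


@dataclass
class DStatResult:
    abba: float     # weight of sites where ind3 shares the derived allele with ind1
    baba: float     # ... with ind2
    d: float
    se: float
    z: float
    n_blocks: int
    n_sites: int

    @property
    def significant(self) -> bool:
        return abs(self.z) >= Z_SIGNIFICANT


@dataclass
class SharingResult:
    description: str
    n_conditioning: int
    n_matching: int
    fraction: float


def d_statistic(
    sites: SiteTable,
    ind1: str,
    ind2: str,
    ind3: str,
    outgroup: str,
    gmap: Optional[GeneticMap] = None,
    block_size_cm: float = DEFAULT_BLOCK_CM,
    mode: str = "freq",
    seed: Optional[int] = None,
    transversions_only: bool = False,
) -> DStatResult:
    """D(ind1, ind2; ind3, outgroup) with a weighted block jackknife Z.

    Positive D means ind3 shares more derived alleles with ind1; negative,
    with ind2. In the default frequency mode each diploid contributes its
    derived-allele frequency p in {0, 0.5, 1}; per site,

        abba_i = p1 (1-p2) p3 (1-p4),   baba_i = (1-p1) p2 p3 (1-p4)

    and D = sum(abba - baba) / sum(abba + baba). ``mode="sample"`` draws
    one random allele per genome per site instead (requires ``seed``).
    """
    p = sites.derived_dosage([ind1, ind2, ind3, outgroup]) / 2.0
    keep = ~np.isnan(p).any(axis=1)
    if transversions_only:
        keep &= sites.transversion
    p = p[keep]
    if mode == "sample":
        if seed is None:
            raise ValueError("sampled-allele mode requires a seed")
        rng = np.random.default_rng(seed)
        p = (rng.random(p.shape) < p).astype(float)
    elif mode != "freq":
        raise ValueError(f"unknown mode {mode!r}")

    p1, p2, p3, p4 = p.T
    abba = p1 * (1 - p2) * p3 * (1 - p4)
    baba = (1 - p1) * p2 * p3 * (1 - p4)
    num = abba - baba
    den = abba + baba
    den_sum = float(den.sum())
    if den_sum == 0:
        raise ValueError("no informative sites")
    d = float(num.sum()) / den_sum

    se, g = float("nan"), 0
    if gmap is not None:
        blocks = block_ids(sites, keep, gmap, block_size_cm)
        _, se, g = ratio_jackknife(num, den, blocks)
    z = d / se if se and np.isfinite(se) and se > 0 else float("nan")
    return DStatResult(
        abba=float(abba.sum()),
        baba=float(baba.sum()),
        d=d,
        se=se,
        z=z,
        n_blocks=g,
        n_sites=int(keep.sum()),
    )


def f_a_given_b(
    sites: SiteTable,
    target: str,
    derived_in: Sequence[str],
    mode: str = "all",
    exclude_derived_in: Sequence[str] = (),
) -> SharingResult:
    """F(A|B): fraction of conditioning sites where ``target`` is derived.

    The conditioning set B holds polarized sites where the ``derived_in``
    genomes carry a derived allele (dosage >= 1) — all of them
    (``mode="all"``) or at least one (``mode="any"``) — and none of the
    ``exclude_derived_in`` genomes does ("unique-to" conditioning). Sites
    missing in any involved genome are ignored.
    """
    cond_names = list(derived_in)
    excl_names = list(exclude_derived_in)
    if not cond_names:
        raise ValueError("empty conditioning description")
    d = sites.derived_dosage(cond_names + excl_names + [target])
    ok = ~np.isnan(d).any(axis=1)
    dc = d[:, : len(cond_names)] >= 1
    cond = dc.all(axis=1) if mode == "all" else dc.any(axis=1)
    if excl_names:
        de = d[:, len(cond_names) : len(cond_names) + len(excl_names)] >= 1
        cond &= ~de.any(axis=1)
    cond &= ok
    n_cond = int(cond.sum())
    if n_cond == 0:
        raise ValueError("conditioning set is empty after filters")
    n_match = int((d[cond, -1] >= 1).sum())
    join = " & ".join(cond_names) if mode == "all" else " | ".join(cond_names)
    desc = f"derived in {join}"
    if excl_names:
        desc += f", not derived in {' | '.join(excl_names)}"
    return SharingResult(desc, n_cond, n_match, n_match / n_cond)


def assign_tracts(
    tracts: Dict[str, IntervalTrack],
    sites: SiteTable,
    neandertals: Sequence[str],
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Assign each introgressed tract to the archaic genome it matches best.

    For every tract of every modern carrier, variants where the carrier
    holds a derived allele are compared against each archaic reference
    genome; the tract is assigned to the genome carrying the derived allele
    at the most positions. Ties are reported as ``unassigned``; tracts
    without informative variants as ``uninformative``.
    """
    refs = list(neandertals)
    d_ref = sites.derived_dosage(refs) >= 1
    rows = []
    totals: Dict[str, int] = {r: 0 for r in refs}
    totals["unassigned"] = 0
    totals["uninformative"] = 0
    for sample, track in tracts.items():
        d_t = sites.derived_dosage([sample])[:, 0]
        for _, tr in track.df.iterrows():
            inside = (
                (sites.chrom == tr["chrom"])
                & (sites.pos - 1 >= tr["start"])
                & (sites.pos - 1 < tr["end"])
            )
            informative = inside & (d_t >= 1)
            counts = d_ref[informative].sum(axis=0)
            n_inf = int(informative.sum())
            if n_inf == 0 or counts.max() == 0:
                assigned = "uninformative"
            else:
                best = np.flatnonzero(counts == counts.max())
                assigned = refs[best[0]] if len(best) == 1 else "unassigned"
            totals[assigned] = totals.get(assigned, 0) + 1
            rows.append(
                {
                    "sample": sample,
                    "chrom": tr["chrom"],
                    "start": int(tr["start"]),
                    "end": int(tr["end"]),
                    "n_informative": n_inf,
                    **{f"match_{r}": int(c) for r, c in zip(refs, counts)},
                    "assigned": assigned,
                }
            )
    return pd.DataFrame(rows), totals
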