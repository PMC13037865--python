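"""Hudson F_ST between cohorts or single diploid genomes.

The estimator is the ratio-of-sums form of Hudson's F_ST: per biallelic
site with sample allele frequencies p1 = x1/n1, p2 = x2/n2,

    N_i = (p1 - p2)^2 - p1(1-p1)/(n1 - 1) - p2(1-p2)/(n2 - 1)
    D_i = p1(1-p2) + p2(1-p1)

and F_ST = sum(N_i) / sum(D_i). The within-population terms remove
finite-sample noise in the squared frequency difference, which is what lets
a single diploid genome (n = 2) stand in for a population sample.

That removal assumes the two alleles of a diploid are independent draws.
In an autozygous genome a fraction f of the genome carries two copies of
one recent ancestral haplotype, making the draws correlated (correlation f)
and inflating F_ST between single genomes. The correction replaces each
diploid's two observations with an effective count

    n_eff = 2 / (1 + f)

— the design-effect formula n/(1 + (n-1) rho) — used in the n-1 divisors
of the correction terms (allele frequencies themselves are unchanged).
For a single diploid the divisor becomes (1-f)/(1+f), which exactly offsets
the autozygosity-inflated sampling variance Var(p_hat) = p(1-p)(1+f)/2.

Confidence intervals come from a weighted delete-one block jackknife over
contiguous blocks of fixed genetic length (default 5 cM, so each block
carries comparable linkage information).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import GeneticMap, IntervalTrack, SiteTable
from .jackknife import block_ids, ratio_jackknife

DEFAULT_BLOCK_CM = 5.0


@dataclass
class FstEstimate:
    fst: float
    num_sum: float
    den_sum: float
    n_sites: int
    se: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_blocks: int = 0
    n_eff: Dict[str, float] = field(default_factory=dict)


def _site_terms(
    sites: SiteTable,
    popA: Sequence[str],
    popB: Sequence[str],
    autozygosity: Optional[Dict[str, float]],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, Dict[str, float]]:
    """Per-site Hudson numerator/denominator and the site keep-mask."""
    f = autozygosity or {}
    gA = sites.alt_dosage(list(popA))
    gB = sites.alt_dosage(list(popB))
    complete = ~np.isnan(gA).any(axis=1) & ~np.isnan(gB).any(axis=1)

    neffA = sum(2.0 / (1.0 + f.get(s, 0.0)) for s in popA)
    neffB = sum(2.0 / (1.0 + f.get(s, 0.0)) for s in popB)
    if neffA <= 1 or neffB <= 1:
        raise ValueError("effective allele count <= 1 in a population")

    nA, nB = 2 * len(popA), 2 * len(popB)
    xA = np.nansum(gA, axis=1)
    xB = np.nansum(gB, axis=1)
    p1 = xA / nA
    p2 = xB / nB
    variable = (xA + xB > 0) & (xA + xB < nA + nB)
    keep = complete & variable

    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (neffA - 1)
        - p2 * (1 - p2) / (neffB - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den, keep, {"A": neffA, "B": neffB}


def hudson_fst(
    sites: SiteTable,
    popA: Sequence[str],
    popB: Sequence[str],
    mask: Optional[IntervalTrack] = None,
    gmap: Optional[GeneticMap] = None,
    block_size_cm: float = DEFAULT_BLOCK_CM,
    autozygosity: Optional[Dict[str, float]] = None,
) -> FstEstimate:
    """Ratio-of-sums Hudson F_ST with a weighted block jackknife CI.

    Sites used: biallelic, complete data in every used sample, variable in
    the union of the two population samples. ``autozygosity`` maps sample
    name -> HBD genome fraction f; absent samples are treated as outbred.
    The jackknife needs ``gmap``; without it only the point estimate is
    returned.
    """
    if mask is not None:
        sites = sites.restrict_to(mask)
    num, den, keep, neff = _site_terms(sites, popA, popB, autozygosity)
    num, den = num[keep], den[keep]
    den_sum = float(den.sum())
    if den_sum <= 0:
        raise ValueError("no informative sites")
    num_sum = float(num.sum())
    est = FstEstimate(
        fst=num_sum / den_sum,
        num_sum=num_sum,
        den_sum=den_sum,
        n_sites=int(keep.sum()),
        n_eff=neff,
    )
    if gmap is not None:
        blocks = block_ids(sites, keep, gmap, block_size_cm)
        _, se, g = ratio_jackknife(num, den, blocks)
        if np.isfinite(se):
            est.se = se
            est.ci_low = est.fst - 1.96 * se
            est.ci_high = est.fst + 1.96 * se
            est.n_blocks = g
    return est


def subsample_single_genome_fst(
    sites: SiteTable,
    popA: Sequence[str],
    popB: Sequence[str],
    n_pairs: int,
    seed: int,
    autozygosity: Optional[Dict[str, float]] = None,
    mask: Optional[IntervalTrack] = None,
    gmap: Optional[GeneticMap] = None,
    block_size_cm: float = DEFAULT_BLOCK_CM,
) -> Dict[str, object]:
    """Distribution of Hudson F_ST over random single-genome pairs.

    Mirrors the validation in which random (one genome from each cohort)
    pairs are compared against the full-cohort estimate.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    estimates = []
    pairs = []
    for _ in range(n_pairs):
        a = popA[rng.integers(len(popA))]
        b = popB[rng.integers(len(popB))]
        est = hudson_fst(
            sites,
            [a],
            [b],
            mask=mask,
            gmap=gmap,
            block_size_cm=block_size_cm,
            autozygosity=autozygosity,
        )
        estimates.append(est.fst)
        pairs.append((a, b))
    arr = np.array(estimates)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
        "quantiles": {
            q: float(np.quantile(arr, q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)
        },
        "estimates": estimates,
        "pairs": pairs,
    }


def pairwise_fst_matrix(
    sites: SiteTable,
    samples: Sequence[str],
    autozygosity: Optional[Dict[str, float]] = None,
    mask: Optional[IntervalTrack] = None,
    gmap: Optional[GeneticMap] = None,
    block_size_cm: float = DEFAULT_BLOCK_CM,
) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], FstEstimate]]:
    """Symmetric matrix of corrected single-genome F_ST (diagonal 0)."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    mat = pd.DataFrame(0.0, index=list(samples), columns=list(samples))
    details: Dict[Tuple[str, str], FstEstimate] = {}
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            est = hudson_fst(
                sites,
                [a],
                [b],
                mask=mask,
                gmap=gmap,
                block_size_cm=block_size_cm,
                autozygosity=autozygosity,
            )
            mat.loc[a, b] = mat.loc[b, a] = est.fst
            details[(a, b)] = est
    return mat, details
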