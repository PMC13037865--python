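"""Weighted block jackknife for ratio-of-sums statistics.

Genome-wide ratio estimators (Hudson F_ST, D) are resampled over contiguous
blocks of fixed genetic length so that each block carries a comparable
amount of linkage information. Blocks vary in site content, so the
delete-one pseudovalues are weighted by each block's share of the
denominator (the standard weighted jackknife for unequal block sizes).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .datamodel import GeneticMap, SiteTable


def block_ids(
    sites: SiteTable, keep: np.ndarray, gmap: GeneticMap, block_size_cm: float
) -> np.ndarray:
    """Contiguous genetic-distance block index for each kept site,
    numbered consecutively across chromosomes."""
    ids = np.zeros(int(keep.sum()), dtype=int)
    offset = 0
    out_i = 0
    for chrom in sites.chromosomes:
        sel = (sites.chrom == chrom) & keep
        n = int(sel.sum())
        if n == 0:
            continue
        cm = gmap.interpolate_cm(chrom, sites.pos[sel].astype(float))
        c0, _ = gmap.span_cm(chrom)
        b = ((cm - c0) / block_size_cm).astype(int)
        _, b = np.unique(b, return_inverse=True)
        ids[out_i : out_i + n] = b + offset
        offset += int(b.max()) + 1
        out_i += n
    return ids


def ratio_jackknife(
    num: np.ndarray, den: np.ndarray, blocks: np.ndarray
) -> Tuple[float, float, int]:
    """(estimate, standard error, n_blocks) for sum(num)/sum(den).

    Weighted delete-one jackknife: with block denominator masses w_j,
    W = sum w_j, h_j = W / w_j and leave-one-out estimates theta_j,
    pseudovalues tau_j = h_j * theta - (h_j - 1) * theta_j give
    var = (1/g) * sum (tau_j - theta_J)^2 / (h_j - 1).
    """
    num_sum, den_sum = float(num.sum()), float(den.sum())
    if den_sum == 0:
        raise ValueError("zero denominator")
    theta = num_sum / den_sum
    g = int(blocks.max()) + 1 if len(blocks) else 0
    if g < 2:
        return theta, float("nan"), g
    N_j = np.bincount(blocks, weights=num, minlength=g)
    D_j = np.bincount(blocks, weights=den, minlength=g)
    ok = np.abs(den_sum - D_j) > 1e-12 * max(1.0, abs(den_sum))
    theta_del = (num_sum - N_j[ok]) / (den_sum - D_j[ok])
    w = np.abs(D_j[ok])
    W = w.sum()
    if W == 0 or ok.sum() < 2:
        return theta, float("nan"), int(ok.sum())
    h = W / np.maximum(w, 1e-300)
    g_eff = int(ok.sum())
    tau = h * theta - (h - 1.0) * theta_del
    theta_J = g_eff * theta - float(((1.0 - w / W) * theta_del).sum())
    var = float((((tau - theta_J) ** 2) / (h - 1.0)).sum()) / g_eff
    return theta, float(np.sqrt(var)), g_eff
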