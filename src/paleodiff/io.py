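"""Readers and writers: VCF genotypes, BED interval tracks, genetic maps.

VCF parsing goes through :mod:`cyvcf2`; writing emits minimal VCF 4.2 text
(sites + GT columns + the ancestral-allele INFO tag), which is all the
package needs for round-tripping its own tables.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    ANC_ALT,
    ANC_REF,
    ANC_UNKNOWN,
    GeneticMap,
    IntervalTrack,
    SiteTable,
)

_NUCS = {"A", "C", "G", "T"}


def read_genotypes(
    path,
    samples: Optional[Sequence[str]] = None,
    ancestral_tag: str = "AA",
) -> SiteTable:
    """Read biallelic SNPs from a VCF into a :class:`SiteTable`.

    Multiallelic records and indels are dropped (the count is reported via a
    warning). The ancestral allele is taken from the INFO field
    ``ancestral_tag``; sites where it is absent or matches neither allele are
    kept with unknown ancestral state and simply excluded from polarized
    statistics downstream.
    """
    vcf = VCF(str(path))
    available = list(vcf.samples)
    if samples is None:
        samples = available
    else:
        missing = [s for s in samples if s not in available]
        if missing:
            raise KeyError(
                f"samples not in VCF: {missing}; available: {available}"
            )
        vcf.set_samples(list(samples))
    order = list(vcf.samples)  # cyvcf2 preserves file order after set_samples
    reorder = [order.index(s) for s in samples]

    chrom, pos, ref, alt, anc, gts = [], [], [], [], [], []
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or rec.REF not in _NUCS or rec.ALT[0] not in _NUCS:
            n_dropped += 1
            continue
        aa = rec.INFO.get(ancestral_tag)
        if aa is not None:
            aa = str(aa).upper().strip(".|")
        if aa == rec.REF:
            code = ANC_REF
        elif aa == rec.ALT[0]:
            code = ANC_ALT
        else:
            code = ANC_UNKNOWN
        g = np.asarray(rec.genotype.array())[:, :2]
        dosage = np.where((g < 0).any(axis=1), -1, (g > 0).sum(axis=1)).astype(np.int8)
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        anc.append(code)
        gts.append(dosage[reorder])
    vcf.close()
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} non-biallelic-SNP records")
    gt = (
        np.vstack(gts) if gts else np.empty((0, len(samples)), dtype=np.int8)
    )
    return SiteTable(
        np.array(chrom, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(ref, dtype=object),
        np.array(alt, dtype=object),
        np.array(anc, dtype=np.int8),
        list(samples),
        gt,
    )


def write_vcf(table: SiteTable, path, ancestral_tag: str = "AA") -> None:
    """Write a SiteTable as minimal VCF 4.2 with unphased GT fields."""
    gt_strings = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##INFO=<ID={ancestral_tag},Number=1,Type=String,'
            'Description="Ancestral allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in table.chromosomes:
            sel = table.chrom == c
            fh.write(f"##contig=<ID={c},length={int(table.pos[sel].max()) + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for i in range(table.n_sites):
            if table.anc[i] == ANC_REF:
                info = f"{ancestral_tag}={table.ref[i]}"
            elif table.anc[i] == ANC_ALT:
                info = f"{ancestral_tag}={table.alt[i]}"
            else:
                info = "."
            row = [
                str(table.chrom[i]),
                str(table.pos[i]),
                ".",
                table.ref[i],
                table.alt[i],
                ".",
                "PASS",
                info,
                "GT",
            ] + [gt_strings[int(g)] for g in table.gt[i]]
            fh.write("\t".join(row) + "\n")


def read_bed(path, merge: bool = False) -> IntervalTrack:
    """Read a BED3/BED6 file; malformed records (end <= start) are skipped
    with a warning."""
    rows = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                n_bad += 1
                continue
            label = parts[3] if len(parts) > 3 else "."
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else np.nan
            rows.append((chrom, start, end, score, label))
    if n_bad:
        warnings.warn(f"skipped {n_bad} BED records with end <= start")
    if not rows:
        return IntervalTrack.empty()
    track = IntervalTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "label"])
    )
    return track.merged() if merge else track


def write_bed(track: IntervalTrack, path, bed6: bool = False) -> None:
    df = track.df
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            if bed6:
                score = "." if np.isnan(r["score"]) else f"{r['score']:g}"
                fh.write(
                    f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['label']}\t{score}\t+\n"
                )
            else:
                fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\n")


def read_genetic_map(path) -> GeneticMap:
    """Tab-separated (chrom, bp, cM) with a header line."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    maps: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in df.groupby(df.columns[0], sort=False):
        maps[str(chrom)] = (
            sub.iloc[:, 1].to_numpy(dtype=float),
            sub.iloc[:, 2].to_numpy(dtype=float),
        )
    return GeneticMap(maps)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)
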