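"""Coalescent synthetic datasets with full ground truth.

Every analysis stage in this package is validated by parameter recovery on
simulated data. This module wraps :mod:`msprime` to generate multi-chromosome
diploid genotype datasets together with the quantities the simulator knows
exactly but an analyst must infer:

* true HBD tracts — intervals where an individual's two lineages coalesce
  more recently than a threshold (default 1,000 generations; tracts long
  enough to report, >=2.5 cM, overwhelmingly coalesce much more recently);
* true introgressed segments — intervals whose lineage sat in the donor
  population at the admixture pulse, recovered from a census recorded just
  above the pulse;
* true cohort allele-frequency F_ST, sampling ages, and the admixture
  time/fraction.

Scenario builders (:func:`panmictic_config`, :func:`inbred_config`,
:func:`split_config`, :func:`introgression_config`, :func:`trio_config`)
encode the study designs used throughout: small inbred demes in an island
metapopulation, diverged Neandertal-like populations, a Denisovan-like
donor pulse, and ancient samples drawn at nonzero ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import msprime
import numpy as np

from .datamodel import ANC_ALT, ANC_REF, GeneticMap, IntervalTrack, SiteTable

_NUC = np.array(["A", "C", "G", "T"])
# default human-like rates, per bp per generation
DEFAULT_RECOMB = 1e-8
DEFAULT_MUT = 1.25e-8
DEFAULT_GENERATION_TIME = 29.0


@dataclass
class SampleSpec:
    """A set of diploid samples drawn from one population at one time."""

    population: str
    n: int = 1
    time: float = 0.0  # sampling age in generations before present


@dataclass
class PulseSpec:
    """An admixture pulse: at `time` generations ago, `fraction` of the
    `dest` population's ancestry is replaced by `source` lineages."""

    time: float
    fraction: float
    source: str
    dest: str


@dataclass
class SynthConfig:
    seed: int
    demography: msprime.Demography
    samples: List[SampleSpec]
    n_chrom: int = 4
    chrom_length: float = 10e6
    recomb_rate: float = DEFAULT_RECOMB
    mut_rate: float = DEFAULT_MUT
    pulse: Optional[PulseSpec] = None
    hbd_truth_samples: Optional[List[str]] = None  # None = skip HBD truth
    hbd_time_threshold: float = 1000.0
    fst_cohorts: Optional[Tuple[List[str], List[str]]] = None
    generation_time: float = DEFAULT_GENERATION_TIME
    p_ref_ancestral: float = 1.0  # prob REF allele is the ancestral one

    def __post_init__(self):
        if self.recomb_rate < 0 or self.mut_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.pulse is not None and not (0.0 <= self.pulse.fraction <= 1.0):
            raise ValueError("admixture fraction must be in [0, 1]")

    def sample_names(self) -> List[str]:
        names = []
        counter: Dict[str, int] = {}
        for spec in self.samples:
            for _ in range(spec.n):
                i = counter.get(spec.population, 0)
                counter[spec.population] = i + 1
                names.append(f"{spec.population}_{i}")
        return names

    def samples_of(self, population: str) -> List[str]:
        return [n for n in self.sample_names() if n.rsplit("_", 1)[0] == population]


@dataclass
class SynthTruth:
    """Ground truth recorded alongside a simulated dataset."""

    hbd: Dict[str, IntervalTrack] = dc_field(default_factory=dict)
    introgressed: Dict[str, IntervalTrack] = dc_field(default_factory=dict)
    introgressed_hom: Dict[str, IntervalTrack] = dc_field(default_factory=dict)
    introgressed_hap: Dict[str, Tuple[IntervalTrack, IntervalTrack]] = dc_field(
        default_factory=dict
    )
    pulse_time: Optional[float] = None
    pulse_fraction: Optional[float] = None
    sample_ages: Dict[str, float] = dc_field(default_factory=dict)
    fst_cohort: Optional[float] = None
    sequence_length: float = 0.0


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SynthConfig,
) -> Tuple[SiteTable, GeneticMap, SynthTruth]:
    """Simulate a multi-chromosome diploid dataset with ground truth.

    Chromosomes are simulated independently with seeds derived from
    ``config.seed``; the run is bit-reproducible for a fixed config.
    Genotypes are polarized from the simulated ancestral state (the
    outgroup-polarized annotation a real dataset would carry).
    """
    rng = np.random.default_rng(config.seed)
    chrom_seeds = rng.integers(1, 2**31 - 1, size=(config.n_chrom, 2))

    demog = config.demography
    census_time = None
    if config.pulse is not None and config.pulse.fraction > 0:
        census_time = config.pulse.time + 1e-3
        demog = _with_census(demog, census_time)

    sample_sets = [
        msprime.SampleSet(s.n, population=s.population, time=s.time, ploidy=2)
        for s in config.samples
    ]
    names = config.sample_names()

    truth = SynthTruth(
        pulse_time=config.pulse.time if config.pulse else None,
        pulse_fraction=config.pulse.fraction if config.pulse else None,
        sample_ages={
            n: s.time
            for s, ns in zip(config.samples, _chunks(names, config.samples))
            for n in ns
        },
        sequence_length=config.n_chrom * config.chrom_length,
    )
    if config.pulse is not None:
        for n in names:
            truth.introgressed[n] = IntervalTrack.empty()
            truth.introgressed_hom[n] = IntervalTrack.empty()
            truth.introgressed_hap[n] = (IntervalTrack.empty(), IntervalTrack.empty())
    hbd_names = config.hbd_truth_samples
    if hbd_names is not None:
        for n in hbd_names:
            truth.hbd[n] = IntervalTrack.empty()

    all_chrom, all_pos, all_ref, all_alt, all_anc, all_gt = [], [], [], [], [], []
    donor_pop_id = (
        demog[config.pulse.source].id if config.pulse is not None else None
    )

    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        ts = msprime.sim_ancestry(
            samples=sample_sets,
            demography=demog,
            sequence_length=config.chrom_length,
            recombination_rate=config.recomb_rate,
            discrete_genome=True,
            random_seed=int(chrom_seeds[ci, 0]),
        )
        ts = msprime.sim_mutations(
            ts,
            rate=config.mut_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=int(chrom_seeds[ci, 1]),
        )
        node_pairs = _diploid_node_pairs(ts, names)

        pos, ref, alt, anc, gt = _extract_genotypes(ts, names, node_pairs, rng, config)
        all_chrom.append(np.full(len(pos), chrom, dtype=object))
        all_pos.append(pos)
        all_ref.append(ref)
        all_alt.append(alt)
        all_anc.append(anc)
        all_gt.append(gt)

        if hbd_names is not None:
            for name in hbd_names:
                tr = _hbd_truth(ts, node_pairs[name], config.hbd_time_threshold)
                truth.hbd[name] = _append_track(truth.hbd[name], chrom, tr)
        if census_time is not None:
            seg = _introgression_truth(ts, census_time, donor_pop_id, node_pairs)
            for name, (any_iv, hom_iv, hap_a, hap_b) in seg.items():
                truth.introgressed[name] = _append_track(
                    truth.introgressed[name], chrom, any_iv
                )
                truth.introgressed_hom[name] = _append_track(
                    truth.introgressed_hom[name], chrom, hom_iv
                )
                ta, tb = truth.introgressed_hap[name]
                truth.introgressed_hap[name] = (
                    _append_track(ta, chrom, hap_a),
                    _append_track(tb, chrom, hap_b),
                )

    table = SiteTable(
        np.concatenate(all_chrom),
        np.concatenate(all_pos),
        np.concatenate(all_ref),
        np.concatenate(all_alt),
        np.concatenate(all_anc),
        names,
        np.vstack(all_gt) if all_gt else np.empty((0, len(names)), dtype=np.int8),
    )
    gmap = GeneticMap.uniform(
        {f"chr{i + 1}": int(config.chrom_length) for i in range(config.n_chrom)},
        cm_per_mb=config.recomb_rate * 1e8,
    )

    if config.fst_cohorts is not None:
        from .fst import hudson_fst  # local import: fst does not import simulate

        a, b = config.fst_cohorts
        truth.fst_cohort = hudson_fst(table, a, b, gmap=gmap).fst

    return table, gmap, truth


def _chunks(names: List[str], specs: List[SampleSpec]):
    out, i = [], 0
    for s in specs:
        out.append(names[i : i + s.n])
        i += s.n
    return out


def _with_census(demog: msprime.Demography, time: float) -> msprime.Demography:
    d = demog.copy() if hasattr(demog, "copy") else demog
    d.add_census(time=time)
    d.sort_events()
    return d


def _diploid_node_pairs(ts, names: List[str]) -> Dict[str, Tuple[int, int]]:
    pairs = {}
    for ind, name in zip(ts.individuals(), names):
        a, b = ind.nodes
        pairs[name] = (int(a), int(b))
    return pairs


def _extract_genotypes(ts, names, node_pairs, rng, config):
    """Variant sites polymorphic among the sampled genotypes, as derived
    dosages, with nucleotide alleles drawn at random (ancestral uniform over
    ACGT, derived uniform over the other three, so 2/3 of sites are
    transversions)."""
    G = ts.genotype_matrix()  # (n_sites, n_sample_nodes); allele 1 = derived
    order = np.array(
        [node_pairs[n] for n in names]
    )  # (n_samples, 2) node ids; sample nodes are 0..2n-1
    dos = (G[:, order[:, 0]] > 0).astype(np.int8) + (G[:, order[:, 1]] > 0).astype(
        np.int8
    )
    tot = dos.sum(axis=1)
    poly = (tot > 0) & (tot < 2 * len(names))
    dos = dos[poly]
    pos = (ts.tables.sites.position.astype(np.int64) + 1)[poly]

    n = len(pos)
    anc_idx = rng.integers(0, 4, size=n)
    der_idx = (anc_idx + rng.integers(1, 4, size=n)) % 4
    anc_nuc = _NUC[anc_idx]
    der_nuc = _NUC[der_idx].astype(object)
    ref_is_anc = rng.random(n) < config.p_ref_ancestral
    ref = np.where(ref_is_anc, anc_nuc, der_nuc).astype(object)
    alt = np.where(ref_is_anc, der_nuc, anc_nuc).astype(object)
    anc = np.where(ref_is_anc, ANC_REF, ANC_ALT).astype(np.int8)
    gt = np.where(ref_is_anc[:, None], dos, 2 - dos).astype(np.int8)
    return pos, ref, alt, anc, gt


def _hbd_truth(ts, pair: Tuple[int, int], threshold: float) -> List[Tuple[int, int]]:
    """Maximal intervals where the two within-individual lineages coalesce
    more recently than `threshold` generations."""
    a, b = pair
    out: List[Tuple[int, int]] = []
    cur = None
    for tree in ts.trees():
        recent = tree.tmrca(a, b) < threshold
        left, right = int(tree.interval.left), int(tree.interval.right)
        if recent:
            if cur is None:
                cur = [left, right]
            else:
                cur[1] = right
        elif cur is not None:
            out.append((cur[0], cur[1]))
            cur = None
    if cur is not None:
        out.append((cur[0], cur[1]))
    return out


def _introgression_truth(ts, census_time, donor_pop_id, node_pairs):
    """Per sample: (any-copy, both-copies, haplotype A, haplotype B)
    introgressed intervals, from the census nodes recorded just above the
    admixture pulse."""
    tabs = ts.dump_tables()
    node_time = tabs.nodes.time
    node_pop = tabs.nodes.population
    census_nodes = np.where(np.isclose(node_time, census_time))[0]
    anc_table = tabs.link_ancestors(
        samples=ts.samples().astype(np.int32),
        ancestors=census_nodes.astype(np.int32),
    )
    donor_of_child: Dict[int, List[Tuple[float, float]]] = {}
    for left, right, parent, child in zip(
        anc_table.left, anc_table.right, anc_table.parent, anc_table.child
    ):
        if node_pop[parent] == donor_pop_id:
            donor_of_child.setdefault(int(child), []).append((left, right))

    out = {}
    for name, (a, b) in node_pairs.items():
        iv_a = _merge_intervals(donor_of_child.get(a, []))
        iv_b = _merge_intervals(donor_of_child.get(b, []))
        out[name] = (
            _merge_intervals(iv_a + iv_b),
            _intersect_intervals(iv_a, iv_b),
            iv_a,
            iv_b,
        )
    return out


def _merge_intervals(ivs):
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _intersect_intervals(a, b):
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _append_track(track: IntervalTrack, chrom: str, ivs) -> IntervalTrack:
    if not ivs:
        return track
    import pandas as pd

    new = pd.DataFrame(
        [(chrom, int(s), int(e)) for s, e in ivs], columns=["chrom", "start", "end"]
    )
    if len(track) == 0:
        return IntervalTrack(new)
    return IntervalTrack(
        pd.concat([track.df[["chrom", "start", "end"]], new], ignore_index=True)
    )


# ---------------------------------------------------------------------------
# scenario builders
# ---------------------------------------------------------------------------

def panmictic_config(
    seed: int,
    N: float = 10_000,
    n_diploid: int = 2,
    sample_times: Optional[Sequence[float]] = None,
    **kwargs,
) -> SynthConfig:
    """Single random-mating population; optionally ancient samples."""
    demog = msprime.Demography()
    demog.add_population(name="POP", initial_size=N)
    if sample_times is None:
        samples = [SampleSpec("POP", n=n_diploid)]
    else:
        samples = [SampleSpec("POP", n=1, time=t) for t in sample_times]
    return SynthConfig(seed=seed, demography=demog, samples=samples, **kwargs)


def _add_island_group(
    demog: msprime.Demography,
    prefix: str,
    deme_size: float,
    n_demes: int,
    migration: float,
    t_found: float,
    trunk: str,
) -> List[str]:
    """Attach an island metapopulation (demes founded `t_found` generations
    ago from `trunk`) to a demography. `migration` is the total per-generation
    emigration probability of a lineage, split evenly among other demes."""
    demes = [f"{prefix}{i}" for i in range(n_demes)]
    for d in demes:
        demog.add_population(name=d, initial_size=deme_size)
    if n_demes > 1 and migration > 0:
        demog.set_symmetric_migration_rate(demes, migration / (n_demes - 1))
    demog.add_population_split(time=t_found, derived=demes, ancestral=trunk)
    return demes


def inbred_config(
    seed: int,
    deme_size: float = 25,
    n_demes: int = 10,
    migration: float = 1e-3,
    n_diploid: int = 1,
    t_found: float = 5_000,
    N_anc: float = 10_000,
    **kwargs,
) -> SynthConfig:
    """Island metapopulation producing inbred individuals with long HBD
    tracts. Samples are drawn one diploid per deme, cycling."""
    if deme_size < 2 or n_demes < 1 or not (0 <= migration <= 1):
        raise ValueError("require deme_size >= 2, n_demes >= 1, 0 <= m <= 1")
    demog = msprime.Demography()
    demog.add_population(name="ANC", initial_size=N_anc)
    if n_demes == 1:
        # degenerate case: one deme = a single population of size deme_size
        demog.add_population(name="D0", initial_size=deme_size)
        demog.add_population_split(time=t_found, derived=["D0"], ancestral="ANC")
        demes = ["D0"]
    else:
        demes = _add_island_group(
            demog, "D", deme_size, n_demes, migration, t_found, "ANC"
        )
    demog.sort_events()
    samples = [SampleSpec(demes[i % n_demes], n=1) for i in range(n_diploid)]
    cfg = SynthConfig(seed=seed, demography=demog, samples=samples, **kwargs)
    if cfg.hbd_truth_samples is None:
        cfg.hbd_truth_samples = cfg.sample_names()
    return cfg


def simulate_inbred_individual(
    deme_size: float,
    n_demes: int,
    migration: float,
    seed: int = 1,
    **kwargs,
):
    """One diploid from an island metapopulation with its true HBD tracts.

    Returns (SiteTable, GeneticMap, true HBD IntervalTrack).
    """
    cfg = inbred_config(
        seed, deme_size=deme_size, n_demes=n_demes, migration=migration, **kwargs
    )
    table, gmap, truth = simulate_dataset(cfg)
    name = cfg.sample_names()[0]
    return table, gmap, truth.hbd[name]


# Default band substructure for autozygous-genome studies: band size 10 and
# per-lineage escape rate 0.065 give an expected autozygous fraction
# 1/(1 + 4*N*m) ~ 0.28, of which the mass in tracts >= 2.5 cM — the reported
# f — lands in the 0.2–0.25 range typical of the most inbred archaic genomes.
DEFAULT_BANDS = {"band_size": 10, "escape_rate": 0.065, "t_found": 100}


def split_config(
    seed: int,
    T_split: float = 3_500,
    N: float = 10_000,
    N_anc: float = 10_000,
    n_per_pop: int = 10,
    substructure: Optional[dict] = None,
    three_pops: bool = False,
    T_split2: Optional[float] = None,
    **kwargs,
) -> SynthConfig:
    """Two (or three) diverged populations for F_ST studies.

    Two substructure modes produce autozygous single genomes while cohort
    allele frequencies remain those of the wider population:

    * island (dict: deme_size, n_demes, migration, t_found) — each
      population is an island metapopulation founded from its trunk and
      cohorts are sampled across demes;
    * bands (dict: band_size, escape_rate, t_found) — every sampled diploid
      lives in its own small band attached to the trunk by one-way lineage
      escape at ``escape_rate`` per lineage per generation. Within-band
      pair coalescence (rate 1/(2*band_size)) against escape (rate
      2*escape_rate) makes the autozygous genome fraction approximately
      1 / (1 + 4*N_band*escape_rate), concentrated in long tracts — the
      close-kin mating signature — over a clean deep background.
    """
    demog = msprime.Demography()
    demog.add_population(name="ANC", initial_size=N_anc)
    pops = ["A", "B", "C"] if three_pops else ["A", "B"]
    for p in pops:
        demog.add_population(name=p, initial_size=N)
    if three_pops:
        t2 = T_split2 if T_split2 is not None else 4 * T_split
        demog.add_population(name="AB", initial_size=N_anc)
        demog.add_population_split(time=T_split, derived=["A", "B"], ancestral="AB")
        demog.add_population_split(time=t2, derived=["AB", "C"], ancestral="ANC")
    else:
        demog.add_population_split(time=T_split, derived=["A", "B"], ancestral="ANC")

    samples = []
    if substructure is None:
        for p in pops:
            samples.append(SampleSpec(p, n=n_per_pop))
    elif "band_size" in substructure:
        ss = dict(substructure)
        t_found = ss.get("t_found", 100)
        if t_found >= T_split:
            raise ValueError("band founding must be more recent than the split")
        for p in pops:
            demog[p].initially_active = True  # lineages escape into the trunk
            bands = [f"{p}b{i}" for i in range(n_per_pop)]
            for b in bands:
                demog.add_population(name=b, initial_size=ss["band_size"])
                demog.set_migration_rate(source=b, dest=p, rate=ss["escape_rate"])
            demog.add_population_split(time=t_found, derived=bands, ancestral=p)
            for b in bands:
                samples.append(SampleSpec(b, n=1))
    else:
        ss = dict(substructure)
        t_found = ss.get("t_found", 1_000)
        if t_found >= T_split:
            raise ValueError("deme founding must be more recent than the split")
        for p in pops:
            demes = _add_island_group(
                demog,
                f"{p}d",
                ss["deme_size"],
                ss["n_demes"],
                ss["migration"],
                t_found,
                p,
            )
            for i in range(n_per_pop):
                samples.append(SampleSpec(demes[i % len(demes)], n=1))
    demog.sort_events()
    return SynthConfig(seed=seed, demography=demog, samples=samples, **kwargs)


def introgression_config(
    seed: int,
    T_split: float = 14_000,
    t_pulse: float = 1_500,
    fraction: float = 0.05,
    N_target: float = 3_000,
    N_donor: float = 2_000,
    N_anc: float = 10_000,
    T_sib: float = 4_000,
    n_target: int = 1,
    target_times: Optional[Sequence[float]] = None,
    **kwargs,
) -> SynthConfig:
    """Archaic introgression scenario: a Denisovan-like DONOR pulses into a
    Neandertal-like TARGET; SIB is an unadmixed sister of TARGET used as the
    background panel; OUT is a deep outgroup for polarization checks.
    """
    if not t_pulse < T_sib < T_split:
        raise ValueError("need t_pulse < T_sib < T_split")
    demog = msprime.Demography()
    demog.add_population(name="ANC", initial_size=N_anc)
    demog.add_population(name="NEA", initial_size=N_target)
    demog.add_population(name="TARGET", initial_size=N_target)
    demog.add_population(name="SIB", initial_size=N_target)
    demog.add_population(name="DONOR", initial_size=N_donor)
    demog.add_population(name="ARCH", initial_size=N_anc)
    demog.add_population(name="OUT", initial_size=10_000)
    demog.add_mass_migration(
        time=t_pulse, source="TARGET", dest="DONOR", proportion=fraction
    )
    demog.add_population_split(
        time=T_sib, derived=["TARGET", "SIB"], ancestral="NEA"
    )
    demog.add_population_split(
        time=T_split, derived=["NEA", "DONOR"], ancestral="ARCH"
    )
    demog.add_population_split(
        time=20_000 if T_split < 20_000 else 1.5 * T_split,
        derived=["ARCH", "OUT"],
        ancestral="ANC",
    )
    demog.sort_events()
    if target_times is None:
        samples = [SampleSpec("TARGET", n=n_target)]
    else:
        samples = [SampleSpec("TARGET", n=1, time=t) for t in target_times]
    samples += [SampleSpec("SIB", n=1), SampleSpec("DONOR", n=1), SampleSpec("OUT", n=1)]
    return SynthConfig(
        seed=seed,
        demography=demog,
        samples=samples,
        pulse=PulseSpec(time=t_pulse, fraction=fraction, source="DONOR", dest="TARGET"),
        **kwargs,
    )


def trio_config(
    seed: int,
    topology: str = "asymmetric",
    T_recent: float = 2_000,
    T_deep: float = 6_000,
    T_out: float = 20_000,
    N: float = 10_000,
    **kwargs,
) -> SynthConfig:
    """Four-population scenario for D-statistics.

    ``asymmetric``: ((P1,P3),P2) — P1 and P3 split at T_recent, their
    ancestor and P2 at T_deep; a D(P1, P2; P3, OUT) test should be
    significantly positive (P3 shares more derived alleles with P1).
    ``symmetric``: P1 and P2 split from one another at T_recent and P3 is an
    equidistant relative — D should be consistent with zero.
    """
    demog = msprime.Demography()
    demog.add_population(name="ANC", initial_size=N)
    for p in ("P1", "P2", "P3"):
        demog.add_population(name=p, initial_size=N)
    demog.add_population(name="INT", initial_size=N)
    demog.add_population(name="OUT", initial_size=N)
    if topology == "asymmetric":
        demog.add_population_split(time=T_recent, derived=["P1", "P3"], ancestral="INT")
        demog.add_population_split(time=T_deep, derived=["INT", "P2"], ancestral="ANC")
    elif topology == "symmetric":
        demog.add_population_split(time=T_recent, derived=["P1", "P2"], ancestral="INT")
        demog.add_population_split(time=T_deep, derived=["INT", "P3"], ancestral="ANC")
    else:
        raise ValueError(f"unknown topology {topology!r}")
    demog.add_population(name="ROOT", initial_size=N)
    demog.add_population_split(time=T_out, derived=["ANC", "OUT"], ancestral="ROOT")
    demog.sort_events()
    samples = [SampleSpec(p, n=1) for p in ("P1", "P2", "P3", "OUT")]
    return SynthConfig(seed=seed, demography=demog, samples=samples, **kwargs)
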