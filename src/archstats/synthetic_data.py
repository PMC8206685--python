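"""Coalescent simulation of the serial-founder + archaic-admixture scenario.

The demography is a chimpanzee outgroup, two sister archaic lineages
(Neanderthal and Denisovan), an African population and six serially founded
non-African populations linked by bidirectional stepping-stone migration.
Forward in time: the non-African lineage leaves Africa at 70 kyr ago through
a severe bottleneck (size factor 0.007 until 68.5 kyr), receives a pulse of
Neanderthal ancestry at 60 kyr, then buds off daughter populations every
2 kyr from 50 kyr until six demes exist; the last-founded deme receives a
Denisovan pulse at 40 kyr.  The archaics split from each other at 450 kyr,
from humans at 500 kyr, and the chimpanzee at 6 Myr.  Independent 500-kb
fragments are simulated with msprime and converted to the same
:class:`~archstats.genotype_io.AlignedSiteTable` representation the real-data
readers produce, so every downstream statistic runs unchanged on simulated
data.

Scaling: with a diploid reference size N0 = 10,000, a mutation rate of 1e-8
per bp per generation and 500-kb fragments, theta = 4*N0*mu*L = 200 per
fragment and one coalescent time unit (4*N0 generations at 25 yr/generation)
is 1 Myr.  Migration rates are in units of 4*N0*m per adjacent deme pair
(the ms ``-m i j M`` convention).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, AlignedSiteTable, classify_mutation

TAXA = ("chimpanzee", "neanderthal", "denisovan")
_MAX_SEED = 2**31 - 2


@dataclass
class DemographyConfig:
    """All parameters of the simulation scenario (times in years)."""

    n0: int = 10_000                      # diploid reference population size
    generation_years: float = 25.0
    mutation_rate: float = 1e-8           # per bp per generation
    fragment_length: int = 500_000        # bp
    num_fragments: int = 1000
    rho: float = 100.0                    # 4*N0*r*L per fragment

    chimp_split: float = 6_000_000
    human_archaic_split: float = 500_000
    nea_den_split: float = 450_000
    ooa_time: float = 70_000
    bottleneck_time: float = 68_500
    bottleneck_factor: float = 0.007
    serial_founding_start: float = 50_000
    serial_founding_interval: float = 2_000
    n_non_african: int = 6

    nea_pulse_time: float = 60_000
    nea_pulse_fraction: float = 0.034
    den_pulse_time: float = 40_000
    den_pulse_fraction: float = 0.034

    migration_rate: float = 1.0           # 4*N0*m between adjacent non-African demes
    african_migration_rate: float = 0.0   # 4*N0*m between Africa and the first deme

    sample_chimp: int = 1                 # haploid lineages
    sample_archaic: int = 20
    sample_human: int = 100

    #: how many leading archaic lineages act as the called reference genome
    #: (2 = one diploid individual, matching a single homozygote-filtered
    #: archaic genome); the fraction of those lineages that must carry the
    #: derived allele for a "B" call
    archaic_genome_lineages: int = 2
    archaic_fixed_threshold: float = 1.0

    #: optional deep outgroups emulating gorilla/orangutan (extension, not
    #: part of the core scenario)
    deep_outgroups: dict = field(default_factory=dict)  # name -> split time (years)
    sample_deep_outgroup: int = 2

    #: mutation-rate multiplier on branches inside the African population more
    #: recent than the out-of-Africa split (1.0 = off); used to demonstrate
    #: that lineage-specific mutation-rate variation alone produces positive D
    african_mutation_scale: float = 1.0

    # -- derived quantities -------------------------------------------
    @property
    def theta(self) -> float:
        return 4 * self.n0 * self.mutation_rate * self.fragment_length

    @property
    def recombination_rate(self) -> float:
        return self.rho / (4 * self.n0 * self.fragment_length)

    @property
    def time_unit_years(self) -> float:
        """Years per coalescent time unit (4*N0 generations)."""
        return 4 * self.n0 * self.generation_years

    def generations(self, years: float) -> float:
        return years / self.generation_years

    def founding_times(self) -> list[float]:
        """Founding time (years ago) of non-African demes 2..n in founding
        order (deme 1 is the out-of-Africa population itself): deme 2 buds off
        at ``serial_founding_start``, the last deme most recently."""
        return [self.serial_founding_start - i * self.serial_founding_interval
                for i in range(self.n_non_african - 1)]

    @property
    def non_african_populations(self) -> list[str]:
        return [f"nonafrican_{i}" for i in range(1, self.n_non_african + 1)]

    @property
    def human_populations(self) -> list[str]:
        return ["african"] + self.non_african_populations

    @property
    def total_haploid_samples(self) -> int:
        return (self.sample_chimp + 2 * self.sample_archaic
                + (1 + self.n_non_african) * self.sample_human
                + len(self.deep_outgroups) * self.sample_deep_outgroup)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        problems = []
        founds = self.founding_times()
        order = [
            ("den_pulse_time", self.den_pulse_time),
            ("last founding", founds[-1] if founds else self.serial_founding_start),
            ("serial_founding_start", self.serial_founding_start),
            ("nea_pulse_time", self.nea_pulse_time),
            ("bottleneck_time", self.bottleneck_time),
            ("ooa_time", self.ooa_time),
            ("nea_den_split", self.nea_den_split),
            ("human_archaic_split", self.human_archaic_split),
            ("chimp_split", self.chimp_split),
        ]
        for (n1, t1), (n2, t2) in zip(order, order[1:]):
            if not t1 < t2:
                problems.append(f"{n1} ({t1}) must predate {n2} ({t2})")
        for name, frac in (("nea_pulse_fraction", self.nea_pulse_fraction),
                           ("den_pulse_fraction", self.den_pulse_fraction)):
            if not 0 <= frac < 1:
                problems.append(f"{name} must be in [0, 1)")
        for name, n in (("sample_chimp", self.sample_chimp),
                        ("sample_archaic", self.sample_archaic),
                        ("sample_human", self.sample_human),
                        ("num_fragments", self.num_fragments),
                        ("fragment_length", self.fragment_length),
                        ("n_non_african", self.n_non_african)):
            if n < 1:
                problems.append(f"{name} must be positive")
        if self.migration_rate < 0 or self.african_migration_rate < 0:
            problems.append("migration rates must be non-negative")
        if problems:
            raise ValueError("invalid demography configuration:\n  " + "\n  ".join(problems))

    # -- serialization ---------------------------------------------------
    def to_file(self, path) -> None:
        import yaml

        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "DemographyConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def command_preset(cls, **overrides) -> "DemographyConfig":
        """The variant implied by the literal ms example command: 3% pulses
        and a 400-kyr Neanderthal-Denisovan split (the prose values, 3.4% and
        450 kyr, are the package defaults)."""
        params = dict(nea_den_split=400_000, nea_pulse_fraction=0.03,
                      den_pulse_fraction=0.03)
        params.update(overrides)
        return cls(**params)


def build_demography(config: DemographyConfig):
    """Render the configuration as an :class:`msprime.Demography` (events in
    backward time)."""
    import msprime

    config.validate()
    dem = msprime.Demography()
    names = list(TAXA) + config.human_populations
    for name in names:
        dem.add_population(name=name, initial_size=config.n0, initially_active=True)
    for name in config.deep_outgroups:
        dem.add_population(name=name, initial_size=config.n0, initially_active=True)

    g = config.generations
    m_adj = config.migration_rate / (4 * config.n0)
    for i in range(1, config.n_non_african):
        dem.set_symmetric_migration_rate(
            [f"nonafrican_{i}", f"nonafrican_{i + 1}"], m_adj)
    if config.african_migration_rate > 0:
        dem.set_symmetric_migration_rate(
            ["african", "nonafrican_1"], config.african_migration_rate / (4 * config.n0))

    if config.den_pulse_fraction > 0:
        dem.add_mass_migration(
            time=g(config.den_pulse_time),
            source=f"nonafrican_{config.n_non_african}",
            dest="denisovan", proportion=config.den_pulse_fraction)
    for i, years in zip(range(2, config.n_non_african + 1), config.founding_times()):
        dem.add_population_split(
            time=g(years), derived=[f"nonafrican_{i}"], ancestral=f"nonafrican_{i - 1}")
    if config.nea_pulse_fraction > 0:
        dem.add_mass_migration(
            time=g(config.nea_pulse_time), source="nonafrican_1",
            dest="neanderthal", proportion=config.nea_pulse_fraction)
    dem.add_population_parameters_change(
        time=g(config.bottleneck_time), population="nonafrican_1",
        initial_size=config.bottleneck_factor * config.n0)
    dem.add_population_split(
        time=g(config.ooa_time), derived=["nonafrican_1"], ancestral="african")
    dem.add_population_split(
        time=g(config.nea_den_split), derived=["denisovan"], ancestral="neanderthal")
    dem.add_population_split(
        time=g(config.human_archaic_split), derived=["neanderthal"], ancestral="african")
    dem.add_population_split(
        time=g(config.chimp_split), derived=["african"], ancestral="chimpanzee")
    trunk = "chimpanzee"
    for name, years in sorted(config.deep_outgroups.items(), key=lambda kv: kv[1]):
        dem.add_population_split(time=g(years), derived=[trunk], ancestral=name)
        trunk = name
    dem.sort_events()
    return dem


def export_ms_command(config: DemographyConfig) -> str:
    """Render the scenario as an ms-style command string for audit.

    Deme indices follow the ms convention used throughout: 1 = chimpanzee,
    2 = Neanderthal, 3 = Denisovan, 4 = African, 5..(4+n) = non-African demes
    in founding order.  Times are in units of 4*N0 generations.
    """
    config.validate()
    unit_years = config.time_unit_years

    def t(years: float) -> str:
        return format(years / unit_years, "g")

    nhap = config.total_haploid_samples
    sizes = [config.sample_chimp, config.sample_archaic, config.sample_archaic]
    sizes += [config.sample_human] * (1 + config.n_non_african)
    ndeme = len(sizes)
    parts = [f"./ms {nhap} {config.num_fragments} -t {config.theta:g}",
             "-I " + " ".join(str(s) for s in [ndeme] + sizes),
             f"-r {config.rho:g} {config.fragment_length}"]
    first = 5
    last = 4 + config.n_non_african
    for i in range(first, last):
        M = format(config.migration_rate, "g")
        parts.append(f"-m {i} {i + 1} {M} -m {i + 1} {i} {M}")
    if config.african_migration_rate > 0:
        M = format(config.african_migration_rate, "g")
        parts.append(f"-m 4 {first} {M} -m {first} 4 {M}")
    new_pop = ndeme
    eps = 1e-4 * (40_000 / unit_years) / 0.04  # matches the printed +0.0001 offsets
    if config.den_pulse_fraction > 0:
        new_pop += 1
        parts.append(f"-es {t(config.den_pulse_time)} {last} "
                     f"{1 - config.den_pulse_fraction:g}")
        parts.append(f"-ej {format(config.den_pulse_time / unit_years + eps, 'g')} {new_pop} 3")
    if config.nea_pulse_fraction > 0:
        new_pop += 1
        parts.append(f"-es {t(config.nea_pulse_time)} {first} "
                     f"{1 - config.nea_pulse_fraction:g}")
        parts.append(f"-ej {format(config.nea_pulse_time / unit_years + eps, 'g')} {new_pop} 2")
    for i, years in zip(range(config.n_non_african, 1, -1),
                        reversed(config.founding_times())):
        parts.append(f"-ej {t(years)} {i + 4} {i + 3}")
    parts.append(f"-ej {t(config.ooa_time)} {first} 4")
    parts.append(f"-en {t(config.bottleneck_time)} {first} {config.bottleneck_factor:g}")
    parts.append(f"-ej {t(config.nea_den_split)} 3 2")
    parts.append(f"-ej {t(config.human_archaic_split)} 4 2")
    parts.append(f"-ej {t(config.chimp_split)} 2 1")
    return " ".join(parts)


@dataclass
class SimReplicate:
    """One simulated fragment: a site-by-haplotype derived-allele matrix plus
    the allele pair (ancestral, derived base) of every site and the mapping
    from taxon/population label to haplotype columns."""

    fragment_index: int
    positions: np.ndarray          # 1-based positions within the fragment
    ancestral: np.ndarray          # ancestral base per site (str)
    derived: np.ndarray            # derived base per site (str)
    matrix: np.ndarray             # (n_sites, n_haplotypes) int8 of 0/1
    sample_sets: dict[str, slice]  # label -> haplotype column range

    def __post_init__(self) -> None:
        n_sites, n_hap = self.matrix.shape
        if not (len(self.positions) == len(self.ancestral) == len(self.derived) == n_sites):
            raise ValueError("inconsistent replicate dimensions")
        top = max((s.stop for s in self.sample_sets.values()), default=0)
        if top > n_hap:
            raise ValueError("sample sets exceed haplotype matrix width")


def _sample_layout(config: DemographyConfig) -> dict[str, slice]:
    layout: dict[str, slice] = {}
    at = 0
    for name, n in [("chimpanzee", config.sample_chimp),
                    ("neanderthal", config.sample_archaic),
                    ("denisovan", config.sample_archaic)]:
        layout[name] = slice(at, at + n)
        at += n
    for pop in config.human_populations:
        layout[pop] = slice(at, at + config.sample_human)
        at += config.sample_human
    for name in config.deep_outgroups:
        layout[name] = slice(at, at + config.sample_deep_outgroup)
        at += config.sample_deep_outgroup
    return layout


def _extra_african_mutations(ts, config: DemographyConfig, rng: np.random.Generator):
    """Poisson-sample additional mutations on branches whose child node lives
    in the African population more recently than the out-of-Africa split,
    emulating an elevated African mutation rate (heterozygote-instability
    style).

    Returns a list of ``(position, carrier sample columns)`` sorted by
    position; carriers are the samples subtended by the mutated branch.
    Positions are drawn on the discrete genome, so extra mutations can hit
    existing sites — those recurrent hits (including back mutations at sites
    where the derived allele is otherwise fixed) are exactly what lets an
    elevated African rate masquerade as an introgression signal.
    """
    afr_id = next(i for i, p in enumerate(ts.tables.populations)
                  if (p.metadata or {}).get("name") == "african")
    ooa_gen = config.generations(config.ooa_time)
    extra_rate = (config.african_mutation_scale - 1.0) * config.mutation_rate
    node_time = ts.tables.nodes.time
    node_pop = ts.tables.nodes.population
    hits: list[tuple[int, int]] = []  # (0-based position, child node)
    for edge in ts.edges():
        if node_pop[edge.child] != afr_id or node_time[edge.child] >= ooa_gen:
            continue
        tspan = min(node_time[edge.parent], ooa_gen) - node_time[edge.child]
        lam = extra_rate * (edge.right - edge.left) * tspan
        for _ in range(rng.poisson(lam)):
            hits.append((int(rng.integers(edge.left, edge.right)), edge.child))
    hits.sort()
    out = []
    it = iter(ts.trees())
    tree = next(it)
    for pos, child in hits:
        while tree.interval.right <= pos:
            tree = next(it)
        carriers = np.fromiter(tree.samples(child), dtype=np.int64)
        if carriers.size:
            out.append((pos, carriers))
    return out


_OTHER_BASES = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _apply_extra_mutations(positions, anc, der, matrix, extra, rng):
    """Overlay extra (African-branch) mutations on a fragment's site arrays.

    A hit at a new position creates an African-private site; a hit at an
    existing position mutates the carriers to a random different base --
    a back mutation to the site's other allele flips their state, any third
    base makes the site triallelic and removes it.
    """
    index = {int(p): i for i, p in enumerate(positions)}
    drop: set[int] = set()
    new_rows = []
    seen_new: set[int] = set()
    n_hap = matrix.shape[1] if matrix.size else 0
    for pos0, carriers in extra:
        pos = pos0 + 1
        if pos in index:
            i = index[pos]
            if i in drop:
                continue
            vals = matrix[i, carriers]
            if vals.min() != vals.max():  # carriers straddle a newer mutation
                continue
            cur = der[i] if vals[0] == 1 else anc[i]
            other = anc[i] if vals[0] == 1 else der[i]
            new_base = _OTHER_BASES[cur][rng.integers(3)]
            if new_base == other:
                matrix[i, carriers] = 1 - vals[0]
            else:
                drop.add(i)
        elif pos not in seen_new:
            seen_new.add(pos)
            a = "ACGT"[rng.integers(4)]
            d = _OTHER_BASES[a][rng.integers(3)]
            row = np.zeros(n_hap, dtype=np.int8)
            row[carriers] = 1
            new_rows.append((pos, a, d, row))
    keep = np.array([i not in drop for i in range(len(positions))], dtype=bool)
    positions, anc, der = positions[keep], anc[keep], der[keep]
    matrix = matrix[keep] if matrix.size else matrix
    if new_rows:
        positions = np.append(positions, [r[0] for r in new_rows])
        anc = np.append(anc, [r[1] for r in new_rows])
        der = np.append(der, [r[2] for r in new_rows])
        stacked = np.vstack([r[3] for r in new_rows])
        matrix = np.vstack([matrix, stacked]) if matrix.size else stacked
    return positions, anc, der, matrix


def simulate(config: DemographyConfig, seed: int,
             num_fragments: int | None = None) -> Iterator[SimReplicate]:
    """Simulate independent fragments under the configured demography.

    Yields one :class:`SimReplicate` per fragment.  A master seed
    deterministically derives per-fragment ancestry and mutation seeds, so
    identical (config, seed) pairs reproduce identical site tables.
    """
    import msprime

    config.validate()
    nfrag = config.num_fragments if num_fragments is None else num_fragments
    dem = build_demography(config)
    layout = _sample_layout(config)
    samples = [msprime.SampleSet(sl.stop - sl.start, population=name, ploidy=1)
               for name, sl in layout.items()]
    rng = np.random.default_rng(seed)
    anc_seed = int(rng.integers(1, _MAX_SEED))
    mut_seeds = rng.integers(1, _MAX_SEED, size=nfrag)
    extra_rng = np.random.default_rng(rng.integers(1, _MAX_SEED))
    replicates = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=config.fragment_length,
        recombination_rate=config.recombination_rate, ploidy=2,
        num_replicates=nfrag, random_seed=anc_seed)
    for index, ts in enumerate(replicates):
        mts = msprime.sim_mutations(ts, rate=config.mutation_rate,
                                    random_seed=int(mut_seeds[index]))
        positions, anc, der, rows = [], [], [], []
        for var in mts.variants():
            alleles = var.alleles
            if len(alleles) != 2:  # recurrent/multiallelic: excluded before any statistic
                continue
            positions.append(int(var.site.position) + 1)
            anc.append(var.site.ancestral_state)
            derived = alleles[1] if alleles[0] == var.site.ancestral_state else alleles[0]
            der.append(derived)
            derived_idx = alleles.index(derived)
            rows.append((var.genotypes == derived_idx).astype(np.int8))
        matrix = (np.vstack(rows) if rows
                  else np.empty((0, mts.num_samples), dtype=np.int8))
        positions = np.asarray(positions, dtype=np.int64)
        anc = np.asarray(anc, dtype=object)
        der = np.asarray(der, dtype=object)
        if config.african_mutation_scale != 1.0:
            extra = _extra_african_mutations(mts, config, extra_rng)
            if matrix.size == 0:
                matrix = np.empty((0, mts.num_samples), dtype=np.int8)
            positions, anc, der, matrix = _apply_extra_mutations(
                positions, anc, der, matrix, extra, extra_rng)
        order = np.argsort(positions, kind="stable")
        yield SimReplicate(index, positions[order], anc[order], der[order],
                           matrix[order] if matrix.size else matrix, dict(layout))


def sim_to_site_table(
    replicates: Iterable[SimReplicate],
    config: DemographyConfig,
    focal_per_pop: int = 2,
) -> AlignedSiteTable:
    """Convert simulated replicates to the aligned-site-table representation.

    The chimpanzee lineage defines the ancestral allele "A" at every site
    (exactly as in the real-data polarization); archaic taxon states follow
    the reference-genome rule (first ``archaic_genome_lineages`` lineages,
    state B only when the derived-allele fraction among them reaches
    ``archaic_fixed_threshold``, A when it is at most 1 - threshold, missing
    otherwise).  Sites monomorphic across all samples, or with more than two
    observed alleles, are dropped.  The fragment index (1-based) becomes the
    chromosome label so genome-scan operations can group fragments.

    ``focal_per_pop`` diploid individuals per human population (consecutive
    haplotype pairs) are retained as per-sample genotypes named
    ``<population>_d<k>``.
    """
    frames = []
    human_pops = config.human_populations
    glin = config.archaic_genome_lineages
    thr = config.archaic_fixed_threshold
    for rep in replicates:
        if rep.matrix.shape[0] == 0:
            continue
        m = rep.matrix
        chimp_sl = rep.sample_sets["chimpanzee"]
        chimp_derived = m[:, chimp_sl].mean(axis=1) == 1.0  # chimp-branch mutations
        # polarize: B = the allele the chimpanzee does not carry
        b = np.where(chimp_derived[:, None], 1 - m, m).astype(np.int8)
        allele_a = np.where(chimp_derived, rep.derived, rep.ancestral)
        allele_b = np.where(chimp_derived, rep.ancestral, rep.derived)
        # biallelic across taxa: both alleles must actually be observed
        bsum = b.sum(axis=1)
        keep = (bsum > 0) & (bsum < b.shape[1])
        if not keep.any():
            continue
        b, allele_a, allele_b = b[keep], allele_a[keep], allele_b[keep]
        data = {
            "chrom": np.full(keep.sum(), str(rep.fragment_index + 1), dtype=object),
            "pos": rep.positions[keep],
            "allele_A": allele_a,
            "allele_B": allele_b,
            "mutation_class": [classify_mutation(a, d)
                               for a, d in zip(allele_a, allele_b)],
            "state_chimpanzee": np.zeros(keep.sum(), dtype=np.int8),
        }
        for taxon in ("neanderthal", "denisovan"):
            genome = b[:, rep.sample_sets[taxon]][:, :glin]
            frac = genome.mean(axis=1)
            state = np.full(len(frac), MISSING, dtype=np.int8)
            state[frac >= thr] = 1
            state[frac <= 1.0 - thr] = 0
            data[f"state_{taxon}"] = state
        for taxon in config.deep_outgroups:
            genome = b[:, rep.sample_sets[taxon]]
            frac = genome.mean(axis=1)
            state = np.full(len(frac), MISSING, dtype=np.int8)
            state[frac >= thr] = 1
            state[frac <= 1.0 - thr] = 0
            data[f"state_{taxon}"] = state
        for pop in human_pops:
            sub = b[:, rep.sample_sets[pop]]
            data[f"bcount_{pop}"] = sub.sum(axis=1).astype(np.int64)
            data[f"ncalled_{pop}"] = np.full(sub.shape[0], sub.shape[1], dtype=np.int64)
        for pop in human_pops:
            start = rep.sample_sets[pop].start
            for k in range(focal_per_pop):
                pair = b[:, start + 2 * k: start + 2 * k + 2]
                data[f"gt_{pop}_d{k + 1}"] = pair.sum(axis=1).astype(np.int8)
        frames.append(pd.DataFrame(data))
    if not frames:
        empty = pd.DataFrame(columns=["chrom", "pos", "allele_A", "allele_B",
                                      "mutation_class"])
        return AlignedSiteTable(empty)
    return AlignedSiteTable(pd.concat(frames, ignore_index=True))


def run_migration_sweep(
    config: DemographyConfig,
    rates: Iterable[float],
    seed: int,
    num_fragments: int | None = None,
    conditioned: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run one full simulation per migration rate and tabulate the statistic
    profiles (nd, heterozygosity, AFD, F_ST, D) underlying the migration-rate
    comparison figures.

    Returns tidy tables: ``per_population`` (rate x population: nd_nea,
    nd_den, het, founding order), ``per_pair`` (rate x non-African pair: AFD
    and F_ST), and ``per_rate`` (aggregate D of African vs first non-African
    against the Neanderthal).  Per-rate seeds derive deterministically from
    the master seed, which is recorded in every table.
    """
    from .introgression_stats import (compute_AFD, compute_D, compute_FST,
                                      compute_heterozygosity, compute_nd)

    rates = list(rates)
    if any(r <= 0 for r in rates):
        raise ValueError("migration rates must be positive")
    rng = np.random.default_rng(seed)
    rate_seeds = rng.integers(1, _MAX_SEED, size=len(rates))
    pop_rows, pair_rows, rate_rows = [], [], []
    panel = ("african",)
    for rate, rate_seed in zip(rates, rate_seeds):
        cfg = dataclasses.replace(config, migration_rate=float(rate))
        table = sim_to_site_table(
            simulate(cfg, int(rate_seed), num_fragments=num_fragments), cfg)
        for order, pop in enumerate(cfg.human_populations):
            nd_nea = compute_nd(table, pop, "neanderthal", conditioned=conditioned,
                                conditioning_panel=panel)
            nd_den = compute_nd(table, pop, "denisovan", conditioned=conditioned,
                                conditioning_panel=panel)
            pop_rows.append(dict(seed=seed, rate=rate, population=pop,
                                 founding_order=order, nd_nea=nd_nea.nd,
                                 nd_den=nd_den.nd,
                                 het=compute_heterozygosity(table, pop)))
        nonafr = cfg.non_african_populations
        for i, pa in enumerate(nonafr):
            for pb in nonafr[i + 1:]:
                afd = compute_AFD(table, pa, pb)
                fst = compute_FST(table, pa, pb)
                pair_rows.append(dict(seed=seed, rate=rate, pop_a=pa, pop_b=pb,
                                      afd=afd.value, fst=fst.value,
                                      n_sites=afd.n_sites))
        d = compute_D(table, "african", "nonafrican_1", "neanderthal")
        rate_rows.append(dict(seed=seed, rate=rate, D=d.D, abba=d.abba,
                              baba=d.baba, n_sites=len(table)))
    return {"per_population": pd.DataFrame(pop_rows),
            "per_pair": pd.DataFrame(pair_rows),
            "per_rate": pd.DataFrame(rate_rows)}
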