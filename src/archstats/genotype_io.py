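"""Reading of human/archaic/outgroup variant calls and assembly of the
multi-taxon aligned site table.

The central container is :class:`AlignedSiteTable`: one row per biallelic
site callable in every requested taxon, with alleles polarized so that the
chimpanzee always carries allele "A".  Per-population derived ("B") allele
counts, per-taxon A/B states and, optionally, per-sample diploid genotypes
for focal individuals are stored alongside.  All downstream statistics
(D, nd, f4, AFD, F_ST, heterozygosity) operate on this table, so the same
code paths serve both real VCF-derived data and coalescent simulations.

Archaic genomes are single, low-coverage individuals; their base calls are
accepted only when covered by 10-249 reads with >80% of reads supporting a
single base, and the call is then treated as homozygous for that base
(heterozygous candidates are treated as missing rather than as errors).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")
PURINES = frozenset("AG")

#: integer codes for taxon states / genotypes
MISSING = -1
STATE_A = 0
STATE_B = 1


class MalformedRecordError(ValueError):
    """Raised for structurally invalid genotype records (e.g. negative counts)."""


class InvalidSiteError(ValueError):
    """Raised for site definitions that are not a valid biallelic SNV."""


def normalize_chrom(label: str | int) -> str:
    """Normalize a chromosome label: "chr1" and "1" map to "1"."""
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


def classify_mutation(base1: str, base2: str) -> str:
    """Classify the substitution between two bases.

    Returns ``"transition"`` for purine<->purine or pyrimidine<->pyrimidine
    changes ({A,G} or {C,T}) and ``"transversion"`` otherwise.
    """
    b1, b2 = base1.upper(), base2.upper()
    if b1 not in BASES or b2 not in BASES:
        raise InvalidSiteError(f"non-ACGT base in ({base1}, {base2})")
    if b1 == b2:
        raise InvalidSiteError(f"identical bases ({base1}, {base2}) do not define a SNV")
    return "transition" if (b1 in PURINES) == (b2 in PURINES) else "transversion"


@dataclass(frozen=True)
class ArchaicCall:
    """A raw archaic genotype record prior to depth/majority filtering."""

    chrom: str
    pos: int  # 1-based
    base_counts: Mapping[str, int]
    called_genotype: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        for base, count in self.base_counts.items():
            if base.upper() not in BASES:
                raise MalformedRecordError(f"non-ACGT base {base!r} at {self.chrom}:{self.pos}")
            if count < 0:
                raise MalformedRecordError(f"negative read count at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        return int(sum(self.base_counts.values()))


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    base: str | None
    reason: str


def filter_archaic_call(
    call: ArchaicCall,
    min_depth: int = 10,
    max_depth: int = 250,
    majority: float = 0.8,
) -> FilterResult:
    """Apply the archaic base-call quality filter.

    A call passes when total depth is at least ``min_depth``, strictly below
    ``max_depth``, and strictly more than ``majority`` of reads support one
    base; the call is then taken as homozygous for that base.  Candidate
    heterozygotes (no base above the majority fraction) fail and are treated
    as missing downstream.
    """
    if not call.base_counts:
        raise MalformedRecordError(f"empty base counts at {call.chrom}:{call.pos}")
    depth = call.depth
    if depth < min_depth or depth == 0:
        return FilterResult(False, None, "low_depth")
    if depth >= max_depth:
        return FilterResult(False, None, "high_depth")
    top_base, top_count = max(call.base_counts.items(), key=lambda kv: kv[1])
    if top_count / depth <= majority:
        return FilterResult(False, None, "no_majority_base")
    return FilterResult(True, top_base.upper(), "pass")


@dataclass(frozen=True)
class PopulationPanel:
    """Sample -> population -> region mapping plus coordinates and the
    conditioning panel (populations in which the derived archaic allele must
    be absent for conditioned nd)."""

    sample_to_population: Mapping[str, str]
    population_to_region: Mapping[str, str] = field(default_factory=dict)
    coordinates: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    conditioning_panel: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        pops = set(self.sample_to_population.values())
        unknown = set(self.conditioning_panel) - pops
        if unknown:
            raise ValueError(f"conditioning panel populations not present: {sorted(unknown)}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_to_population.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.sample_to_population.items() if p == population]

    @classmethod
    def from_files(
        cls,
        panel_path: str | Path,
        coords_path: str | Path | None = None,
        conditioning_panel: Iterable[str] = (),
    ) -> "PopulationPanel":
        """Read a tab-separated ``sample  population  region`` panel file and an
        optional ``population  lat  lon`` coordinates file."""
        panel = pd.read_csv(panel_path, sep="\t", header=None,
                            names=["sample", "population", "region"], comment="#")
        coords: dict[str, tuple[float, float]] = {}
        if coords_path is not None:
            cdf = pd.read_csv(coords_path, sep="\t", header=None,
                              names=["population", "lat", "lon"], comment="#")
            coords = {r.population: (float(r.lat), float(r.lon)) for r in cdf.itertuples()}
        return cls(
            sample_to_population=dict(zip(panel["sample"], panel["population"])),
            population_to_region=dict(zip(panel["population"], panel["region"])),
            coordinates=coords,
            conditioning_panel=frozenset(conditioning_panel),
        )


class AlignedSiteTable:
    """Per-site allele states and per-population derived-allele counts.

    The table is backed by a single :class:`pandas.DataFrame` with columns

    ``chrom, pos, allele_A, allele_B, mutation_class`` plus
    ``state_<taxon>`` (int8; 0 = allele A, 1 = allele B, -1 = missing),
    ``bcount_<population>`` / ``ncalled_<population>`` (integer counts of the
    B allele and of called alleles), and optionally ``gt_<sample>`` (diploid
    B-allele dosage 0/1/2, -1 = missing) for focal individuals.

    Counts rather than frequencies are stored so that serialization is exact.
    The chimpanzee state is 0 at every site by construction (polarization).
    """

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "pos", "allele_A", "allele_B", "mutation_class"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"site table missing columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)

    # -- introspection -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def taxa(self) -> list[str]:
        return [c[len("state_"):] for c in self.df.columns if c.startswith("state_")]

    @property
    def populations(self) -> list[str]:
        return [c[len("bcount_"):] for c in self.df.columns if c.startswith("bcount_")]

    @property
    def samples(self) -> list[str]:
        return [c[len("gt_"):] for c in self.df.columns if c.startswith("gt_")]

    # -- accessors ------------------------------------------------------
    def state(self, taxon: str) -> np.ndarray:
        """Per-site A/B state of a taxon as int8 (0/1, -1 missing)."""
        return self.df[f"state_{taxon}"].to_numpy(dtype=np.int8)

    def b_count(self, population: str) -> np.ndarray:
        return self.df[f"bcount_{population}"].to_numpy(dtype=np.int64)

    def n_called(self, population: str) -> np.ndarray:
        return self.df[f"ncalled_{population}"].to_numpy(dtype=np.int64)

    def frequency(self, population: str) -> np.ndarray:
        """Per-site B-allele frequency; NaN where no allele was called."""
        n = self.n_called(population).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.b_count(population) / n, np.nan)

    def dosage(self, sample: str) -> np.ndarray:
        """Diploid B dosage (0/1/2) of a focal sample, -1 missing."""
        return self.df[f"gt_{sample}"].to_numpy(dtype=np.int8)

    def class_mask(self, mutation_class: str = "both") -> np.ndarray:
        if mutation_class in ("both", "all"):
            return np.ones(len(self.df), dtype=bool)
        singular = {"transitions": "transition", "transversions": "transversion"}
        cls = singular.get(mutation_class, mutation_class)
        if cls not in ("transition", "transversion"):
            raise ValueError(f"unknown mutation class {mutation_class!r}")
        return (self.df["mutation_class"] == cls).to_numpy()

    def subset(self, mask: np.ndarray) -> "AlignedSiteTable":
        return AlignedSiteTable(self.df.loc[np.asarray(mask, dtype=bool)].copy())

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the table as tab-separated text (integer/string columns only,
        so the round trip through :meth:`from_tsv` is exact)."""
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlignedSiteTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        for col in df.columns:
            if col.startswith(("state_", "gt_")):
                df[col] = df[col].astype(np.int8)
        return cls(df)

    def equals(self, other: "AlignedSiteTable") -> bool:
        return self.df.equals(other.df)


@dataclass
class BuildReport:
    """Counters for sites dropped while assembling a table."""

    n_retained: int = 0
    n_multiallelic: int = 0
    n_indel: int = 0
    n_missing_outgroup: int = 0
    n_missing_taxon: int = 0
    n_monomorphic: int = 0


def read_site_calls(
    path: str | Path,
    kind: str = "auto",
    filter_kwargs: Mapping | None = None,
) -> dict[tuple[str, int], str]:
    """Read per-site single-base calls for an archaic or outgroup taxon.

    Two formats are supported:

    * a VCF with AD (allelic depth) or equivalent per-base read counts, to
      which the archaic call filter is applied (``kind="vcf"``), and
    * a tab-separated ``chrom  pos  base`` table of pre-made calls, e.g. an
      ancestral-allele annotation (``kind="table"``).

    Returns a mapping ``(chrom, pos) -> base`` with normalized chromosome
    labels and 1-based positions.
    """
    path = Path(path)
    if kind == "auto":
        kind = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "table"
    calls: dict[tuple[str, int], str] = {}
    if kind == "table":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "base"],
                         comment="#", dtype={"chrom": str})
        for row in df.itertuples():
            base = str(row.base).upper()
            if base in BASES:
                calls[(normalize_chrom(row.chrom), int(row.pos))] = base
        return calls
    import cyvcf2

    kwargs = dict(filter_kwargs or {})
    for var in cyvcf2.VCF(str(path)):
        if var.ALT and any(len(a) != 1 for a in var.ALT) or len(var.REF) != 1:
            continue
        alleles = [var.REF] + list(var.ALT)
        ad = var.format("AD")
        if ad is not None:
            counts = {a: int(c) for a, c in zip(alleles, np.asarray(ad[0]).ravel()) if c > 0}
        else:
            # fall back to the called genotype with DP as pseudo-depth
            gt = var.genotypes[0]
            dp = int(var.INFO.get("DP", 0) or (var.format("DP") or [[0]])[0][0])
            picked = {alleles[i] for i in gt[:2] if i >= 0}
            if len(picked) != 1:
                continue
            counts = {picked.pop(): dp}
        try:
            result = filter_archaic_call(
                ArchaicCall(normalize_chrom(var.CHROM), var.POS, counts), **kwargs)
        except MalformedRecordError:
            continue
        if result.passed:
            calls[(normalize_chrom(var.CHROM), var.POS)] = result.base
    return calls


def build_site_table(
    human_vcf: str | Path,
    archaic_calls: Mapping[str, Mapping[tuple[str, int], str]],
    outgroup_calls: Mapping[tuple[str, int], str],
    panel: PopulationPanel,
    focal_samples: Iterable[str] = (),
    outgroup_name: str = "chimpanzee",
) -> tuple[AlignedSiteTable, BuildReport]:
    """Join human, archaic and outgroup calls into an :class:`AlignedSiteTable`.

    Only biallelic SNVs with a call in the outgroup and in every archaic taxon
    are retained; sites where more than two bases are observed across all taxa
    are dropped (counted in the report).  Alleles are polarized so the
    outgroup (chimpanzee) carries allele "A".
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(human_vcf))
    vcf_samples = list(vcf.samples)
    sample_pop = [panel.sample_to_population.get(s) for s in vcf_samples]
    pops = panel.populations
    pop_cols = {p: [i for i, sp in enumerate(sample_pop) if sp == p] for p in pops}
    focal_samples = [s for s in focal_samples if s in vcf_samples]
    focal_idx = {s: vcf_samples.index(s) for s in focal_samples}

    report = BuildReport()
    rows: list[dict] = []
    for var in vcf:
        chrom = normalize_chrom(var.CHROM)
        if len(var.REF) != 1 or any(len(a) != 1 for a in var.ALT):
            report.n_indel += 1
            continue
        if len(var.ALT) != 1:
            report.n_multiallelic += 1
            continue
        key = (chrom, var.POS)
        out_base = outgroup_calls.get(key)
        if out_base is None:
            report.n_missing_outgroup += 1
            continue
        arch_bases = {}
        ok = True
        for taxon, calls in archaic_calls.items():
            base = calls.get(key)
            if base is None:
                ok = False
                break
            arch_bases[taxon] = base
        if not ok:
            report.n_missing_taxon += 1
            continue
        observed = {var.REF.upper(), var.ALT[0].upper(), out_base} | set(arch_bases.values())
        if len(observed) > 2:
            report.n_multiallelic += 1
            continue
        if len(observed) < 2:
            report.n_monomorphic += 1
            continue
        allele_a = out_base
        allele_b = (observed - {allele_a}).pop()
        # diploid genotype array: rows = samples, entries = allele index or -1
        gts = np.asarray(var.genotype.array())[:, :2]
        is_b: dict[int, int] = {}  # allele index -> 0/1
        for idx, allele in enumerate([var.REF.upper()] + [a.upper() for a in var.ALT]):
            is_b[idx] = int(allele == allele_b)
        bmat = np.full(gts.shape, MISSING, dtype=np.int8)
        for idx, isb in is_b.items():
            bmat[gts == idx] = isb
        row = {
            "chrom": chrom,
            "pos": var.POS,
            "allele_A": allele_a,
            "allele_B": allele_b,
            "mutation_class": classify_mutation(allele_a, allele_b),
            f"state_{outgroup_name}": STATE_A,
        }
        for taxon, base in arch_bases.items():
            row[f"state_{taxon}"] = STATE_B if base == allele_b else STATE_A
        for p in pops:
            sub = bmat[pop_cols[p]]
            called = sub >= 0
            row[f"bcount_{p}"] = int(sub[called].sum())
            row[f"ncalled_{p}"] = int(called.sum())
        for s, i in focal_idx.items():
            pair = bmat[i]
            row[f"gt_{s}"] = int(pair.sum()) if (pair >= 0).all() else MISSING
        rows.append(row)
    report.n_retained = len(rows)
    logger.info("site table: %d sites retained, %d multiallelic, %d indel, "
                "%d missing outgroup, %d missing archaic",
                report.n_retained, report.n_multiallelic, report.n_indel,
                report.n_missing_outgroup, report.n_missing_taxon)
    columns = None
    if rows:
        columns = list(rows[0])
    df = pd.DataFrame(rows, columns=columns)
    if len(df):
        for col in df.columns:
            if col.startswith(("state_", "gt_")):
                df[col] = df[col].astype(np.int8)
    return AlignedSiteTable(df), report
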