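"""The introgression statistic family: D, conditioned D, nd, f4, AFD, F_ST
and expected heterozygosity, all computed from an :class:`AlignedSiteTable`.

Conventions
-----------
Sites are polarized so the chimpanzee outgroup carries allele "A"; "B" is the
putatively derived allele.  The ABBA/BABA D statistic compares two diploid
humans against an archaic genome: with the archaic carrying B and the
chimpanzee A, a site is ABBA when the first human is A and the second B, and
BABA for the reverse.  Diploid humans contribute fractionally through their
B-allele dosage (an optional haplotype mode samples one allele per site
instead).  nd sums, over sites whose derived allele is private to one archaic
(XXBAA for Neanderthal, XXABA for Denisovan), the focal population's derived
allele frequency, divided by the total number of biallelic callable sites N.
f4 is the mean over sites of the product of paired frequency differences
(p1-p2)(p3-p4).  AFD is the mean absolute frequency difference, and F_ST is
Hudson's two-population estimator combined across sites as a ratio of sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, STATE_A, STATE_B, AlignedSiteTable

CONDITIONING_MODES = ("none", "het-p1", "hom-p1", "het-p2", "hom-p2")


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class DStatResult:
    p1: str
    p2: str
    archaic: str
    abba: float
    baba: float
    n_informative: int
    conditioning: str = "none"
    defined: bool = True

    @property
    def D(self) -> float:
        if not self.defined:
            return float("nan")
        return (self.abba - self.baba) / (self.abba + self.baba)


@dataclass(frozen=True)
class NdResult:
    population: str
    focal_archaic: str
    conditioned: bool
    mutation_class: str
    numerator: float
    N: int
    n_qualifying: int

    @property
    def nd(self) -> float:
        return self.numerator / self.N if self.N > 0 else 0.0


@dataclass(frozen=True)
class F4Result:
    p1: str
    p2: str
    p3: str
    p4: str
    f4: float
    n_sites: int
    correlation: float
    defined: bool = True


@dataclass(frozen=True)
class PairwiseDistanceResult:
    statistic: str  # "AFD" | "FST"
    pop_a: str
    pop_b: str
    value: float
    n_sites: int
    defined: bool = True


# ---------------------------------------------------------------------------
# helpers


def classify_site_pattern(p1_dosage: int, p2_dosage: int, archaic_state: int) -> str:
    """Classify one site for two diploid humans against an archaic genome.

    Humans enter as B-allele dosages (0/1/2, -1 missing); the site is only
    informative when the archaic carries B (the chimpanzee carries A at every
    table site by construction) and the two humans are fixed for opposite
    alleles.  Heterozygous humans make the site fractionally informative in
    :func:`compute_D`; here, for the hard pattern call, they are reported
    uninformative.
    """
    if archaic_state != STATE_B:
        return "uninformative"
    if p1_dosage == MISSING or p2_dosage == MISSING:
        return "uninformative"
    if p1_dosage == 0 and p2_dosage == 2:
        return "ABBA"
    if p1_dosage == 2 and p2_dosage == 0:
        return "BABA"
    return "uninformative"


def classify_archaic_state(nea_state: int, den_state: int) -> str:
    """Five-taxon archaic-allele configuration at a polarized site.

    XXBAA: derived in Neanderthal only; XXABA: derived in Denisovan only;
    XXBBA: both archaics derived (contributes to neither nd numerator).
    """
    if nea_state == MISSING or den_state == MISSING:
        return "other"
    if nea_state == STATE_B and den_state == STATE_A:
        return "XXBAA"
    if nea_state == STATE_A and den_state == STATE_B:
        return "XXABA"
    if nea_state == STATE_B and den_state == STATE_B:
        return "XXBBA"
    return "other"


def _frequency_vector(table: AlignedSiteTable, name: str) -> np.ndarray:
    """Resolve a population, taxon or focal-sample name to a per-site
    B-allele frequency vector (NaN = missing)."""
    if name in table.populations:
        return table.frequency(name)
    if name in table.taxa:
        state = table.state(name).astype(float)
        return np.where(state == MISSING, np.nan, state)
    if name in table.samples:
        dosage = table.dosage(name).astype(float)
        return np.where(dosage == MISSING, np.nan, dosage / 2.0)
    raise KeyError(f"{name!r} is not a population, taxon or focal sample of this table")


# ---------------------------------------------------------------------------
# statistics


def compute_D(
    table: AlignedSiteTable,
    p1: str,
    p2: str,
    archaic: str,
    conditioning: str = "none",
    mode: str = "frequency",
    seed: int | None = None,
) -> DStatResult:
    """ABBA/BABA D between two humans versus an archaic genome.

    ``p1``/``p2`` are focal-sample names (diploid individuals) or population
    names; per-site B frequencies weight the two patterns, so a heterozygous
    site is ABBA with probability equal to the second human's B frequency
    times the first human's A frequency.  ``mode="haplotype"`` instead samples
    one allele per human per site with a seeded RNG.  ``conditioning``
    restricts sites on the zygosity of one focal human (requires that human
    to be a diploid sample): "het-p1", "hom-p1", "het-p2", "hom-p2".

    When no informative site remains the result is flagged undefined rather
    than raising.
    """
    if p1 == p2:
        return DStatResult(p1, p2, archaic, 0.0, 0.0, 0, conditioning, defined=False)
    if conditioning not in CONDITIONING_MODES:
        raise ValueError(f"unknown conditioning {conditioning!r}")
    x1 = _frequency_vector(table, p1)
    x2 = _frequency_vector(table, p2)
    arch = table.state(archaic)
    keep = (arch == STATE_B) & ~np.isnan(x1) & ~np.isnan(x2)

    if conditioning != "none":
        which, target = conditioning.split("-")[0], conditioning.split("-")[1]
        name = p1 if target == "p1" else p2
        if name not in table.samples:
            raise ValueError(
                f"conditioning {conditioning!r} requires {name!r} to be a diploid focal sample")
        dosage = table.dosage(name)
        zyg = dosage == 1 if which == "het" else (dosage == 0) | (dosage == 2)
        keep &= zyg & (dosage != MISSING)

    x1, x2 = x1[keep], x2[keep]
    if mode == "haplotype":
        rng = np.random.default_rng(seed)
        x1 = (rng.random(x1.shape) < x1).astype(float)
        x2 = (rng.random(x2.shape) < x2).astype(float)
    elif mode != "frequency":
        raise ValueError(f"unknown mode {mode!r}")
    abba = float(((1.0 - x1) * x2).sum())
    baba = float((x1 * (1.0 - x2)).sum())
    informative = int(np.count_nonzero((x1 != x2)))
    if abba + baba == 0:
        return DStatResult(p1, p2, archaic, abba, baba, informative, conditioning, defined=False)
    return DStatResult(p1, p2, archaic, abba, baba, informative, conditioning)


def _archaic_private_mask(
    table: AlignedSiteTable,
    focal_archaic: str,
    neanderthal: str = "neanderthal",
    denisovan: str = "denisovan",
) -> np.ndarray:
    nea = table.state(neanderthal)
    den = table.state(denisovan)
    if focal_archaic in (neanderthal, "NEA", "nea"):
        return (nea == STATE_B) & (den == STATE_A)
    if focal_archaic in (denisovan, "DEN", "den"):
        return (den == STATE_B) & (nea == STATE_A)
    raise ValueError(f"unknown focal archaic {focal_archaic!r}")


def compute_nd(
    table: AlignedSiteTable,
    population: str,
    focal_archaic: str,
    conditioned: bool = True,
    mutation_class: str = "both",
    conditioning_panel: tuple[str, ...] | frozenset[str] | None = None,
    neanderthal: str = "neanderthal",
    denisovan: str = "denisovan",
) -> NdResult:
    """Average derived-archaic-allele frequency nd = sum(d_i) / N.

    Qualifying sites carry the derived allele privately in the focal archaic
    (XXBAA for Neanderthal, XXABA for Denisovan: the other archaic and the
    chimpanzee are ancestral) within the requested mutation class; when
    ``conditioned`` the B allele must additionally be absent (zero copies,
    with at least one called allele) from every conditioning-panel
    population.  d_i is the focal population's B frequency.  N is the number
    of *all* biallelic callable sites in the same mutation class, not only
    qualifying ones, so nd is comparable across populations and variants.
    """
    cls_mask = table.class_mask(mutation_class)
    N = int(cls_mask.sum())
    qual = _archaic_private_mask(table, focal_archaic, neanderthal, denisovan) & cls_mask
    if conditioned:
        if not conditioning_panel:
            raise ValueError("conditioned nd requires a non-empty conditioning panel")
        panel_b = np.zeros(len(table), dtype=np.int64)
        panel_n = np.zeros(len(table), dtype=np.int64)
        for pop in conditioning_panel:
            panel_b += table.b_count(pop)
            panel_n += table.n_called(pop)
        qual &= (panel_b == 0) & (panel_n > 0)
    freq = table.frequency(population)
    qual &= ~np.isnan(freq)
    numerator = float(freq[qual].sum())
    return NdResult(population, focal_archaic, conditioned, mutation_class,
                    numerator, N, int(qual.sum()))


def compute_f4(table: AlignedSiteTable, p1: str, p2: str, p3: str, p4: str) -> F4Result:
    """f4(P1,P2;P3,P4) = mean over sites of (p1-p2)(p3-p4).

    Any mix of populations, taxa (single genomes contribute frequency 0 or 1;
    focal diploids 0, 1/2 or 1) and focal samples is accepted.  The Pearson
    correlation of the paired differences is reported as a secondary output.
    """
    vecs = [_frequency_vector(table, p) for p in (p1, p2, p3, p4)]
    keep = ~np.isnan(vecs[0])
    for v in vecs[1:]:
        keep &= ~np.isnan(v)
    a, b, c, d = (v[keep] for v in vecs)
    n = int(keep.sum())
    if n == 0:
        return F4Result(p1, p2, p3, p4, float("nan"), 0, float("nan"), defined=False)
    d12 = a - b
    d34 = c - d
    f4 = float((d12 * d34).mean())
    if d12.std() > 0 and d34.std() > 0:
        corr = float(np.corrcoef(d12, d34)[0, 1])
    else:
        corr = float("nan")
    return F4Result(p1, p2, p3, p4, f4, n, corr)


def compute_AFD(table: AlignedSiteTable, pop_a: str, pop_b: str) -> PairwiseDistanceResult:
    """Average absolute B-allele frequency difference between two populations
    over all shared callable sites."""
    fa = _frequency_vector(table, pop_a)
    fb = _frequency_vector(table, pop_b)
    keep = ~np.isnan(fa) & ~np.isnan(fb)
    n = int(keep.sum())
    if n == 0:
        return PairwiseDistanceResult("AFD", pop_a, pop_b, float("nan"), 0, defined=False)
    value = float(np.abs(fa[keep] - fb[keep]).mean())
    return PairwiseDistanceResult("AFD", pop_a, pop_b, value, n)


def compute_FST(table: AlignedSiteTable, pop_a: str, pop_b: str) -> PairwiseDistanceResult:
    """Hudson's two-population F_ST, combined across sites as a ratio of sums.

    Per site, the numerator is (p_a - p_b)^2 - p_a(1-p_a)/(n_a-1)
    - p_b(1-p_b)/(n_b-1) and the denominator p_a(1-p_b) + p_b(1-p_a); sites
    monomorphic across both samples contribute zero to both.  Requires at
    least two called alleles per population at a site.
    """
    pa, pb = table.frequency(pop_a), table.frequency(pop_b)
    na = table.n_called(pop_a).astype(float)
    nb = table.n_called(pop_b).astype(float)
    keep = ~np.isnan(pa) & ~np.isnan(pb) & (na > 1) & (nb > 1)
    pa, pb, na, nb = pa[keep], pb[keep], na[keep], nb[keep]
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    total_den = float(den.sum())
    if total_den == 0:
        return PairwiseDistanceResult("FST", pop_a, pop_b, float("nan"),
                                      int(keep.sum()), defined=False)
    return PairwiseDistanceResult("FST", pop_a, pop_b, float(num.sum()) / total_den,
                                  int(keep.sum()))


def compute_heterozygosity(table: AlignedSiteTable, population: str,
                           mutation_class: str = "both") -> float:
    """Mean expected heterozygosity 2p(1-p) over callable sites (sample
    frequencies)."""
    mask = table.class_mask(mutation_class)
    p = table.frequency(population)[mask]
    p = p[~np.isnan(p)]
    if p.size == 0:
        return float("nan")
    return float((2.0 * p * (1.0 - p)).mean())


def heterozygosity_loss(table: AlignedSiteTable, reference_pop: str, focal_pop: str) -> float:
    """Proportional loss of expected heterozygosity of ``focal_pop`` relative
    to ``reference_pop``: 1 - H_focal / H_reference (e.g. the out-of-Africa
    bottleneck loss when the reference is the African population)."""
    h_ref = compute_heterozygosity(table, reference_pop)
    h_foc = compute_heterozygosity(table, focal_pop)
    return 1.0 - h_foc / h_ref


def nd_to_genomic_fraction(nd_value: float, reference_nd: float,
                           reference_fraction: float) -> float:
    """Rescale an nd value to a genomic introgressed fraction using a
    reference population with an assumed fraction (e.g. French at 2%
    Neanderthal, Papuans at 5% Denisovan)."""
    return nd_value / reference_nd * reference_fraction
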