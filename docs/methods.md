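# Methods

## The statistics

All statistics operate on an aligned site table: one row per biallelic SNV
with a call in every requested taxon, polarized so the chimpanzee outgroup
carries allele "A" at every site ("B" is the putatively derived allele).
Per-population derived-allele counts and call counts are stored as integers;
frequencies are derived on access, which makes serialization exact and the
conditioning rules unambiguous.

**D (ABBA/BABA).** For two humans P1, P2, an archaic P3 and the chimpanzee
P4, informative sites have P3 = B and P4 = A; ABBA means P1 = A, P2 = B and
BABA the reverse, and D = (ABBA − BABA)/(ABBA + BABA). The definition is
individual-based ("the two humans"), so the default granularity is one
diploid per side with heterozygous sites contributing fractionally through
the B-allele dosage: a site is ABBA with weight (1 − x1)·x2 where x is
dosage/2. A strict haplotype mode (one allele sampled per site with a seeded
RNG) is provided; on homozygous sites the two modes coincide. Passing a
population name instead of a sample uses the population frequency, which is
algebraically identical to averaging the individual-based counts over every
possible diploid pair from that population — same expectation, much smaller
Monte-Carlo error — and is what the large simulation runs report.
Conditioned D restricts sites to those heterozygous (or homozygous) in one
named human before counting. Zero informative sites yield a flagged result,
not NaN.

**nd.** nd = Σ d_i / N, where the sum runs over sites whose derived allele
is private to the focal archaic (Neanderthal derived + Denisovan ancestral,
or vice versa; sites where both archaics are derived qualify for neither),
d_i is the focal population's B frequency, and N is the number of *all*
biallelic callable sites in the chosen mutation class (transitions,
transversions, or both) — not just qualifying sites. Conditioning requires
the B allele to be absent (zero copies among at least one called allele)
from every population of the conditioning panel; a panel population
therefore has conditioned nd = 0 identically. A helper converts nd to a
genomic fraction by rescaling against a reference population with an assumed
fraction; it is a trivial proportionality and is not used by any analysis
here.

**f4.** Mean over sites of (p1 − p2)(p3 − p4), accepting any mix of
population frequencies, single genomes (0/1) and focal diploids (0, 1/2, 1).
The Pearson correlation of the paired differences is reported alongside,
since the correlation view is how the statistic is often described; both are
tested. f4 with P3 = P4 is exactly zero.

**AFD and F_ST.** AFD is the mean absolute B-frequency difference over
shared callable sites. F_ST is Hudson's two-population estimator, combined
across sites as a ratio of sums, chosen for robustness to rare variants (the
per-site numerator has the n−1 sample-size correction; sites monomorphic in
both samples contribute zero to both sums). The exact coalescent expectation
used as the test oracle for a symmetric two-deme island model is
F_ST = 1/(1 + 8Nm) (E[T_within] = 4N, E[T_between] = 4N + 1/(2m)); note this
differs from the infinite-island shorthand 1/(1 + 4Nm).

**Heterozygosity.** Mean of 2p(1 − p) over callable sites from sample
frequencies, without the n/(n−1) correction; the bottleneck loss
1 − H_focal/H_reference is a ratio over the same site set, so the small
bias cancels.

## The simulated scenario

The demography (msprime, diploid reference size N0 = 10,000, generation
25 yr): chimpanzee splits 6 Myr ago; archaics split from humans 500 kyr and
from each other 450 kyr ago; the non-African lineage leaves Africa 70 kyr
ago through a bottleneck (size factor 0.007 until 68.5 kyr, i.e. 70 diploids
for 60 generations), receives a 3.4% Neanderthal pulse at 60 kyr, then buds
off five daughter demes at 2-kyr intervals from 50 kyr; the last-founded
deme receives a 3.4% Denisovan pulse at 40 kyr. Adjacent non-African demes
exchange migrants at a symmetric rate expressed as 4·N0·m (the ms ``-m``
unit), swept over {1, 10, 20, 50}; African gene flow is off by default.
Samples: 1 chimpanzee, 20 lineages per archaic, 100 per human population
(741 haploid genomes). Fragments are independent 500-kb stretches with
θ = 4·N0·μ·L = 200 and ρ = 100 per fragment (μ = 1e-8/bp/gen); mutations use
JC69 on a discrete genome, so transition/transversion classes are real and
rare recurrent hits make a site multiallelic, which removes it.

An ms-style command string can be exported for audit. Two parameter
conventions exist in the scenario's description: the narrative one (450-kyr
archaic split, 3.4% pulses — the package default) and the literal example
command (400 kyr, 3%) available as ``DemographyConfig.command_preset()``.
The command's ``-r 100 25000`` pairs ρ = 100 with a site count inconsistent
with a 500-kb fragment; we keep ρ = 100 per 500 kb.

**Archaic genome states.** The real-data pipeline sees each archaic as a
single low-coverage genome restricted to homozygous calls (10 ≤ depth < 250,
>80% majority). Simulated data mimic that genome with the first
``archaic_genome_lineages`` (default 2 = one diploid) sampled archaic
lineages: state B when the derived-allele fraction among them reaches the
configured threshold (default 1, i.e. "homozygous derived"), A when none
carry it, missing otherwise — heterozygous genomes are discarded exactly as
the depth filter discards them in real data. Requiring fixation across the
full 20-lineage sample instead (configurable) is far stricter than a single
genome and shrinks both D and nd by an order of magnitude.

**Site universe.** Simulated tables retain every site with exactly two
observed alleles across all 741 sampled genomes, including sites monomorphic
within humans (e.g. chimpanzee-branch or archaic-branch substitutions).
Real-data tables are built from a human VCF and therefore contain only
human-polymorphic sites; the union universe is what the simulation's
denominators (nd's N, AFD's site count) are defined over, and a
human-polymorphic subset is one ``subset()`` call away.

**Seeds.** A master seed drives a NumPy generator from which the ancestry
seed, per-fragment mutation seeds and any extension seeds are derived; all
outputs are reproducible bit-for-bit from (config, seed), and experiment
tables record the master seed.

**Mutation-rate extension (off by default).** Setting
``african_mutation_scale`` > 1 overlays extra mutations on branches whose
child node lies in the African population more recently than the
out-of-Africa split. Positions are drawn on the discrete genome, so extra
mutations can hit existing sites: a back mutation at a site where the
archaic is derived and humans are ancestrally fixed derived flips African
carriers to "A" and manufactures ABBA excess — positive D with no admixture
at all. Hits that create a third allele drop the site (consistent with the
multiallelic rule); hits at new positions create African-private variants.
This demonstrates the confounding between admixture and lineage-specific
mutation-rate variation; the effect on D is real but small at realistic
scale factors, so the test exercises it at an exaggerated scale (100×).

## What the generator does and does not emulate

It reproduces the scenario's topology, times, pulse fractions, bottleneck
and sampling design, and it feeds the identical statistics code used for
real data. It does not model sequencing error, missing genotypes, archaic
ascertainment or coverage variation, selection, gene conversion, or realistic
recombination-rate and mutation-spectrum heterogeneity. Passing tests
therefore validate the statistics and the drift/migration logic of the
scenario, not the real-data provenance chain.

## Problem sizes and numerical choices

The full study scale is 1000 fragments; the test suite uses 120–200
fragments per scenario and the acceptance script 300 per run, with
Monte-Carlo standard errors computed by delete-one-fragment jackknife over
independent fragments (a ratio-of-sums jackknife for D, AFD and the
heterozygosity-loss ratio). Per-fragment individual-based D has a fragment
standard deviation near 0.25 — introgressed tracts are all-or-nothing for a
single diploid — so headline D values are reported at population granularity
(the pair-averaged individual statistic). Undefined statistics are flagged,
never silently NaN. Windows are half-open, 1-anchored, with partial final
windows retained; the window outlier rule (minimum informative sites,
absolute-value clip 0.004) is declared config, not an inference about the
original analysis. Pearson correlations are used throughout; p-values are
two-sided with no multiple-testing correction.

## Calibration outcomes worth knowing

Four published calibration values are checked end to end. The bottleneck
loss lands at 22–26% across seeds (target ~25%), and the migration-1 AFD at
~0.0134–0.0139 (target 0.0135). Two calibrations do not reproduce, and the
discrepancies are stable across seeds and scales: the Neanderthal-pulse-only
D comes out near 0.09–0.11 rather than "approximately 4%" (the standard
coalescent expectation for a 3.4% pulse given this topology — by the same
scaling that makes a ~2% real legacy correspond to D ≈ 5% — is ~0.1, so the
published 4% appears to reflect a different, unstated D convention), and the
migration-50 AFD comes out near 0.010 rather than 0.007 — with n = 100
sampled haplotypes per deme, pure binomial sampling noise floors AFD above
0.007 even at high migration under every site-universe convention we tried.
Both measured values are reported as computed.

## Known limitations

Land-route distances are great-circle legs through a declared waypoint
table, not least-cost paths over a landmass raster; they are intended as a
regression covariate in arbitrary units. The VCF reader expects biallelic
SNV records with standard GT (and optionally AD) fields and does not perform
genotype calling, phasing or liftover. Block-jackknife standard errors for
D/f4 on real genomes (correlated sites) are out of scope; the fragment
jackknife used here relies on the independence of simulated fragments.
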