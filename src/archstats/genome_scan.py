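"""Genome-wide consistency analyses.

Two complementary checks that a population-level signal is a property of the
whole genome rather than of a few loci: (i) per-chromosome leave-one-out
correlations of nd profiles across populations (each chromosome's profile
against the mean profile of all the others), and (ii) f4 computed in
non-overlapping megabase windows, filtered for low-information outlier
windows, and correlated between taxon configurations (e.g. Neanderthal vs
great-ape outgroups).  Simulated fragments are grouped into pseudo-
chromosomes so the same operations run on synthetic tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import AlignedSiteTable, normalize_chrom
from .introgression_stats import compute_f4, compute_nd


@dataclass
class ChromStatMatrix:
    """Rows = chromosome (or fragment-group) labels, columns = populations."""

    values: pd.DataFrame
    excluded: list = field(default_factory=list)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.values.index)

    @property
    def populations(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class WindowStatTrack:
    """Per-window statistic values in BED-like form: half-open windows
    [start, end) anchored at position 1, one value and an informative-site
    count per window."""

    windows: pd.DataFrame  # chrom, start, end, value, n_sites
    statistic: str = "f4"

    def to_tsv(self, path) -> None:
        self.windows.to_csv(path, sep="\t", index=False)


def nd_matrix(
    table: AlignedSiteTable,
    populations: list[str] | None = None,
    focal_archaic: str = "neanderthal",
    conditioned: bool = True,
    conditioning_panel=("african",),
    mutation_class: str = "both",
) -> ChromStatMatrix:
    """nd per chromosome per population (the substrate of the leave-one-out
    consistency analysis)."""
    populations = populations or table.populations
    rows = {}
    for chrom, sub in table.df.groupby("chrom", sort=False):
        subtable = AlignedSiteTable(sub)
        rows[str(chrom)] = {
            pop: compute_nd(subtable, pop, focal_archaic, conditioned=conditioned,
                            mutation_class=mutation_class,
                            conditioning_panel=conditioning_panel).nd
            for pop in populations}
    return ChromStatMatrix(pd.DataFrame.from_dict(rows, orient="index",
                                                  columns=populations))


def group_fragments(table: AlignedSiteTable, n_groups: int = 22) -> AlignedSiteTable:
    """Relabel simulated fragment chromosomes into ``n_groups``
    pseudo-chromosomes (fragment i -> group i mod n_groups) so chromosome-
    level operations can run on fragment-based tables."""
    df = table.df.copy()
    codes = pd.factorize(df["chrom"])[0]
    df["chrom"] = pd.Series((codes % n_groups) + 1).astype(str).to_numpy()
    return AlignedSiteTable(df)


def leave_one_out_correlation(matrix: ChromStatMatrix) -> pd.DataFrame:
    """For each chromosome, the Pearson r between its per-population profile
    and the mean profile of all other chromosomes.

    Returns a frame indexed by chromosome with columns ``r`` and ``defined``
    (False where a zero-variance profile leaves r undefined).  The summary
    mean is over defined rows.
    """
    vals = matrix.values
    if vals.shape[0] < 3 or vals.shape[1] < 3:
        raise ValueError("need at least 3 chromosomes and 3 populations")
    out = []
    total = vals.sum(axis=0)
    for chrom in vals.index:
        row = vals.loc[chrom]
        others = (total - row) / (len(vals) - 1)
        if row.std() == 0 or others.std() == 0:
            out.append((chrom, float("nan"), False))
            continue
        r = float(np.corrcoef(row.to_numpy(), others.to_numpy())[0, 1])
        out.append((chrom, r, True))
    return pd.DataFrame(out, columns=["chrom", "r", "defined"]).set_index("chrom")


def exclude_chromosomes(matrix: ChromStatMatrix, labels=("21",)) -> ChromStatMatrix:
    """Drop chromosomes (default: chromosome 21, which contributes far fewer
    callable sites than any other autosome).  Labels are normalized, a
    missing label is a warned no-op, and dropping every row is an error."""
    norm = {normalize_chrom(l) for l in labels}
    index_norm = {c: normalize_chrom(c) for c in matrix.values.index}
    present = {c for c, n in index_norm.items() if n in norm}
    missing = norm - set(index_norm.values())
    if missing:
        warnings.warn(f"labels not present, ignored: {sorted(missing)}")
    remaining = matrix.values.drop(index=list(present))
    if remaining.empty and len(matrix.values):
        raise ValueError("exclusion would drop every chromosome")
    return ChromStatMatrix(remaining, excluded=sorted(present))


def windowed_f4(
    table: AlignedSiteTable,
    p1: str, p2: str, p3: str, p4: str,
    window_bp: int = 1_000_000,
) -> WindowStatTrack:
    """f4 in non-overlapping windows of ``window_bp`` along each chromosome.

    Windows are half-open [start, end) anchored at position 1; the final
    partial window of each chromosome is retained.  Windows without
    informative sites get a missing value (NaN), not zero.  Requires the
    table sorted by (chrom, pos).
    """
    df = table.df
    for _, sub in df.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise ValueError("site table must be sorted by chrom, pos "
                             "(sort before windowing)")
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        last = int(pos.max())
        for start in range(1, last + 1, window_bp):
            end = start + window_bp
            chunk = sub[(pos >= start) & (pos < end)]
            if len(chunk) == 0:
                rows.append((chrom, start, end, float("nan"), 0))
                continue
            res = compute_f4(AlignedSiteTable(chunk), p1, p2, p3, p4)
            rows.append((chrom, start, end,
                         res.f4 if res.defined else float("nan"), res.n_sites))
    return WindowStatTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_sites"]),
        statistic=f"f4({p1},{p2};{p3},{p4})")


def filter_window_outliers(
    track: WindowStatTrack,
    min_sites: int = 10,
    clip: float = 0.004,
) -> tuple[WindowStatTrack, float]:
    """Drop windows with fewer than ``min_sites`` informative sites or
    |value| > ``clip`` (outliers are mostly windows with much-reduced
    information).  Returns the filtered track and the excluded fraction of
    non-missing windows."""
    if len(track.windows) == 0:
        raise ValueError("empty track")
    df = track.windows
    valued = df["value"].notna()
    bad = valued & ((df["n_sites"] < min_sites) | (df["value"].abs() > clip))
    n_valued = int(valued.sum())
    fraction = float(bad.sum() / n_valued) if n_valued else 0.0
    return WindowStatTrack(df[~bad].reset_index(drop=True), track.statistic), fraction


def correlate_tracks(track_a: WindowStatTrack, track_b: WindowStatTrack):
    """Pearson correlation of two window tracks over shared, non-missing
    windows (matched on chrom/start).  Returns (r, n, p); fewer than 3 shared
    windows yields (nan, n, nan)."""
    merged = track_a.windows.merge(track_b.windows, on=["chrom", "start"],
                                   suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["value_a", "value_b"])
    n = len(merged)
    if n < 3:
        return float("nan"), n, float("nan")
    r, p = stats.pearsonr(merged["value_a"], merged["value_b"])
    return float(r), n, float(p)
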