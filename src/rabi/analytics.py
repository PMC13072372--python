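"""Assemblage-level analytics over scored communities.

These functions reproduce the descriptive statistics typically reported
alongside the index: per-ecozone richness summaries, unique and shared
species, a chi-squared test of species composition across ecozones,
correlations among the three sub-indices, species-index and site-index
distributions, priority binning/ranking of sites, and permutation-based
species accumulation curves.

All functions are pure: given the same inputs (and seed, where sampling
is involved) they return identical results.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalyticsWarning, ValidationError
from .occurrence import OccurrenceMatrix
from .scheme import DEFAULT_SCHEME, ScoringScheme
from .scoring import SiteAssessment, SpeciesScore


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (print style of the summary tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# ecozone summaries


@dataclass(frozen=True)
class EcozoneSummary:
    """Richness summary of one ecozone (or the all-zones total row).

    ``unique_pct`` is the percentage of the zone's species recorded in no
    other zone, rounded half-up to one decimal (reporting convention);
    it is ``None`` for the total row and for zones without species.
    """

    ecozone: str
    n_sites: int
    total_species: int
    mean_species_per_site: float
    unique_species: Optional[int]
    unique_pct: Optional[float]
    most_common_species: tuple


def ecozone_summaries(
    occurrence: OccurrenceMatrix,
    ecozones: Optional[Sequence[str]] = None,
) -> list[EcozoneSummary]:
    """Per-ecozone richness, mean per-site richness, unique species and
    the most frequently recorded species (ties included), plus a final
    all-zones total row labelled ``"total"``.

    A species is *unique* to an ecozone iff it was recorded in no other
    ecozone.  Passing ``ecozones`` explicitly allows zones with no
    sampled sites, which are reported as zero rows with a warning.
    """
    zones = list(ecozones) if ecozones is not None else occurrence.ecozones
    per_zone = occurrence.ecozone_species()
    richness = occurrence.site_richness()
    summaries = []
    for ez in zones:
        sites = occurrence.sites_in(ez)
        if not sites:
            warnings.warn(f"ecozone {ez!r} has no sites", AnalyticsWarning, stacklevel=2)
            summaries.append(EcozoneSummary(ez, 0, 0, 0.0, 0, None, ()))
            continue
        spp = per_zone.get(ez, frozenset())
        others = frozenset().union(
            *(per_zone.get(z, frozenset()) for z in per_zone if z != ez)
        )
        unique = spp - others
        if spp:
            pct = round_half_up(100.0 * len(unique) / len(spp), 1)
        else:
            warnings.warn(
                f"ecozone {ez!r} has no recorded species", AnalyticsWarning, stacklevel=2
            )
            pct = None
        site_counts = occurrence.presence.loc[sites].sum(axis=0)
        commonest = _argmax_ties(site_counts) if spp else ()
        summaries.append(
            EcozoneSummary(
                ecozone=ez,
                n_sites=len(sites),
                total_species=len(spp),
                mean_species_per_site=float(richness.loc[sites].mean()),
                unique_species=len(unique),
                unique_pct=pct,
                most_common_species=commonest,
            )
        )
    all_species = frozenset().union(*per_zone.values()) if per_zone else frozenset()
    overall_counts = occurrence.presence.sum(axis=0)
    summaries.append(
        EcozoneSummary(
            ecozone="total",
            n_sites=occurrence.n_sites,
            total_species=len(all_species),
            mean_species_per_site=float(richness.mean()) if occurrence.n_sites else 0.0,
            unique_species=None,
            unique_pct=None,
            most_common_species=_argmax_ties(overall_counts) if all_species else (),
        )
    )
    return summaries


def _argmax_ties(counts: pd.Series) -> tuple:
    top = counts.max()
    if top <= 0:
        return ()
    return tuple(sorted(counts.index[counts == top]))


# ---------------------------------------------------------------------------
# shared species


@dataclass(frozen=True)
class SharedSpeciesMatrix:
    """Pairwise shared-species counts between ecozones.

    ``counts`` is symmetric with each zone's richness on the diagonal;
    ``row_pct`` normalizes each row by the row zone's richness (hence is
    generally asymmetric, with 100 on the diagonal).  Rows for zones with
    zero species are NaN in ``row_pct``.
    """

    ecozones: tuple
    counts: pd.DataFrame
    row_pct: pd.DataFrame


def shared_species_matrix(occurrence: OccurrenceMatrix) -> SharedSpeciesMatrix:
    """Count species shared between every pair of ecozones."""
    zones = occurrence.ecozones
    if len(zones) < 2:
        raise ValidationError("shared-species matrix requires at least 2 ecozones")
    per_zone = occurrence.ecozone_species()
    counts = pd.DataFrame(0, index=zones, columns=zones, dtype=int)
    for a in zones:
        for b in zones:
            counts.loc[a, b] = len(per_zone[a] & per_zone[b])
    richness = pd.Series({z: len(per_zone[z]) for z in zones})
    empty = [z for z in zones if richness[z] == 0]
    if empty:
        warnings.warn(
            f"ecozone(s) with zero species: {empty}; their shared percentages are undefined",
            AnalyticsWarning,
            stacklevel=2,
        )
    row_pct = 100.0 * counts.div(richness.replace(0, np.nan), axis=0)
    return SharedSpeciesMatrix(tuple(zones), counts, row_pct)


# ---------------------------------------------------------------------------
# composition chi-squared

ChisqResult = namedtuple("ChisqResult", ["statistic", "df", "p_value"])


def composition_chisq(
    occurrence: Union[OccurrenceMatrix, pd.DataFrame],
    cells: str = "site-counts",
) -> ChisqResult:
    """Pearson chi-squared test of species composition across ecozones.

    The contingency table has one row per species and one column per
    ecozone.  With ``cells="site-counts"`` (default) each cell is the
    number of sites within the ecozone at which the species was recorded;
    ``cells="binary"`` reduces cells to presence/absence.  A ready-made
    contingency table (DataFrame) may be passed directly.

    Rows or columns summing to zero are dropped with a warning before
    testing; a warning is also emitted when any expected count falls
    below 5, where the chi-squared approximation is unreliable.
    """
    if isinstance(occurrence, OccurrenceMatrix):
        table = _species_by_ecozone_table(occurrence)
    else:
        table = pd.DataFrame(occurrence).astype(float)
    if cells == "binary":
        table = (table > 0).astype(int)
    elif cells != "site-counts":
        raise ValidationError("cells must be 'site-counts' or 'binary'")

    zero_rows = table.index[table.sum(axis=1) == 0]
    zero_cols = table.columns[table.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping {len(zero_rows)} empty row(s) and {len(zero_cols)} empty "
            "column(s) from the contingency table",
            AnalyticsWarning,
            stacklevel=2,
        )
        table = table.drop(index=zero_rows, columns=zero_cols)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError(
            f"contingency table must be at least 2x2 after dropping empty "
            f"rows/columns; got {table.shape}"
        )
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    if (res.expected_freq < 5).any():
        n_low = int((res.expected_freq < 5).sum())
        warnings.warn(
            f"{n_low} of {res.expected_freq.size} expected counts are below 5; "
            "the chi-squared approximation may be inaccurate",
            AnalyticsWarning,
            stacklevel=2,
        )
    return ChisqResult(float(res.statistic), int(res.dof), float(res.pvalue))


def _species_by_ecozone_table(occurrence: OccurrenceMatrix) -> pd.DataFrame:
    zones = occurrence.ecozones
    table = pd.DataFrame(0, index=occurrence.species, columns=zones, dtype=int)
    for ez in zones:
        block = occurrence.presence.loc[occurrence.sites_in(ez)]
        table[ez] = block.sum(axis=0).astype(int)
    return table


# ---------------------------------------------------------------------------
# sub-index correlations

_PAIRS = (("dbs", "tbs"), ("dbs", "sbs"), ("sbs", "tbs"))


def subindex_correlations(
    scores: Iterable[SpeciesScore],
    method: str = "pearson",
) -> dict:
    """Pairwise correlation of the three sub-indices across species.

    Pearson product–moment correlation on the raw (doubling-scale) score
    values by default; ``method="spearman"`` switches to rank
    correlation.  A pair involving a zero-variance sub-index is reported
    as ``None`` with a warning.
    """
    frame = pd.DataFrame(
        [{"dbs": s.dbs, "tbs": s.tbs, "sbs": s.sbs} for s in scores]
    )
    if len(frame) < 3:
        raise ValidationError("correlations require at least 3 scored species")
    if method not in ("pearson", "spearman"):
        raise ValidationError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    out = {}
    for a, b in _PAIRS:
        if frame[a].std() == 0 or frame[b].std() == 0:
            warnings.warn(
                f"sub-index pair ({a}, {b}) has zero variance; correlation undefined",
                AnalyticsWarning,
                stacklevel=2,
            )
            out[(a, b)] = None
        else:
            out[(a, b)] = float(corr(frame[a], frame[b]).statistic)
    return out


# ---------------------------------------------------------------------------
# distributions and summaries


@dataclass(frozen=True)
class SIDistribution:
    """Histogram of species-index values plus their median."""

    counts: pd.Series  # indexed by every attainable integer SI value
    median: float


def si_distribution(
    scores: Iterable[SpeciesScore],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> SIDistribution:
    """Frequency of each integer species-index value, and the median SI.

    Bins span the scheme's full attainable range so empty classes are
    reported explicitly.  The median of an even-sized set is the
    arithmetic mean of the two middle values.
    """
    values = [s.si for s in scores]
    if not values:
        raise ValidationError("si_distribution requires at least one scored species")
    lo, hi = scheme.si_bounds()
    idx = pd.RangeIndex(lo, hi + 1, name="si")
    counts = pd.Series(0, index=idx, dtype=int)
    observed = pd.Series(values).value_counts()
    counts.loc[observed.index] = observed.values
    return SIDistribution(counts=counts, median=float(np.median(values)))


def rabi_summary_by_ecozone(assessments: Iterable[SiteAssessment]) -> pd.DataFrame:
    """Per-ecozone site count and min/max/median of the site index.

    The median of an even-sized group is the arithmetic mean of the two
    middle values.
    """
    rows = [{"ecozone": a.ecozone, "rabi": a.rabi} for a in assessments]
    if not rows:
        raise ValidationError("no site assessments given")
    frame = pd.DataFrame(rows)
    grouped = frame.groupby("ecozone")["rabi"]
    out = pd.DataFrame(
        {
            "n_sites": grouped.size(),
            "min": grouped.min(),
            "max": grouped.max(),
            "median": grouped.median(),
        }
    ).sort_index()
    out.index.name = "ecozone"
    return out


@dataclass(frozen=True)
class PriorityReport:
    """Binned site-index counts and the priority-ranked site list."""

    bin_counts: pd.Series
    ranked: pd.DataFrame
    threshold: int


def priority_bins(
    assessments: Sequence[SiteAssessment],
    bin_width: int = 10,
    threshold: int = 20,
) -> PriorityReport:
    """Bin sites by index value and rank them for conservation priority.

    Sites are ranked by index descending, ties broken by species richness
    descending, then site id ascending.  A site is flagged high priority
    iff its index strictly exceeds ``threshold``.  Bins are ``1-10``,
    ``11-20``, ... (width configurable) with a separate ``0`` bin.
    """
    from .scoring import priority_bin_label

    if not assessments:
        return PriorityReport(
            bin_counts=pd.Series(dtype=int),
            ranked=pd.DataFrame(
                columns=["site", "ecozone", "n_species", "rabi", "priority_bin", "high_priority"]
            ),
            threshold=threshold,
        )
    rows = [
        {
            "site": a.site_id,
            "ecozone": a.ecozone,
            "n_species": a.n_species,
            "rabi": a.rabi,
            "priority_bin": priority_bin_label(a.rabi, bin_width),
            "high_priority": a.rabi > threshold,
        }
        for a in assessments
    ]
    ranked = (
        pd.DataFrame(rows)
        .sort_values(
            by=["rabi", "n_species", "site"], ascending=[False, False, True]
        )
        .reset_index(drop=True)
    )
    max_rabi = int(ranked["rabi"].max())
    labels = ["0"] + [
        priority_bin_label(lo, bin_width)
        for lo in range(1, max_rabi + 1, bin_width)
    ]
    bin_counts = pd.Series(0, index=pd.Index(labels, name="bin"), dtype=int)
    observed = ranked["priority_bin"].value_counts()
    bin_counts.loc[observed.index] = observed.values
    return PriorityReport(bin_counts=bin_counts, ranked=ranked, threshold=threshold)


# ---------------------------------------------------------------------------
# species accumulation


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean (± SD) cumulative richness as sites are added in random order."""

    k: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_runs: int
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "mean_richness": self.mean_richness, "sd_richness": self.sd_richness}
        )


def accumulation_curve(
    occurrence: OccurrenceMatrix,
    n_runs: int = 1000,
    seed: Optional[int] = None,
) -> AccumulationCurve:
    """Species accumulation curve by random site permutation.

    For each run, the sites are taken in a uniformly random order without
    replacement; the richness after ``k`` sites is the size of the union
    of their species sets.  Mean and sample (n−1) standard deviation are
    taken across runs at each ``k``.  Reproducible under a fixed seed.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    m = occurrence.presence.to_numpy(dtype=bool)
    n_sites = m.shape[0]
    if n_sites == 0:
        raise ValidationError("accumulation curve requires at least one site")
    runs = np.empty((n_runs, n_sites), dtype=np.int64)
    for i in range(n_runs):
        order = rng.permutation(n_sites)
        cumulative = np.cumsum(m[order], axis=0) > 0
        runs[i] = cumulative.sum(axis=1)
    mean = runs.mean(axis=0)
    sd = runs.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(n_sites)
    return AccumulationCurve(
        k=np.arange(1, n_sites + 1),
        mean_richness=mean,
        sd_richness=sd,
        n_runs=n_runs,
        seed=seed,
    )
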