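"""Per-species and per-site index computation.

Each species receives three integer sub-scores — distribution (DBS),
threat (TBS), and habitat sensitivity (SBS) — from its categorical traits
under a :class:`~rabi.scheme.ScoringScheme`.  Their sum is the Species
Index (SI; 1–20 under the default scheme).  A site's biotic-integrity
index is the plain sum of the SIs of all species recorded there, so a
site gains from both richness and the presence of range-restricted,
threatened, habitat-sensitive species; a site with no species scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

from .errors import ScoringWarning, ValidationError
from .occurrence import OccurrenceMatrix
from .scheme import DEFAULT_SCHEME, ScoringScheme


@dataclass(frozen=True)
class SpeciesTraits:
    """Categorical traits from which a species is scored.

    ``ecozones_occupied`` is either the set of ecozone labels the species
    is known from, or a bare count when only the number is known (the
    occupancy is treated as a supplied range attribute, not re-derived
    from any particular survey matrix).
    """

    species_id: str
    ecozones_occupied: Union[frozenset, int]
    endemic: bool = False
    red_list: str = "LC"
    sensitivity: str = "wide-range generalist"

    def __post_init__(self) -> None:
        ez = self.ecozones_occupied
        if not isinstance(ez, (int, frozenset)):
            if isinstance(ez, str):
                raise ValidationError(
                    f"{self.species_id}: ecozones_occupied must be a set of labels "
                    "or an integer count, not a bare string"
                )
            object.__setattr__(self, "ecozones_occupied", frozenset(ez))

    @property
    def occupancy(self) -> int:
        """Number of ecozones the species occupies."""
        ez = self.ecozones_occupied
        return ez if isinstance(ez, int) else len(ez)

    @property
    def ecozone_set(self) -> Union[frozenset, None]:
        """The occupied ecozone labels, or ``None`` if only a count is known."""
        ez = self.ecozones_occupied
        return None if isinstance(ez, int) else ez


@dataclass(frozen=True)
class SpeciesScore:
    """A species' three sub-scores; the species index is their sum."""

    species_id: str
    dbs: int
    tbs: int
    sbs: int

    @property
    def si(self) -> int:
        return self.dbs + self.tbs + self.sbs


@dataclass(frozen=True)
class SiteAssessment:
    """Scored assemblage of one site."""

    site_id: str
    ecozone: str
    species_present: tuple
    per_species_si: tuple
    rabi: int
    priority_bin: str
    high_priority: bool

    @property
    def n_species(self) -> int:
        return len(self.species_present)


def compute_dbs(traits: SpeciesTraits, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Distribution-based score of one species.

    The score is set by the occupancy class containing the species'
    ecozone count; the top (endemic) class requires both single-class
    occupancy and the endemic flag.  An endemic species recorded in more
    ecozones than the narrowest class is scored by occupancy alone, with
    a warning, since no scheme category covers that combination.
    """
    ez_set = traits.ecozone_set
    if ez_set is not None:
        unknown = ez_set - set(scheme.ecozone_labels)
        if unknown:
            raise ValidationError(
                f"{traits.species_id}: unknown ecozone label(s) {sorted(unknown)}; "
                f"scheme declares {list(scheme.ecozone_labels)}"
            )
    n = traits.occupancy
    if n == 0:
        raise ValidationError(f"species {traits.species_id!r} has no recorded ecozone")
    if n > scheme.n_ecozones:
        raise ValidationError(
            f"{traits.species_id}: occupancy {n} exceeds the scheme's "
            f"{scheme.n_ecozones} ecozones"
        )
    if traits.endemic and n > scheme.dbs_breakpoints[0]:
        warnings.warn(
            f"{traits.species_id}: endemic but recorded in {n} ecozones; "
            "endemism confers no score bonus outside the narrowest occupancy class",
            ScoringWarning,
            stacklevel=2,
        )
    return scheme.dbs_for(n, traits.endemic)


def compute_tbs(red_list: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Threat-based score for an IUCN Red List category."""
    return scheme.tbs_for(red_list)


def compute_sbs(sensitivity: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> int:
    """Sensitivity-based score for a habitat-sensitivity category."""
    return scheme.sbs_for(sensitivity)


def species_index(
    dbs: int, tbs: int, sbs: int, scheme: ScoringScheme = DEFAULT_SCHEME
) -> int:
    """Species Index: the sum of the three sub-scores.

    Each score must be attainable for its sub-index under the active
    scheme (e.g. a DBS of 3 is rejected under the default 1/2/4/8 ladder).
    """
    valid_dbs = set(scheme.dbs_scores) | {scheme.dbs_endemic_score}
    if dbs not in valid_dbs:
        raise ValidationError(f"DBS {dbs} is not attainable; valid: {sorted(valid_dbs)}")
    valid_tbs = set(scheme.tbs_scores.values())
    if tbs not in valid_tbs:
        raise ValidationError(f"TBS {tbs} is not attainable; valid: {sorted(valid_tbs)}")
    valid_sbs = {s for _, s in scheme.sbs_levels}
    if sbs not in valid_sbs:
        raise ValidationError(f"SBS {sbs} is not attainable; valid: {sorted(valid_sbs)}")
    return dbs + tbs + sbs


def score_species(
    traits: SpeciesTraits, scheme: ScoringScheme = DEFAULT_SCHEME
) -> SpeciesScore:
    """Score one species on all three sub-indices."""
    return SpeciesScore(
        species_id=traits.species_id,
        dbs=compute_dbs(traits, scheme),
        tbs=compute_tbs(traits.red_list, scheme),
        sbs=compute_sbs(traits.sensitivity, scheme),
    )


def site_rabi(per_species_si: Sequence[int]) -> int:
    """Site index: the sum of the species indices of the species present.

    An empty assemblage scores 0.  Every present species carries an SI of
    at least 1 (each species earns at least one distribution point), so
    non-positive entries are rejected.
    """
    bad = [si for si in per_species_si if not isinstance(si, int) or si < 1]
    if bad:
        raise ValidationError(
            f"species indices must be integers >= 1; offending values: {bad}"
        )
    return sum(per_species_si)


def priority_bin_label(rabi: int, bin_width: int = 10) -> str:
    """Reporting bin for a site index value: "0", "1-10", "11-20", ..."""
    if rabi < 0:
        raise ValidationError("site index cannot be negative")
    if rabi == 0:
        return "0"
    lo = ((rabi - 1) // bin_width) * bin_width + 1
    return f"{lo}-{lo + bin_width - 1}"


def score_assemblage(
    occurrence: OccurrenceMatrix,
    traits: Union[Mapping[str, SpeciesTraits], Iterable[SpeciesTraits]],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[SiteAssessment]:
    """Score every site of an occurrence matrix.

    Every species in the matrix must have a trait record; trait records
    for species absent from the matrix are tolerated with a warning.
    Returns one :class:`SiteAssessment` per site, in matrix order.
    """
    trait_map = _as_trait_map(traits)
    missing = [sp for sp in occurrence.species if sp not in trait_map]
    if missing:
        raise ValidationError(
            f"species in occurrence matrix without trait records: {missing}"
        )
    extra = sorted(set(trait_map) - set(occurrence.species))
    if extra:
        warnings.warn(
            f"{len(extra)} trait record(s) for species absent from the matrix: {extra}",
            ScoringWarning,
            stacklevel=2,
        )

    si_of = {
        sp: score_species(trait_map[sp], scheme).si for sp in occurrence.species
    }
    assessments = []
    for site in occurrence.sites:
        present = tuple(occurrence.species_at(site))
        sis = tuple(si_of[sp] for sp in present)
        rabi = site_rabi(list(sis))
        assessments.append(
            SiteAssessment(
                site_id=site,
                ecozone=occurrence.site_ecozone[site],
                species_present=present,
                per_species_si=sis,
                rabi=rabi,
                priority_bin=priority_bin_label(rabi),
                high_priority=rabi > scheme.high_priority_threshold,
            )
        )
    return assessments


def _as_trait_map(
    traits: Union[Mapping[str, SpeciesTraits], Iterable[SpeciesTraits]],
) -> Mapping[str, SpeciesTraits]:
    if isinstance(traits, Mapping):
        return traits
    trait_map: dict[str, SpeciesTraits] = {}
    for t in traits:
        if t.species_id in trait_map:
            raise ValidationError(f"duplicate trait record for species {t.species_id!r}")
        trait_map[t.species_id] = t
    return trait_map
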