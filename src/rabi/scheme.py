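"""Scoring schemes: the category-to-score lookups behind the index.

A scheme assigns integer conservation scores to categorical species traits
along three axes:

* **DBS** (distribution-based score) — how many ecozones of the study
  region a species occupies, with a bonus class for species that occupy a
  single ecozone *and* are endemic to the region;
* **TBS** (threat-based score) — the species' IUCN Red List category;
* **SBS** (sensitivity-based score) — how tolerant the species is of
  habitat disturbance.

The default scheme is the five-ecozone calibration used for Rwandan
anurans: DBS 1/2/4/8 over the occupancy classes 4–5, 2–3 and 1 ecozone(s)
plus the single-ecozone-endemic class; TBS 0–8 over LC/NT/VU-DD/EN/CR;
SBS 0–4 over four habitat-sensitivity categories.  Scores double with each
successive category, so a species one category up carries twice the
conservation weight of one in the category below.  Both the number of
ecozones and every category-to-score mapping are configurable so the index
can be recalibrated for other regions.
"""

from __future__ import annotations

import hashlib
import json
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Mapping

from .errors import SchemeError

#: IUCN Red List categories accepted by the default scheme.
RED_LIST_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "DD")

#: Severity ladder used to validate threat scores.  DD (Data Deficient)
#: sits outside the ladder; the default scheme scores it like VU as a
#: precautionary choice.
_THREAT_LADDER = ("LC", "NT", "VU", "EN", "CR")

DEFAULT_TBS_SCORES: Mapping[str, int] = {
    "LC": 0,
    "NT": 1,
    "VU": 2,
    "DD": 2,
    "EN": 4,
    "CR": 8,
}

#: Habitat-sensitivity categories, least to most sensitive.
DEFAULT_SBS_LEVELS: tuple[tuple[str, int], ...] = (
    ("wide-range generalist", 0),
    ("few disturbed microhabitats", 1),
    ("near-natural only", 2),
    ("undisturbed only", 4),
)


def _is_int(x: Any) -> bool:
    return isinstance(x, int) and not isinstance(x, bool)


@dataclass(frozen=True)
class ScoringScheme:
    """Category-to-score lookups for the three sub-indices.

    Parameters
    ----------
    n_ecozones:
        Number of ecozones the study region is divided into.
    ecozone_labels:
        Labels of those ecozones; defaults to ``EZ1 .. EZn``.
    dbs_breakpoints:
        Upper bounds of the occupancy classes, in increasing occupancy;
        the default ``(1, 3, 5)`` yields the classes 1, 2–3 and 4–5
        ecozones.  The last breakpoint must equal ``n_ecozones``.
    dbs_scores:
        Score of each occupancy class, aligned with ``dbs_breakpoints``
        (narrowest class first, so scores decrease along the tuple).
    dbs_endemic_score:
        Score of the bonus class for endemics in the narrowest occupancy
        class.
    tbs_scores:
        Red List category -> score.  Must cover the six standard
        categories; extra entries (e.g. ``NE``) may be added explicitly.
    sbs_levels:
        Ordered ``(label, score)`` pairs, least sensitive first.
    high_priority_threshold:
        A site whose index strictly exceeds this value is flagged as a
        high-conservation-priority site.
    """

    n_ecozones: int = 5
    ecozone_labels: tuple[str, ...] | None = None
    dbs_breakpoints: tuple[int, ...] = (1, 3, 5)
    dbs_scores: tuple[int, ...] = (4, 2, 1)
    dbs_endemic_score: int = 8
    tbs_scores: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TBS_SCORES)
    )
    sbs_levels: tuple[tuple[str, int], ...] = DEFAULT_SBS_LEVELS
    high_priority_threshold: int = 20

    def __post_init__(self) -> None:
        if not _is_int(self.n_ecozones) or self.n_ecozones < 1:
            raise SchemeError("n_ecozones must be a positive integer")
        labels = self.ecozone_labels
        if labels is None:
            labels = tuple(f"EZ{i}" for i in range(1, self.n_ecozones + 1))
            object.__setattr__(self, "ecozone_labels", labels)
        labels = tuple(str(x) for x in labels)
        object.__setattr__(self, "ecozone_labels", labels)
        if len(labels) != self.n_ecozones or len(set(labels)) != len(labels):
            raise SchemeError(
                f"expected {self.n_ecozones} distinct ecozone labels, got {labels!r}"
            )

        bp = tuple(self.dbs_breakpoints)
        object.__setattr__(self, "dbs_breakpoints", bp)
        if not bp or any(not _is_int(b) for b in bp):
            raise SchemeError("dbs_breakpoints must be a non-empty tuple of integers")
        if list(bp) != sorted(set(bp)) or bp[0] < 1 or bp[-1] != self.n_ecozones:
            raise SchemeError(
                "dbs_breakpoints must increase strictly from >=1 and end at n_ecozones"
            )

        ds = tuple(self.dbs_scores)
        object.__setattr__(self, "dbs_scores", ds)
        if len(ds) != len(bp):
            raise SchemeError("dbs_scores and dbs_breakpoints must have equal length")
        self._check_scores("DBS", ds)
        if any(ds[i] <= ds[i + 1] for i in range(len(ds) - 1)):
            raise SchemeError("DBS scores must strictly decrease with wider occupancy")
        if not _is_int(self.dbs_endemic_score) or self.dbs_endemic_score <= ds[0]:
            raise SchemeError(
                "the endemic DBS class must outrank the narrowest occupancy class"
            )

        tbs = {str(k).upper(): v for k, v in dict(self.tbs_scores).items()}
        object.__setattr__(self, "tbs_scores", tbs)
        missing = [c for c in RED_LIST_CATEGORIES if c not in tbs]
        if missing:
            raise SchemeError(f"tbs_scores missing Red List categories: {missing}")
        self._check_scores("TBS", tuple(tbs.values()))
        ladder = [tbs[c] for c in _THREAT_LADDER]
        if any(ladder[i] >= ladder[i + 1] for i in range(len(ladder) - 1)):
            raise SchemeError(
                "TBS scores must strictly increase along LC < NT < VU < EN < CR"
            )

        sbs = tuple((str(lbl), sc) for lbl, sc in self.sbs_levels)
        object.__setattr__(self, "sbs_levels", sbs)
        if not sbs:
            raise SchemeError("sbs_levels must not be empty")
        self._check_scores("SBS", tuple(s for _, s in sbs))
        sbs_scores = [s for _, s in sbs]
        if any(sbs_scores[i] >= sbs_scores[i + 1] for i in range(len(sbs_scores) - 1)):
            raise SchemeError("SBS scores must strictly increase across categories")
        norm = [self._norm_label(lbl) for lbl, _ in sbs]
        if len(set(norm)) != len(norm):
            raise SchemeError("duplicate SBS category labels")

        if not _is_int(self.high_priority_threshold) or self.high_priority_threshold < 0:
            raise SchemeError("high_priority_threshold must be a non-negative integer")

    @staticmethod
    def _check_scores(name: str, scores: tuple) -> None:
        if any(not _is_int(s) or s < 0 for s in scores):
            raise SchemeError(f"{name} scores must be non-negative integers")

    # -- lookups ---------------------------------------------------------

    @staticmethod
    def _norm_label(label: str) -> str:
        return " ".join(str(label).strip().lower().split())

    def occupancy_class(self, n_occupied: int) -> int:
        """Index of the occupancy class containing ``n_occupied``."""
        if not _is_int(n_occupied) or n_occupied < 1:
            raise SchemeError("occupancy must be a positive integer")
        if n_occupied > self.n_ecozones:
            raise SchemeError(
                f"occupancy {n_occupied} exceeds the scheme's {self.n_ecozones} ecozones"
            )
        return bisect_left(self.dbs_breakpoints, n_occupied)

    def dbs_for(self, n_occupied: int, endemic: bool) -> int:
        """Distribution score for a species occupying ``n_occupied`` ecozones.

        The endemic bonus class applies only within the narrowest
        occupancy class; endemism confers nothing outside it.
        """
        cls = self.occupancy_class(n_occupied)
        if endemic and n_occupied <= self.dbs_breakpoints[0]:
            return self.dbs_endemic_score
        return self.dbs_scores[cls]

    def tbs_for(self, red_list: str) -> int:
        """Threat score for a Red List category."""
        key = str(red_list).strip().upper()
        try:
            return self.tbs_scores[key]
        except KeyError:
            accepted = ", ".join(sorted(self.tbs_scores))
            raise SchemeError(
                f"unrecognized Red List category {red_list!r}; accepted: {accepted}"
            ) from None

    def sbs_for(self, sensitivity: str) -> int:
        """Sensitivity score for a habitat-sensitivity category label."""
        key = self._norm_label(sensitivity)
        for label, score in self.sbs_levels:
            if self._norm_label(label) == key:
                return score
        accepted = ", ".join(lbl for lbl, _ in self.sbs_levels)
        raise SchemeError(
            f"unrecognized sensitivity category {sensitivity!r}; accepted: {accepted}"
        )

    # -- enumeration -----------------------------------------------------

    def iter_category_scores(self) -> Iterator[tuple[int, int, int]]:
        """Yield (dbs, tbs, sbs) for every category combination.

        The DBS axis enumerates each occupancy class plus the endemic
        class; the TBS axis enumerates each mapped Red List category.
        """
        dbs_options = tuple(self.dbs_scores) + (self.dbs_endemic_score,)
        tbs_options = tuple(self.tbs_scores[c] for c in sorted(self.tbs_scores))
        sbs_options = tuple(s for _, s in self.sbs_levels)
        for d in dbs_options:
            for t in tbs_options:
                for s in sbs_options:
                    yield d, t, s

    def n_category_combinations(self) -> int:
        return (
            (len(self.dbs_scores) + 1) * len(self.tbs_scores) * len(self.sbs_levels)
        )

    def attainable_si(self) -> tuple[int, ...]:
        """Sorted distinct species-index values the scheme can produce."""
        return tuple(sorted({d + t + s for d, t, s in self.iter_category_scores()}))

    def si_bounds(self) -> tuple[int, int]:
        """(minimum, maximum) attainable species index, by exhaustive
        enumeration of all category combinations."""
        values = self.attainable_si()
        return values[0], values[-1]

    # -- (de)serialization -----------------------------------------------

    def to_mapping(self) -> dict[str, Any]:
        """Plain-dict form suitable for YAML/JSON serialization."""
        return {
            "n_ecozones": self.n_ecozones,
            "ecozone_labels": list(self.ecozone_labels),
            "dbs_breakpoints": list(self.dbs_breakpoints),
            "dbs_scores": list(self.dbs_scores),
            "dbs_endemic_score": self.dbs_endemic_score,
            "tbs_scores": dict(self.tbs_scores),
            "sbs_levels": [[lbl, sc] for lbl, sc in self.sbs_levels],
            "high_priority_threshold": self.high_priority_threshold,
        }

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "ScoringScheme":
        """Build a scheme from a flat key/value document.

        Omitted keys fall back to the default scheme.  ``tbs_scores``
        entries are merged into the defaults, so a single extra category
        (e.g. ``NE``) can be mapped without restating the whole table.
        ``sbs_levels`` may be a list of pairs or an ordered mapping and
        replaces the default ladder wholesale.
        """
        known = set(cls().to_mapping())
        unknown = set(mapping) - known
        if unknown:
            raise SchemeError(f"unknown scheme keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key in ("n_ecozones", "dbs_endemic_score", "high_priority_threshold"):
            if key in mapping:
                kwargs[key] = mapping[key]
        for key in ("ecozone_labels", "dbs_breakpoints", "dbs_scores"):
            if key in mapping:
                kwargs[key] = tuple(mapping[key])
        if "tbs_scores" in mapping:
            merged = dict(DEFAULT_TBS_SCORES)
            merged.update(
                {str(k).upper(): v for k, v in dict(mapping["tbs_scores"]).items()}
            )
            kwargs["tbs_scores"] = merged
        if "sbs_levels" in mapping:
            raw = mapping["sbs_levels"]
            if isinstance(raw, Mapping):
                kwargs["sbs_levels"] = tuple((k, v) for k, v in raw.items())
            else:
                kwargs["sbs_levels"] = tuple((lbl, sc) for lbl, sc in raw)
        return cls(**kwargs)

    def with_threshold(self, threshold: int) -> "ScoringScheme":
        return replace(self, high_priority_threshold=threshold)

    def digest(self) -> str:
        """Stable hex digest of the scheme, for provenance logging."""
        payload = json.dumps(self.to_mapping(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


#: The five-ecozone default calibration.
DEFAULT_SCHEME = ScoringScheme()
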