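"""Site-by-species presence–absence matrix with a site-to-ecozone mapping."""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Union

import pandas as pd

from .errors import AnalyticsWarning, ValidationError


class OccurrenceMatrix:
    """Presence–absence records of species across survey sites.

    Parameters
    ----------
    presence:
        sites × species grid of 0/1 or booleans; rows are sites, columns
        species.  Anything :class:`pandas.DataFrame` accepts works.
    site_ecozone:
        mapping from site id to ecozone label; must cover every site.
    """

    def __init__(
        self,
        presence: pd.DataFrame,
        site_ecozone: Mapping[str, str],
    ) -> None:
        frame = pd.DataFrame(presence)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        if frame.index.duplicated().any():
            dups = sorted(set(frame.index[frame.index.duplicated()]))
            raise ValidationError(f"duplicate site ids: {dups}")
        if frame.columns.duplicated().any():
            dups = sorted(set(frame.columns[frame.columns.duplicated()]))
            raise ValidationError(f"duplicate species ids: {dups}")
        if not frame.isin([0, 1, True, False]).all().all():
            raise ValidationError("presence cells must be 0/1 or boolean")
        self.presence: pd.DataFrame = frame.astype(bool)
        missing = [s for s in self.presence.index if s not in site_ecozone]
        if missing:
            raise ValidationError(f"sites without an ecozone assignment: {missing}")
        self.site_ecozone: dict[str, str] = {
            s: str(site_ecozone[s]) for s in self.presence.index
        }
        self.presence.index.name = "site"
        self.presence.columns.name = "species"

    # -- construction ------------------------------------------------------

    @classmethod
    def from_long(
        cls,
        records: Union[pd.DataFrame, Iterable[tuple]],
        site_ecozone: Mapping[str, str],
        sites: Union[list, None] = None,
        species: Union[list, None] = None,
    ) -> "OccurrenceMatrix":
        """Build from long-format ``(site, species)`` presence records.

        Duplicate pairs are collapsed with a warning.  ``sites`` /
        ``species`` fix the row/column order (and may add empty rows or
        columns); by default order of first appearance is used.
        """
        if isinstance(records, pd.DataFrame):
            pairs = [
                (str(r), str(c)) for r, c in records.iloc[:, :2].itertuples(index=False)
            ]
        else:
            pairs = [(str(r), str(c)) for r, c in records]
        seen = set()
        deduped = []
        for p in pairs:
            if p in seen:
                continue
            seen.add(p)
            deduped.append(p)
        if len(deduped) < len(pairs):
            warnings.warn(
                f"{len(pairs) - len(deduped)} duplicate (site, species) record(s) ignored",
                AnalyticsWarning,
                stacklevel=2,
            )
        if sites is None:
            sites = list(dict.fromkeys(s for s, _ in deduped))
        if species is None:
            species = list(dict.fromkeys(sp for _, sp in deduped))
        frame = pd.DataFrame(False, index=sites, columns=species)
        for s, sp in deduped:
            if s not in frame.index or sp not in frame.columns:
                raise ValidationError(f"record ({s!r}, {sp!r}) outside declared sites/species")
            frame.loc[s, sp] = True
        return cls(frame, site_ecozone)

    # -- basic accessors ---------------------------------------------------

    @property
    def sites(self) -> list:
        return list(self.presence.index)

    @property
    def species(self) -> list:
        return list(self.presence.columns)

    @property
    def n_sites(self) -> int:
        return self.presence.shape[0]

    @property
    def n_species(self) -> int:
        return self.presence.shape[1]

    @property
    def ecozones(self) -> list:
        """Ecozone labels occurring in the site mapping, sorted."""
        return sorted(set(self.site_ecozone.values()))

    def species_at(self, site: str) -> list:
        """Species recorded at a site, in matrix column order."""
        row = self.presence.loc[site]
        return list(row.index[row])

    def sites_in(self, ecozone: str) -> list:
        return [s for s in self.sites if self.site_ecozone[s] == ecozone]

    def site_richness(self) -> pd.Series:
        """Number of species recorded per site."""
        return self.presence.sum(axis=1).astype(int)

    def ecozone_species(self) -> dict:
        """Ecozone label -> frozenset of species recorded in that zone."""
        out = {}
        for ez in self.ecozones:
            block = self.presence.loc[self.sites_in(ez)]
            out[ez] = frozenset(block.columns[block.any(axis=0)])
        return out

    def species_ecozones(self) -> dict:
        """Species id -> frozenset of ecozones where it was recorded."""
        per_zone = self.ecozone_species()
        return {
            sp: frozenset(ez for ez, spp in per_zone.items() if sp in spp)
            for sp in self.species
        }

    def to_long(self) -> pd.DataFrame:
        """Long-format frame of the present (site, species) pairs."""
        rows = [
            {"site": s, "species": sp}
            for s in self.sites
            for sp in self.species_at(s)
        ]
        return pd.DataFrame(rows, columns=["site", "species"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OccurrenceMatrix):
            return NotImplemented
        return (
            self.presence.equals(other.presence)
            and self.site_ecozone == other.site_ecozone
        )

    def __repr__(self) -> str:
        return (
            f"<OccurrenceMatrix {self.n_sites} sites x {self.n_species} species, "
            f"{len(self.ecozones)} ecozones>"
        )
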