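"""Readers and writers for the delimited-text interchange formats.

Traits, occurrence matrices and site metadata travel as CSV/TSV (the
delimiter is auto-detected between comma and tab); scoring schemes as
flat YAML/JSON documents.  Species and site ids are opaque,
case-sensitive strings.  Every writer emits a file its paired reader
parses back to an equal in-memory structure.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .analytics import (
    AccumulationCurve,
    EcozoneSummary,
    SharedSpeciesMatrix,
    round_half_up,
)
from .errors import ValidationError
from .occurrence import OccurrenceMatrix
from .scheme import DEFAULT_SCHEME, ScoringScheme
from .scoring import SiteAssessment, SpeciesTraits

_TRUE = {"true", "t", "yes", "y", "1"}
_FALSE = {"false", "f", "no", "n", "0"}


def _detect_delimiter(path: Union[str, Path]) -> str:
    """Comma or tab, decided from the header line."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep=_detect_delimiter(path), dtype=str, keep_default_na=False
    )
    frame.columns = [str(c).strip() for c in frame.columns]
    return frame


def _parse_bool(raw: str, line: int, column: str, problems: list) -> bool:
    val = raw.strip().lower()
    if val in _TRUE:
        return True
    if val in _FALSE:
        return False
    problems.append(f"line {line}: cannot parse {column}={raw!r} as boolean")
    return False


# ---------------------------------------------------------------------------
# traits


def read_traits(
    path: Union[str, Path],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[SpeciesTraits]:
    """Read a species trait table.

    Required columns: ``species``, ``endemic``, ``red_list``,
    ``sensitivity`` and either ``ecozones`` (semicolon-separated labels)
    or ``n_ecozones``.  All validation problems are collected and raised
    together with their line numbers.
    """
    frame = _read_table(path)
    cols = set(frame.columns)
    required = {"species", "endemic", "red_list", "sensitivity"}
    missing = required - cols
    if missing:
        raise ValidationError(f"{path}: missing required column(s): {sorted(missing)}")
    if "ecozones" not in cols and "n_ecozones" not in cols:
        raise ValidationError(f"{path}: need an 'ecozones' or 'n_ecozones' column")

    problems: list[str] = []
    seen: dict[str, int] = {}
    traits: list[SpeciesTraits] = []
    valid_sens = {ScoringScheme._norm_label(lbl) for lbl, _ in scheme.sbs_levels}
    for i, row in frame.iterrows():
        line = int(i) + 2  # header is line 1
        sp = row["species"].strip()
        if not sp:
            problems.append(f"line {line}: empty species id")
            continue
        if sp in seen:
            problems.append(
                f"line {line}: duplicate species {sp!r} (first seen on line {seen[sp]})"
            )
            continue
        seen[sp] = line

        if "ecozones" in cols and row.get("ecozones", "").strip():
            zones = frozenset(
                z.strip() for z in row["ecozones"].split(";") if z.strip()
            )
            unknown = zones - set(scheme.ecozone_labels)
            if unknown:
                problems.append(f"line {line}: unknown ecozone label(s) {sorted(unknown)}")
                continue
            ez: Union[frozenset, int] = zones
        elif "n_ecozones" in cols and row.get("n_ecozones", "").strip():
            try:
                ez = int(row["n_ecozones"])
            except ValueError:
                problems.append(
                    f"line {line}: n_ecozones={row['n_ecozones']!r} is not an integer"
                )
                continue
        else:
            problems.append(f"line {line}: species {sp!r} has no recorded ecozone")
            continue

        endemic = _parse_bool(row["endemic"], line, "endemic", problems)
        red_list = row["red_list"].strip().upper()
        if red_list not in scheme.tbs_scores:
            problems.append(
                f"line {line}: unknown red_list value {row['red_list']!r}; "
                f"accepted: {sorted(scheme.tbs_scores)}"
            )
            continue
        sens = row["sensitivity"].strip()
        if ScoringScheme._norm_label(sens) not in valid_sens:
            problems.append(
                f"line {line}: unknown sensitivity value {sens!r}; "
                f"accepted: {[lbl for lbl, _ in scheme.sbs_levels]}"
            )
            continue
        traits.append(SpeciesTraits(sp, ez, endemic, red_list, sens))
    if problems:
        raise ValidationError(f"{path}:\n" + "\n".join(problems))
    return traits


def write_traits(
    traits: Sequence[SpeciesTraits],
    path: Union[str, Path],
    delimiter: str = ",",
) -> None:
    """Write a trait table readable by :func:`read_traits`."""
    with_sets = [t.ecozone_set is not None for t in traits]
    if any(with_sets) and not all(with_sets):
        raise ValidationError(
            "cannot mix set-based and count-based occupancy in one trait table"
        )
    rows = []
    for t in traits:
        row = {"species": t.species_id}
        if t.ecozone_set is not None:
            row["ecozones"] = ";".join(sorted(t.ecozone_set))
        else:
            row["n_ecozones"] = t.occupancy
        row.update(
            endemic=str(t.endemic).lower(),
            red_list=t.red_list,
            sensitivity=t.sensitivity,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# site metadata and occurrence


def read_metadata(path: Union[str, Path]) -> pd.DataFrame:
    """Read site metadata: columns ``site``, ``ecozone``, optional ``protected``."""
    frame = _read_table(path)
    missing = {"site", "ecozone"} - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing metadata column(s): {sorted(missing)}")
    frame["site"] = frame["site"].str.strip()
    dups = frame["site"][frame["site"].duplicated()]
    if not dups.empty:
        raise ValidationError(f"{path}: duplicate site id(s): {sorted(set(dups))}")
    problems: list[str] = []
    if "protected" in frame.columns:
        frame["protected"] = [
            _parse_bool(v, i + 2, "protected", problems)
            for i, v in enumerate(frame["protected"])
        ]
    else:
        frame["protected"] = False
    if problems:
        raise ValidationError(f"{path}:\n" + "\n".join(problems))
    return frame[["site", "ecozone", "protected"]]


def read_occurrence(
    path: Union[str, Path],
    metadata_path: Union[str, Path],
) -> OccurrenceMatrix:
    """Read an occurrence matrix and join its sites to ecozones.

    The dialect is auto-detected from the header: a two-column
    ``site,species`` file is treated as long format (duplicate pairs are
    collapsed with a warning); anything else as a wide matrix whose first
    column holds site ids and whose cells must be 0/1.
    """
    meta = read_metadata(metadata_path)
    site_ecozone = dict(zip(meta["site"], meta["ecozone"]))
    frame = _read_table(path)
    lowered = [c.lower() for c in frame.columns]
    if lowered == ["site", "species"]:
        records = frame.rename(columns=dict(zip(frame.columns, lowered)))
        _require_known_sites(records["site"], site_ecozone, path)
        return OccurrenceMatrix.from_long(records, site_ecozone)
    wide = frame.set_index(frame.columns[0])
    bad = ~wide.isin(["0", "1"])
    if bad.any().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise ValidationError(
            f"{path}: non-0/1 cell at site {wide.index[r]!r}, "
            f"species {wide.columns[c]!r}: {wide.iat[r, c]!r}"
        )
    _require_known_sites(wide.index.to_series(), site_ecozone, path)
    return OccurrenceMatrix(wide.astype(int), site_ecozone)


def _require_known_sites(sites: pd.Series, site_ecozone: Mapping, path) -> None:
    unknown = sorted(set(sites) - set(site_ecozone))
    if unknown:
        raise ValidationError(f"{path}: site(s) missing from metadata: {unknown}")


def write_occurrence(
    occurrence: OccurrenceMatrix,
    path: Union[str, Path],
    fmt: str = "wide",
    delimiter: str = ",",
) -> None:
    """Write an occurrence matrix in wide (0/1 grid) or long format."""
    if fmt == "wide":
        occurrence.presence.astype(int).to_csv(path, sep=delimiter)
    elif fmt == "long":
        occurrence.to_long().to_csv(path, sep=delimiter, index=False)
    else:
        raise ValidationError("fmt must be 'wide' or 'long'")


def write_metadata(
    occurrence: OccurrenceMatrix,
    path: Union[str, Path],
    protected: Optional[Mapping[str, bool]] = None,
    delimiter: str = ",",
) -> None:
    protected = protected or {}
    rows = [
        {
            "site": s,
            "ecozone": occurrence.site_ecozone[s],
            "protected": str(bool(protected.get(s, False))).lower(),
        }
        for s in occurrence.sites
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# scheme config


def read_scheme(path: Union[str, Path]) -> ScoringScheme:
    """Read a scoring-scheme configuration (YAML or JSON).

    Omitted keys fall back to the default scheme.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return ScoringScheme()
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: scheme config must be a key/value mapping")
    return ScoringScheme.from_mapping(doc)


def write_scheme(scheme: ScoringScheme, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(scheme.to_mapping(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# report writers


def write_assessments(
    assessments: Iterable[SiteAssessment],
    path: Union[str, Path],
    delimiter: str = ",",
) -> None:
    """Per-site assessment table: site, ecozone, n_species, rabi, bin, flag."""
    rows = [
        {
            "site": a.site_id,
            "ecozone": a.ecozone,
            "n_species": a.n_species,
            "rabi": a.rabi,
            "priority_bin": a.priority_bin,
            "high_priority": str(a.high_priority).lower(),
        }
        for a in assessments
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def write_ecozone_summaries(
    summaries: Sequence[EcozoneSummary],
    path: Union[str, Path],
    delimiter: str = ",",
) -> None:
    rows = [
        {
            "ecozone": s.ecozone,
            "n_sites": s.n_sites,
            "total_species": s.total_species,
            "mean_species_per_site": round_half_up(s.mean_species_per_site, 1),
            "unique_species": "" if s.unique_species is None else s.unique_species,
            "unique_pct": "" if s.unique_pct is None else s.unique_pct,
            "most_common_species": "; ".join(s.most_common_species),
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def write_shared_matrix(
    shared: SharedSpeciesMatrix,
    path: Union[str, Path],
    delimiter: str = ",",
) -> None:
    """Shared-species table with ``count (pct%)`` cells, row-normalized."""
    rows = []
    for a in shared.ecozones:
        row = {"ecozone": a, "total_species": int(shared.counts.loc[a, a])}
        for b in shared.ecozones:
            n = int(shared.counts.loc[a, b])
            pct = shared.row_pct.loc[a, b]
            cell = f"{n}" if pd.isna(pct) else f"{n} ({round_half_up(pct, 1)}%)"
            row[f"shared_with_{b}"] = cell
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


def write_accumulation(
    curve: AccumulationCurve,
    path: Union[str, Path],
    delimiter: str = ",",
) -> None:
    curve.to_frame().to_csv(path, sep=delimiter, index=False)
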