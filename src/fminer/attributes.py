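"""Herb attribute statistics: four natures, five flavors, meridian tropism, efficacy.

Each herb in the materia medica carries one thermal nature (cold, cool,
neutral, warm, hot), one or more flavors, one or more meridian tropisms and
a hierarchical efficacy class (e.g. ``tonifying/qi``). Given a cleaned
prescription dataset, this module tallies those attributes two ways:

* unweighted — each distinct herb in the dataset counts once per category;
* weighted — each herb contributes its occurrence count across formulas.

Multi-valued attributes (flavors, meridians) contribute to every category
they carry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .standardize import FormulaDataset

__all__ = [
    "NATURES",
    "FLAVORS",
    "MERIDIANS",
    "HerbAttributeTable",
    "PropertyStats",
    "MissingHerbsError",
    "calc_property",
    "calc_func",
]

logger = logging.getLogger(__name__)

NATURES = ("cold", "cool", "neutral", "warm", "hot")
FLAVORS = ("sour", "bitter", "sweet", "pungent", "salty", "bland", "astringent")
MERIDIANS = (
    "Lung",
    "Large Intestine",
    "Stomach",
    "Spleen",
    "Heart",
    "Small Intestine",
    "Bladder",
    "Kidney",
    "Pericardium",
    "Triple Burner",
    "Gallbladder",
    "Liver",
)


class MissingHerbsError(KeyError):
    def __init__(self, herbs: list[str]):
        self.herbs = herbs
        super().__init__(f"herbs absent from attribute table: {sorted(herbs)}")


@dataclass
class HerbAttributeTable:
    """Per-herb attribute records.

    ``nature`` maps herb -> single nature; ``flavors``/``meridians`` map
    herb -> tuple of categories; ``efficacy`` maps herb -> hierarchical
    class path such as ``("tonifying", "qi")``.
    """

    nature: dict[str, str]
    flavors: dict[str, tuple[str, ...]]
    meridians: dict[str, tuple[str, ...]]
    efficacy: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        bad = {h: n for h, n in self.nature.items() if n not in NATURES}
        if bad:
            raise ValueError(f"invalid nature value(s): {bad}")

    def herbs(self) -> set[str]:
        return set(self.nature)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HerbAttributeTable":
        """Build from a table with columns herb, nature, flavors (``|``-separated),
        meridians (``|``-separated), efficacy_class (``/``-separated hierarchy)."""
        need = {"herb", "nature", "flavors", "meridians", "efficacy_class"}
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"attribute table lacks column(s): {sorted(missing)}")

        def split(s: object, sep: str) -> tuple[str, ...]:
            if pd.isna(s) or not str(s).strip():
                return ()
            return tuple(p.strip() for p in str(s).split(sep) if p.strip())

        herbs = df["herb"].astype(str)
        return cls(
            nature=dict(zip(herbs, df["nature"].astype(str).str.strip())),
            flavors={h: split(v, "|") for h, v in zip(herbs, df["flavors"])},
            meridians={h: split(v, "|") for h, v in zip(herbs, df["meridians"])},
            efficacy={h: split(v, "/") for h, v in zip(herbs, df["efficacy_class"])},
        )


@dataclass
class PropertyStats:
    """Three category tables (nature, flavor, meridian), each with columns
    category, unweighted_count, weighted_count."""

    nature: pd.DataFrame
    flavor: pd.DataFrame
    meridian: pd.DataFrame


def _occurrence_counts(ds: FormulaDataset) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, s in ds.formulas:
        for h in s:
            counts[h] = counts.get(h, 0) + 1
    return counts


def _check_coverage(
    herbs: set[str], attrs: HerbAttributeTable, skip_missing: bool
) -> set[str]:
    missing = herbs - attrs.herbs()
    if missing:
        if not skip_missing:
            raise MissingHerbsError(sorted(missing))
        logger.info("skipping %d herb(s) absent from attribute table", len(missing))
    return herbs - missing


def _tally(
    herb_cats: dict[str, tuple[str, ...]],
    occ: dict[str, int],
    order: tuple[str, ...] | None,
) -> pd.DataFrame:
    unweighted: dict[str, int] = {}
    weighted: dict[str, int] = {}
    for herb, cats in herb_cats.items():
        for c in cats:
            unweighted[c] = unweighted.get(c, 0) + 1
            weighted[c] = weighted.get(c, 0) + occ[herb]
    if order is not None:
        cats_sorted = [c for c in order if c in unweighted] + sorted(
            set(unweighted) - set(order)
        )
    else:
        cats_sorted = sorted(unweighted, key=lambda c: (-weighted[c], c))
    return pd.DataFrame(
        {
            "category": cats_sorted,
            "unweighted_count": [unweighted[c] for c in cats_sorted],
            "weighted_count": [weighted[c] for c in cats_sorted],
        }
    )


def calc_property(
    ds: FormulaDataset, attrs: HerbAttributeTable, *, skip_missing: bool = False
) -> PropertyStats:
    """Nature/flavor/meridian frequency tables over the herbs of a dataset.

    Raises :class:`MissingHerbsError` when a dataset herb has no attribute
    record, unless ``skip_missing`` is set (missing herbs are then excluded
    and logged).
    """
    occ = _occurrence_counts(ds)
    covered = _check_coverage(set(occ), attrs, skip_missing)
    return PropertyStats(
        nature=_tally({h: (attrs.nature[h],) for h in covered}, occ, NATURES),
        flavor=_tally({h: attrs.flavors[h] for h in covered}, occ, FLAVORS),
        meridian=_tally({h: attrs.meridians[h] for h in covered}, occ, MERIDIANS),
    )


def calc_func(
    ds: FormulaDataset, attrs: HerbAttributeTable, *, skip_missing: bool = False
) -> pd.DataFrame:
    """Efficacy-classification counts with parent/child structure.

    Returns one row per full class path plus ``parent``/``child`` columns so
    the table can feed a sunburst-style plot directly. Herbs with an empty
    efficacy class are excluded (logged) when ``skip_missing`` is set.
    """
    occ = _occurrence_counts(ds)
    covered = _check_coverage(set(occ), attrs, skip_missing)
    no_class = {h for h in covered if not attrs.efficacy[h]}
    if no_class:
        if not skip_missing:
            raise MissingHerbsError(sorted(no_class))
        logger.info("excluding %d herb(s) without efficacy class", len(no_class))
        covered -= no_class
    herb_paths = {h: ("/".join(attrs.efficacy[h]),) for h in covered}
    out = _tally(herb_paths, occ, None)
    out = out.rename(columns={"category": "efficacy_class"})
    parts = out["efficacy_class"].str.split("/")
    out["parent"] = parts.str[0]
    out["child"] = parts.map(lambda p: "/".join(p[1:]) if len(p) > 1 else "")
    return out[["efficacy_class", "parent", "child", "unweighted_count", "weighted_count"]]
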