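"""Cleaning and reshaping of raw prescription tables.

A raw prescription table is "long": one row per (formula, recorded term),
where a term may be an ingredient, a diagnosis, a syndrome or a symptom.
Real-world tables of this kind carry synonym variants (regional names,
processed forms, full-width punctuation) and accidental duplicate entries.
This module resolves terms against a synonym lookup table, collapses
duplicates, and converts between the long form and the binary
formula-by-ingredient incidence matrix used by all downstream statistics.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FIELD_TYPES",
    "LookupTable",
    "FormulaDataset",
    "LookupCollisionError",
    "UnmatchedTermsError",
    "normalize_term",
    "make_lookup",
    "add_reference_terms",
    "clean_dataset",
    "to_wide",
    "to_long",
    "freq_table",
]

logger = logging.getLogger(__name__)

FIELD_TYPES = ("ingredient", "diagnosis", "syndrome", "symptom")

#: columns expected in a raw record table
RAW_COLUMNS = ("formula_id", "field_type", "raw_term")


class LookupCollisionError(ValueError):
    """Raised when an addition maps an existing raw term to a different standard term."""

    def __init__(self, conflicts: list[tuple[str, str, str]]):
        self.conflicts = conflicts
        lines = ", ".join(f"{r!r}: {old!r} vs {new!r}" for r, old, new in conflicts)
        super().__init__(f"conflicting lookup additions: {lines}")


class UnmatchedTermsError(ValueError):
    """Raised when raw terms have no standard mapping and dropping was not requested."""

    def __init__(self, terms: list[str]):
        self.terms = terms
        shown = ", ".join(repr(t) for t in sorted(terms)[:20])
        more = "" if len(terms) <= 20 else f" (+{len(terms) - 20} more)"
        super().__init__(f"{len(terms)} unmatched term(s): {shown}{more}")


def normalize_term(term: str) -> str:
    """Canonical form used for matching: trim, collapse internal whitespace,
    full-width -> half-width, case-fold Latin. CJK characters are kept as-is
    (NFKC maps full-width Latin/punctuation without touching ordinary CJK).
    """
    t = unicodedata.normalize("NFKC", str(term))
    t = " ".join(t.split())
    return t.casefold()


@dataclass
class LookupTable:
    """Mapping from raw/variant terms to standardized terms.

    ``entries`` keys are stored verbatim; matching is done on the normalized
    form, so ``"Huang Qi"`` and ``"huang  qi"`` hit the same entry.
    """

    entries: dict[str, str] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._norm = {normalize_term(k): v for k, v in self.entries.items()}
        if len(self._norm) < len(self.entries):
            seen: dict[str, str] = {}
            for k, v in self.entries.items():
                nk = normalize_term(k)
                if nk in seen and seen[nk] != v:
                    raise LookupCollisionError([(k, seen[nk], v)])
                seen[nk] = v

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self._norm

    def get(self, term: str) -> str | None:
        """Standard term for ``term``, or None if unmapped."""
        return self._norm.get(normalize_term(term))

    @property
    def standard_terms(self) -> set[str]:
        return set(self.entries.values())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LookupTable":
        """Build from a 2-column table (raw, standard); extra columns ignored."""
        raw_col, std_col = df.columns[:2]
        return cls(entries=dict(zip(df[raw_col].astype(str), df[std_col].astype(str))))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw": list(self.entries), "standard": list(self.entries.values())}
        )


@dataclass
class FormulaDataset:
    """A collection of prescriptions, each a set of standardized ingredient labels.

    ``formulas`` preserves input order; ``annotations`` optionally carries
    per-formula syndrome/symptom/dose records keyed by formula_id.
    """

    formulas: list[tuple[str, frozenset[str]]] = field(default_factory=list)
    annotations: dict[str, dict[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [fid for fid, _ in self.formulas]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate formula_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.formulas)

    def __iter__(self):
        return iter(self.formulas)

    @property
    def ids(self) -> list[str]:
        return [fid for fid, _ in self.formulas]

    @property
    def ingredient_sets(self) -> list[frozenset[str]]:
        return [s for _, s in self.formulas]

    def vocabulary(self) -> set[str]:
        out: set[str] = set()
        for _, s in self.formulas:
            out |= s
        return out

    def get(self, formula_id: str) -> frozenset[str]:
        for fid, s in self.formulas:
            if fid == formula_id:
                return s
        raise KeyError(formula_id)

    def subset(self, ids: list[str]) -> "FormulaDataset":
        wanted = set(ids)
        return FormulaDataset(
            formulas=[(f, s) for f, s in self.formulas if f in wanted],
            annotations={k: v for k, v in self.annotations.items() if k in wanted},
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "FormulaDataset":
        """Build from a long table with columns formula_id, ingredient."""
        groups: dict[str, set[str]] = {}
        order: list[str] = []
        for fid, ing in zip(df["formula_id"].astype(str), df["ingredient"].astype(str)):
            if fid not in groups:
                groups[fid] = set()
                order.append(fid)
            groups[fid].add(ing)
        return cls(formulas=[(fid, frozenset(groups[fid])) for fid in order])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (fid, ing) for fid, s in self.formulas for ing in sorted(s)
        ]
        return pd.DataFrame(rows, columns=["formula_id", "ingredient"])


def _validate_raw(raw: pd.DataFrame) -> pd.DataFrame:
    if raw.empty:
        raise ValueError("raw record table is empty")
    missing = [c for c in ("formula_id", "raw_term") if c not in raw.columns]
    if missing:
        raise ValueError(f"raw record table lacks column(s): {missing}")
    out = raw.copy()
    if "field_type" not in out.columns:
        out["field_type"] = "ingredient"
    bad = ~out["field_type"].isin(FIELD_TYPES)
    if bad.any():
        raise ValueError(
            f"unknown field_type value(s): {sorted(out.loc[bad, 'field_type'].unique())}"
        )
    out["formula_id"] = out["formula_id"].astype(str).str.strip()
    out["raw_term"] = out["raw_term"].astype(str).str.strip()
    if (out["formula_id"] == "").any():
        raise ValueError("empty formula_id in raw record table")
    out = out[out["raw_term"] != ""]
    if out.empty:
        raise ValueError("raw record table has no non-blank terms")
    return out


def make_lookup(raw: pd.DataFrame, reference: LookupTable) -> LookupTable:
    """Match distinct raw terms against a reference lookup table.

    Returns a lookup covering exactly the raw terms: matched ones carry
    their standard mapping, the rest land in ``unmatched`` (the report a
    curator works through before re-running the cleaning step).
    """
    if len(reference) == 0:
        raise ValueError("reference lookup table is empty")
    raw = _validate_raw(raw)
    entries: dict[str, str] = {}
    unmatched: list[str] = []
    seen: set[str] = set()
    for term in raw["raw_term"]:
        key = normalize_term(term)
        if key in seen:
            continue
        seen.add(key)
        std = reference.get(term)
        if std is None:
            unmatched.append(term)
        else:
            entries[term] = std
    return LookupTable(entries=entries, unmatched=sorted(unmatched))


def add_reference_terms(
    reference: LookupTable, additions: list[tuple[str, str]]
) -> LookupTable:
    """Extend a lookup with user-supplied (raw, standard) pairs.

    Re-adding an identical entry is a no-op; mapping an existing raw term to
    a *different* standard term is reported as a collision, never silently
    overwritten.
    """
    entries = dict(reference.entries)
    norm = {normalize_term(k): v for k, v in entries.items()}
    conflicts: list[tuple[str, str, str]] = []
    for item in additions:
        raw, std = item[0], item[1]  # trailing attribute payloads ignored here
        if not str(raw).strip() or not str(std).strip():
            raise ValueError("additions must have non-empty raw and standard fields")
        key = normalize_term(raw)
        if key in norm:
            if norm[key] != std:
                conflicts.append((raw, norm[key], std))
            continue
        entries[raw] = std
        norm[key] = std
    if conflicts:
        raise LookupCollisionError(conflicts)
    return LookupTable(entries=entries, unmatched=list(reference.unmatched))


def clean_dataset(
    raw: pd.DataFrame,
    lookup: LookupTable,
    *,
    drop_unmatched: bool = False,
    keep_empty: bool = False,
) -> FormulaDataset:
    """Standardize a raw record table into a :class:`FormulaDataset`.

    Every ingredient term is mapped through ``lookup``; duplicates within a
    formula collapse to one (set semantics). Terms without a mapping abort
    with :class:`UnmatchedTermsError` unless ``drop_unmatched`` is set, in
    which case they are discarded with a logged count. Formulas left empty
    after cleaning are dropped by default.

    Non-ingredient rows (syndrome, symptom, diagnosis) are standardized the
    same way where the lookup covers them (kept verbatim otherwise) and
    stored in ``annotations``.
    """
    raw = _validate_raw(raw)
    unmatched = sorted(
        {
            t
            for t in raw.loc[raw["field_type"] == "ingredient", "raw_term"]
            if lookup.get(t) is None
        }
    )
    if unmatched and not drop_unmatched:
        raise UnmatchedTermsError(unmatched)
    if unmatched:
        n_rows = int(
            (
                (raw["field_type"] == "ingredient")
                & raw["raw_term"].map(lambda t: lookup.get(t) is None)
            ).sum()
        )
        logger.info(
            "dropping %d unmatched ingredient term(s) across %d row(s)",
            len(unmatched),
            n_rows,
        )

    order: list[str] = []
    sets: dict[str, set[str]] = {}
    annotations: dict[str, dict[str, object]] = {}
    for row in raw.itertuples(index=False):
        fid = row.formula_id
        if fid not in sets:
            sets[fid] = set()
            order.append(fid)
        if row.field_type == "ingredient":
            std = lookup.get(row.raw_term)
            if std is not None:
                sets[fid].add(std)
        else:
            std = lookup.get(row.raw_term) or row.raw_term
            ann = annotations.setdefault(fid, {})
            bucket = ann.setdefault(row.field_type, [])
            if std not in bucket:  # dedup within record
                bucket.append(std)

    empties = [fid for fid in order if not sets[fid]]
    if empties and not keep_empty:
        logger.info("dropping %d formula(s) left empty after cleaning", len(empties))
        order = [fid for fid in order if sets[fid]]
    return FormulaDataset(
        formulas=[(fid, frozenset(sets[fid])) for fid in order],
        annotations={k: v for k, v in annotations.items() if k in set(order)},
    )


def _ordered_columns(counts: dict[str, int]) -> list[str]:
    # frequency descending, ties alphabetical: byte-reproducible column order
    return sorted(counts, key=lambda t: (-counts[t], t))


def to_wide(ds: FormulaDataset) -> pd.DataFrame:
    """Binary formula-by-ingredient incidence matrix.

    Rows follow dataset order; columns are ordered by descending total
    frequency with alphabetical tie-break, so output is reproducible.
    """
    counts: dict[str, int] = {}
    for _, s in ds.formulas:
        for ing in s:
            counts[ing] = counts.get(ing, 0) + 1
    cols = _ordered_columns(counts)
    data = [[1 if c in s else 0 for c in cols] for _, s in ds.formulas]
    return pd.DataFrame(data, index=pd.Index(ds.ids, name="formula_id"), columns=cols)


def to_long(m: pd.DataFrame) -> FormulaDataset:
    """Inverse of :func:`to_wide` (annotations are not representable in wide form)."""
    vals = m.to_numpy()
    if not ((vals == 0) | (vals == 1)).all():
        bad = [
            (m.index[i], m.columns[j])
            for i, j in zip(*((vals != 0) & (vals != 1)).nonzero())
        ]
        raise ValueError(f"non-binary cell(s) in wide matrix: {bad[:5]}")
    formulas = [
        (str(fid), frozenset(m.columns[vals[i].astype(bool)]))
        for i, fid in enumerate(m.index)
    ]
    return FormulaDataset(formulas=formulas)


def freq_table(ds: FormulaDataset, field: str = "ingredient") -> pd.DataFrame:
    """Term frequency table sorted by count descending (ties alphabetical).

    ``relative_frequency`` is count over the number of formulas, i.e. the
    support of the single term.
    """
    if field not in FIELD_TYPES:
        raise ValueError(f"unknown field {field!r}; expected one of {FIELD_TYPES}")
    counts: dict[str, int] = {}
    if field == "ingredient":
        for _, s in ds.formulas:
            for ing in s:
                counts[ing] = counts.get(ing, 0) + 1
    else:
        for fid in ds.ids:
            for term in ds.annotations.get(fid, {}).get(field, []):
                counts[term] = counts.get(term, 0) + 1
    n = len(ds)
    terms = _ordered_columns(counts)
    return pd.DataFrame(
        {
            "term": terms,
            "count": [counts[t] for t in terms],
            "relative_frequency": [counts[t] / n if n else 0.0 for t in terms],
        }
    )
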