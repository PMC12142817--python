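"""Synthetic prescription datasets with known ground truth.

Real prescription corpora have a heavy-tailed ingredient usage profile (a
handful of harmonizing herbs appear everywhere, most herbs rarely) and
recurrent core combinations that association-rule mining is supposed to
recover. The generator reproduces both: background ingredients are drawn
from a Zipf rank-frequency law over the vocabulary, and "planted motifs" —
fixed ingredient combinations — are included wholesale with a configurable
probability per formula. Two noise knobs emulate transcription problems:
``synonym_noise_rate`` swaps a standardized name for a known variant from
the packaged lookup, ``duplicate_entry_rate`` repeats an entry within a
record. Ground truth (true ingredient sets, motif placements) is always
returned alongside so tests never reverse-engineer it from the output.

The packaged fixtures (``load_fixture``) are a small synthetic stand-in for
a curated reference: a synonym lookup (~140 pairs over 60 herbs), a herb
attribute table, and 15 classical formula compositions. They emulate the
*shape* of a real curated reference, not its content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .attributes import HerbAttributeTable
from .standardize import FormulaDataset, LookupTable

__all__ = ["SimConfig", "GroundTruth", "simulate", "load_fixture", "fixture_herbs"]

_FIXTURE_FILES = {
    "lookup": "synthetic_lookup.csv",
    "attributes": "synthetic_attributes.csv",
    "classics": "synthetic_classics.csv",
}


def _read_fixture(name: str) -> pd.DataFrame:
    if name not in _FIXTURE_FILES:
        raise ValueError(
            f"unknown fixture {name!r}; expected one of {sorted(_FIXTURE_FILES)}"
        )
    path = resources.files("fminer.data") / _FIXTURE_FILES[name]
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def load_fixture(name: str):
    """Load a packaged fixture table.

    ``lookup`` -> :class:`LookupTable`; ``attributes`` ->
    :class:`HerbAttributeTable`; ``classics`` -> :class:`FormulaDataset`.
    """
    df = _read_fixture(name)
    if name == "lookup":
        return LookupTable.from_frame(df)
    if name == "attributes":
        return HerbAttributeTable.from_frame(df)
    return FormulaDataset.from_long(df)


def fixture_herbs() -> list[str]:
    """Standardized herb vocabulary of the packaged fixtures (61 terms max)."""
    return list(_read_fixture("attributes")["herb"])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic prescription generator.

    Defaults emulate a mid-sized clinical corpus: 2000 formulas over an
    80-herb vocabulary, 8-15 ingredients each, Zipf exponent 1.0 for the
    rank-frequency law, and noise off.
    """

    n_formulas: int = 2000
    vocabulary_size: int = 80
    formula_size_range: tuple[int, int] = (8, 15)
    zipf_exponent: float = 1.0
    planted_motifs: tuple[tuple[tuple[str, ...], float], ...] = ()
    synonym_noise_rate: float = 0.0
    duplicate_entry_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.formula_size_range
        if not (1 <= lo <= hi):
            raise ValueError("formula_size_range must satisfy 1 <= min <= max")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        for rate in (self.synonym_noise_rate, self.duplicate_entry_rate):
            if not 0 <= rate <= 1:
                raise ValueError("noise rates must be in [0, 1]")
        for motif, prob in self.planted_motifs:
            if not 0 <= prob <= 1:
                raise ValueError("motif inclusion probabilities must be in [0, 1]")
            if len(motif) > hi:
                raise ValueError(
                    f"motif {motif} larger than the maximum formula size {hi}"
                )


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    vocabulary: list[str]
    true_sets: dict[str, frozenset[str]]
    motif_members: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)
    term_map: dict[str, str] = field(default_factory=dict)  # variant -> standard used


def _vocabulary(size: int) -> list[str]:
    base = fixture_herbs()
    if size <= len(base):
        return base[:size]
    extra = [f"Herb{i:03d}" for i in range(size - len(base))]
    return base + extra


def _variant_map() -> dict[str, list[str]]:
    """standard -> non-identity raw variants from the packaged lookup."""
    df = _read_fixture("lookup")
    out: dict[str, list[str]] = {}
    for raw, std in zip(df["raw"], df["standard"]):
        if raw != std:
            out.setdefault(std, []).append(raw)
    return out


def simulate(cfg: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a raw record table plus its ground truth.

    Returns a long table with columns formula_id, field_type, raw_term,
    dose; doses are uniform placeholders. Identical config and seed give
    byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    vocab = _vocabulary(cfg.vocabulary_size)
    vocab_index = {h: i for i, h in enumerate(vocab)}
    for motif, _ in cfg.planted_motifs:
        missing = [h for h in motif if h not in vocab_index]
        if missing:
            raise ValueError(f"motif herb(s) outside vocabulary: {missing}")

    ranks = np.arange(1, len(vocab) + 1, dtype=float)
    weights = ranks**-cfg.zipf_exponent
    weights /= weights.sum()
    variants = _variant_map() if cfg.synonym_noise_rate > 0 else {}

    lo, hi = cfg.formula_size_range
    rows: list[tuple[str, str, str, float]] = []
    true_sets: dict[str, frozenset[str]] = {}
    motif_members: dict[str, list[tuple[str, ...]]] = {}
    term_map: dict[str, str] = {}
    for i in range(cfg.n_formulas):
        fid = f"F{i + 1:05d}"
        size = int(rng.integers(lo, hi + 1))
        chosen: set[str] = set()
        planted: list[tuple[str, ...]] = []
        for motif, prob in cfg.planted_motifs:
            if rng.random() < prob:
                chosen.update(motif)
                planted.append(tuple(motif))
        # fill up with Zipf-weighted background draws (without replacement)
        while len(chosen) < size:
            draw = vocab[int(rng.choice(len(vocab), p=weights))]
            chosen.add(draw)
        true_sets[fid] = frozenset(chosen)
        if planted:
            motif_members[fid] = planted
        entries = sorted(chosen)
        records: list[str] = []
        for herb in entries:
            raw = herb
            if variants.get(herb) and rng.random() < cfg.synonym_noise_rate:
                raw = variants[herb][int(rng.integers(len(variants[herb])))]
                term_map[raw] = herb
            records.append(raw)
        if cfg.duplicate_entry_rate > 0:
            for raw in list(records):
                if rng.random() < cfg.duplicate_entry_rate:
                    records.append(raw)
        for raw in records:
            dose = float(rng.integers(3, 31))
            rows.append((fid, "ingredient", raw, dose))
    table = pd.DataFrame(rows, columns=["formula_id", "field_type", "raw_term", "dose"])
    truth = GroundTruth(
        vocabulary=vocab,
        true_sets=true_sets,
        motif_members=motif_members,
        term_map=term_map,
    )
    return table, truth
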