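"""Planted-signature alignment simulator and recovery scoring.

Generates three-group (or k-group) alignments in which every column's
conservation category is planted and recorded in a truth table, so the
scanner's sensitivity and precision can be measured without any sequence
download.  Columns are generated independently — the scanner's claims
concern per-column exclusivity patterns, not phylogenetic correlation, so
no tree is simulated.

Defaults mirror the published study conditions: 124 bacterial, 21 archaeal
and 362 eukaryotic taxa, with planted counts following the reported site
census (26 archaea+eukaryote signatures, 6 archaea+bacteria, 1
bacteria+eukaryote, 7 eukaryote synapomorphies) plus universal and
background columns.

Guarantee: with ``noise_rate`` 0 and strict scanning, recovery is exact —
sensitivity and precision 1.0 for every planted category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .msaio import Alignment, GroupMap, RegionMask
from .scan import (
    Category,
    INDEL,
    SUBSTITUTION,
    SignatureSite,
    UNCLASSIFIED,
    UNIVERSAL,
    parse_category,
)
from .symbols import ALPHABET, BASES, GAP


def _default_group_sizes() -> dict[str, int]:
    return {"Bacteria": 124, "Archaea": 21, "Eukaryota": 362}


def _default_pair_substitutions() -> dict[tuple[str, str], int]:
    return {
        ("Archaea", "Eukaryota"): 22,
        ("Archaea", "Bacteria"): 5,
        ("Bacteria", "Eukaryota"): 1,
    }


def _default_pair_indels() -> dict[tuple[str, str], int]:
    return {("Archaea", "Eukaryota"): 4, ("Archaea", "Bacteria"): 1}


def _default_only_substitutions() -> dict[str, int]:
    return {"Eukaryota": 7}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    ``shared_extra_max`` controls within-group diversity of the *sharing*
    groups at a planted pair column (0–N extra non-gap symbols on top of
    the shared one); ``excluded_set_max`` bounds the sampled symbol-set
    size of the excluded/variable group (1–4 per the IUPAC code range).
    ``noise_rate`` flips each cell to a uniformly random symbol of the
    five-letter alphabet independently.
    """

    group_sizes: Mapping[str, int] = field(default_factory=_default_group_sizes)
    n_universal: int = 30
    pair_substitutions: Mapping[tuple[str, str], int] = field(
        default_factory=_default_pair_substitutions
    )
    pair_indels: Mapping[tuple[str, str], int] = field(
        default_factory=_default_pair_indels
    )
    only_substitutions: Mapping[str, int] = field(
        default_factory=_default_only_substitutions
    )
    only_indels: Mapping[str, int] = field(default_factory=dict)
    n_background: int = 60
    shared_extra_max: int = 1
    excluded_set_max: int = 4
    noise_rate: float = 0.0
    masked_intervals: tuple = ()
    seed: int = 0

    @property
    def total_columns(self) -> int:
        return (
            self.n_universal
            + sum(self.pair_substitutions.values())
            + sum(self.pair_indels.values())
            + sum(self.only_substitutions.values())
            + sum(self.only_indels.values())
            + self.n_background
        )

    def validate(self) -> None:
        groups = sorted(self.group_sizes)
        if len(groups) < 2:
            raise ValueError("need at least 2 groups")
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        for counts in (
            self.pair_substitutions,
            self.pair_indels,
        ):
            for (x, y), n in counts.items():
                if n < 0:
                    raise ValueError("negative planted count")
                if x not in self.group_sizes or y not in self.group_sizes or x == y:
                    raise ValueError(f"bad pair {(x, y)!r}")
        for counts in (self.only_substitutions, self.only_indels):
            for g, n in counts.items():
                if n < 0:
                    raise ValueError("negative planted count")
                if g not in self.group_sizes:
                    raise ValueError(f"unknown group {g!r}")
        if self.n_universal < 0 or self.n_background < 0:
            raise ValueError("negative planted count")
        if self.total_columns == 0:
            raise ValueError("config generates zero columns")
        if not (0 <= self.noise_rate < 1):
            raise ValueError("noise_rate must be in [0, 1)")
        if not (0 <= self.shared_extra_max <= 2):
            raise ValueError("shared_extra_max must be in 0..2")
        if not (1 <= self.excluded_set_max <= 4):
            raise ValueError("excluded_set_max must be in 1..4")
        # ONLY columns give each non-focal group a 2-symbol set, so a
        # 3-group config planting ONLY needs the 4 non-diagnostic symbols;
        # with >3 groups the leftover groups reuse the two 2-symbol sets.
        for start, end in self.masked_intervals:
            if not (0 <= start < end <= self.total_columns):
                raise ValueError(f"masked interval [{start}, {end}) out of range")


@dataclass(frozen=True)
class TruthEntry:
    category: Category
    subtype: Optional[str]


@dataclass(frozen=True)
class TruthTable:
    """Planted category per generated column."""

    entries: Mapping[int, TruthEntry]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "column": col,
                "category": str(e.category),
                "subtype": e.subtype or "",
            }
            for col, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["column", "category", "subtype"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype={"subtype": str}, keep_default_na=False)
        entries = {
            int(r.column): TruthEntry(parse_category(r.category), r.subtype or None)
            for r in df.itertuples()
        }
        return cls(entries)


@dataclass(frozen=True)
class SyntheticDataset:
    alignment: Alignment
    group_map: GroupMap
    mask: RegionMask
    truth: TruthTable
    config: SyntheticConfig


def _fill_group(rng, symbols: Sequence[str], n: int) -> list[str]:
    """Sample n residues from ``symbols`` guaranteeing every symbol occurs."""
    symbols = list(symbols)
    if len(symbols) > n:
        raise ValueError(
            f"group of {n} taxa cannot exhibit {len(symbols)} distinct symbols"
        )
    out = [symbols[int(i)] for i in rng.integers(0, len(symbols), size=n)]
    slots = rng.permutation(n)[: len(symbols)]
    for sym, slot in zip(symbols, slots):
        out[int(slot)] = sym
    return out


def _plant_pair(rng, groups, sizes, x, y, indel, cfg):
    """Column where x and y exclusively share a symbol (gap if indel)."""
    shared = GAP if indel else str(rng.choice(BASES))
    base_pool = [b for b in BASES if b != shared]
    sets = {}
    for g in (x, y):
        extra_n = int(rng.integers(0, cfg.shared_extra_max + 1))
        extras = list(rng.choice(base_pool, size=extra_n, replace=False))
        cap = sizes[g]
        sets[g] = [shared] + extras[: max(0, cap - 1)]
    used = {s for g in (x, y) for s in sets[g]}
    pool = [s for s in ALPHABET if s not in used]
    assert pool, "infeasible pair column"
    excluded = [g for g in groups if g not in (x, y)]
    for g in excluded:
        k = int(rng.integers(1, min(cfg.excluded_set_max, len(pool), sizes[g]) + 1))
        sets[g] = list(rng.choice(pool, size=k, replace=False))
    col = {g: _fill_group(rng, sets[g], sizes[g]) for g in groups}
    return col, TruthEntry(
        Category("PAIR", (x, y)), INDEL if indel else SUBSTITUTION
    )


def _plant_only(rng, groups, sizes, focal, indel, cfg):
    """Column where ``focal`` is fixed for a private symbol.

    The remaining groups get 2-symbol sets drawn from the other four
    symbols, pairwise-disjoint between the first two of them, so no PAIR
    and no competing ONLY arises at the column.
    """
    diag = GAP if indel else str(rng.choice(BASES))
    rest = [s for s in ALPHABET if s != diag]
    perm = list(rng.permutation(rest))
    others = [g for g in groups if g != focal]
    # First two non-focal groups get disjoint 2-symbol halves (no PAIR, no
    # competing ONLY); any further groups straddle the halves so that no
    # subset of non-focal groups is exclusively shared either.
    assigned = [perm[:2], perm[2:4]] + [
        [perm[1], perm[2]] for _ in range(max(0, len(others) - 2))
    ]
    sets = {focal: [diag]}
    for g, chosen in zip(others, assigned):
        sets[g] = chosen[: max(1, min(len(chosen), sizes[g]))]
    col = {g: _fill_group(rng, sets[g], sizes[g]) for g in groups}
    return col, TruthEntry(
        Category("ONLY", (focal,)), INDEL if indel else SUBSTITUTION
    )


def generate_alignment(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate alignment + group map + mask + truth table.

    Deterministic under a fixed seed; planted columns are shuffled over the
    matrix so category is independent of position.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    groups = sorted(cfg.group_sizes)
    sizes = dict(cfg.group_sizes)

    columns: list[dict[str, list[str]]] = []
    truths: list[TruthEntry] = []

    for _ in range(cfg.n_universal):
        sym = str(rng.choice(BASES))
        columns.append({g: [sym] * sizes[g] for g in groups})
        truths.append(TruthEntry(UNIVERSAL, SUBSTITUTION))
    for (x, y), n in sorted(cfg.pair_substitutions.items()):
        for _ in range(n):
            col, t = _plant_pair(rng, groups, sizes, x, y, False, cfg)
            columns.append(col)
            truths.append(t)
    for (x, y), n in sorted(cfg.pair_indels.items()):
        for _ in range(n):
            col, t = _plant_pair(rng, groups, sizes, x, y, True, cfg)
            columns.append(col)
            truths.append(t)
    for g, n in sorted(cfg.only_substitutions.items()):
        for _ in range(n):
            col, t = _plant_only(rng, groups, sizes, g, False, cfg)
            columns.append(col)
            truths.append(t)
    for g, n in sorted(cfg.only_indels.items()):
        for _ in range(n):
            col, t = _plant_only(rng, groups, sizes, g, True, cfg)
            columns.append(col)
            truths.append(t)
    for _ in range(cfg.n_background):
        columns.append(
            {
                g: [str(s) for s in rng.choice(BASES, size=sizes[g])]
                for g in groups
            }
        )
        truths.append(TruthEntry(UNCLASSIFIED, None))

    order = rng.permutation(len(columns))
    columns = [columns[int(i)] for i in order]
    truths = [truths[int(i)] for i in order]

    taxa: list[tuple[str, str]] = []  # (taxon, group)
    for g in groups:
        for i in range(sizes[g]):
            taxa.append((f"{g}_{i + 1:03d}", g))

    matrix = np.empty((len(taxa), len(columns)), dtype="U1")
    for c, col in enumerate(columns):
        r = 0
        for g in groups:
            matrix[r : r + sizes[g], c] = col[g]
            r += sizes[g]

    if cfg.noise_rate > 0:
        flip = rng.random(matrix.shape) < cfg.noise_rate
        noise = np.array(ALPHABET)[
            rng.integers(0, len(ALPHABET), size=matrix.shape)
        ]
        matrix = np.where(flip, noise, matrix)

    aln = Alignment(
        tuple(t for t, _ in taxa),
        tuple("".join(row) for row in matrix),
    )
    gmap = GroupMap({t: g for t, g in taxa})
    mask = RegionMask.from_intervals(list(cfg.masked_intervals))
    truth = TruthTable({c: t for c, t in enumerate(truths)})
    return SyntheticDataset(aln, gmap, mask, truth, cfg)


@dataclass(frozen=True)
class RecoveryReport:
    """Sensitivity/precision per planted category plus a confusion matrix."""

    sensitivity: Mapping[str, float]
    precision: Mapping[str, float]
    n_planted: Mapping[str, int]
    n_reported: Mapping[str, int]
    confusion: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "sensitivity": dict(self.sensitivity),
            "precision": dict(self.precision),
            "n_planted": dict(self.n_planted),
            "n_reported": dict(self.n_reported),
        }


def evaluate_recovery(
    sites: Sequence[SignatureSite], truth: TruthTable
) -> RecoveryReport:
    """Score scanned sites against the planted truth (exact category match).

    Sensitivity(cat) = planted-cat columns recovered as cat / planted;
    precision(cat) = reported-cat sites that were planted cat / reported.
    Sites must be unmerged (one column each) and lie within the truth's
    column set.
    """
    reported: dict[int, str] = {}
    for s in sites:
        if s.column != s.end_column:
            raise ValueError("recovery scoring needs unmerged single-column sites")
        if s.column not in truth.entries:
            raise ValueError(f"site column {s.column} not in truth table")
        reported[s.column] = str(s.category)

    planted = {c: str(e.category) for c, e in truth.entries.items()}
    cats = sorted(
        {c for c in planted.values() if c != "UNCLASSIFIED"}
        | set(reported.values())
    )
    sens: dict[str, float] = {}
    prec: dict[str, float] = {}
    n_planted: dict[str, int] = {}
    n_reported: dict[str, int] = {}
    for cat in cats:
        p_cols = [c for c, pc in planted.items() if pc == cat]
        r_cols = [c for c, rc in reported.items() if rc == cat]
        n_planted[cat] = len(p_cols)
        n_reported[cat] = len(r_cols)
        hits = sum(1 for c in p_cols if reported.get(c) == cat)
        sens[cat] = hits / len(p_cols) if p_cols else float("nan")
        prec[cat] = (
            sum(1 for c in r_cols if planted[c] == cat) / len(r_cols)
            if r_cols
            else float("nan")
        )
    confusion = pd.crosstab(
        pd.Series(
            {c: planted[c] for c in planted}, name="planted"
        ),
        pd.Series(
            {c: reported.get(c, "UNREPORTED") for c in planted}, name="reported"
        ),
    )
    return RecoveryReport(sens, prec, n_planted, n_reported, confusion)
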