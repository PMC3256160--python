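"""Join signature sites to functional ribosome annotations.

Many reference rRNA positions have known roles: the peptidyl transferase
centre (PTC), the A/P/E tRNA binding sites, intersubunit bridges, and
antibiotic-resistance determinants (the classic example being position
2058 of the bacterial large-subunit rRNA, whose A vs. G state separates
macrolide-sensitive from macrolide-resistant ribosomes).  Annotations are
user-supplied BED-like files in reference numbering; this module overlays
them on scanned sites and tabulates category × function.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import pandas as pd

from .coordmap import Flank, Point, RefCoordinate
from .msaio import _data_lines
from .scan import SignatureSite

NO_FUNCTION = "NONE"


@dataclass(frozen=True)
class FunctionalAnnotation:
    """Tags per reference position (1-based, reported numbering)."""

    ref_taxon: str
    tags: Mapping[int, frozenset]

    def tags_at(self, position: int) -> frozenset:
        return self.tags.get(position, frozenset())


def read_annotations(path) -> FunctionalAnnotation:
    """Read a BED-like annotation file: ``ref  start  end  tag[,tag...]``.

    Intervals are 0-based half-open in the reference's reported numbering;
    they expand to per-position tag sets, unioned where intervals overlap.
    All records must name the same reference taxon.
    """
    ref: Optional[str] = None
    tags: dict[int, set] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(
                f"{path}:{lineno}: expected 'ref start end tags' (4 columns)"
            )
        name, tag_field = parts[0], parts[3]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
        if start < 0 or start >= end:
            raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        entry_tags = frozenset(t.strip() for t in tag_field.split(",") if t.strip())
        if not entry_tags:
            raise ValueError(f"{path}:{lineno}: empty tag column")
        if ref is None:
            ref = name
        elif name != ref:
            raise ValueError(
                f"{path}:{lineno}: mixed reference taxa {ref!r} and {name!r}"
            )
        for pos in range(start + 1, end + 1):
            tags.setdefault(pos, set()).update(entry_tags)
    return FunctionalAnnotation(ref or "", {p: frozenset(t) for p, t in tags.items()})


def tags_for_coordinate(
    coord: RefCoordinate, ann: FunctionalAnnotation, match_flanks: bool = False
) -> frozenset:
    """Tags carried by a point coordinate, or (optionally) by either flank
    of a flanked-gap coordinate."""
    if isinstance(coord, Point):
        return ann.tags_at(coord.position)
    if isinstance(coord, Flank) and match_flanks:
        out: frozenset = frozenset()
        for side in (coord.left, coord.right):
            if side is not None:
                out |= ann.tags_at(side.position)
        return out
    return frozenset()


def overlap_sites(
    sites: Sequence[SignatureSite],
    ann: FunctionalAnnotation,
    match_flanks: bool = False,
) -> list[SignatureSite]:
    """Attach function tags to each site via its coordinate on the
    annotation's reference.  Every input site appears exactly once in the
    output; re-annotating is idempotent (tags are recomputed, not stacked).
    """
    out: list[SignatureSite] = []
    for site in sites:
        if ann.ref_taxon not in site.ref_coords:
            raise ValueError(
                f"site at column {site.column} has no coordinates for "
                f"reference {ann.ref_taxon!r}"
            )
        tags: frozenset = frozenset()
        for coord in site.ref_coords[ann.ref_taxon]:
            tags |= tags_for_coordinate(coord, ann, match_flanks)
        out.append(replace(site, functions=tags))
    return out


def summarize_by_function(sites: Sequence[SignatureSite]) -> pd.DataFrame:
    """Contingency table of category × function tag with margins.

    Sites carrying no tag count under ``NONE``; a site with several tags
    counts once per tag, so margins are sums of the cells they border.
    """
    rows = []
    for site in sites:
        for tag in sorted(site.functions) or [NO_FUNCTION]:
            rows.append({"category": str(site.category), "function": tag})
    if not rows:
        return pd.DataFrame(
            {"All": pd.Series({"All": 0})}, dtype=int
        ).rename_axis(index="category", columns="function")
    df = pd.DataFrame(rows)
    table = pd.crosstab(df["category"], df["function"], margins=True)
    return table.sort_index(axis=0).sort_index(axis=1)
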