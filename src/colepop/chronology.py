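"""Ultrametricisation and node-calibration dating.

The dating procedure is deliberately simple, mirroring a crude but
transparent chronology workflow: (1) make a branch-length tree (lengths in
accumulated-SNP units) ultrametric by the max-descendant-path rule, so every
node's height is the largest summed branch length to any descendant tip;
(2) calibrate a clock-like SNP-per-year rate r = height / age at one or more
nodes of known age; (3) convert every node height to an age in years before
present and to a calendar year.  The worked reference arithmetic: a node of
height 3100 SNP units calibrated at 2 500 years gives r = 1.24 SNP·yr⁻¹,
so a root of height 5680 dates to 5680 / 1.24 = 4581 yr ≈ 2560 BC with the
default present year 2021.  No molecular-clock model fitting, rate smoothing
or confidence intervals are attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy

from .errors import ValidationError

DEFAULT_PRESENT_YEAR = 2021


@dataclass
class Calibration:
    """Calibration nodes identified by the tip set of their clade."""

    points: list[tuple[frozenset, float]]  # (clade tip labels, age yr BP)

    def __post_init__(self) -> None:
        if not self.points:
            raise ValidationError("need at least one calibration node")
        for tips, age in self.points:
            if age <= 0:
                raise ValidationError(f"calibration age must be > 0, got {age}")


@dataclass
class Chronogram:
    """An ultrametric tree with node heights (tip = 0), optional rate/ages."""

    tree: dendropy.Tree
    heights: dict  # dendropy.Node -> height in SNP units
    rate: float | None = None  # SNP units per year
    present_year: int = DEFAULT_PRESENT_YEAR

    @property
    def root_height(self) -> float:
        return self.heights[self.tree.seed_node]

    def node_of_clade(self, tip_labels: frozenset) -> dendropy.Node:
        node = self.tree.mrca(taxon_labels=sorted(tip_labels))
        if node is None:
            raise ValidationError(f"no node for clade {sorted(tip_labels)}")
        return node


def ultrametricize(tree: dendropy.Tree) -> Chronogram:
    """Arbitrarily make a rooted branch-length tree ultrametric.

    Node height = maximum summed branch length from the node to any
    descendant tip; branch lengths are rewritten as parent height − child
    height.  Topology is unchanged and the root height equals the original
    maximum root-to-tip path, so the deepest (most SNP-rich) paths are
    preserved exactly.  Idempotent on already-ultrametric trees.
    """
    if not tree.is_rooted:
        raise ValidationError("ultrametricize requires a rooted tree (root it first)")
    work = tree.clone(depth=1)
    heights: dict = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            heights[node] = 0.0
            continue
        hs = []
        for child in node.child_nodes():
            bl = child.edge.length if child.edge.length is not None else 0.0
            if bl < 0:
                raise ValidationError(f"negative branch length {bl}")
            hs.append(heights[child] + bl)
        heights[node] = max(hs)
    for node in work.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = heights[node.parent_node] - heights[node]
    return Chronogram(work, heights)


def rate_from_height(height: float, age_yr: float) -> float:
    """Clock rate r = node height / node age (SNP units per year)."""
    if age_yr <= 0:
        raise ValidationError("calibration age must be > 0")
    if height <= 0:
        raise ValidationError("calibration node height must be > 0")
    return height / age_yr


def calibrate_rate(chronogram: Chronogram, calibration: Calibration) -> float:
    """Mean per-node rate height/age over the calibration nodes."""
    rates = []
    for tips, age in calibration.points:
        node = chronogram.node_of_clade(tips)
        rates.append(rate_from_height(chronogram.heights[node], age))
    r = sum(rates) / len(rates)
    chronogram.rate = r
    return r


def node_ages(chronogram: Chronogram, rate: float | None = None) -> dict:
    """Age (years before present) per node: height / rate (unrounded)."""
    r = rate if rate is not None else chronogram.rate
    if r is None or r <= 0:
        raise ValidationError("need a positive calibrated rate")
    return {node: h / r for node, h in chronogram.heights.items()}


def to_calendar(age_yr: float, present_year: int = DEFAULT_PRESENT_YEAR) -> int:
    """Signed calendar year for an age in years before present.

    Ages are rounded to the nearest year; a negative result is a BCE year
    (e.g. −2560 → "2560 BC").  There is no year zero in the calendar, but
    this crude chronology does not correct for it.
    """
    return present_year - int(round(age_yr))


def format_calendar(year: int) -> str:
    return f"{-year} BC" if year < 0 else f"{year} CE"
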