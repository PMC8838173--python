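"""Segment linking and found/omitted/intruded (F/O/I) accuracy.

The first evaluation stage asks whether the tool saw each edible component the
gold-standard diary recorded.  Reference and tool segments are paired within
each record; reference segments with no partner are *omissions* (O), tool
segments with no partner are *intrusions* (I), pairs are *found* (F).
Accuracy is reported per record-type stratum as percentages of the reference
segment total, with a normal-approximation half-width that uses ``n - 1`` in
the standard-error denominator (the convention that reproduces the study's
printed +/- values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .records import Record
from .taxonomy import FoodTaxonomy

__all__ = [
    "MatchTable",
    "LinkedPair",
    "SegmentationCoding",
    "link_segments",
    "segmentation_accuracy",
    "proportion_halfwidth",
]

#: taxonomy distance above which two segments are not linked automatically
LINK_THRESHOLD = 2.0
_FORBIDDEN = 1e6  # assignment cost standing in for "no link allowed"


@dataclass(frozen=True)
class LinkedPair:
    record_id: str
    ref_idx: int
    app_idx: int


@dataclass
class MatchTable:
    """Outcome of pairing tool segments with reference segments.

    ``links`` are the found pairs; ``omissions``/``intrusions`` hold
    (record_id, segment index) of unpaired reference / tool segments.
    """

    links: list[LinkedPair] = field(default_factory=list)
    omissions: list[tuple[str, int]] = field(default_factory=list)
    intrusions: list[tuple[str, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"record_id": l.record_id, "ref_idx": l.ref_idx, "app_idx": l.app_idx, "code": "F"}
            for l in self.links
        ]
        rows += [
            {"record_id": rid, "ref_idx": i, "app_idx": -1, "code": "O"}
            for rid, i in self.omissions
        ]
        rows += [
            {"record_id": rid, "ref_idx": -1, "app_idx": i, "code": "I"}
            for rid, i in self.intrusions
        ]
        return pd.DataFrame(rows, columns=["record_id", "ref_idx", "app_idx", "code"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MatchTable":
        table = cls()
        for row in df.itertuples(index=False):
            if row.code == "F":
                table.links.append(LinkedPair(str(row.record_id), int(row.ref_idx), int(row.app_idx)))
            elif row.code == "O":
                table.omissions.append((str(row.record_id), int(row.ref_idx)))
            elif row.code == "I":
                table.intrusions.append((str(row.record_id), int(row.app_idx)))
            else:
                raise ValueError(f"unknown segmentation code {row.code!r}")
        return table


def taxonomy_distance(type_a: str, type_b: str, tax: FoodTaxonomy) -> float:
    """0 same type, 1 same group, 2 same category, 3 otherwise."""
    if type_a == type_b:
        return 0.0
    ga, ca = tax.roll_up(type_a)
    gb, cb = tax.roll_up(type_b)
    if ga == gb:
        return 1.0
    if ca == cb:
        return 2.0
    return 3.0


def _pair_cost(ref_seg, app_seg, tax: FoodTaxonomy) -> float:
    dist = taxonomy_distance(ref_seg.food_type, app_seg.food_type, tax)
    if dist > LINK_THRESHOLD:
        return _FORBIDDEN
    denom = max(ref_seg.weight_g, app_seg.weight_g, 1e-9)
    # weight term < 1: it only breaks ties between equal taxonomy distances
    return dist + 0.5 * abs(ref_seg.weight_g - app_seg.weight_g) / denom


def link_segments(
    ref: Sequence[Record],
    app: Sequence[Record],
    tax: FoodTaxonomy,
    manual_links: Optional[Sequence[LinkedPair]] = None,
) -> MatchTable:
    """Pair tool segments with reference segments record by record.

    Within each record the minimum-total-cost one-to-one assignment is used,
    where cost is taxonomy distance (same type 0, same group 1, same category
    2, else unlinkable) plus a sub-unit weight-difference tie-breaker; pairs
    whose taxonomy distance exceeds 2 are never linked.  Optimal assignment is
    deterministic and agrees with exhaustive search, which a greedy pass does
    not guarantee.  ``manual_links`` (as in the study, where linking was a
    human judgement) are fixed first and override the automatic step.

    Raises ``ValueError`` on conflicting manual links or on manual links whose
    record_id/segment indices do not exist.
    """
    ref_by_id = {r.record_id: r for r in ref}
    app_by_id = {r.record_id: r for r in app}

    manual_by_record: dict[str, list[LinkedPair]] = {}
    if manual_links:
        seen_ref: set[tuple[str, int]] = set()
        seen_app: set[tuple[str, int]] = set()
        for link in manual_links:
            if link.record_id not in ref_by_id or link.record_id not in app_by_id:
                raise ValueError(f"manual link references unknown record_id {link.record_id!r}")
            if link.ref_idx >= ref_by_id[link.record_id].n_segments or link.ref_idx < 0:
                raise ValueError(f"manual link {link} references missing reference segment")
            if link.app_idx >= app_by_id[link.record_id].n_segments or link.app_idx < 0:
                raise ValueError(f"manual link {link} references missing app segment")
            rkey, akey = (link.record_id, link.ref_idx), (link.record_id, link.app_idx)
            if rkey in seen_ref or akey in seen_app:
                raise ValueError(f"conflicting manual links at {link}")
            seen_ref.add(rkey)
            seen_app.add(akey)
            manual_by_record.setdefault(link.record_id, []).append(link)

    table = MatchTable()
    for rid in sorted(set(ref_by_id) | set(app_by_id)):
        ref_rec = ref_by_id.get(rid)
        app_rec = app_by_id.get(rid)
        ref_segs = ref_rec.segments if ref_rec else []
        app_segs = app_rec.segments if app_rec else []

        fixed = manual_by_record.get(rid, [])
        used_ref = {l.ref_idx for l in fixed}
        used_app = {l.app_idx for l in fixed}
        table.links.extend(fixed)

        free_ref = [i for i in range(len(ref_segs)) if i not in used_ref]
        free_app = [j for j in range(len(app_segs)) if j not in used_app]
        linked_ref: set[int] = set(used_ref)
        linked_app: set[int] = set(used_app)

        if free_ref and free_app:
            cost = np.array(
                [[_pair_cost(ref_segs[i], app_segs[j], tax) for j in free_app] for i in free_ref]
            )
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < _FORBIDDEN:
                    table.links.append(LinkedPair(rid, free_ref[r], free_app[c]))
                    linked_ref.add(free_ref[r])
                    linked_app.add(free_app[c])

        table.omissions.extend((rid, i) for i in range(len(ref_segs)) if i not in linked_ref)
        table.intrusions.extend((rid, j) for j in range(len(app_segs)) if j not in linked_app)

    table.links.sort(key=lambda l: (l.record_id, l.ref_idx))
    return table


@dataclass(frozen=True)
class SegmentationCoding:
    """F/O/I counts per record-type stratum; F + O must equal n_true."""

    counts: pd.DataFrame  # index: stratum; columns: F, O, I, n_true

    def __post_init__(self) -> None:
        c = self.counts
        if not ((c["F"] + c["O"]) == c["n_true"]).all():
            raise ValueError("F + O must equal n_true in every stratum")
        if (c[["F", "O", "I"]] < 0).any().any():
            raise ValueError("segment counts must be non-negative")

    @classmethod
    def from_match_table(cls, table: MatchTable, ref: Sequence[Record]) -> "SegmentationCoding":
        stratum_of = {r.record_id: r.stratum() for r in ref}
        strata = sorted(set(stratum_of.values()))
        counts = pd.DataFrame(0, index=strata, columns=["F", "O", "I", "n_true"])
        for link in table.links:
            counts.loc[stratum_of[link.record_id], "F"] += 1
        for rid, _ in table.omissions:
            counts.loc[stratum_of[rid], "O"] += 1
        for rid, _ in table.intrusions:
            if rid in stratum_of:
                counts.loc[stratum_of[rid], "I"] += 1
        counts["n_true"] = counts["F"] + counts["O"]
        return cls(counts=counts)


def proportion_halfwidth(x: int, n: int) -> float:
    """95% half-width (in percent) of a proportion, with n-1 in the SE denominator.

    Returns ``100 * 1.96 * sqrt(p(1-p)/(n-1))`` for ``p = x/n`` — the
    convention that reproduces the study's printed "+/-" columns (the n-1 form
    is what a t-based CI of a binary variable's mean uses for its SE).
    """
    if n < 2:
        raise ValueError("half-width needs n >= 2")
    if not 0 <= x <= n:
        raise ValueError("x must be between 0 and n")
    p = x / n
    return 100.0 * 1.96 * math.sqrt(p * (1.0 - p) / (n - 1))


def segmentation_accuracy(coding: SegmentationCoding, include_total: bool = True) -> pd.DataFrame:
    """Per-stratum %found/%omitted/%intruded with half-widths and echoed counts.

    All three percentages use the reference segment total ``n_true`` as the
    denominator — intrusions included, although they are not a subset of the
    reference segments, so %F + %I can exceed 100 in principle.
    """
    counts = coding.counts.copy()
    if include_total:
        counts.loc["total"] = counts.sum()
    rows = []
    for stratum, row in counts.iterrows():
        n = int(row["n_true"])
        if n == 0:
            raise ValueError(f"stratum {stratum!r} has no reference segments")
        entry = {"stratum": stratum, "n_true": n}
        for code, col in (("found", "F"), ("omitted", "O"), ("intruded", "I")):
            k = int(row[col])
            entry[f"n_{code}"] = k
            entry[f"pct_{code}"] = 100.0 * k / n
            entry[f"hw_{code}"] = proportion_halfwidth(min(k, n), n) if n >= 2 else float("nan")
        rows.append(entry)
    return pd.DataFrame(rows).set_index("stratum")
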