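"""Scalar social indices: preference, dominance, receptivity, concordance.

All indices share one convention — a difference normalized by a sum —
yielding values in [−1, 1] (or [0, 1] for the unsigned dominance bias).
An index is *undefined* when its denominator is zero; undefined values
are flagged and excluded from group statistics rather than silently
coerced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class PreferenceResult:
    index: float
    t1: float
    t2: float
    defined: bool


def preference_index(t1: float, t2: float) -> PreferenceResult:
    """(t1 − t2)/(t1 + t2): difference in time courting each target
    normalized by the sum. Undefined when both times are zero."""
    if t1 < 0 or t2 < 0:
        raise ValueError("times must be non-negative")
    tot = t1 + t2
    if tot == 0:
        return PreferenceResult(float("nan"), t1, t2, defined=False)
    return PreferenceResult((t1 - t2) / tot, t1, t2, defined=True)


@dataclass(frozen=True)
class DominanceResult:
    bias: float
    dominant: Optional[str]
    times: dict[str, float]

    @property
    def defined(self) -> bool:
        return sum(self.times.values()) > 0


def dominance(
    tA: float, tB: float, fly_a: str = "A", fly_b: str = "B"
) -> DominanceResult:
    """One-sidedness of a behavior within a pair: |tA − tB|/(tA + tB).

    The dominant fly is the one with the larger total time; a tie (or no
    behavior at all) leaves the dominant undefined with bias 0.
    """
    if tA < 0 or tB < 0:
        raise ValueError("times must be non-negative")
    tot = tA + tB
    times = {fly_a: tA, fly_b: tB}
    if tot == 0:
        return DominanceResult(0.0, None, times)
    if tA == tB:
        return DominanceResult(0.0, None, times)
    return DominanceResult(abs(tA - tB) / tot, fly_a if tA > tB else fly_b, times)


def action_concordance(
    pairs: Sequence[tuple[DominanceResult, DominanceResult]],
) -> dict:
    """Fraction of pairs where the same fly dominates both actions.

    Each entry pairs a first-action (e.g. attack) with a second-action
    (e.g. courtship) dominance result from the same fly pair; pairs where
    either action has no defined dominant are excluded. The returned
    counts feed a binomial test against chance (0.5).
    """
    qual = [
        (a, c)
        for a, c in pairs
        if a.dominant is not None and c.dominant is not None
    ]
    if not qual:
        raise ValueError("no pairs with both actions defined")
    concordant = sum(1 for a, c in qual if a.dominant == c.dominant)
    return {
        "fraction": concordant / len(qual),
        "concordant": concordant,
        "n": len(qual),
    }


def oe_normalized(t_oe: float, t_uwe: float) -> float:
    """Courtship-normalized ovipositor extrusion:
    (t_OE − t_UWE)/(t_OE + t_UWE), the female's rejection display scaled
    against the male's courtship drive. NaN when both are zero."""
    if t_oe < 0 or t_uwe < 0:
        raise ValueError("times must be non-negative")
    tot = t_oe + t_uwe
    if tot == 0:
        return float("nan")
    return (t_oe - t_uwe) / tot


@dataclass(frozen=True)
class ReceptivityResult:
    contributions: tuple[int, ...]
    group_index: float
    n: int


def receptivity_index(
    females: Sequence[dict],
    oe_norm_cutoff: float = -0.25,
) -> ReceptivityResult:
    """Group female receptivity from wing spreading (WS) and OE.

    Per female: WS present iff t_WS > 0 (strict); OE present iff the
    courtship-normalized OE exceeds the cutoff (strict >, default −0.25).
    The contribution is WS_present − OE_present ∈ {1, 0, −1} and the
    group index is the mean contribution. Females whose OE normalization
    is undefined (no OE and no courtship) count OE as absent.
    """
    if not females:
        raise ValueError("need at least one female")
    contribs = []
    any_signal = False
    for f in females:
        ws = f["t_WS"] > 0
        oe_n = oe_normalized(f["t_OE"], f["t_UWE"])
        oe = (not np.isnan(oe_n)) and oe_n > oe_norm_cutoff
        if ws or not np.isnan(oe_n):
            any_signal = True
        contribs.append(int(ws) - int(oe))
    if not any_signal:
        return ReceptivityResult(tuple(contribs), float("nan"), len(contribs))
    return ReceptivityResult(
        tuple(contribs), float(np.mean(contribs)), len(contribs)
    )


@dataclass(frozen=True)
class PrimingRow:
    pair_id: str
    dominant_fly: str
    pair_dominance: float
    trio_dominance: float
    total_pair_courtship: float
    concordant: bool
    high_bias: bool


def priming_concordance(
    records: Sequence[dict],
    min_pair_courtship: float = 20.0,
    high_bias_threshold: float = 0.8,
) -> dict:
    """Does male-male courtship dominance predict later female-directed
    dominance in a trio?

    Each record holds matched per-fly times from the two phases::

        {"pair_id": ..., "pair_times": {fly: s}, "trio_times": {fly: s}}

    Pairs with less than ``min_pair_courtship`` seconds of total
    male-male courtship are filtered out (inclusive at the threshold).
    For each surviving pair, x is the pair-phase dominance signed toward
    the pair-dominant fly (so x ≥ 0) and y is that same fly's signed
    female-directed dominance in the trio; the trio is concordant when
    y > 0 (ties are non-concordant). The concordant fraction over all
    filtered rows and over high-bias rows (x ≥ threshold) are returned
    along with counts for a binomial test.
    """
    rows: list[PrimingRow] = []
    for rec in records:
        pair_t, trio_t = rec["pair_times"], rec["trio_times"]
        if set(pair_t) != set(trio_t):
            raise ValueError(
                f"fly identities differ across phases in pair {rec.get('pair_id')}"
            )
        total = sum(pair_t.values())
        if total < min_pair_courtship:
            continue
        flies = sorted(pair_t)
        dom = dominance(pair_t[flies[0]], pair_t[flies[1]], *flies)
        if dom.dominant is None:
            continue
        other = flies[1] if dom.dominant == flies[0] else flies[0]
        trio_tot = trio_t[dom.dominant] + trio_t[other]
        y = (
            (trio_t[dom.dominant] - trio_t[other]) / trio_tot
            if trio_tot > 0
            else 0.0
        )
        rows.append(
            PrimingRow(
                pair_id=str(rec.get("pair_id", len(rows))),
                dominant_fly=dom.dominant,
                pair_dominance=dom.bias,
                trio_dominance=y,
                total_pair_courtship=total,
                concordant=y > 0,
                high_bias=dom.bias >= high_bias_threshold,
            )
        )
    n = len(rows)
    concordant = sum(r.concordant for r in rows)
    high = [r for r in rows if r.high_bias]
    return {
        "rows": rows,
        "n": n,
        "concordant": concordant,
        "fraction": concordant / n if n else float("nan"),
        "n_high_bias": len(high),
        "concordant_high_bias": sum(r.concordant for r in high),
        "fraction_high_bias": (
            sum(r.concordant for r in high) / len(high) if high else float("nan")
        ),
    }
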