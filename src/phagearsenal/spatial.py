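"""Spatial distribution of systems along linear replicons.

Every hit on a linear replicon gets a normalized position in [0, 1): its
start coordinate (min gene start) divided by the replicon length.  The
"extremities" at threshold ``t`` are the first and last ``t`` of that
range (x < t or x >= 1 - t); at the default thresholds 0.10 and 0.01 they
correspond to the variable chromosomal arms and the very chromosome ends
of linear replicons, against a null expectation of 2 t under uniform
placement.  Circularly annotated replicons are rejected, not re-linearized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    GenomeMetadata,
    RepliconMetadata,
    SystemHit,
    ValidationError,
    index_replicons,
)


@dataclass
class SpatialProfile:
    system_type: str
    positions: list[float]
    n: int
    extremity_fraction_10: float
    extremity_fraction_1: float


def normalized_position(hit: SystemHit, replicon: RepliconMetadata) -> float:
    """Min gene start / replicon length, in [0, 1); linear replicons only."""
    if hit.replicon_id != replicon.replicon_id:
        raise ValidationError(
            f"hit {hit.hit_id} is on {hit.replicon_id}, not {replicon.replicon_id}"
        )
    if replicon.topology != "linear":
        raise ValidationError(
            f"replicon {replicon.replicon_id} is circular: normalized positions "
            "are defined only on linear replicons (filter or exclude it)"
        )
    return hit.start / replicon.length


def extremity_fraction(positions: Sequence[float], threshold: float) -> float:
    """Fraction of positions in the first or last ``threshold`` of the axis."""
    if not 0.0 < threshold < 0.5:
        raise ValidationError(f"threshold must be in (0, 0.5), got {threshold}")
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValidationError("extremity_fraction is undefined for no positions")
    if np.any((pos < 0) | (pos >= 1)):
        raise ValidationError("positions must lie in [0, 1)")
    in_extremity = (pos < threshold) | (pos >= 1.0 - threshold)
    return float(in_extremity.mean())


def spatial_profiles(
    hits: Sequence[SystemHit],
    genomes: Sequence[GenomeMetadata],
    min_occurrences: int = 45,
    thresholds: tuple[float, float] = (0.10, 0.01),
) -> list[SpatialProfile]:
    """Per-type positional profiles over linear replicons.

    Only system types with **more than** ``min_occurrences`` occurrences on
    linear replicons are profiled (the occurrence floor keeps per-type
    fractions out of small-sample noise).
    """
    replicons = index_replicons(genomes)
    by_type: dict[str, list[float]] = {}
    for hit in hits:
        rep = replicons.get(hit.replicon_id)
        if rep is None:
            raise ValidationError(
                f"hit {hit.hit_id}: unknown replicon {hit.replicon_id}"
            )
        if rep.topology != "linear":
            continue
        by_type.setdefault(hit.system_type, []).append(
            normalized_position(hit, rep)
        )
    t10, t1 = thresholds
    profiles = []
    for system_type in sorted(by_type):
        positions = by_type[system_type]
        if len(positions) <= min_occurrences:
            continue
        profiles.append(
            SpatialProfile(
                system_type=system_type,
                positions=positions,
                n=len(positions),
                extremity_fraction_10=extremity_fraction(positions, t10),
                extremity_fraction_1=extremity_fraction(positions, t1),
            )
        )
    return profiles


def uniformity_test(positions: Sequence[float], threshold: float) -> float:
    """Two-sided exact binomial test of the extremity count against 2*threshold.

    Uses the doubled-smaller-tail convention: p = min(1, 2 * min(P(X <= k),
    P(X >= k))) for k extremity positions out of n, X ~ Binom(n, 2*threshold).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValidationError("uniformity_test is undefined for no positions")
    frac = extremity_fraction(positions, threshold)
    n = pos.size
    k = int(round(frac * n))
    p0 = 2.0 * threshold
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def profiles_to_frame(
    profiles: Sequence[SpatialProfile], with_p: bool = False
) -> pd.DataFrame:
    rows = []
    for prof in profiles:
        row = {
            "system_type": prof.system_type,
            "n": prof.n,
            "extremity_fraction_10": prof.extremity_fraction_10,
            "extremity_fraction_1": prof.extremity_fraction_1,
        }
        if with_p:
            row["binomial_p_10"] = uniformity_test(prof.positions, 0.10)
        rows.append(row)
    columns = ["system_type", "n", "extremity_fraction_10", "extremity_fraction_1"]
    if with_p:
        columns.append("binomial_p_10")
    return pd.DataFrame(rows, columns=columns)


def positions_to_frame(
    hits: Sequence[SystemHit], genomes: Sequence[GenomeMetadata]
) -> pd.DataFrame:
    """Per-hit normalized positions on linear replicons."""
    replicons = index_replicons(genomes)
    rows = []
    for hit in hits:
        rep = replicons[hit.replicon_id]
        if rep.topology != "linear":
            continue
        rows.append(
            {
                "hit_id": hit.hit_id,
                "system_type": hit.system_type,
                "replicon_id": hit.replicon_id,
                "position": normalized_position(hit, rep),
            }
        )
    return pd.DataFrame(
        rows, columns=["hit_id", "system_type", "replicon_id", "position"]
    )
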