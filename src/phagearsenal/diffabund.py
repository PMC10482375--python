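"""Differential abundance of system types between a focal group and a background.

For each system type the effect size is the normalized abundance difference

    estimator = (abundance_focal - abundance_background) / abundance_pooled

where abundance is the mean number of copies per genome in the group and
the pooled abundance is the genome-weighted mean over both groups.  A
negative value marks a system rarer in the focal group, a positive one a
system more abundant there.  Significance comes from a one-way two-group
ANOVA on the raw per-genome copy counts, Bonferroni-corrected across the
system types tested; types never seen in the focal group but present in
the background are classified ``absent`` without testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GenomeMetadata, SystemHit, ValidationError

CLASS_LABELS = ("absent", "enriched", "depleted", "not_significant")


class UndefinedEstimatorError(ValueError):
    """The system is absent from the whole cohort: the estimator is undefined."""


class AnovaResult(NamedTuple):
    f_stat: float
    p_value: float
    degenerate: bool = False


@dataclass
class DifferentialAbundanceResult:
    system_type: str
    n_in: int
    n_out: int
    abundance_in: float
    abundance_out: float
    abundance_all: float
    estimator: float
    f_stat: float
    p_raw: float
    p_adj: float
    class_label: str = "not_significant"
    degenerate: bool = False


def estimator(abundance_in: float, abundance_out: float, abundance_all: float) -> float:
    """Normalized abundance difference; undefined when the pooled abundance is 0."""
    if abundance_all <= 0:
        raise UndefinedEstimatorError(
            "estimator undefined: system absent from the whole cohort"
        )
    return (abundance_in - abundance_out) / abundance_all


def pooled_abundance(
    abundance_in: float, n_in: int, abundance_out: float, n_out: int
) -> float:
    """Genome-weighted mean abundance over both groups."""
    if n_in + n_out == 0:
        raise ValidationError("empty cohort")
    return (n_in * abundance_in + n_out * abundance_out) / (n_in + n_out)


def two_group_anova(
    copies_in: Sequence[float], copies_out: Sequence[float]
) -> AnovaResult:
    """One-way fixed-effects ANOVA with two groups: F with (1, n-2) df.

    Degenerate inputs (zero within-group variance) are resolved explicitly:
    equal means give F = 0, p = 1; unequal means give p = 0 with the
    ``degenerate`` flag set, since the F statistic diverges.
    """
    x = np.asarray(copies_in, dtype=float)
    y = np.asarray(copies_out, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    if x.size + y.size < 3:
        raise ValidationError("ANOVA needs a combined sample size of >= 3")
    ssw = float(np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2))
    if ssw == 0.0:
        if x.mean() == y.mean():
            return AnovaResult(0.0, 1.0, False)
        return AnovaResult(math.inf, 0.0, True)
    f_stat, p_value = stats.f_oneway(x, y)
    # guard against catastrophic cancellation in the between-group sum of
    # squares when the group means coincide (tiny negative F, NaN p)
    if not np.isfinite(f_stat) or f_stat < 0.0:
        f_stat = max(float(f_stat), 0.0) if np.isfinite(f_stat) else 0.0
        p_value = float(stats.f.sf(f_stat, 1, x.size + y.size - 2))
    return AnovaResult(float(f_stat), float(p_value), False)


def bonferroni(
    p_values: Sequence[float], m: Optional[int] = None
) -> list[float]:
    """Bonferroni adjustment ``min(1, m * p)``; ``m`` defaults to the family size."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValidationError(
            f"family size m={m} smaller than number of p-values ({len(p)})"
        )
    for value in p:
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"p-value {value} outside [0,1]")
    return [min(1.0, m * value) for value in p]


def copy_count_matrix(
    hits: Sequence[SystemHit], genomes: Sequence[GenomeMetadata]
) -> pd.DataFrame:
    """Genomes x system types matrix of copy counts (zeros included)."""
    genome_ids = [g.genome_id for g in genomes]
    known = set(genome_ids)
    for hit in hits:
        if hit.genome_id not in known:
            raise ValidationError(
                f"hit {hit.hit_id} references unknown genome {hit.genome_id}"
            )
    if hits:
        df = pd.DataFrame(
            {
                "genome_id": [h.genome_id for h in hits],
                "system_type": [h.system_type for h in hits],
            }
        )
        mat = pd.crosstab(df["genome_id"], df["system_type"])
    else:
        mat = pd.DataFrame()
    mat = mat.reindex(index=genome_ids, fill_value=0)
    return mat.fillna(0).astype(int)


def screen(
    hits: Sequence[SystemHit],
    genomes: Sequence[GenomeMetadata],
    focal_phylum: str,
    alpha: float = 0.05,
    family_size: Optional[int] = None,
) -> pd.DataFrame:
    """Run the full differential-abundance screen over all system types.

    ``family_size`` overrides the Bonferroni family (default: the number of
    types actually tested) for fidelity runs against a larger model set.
    Returns one row per system type with estimator, test, and class label.
    """
    focal_mask = np.array([g.phylum == focal_phylum for g in genomes])
    n_in = int(focal_mask.sum())
    n_out = int((~focal_mask).sum())
    if n_in == 0 or n_out == 0:
        raise ValidationError(
            f"screen needs non-empty focal ({n_in}) and background ({n_out}) groups"
        )
    mat = copy_count_matrix(hits, genomes)
    results: list[DifferentialAbundanceResult] = []
    tested_idx: list[int] = []
    raw_p: list[float] = []
    for system_type in sorted(mat.columns):
        counts = mat[system_type].to_numpy(dtype=float)
        cin, cout = counts[focal_mask], counts[~focal_mask]
        ab_in, ab_out = float(cin.mean()), float(cout.mean())
        ab_all = pooled_abundance(ab_in, n_in, ab_out, n_out)
        if ab_all == 0.0:
            continue  # absent everywhere: estimator undefined, type excluded
        res = DifferentialAbundanceResult(
            system_type=system_type,
            n_in=n_in,
            n_out=n_out,
            abundance_in=ab_in,
            abundance_out=ab_out,
            abundance_all=ab_all,
            estimator=estimator(ab_in, ab_out, ab_all),
            f_stat=float("nan"),
            p_raw=float("nan"),
            p_adj=float("nan"),
        )
        if ab_in == 0.0 and ab_out > 0.0:
            res.class_label = "absent"  # absence precedes testing
        else:
            anova = two_group_anova(cin, cout)
            res.f_stat = anova.f_stat
            res.p_raw = anova.p_value
            res.degenerate = anova.degenerate
            tested_idx.append(len(results))
            raw_p.append(anova.p_value)
        results.append(res)

    adj = bonferroni(raw_p, m=family_size if family_size else len(raw_p) or None)
    for idx, p_adj in zip(tested_idx, adj):
        results[idx].p_adj = p_adj
    classify(results, alpha=alpha)
    return results_to_frame(results)


def classify(
    results: Sequence[DifferentialAbundanceResult], alpha: float = 0.05
) -> Sequence[DifferentialAbundanceResult]:
    """Assign enriched / depleted / absent / not_significant in place."""
    for res in results:
        if res.class_label == "absent":
            continue
        if (
            not math.isnan(res.p_adj)
            and res.p_adj <= alpha
            and res.estimator > 0
        ):
            res.class_label = "enriched"
        elif (
            not math.isnan(res.p_adj)
            and res.p_adj <= alpha
            and res.estimator < 0
        ):
            res.class_label = "depleted"
        else:
            res.class_label = "not_significant"
    return results


def results_to_frame(
    results: Sequence[DifferentialAbundanceResult],
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "system_type": r.system_type,
                "n_in": r.n_in,
                "n_out": r.n_out,
                "abundance_in": r.abundance_in,
                "abundance_out": r.abundance_out,
                "abundance_all": r.abundance_all,
                "estimator": r.estimator,
                "f_stat": r.f_stat,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "class_label": r.class_label,
                "degenerate": r.degenerate,
            }
            for r in results
        ],
        columns=[
            "system_type",
            "n_in",
            "n_out",
            "abundance_in",
            "abundance_out",
            "abundance_all",
            "estimator",
            "f_stat",
            "p_raw",
            "p_adj",
            "class_label",
            "degenerate",
        ],
    )
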