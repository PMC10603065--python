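"""Per-ROI relative frequencies, absent-round corrections and fold enrichment.

Frequencies are percentages of reads within one sorted population, computed
after condensing identical ROI strings (counts of all full-length clones
sharing a ROI value are summed).  Fold enrichment compares the late (1 nM)
sort to the early (10 nM) sort; a ROI absent from one round receives a
pseudo-count equal to that round's minimum observed count divided by a
correction factor -- 2 when absent early, 10 when absent late, so depletion
is penalised more heavily than enrichment is rewarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedClone, RoiSpec, roi_string


@dataclass(frozen=True)
class CorrectionPolicy:
    """Divisors applied to the round-minimum count for absent ROIs."""

    factor_absent_early: float = 2.0
    factor_absent_late: float = 10.0

    def __post_init__(self) -> None:
        if self.factor_absent_early < 1 or self.factor_absent_late < 1:
            raise ValueError("correction factors must be >= 1")
        if self.factor_absent_late < self.factor_absent_early:
            raise ValueError("depletion must be penalised at least as heavily "
                             "as absence from the early round")


def roi_counts(
    clones: Sequence[AnnotatedClone],
    roi: RoiSpec | str,
    population: str,
) -> dict[str, int]:
    """Read counts per ROI value in one population (identical ROIs condensed)."""
    counts: dict[str, int] = {}
    for clone in clones:
        c = clone.counts.get(population, 0)
        if c > 0:
            v = roi_string(clone, roi)
            counts[v] = counts.get(v, 0) + c
    return counts


def relative_frequency(counts: Mapping[str, int]) -> dict[str, float]:
    """Percent relative frequency of each ROI value; values sum to 100."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty count group")
    return {v: 100.0 * c / total for v, c in counts.items()}


def fold_enrichment(
    early_counts: Mapping[str, int],
    late_counts: Mapping[str, int],
    policy: CorrectionPolicy = CorrectionPolicy(),
    percent_scale: bool = False,
    corrected_denominator: bool = False,
) -> pd.DataFrame:
    """Early-to-late enrichment per ROI value.

    Returns a frame with columns roi_value, rel_freq_early, rel_freq_late,
    corrected (none/early/late) and enrichment (late/early fold ratio;
    ``percent_scale`` multiplies by 100).  By default pseudo-counts for
    absent ROIs enter only the numerator of the absent side, leaving all
    observed frequencies untouched; ``corrected_denominator`` adds them to
    the round total as well.
    """
    if not early_counts and not late_counts:
        raise ValueError("no counts in either round")
    sum_early = float(sum(early_counts.values()))
    sum_late = float(sum(late_counts.values()))
    min_early = min(early_counts.values()) if early_counts else 0
    min_late = min(late_counts.values()) if late_counts else 0
    scale = 100.0 if percent_scale else 1.0

    rows = []
    for v in sorted(set(early_counts) | set(late_counts)):
        ce = early_counts.get(v)
        cl = late_counts.get(v)
        corrected = "none"
        den_early, den_late = sum_early, sum_late
        if ce is None:
            ce = min_early / policy.factor_absent_early
            corrected = "early"
            if corrected_denominator:
                den_early = sum_early + ce
        if cl is None:
            cl = min_late / policy.factor_absent_late
            corrected = "late"
            if corrected_denominator:
                den_late = sum_late + cl
        if den_early <= 0 or den_late <= 0:
            raise ValueError("cannot correct against an empty round")
        fe = 100.0 * ce / den_early
        fl = 100.0 * cl / den_late
        rows.append((v, fe, fl, corrected, scale * fl / fe))
    return pd.DataFrame(
        rows,
        columns=["roi_value", "rel_freq_early", "rel_freq_late", "corrected", "enrichment"],
    )


def population_roi_stats(
    clones: Sequence[AnnotatedClone],
    roi: RoiSpec | str,
    early_population: str,
    late_population: str,
    policy: CorrectionPolicy = CorrectionPolicy(),
    **kwargs,
) -> pd.DataFrame:
    """Convenience wrapper: condense clone counts and compute enrichment stats."""
    early = roi_counts(clones, roi, early_population)
    late = roi_counts(clones, roi, late_population)
    return fold_enrichment(early, late, policy, **kwargs)


def cumulative_abundance(
    freqs: Mapping[str, float],
    cluster_of: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Descending-frequency cumulative abundance curve.

    ``cluster_of`` restricts the curve to the most abundant representative of
    each cluster (values without a cluster id are dropped); the running sum
    then ends at the representatives' summed share instead of 100.
    """
    items = list(freqs.items())
    if cluster_of is not None:
        best: dict[int, tuple[str, float]] = {}
        for v, f in items:
            cid = cluster_of.get(v)
            if cid is None:
                continue
            if cid not in best or (-f, v) < (-best[cid][1], best[cid][0]):
                best[cid] = (v, f)
        items = list(best.values())
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    values = [v for v, _ in items]
    f = np.array([x for _, x in items], dtype=float)
    return pd.DataFrame(
        {"roi_value": values, "frequency": f, "cumulative": np.cumsum(f)}
    )
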