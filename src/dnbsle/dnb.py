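"""DNB member selection and verification of the three statistical conditions.

A dynamic network biomarker (DNB) is a gene group that, approaching a
critical transition, shows (1) markedly increased within-group standard
deviation SD_in, (2) sharply increased within-group correlation PCC_in and
(3) rapidly decreasing group-to-outside correlation PCC_out.  Members are
selected from the local SLE perturbation ranking at the detected critical
time; any candidate group can then be checked against the three conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from dnbsle.dataset import CASE, ExpressionDataset
from dnbsle.sle import LocalSLE, pearson_abs, _abs_corr_matrix

logger = logging.getLogger(__name__)


class DNBError(ValueError):
    pass


@dataclass(frozen=True)
class DNBConditionStats:
    """SD_in / PCC_in / PCC_out of a gene group at one time point.

    ``composite`` = SD_in * PCC_in / PCC_out is a classical convenience
    summary of the three conditions (infinite when PCC_out = 0).
    """

    time: str
    sd_in: float
    pcc_in: float
    pcc_out: float

    @property
    def composite(self) -> float:
        if self.pcc_out == 0.0:
            return math.inf
        return self.sd_in * self.pcc_in / self.pcc_out


@dataclass
class DNBResult:
    """Selected DNB members (sorted by descending mean local score)."""

    critical_time: str
    members: list[tuple[str, float]]
    selection_rule: dict

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.members]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"gene": g, "score": s, "rank": i + 1}
                for i, (g, s) in enumerate(self.members)
            ]
        )


def rank_local_scores(
    locals_by_case: dict[str, list[LocalSLE]],
) -> list[tuple[str, float]]:
    """Mean local SLE score per gene across case samples, descending.

    All case samples must cover the same gene set; ties break
    lexicographically.
    """
    if not locals_by_case:
        raise DNBError("no case samples")
    gene_sets = [frozenset(l.center for l in locs) for locs in locals_by_case.values()]
    if len(set(gene_sets)) != 1:
        raise DNBError("case samples cover inconsistent gene sets")
    sums: dict[str, float] = {}
    for locs in locals_by_case.values():
        for l in locs:
            sums[l.center] = sums.get(l.center, 0.0) + l.delta_h
    n = len(locals_by_case)
    means = {g: s / n for g, s in sums.items()}
    return sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))


def select_dnb_members(
    ranked: list[tuple[str, float]],
    rule: str,
    parameter: float | None = None,
    critical_time: str = "",
) -> DNBResult:
    """Cut the score ranking into a DNB member set.

    ``top_fraction q`` keeps the ceil(q * len) highest-scoring genes;
    ``score_quantile q`` keeps genes strictly above the q-quantile of the
    scores; ``knee`` keeps genes above the maximum-curvature point of the
    sorted score profile (discrete second-difference argmax).  The rule used
    is recorded in the result.
    """
    if not ranked:
        raise DNBError("empty ranking")
    scores = np.array([s for _, s in ranked])
    if rule == "top_fraction":
        if parameter is None or not (0 < parameter <= 1):
            raise DNBError("top_fraction needs a parameter in (0, 1]")
        k = math.ceil(parameter * len(ranked))
        members = ranked[:k]
    elif rule == "score_quantile":
        if parameter is None or not (0 < parameter <= 1):
            raise DNBError("score_quantile needs a parameter in (0, 1]")
        cut = float(np.quantile(scores, parameter))
        members = [(g, s) for g, s in ranked if s > cut]
        if not members:
            logger.warning("score_quantile %.3g selected no genes (ties at cut)", parameter)
    elif rule == "knee":
        if len(ranked) < 3:
            raise DNBError("knee rule needs >= 3 genes")
        # maximum-curvature point of the descending profile; genes strictly
        # above it are kept
        second_diff = scores[:-2] - 2 * scores[1:-1] + scores[2:]
        knee_idx = int(np.argmax(second_diff)) + 1
        members = ranked[:knee_idx]
    else:
        raise DNBError(f"unknown selection rule: {rule!r}")
    return DNBResult(
        critical_time=critical_time,
        members=list(members),
        selection_rule={"rule": rule, "parameter": parameter},
    )


def dnb_condition_stats(
    group: set[str],
    data: ExpressionDataset,
    time: str,
    cohort: str = "case",
) -> DNBConditionStats:
    """SD_in, PCC_in, PCC_out of ``group`` at one time point.

    SD_in is the mean sample SD of the group genes; PCC_in the mean |Pearson|
    over within-group pairs; PCC_out the mean |Pearson| over (group,
    non-group) pairs.  ``cohort='case'`` (default) uses the treated samples,
    ``'all'`` every sample at that time.
    """
    if len(group) < 2:
        raise DNBError("group must contain >= 2 genes")
    missing = group - set(data.genes)
    if missing:
        raise DNBError(f"group genes not in dataset: {sorted(missing)[:5]}")
    if cohort == "case":
        ids = data.samples(time=time, group=CASE)
    elif cohort == "all":
        ids = data.samples(time=time)
    else:
        raise DNBError(f"unknown cohort: {cohort!r}")
    if len(ids) < 3:
        raise DNBError(f"time {time!r}: {len(ids)} samples in cohort (< 3)")

    group_sorted = sorted(group)
    others = sorted(set(data.genes) - group)
    order = group_sorted + others
    values = data.matrix(ids, genes=order)
    n_in = len(group_sorted)

    sd_in = float(np.mean(np.std(values[:n_in], axis=1, ddof=1)))
    absr = _abs_corr_matrix(values)
    iu = np.triu_indices(n_in, k=1)
    pcc_in = float(np.mean(absr[:n_in, :n_in][iu])) if n_in > 1 else 0.0
    pcc_out = float(np.mean(absr[:n_in, n_in:])) if others else 0.0
    return DNBConditionStats(time=str(time), sd_in=sd_in, pcc_in=pcc_in, pcc_out=pcc_out)


def verify_dnb_conditions(
    group: set[str],
    data: ExpressionDataset,
    t_star: str,
    cohort: str = "case",
) -> dict:
    """Check the three DNB conditions for a candidate group at time t*.

    Each condition compares the statistic at t* against the most adverse
    value over all other times (strict inequality): SD_in and PCC_in must
    exceed their maximum elsewhere, PCC_out must undercut its minimum
    elsewhere.  The report also carries the composite index per time.
    """
    times = data.time_labels
    if len(times) < 2:
        raise DNBError("need >= 2 time points")
    if str(t_star) not in [str(t) for t in times]:
        raise DNBError(f"t_star {t_star!r} not among time labels {times}")
    stats = {t: dnb_condition_stats(group, data, t, cohort=cohort) for t in times}
    at_star = stats[str(t_star)]
    others = [stats[t] for t in times if str(t) != str(t_star)]
    max_sd = max(s.sd_in for s in others)
    max_pin = max(s.pcc_in for s in others)
    min_pout = min(s.pcc_out for s in others)
    return {
        "t_star": str(t_star),
        "conditions": {
            "sd_in_increases": {
                "at_t_star": at_star.sd_in,
                "max_other": max_sd,
                "passed": at_star.sd_in > max_sd,
            },
            "pcc_in_increases": {
                "at_t_star": at_star.pcc_in,
                "max_other": max_pin,
                "passed": at_star.pcc_in > max_pin,
            },
            "pcc_out_decreases": {
                "at_t_star": at_star.pcc_out,
                "min_other": min_pout,
                "passed": at_star.pcc_out < min_pout,
            },
        },
        "all_passed": (
            at_star.sd_in > max_sd
            and at_star.pcc_in > max_pin
            and at_star.pcc_out < min_pout
        ),
        "composite_by_time": {t: stats[t].composite for t in times},
        "stats_by_time": {
            t: {
                "sd_in": stats[t].sd_in,
                "pcc_in": stats[t].pcc_in,
                "pcc_out": stats[t].pcc_out,
            }
            for t in times
        },
    }
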