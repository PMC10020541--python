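"""Single-sample landscape entropy (SLE) scoring.

The SLE quantifies the perturbation a single case sample induces on the
correlation structure of a reference cohort, aggregated over the local
networks of a template interaction graph.  For a local network centred on
gene g with M neighbours:

    H_n      = -(1/ln M) * sum_i p_i ln p_i          (normalised entropy)
    p_i      = |r(g_i, g)| / sum_j |r(g_j, g)|       (|Pearson| weights)
    dSD      = |SD_{n+1}(g) - SD_n(g)|               (centre-gene SD shift)
    dH_local = dSD * |H_{n+1} - H_n|                 (local perturbation)
    dH(t)    = (1/K) * sum over scoreable locals     (global SLE score)

where the n-sample quantities use the reference cohort and the (n+1)-sample
quantities the reference cohort plus the case sample.  The global score,
averaged over case replicates per time point, peaks at the critical
(pre-transition) time.

Conventions (each makes the formulas total; all logged per occurrence at
DEBUG): |r| := 0 when either vector has zero variance; uniform weights when
all |r| = 0; entropy := 0 when M = 1.  Locals with M < 2 are excluded from
the global divisor K by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dnbsle.dataset import CASE, REFERENCE, ExpressionDataset
from dnbsle.network import LocalNetwork, TemplateNetwork, local_networks

logger = logging.getLogger(__name__)


class SLEError(ValueError):
    pass


@dataclass(frozen=True)
class LocalSLE:
    """Per-gene local entropy pair and perturbation score."""

    center: str
    M: int
    H_ref: float
    H_mix: float
    delta_sd: float
    delta_h: float


@dataclass
class GlobalSLECurve:
    """Global SLE scores per (time, case sample) with per-time summaries."""

    time_labels: list[str]
    scores: dict[str, dict[str, float]]  # time -> {case sample id -> score}
    K: int
    critical_time: str | None = None

    def mean(self, time: str) -> float:
        vals = list(self.scores[time].values())
        return float(np.mean(vals))

    def sem(self, time: str) -> float:
        vals = list(self.scores[time].values())
        if len(vals) < 2:
            return 0.0
        return float(np.std(vals, ddof=1) / np.sqrt(len(vals)))

    def means(self) -> list[float]:
        return [self.mean(t) for t in self.time_labels]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.time_labels:
            for sid, s in self.scores[t].items():
                rows.append({"time": t, "sample": sid, "score": s})
        return pd.DataFrame(rows)


def pearson_abs(x: np.ndarray, y: np.ndarray) -> float:
    """|Pearson r|; 0 when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SLEError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise SLEError(f"need >= 3 observations, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    nx_ = float(np.sqrt(xc @ xc))
    ny_ = float(np.sqrt(yc @ yc))
    if nx_ == 0.0 or ny_ == 0.0:
        logger.debug("zero-variance vector in Pearson; returning 0")
        return 0.0
    return min(abs(float(xc @ yc) / (nx_ * ny_)), 1.0)


def neighbor_weights(local: LocalNetwork, data: pd.DataFrame) -> np.ndarray:
    """Normalised |Pearson| weights of the centre gene against its neighbours.

    ``data`` is a genes x samples frame covering the centre and all
    neighbours.  If every |r| is zero the weights fall back to uniform 1/M.
    """
    if local.M == 0:
        raise SLEError(f"gene {local.center} has no neighbours; caller must skip")
    if data.shape[1] < 3:
        raise SLEError("need >= 3 samples for correlation")
    center = data.loc[local.center].to_numpy(dtype=float)
    abs_r = np.array(
        [pearson_abs(data.loc[g].to_numpy(dtype=float), center) for g in local.neighbors]
    )
    total = abs_r.sum()
    if total == 0.0:
        logger.debug("all-zero |PCC| for %s; uniform weights", local.center)
        return np.full(local.M, 1.0 / local.M)
    return abs_r / total


def local_entropy(p: np.ndarray) -> float:
    """Normalised Shannon entropy of a weight vector, in [0, 1].

    Natural log; terms with p_i = 0 contribute 0; M = 1 returns 0 (the
    normaliser ln M vanishes and a single-point distribution carries no
    entropy).
    """
    p = np.asarray(p, dtype=float)
    M = p.size
    if abs(p.sum() - 1.0) > 1e-9:
        raise SLEError(f"weights must sum to 1 (got {p.sum()!r})")
    if np.any(p < -1e-12):
        raise SLEError("negative weight")
    if M == 1:
        return 0.0
    pz = p[p > 0]
    h = -float(np.sum(pz * np.log(pz))) / np.log(M)
    return min(max(h, 0.0), 1.0)


def delta_sd(center_values_ref: np.ndarray, case_value: float) -> float:
    """|SD of the mixed n+1 values - SD of the n reference values|.

    Sample SD (denominator n - 1) on both cohorts.
    """
    ref = np.asarray(center_values_ref, dtype=float)
    if ref.size < 3:
        raise SLEError(f"need >= 3 reference values, got {ref.size}")
    mixed = np.append(ref, float(case_value))
    return abs(float(np.std(mixed, ddof=1)) - float(np.std(ref, ddof=1)))


def local_perturbation(
    local: LocalNetwork, ref: pd.DataFrame, case: pd.Series
) -> LocalSLE:
    """Local SLE score of one local network for one case sample.

    ``ref`` is a genes x samples frame of the reference cohort; ``case`` a
    gene-indexed expression column for the case sample.
    """
    if local.M < 2:
        raise SLEError(f"gene {local.center} has M={local.M} < 2; caller must skip")
    mixed = ref.copy()
    mixed["__case__"] = case.loc[ref.index]
    h_ref = local_entropy(neighbor_weights(local, ref))
    h_mix = local_entropy(neighbor_weights(local, mixed))
    dsd = delta_sd(
        ref.loc[local.center].to_numpy(dtype=float), float(case.loc[local.center])
    )
    return LocalSLE(
        center=local.center,
        M=local.M,
        H_ref=h_ref,
        H_mix=h_mix,
        delta_sd=dsd,
        delta_h=dsd * abs(h_mix - h_ref),
    )


def _abs_corr_matrix(values: np.ndarray) -> np.ndarray:
    # |Pearson| between all gene rows; zero-variance rows give |r| = 0.
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    cov = centered @ centered.T
    denom = np.outer(norms, norms)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return np.minimum(np.abs(r), 1.0)


def _entropy_from_abs_r(abs_r: np.ndarray) -> float:
    M = abs_r.size
    total = abs_r.sum()
    p = np.full(M, 1.0 / M) if total == 0.0 else abs_r / total
    pz = p[p > 0]
    return min(max(-float(np.sum(pz * np.log(pz))) / np.log(M), 0.0), 1.0)


def global_sle(
    network: TemplateNetwork,
    ref: pd.DataFrame,
    case: pd.Series,
    divisor: str = "scoreable",
) -> tuple[float, list[LocalSLE]]:
    """Global SLE score of one case sample against the reference cohort.

    Locals with fewer than two neighbours are uninformative (their entropy is
    constant) and are skipped; with ``divisor='scoreable'`` (default) K counts
    only the scored locals, with ``divisor='all'`` every gene.
    """
    if divisor not in ("scoreable", "all"):
        raise SLEError(f"unknown divisor mode: {divisor!r}")
    locs = local_networks(network)
    genes = [l.center for l in locs]
    idx = {g: i for i, g in enumerate(genes)}
    ref_m = ref.loc[genes].to_numpy(dtype=float)
    if ref_m.shape[1] < 3:
        raise SLEError("need >= 3 reference samples")
    case_v = case.loc[genes].to_numpy(dtype=float)
    mix_m = np.column_stack([ref_m, case_v])

    a_ref = _abs_corr_matrix(ref_m)
    a_mix = _abs_corr_matrix(mix_m)
    sd_ref = np.std(ref_m, axis=1, ddof=1)
    sd_mix = np.std(mix_m, axis=1, ddof=1)

    out: list[LocalSLE] = []
    total = 0.0
    n_scored = 0
    for loc in locs:
        if loc.M < 2:
            continue
        i = idx[loc.center]
        nbr = [idx[g] for g in loc.neighbors]
        h_ref = _entropy_from_abs_r(a_ref[i, nbr])
        h_mix = _entropy_from_abs_r(a_mix[i, nbr])
        dsd = abs(float(sd_mix[i]) - float(sd_ref[i]))
        dh = dsd * abs(h_mix - h_ref)
        out.append(
            LocalSLE(loc.center, loc.M, h_ref, h_mix, dsd, dh)
        )
        total += dh
        n_scored += 1
    if n_scored == 0:
        raise SLEError("no scoreable local network (all genes have < 2 neighbours)")
    k = n_scored if divisor == "scoreable" else len(locs)
    return total / k, out


def _reference_frame(
    data: ExpressionDataset,
    time: str,
    reference_spec: str,
    baseline_time: str | None,
) -> pd.DataFrame:
    if reference_spec == "control_group":
        ids = data.samples(time=time, group=REFERENCE)
        if len(ids) < 3:
            raise SLEError(
                f"time {time!r}: {len(ids)} reference samples (< 3); "
                "consider reference_spec='baseline_time'"
            )
    elif reference_spec == "baseline_time":
        t0 = baseline_time if baseline_time is not None else data.time_labels[0]
        ids = data.samples(time=t0)
        if len(ids) < 3:
            raise SLEError(f"baseline time {t0!r} has {len(ids)} samples (< 3)")
    else:
        raise SLEError(f"unknown reference_spec: {reference_spec!r}")
    return data.values[ids]


def sle_curve(
    network: TemplateNetwork,
    data: ExpressionDataset,
    reference_spec: str = "control_group",
    baseline_time: str | None = None,
    divisor: str = "scoreable",
) -> GlobalSLECurve:
    """Global SLE score for every case sample at every time point.

    ``reference_spec='control_group'`` uses the reference-group samples at
    the same time point as the case sample (the default cohort);
    ``'baseline_time'`` pools all samples at one baseline time.
    """
    from dnbsle.network import restrict_to_measured

    net = restrict_to_measured(network, set(data.genes))
    scores: dict[str, dict[str, float]] = {}
    k_used = 0
    for t in data.time_labels:
        case_ids = data.samples(time=t, group=CASE)
        if not case_ids:
            raise SLEError(f"time {t!r} has no case samples")
        ref = _reference_frame(data, t, reference_spec, baseline_time)
        per_sample: dict[str, float] = {}
        for sid in case_ids:
            score, locs = global_sle(net, ref, data.values[sid], divisor=divisor)
            per_sample[sid] = score
            k_used = len(locs)
        scores[t] = per_sample
    curve = GlobalSLECurve(time_labels=data.time_labels, scores=scores, K=k_used)
    if len(curve.time_labels) >= 2:
        curve.critical_time = detect_tipping_point(curve)
    return curve


def detect_tipping_point(curve: GlobalSLECurve) -> str:
    """Time label at which the mean global SLE score peaks.

    Ties are broken toward the earliest time (logged).
    """
    if len(curve.time_labels) < 2:
        raise SLEError("need >= 2 time points to detect a tipping point")
    means = curve.means()
    best = max(means)
    winners = [t for t, m in zip(curve.time_labels, means) if m == best]
    if len(winners) > 1:
        logger.warning("tie at peak SLE among %s; taking earliest", winners)
    return winners[0]


def local_scores_at(
    network: TemplateNetwork,
    data: ExpressionDataset,
    time: str,
    reference_spec: str = "control_group",
    baseline_time: str | None = None,
    divisor: str = "scoreable",
) -> dict[str, list[LocalSLE]]:
    """Per-case-sample local SLE scores at one time point (for DNB ranking)."""
    from dnbsle.network import restrict_to_measured

    net = restrict_to_measured(network, set(data.genes))
    ref = _reference_frame(data, time, reference_spec, baseline_time)
    case_ids = data.samples(time=time, group=CASE)
    if not case_ids:
        raise SLEError(f"time {time!r} has no case samples")
    return {
        sid: global_sle(net, ref, data.values[sid], divisor=divisor)[1]
        for sid in case_ids
    }


def peak_permutation_test(
    network: TemplateNetwork,
    data: ExpressionDataset,
    n_permutations: int = 100,
    seed: int = 0,
    reference_spec: str = "control_group",
) -> float:
    """Permutation p-value for the height of the SLE peak.

    Shuffles case/reference labels within each time point and recomputes the
    peak mean score; p = fraction of permutations with a peak at least as
    high as observed.  Off by default in the pipeline.
    """
    rng = np.random.default_rng(seed)
    observed = max(sle_curve(network, data, reference_spec).means())
    hits = 0
    for _ in range(n_permutations):
        meta = data.meta.copy()
        for t in data.time_labels:
            ids = data.samples(time=t)
            perm = rng.permutation(meta.loc[ids, "group"].to_numpy())
            meta.loc[ids, "group"] = perm
        shuffled = ExpressionDataset(data.values, meta)
        try:
            peak = max(sle_curve(network, shuffled, reference_spec).means())
        except SLEError:
            continue
        if peak >= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
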