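"""Inoculum-effect-size metrics and their sampling variances.

Two metrics quantify how much decay varies across inoculum treatments
within one study x litter x time cell:

* ``CV`` — sample SD of the treatment means divided by their mean
  (unitless, comparable across response types);
* ``D``  — mean pairwise Euclidean distance among treatment means
  (response units; mass-loss and CO2 studies are kept in separate
  pools because their units differ).

Sampling variances are estimated by a parametric bootstrap: each
treatment mean is redrawn from a normal centred on the reported mean
with variance ``sd^2 / n`` (truncated at zero, since neither mass loss
nor CO2 evolution can be negative), the metric is recomputed, and the
variance of the bootstrap replicates is returned.  The bootstrap is
metric-agnostic, which matters for D whose absolute differences are not
smooth.  All draws are seeded deterministically per cell so that results
are reproducible and independent of which other cells are present.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .dataset import CELL_KEY, ExperimentDataset
from .errors import DegenerateCellError

logger = logging.getLogger(__name__)

EFFECT_COLUMNS = [
    "study_id",
    "litter_id",
    "time_days",
    "response_type",
    "metric",
    "estimate",
    "sampling_variance",
    "k_treatments",
]


@dataclass
class EffectConfig:
    """Options controlling effect-size computation.

    n_boot
        bootstrap replicates per cell (>= 100).
    seed
        root seed; per-cell streams are derived from it and from a hash
        of the cell key, so removing one study never perturbs another.
    epsilon
        grand means at or below this are treated as degenerate for CV.
    metrics
        which metrics to emit.
    time_integration
        "mean_trajectory": average each treatment's trajectory over time
        before computing the metric (default); "mean_of_cvs": average
        the per-time metrics instead.
    """

    n_boot: int = 2000
    seed: int = 0
    epsilon: float = 1e-8
    metrics: tuple = ("CV", "D")
    time_integration: str = "mean_trajectory"


@dataclass
class EffectTable:
    """A table of effect-size records plus the provenance of its variances."""

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.records)

    def filter(self, **conditions) -> "EffectTable":
        """Subset records by equality on columns, e.g. ``metric="CV"``."""
        mask = pd.Series(True, index=self.records.index)
        for col, val in conditions.items():
            mask &= self.records[col] == val
        return EffectTable(self.records.loc[mask].copy(), dict(self.provenance))

    def to_csv(self, path):
        self.records.to_csv(path, index=False)

    @staticmethod
    def concat(tables) -> "EffectTable":
        frames = [t.records for t in tables]
        prov = {}
        for t in tables:
            prov.update(t.provenance)
        return EffectTable(
            pd.concat(frames, ignore_index=True) if frames else _empty_records(),
            prov,
        )


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(columns=EFFECT_COLUMNS)


# ----------------------------------------------------------------------
# point estimates
# ----------------------------------------------------------------------

def cv_across_treatments(means, epsilon: float = 1e-8) -> float:
    """Coefficient of variation of >= 2 treatment means.

    Sample SD (n-1 denominator) over the arithmetic mean.  Scale
    invariant.  Raises :class:`DegenerateCellError` when the grand mean
    is at or below ``epsilon`` (CV is undefined near a zero mean).
    """
    m = np.asarray(means, dtype=float)
    if m.size < 2:
        raise ValueError(f"need >= 2 treatment means, got {m.size}")
    grand = m.mean()
    if grand <= epsilon:
        raise DegenerateCellError(
            f"grand mean {grand!r} <= epsilon {epsilon!r}: CV undefined"
        )
    return float(m.std(ddof=1) / grand)


def mean_pairwise_distance(means) -> float:
    """Mean pairwise absolute difference among >= 2 treatment means.

    For scalar decay values the Euclidean distance between two
    treatments reduces to |m_i - m_j|; the mean runs over all k(k-1)/2
    unordered pairs.  Homogeneous of degree one in the means.
    """
    m = np.asarray(means, dtype=float)
    if m.size < 2:
        raise ValueError(f"need >= 2 treatment means, got {m.size}")
    diffs = np.abs(m[:, None] - m[None, :])
    k = m.size
    return float(diffs[np.triu_indices(k, 1)].sum() * 2.0 / (k * (k - 1)))


_METRIC_FUNCS = {
    "CV": cv_across_treatments,
    "D": mean_pairwise_distance,
}


# ----------------------------------------------------------------------
# bootstrap sampling variance
# ----------------------------------------------------------------------

def _draw_truncated_means(means, scales, n_boot, rng):
    """Draw an (n_boot, m) matrix of means ~ N(mean, scale^2) truncated at 0."""
    means = np.asarray(means, float)
    scales = np.asarray(scales, float)
    out = np.tile(means, (n_boot, 1))
    pos = scales > 0
    if pos.any():
        a = (0.0 - means[pos]) / scales[pos]
        draws = truncnorm.rvs(
            a,
            np.inf,
            loc=means[pos],
            scale=scales[pos],
            size=(n_boot, int(pos.sum())),
            random_state=rng,
        )
        out[:, pos] = draws
    return out


def _cv_rows(mat, epsilon):
    """Row-wise CV of a bootstrap matrix; rows with degenerate grand means
    are dropped.  Raises if every row is degenerate."""
    grand = mat.mean(axis=1)
    ok = grand > epsilon
    if not ok.any():
        raise DegenerateCellError(
            "all bootstrap replicates have grand mean <= epsilon"
        )
    return mat[ok].std(axis=1, ddof=1) / grand[ok]


def _d_rows(mat):
    k = mat.shape[1]
    iu, ju = np.triu_indices(k, 1)
    return np.abs(mat[:, iu] - mat[:, ju]).sum(axis=1) * 2.0 / (k * (k - 1))


def sampling_variance(
    means,
    sds,
    ns,
    metric: str,
    n_boot: int = 2000,
    seed=0,
    epsilon: float = 1e-8,
) -> float:
    """Parametric-bootstrap variance of CV or D for one cell.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.
    Deterministic given the seed.  With all SDs zero the variance is
    exactly zero.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns, float)
    if not (means.shape == sds.shape == ns.shape):
        raise ValueError("means, sds, ns must have equal length")
    if np.any(sds < 0) or np.any(ns < 1):
        raise ValueError("sds must be >= 0 and ns >= 1")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"metric must be one of {list(_METRIC_FUNCS)}")

    if np.all(sds == 0):
        return 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = _draw_truncated_means(means, sds / np.sqrt(ns), n_boot, rng)
    reps = _cv_rows(mat, epsilon) if metric == "CV" else _d_rows(mat)
    return float(np.var(reps, ddof=1))


def _cell_seed(root_seed: int, *key_parts) -> np.random.Generator:
    """Deterministic per-cell stream independent of the rest of the table."""
    tag = zlib.crc32("|".join(str(p) for p in key_parts).encode())
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), tag]))


# ----------------------------------------------------------------------
# table builders
# ----------------------------------------------------------------------

def compute_effect_table(
    dataset: ExperimentDataset, config: EffectConfig | None = None
) -> EffectTable:
    """One CV and one D record per study x litter x time x response cell.

    Cells whose grand mean is degenerate for CV are flagged, logged and
    excluded from the CV pool (D is still emitted).
    """
    cfg = config or EffectConfig()
    rows, dropped = [], []
    for key, cell in dataset.cells():
        study, litter, time_days, resp = key
        means = cell["mean"].to_numpy(float)
        sds = cell["sd"].to_numpy(float)
        ns = cell["n"].to_numpy(float)
        k = len(means)
        for metric in cfg.metrics:
            rng = _cell_seed(cfg.seed, study, litter, time_days, resp, metric)
            try:
                est = _METRIC_FUNCS[metric](
                    means, **({"epsilon": cfg.epsilon} if metric == "CV" else {})
                )
                var = sampling_variance(
                    means, sds, ns, metric, cfg.n_boot, rng, cfg.epsilon
                )
            except DegenerateCellError as exc:
                dropped.append((key, metric, str(exc)))
                logger.warning("degenerate cell %s (%s): %s", key, metric, exc)
                continue
            rows.append((study, litter, time_days, resp, metric, est, var, k))
    table = EffectTable(
        pd.DataFrame(rows, columns=EFFECT_COLUMNS),
        {
            "n_boot": cfg.n_boot,
            "seed": cfg.seed,
            "epsilon": cfg.epsilon,
            "degenerate_cells": [str(d) for d in dropped],
        },
    )
    return table


def litter_type_cv(
    dataset: ExperimentDataset, config: EffectConfig | None = None
) -> EffectTable:
    """CV of decay across litter types, averaged over inoculum treatments.

    For studies with >= 2 litter types: per study x time x response,
    each litter type's mean response is averaged over inoculum
    treatments, then the CV across those litter-type means is taken.
    Measures the litter-chemistry effect on the same scale as the
    inoculum CV.  Single-litter studies are skipped with a log notice.
    """
    cfg = config or EffectConfig()
    rows = []
    grouped = dataset.summaries.groupby(
        ["study_id", "time_days", "response_type"], sort=True
    )
    for (study, time_days, resp), sub in grouped:
        litters = sub.groupby("litter_id", sort=True)
        if litters.ngroups < 2:
            logger.info(
                "study %s t=%s: single litter type, no litter CV", study, time_days
            )
            continue
        litter_means = litters["mean"].mean()
        rng = _cell_seed(cfg.seed, study, time_days, resp, "litterCV")
        try:
            est = cv_across_treatments(litter_means.to_numpy(), cfg.epsilon)
            var = _bootstrap_litter_cv_var(sub, cfg, rng)
        except DegenerateCellError as exc:
            logger.warning("degenerate litter cell (%s, %s): %s", study, time_days, exc)
            continue
        rows.append(
            (study, "*", time_days, resp, "CV", est, var, litters.ngroups)
        )
    return EffectTable(
        pd.DataFrame(rows, columns=EFFECT_COLUMNS),
        {"n_boot": cfg.n_boot, "seed": cfg.seed, "kind": "litter_type_cv"},
    )


def _bootstrap_litter_cv_var(sub: pd.DataFrame, cfg: EffectConfig, rng):
    """Bootstrap the litter-type CV: redraw every treatment mean, average
    within litter, take CV across litter averages."""
    means = sub["mean"].to_numpy(float)
    scales = sub["sd"].to_numpy(float) / np.sqrt(sub["n"].to_numpy(float))
    if np.all(scales == 0):
        return 0.0
    codes, _ = pd.factorize(sub["litter_id"], sort=True)
    n_lit = codes.max() + 1
    mat = _draw_truncated_means(means, scales, cfg.n_boot, rng)
    sums = np.zeros((cfg.n_boot, n_lit))
    counts = np.bincount(codes, minlength=n_lit)
    for j in range(n_lit):
        sums[:, j] = mat[:, codes == j].sum(axis=1)
    lit_means = sums / counts
    reps = _cv_rows(lit_means, cfg.epsilon)
    return float(np.var(reps, ddof=1))


def integrate_over_time(
    dataset: ExperimentDataset, config: EffectConfig | None = None
) -> EffectTable:
    """Time-integrated effect sizes: one record per study x litter x response.

    Default ("mean_trajectory"): each treatment's reported means are
    averaged over its time points (unweighted) and the metric is
    computed across those time-averaged treatment values.  The
    alternative reading ("mean_of_cvs") averages the per-time metrics
    instead.  With a single time point both coincide with the per-time
    record.  Records carry ``time_days = NaN``.
    """
    cfg = config or EffectConfig()
    rows = []
    grouped = dataset.summaries.groupby(
        ["study_id", "litter_id", "response_type"], sort=True
    )
    for (study, litter, resp), sub in grouped:
        for metric in cfg.metrics:
            rng = _cell_seed(cfg.seed, study, litter, resp, metric, "timeint")
            try:
                est, var, k = _time_integrated_cell(sub, metric, cfg, rng)
            except DegenerateCellError as exc:
                logger.warning(
                    "degenerate time-integrated cell (%s, %s): %s", study, litter, exc
                )
                continue
            rows.append((study, litter, np.nan, resp, metric, est, var, k))
    return EffectTable(
        pd.DataFrame(rows, columns=EFFECT_COLUMNS),
        {
            "n_boot": cfg.n_boot,
            "seed": cfg.seed,
            "kind": "time_integrated",
            "mode": cfg.time_integration,
        },
    )


def _time_integrated_cell(sub: pd.DataFrame, metric, cfg: EffectConfig, rng):
    means = sub["mean"].to_numpy(float)
    scales = sub["sd"].to_numpy(float) / np.sqrt(sub["n"].to_numpy(float))
    tcodes, tlabels = pd.factorize(sub["treatment_id"], sort=True)
    k = len(tlabels)
    if k < 2:
        raise DegenerateCellError("fewer than 2 treatments")
    fn = _METRIC_FUNCS[metric]
    kwargs = {"epsilon": cfg.epsilon} if metric == "CV" else {}

    if cfg.time_integration == "mean_trajectory":
        tavg = np.array([means[tcodes == j].mean() for j in range(k)])
        est = fn(tavg, **kwargs)
    elif cfg.time_integration == "mean_of_cvs":
        per_time = []
        for _, tp in sub.groupby("time_days"):
            if tp["treatment_id"].nunique() < 2:
                continue
            per_time.append(fn(tp["mean"].to_numpy(float), **kwargs))
        if not per_time:
            raise DegenerateCellError("no time point with >= 2 treatments")
        est = float(np.mean(per_time))
    else:
        raise ValueError(f"unknown time_integration mode {cfg.time_integration!r}")

    if np.all(scales == 0):
        return est, 0.0, k
    mat = _draw_truncated_means(means, scales, cfg.n_boot, rng)
    if cfg.time_integration == "mean_trajectory":
        tmat = np.zeros((cfg.n_boot, k))
        for j in range(k):
            sel = tcodes == j
            tmat[:, j] = mat[:, sel].mean(axis=1)
        reps = _cv_rows(tmat, cfg.epsilon) if metric == "CV" else _d_rows(tmat)
    else:
        # per-time metrics averaged; replicates with a degenerate grand
        # mean at any time point are dropped wholesale via NaN
        parts = []
        sub_pos = sub.reset_index(drop=True)
        for _, idx in sub_pos.groupby("time_days").indices.items():
            tp = mat[:, idx]
            if tp.shape[1] < 2:
                continue
            if metric == "CV":
                grand = tp.mean(axis=1)
                vals = np.where(
                    grand > cfg.epsilon, tp.std(axis=1, ddof=1) / grand, np.nan
                )
            else:
                vals = _d_rows(tp)
            parts.append(vals)
        reps = np.mean(parts, axis=0)
        reps = reps[np.isfinite(reps)]
        if reps.size < 2:
            raise DegenerateCellError("bootstrap degenerate at all replicates")
    return est, float(np.var(reps, ddof=1)), k
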