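"""Within-study community-function correspondence via Mantel tests.

Each study contributes a matrix of pairwise dissimilarities between
inoculum treatments in ordination space (NMDS/PCA axes 1-2, whose raw
coordinates are only meaningful within a study) and a matrix of
pairwise dissimilarities in mass loss.  The Mantel statistic r is the
Pearson (optionally Spearman) correlation of the two upper triangles;
its p value comes from randomly permuting the treatment labels of one
matrix.  The default alternative is one-sided upper tail (more
dissimilar communities decompose litter at more dissimilar rates), so a
strongly negative r yields p near 1.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .dataset import ExperimentDataset
from .errors import AlignmentError, UndefinedStatisticError

logger = logging.getLogger(__name__)

COMMUNITY_TYPES = ("bacteria", "fungi")

SCORE_COLUMNS = ["study_id", "community_type", "treatment_id", "axis1", "axis2"]


@dataclass
class MantelResult:
    study_id: str
    community_type: str
    r: float
    p_value: float
    n_perm: int
    seed: int
    n_items: int

    def to_dict(self):
        return self.__dict__.copy()


def pairwise_distance_matrix(points) -> np.ndarray:
    """Euclidean distance matrix for >= 3 items (rows = items)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < 3:
        raise ValueError(f"need >= 3 items for a distance matrix, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    return squareform(pdist(pts, metric="euclidean"))


def _check_dm(d, name):
    d = np.asarray(d, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 3:
        raise ValueError(f"{name} must be a square matrix of size >= 3")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError(f"{name} must be symmetric with a zero diagonal")
    return d


def mantel_test(
    d1,
    d2,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
    method: str = "pearson",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r correlates the upper triangles; the null distribution permutes the
    item labels of ``d2`` ``n_perm`` times.  p = (1 + #{r_perm >= r_obs})
    / (n_perm + 1) for ``alternative="greater"``; ``"two_sided"``
    compares |r_perm| >= |r_obs|.  Deterministic given the seed.
    """
    d1 = _check_dm(d1, "d1")
    d2 = _check_dm(d2, "d2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must have the same shape")
    if alternative not in ("greater", "two_sided"):
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    n = d1.shape[0]
    iu = np.triu_indices(n, 1)

    def _corr(a, b):
        if method == "spearman":
            a, b = rankdata(a), rankdata(b)
        elif method != "pearson":
            raise ValueError("method must be 'pearson' or 'spearman'")
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            raise UndefinedStatisticError(
                "a distance vector is constant; Mantel r undefined"
            )
        return float(np.corrcoef(a, b)[0, 1])

    x = d1[iu]
    r_obs = _corr(x, d2[iu])

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        d2p = d2[np.ix_(perm, perm)]
        r_p = _corr(x, d2p[iu])
        if alternative == "greater":
            exceed += r_p >= r_obs
        else:
            exceed += abs(r_p) >= abs(r_obs)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return MantelResult(
        study_id="",
        community_type="",
        r=r_obs,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        n_items=n,
    )


def _mass_loss_vector(dataset: ExperimentDataset, study_id, time_policy="final"):
    """Per-treatment decay value for one study: final time point by
    default, averaged across litter types when several exist."""
    sub = dataset.summaries.loc[dataset.summaries["study_id"] == study_id]
    if sub.empty:
        raise KeyError(f"study {study_id!r} not in dataset")
    resp_types = sub["response_type"].unique()
    # mass loss preferred when a study reports both response types
    resp = "mass_loss_pct" if "mass_loss_pct" in resp_types else resp_types[0]
    sub = sub.loc[sub["response_type"] == resp]
    if time_policy == "final":
        sub = sub.loc[sub["time_days"] == sub["time_days"].max()]
    elif time_policy != "all":
        raise ValueError("time_policy must be 'final' or 'all'")
    return sub.groupby("treatment_id")["mean"].mean()


def run_mantel_suite(
    dataset: ExperimentDataset,
    scores: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
    method: str = "pearson",
    time_policy: str = "final",
) -> list[MantelResult]:
    """One Mantel test per study x community type present in ``scores``.

    ``scores`` columns: study_id, community_type, treatment_id, axis1,
    axis2.  Studies reporting a single community type yield a single
    result; treatment identifiers must match the decay dataset exactly.
    """
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise ValueError(f"scores table is missing column(s): {missing}")
    results = []
    for (study, ctype), grp in scores.groupby(
        ["study_id", "community_type"], sort=True
    ):
        if ctype not in COMMUNITY_TYPES:
            raise ValueError(f"unknown community_type {ctype!r}")
        ml = _mass_loss_vector(dataset, study, time_policy)
        grp = grp.set_index("treatment_id")
        unmatched = sorted(set(grp.index) ^ set(ml.index))
        if unmatched:
            raise AlignmentError(
                f"study {study!r} ({ctype}): treatment ids disagree between "
                f"ordination scores and decay data: {unmatched}",
                unmatched,
            )
        treatments = sorted(grp.index)
        if len(treatments) < 3:
            logger.info(
                "study %s (%s): fewer than 3 treatments, Mantel skipped",
                study,
                ctype,
            )
            continue
        d_comm = pairwise_distance_matrix(
            grp.loc[treatments, ["axis1", "axis2"]].to_numpy(float)
        )
        d_func = pairwise_distance_matrix(ml.loc[treatments].to_numpy(float))
        pair_seed = int(
            np.random.SeedSequence(
                [int(seed), zlib.crc32(f"{study}|{ctype}".encode())]
            ).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        res = mantel_test(d_comm, d_func, n_perm, pair_seed, alternative, method)
        res.study_id = str(study)
        res.community_type = str(ctype)
        results.append(res)
    return results


def results_to_frame(results) -> pd.DataFrame:
    """Flat table mirroring a per-study r (p) report layout."""
    return pd.DataFrame([r.to_dict() for r in results])
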