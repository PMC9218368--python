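"""Synthetic multi-study litter-decay datasets with known truth.

The generator inverts the analysis model: each study x litter x time
cell is assigned a true effect

    theta_ij = mu + u_i + w_ij + moderator terms,
    u_i ~ N(0, tau_between^2),  w_ij ~ N(0, tau_within^2),

and the cell's k treatment means are constructed to have coefficient of
variation exactly theta_ij around a realistic grand mean (25% mass loss
or 18 mg CO2-C g^-1).  Two structural features of real experiments are
built in: litter chemistry shifts each litter type's overall decay
level (relative SD ``litter_effect_cv``, so the across-litter CV is of
the same order as the inoculum CV), and the *pattern* of treatment
differences persists across a litter's time points (fast inocula stay
fast), so time-integrated effect sizes do not cancel.  Reported
per-treatment means and SDs are then
produced by layering replicate noise: the reported mean is drawn from
N(m_t, sigma^2/n) and the reported SD from the sampling distribution of
a sample SD with n-1 degrees of freedom.  With all noise terms at zero
the computed CV of every cell equals ``true_mean_cv`` exactly, which
makes the generator a direct oracle for the effect-size and pooling
stages.

The default scenario mirrors the structure of a compiled
decomposition-experiment dataset: 36 studies, 2-6 inoculum treatments,
one litter type for most studies (a ~1-in-6 minority crosses 2-3 litter
types with the inocula) and 1-5 time points per study, giving ~140
effect-size cells in total; roughly 70% mass-loss and 30% CO2 studies,
and a mix of field/laboratory and reduced/whole-community designs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExperimentDataset

_THETA_MIN = 1e-3  # smallest admissible true cell CV
_MAX_TRIES = 1000


@dataclass
class SimulationParams:
    """Knobs of the multi-study generator (all effects on the CV scale)."""

    n_studies: int = 36
    treatments_per_study: tuple = (2, 6)
    litters_per_study: tuple = (1, 3)
    prop_multilitter: float = 6.0 / 36.0
    timepoints_per_study: tuple = (1, 5)
    replicate_n: tuple = (3, 10)
    true_mean_cv: float = 0.20
    tau_between: float = 0.07
    tau_within: float = 0.05
    replicate_noise_sd: float = 2.0
    litter_effect_cv: float = 0.25
    moderator_effects: dict = field(default_factory=dict)
    prop_co2: float = 11.0 / 36.0
    grand_mean_ml: float = 25.0
    grand_mean_co2: float = 18.0
    seed: int = 0

    def __post_init__(self):
        for name in ("tau_between", "tau_within", "replicate_noise_sd",
                     "litter_effect_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.true_mean_cv < 0:
            raise ValueError("true_mean_cv must be >= 0")
        for name in (
            "treatments_per_study",
            "litters_per_study",
            "timepoints_per_study",
            "replicate_n",
        ):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must be a nonempty range, got ({lo}, {hi})")
        if self.treatments_per_study[0] < 2:
            raise ValueError("every study needs >= 2 inoculum treatments")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    params: SimulationParams
    mu: float
    tau_between: float
    tau_within: float
    study_effects: dict  # study_id -> u_i
    cell_cv: dict  # "study|litter|time|response" -> theta_ij
    moderator_effects: dict

    def to_json(self, path):
        payload = {
            "params": asdict(self.params),
            "mu": self.mu,
            "tau_between": self.tau_between,
            "tau_within": self.tau_within,
            "study_effects": self.study_effects,
            "cell_cv": self.cell_cv,
            "moderator_effects": self.moderator_effects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _draw_moderators(rng, study_id, k, params):
    complexity = rng.choice(["reduced", "whole_community"])
    mods = {
        "study_id": study_id,
        "setting": rng.choice(["field", "laboratory"]),
        "environment": rng.choice(["terrestrial", "freshwater"], p=[0.75, 0.25]),
        "inoculum_complexity": complexity,
        "inoculum_taxa": rng.choice(["bacteria", "fungi", "both"]),
        "max_richness": float(rng.integers(2, 65)) if complexity == "reduced" else np.nan,
        "litter_cn": float(np.round(rng.uniform(15, 80), 1))
        if rng.random() > 0.1
        else np.nan,
        "litter_lignin_pct": float(np.round(rng.uniform(2, 25), 1))
        if rng.random() > 0.1
        else np.nan,
        "n_inoculum_treatments": int(k),
    }
    return mods


def _moderator_shift(mods, effects: dict) -> float:
    """Sum of configured moderator effects for one study.

    Keys: ``"column:level"`` adds an offset when the study's categorical
    column equals the level; a bare column name multiplies the numeric
    moderator value by the slope (missing values contribute nothing).
    """
    shift = 0.0
    for key, val in effects.items():
        if ":" in key:
            col, level = key.split(":", 1)
            if str(mods.get(col)) == level:
                shift += val
        else:
            x = mods.get(key)
            if x is not None and np.isfinite(x):
                shift += val * float(x)
    return shift


def _contrast(rng, k):
    """A standardized treatment contrast: zero mean, unit sample SD."""
    for _ in range(_MAX_TRIES):
        c = rng.standard_normal(k)
        c = c - c.mean()
        s = c.std(ddof=1)
        if s > 0:
            return c / s
    raise RuntimeError("degenerate contrast draws")


def _cell_means(rng, k, grand_mean, theta, contrast=None):
    """k treatment means with grand mean ``grand_mean`` and sample CV
    exactly ``theta`` (all means positive; rejection on sign).

    ``contrast`` carries the persistent treatment pattern of a litter's
    trajectory; a fresh one is drawn if it yields a negative mean.
    """
    if contrast is not None:
        m = grand_mean * (1.0 + theta * contrast)
        if np.all(m > 0):
            return m
    for _ in range(_MAX_TRIES):
        c = _contrast(rng, k)
        m = grand_mean * (1.0 + theta * c)
        if np.all(m > 0):
            return m
    raise RuntimeError("could not construct positive treatment means")


def simulate_meta_dataset(
    params: SimulationParams | None = None,
) -> tuple[ExperimentDataset, SyntheticTruth]:
    """Generate one dataset plus its ground truth (deterministic in seed)."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    sum_rows, mod_rows = [], []
    study_effects, cell_cv = {}, {}
    warned_negative = False

    for i in range(params.n_studies):
        study_id = f"S{i + 1:03d}"
        k = int(rng.integers(params.treatments_per_study[0], params.treatments_per_study[1] + 1))
        # most compiled studies use a single litter type; only a minority
        # cross litter chemistry with inoculum treatments
        lit_lo, lit_hi = params.litters_per_study
        if lit_lo == 1 and lit_hi > 1 and rng.random() >= params.prop_multilitter:
            n_lit = 1
        else:
            n_lit = int(rng.integers(max(lit_lo, min(2, lit_hi)), lit_hi + 1))
        n_time = int(rng.integers(params.timepoints_per_study[0], params.timepoints_per_study[1] + 1))
        response = "co2_cum_mg_per_g" if rng.random() < params.prop_co2 else "mass_loss_pct"
        grand = params.grand_mean_co2 if response == "co2_cum_mg_per_g" else params.grand_mean_ml
        mods = _draw_moderators(rng, study_id, k, params)
        mod_rows.append(mods)
        shift = _moderator_shift(mods, params.moderator_effects)

        u_i = rng.normal(0.0, params.tau_between) if params.tau_between > 0 else 0.0
        study_effects[study_id] = float(u_i)
        times = np.sort(rng.choice(np.arange(14, 541), size=n_time, replace=False)).astype(float)
        treatments = [f"T{j + 1}" for j in range(k)]

        for lit in range(n_lit):
            litter_id = f"L{lit + 1}"
            # litter chemistry shifts the decay level of the whole litter
            # type; treatment rank order persists across its time points
            mult = 1.0
            if params.litter_effect_cv > 0:
                for _ in range(_MAX_TRIES):
                    mult = 1.0 + rng.normal(0.0, params.litter_effect_cv)
                    if mult >= 0.2:
                        break
                else:
                    mult = 0.2
            grand_l = grand * mult
            base_contrast = _contrast(rng, k)
            for t in times:
                theta = np.nan
                for _ in range(_MAX_TRIES):
                    w_ij = rng.normal(0.0, params.tau_within) if params.tau_within > 0 else 0.0
                    theta = params.true_mean_cv + u_i + w_ij + shift
                    if theta >= _THETA_MIN:
                        break
                else:
                    if not warned_negative:
                        warnings.warn(
                            "true cell CVs repeatedly non-positive; clamping at "
                            f"{_THETA_MIN}", stacklevel=2,
                        )
                        warned_negative = True
                    theta = _THETA_MIN
                cell_cv[f"{study_id}|{litter_id}|{t:g}|{response}"] = float(theta)
                m = _cell_means(rng, k, grand_l, theta, base_contrast)
                for trt, m_t in zip(treatments, m):
                    n = int(rng.integers(params.replicate_n[0], params.replicate_n[1] + 1))
                    sigma = params.replicate_noise_sd
                    if sigma > 0:
                        for _ in range(_MAX_TRIES):
                            m_hat = rng.normal(m_t, sigma / np.sqrt(n))
                            if m_hat > 0 and (
                                response != "mass_loss_pct" or m_hat <= 100
                            ):
                                break
                        else:
                            m_hat = m_t
                        sd_hat = (
                            sigma * np.sqrt(rng.chisquare(n - 1) / (n - 1))
                            if n > 1
                            else 0.0
                        )
                    else:
                        m_hat, sd_hat = m_t, 0.0
                    sum_rows.append(
                        {
                            "study_id": study_id,
                            "litter_id": litter_id,
                            "time_days": float(t),
                            "treatment_id": trt,
                            "response_type": response,
                            "mean": float(m_hat),
                            "sd": float(sd_hat),
                            "n": n,
                        }
                    )

    dataset = ExperimentDataset.from_frames(
        pd.DataFrame(sum_rows), pd.DataFrame(mod_rows)
    )
    truth = SyntheticTruth(
        params=params,
        mu=params.true_mean_cv,
        tau_between=params.tau_between,
        tau_within=params.tau_within,
        study_effects=study_effects,
        cell_cv=cell_cv,
        moderator_effects=dict(params.moderator_effects),
    )
    return dataset, truth


def simulate_structure_function_pair(
    n_treatments: int,
    coupling: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    base_mass_loss: float = 25.0,
    effect_scale: float = 5.0,
):
    """One study's ordination scores and matched mass-loss values.

    A latent axis t drives decay: mass loss = base + effect_scale *
    (coupling * t + noise_sd * eps).  Ordination scores put t on axis 1;
    the variance of axis 2 (community variation orthogonal to function)
    shrinks as the coupling rises, so at coupling 1 with zero noise the
    two distance matrices are proportional and Mantel r = 1.

    Returns (scores DataFrame, mass-loss Series indexed by treatment,
    truth dict).
    """
    if n_treatments < 3:
        raise ValueError("need >= 3 treatments for a Mantel-testable study")
    if not (0.0 <= coupling <= 1.0):
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    treatments = [f"T{j + 1}" for j in range(n_treatments)]
    t = rng.standard_normal(n_treatments)
    axis2 = rng.standard_normal(n_treatments) * (1.0 - coupling)
    eps = rng.standard_normal(n_treatments)
    ml = base_mass_loss + effect_scale * (coupling * t + noise_sd * eps)
    ml = np.clip(ml, 0.0, 100.0)
    scores = pd.DataFrame(
        {
            "study_id": "SYN",
            "community_type": "bacteria",
            "treatment_id": treatments,
            "axis1": t,
            "axis2": axis2,
        }
    )
    truth = {"coupling": coupling, "noise_sd": noise_sd, "seed": seed}
    return scores, pd.Series(ml, index=treatments, name="mass_loss"), truth
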