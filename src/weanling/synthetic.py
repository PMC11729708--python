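"""Synthetic dentine cohorts with known weaning ground truth.

The generator emulates the canonical first-molar isotopic life history: an
elevated-delta15N nursing plateau (milk is trophically enriched over the
maternal diet), a linear decline beginning when complementary foods are
introduced, and a post-weaning plateau from the age at which breastfeeding
ceased.  delta13C co-varies with the same schedule at reduced amplitude,
reflecting that the weaning signal is primarily a nitrogen one.  Each
simulated increment records the exact average of the latent trajectory over
its age span (tooth growth is nonuniform, so equal dentine slices cover
unequal age spans) plus independent Gaussian measurement noise.

Every generating parameter travels alongside the data as a
:class:`SyntheticTruth`, so each pipeline stage can be scored against the
values that produced its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tooth_time import GrowthModel, default_growth

__all__ = [
    "SyntheticTruth",
    "latent_trajectory",
    "trajectory_mean",
    "generate_individual",
    "generate_cohort",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters for one synthetic individual.

    Units: ages in years, isotope values and noise in per-mil.
    ``nursing_enrichment`` is the delta15N elevation of the nursing plateau
    over the post-weaning baseline; delta13C uses the same schedule scaled
    by ``d13C_scale``.  ``degrade`` marks a fraction of increments with
    failing collagen chemistry (C:N and %N outside the acceptance window)
    to emulate a poorly preserved individual.
    """

    cessation_age: float = 2.0
    weaning_onset: float = 0.5
    nursing_enrichment: float = 2.5
    post_weaning_d15N: float = 9.0
    post_weaning_d13C: float = -20.0
    noise_sd: float = 0.15
    n_increments: int = 14
    growth: GrowthModel = field(default_factory=default_growth)
    seed: int = 0
    d13C_scale: float = 0.4
    tooth_length_mm: float = 16.0
    degrade: bool = False
    degrade_fraction: float = 0.6

    def __post_init__(self):
        if not self.weaning_onset < self.cessation_age:
            raise ValueError("weaning_onset must be < cessation_age")
        if self.nursing_enrichment <= 0:
            raise ValueError("nursing_enrichment must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_increments < 2:
            raise ValueError("need at least 2 increments")


def _enrichment_at(truth: SyntheticTruth, age: np.ndarray) -> np.ndarray:
    """Unit nursing signal: 1 on the plateau, linear decline, 0 after."""
    rise = (truth.cessation_age - age) / (truth.cessation_age - truth.weaning_onset)
    return np.clip(rise, 0.0, 1.0)


def latent_trajectory(truth: SyntheticTruth, age):
    """Noise-free (delta15N, delta13C) at given age(s) in years.

    Plateau at baseline + enrichment until ``weaning_onset``, linear
    decline to the baseline at ``cessation_age``, baseline afterwards.
    """
    age = np.asarray(age, dtype=float)
    lo, hi = truth.growth.age_min, truth.growth.age_max
    if np.any(age < lo - 1e-9) or np.any(age > hi + 1e-9):
        raise ValueError(f"age outside [{lo}, {hi}]")
    u = _enrichment_at(truth, age)
    d15N = truth.post_weaning_d15N + truth.nursing_enrichment * u
    d13C = truth.post_weaning_d13C + truth.d13C_scale * truth.nursing_enrichment * u
    if age.ndim == 0:
        return float(d15N), float(d13C)
    return d15N, d13C


def trajectory_mean(truth: SyntheticTruth, age_start: float, age_end: float):
    """Exact average of the latent trajectory over [age_start, age_end).

    The trajectory is piecewise linear with breakpoints at the weaning
    onset and cessation ages, so the average is computed analytically
    segment by segment.
    """
    a, b = float(age_start), float(age_end)
    if b <= a:
        raise ValueError("age_end must be > age_start")
    cuts = np.unique(
        np.clip(np.array([a, truth.weaning_onset, truth.cessation_age, b]), a, b)
    )
    integral = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        mid_u = _enrichment_at(truth, np.array([(lo + hi) / 2]))[0]
        integral += mid_u * (hi - lo)
    u_mean = integral / (b - a)
    d15N = truth.post_weaning_d15N + truth.nursing_enrichment * u_mean
    d13C = truth.post_weaning_d13C + truth.d13C_scale * truth.nursing_enrichment * u_mean
    return d15N, d13C


def generate_individual(
    truth: SyntheticTruth,
    individual_id: str = "SYN1",
    site: str = "synthetic",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate one individual's increment table.

    Increments tile the tooth in equal dentine slices; each measurement is
    the exact latent average over the increment's age span plus
    Normal(0, noise_sd) noise.  Collagen chemistry is drawn inside the
    quality-control acceptance window unless ``degrade`` is set, in which
    case ``degrade_fraction`` of increments (root-end first) fail it.
    Identical truth (including seed) gives identical output.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_increments
    width = truth.tooth_length_mm / n
    start_mm = width * np.arange(n)
    end_mm = start_mm + width
    rel = np.column_stack([start_mm, end_mm]) / truth.tooth_length_mm
    ages = truth.growth.age_at(rel)

    d15N = np.empty(n)
    d13C = np.empty(n)
    for i in range(n):
        d15N[i], d13C[i] = trajectory_mean(truth, ages[i, 0], ages[i, 1])
    d15N = d15N + truth.noise_sd * rng.standard_normal(n)
    d13C = d13C + truth.noise_sd * truth.d13C_scale * rng.standard_normal(n)

    # Chemistry inside the acceptance window by construction: draw target
    # atomic C:N and %N, then derive %C.
    cn = rng.uniform(3.1, 3.4, size=n)
    pct_N = np.clip(rng.normal(15.0, 0.8, size=n), 13.0, 17.0)
    n_bad = 0
    if truth.degrade:
        n_bad = int(np.ceil(truth.degrade_fraction * n))
        cn[n - n_bad :] = rng.uniform(4.0, 6.0, size=n_bad)
        pct_N[n - n_bad :] = rng.uniform(1.0, 4.0, size=n_bad)
    pct_C = cn * pct_N * 12.011 / 14.007

    df = pd.DataFrame(
        {
            "individual_id": individual_id,
            "site": site,
            "tooth": "M1",
            "increment_index": np.arange(1, n + 1),
            "position_start_mm": start_mm,
            "position_end_mm": end_mm,
            "d13C": np.clip(d13C, -40.0, 0.0),
            "d15N": np.clip(d15N, 0.0, 30.0),
            "pct_C": pct_C,
            "pct_N": pct_N,
        }
    )
    return df, truth


def generate_cohort(
    site_config: dict,
    seed: int,
    base_truth: SyntheticTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-site cohort with per-site cessation distributions.

    ``site_config`` maps site name to a dict with keys ``mu_cessation``
    (years), ``sd_cessation`` (years), ``n`` (individuals), and optionally
    ``n_degraded`` (individuals generated with failing chemistry).  Per-
    individual cessation ages are drawn Normal(mu, sd) truncated to
    [1, 6] years.  Returns the stacked increment table and a truth table
    with one row per individual.
    """
    base = base_truth or SyntheticTruth()
    rng = np.random.default_rng(seed)
    frames, truths = [], []
    for site, cfg in site_config.items():
        n = int(cfg["n"])
        n_deg = int(cfg.get("n_degraded", 0))
        mu, sd = float(cfg["mu_cessation"]), float(cfg["sd_cessation"])
        for k in range(n):
            while True:
                t_w = rng.normal(mu, sd)
                if 1.0 <= t_w <= 6.0:
                    break
            ind_seed = int(rng.integers(0, 2**31 - 1))
            truth = replace(
                base,
                cessation_age=float(t_w),
                seed=ind_seed,
                degrade=k < n_deg,
            )
            ind_id = f"{site}_{k + 1:02d}"
            df, _ = generate_individual(truth, individual_id=ind_id, site=site)
            frames.append(df)
            truths.append(
                {
                    "individual_id": ind_id,
                    "site": site,
                    "cessation_age": truth.cessation_age,
                    "weaning_onset": truth.weaning_onset,
                    "nursing_enrichment": truth.nursing_enrichment,
                    "post_weaning_d15N": truth.post_weaning_d15N,
                    "post_weaning_d13C": truth.post_weaning_d13C,
                    "noise_sd": truth.noise_sd,
                    "n_increments": truth.n_increments,
                    "seed": truth.seed,
                    "degrade": truth.degrade,
                }
            )
    if frames:
        cohort = pd.concat(frames, ignore_index=True)
    else:
        cohort = generate_individual(base)[0].iloc[0:0]
    return cohort, pd.DataFrame(
        truths,
        columns=[
            "individual_id",
            "site",
            "cessation_age",
            "weaning_onset",
            "nursing_enrichment",
            "post_weaning_d15N",
            "post_weaning_d13C",
            "noise_sd",
            "n_increments",
            "seed",
            "degrade",
        ],
    )
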