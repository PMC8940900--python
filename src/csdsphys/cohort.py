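"""Synthetic cohort generator with retained ground truth.

The generator emulates the population structure of a chronic social
defeat stress (CSDS) study: a stress-naive control group (CTL) and a
stressed group that splits into resilient (A, anxiety-only) and
susceptible (AD, anxiety + depressive-like) phenotypes.

The latent structure is deliberately simple and fully documented:

* a latent anxiety trait ``a_i`` is drawn per mouse from a Beta
  distribution; stressed mice receive an additive shift, and the trait is
  clipped to [0, 1];
* elevated-plus-maze open-arm occupancy decreases linearly in the trait;
* dopamine-neuron firing decreases linearly in the same trait — hence
  firing and open-arm time covary positively through the shared trait;
* the social-interaction (SI) ratio is drawn *independently* of the
  trait: a bimodal mixture for stressed mice (susceptible mean below the
  100% cut, resilient above) and a high mean for CTL.  This implements
  the study's central dissociation: circuit activity tracks anxiety-like
  behavior but not social avoidance.

All randomness flows from ``CohortConfig.seed`` through a
``numpy.random.SeedSequence`` splitting scheme (see :func:`mouse_seeds`),
so each mouse's downstream simulations are independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import MouseRecord

__all__ = ["CohortConfig", "CohortGroundTruth", "gen_cohort", "mouse_seeds"]

SENSORS = ("GCaMP6s", "GCaMP6f")

# calcium-indicator kernel time constants (rise, decay), seconds; typical
# literature values for the slow and fast GCaMP6 variants
SENSOR_KERNELS = {"GCaMP6s": (0.18, 1.4), "GCaMP6f": (0.05, 0.40)}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generative parameters.

    Defaults mirror a typical defeat cohort: 28 CTL and 60 stressed mice
    with roughly 60% of the stressed mice susceptible (the usual
    susceptible share in this paradigm), baseline
    dopamine-neuron firing near 4 Hz in controls with a trait-driven
    depression in stressed mice, and photometry transient rates of a few
    events per minute raised on open-arm occupancy.
    """

    n_ctl: int = 28
    n_stressed: int = 60
    p_susceptible: float = 0.6
    trait_alpha: float = 2.0
    trait_beta: float = 4.0
    stress_trait_shift: float = 0.25
    firing_base_hz: float = 5.0
    firing_slope_hz: float = 3.0
    firing_noise_hz: float = 0.4
    transient_base_per_min: float = 6.0
    transient_openarm_gain: float = 4.0
    si_mean_susceptible: float = 60.0
    si_mean_resilient: float = 140.0
    si_mean_ctl: float = 140.0
    si_sd: float = 22.0
    openarm_max_frac: float = 0.45
    openarm_slope: float = 0.40
    openarm_noise: float = 0.03
    sensor: str = "GCaMP6s"
    seed: int = 0

    def validate(self) -> None:
        numeric = {k: v for k, v in asdict(self).items() if k != "sensor"}
        for k, v in numeric.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite config value {k}={v}")
        if self.n_ctl < 0 or self.n_stressed < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.p_susceptible <= 1.0:
            raise ValueError("p_susceptible must be in [0, 1]")
        if self.trait_alpha <= 0 or self.trait_beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.firing_base_hz <= 0:
            raise ValueError("firing_base_hz must be positive")
        if self.sensor not in SENSORS:
            raise ValueError(f"sensor must be one of {SENSORS}")


@dataclass
class CohortGroundTruth:
    """Latent per-mouse parameters retained for recovery tests.

    The analysis stages never read this object (enforced by the test
    suite): it exists so tests can compare extracted quantities with what
    was programmed.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def programmed_firing_depression_hz(self) -> float:
        """Mean true CTL firing minus mean true stressed firing."""
        t = self.table
        if t.empty or not t["stressed"].any() or t["stressed"].all():
            raise ValueError("need both stressed and control mice")
        return float(
            t.loc[~t["stressed"], "firing_hz"].mean()
            - t.loc[t["stressed"], "firing_hz"].mean()
        )


def mouse_seeds(seed: int, n: int, stage: str) -> list[np.random.SeedSequence]:
    """Per-mouse seed sequences for one simulation stage.

    The master seed spawns one child per named stage (hashed into the
    spawn key), and each stage child spawns one sequence per mouse, so a
    stage can be re-simulated for one mouse without touching the others.
    """
    stage_key = zlib.crc32(stage.encode("utf-8")) % (2**31)
    root = np.random.SeedSequence([int(seed) % (2**31), stage_key])
    return root.spawn(n)


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def gen_cohort(config: CohortConfig) -> tuple[list[MouseRecord], CohortGroundTruth]:
    """Draw a cohort of mouse stubs plus its latent ground truth.

    Deterministic given ``config.seed``.  Returns mouse records carrying
    only identity and stress status (behavior/physiology are simulated by
    the other generator stages from the ground-truth row), and the
    ground-truth table with columns ``mouse_id, stressed, susceptible,
    trait, si_mean, firing_hz, openarm_frac, transient_base_per_min,
    transient_openarm_gain, sensor``.
    """
    config.validate()
    n = config.n_ctl + config.n_stressed
    if n == 0:
        return [], CohortGroundTruth(
            pd.DataFrame(
                columns=[
                    "mouse_id",
                    "stressed",
                    "susceptible",
                    "trait",
                    "si_mean",
                    "firing_hz",
                    "openarm_frac",
                    "transient_base_per_min",
                    "transient_openarm_gain",
                    "sensor",
                ]
            )
        )

    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), 0])
    )
    stressed = np.concatenate(
        [np.zeros(config.n_ctl, dtype=bool), np.ones(config.n_stressed, dtype=bool)]
    )

    trait = rng.beta(config.trait_alpha, config.trait_beta, size=n)
    trait = _clip01(trait + config.stress_trait_shift * stressed)

    susceptible = stressed & (rng.random(n) < config.p_susceptible)

    si_mean = np.where(
        ~stressed,
        config.si_mean_ctl,
        np.where(susceptible, config.si_mean_susceptible, config.si_mean_resilient),
    ) + config.si_sd * rng.standard_normal(n)
    # the true phenotype means respect the 100% classification boundary:
    # susceptible mice sit strictly below it, the rest at or above
    si_mean = np.where(susceptible, np.clip(si_mean, 5.0, 95.0),
                       np.clip(si_mean, 105.0, 300.0))

    firing = (
        config.firing_base_hz
        - config.firing_slope_hz * trait
        + config.firing_noise_hz * rng.standard_normal(n)
    )
    firing = np.clip(firing, 0.5, 12.0)

    openarm = (
        config.openarm_max_frac
        - config.openarm_slope * trait
        + config.openarm_noise * rng.standard_normal(n)
    )
    openarm = np.clip(openarm, 0.02, 0.60)

    ids = [f"m{i:03d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "mouse_id": ids,
            "stressed": stressed,
            "susceptible": susceptible,
            "trait": trait,
            "si_mean": si_mean,
            "firing_hz": firing,
            "openarm_frac": openarm,
            "transient_base_per_min": config.transient_base_per_min,
            "transient_openarm_gain": config.transient_openarm_gain,
            "sensor": config.sensor,
        }
    )
    mice = [MouseRecord(mouse_id=i, stressed=bool(s)) for i, s in zip(ids, stressed)]
    return mice, CohortGroundTruth(table)
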