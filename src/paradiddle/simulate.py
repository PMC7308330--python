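"""Synthetic drummers and synthetic cohorts.

Two generators make the whole pipeline exercisable without any recorded
data:

* :func:`simulate_performance` renders a novice drummer playing an
  assessment pattern: each expected strike is emitted with probability
  ``1 - miss_prob`` at its nominal grid time plus a per-limb systematic lag
  and i.i.d. Gaussian jitter, plus spurious extra hits scattered uniformly
  over the capture window.  Gaussian i.i.d. jitter keeps a closed-form
  completion probability available as an analytic oracle
  (:func:`closed_form_completion_prob`).

* :func:`simulate_cohort` draws a two-group (drum / control) pre/post table
  of brain measures and drum scores with configurable group-by-time effects.
  Lobular volumes share a latent per-subject scale factor, so total
  cerebellar volume carries real between-subject structure for the TCV
  residualization to remove.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .events import CaptureWindow, DrumEvent
from .scoring import PatternTemplate, build_grid

__all__ = [
    "DrummerParams",
    "CohortParams",
    "simulate_performance",
    "simulate_cohort",
    "closed_form_completion_prob",
    "DEFAULT_BASELINE_MEANS",
]

ALL_LIMBS = ("RH", "LH", "RF", "LF")


@dataclass(frozen=True)
class DrummerParams:
    """Timing model of one (novice) drummer.

    ``jitter_sd_ms`` and ``lag_ms`` may be a scalar (all limbs) or a
    per-limb mapping.  ``learning_gain`` multiplies jitter and miss
    probability at the post-training assessment (1.0 = no learning; 0.5 =
    half the jitter and half the misses after training).
    """

    jitter_sd_ms: float | Mapping[str, float] = 60.0
    lag_ms: float | Mapping[str, float] = 0.0
    miss_prob: float = 0.05
    extra_rate: float = 0.2  # spurious strikes per bar (Poisson mean)
    learning_gain: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must be in [0, 1]")
        if not 0.0 < self.learning_gain <= 1.0:
            raise ValueError("learning_gain must be in (0, 1]")
        if self.extra_rate < 0:
            raise ValueError("extra_rate must be >= 0")
        for limb in ALL_LIMBS:
            if self.jitter(limb) < 0:
                raise ValueError("jitter_sd_ms must be >= 0")

    def jitter(self, limb: str) -> float:
        if isinstance(self.jitter_sd_ms, Mapping):
            return float(self.jitter_sd_ms.get(limb, 0.0))
        return float(self.jitter_sd_ms)

    def lag(self, limb: str) -> float:
        if isinstance(self.lag_ms, Mapping):
            return float(self.lag_ms.get(limb, 0.0))
        return float(self.lag_ms)

    def after_training(self) -> "DrummerParams":
        """The same drummer at the post assessment: jitter and misses shrunk."""
        g = self.learning_gain
        jitter = ({k: v * g for k, v in self.jitter_sd_ms.items()}
                  if isinstance(self.jitter_sd_ms, Mapping) else self.jitter_sd_ms * g)
        return replace(self, jitter_sd_ms=jitter, miss_prob=self.miss_prob * g,
                       seed=self.seed + 1)


def simulate_performance(template: PatternTemplate, window: CaptureWindow,
                         params: DrummerParams,
                         song_offset_ms: float = 0.0,
                         rng: Optional[np.random.Generator] = None) -> list[DrumEvent]:
    """Render one performance as a sorted drum-event stream."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    grid = build_grid(template, window, song_offset_ms)

    instrument_limb = {}
    for slot in grid.slots:
        for limb, instrument in slot.expected:
            instrument_limb[instrument] = limb
    kit = sorted(instrument_limb)

    events = []
    for slot in grid.slots:
        for limb, instrument in sorted(slot.expected):
            if rng.random() < params.miss_prob:
                continue
            onset = slot.nominal_ms + params.lag(limb)
            sd = params.jitter(limb)
            if sd > 0:
                onset += rng.normal(0.0, sd)
            events.append(DrumEvent(max(onset, 0.0), instrument, limb,
                                    int(rng.integers(60, 112))))
    n_extra = rng.poisson(params.extra_rate * grid.n_bars)
    for _ in range(n_extra):
        onset = rng.uniform(window.start_ms, window.end_ms)
        instrument = kit[rng.integers(len(kit))]
        events.append(DrumEvent(onset, instrument, instrument_limb[instrument],
                                int(rng.integers(60, 112))))
    events.sort(key=lambda e: (e.onset_ms, e.instrument))
    return events


def closed_form_completion_prob(jitter_sd: float, miss_prob: float,
                                tolerance_ms: float, strikes_per_bar: int) -> float:
    """P(bar completed) under i.i.d. Gaussian jitter and independent misses.

    Each of the k strikes is present with probability (1 - m) and lands
    within tolerance with probability 2*Phi(tol/sigma) - 1, so
    P = [(1 - m) * (2*Phi(tol/sigma) - 1)]^k (the Gaussian factor is 1 at
    sigma = 0).
    """
    if jitter_sd < 0 or not 0 <= miss_prob <= 1 or tolerance_ms < 0 or strikes_per_bar < 1:
        raise ValueError("invalid parameters for completion probability")
    gauss = 1.0 if jitter_sd == 0 else 2.0 * norm.cdf(tolerance_ms / jitter_sd) - 1.0
    return float(((1.0 - miss_prob) * gauss) ** strikes_per_bar)


# --------------------------------------------------------------------------
# Cohort generator
# --------------------------------------------------------------------------

# Baseline means on the scales the derived tables use.  The four lobular
# volumes, four diffusion and four thickness entries follow the printed
# baseline columns of the study cohort; the remaining lobules are set to
# atlas-plausible proportions on the same scale so TCV has realistic
# composition.  Volumes as tabulated; FA unitless; MD x 1e-3 mm^2/s;
# thickness in mm; drum scores in % and ms.
DEFAULT_BASELINE_MEANS: dict[str, float] = {
    # cerebellar lobular volumes
    "vol_left_i_iv": 3000.0, "vol_right_i_iv": 3000.0,
    "vol_left_v": 4500.0, "vol_right_v": 4500.0,
    "vol_left_vi": 8500.0, "vol_right_vi": 8500.0,
    "vol_left_crus_i": 12000.0, "vol_right_crus_i": 12000.0,
    "vol_left_crus_ii": 8500.0, "vol_right_crus_ii": 8500.0,
    "vol_left_viib": 4500.0, "vol_right_viib": 4500.0,
    "vol_left_viiia": 5555.0, "vol_right_viiia": 5555.0,
    "vol_left_viiib": 4534.0, "vol_right_viiib": 4662.0,
    "vol_left_ix": 3500.0, "vol_right_ix": 3500.0,
    "vol_left_x": 600.0, "vol_right_x": 600.0,
    "vol_vermis_crus_i": 24.0,
    # peduncle diffusion
    "fa_left_icp": 0.564, "fa_right_icp": 0.578,
    "fa_left_scp": 0.550, "fa_right_scp": 0.550, "fa_mcp": 0.600,
    "md_left_icp": 0.720, "md_right_icp": 0.710,
    "md_left_scp": 0.730, "md_right_scp": 0.730, "md_mcp": 0.720,
    # cortical thickness (mm)
    "thick_lparc": 2.425, "thick_lsfg": 2.835,
    "thick_rpcun": 2.590, "thick_rsfg": 2.710,
    # drum scores
    "score_pct_bars_quarter": 15.0, "score_pct_bars_eighth": 10.0,
    "score_hrs_ms": 80.0,
}


@dataclass(frozen=True)
class CohortParams:
    """Two-group pre/post cohort with configurable group-by-time effects.

    ``group_time_effects`` maps a measure column to the additive change (in
    the measure's units) applied to the drum group at T2 only.  Between- and
    within-subject spreads are relative (coefficients of variation), since
    the default measures span four orders of magnitude.
    """

    n_per_group: tuple[int, int] = (15, 16)  # (drum, control)
    group_time_effects: Mapping[str, float] = field(default_factory=dict)
    between_subject_sd: float = 0.08   # relative, between subjects
    within_subject_sd: float = 0.02    # relative, between timepoints
    baseline_means: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_MEANS))
    sex_ratio: float = 0.5             # proportion female
    age_range: tuple[float, float] = (16.0, 19.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_group) < 2:
            raise ValueError("need n_per_group >= 2 in each group")
        if self.between_subject_sd <= 0 or self.within_subject_sd <= 0:
            raise ValueError("subject SDs must be > 0")
        unknown = set(self.group_time_effects) - set(self.baseline_means)
        if unknown:
            raise ValueError(f"effects on unknown measure(s): {sorted(unknown)}")


def simulate_cohort(params: CohortParams) -> pd.DataFrame:
    """Draw a tidy subject x timepoint measure table.

    Volumes: v = baseline * s_subject * (1 + within * z_t) + effect, where the
    latent scale s_subject ~ N(1, between) is shared by all lobules of a
    subject (it *is* the subject's overall cerebellar size, so summed TCV
    correlates with every lobule).  Other measures get independent
    between-subject effects: v = baseline * (1 + between*u + within*z_t) + effect.
    Sexes are assigned deterministically by ``sex_ratio`` (drum 15 / control 16
    at the 0.5 default gives 7/8 and 8/8 male/female).
    """
    rng = np.random.default_rng(params.seed)
    n_drum, n_control = params.n_per_group
    measures = list(params.baseline_means)
    vol_cols = [m for m in measures if m.startswith("vol_")]
    other_cols = [m for m in measures if not m.startswith("vol_")]

    rows = []
    for group, n in (("drum", n_drum), ("control", n_control)):
        n_female = round(n * params.sex_ratio)
        for i in range(n):
            subject_id = f"{group[0].upper()}{i + 1:02d}"
            sex = "male" if i < n - n_female else "female"
            age = float(rng.uniform(*params.age_range))
            scale = max(1.0 + params.between_subject_sd * rng.standard_normal(), 0.2)
            subj_dev = {m: params.between_subject_sd * rng.standard_normal()
                        for m in other_cols}
            for timepoint in ("T1", "T2"):
                treated = group == "drum" and timepoint == "T2"
                row = {"subject_id": subject_id, "group": group, "sex": sex,
                       "age": age, "timepoint": timepoint}
                for m in vol_cols:
                    base = params.baseline_means[m]
                    value = base * scale * (1.0 + params.within_subject_sd
                                            * rng.standard_normal())
                    if treated:
                        value += params.group_time_effects.get(m, 0.0)
                    row[m] = value
                for m in other_cols:
                    base = params.baseline_means[m]
                    value = base * (1.0 + subj_dev[m] + params.within_subject_sd
                                    * rng.standard_normal())
                    if treated:
                        value += params.group_time_effects.get(m, 0.0)
                    row[m] = value
                rows.append(row)
    return pd.DataFrame(rows)
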